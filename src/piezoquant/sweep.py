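"""The universal electrophysiology record.

A :class:`Sweep` holds one time-aligned current/stimulus pair plus acquisition
metadata.  Whole-cell poking sweeps carry a displacement stimulus in µm;
cell-attached pressure-clamp sweeps carry a pressure stimulus in mmHg.  The
sign convention throughout the package is inward current negative; summaries
report magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import InvalidParameterError


@dataclass
class Sweep:
    """One recording: time (s), current (pA), stimulus (µm or mmHg).

    Parameters
    ----------
    time : ndarray
        Seconds, strictly increasing, uniformly sampled.
    current : ndarray
        Picoamperes, inward negative.
    stimulus : ndarray
        Probe displacement (µm) or pipette pressure (mmHg).
    sampling_rate : float
        kHz.
    holding_potential : float
        mV.
    stimulus_onset_index, stimulus_end_index : int
        Sample indices delimiting the stimulus (onset inclusive, end is the
        last stimulated sample).
    metadata : dict
        Free-form; generators embed their ground-truth parameters here.
    """

    time: np.ndarray
    current: np.ndarray
    stimulus: np.ndarray
    sampling_rate: float
    holding_potential: float
    stimulus_onset_index: int
    stimulus_end_index: int
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        n = self.time.size
        if not (self.current.size == n and self.stimulus.size == n):
            raise InvalidParameterError(
                f"time/current/stimulus lengths differ: {n}, "
                f"{self.current.size}, {self.stimulus.size}"
            )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise InvalidParameterError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
                raise InvalidParameterError("time must be uniformly sampled")
        if not (0 <= self.stimulus_onset_index < self.stimulus_end_index < n):
            raise InvalidParameterError(
                "require 0 <= stimulus_onset_index < stimulus_end_index < n; got "
                f"{self.stimulus_onset_index}, {self.stimulus_end_index}, n={n}"
            )
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive and finite")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / (self.sampling_rate * 1000.0)

    @property
    def n_samples(self) -> int:
        return self.time.size

    def pre_stimulus_slice(self) -> slice:
        """Samples strictly before stimulus onset."""
        return slice(0, self.stimulus_onset_index)

    def copy_with(self, **overrides: Any) -> "Sweep":
        kwargs = dict(
            time=self.time,
            current=self.current,
            stimulus=self.stimulus,
            sampling_rate=self.sampling_rate,
            holding_potential=self.holding_potential,
            stimulus_onset_index=self.stimulus_onset_index,
            stimulus_end_index=self.stimulus_end_index,
            metadata=dict(self.metadata),
        )
        kwargs.update(overrides)
        return Sweep(**kwargs)
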