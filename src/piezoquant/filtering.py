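"""Acquisition-style low-pass filtering.

Recordings are filtered with a 4-pole Bessel-type low-pass applied forward
only, mimicking the analogue filter of a patch-clamp amplifier.  The filter
is magnitude-normalised so the -3 dB point sits at the stated cutoff, and it
is initialised at steady state for the first sample so a constant input is
returned unchanged (DC level conserved exactly).

The Bessel filter delays the signal by an approximately constant group delay;
:func:`characterize_filter_delay` measures it on a unit step (50% crossing)
so that onset-latency estimates can subtract it.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal

from .exceptions import InvalidParameterError

BESSEL_ORDER = 4


@lru_cache(maxsize=32)
def _sos(cutoff_khz: float, sampling_khz: float) -> np.ndarray:
    if not (0 < cutoff_khz < sampling_khz / 2):
        raise InvalidParameterError(
            f"cutoff {cutoff_khz} kHz must lie in (0, Nyquist={sampling_khz / 2} kHz)"
        )
    return signal.bessel(
        BESSEL_ORDER,
        cutoff_khz / (sampling_khz / 2),
        btype="low",
        output="sos",
        norm="mag",
    )


def lowpass(x: np.ndarray, cutoff_khz: float, sampling_khz: float) -> np.ndarray:
    """Forward-only 4-pole Bessel low-pass.

    Initial conditions are set to the steady-state response for ``x[0]`` so
    there is no startup transient on a trace that begins at rest.
    """
    x = np.asarray(x, dtype=float)
    sos = _sos(float(cutoff_khz), float(sampling_khz))
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


@lru_cache(maxsize=32)
def characterize_filter_delay(
    cutoff_khz: float, sampling_khz: float, level: float = 0.5
) -> int:
    """Delay, in samples, for the unit-step response to reach ``level``.

    ``level=0.5`` is the usual group-delay surrogate; onset detection uses a
    small level (the detection bound is a small fraction of the eventual
    current step, so the relevant delay is the departure delay, not the 50%
    crossing).
    """
    if not (0 < level < 1):
        raise InvalidParameterError("level must lie in (0, 1)")
    n = max(64, int(20 * sampling_khz / cutoff_khz))
    step = np.zeros(n)
    step[n // 4 :] = 1.0
    y = lowpass(step, cutoff_khz, sampling_khz)
    crossing = int(np.argmax(y >= level))
    return crossing - n // 4
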