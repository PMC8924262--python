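"""Whole-cell poking-sweep generator.

Emulates the standard mechano-clamp protocol: a blunt probe indents the cell
in a series of 13 ramp-and-hold displacement steps of 0.4 µm increments at a
reference velocity of 1 µm/ms, with currents sampled at 200 kHz and low-pass
filtered at 2.9 kHz, holding potential -60 mV.

The evoked-current model is deliberately simple and fully parameterised so
that every analysis quantity has an exact ground truth:

* the current is leak + noise until the displacement crosses the mechanical
  threshold;
* once above threshold it follows ``i_max * B(d(t)) * V(v)`` where ``B`` is a
  Boltzmann displacement-response and ``V`` a Hill velocity-scaling factor
  normalised to 1 at the 1 µm/ms reference velocity;
* from the end of the ramp it decays single-exponentially with ``tau_inact``;
* the probe retracts at stimulus end and the evoked component vanishes.

The trace is then Bessel low-pass filtered like the acquisition chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..exceptions import InvalidParameterError
from ..filtering import lowpass
from ..sweep import Sweep


@dataclass(frozen=True)
class PokingProtocol:
    """Acquisition protocol for a poking series.

    Units: displacement µm, velocity µm/ms, durations ms, rates kHz, V in mV.
    """

    n_steps: int = 13
    step_increment: float = 0.4
    ramp_speed: float = 1.0
    hold_duration: float = 150.0
    pre_stimulus_duration: float = 50.0
    post_stimulus_duration: float = 20.0
    sampling_rate: float = 200.0
    filter_cutoff: float = 2.9
    holding_potential: float = -60.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.step_increment <= 0:
            raise InvalidParameterError("step_increment must be > 0")
        if self.ramp_speed <= 0:
            raise InvalidParameterError("ramp_speed must be > 0")
        if self.sampling_rate <= 2 * self.filter_cutoff:
            raise InvalidParameterError(
                "sampling_rate must exceed 2 x filter_cutoff"
            )
        for name in ("hold_duration", "pre_stimulus_duration", "post_stimulus_duration"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def displacement_of_step(self, step_index: int) -> float:
        """Target displacement of step ``step_index`` (0-based), µm."""
        return self.step_increment * (step_index + 1)


@dataclass(frozen=True)
class VelocityScaling:
    """Hill velocity dependence ``v^h / (v^h + v_half^h)`` normalised to 1 at
    the 1 µm/ms reference velocity.

    The defaults give V(0.25)/V(1) = 0.40, i.e. currents evoked at
    0.25 µm/ms are ~60% smaller than at the reference velocity, matching the
    velocity sensitivity of PIEZO2.
    """

    v_half: float = 1.0
    hill: float = 1.0
    reference_velocity: float = 1.0

    def __call__(self, velocity: float) -> float:
        if velocity <= 0:
            raise InvalidParameterError("velocity must be > 0")
        raw = velocity**self.hill / (velocity**self.hill + self.v_half**self.hill)
        ref = self.reference_velocity**self.hill / (
            self.reference_velocity**self.hill + self.v_half**self.hill
        )
        return raw / ref

    @classmethod
    def from_ratio(
        cls, test_velocity: float, ratio: float, hill: float = 1.0
    ) -> "VelocityScaling":
        """Solve v_half so that V(test_velocity) = ratio (with V(1) = 1)."""
        from scipy.optimize import brentq

        if not (0 < ratio < 1):
            raise InvalidParameterError("ratio must lie in (0, 1)")

        def f(v_half: float) -> float:
            return cls(v_half=v_half, hill=hill)(test_velocity) - ratio

        v_half = brentq(f, 1e-6, 1e6)
        return cls(v_half=v_half, hill=hill)


@dataclass(frozen=True)
class GatingParams:
    """Ground-truth generative parameters of the poking-current model.

    threshold_displacement (µm) is the mechanical activation threshold;
    i_max (pA, negative = inward) the saturating peak amplitude;
    half_displacement / slope (µm) parameterise the Boltzmann
    displacement-response B(A) = 1 / (1 + exp(-(A - A_half)/k));
    tau_inact (ms) the single-exponential inactivation time constant.
    """

    threshold_displacement: float = 2.0
    i_max: float = -1140.0
    half_displacement: float = 3.2
    slope: float = 0.4
    velocity_scaling: VelocityScaling = field(default_factory=VelocityScaling)
    tau_inact: float = 6.0
    leak: float = -20.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        vals = [
            self.threshold_displacement,
            self.i_max,
            self.half_displacement,
            self.slope,
            self.tau_inact,
            self.leak,
            self.noise_sd,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("all gating parameters must be finite")
        if self.tau_inact <= 0:
            raise InvalidParameterError("tau_inact must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.slope <= 0:
            raise InvalidParameterError("slope must be > 0")

    def displacement_response(self, displacement: float | np.ndarray) -> np.ndarray:
        """Saturating Boltzmann B(A) in (0, 1)."""
        return 1.0 / (
            1.0 + np.exp(-(np.asarray(displacement) - self.half_displacement) / self.slope)
        )

    def to_dict(self) -> dict:
        return {
            "threshold_displacement": self.threshold_displacement,
            "i_max": self.i_max,
            "half_displacement": self.half_displacement,
            "slope": self.slope,
            "velocity_v_half": self.velocity_scaling.v_half,
            "velocity_hill": self.velocity_scaling.hill,
            "tau_inact": self.tau_inact,
            "leak": self.leak,
            "noise_sd": self.noise_sd,
        }


def _displacement_trace(
    protocol: PokingProtocol, amplitude: float, n: int, onset: int
) -> tuple[np.ndarray, int]:
    """Ramp-and-hold displacement; returns (trace µm, index of ramp end)."""
    fs_per_ms = protocol.sampling_rate  # samples per ms
    ramp_samples = max(1, int(round(amplitude / protocol.ramp_speed * fs_per_ms)))
    hold_samples = int(round(protocol.hold_duration * fs_per_ms))
    d = np.zeros(n)
    ramp_end = onset + ramp_samples
    d[onset:ramp_end] = np.linspace(0.0, amplitude, ramp_samples, endpoint=False) + (
        amplitude / ramp_samples
    )
    stim_end = min(ramp_end + hold_samples, n - 1)
    d[ramp_end:stim_end] = amplitude
    # probe retracts at the same speed after the hold
    retract_end = min(stim_end + ramp_samples, n)
    k = retract_end - stim_end
    if k > 0:
        d[stim_end:retract_end] = amplitude * (1.0 - np.arange(1, k + 1) / ramp_samples).clip(0)
    return d, ramp_end


def simulate_poking_sweep(
    protocol: PokingProtocol,
    gating: GatingParams,
    step_index: int,
    seed: int | np.random.Generator = 0,
    velocity: float | None = None,
) -> Sweep:
    """Simulate one ramp-and-hold indentation sweep.

    Parameters
    ----------
    step_index : int
        0-based step of the series; target displacement is
        ``step_increment * (step_index + 1)``.
    velocity : float, optional
        Ramp speed in µm/ms; defaults to the protocol's ``ramp_speed``.

    Returns
    -------
    Sweep
        Stimulus trace is the displacement (µm); metadata carries the full
        ground truth under ``"ground_truth"``.
    """
    if step_index < 0 or step_index >= protocol.n_steps:
        raise InvalidParameterError(
            f"step_index {step_index} outside 0..{protocol.n_steps - 1}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = protocol.ramp_speed if velocity is None else float(velocity)
    if v <= 0 or not math.isfinite(v):
        raise InvalidParameterError("velocity must be positive and finite")

    amplitude = protocol.displacement_of_step(step_index)
    fs_per_ms = protocol.sampling_rate
    onset = int(round(protocol.pre_stimulus_duration * fs_per_ms))
    ramp_samples = max(1, int(round(amplitude / v * fs_per_ms)))
    hold_samples = int(round(protocol.hold_duration * fs_per_ms))
    post_samples = int(round(protocol.post_stimulus_duration * fs_per_ms))
    n = onset + ramp_samples + hold_samples + post_samples

    local = PokingProtocol(
        n_steps=protocol.n_steps,
        step_increment=protocol.step_increment,
        ramp_speed=v,
        hold_duration=protocol.hold_duration,
        pre_stimulus_duration=protocol.pre_stimulus_duration,
        post_stimulus_duration=protocol.post_stimulus_duration,
        sampling_rate=protocol.sampling_rate,
        filter_cutoff=protocol.filter_cutoff,
        holding_potential=protocol.holding_potential,
    )
    d, ramp_end = _displacement_trace(local, amplitude, n, onset)
    stim_end = min(ramp_end + hold_samples, n - 1)

    evoked = np.zeros(n)
    if amplitude >= gating.threshold_displacement:
        vscale = gating.velocity_scaling(v)
        above = np.zeros(n, dtype=bool)
        above[onset:stim_end] = d[onset:stim_end] >= gating.threshold_displacement
        # during the ramp the open fraction tracks the instantaneous displacement
        ramp_part = slice(onset, ramp_end)
        evoked[ramp_part] = np.where(
            above[ramp_part],
            gating.i_max * vscale * gating.displacement_response(d[ramp_part]),
            0.0,
        )
        peak_val = gating.i_max * vscale * gating.displacement_response(amplitude)
        # exponential inactivation during the hold
        t_hold = np.arange(stim_end - ramp_end) / fs_per_ms  # ms
        evoked[ramp_end:stim_end] = peak_val * np.exp(-t_hold / gating.tau_inact)

    current = evoked + gating.leak
    if gating.noise_sd > 0:
        current = current + rng.normal(0.0, gating.noise_sd, size=n)
    current = lowpass(current, protocol.filter_cutoff, protocol.sampling_rate)

    time = np.arange(n) / (protocol.sampling_rate * 1000.0)
    metadata = {
        "ground_truth": gating.to_dict(),
        "protocol": {
            "ramp_speed": v,
            "amplitude": amplitude,
            "step_index": step_index,
            "n_steps": protocol.n_steps,
        },
        "filter_cutoff_khz": protocol.filter_cutoff,
        "ramp_end_index": int(ramp_end),
        "expected_peak_pa": (
            gating.i_max
            * gating.velocity_scaling(v)
            * float(gating.displacement_response(amplitude))
            if amplitude >= gating.threshold_displacement
            else 0.0
        ),
    }
    return Sweep(
        time=time,
        current=current,
        stimulus=d,
        sampling_rate=protocol.sampling_rate,
        holding_potential=protocol.holding_potential,
        stimulus_onset_index=onset,
        stimulus_end_index=int(stim_end),
        metadata=metadata,
    )


def simulate_poking_series(
    protocol: PokingProtocol,
    gating: GatingParams,
    seed: int | np.random.Generator = 0,
) -> list[Sweep]:
    """Simulate the full n-step series (default 13 steps, 0.4 µm increments,
    i.e. displacements 0.4 .. 5.2 µm)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        simulate_poking_sweep(protocol, gating, k, seed=rng)
        for k in range(protocol.n_steps)
    ]
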