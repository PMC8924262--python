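"""Cell-attached pressure-clamp generator with stochastic channel gating.

Emulates single-channel recordings: 3-s negative-pressure steps applied to a
membrane patch clamped at -100 mV, sampled at 50 kHz and low-pass filtered at
2.9 kHz.  Each channel is an independent two-state (closed/open)
continuous-time Markov chain whose stationary open probability follows a
Boltzmann function of pressure and whose mean open dwell time is a parameter.
An open channel passes the Ohmic unitary current
``i = g * (V_hold - E_rev) / 1000`` pA.

The generator books every open interval of every channel, and stores the
event count, total open time and expected charge in the sweep metadata: the
charge-transfer and dwell-time recovery tests read their oracles from there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..exceptions import InvalidParameterError
from ..filtering import lowpass
from ..sweep import Sweep


@dataclass(frozen=True)
class PressureProtocol:
    """Pressure-step protocol; pressures mmHg (<= 0), durations s, rates kHz."""

    pressure_steps: tuple[float, ...] = (-20.0, -40.0, -60.0, -80.0)
    step_duration: float = 3.0
    pre_stimulus_duration: float = 0.5
    post_stimulus_duration: float = 0.25
    holding_potential: float = -100.0
    sampling_rate: float = 50.0
    filter_cutoff: float = 2.9

    def __post_init__(self) -> None:
        if any(p > 0 for p in self.pressure_steps):
            raise InvalidParameterError("pressure steps must be <= 0 mmHg")
        if self.step_duration <= 0:
            raise InvalidParameterError("step_duration must be > 0")
        if self.sampling_rate <= 2 * self.filter_cutoff:
            raise InvalidParameterError("sampling_rate must exceed 2 x filter_cutoff")


@dataclass(frozen=True)
class ChannelParams:
    """Ground-truth single-channel parameters.

    unitary_conductance in pS; p_open_half / p_open_slope (mmHg) parameterise
    P_open(p) = 1 / (1 + exp((p - p_half)/slope)) so that more negative
    pressure increases the open probability; mean_open_dwell in ms.
    """

    unitary_conductance: float = 23.4
    reversal_potential: float = 0.0
    n_channels: int = 3
    p_open_half: float = -40.0
    p_open_slope: float = 8.0
    mean_open_dwell: float = 2.0
    leak: float = -1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.unitary_conductance <= 0:
            raise InvalidParameterError("unitary_conductance must be > 0")
        if self.n_channels < 0:
            raise InvalidParameterError("n_channels must be >= 0")
        if self.mean_open_dwell <= 0:
            raise InvalidParameterError("mean_open_dwell must be > 0")
        if self.p_open_slope <= 0:
            raise InvalidParameterError("p_open_slope must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        vals = [self.unitary_conductance, self.reversal_potential,
                self.p_open_half, self.p_open_slope, self.mean_open_dwell,
                self.leak, self.noise_sd]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("all channel parameters must be finite")

    def p_open(self, pressure: float) -> float:
        """Stationary open probability at ``pressure`` (mmHg, <= 0)."""
        return 1.0 / (1.0 + math.exp((pressure - self.p_open_half) / self.p_open_slope))

    def unitary_current(self, holding_potential: float) -> float:
        """Ohmic single-channel current in pA (signed)."""
        return self.unitary_conductance * (
            holding_potential - self.reversal_potential
        ) / 1000.0

    def to_dict(self) -> dict:
        return {
            "unitary_conductance": self.unitary_conductance,
            "reversal_potential": self.reversal_potential,
            "n_channels": self.n_channels,
            "p_open_half": self.p_open_half,
            "p_open_slope": self.p_open_slope,
            "mean_open_dwell": self.mean_open_dwell,
            "leak": self.leak,
            "noise_sd": self.noise_sd,
        }


def _simulate_channel_open_intervals(
    rng: np.random.Generator,
    duration_s: float,
    p_open: float,
    mean_open_dwell_ms: float,
) -> list[tuple[float, float]]:
    """Gillespie simulation of one two-state channel over [0, duration].

    Returns the list of (t_open, t_close) intervals in seconds.  The closing
    rate is 1/mean_open_dwell and the opening rate is chosen so the
    stationary open probability equals ``p_open``.
    """
    if p_open <= 0:
        return []
    tau_open_s = mean_open_dwell_ms / 1000.0
    k_close = 1.0 / tau_open_s
    if p_open >= 1.0 - 1e-9:  # permanently open within numerical resolution
        return [(0.0, duration_s)]
    k_open = k_close * p_open / (1.0 - p_open)

    intervals: list[tuple[float, float]] = []
    t = 0.0
    state_open = rng.random() < p_open  # start from the stationary law
    while t < duration_s:
        if state_open:
            dwell = rng.exponential(1.0 / k_close)
            intervals.append((t, min(t + dwell, duration_s)))
        else:
            dwell = rng.exponential(1.0 / k_open)
        t += dwell
        state_open = not state_open
    return intervals


def simulate_pressure_sweep(
    protocol: PressureProtocol,
    channels: ChannelParams,
    pressure: float,
    seed: int | np.random.Generator = 0,
) -> Sweep:
    """Simulate one negative-pressure step sweep.

    Channels gate with P_open(pressure) during the stimulus and with
    P_open(0) in the stimulus-free pre/post segments.  ``n_channels = 0``
    yields a baseline-only sweep (leak + noise), which is valid input for
    responder analysis, not an error.
    """
    if pressure > 0:
        raise InvalidParameterError("pressure must be <= 0 mmHg")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    fs_hz = protocol.sampling_rate * 1000.0
    n_pre = int(round(protocol.pre_stimulus_duration * fs_hz))
    n_stim = int(round(protocol.step_duration * fs_hz))
    n_post = int(round(protocol.post_stimulus_duration * fs_hz))
    n = n_pre + n_stim + n_post

    i_unit = channels.unitary_current(protocol.holding_potential)
    open_count = np.zeros(n)
    n_events = 0
    total_open_s = 0.0
    dwell_times_ms: list[float] = []

    segments = [
        (0, n_pre, channels.p_open(0.0)),
        (n_pre, n_pre + n_stim, channels.p_open(pressure)),
        (n_pre + n_stim, n, channels.p_open(0.0)),
    ]
    for _ in range(channels.n_channels):
        for start, stop, p_o in segments:
            dur = (stop - start) / fs_hz
            if dur <= 0:
                continue
            for t0, t1 in _simulate_channel_open_intervals(
                rng, dur, p_o, channels.mean_open_dwell
            ):
                i0 = start + int(round(t0 * fs_hz))
                i1 = start + int(round(t1 * fs_hz))
                open_count[i0:i1] += 1
                if start == n_pre:  # stimulus-window bookkeeping
                    n_events += 1
                    total_open_s += t1 - t0
                    dwell_times_ms.append((t1 - t0) * 1000.0)

    current = open_count * i_unit + channels.leak
    if channels.noise_sd > 0:
        current = current + rng.normal(0.0, channels.noise_sd, size=n)
    current = lowpass(current, protocol.filter_cutoff, protocol.sampling_rate)

    time = np.arange(n) / fs_hz
    stimulus = np.zeros(n)
    stimulus[n_pre : n_pre + n_stim] = pressure
    metadata = {
        "ground_truth": channels.to_dict(),
        "pressure_mmHg": pressure,
        "filter_cutoff_khz": protocol.filter_cutoff,
        "unitary_current_pa": i_unit,
        "p_open": channels.p_open(pressure),
        "n_open_events": n_events,
        "total_open_time_s": total_open_s,
        "open_dwell_times_ms": dwell_times_ms,
        "expected_charge_pc": abs(i_unit) * total_open_s,
    }
    return Sweep(
        time=time,
        current=current,
        stimulus=stimulus,
        sampling_rate=protocol.sampling_rate,
        holding_potential=protocol.holding_potential,
        stimulus_onset_index=n_pre,
        stimulus_end_index=n_pre + n_stim - 1,
        metadata=metadata,
    )
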