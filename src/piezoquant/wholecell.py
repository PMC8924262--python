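"""Whole-cell poking-current quantification.

Implements the analysis chain applied to membrane-indentation ("poking")
recordings: off-line leak subtraction, peak-current extraction, onset
detection with the 6xSD baseline rule and the latency-times-velocity
mechanical threshold, single-exponential inactivation fits
(C1 + C2*exp(-(t - t0)/tau_inact)), displacement-response curves,
velocity-ratio analysis with the coefficient-of-variation stability
exclusion, and reversal-potential estimation from an I/V series.

Baseline statistics are computed over the whole pre-stimulus segment minus
its first 5 ms (settling).  Onset latencies measured on the filtered trace
are corrected by the characterized filter group delay whenever the sweep
metadata records a filter cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateBaselineError,
    InvalidParameterError,
    NoDecayError,
    WindowError,
)
from .filtering import characterize_filter_delay
from .sweep import Sweep

BASELINE_SKIP_MS = 5.0
MIN_BASELINE_MS = 10.0


def _baseline_slice(sweep: Sweep) -> slice:
    skip = int(round(BASELINE_SKIP_MS * sweep.sampling_rate))
    start = min(skip, max(0, sweep.stimulus_onset_index - 1))
    return slice(start, sweep.stimulus_onset_index)


def baseline_stats(sweep: Sweep) -> tuple[float, float]:
    """(mean, sd) of the pre-stimulus baseline (sample sd)."""
    seg = sweep.current[_baseline_slice(sweep)]
    if seg.size < 2:
        raise WindowError("pre-stimulus window too short for baseline statistics")
    return float(seg.mean()), float(seg.std(ddof=1))


def subtract_leak(sweep: Sweep) -> Sweep:
    """Subtract the pre-stimulus leak current (off-line leak subtraction).

    The subtracted constant is the baseline mean; it is recorded in
    ``metadata["leak_subtracted_pa"]``.  The returned sweep's baseline mean
    is zero by construction.
    """
    min_samples = int(round(MIN_BASELINE_MS * sweep.sampling_rate))
    n_baseline = sweep.stimulus_onset_index
    if n_baseline < min_samples:
        raise WindowError(
            f"pre-stimulus window has {n_baseline} samples; "
            f"need >= {min_samples} (10 ms at {sweep.sampling_rate} kHz)"
        )
    offset = float(sweep.current[_baseline_slice(sweep)].mean())
    out = sweep.copy_with(current=sweep.current - offset)
    out.metadata["leak_subtracted_pa"] = offset
    return out


def peak_current(sweep: Sweep, window: tuple[int, int] | None = None) -> float:
    """Signed current at the extremum of largest magnitude inside ``window``.

    ``window`` is a (start, stop) sample range; by default the stimulus
    window extended by 5 ms, which avoids off-stimulus artifacts.
    """
    if window is None:
        pad = int(round(5.0 * sweep.sampling_rate))
        window = (sweep.stimulus_onset_index,
                  min(sweep.stimulus_end_index + pad, sweep.n_samples))
    start, stop = window
    if stop <= start or start < 0 or stop > sweep.n_samples:
        raise WindowError(f"empty or out-of-bounds peak window {window}")
    seg = sweep.current[start:stop]
    idx = int(np.argmax(np.abs(seg)))
    return float(seg[idx])


@dataclass(frozen=True)
class OnsetResult:
    """Current-onset detection outcome.

    latency is measured from stimulus onset in ms (filter-delay corrected);
    threshold_displacement = min(latency x ramp_speed, ramp amplitude).
    """

    detected: bool
    latency: float
    threshold_displacement: float
    baseline_mean: float
    baseline_sd: float
    onset_index: int = -1


def detect_onset(
    sweep: Sweep,
    ramp_speed: float,
    k_sd: float = 6.0,
    sd_floor: float = 0.0,
) -> OnsetResult:
    """Detect current onset with the k x SD baseline rule (inward negative).

    The onset is the first sample at/after stimulus onset whose current falls
    below ``baseline_mean - k_sd * baseline_sd``.  The mechanical activation
    threshold is the latency multiplied by the probe velocity, clamped at the
    ramp amplitude when the onset falls in the hold phase.

    ``sd_floor`` (pA) bounds the baseline SD from below; it must be set to a
    positive value to analyse noise-free traces, whose measured baseline SD
    is exactly zero (otherwise a :class:`DegenerateBaselineError` is raised).
    """
    if ramp_speed <= 0:
        raise InvalidParameterError("ramp_speed must be > 0")
    mean, sd = baseline_stats(sweep)
    sd_eff = max(sd, sd_floor)
    if sd_eff == 0 and k_sd > 0:
        raise DegenerateBaselineError(
            "baseline SD is 0; pass sd_floor > 0 to analyse noise-free traces"
        )
    bound = mean - k_sd * sd_eff
    seg = sweep.current[sweep.stimulus_onset_index :]
    below = np.nonzero(seg < bound)[0]
    if below.size == 0:
        return OnsetResult(False, float("nan"), float("nan"), mean, sd_eff)
    onset_rel = int(below[0])

    delay_samples = 0
    cutoff = sweep.metadata.get("filter_cutoff_khz")
    if cutoff is not None:
        # the detection bound is crossed very early in the filtered step's
        # rise, so correct by the departure delay (0.1% level), not the 50%
        # crossing; with noise the crossing happens later and the residual
        # bias is positive, vanishing as noise_sd -> 0
        delay_samples = characterize_filter_delay(
            float(cutoff), float(sweep.sampling_rate), level=0.001
        )
    latency_ms = max(0.0, (onset_rel - delay_samples) / sweep.sampling_rate)

    ramp_amplitude = float(np.max(sweep.stimulus)) if sweep.stimulus.size else 0.0
    threshold = min(latency_ms * ramp_speed, ramp_amplitude)
    return OnsetResult(
        True, latency_ms, threshold, mean, sd_eff,
        onset_index=sweep.stimulus_onset_index + onset_rel,
    )


@dataclass(frozen=True)
class InactivationFit:
    """Single-exponential inactivation fit C1 + C2*exp(-(t - t0)/tau)."""

    C1: float
    C2: float
    t0: float
    tau_inact: float  # ms
    rss: float
    converged: bool


def fit_inactivation(
    sweep: Sweep, fit_window: tuple[int, int] | None = None
) -> InactivationFit:
    """Fit the current decay during the hold with a single exponential.

    ``t0`` is fixed at the peak time (start of the fit window), which makes
    C1 and C2 identifiable.  tau is reported in ms.  A flat decay segment
    (no exponential component above 5x baseline SD) raises
    :class:`NoDecayError`; non-convergence is reported via
    ``converged=False`` without raising.
    """
    _, baseline_sd = baseline_stats(sweep)
    if fit_window is None:
        pk_window = (sweep.stimulus_onset_index, sweep.stimulus_end_index)
        seg = sweep.current[pk_window[0] : pk_window[1]]
        peak_rel = int(np.argmax(np.abs(seg)))
        fit_window = (pk_window[0] + peak_rel, sweep.stimulus_end_index)
    start, stop = fit_window
    if stop - start < 20:
        raise WindowError("fit window must contain >= 20 samples")

    t_ms = (np.arange(stop - start)) / sweep.sampling_rate
    y = sweep.current[start:stop]
    c1_0 = float(np.mean(y[-max(5, y.size // 10) :]))
    c2_0 = float(y[0] - c1_0)
    if abs(c2_0) <= max(5.0 * baseline_sd, 1e-9 * max(1.0, abs(c1_0))):
        raise NoDecayError("no decay component: segment is flat")
    peak_mag = abs(float(y[0]))
    if baseline_sd > 0 and peak_mag <= 5.0 * baseline_sd:
        raise NoDecayError("peak magnitude below 5 x baseline SD")

    # crude tau init: time to decay by 1/e of the C2 span
    target = c1_0 + c2_0 / np.e
    crossed = np.nonzero((y - target) * np.sign(c2_0) < 0)[0]
    tau_0 = float(t_ms[crossed[0]]) if crossed.size else float(t_ms[-1] / 3) or 1.0
    tau_0 = max(tau_0, 2.0 / sweep.sampling_rate)

    def model(t, c1, c2, tau):
        return c1 + c2 * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t_ms, y, p0=(c1_0, c2_0, tau_0),
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = True
    except RuntimeError:
        popt = (c1_0, c2_0, tau_0)
        converged = False
    resid = y - model(t_ms, *popt)
    return InactivationFit(
        C1=float(popt[0]), C2=float(popt[1]),
        t0=float(sweep.time[start]), tau_inact=float(popt[2]),
        rss=float(np.sum(resid**2)), converged=converged,
    )


@dataclass(frozen=True)
class DisplacementResponseCurve:
    """Peak-current magnitude (pA) per displacement (µm)."""

    displacement: list[float]
    peak_amplitude: list[float]
    no_response: bool = False

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.displacement, self.displacement[1:])
        ):
            raise InvalidParameterError("displacements must be strictly increasing")


def displacement_response(series: list[Sweep]) -> DisplacementResponseCurve:
    """Displacement-response curve of peak current magnitudes.

    Sweeps flagged ``metadata["excluded"]`` are omitted, so the curve may
    have fewer points than the protocol has steps.  If no sweep's peak
    magnitude exceeds 6x its baseline SD the curve is flagged
    ``no_response``.
    """
    if not series:
        raise WindowError("empty sweep series")
    disp, amp, responded = [], [], False
    for sweep in series:
        if sweep.metadata.get("excluded"):
            continue
        sub = subtract_leak(sweep)
        _, sd = baseline_stats(sub)
        pk = abs(peak_current(sub))
        disp.append(float(np.max(sweep.stimulus)))
        amp.append(pk)
        if pk > 6.0 * sd:
            responded = True
    order = np.argsort(disp)
    return DisplacementResponseCurve(
        displacement=[disp[i] for i in order],
        peak_amplitude=[amp[i] for i in order],
        no_response=not responded,
    )


@dataclass(frozen=True)
class VelocitySeriesResult:
    """Velocity-ratio analysis with the CV-based stability exclusion."""

    velocities: list[float]
    amplitudes: list[float]
    ratio: float
    stability_cv: float
    excluded: bool


def velocity_ratio(
    sweeps_by_velocity: dict[float, list[Sweep]],
    reference_velocity: float = 1.0,
    test_velocity: float = 0.25,
) -> VelocitySeriesResult:
    """Current-amplitude ratio I(test velocity) / I(reference velocity).

    The stability CV is sd/mean of the amplitudes of the last 3
    reference-velocity sweeps; cells with CV > 0.2 are flagged excluded.
    The ratio is mean test amplitude over mean reference amplitude.
    """
    if reference_velocity not in sweeps_by_velocity:
        raise WindowError(f"missing reference velocity {reference_velocity}")
    if test_velocity not in sweeps_by_velocity:
        raise WindowError(f"missing test velocity {test_velocity}")
    ref = sweeps_by_velocity[reference_velocity]
    if len(ref) < 3:
        raise WindowError("need >= 3 reference-velocity sweeps for the CV check")

    def amplitudes(sweeps: list[Sweep]) -> np.ndarray:
        return np.array([abs(peak_current(subtract_leak(s))) for s in sweeps])

    ref_amp = amplitudes(ref)
    test_amp = amplitudes(sweeps_by_velocity[test_velocity])
    last3 = ref_amp[-3:]
    cv = float(last3.std(ddof=1) / last3.mean()) if last3.mean() != 0 else np.inf
    ratio = float(test_amp.mean() / ref_amp.mean())
    velocities = sorted(sweeps_by_velocity)
    all_amp = [float(a) for v in velocities for a in amplitudes(sweeps_by_velocity[v])]
    return VelocitySeriesResult(
        velocities=velocities,
        amplitudes=all_amp,
        ratio=ratio,
        stability_cv=cv,
        excluded=cv > 0.2,
    )


@dataclass(frozen=True)
class ReversalPotentialResult:
    e_rev: float  # mV
    extrapolated: bool
    slope: float = float("nan")  # pA/mV from the least-squares line


def reversal_potential(
    potentials_mv: np.ndarray | list[float],
    peaks_pa: np.ndarray | list[float],
) -> ReversalPotentialResult:
    """Reversal potential from peak currents across holding potentials.

    The I/V series is sorted by potential; E_rev is the zero crossing of the
    linear interpolation between the sign-change pair.  If no sign change
    exists, the least-squares line is extrapolated and the result flagged.
    """
    v = np.asarray(potentials_mv, dtype=float)
    i = np.asarray(peaks_pa, dtype=float)
    if v.size < 2 or v.size != i.size:
        raise WindowError("need >= 2 (potential, peak) pairs")
    order = np.argsort(v)
    v, i = v[order], i[order]
    fit = stats.linregress(v, i)
    sign_change = np.nonzero(np.diff(np.sign(i)) != 0)[0]
    # exact zeros count as crossings
    zeros = np.nonzero(i == 0)[0]
    if zeros.size:
        return ReversalPotentialResult(float(v[zeros[0]]), False, float(fit.slope))
    if sign_change.size:
        k = int(sign_change[0])
        e = v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])
        return ReversalPotentialResult(float(e), False, float(fit.slope))
    if fit.slope == 0:
        raise WindowError("flat I/V line: reversal potential undefined")
    return ReversalPotentialResult(
        float(-fit.intercept / fit.slope), True, float(fit.slope)
    )
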