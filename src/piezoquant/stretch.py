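"""Cell-attached pressure-clamp (stretch) quantification.

Stretch-evoked currents frequently fail to inactivate, which makes a "peak
current" ill-defined; the stimulus-response quantity used throughout is
therefore the total charge transferred during the pressure stimulus (area
under the curve, pC).  Single-channel unitary currents are measured as the
difference between the two Gaussian peaks of the amplitude histogram over a
500 ms segment, and the unitary conductance of a cell is the slope (pS) of
the ordinary least-squares line through its unitary currents across holding
potentials.  Patches with excessive leak (>4 pA) or unstable baseline are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .exceptions import (
    NoResolvableOpeningsError,
    WindowError,
)
from .sweep import Sweep
from .wholecell import baseline_stats, subtract_leak


@dataclass(frozen=True)
class ChargeTransferResult:
    """Total charge transferred during the stimulus, as a magnitude (pC)."""

    pressure: float  # mmHg
    charge: float  # pC, >= 0
    stimulus_window: tuple[float, float]  # s
    signed_charge: float = 0.0


def charge_transfer(
    sweep: Sweep, stimulus_window: tuple[int, int] | None = None
) -> ChargeTransferResult:
    """Charge = |integral of current dt| over the stimulus window, in pC.

    Trapezoidal integration of the leak-subtracted current; pA x s = pC.
    """
    if stimulus_window is None:
        stimulus_window = (sweep.stimulus_onset_index, sweep.stimulus_end_index + 1)
    start, stop = stimulus_window
    if start < 0 or stop > sweep.n_samples or stop - start < 2:
        raise WindowError(f"stimulus window {stimulus_window} outside sweep")
    signed = float(
        np.trapezoid(sweep.current[start:stop], sweep.time[start:stop])
    )
    pressure = float(sweep.metadata.get("pressure_mmHg", np.min(sweep.stimulus)))
    return ChargeTransferResult(
        pressure=pressure,
        charge=abs(signed),
        stimulus_window=(float(sweep.time[start]), float(sweep.time[stop - 1])),
        signed_charge=signed,
    )


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Two-Gaussian decomposition of a 500 ms amplitude histogram.

    ``components`` are (mean pA, sd pA, weight) sorted closed level first
    (the component nearer 0 pA).  ``unitary_current`` is |mu_open -
    mu_closed|; ``signed_unitary_current`` keeps the sign for I/V work.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[tuple[float, float, float]]
    unitary_current: float
    segment_duration: float
    signed_unitary_current: float = 0.0


def default_bin_width(noise_sd: float) -> float:
    """Histogram bin width: max(0.1 pA, 2*noise_sd/5)."""
    return max(0.1, 2.0 * noise_sd / 5.0)


def amplitude_histogram(
    sweep: Sweep,
    segment: tuple[int, int] | None = None,
    segment_duration_ms: float = 500.0,
    bin_width: float | None = None,
    random_state: int = 0,
    exclude_transitions: bool = True,
) -> AmplitudeHistogram:
    """Amplitude histogram of a segment with a 2-component Gaussian fit.

    The default segment is the first ``segment_duration_ms`` of the stimulus
    window.  The mixture is initialised from the two largest histogram modes
    (ties broken toward the mode nearer 0 pA as the closed level).  If the
    fit collapses to one effective component the openings are declared
    unresolvable.

    With ``exclude_transitions`` (default), samples on the low-pass-smeared
    opening/closing edges — identified by a local slope well above the
    within-level median — are dropped before fitting; keeping them pulls the
    two Gaussian means together and biases the unitary current low.
    """
    if segment is None:
        n_seg = int(round(segment_duration_ms * sweep.sampling_rate))
        segment = (
            sweep.stimulus_onset_index,
            min(sweep.stimulus_onset_index + n_seg, sweep.stimulus_end_index + 1),
        )
    start, stop = segment
    if start < 0 or stop > sweep.n_samples or stop - start < 10:
        raise WindowError(f"segment {segment} outside sweep")
    samples = sweep.current[start:stop]
    duration = (stop - start) / (sweep.sampling_rate * 1000.0)
    if exclude_transitions and samples.size > 10:
        # drop the low-pass-smeared opening/closing edges plus the filter
        # settling time around them (2x the characterized group delay);
        # edge samples pull the level means together and the filter's slight
        # step overshoot pushes them apart — both bias the unitary current
        slope = np.abs(np.gradient(samples))
        transition = slope >= 3.0 * np.median(slope) + 1e-12
        cutoff = sweep.metadata.get("filter_cutoff_khz")
        if cutoff is not None:
            from scipy import ndimage

            from .filtering import characterize_filter_delay

            settle = 2 * characterize_filter_delay(
                float(cutoff), float(sweep.sampling_rate)
            )
            if settle > 0:
                transition = ndimage.binary_dilation(transition, iterations=settle)
        if (~transition).sum() >= 10:
            samples = samples[~transition]

    spread = float(samples.std())
    if spread < 1e-12:
        raise NoResolvableOpeningsError("no resolvable openings: constant segment")
    if bin_width is None:
        noise_sd = float(sweep.metadata.get("ground_truth", {}).get("noise_sd", spread / 4))
        bin_width = default_bin_width(noise_sd)
    edges = np.arange(samples.min() - bin_width, samples.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)

    # initialise the mixture from the two largest separated histogram modes
    order = np.argsort(counts)[::-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    first = centers[order[0]]
    second = None
    for idx in order[1:]:
        if abs(centers[idx] - first) > 3 * bin_width:
            second = centers[idx]
            break
    if second is None:
        second = first + (spread if first <= 0 else -spread)
    means_init = np.array(sorted([first, second], key=abs))[:, None]

    # both levels see the same recording noise, so the components share a
    # variance (tied); this also behaves better when the peaks overlap
    gmm = GaussianMixture(
        n_components=2, means_init=means_init, random_state=random_state,
        covariance_type="tied", reg_covar=1e-6,
    )
    gmm.fit(samples[:, None])
    mus = gmm.means_.ravel()
    sds = np.sqrt(np.full(2, gmm.covariances_.ravel()[0]))
    weights = gmm.weights_.ravel()
    # closed level = the component nearer 0 pA
    closed = int(np.argmin(np.abs(mus)))
    open_ = 1 - closed
    delta = mus[open_] - mus[closed]
    pooled_sd = float(np.sqrt(np.average(sds**2, weights=weights)))
    if weights.min() < 0.02 or abs(delta) < 2.0 * pooled_sd / np.sqrt(samples.size):
        raise NoResolvableOpeningsError(
            "no resolvable openings: mixture collapsed to one effective component"
        )
    components = [
        (float(mus[closed]), float(sds[closed]), float(weights[closed])),
        (float(mus[open_]), float(sds[open_]), float(weights[open_])),
    ]
    return AmplitudeHistogram(
        bin_edges=edges,
        counts=counts,
        components=components,
        unitary_current=float(abs(delta)),
        segment_duration=duration,
        signed_unitary_current=float(delta),
    )


@dataclass(frozen=True)
class ConductanceFit:
    """Per-cell I/V regression: slope in pS ( (pA/mV) * 1000 )."""

    voltages: list[float]
    unitary_currents: list[float]  # signed, pA
    slope: float  # pS
    intercept: float  # pA
    r_squared: float


def unitary_conductance(
    voltages_mv: list[float] | np.ndarray,
    unitary_currents_pa: list[float] | np.ndarray,
) -> ConductanceFit:
    """Unitary conductance from the OLS fit of the per-cell I/V plot.

    ``unitary_currents_pa`` are signed single-channel currents (one per
    holding potential, typically -120..-40 mV in 20 mV steps).
    """
    v = np.asarray(voltages_mv, dtype=float)
    i = np.asarray(unitary_currents_pa, dtype=float)
    if v.size < 3 or v.size != i.size:
        raise WindowError("need >= 3 (voltage, unitary current) pairs")
    fit = stats.linregress(v, i)
    return ConductanceFit(
        voltages=[float(x) for x in v],
        unitary_currents=[float(x) for x in i],
        slope=float(fit.slope * 1000.0),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass(frozen=True)
class ResponderCall:
    """Responder decision: did any pressure step evoke detectable charge?"""

    responded: bool
    max_charge: float  # pC
    criterion_threshold: float  # pC
    pressures_tested: list[float]


def classify_responder(
    stimulus_sweeps: list[Sweep],
    baseline_sweeps: list[Sweep],
) -> ResponderCall:
    """Call a cell a responder if any pressure step's charge exceeds
    5 x the SD of the charge measured on stimulus-free segments.

    The SD is taken over the *signed* baseline charges: the magnitude of a
    zero-mean integral is half-normal, whose SD understates the spread by
    ~40% and would make 5 x SD a weak (~3 sigma) criterion.

    ``baseline_sweeps`` must contain >= 2 stimulus-free sweeps whose
    analysis windows have the same duration as the pressure stimulus.
    """
    if len(baseline_sweeps) < 2:
        raise WindowError("need >= 2 stimulus-free baseline sweeps")
    base_charges = np.array(
        [charge_transfer(subtract_leak(s)).signed_charge for s in baseline_sweeps]
    )
    threshold = 5.0 * float(base_charges.std(ddof=1))
    charges, pressures = [], []
    for s in stimulus_sweeps:
        res = charge_transfer(subtract_leak(s))
        charges.append(res.charge)
        pressures.append(res.pressure)
    max_charge = float(max(charges)) if charges else 0.0
    responded = max_charge >= threshold and max_charge > 0.0
    return ResponderCall(
        responded=responded,
        max_charge=max_charge,
        criterion_threshold=threshold,
        pressures_tested=pressures,
    )


@dataclass(frozen=True)
class PatchQC:
    """Patch quality flags mirroring the exclusion rules for stretch data."""

    excluded: bool
    reasons: list[str] = field(default_factory=list)
    leak_pa: float = 0.0
    drift_pa_per_s: float = 0.0


LEAK_BOUND_PA = 4.0
DRIFT_BOUND_PA_PER_S = 2.0


def qc_patch(
    sweep: Sweep,
    leak_bound_pa: float = LEAK_BOUND_PA,
    drift_bound_pa_per_s: float = DRIFT_BOUND_PA_PER_S,
) -> PatchQC:
    """Exclude patches with excessive leak (|leak| > 4 pA, strict) or an
    unstable baseline (|linear drift| above ``drift_bound_pa_per_s``)."""
    mean, _ = baseline_stats(sweep)
    pre = sweep.pre_stimulus_slice()
    t = sweep.time[pre]
    y = sweep.current[pre]
    drift = float(stats.linregress(t, y).slope) if t.size >= 2 else 0.0
    reasons = []
    if abs(mean) > leak_bound_pa:
        reasons.append(f"leak {mean:.2f} pA exceeds {leak_bound_pa} pA")
    if abs(drift) > drift_bound_pa_per_s:
        reasons.append(
            f"baseline drift {drift:.2f} pA/s exceeds {drift_bound_pa_per_s} pA/s"
        )
    return PatchQC(
        excluded=bool(reasons), reasons=reasons, leak_pa=mean, drift_pa_per_s=drift
    )
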