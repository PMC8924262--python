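"""Parameter-recovery experiments.

Self-contained simulate -> analyse -> score loops that measure how well each
analysis stage recovers the ground truth embedded by the generators.  They
serve as the package's validation benchmarks: the test suite asserts on
their outputs and the reproduction script reports them.

Problem sizes default to the values used throughout the package's
validation: a handful of inactivation time constants and conductances on a
grid with a few hundred replicates in total, 200-track diffusion ensembles,
and a 4 x 100-track motility panel.
"""

from __future__ import annotations

import numpy as np

from . import stretch, tirf, wholecell
from .synthgen import (
    ChannelParams,
    GatingParams,
    MotionModel,
    PokingProtocol,
    PressureProtocol,
    simulate_poking_sweep,
    simulate_pressure_sweep,
    simulate_trajectories,
)

# compact poking protocol for replicate-heavy experiments: full 200 kHz
# sampling but a 20 ms baseline and 120 ms hold
FAST_POKING = PokingProtocol(
    pre_stimulus_duration=20.0, hold_duration=120.0, post_stimulus_duration=10.0
)


def tau_recovery(
    taus_ms: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0),
    noise_fraction: float = 0.05,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Recover tau_inact across a grid at proportional noise.

    Noise SD is ``noise_fraction`` of the peak amplitude.  Returns the
    median absolute relative error (as a fraction) per tau and overall.
    """
    rng = np.random.default_rng(seed)
    per_tau: dict[float, float] = {}
    all_errors = []
    for tau in taus_ms:
        errors = []
        for _ in range(n_replicates):
            gating = GatingParams(
                tau_inact=tau,
                noise_sd=noise_fraction * abs(GatingParams().i_max),
            )
            sweep = simulate_poking_sweep(FAST_POKING, gating, 12, seed=rng)
            fit = wholecell.fit_inactivation(wholecell.subtract_leak(sweep))
            if fit.converged:
                errors.append(abs(fit.tau_inact - tau) / tau)
        per_tau[tau] = float(np.median(errors))
        all_errors.extend(errors)
    return {
        "median_rel_error": float(np.median(all_errors)),
        "per_tau": per_tau,
        "n": len(all_errors),
    }


def threshold_recovery(
    thresholds_um: tuple[float, ...] = (0.8, 1.6, 2.4, 3.2),
    seed: int = 0,
) -> dict:
    """Mechanical-threshold recovery on noiseless sweeps.

    The error budget is one sample-equivalent (ramp_speed / sampling_rate)
    plus the characterized 50% filter delay converted to displacement.
    """
    proto = FAST_POKING
    errors = []
    for thr in thresholds_um:
        gating = GatingParams(threshold_displacement=thr, noise_sd=0.0)
        sweep = simulate_poking_sweep(proto, gating, 12, seed=seed)
        onset = wholecell.detect_onset(
            wholecell.subtract_leak(sweep), proto.ramp_speed, sd_floor=1e-3
        )
        errors.append(abs(onset.threshold_displacement - thr))
    from .filtering import characterize_filter_delay

    delay = characterize_filter_delay(proto.filter_cutoff, proto.sampling_rate)
    sample_um = proto.ramp_speed / proto.sampling_rate
    return {
        "max_error_um": float(max(errors)),
        "allowance_um": sample_um + delay * sample_um,
        "n": len(errors),
    }


def conductance_recovery(
    conductances_ps: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0),
    n_replicates: int = 20,
    seed: int = 0,
    voltages_mv: tuple[float, ...] = (-120.0, -100.0, -80.0, -60.0, -40.0),
) -> dict:
    """Full simulate -> amplitude histogram -> I/V regression recovery of the
    unitary conductance.  Returns median relative error per g and overall,
    plus the signed bias."""
    rng = np.random.default_rng(seed)
    per_g: dict[float, float] = {}
    all_errors, signed = [], []
    for g in conductances_ps:
        errors = []
        for _ in range(n_replicates):
            channels = ChannelParams(
                n_channels=1, unitary_conductance=g, mean_open_dwell=5.0
            )
            currents = []
            for v in voltages_mv:
                proto = PressureProtocol(
                    step_duration=1.0,
                    pre_stimulus_duration=0.2,
                    post_stimulus_duration=0.05,
                    holding_potential=v,
                )
                sweep = simulate_pressure_sweep(proto, channels, -40.0, seed=rng)
                hist = stretch.amplitude_histogram(sweep)
                currents.append(hist.signed_unitary_current)
            fit = stretch.unitary_conductance(list(voltages_mv), currents)
            errors.append((fit.slope - g) / g)
        per_g[g] = float(np.median(np.abs(errors)))
        all_errors.extend(np.abs(errors))
        signed.extend(errors)
    return {
        "median_rel_error": float(np.median(all_errors)),
        "mean_signed_error": float(np.mean(signed)),
        "signed_errors": [float(e) for e in signed],
        "per_g": per_g,
        "n": len(all_errors),
    }


def msd_diffusion_recovery(
    n_tracks: int = 200,
    D: float = 0.05,
    n_frames: int = 100,
    frame_rate: float = 10.0,
    seed: int = 0,
) -> dict:
    """Ensemble time-averaged MSD of Brownian tracks against the 4*D*tau
    closed form at the first 5 lags."""
    motions = [(MotionModel("diffusion", D=D), (0.0, 0.0))] * n_tracks
    truth = simulate_trajectories(motions, n_frames, frame_rate, seed=seed)
    curves = []
    for _, sub in truth.groupby("track_id"):
        track = tirf.Track(
            id=0, frames=list(sub["frame"]), x=list(sub["x_um"]), y=list(sub["y_um"])
        )
        curves.append(tirf.compute_msd(track, frame_rate).msd[1:6])
    mean_msd = np.mean(curves, axis=0)
    lags = np.arange(1, 6) / frame_rate
    expected = 4.0 * D * lags
    rel_dev = np.abs(mean_msd - expected) / expected
    d_fit = float(np.mean(mean_msd / (4.0 * lags)))
    return {
        "max_rel_deviation": float(rel_dev.max()),
        "D_fit": d_fit,
        "D_true": D,
        "n": n_tracks,
    }


MOTILITY_PANEL = {
    "diffusion": MotionModel("diffusion", D=0.05),
    "subdiffusion": MotionModel("subdiffusion", D=0.05, anomalous_exponent=0.7),
    "confined": MotionModel("confined", D=0.1, corral_radius=0.15),
    "directed": MotionModel("directed", D=0.005, drift_speed=1.0),
}
EXPECTED_CATEGORY = {
    "diffusion": "normal diffusion",
    "subdiffusion": "subdiffusion",
    "confined": "confined",
    "directed": "directed",
}


def motility_classification_panel(
    n_per_class: int = 100,
    n_frames: int = 100,
    frame_rate: float = 10.0,
    seed: int = 0,
) -> dict:
    """Per-class classification accuracy on the four-regime synthetic panel
    with well-separated parameters."""
    rng = np.random.default_rng(seed)
    accuracy: dict[str, float] = {}
    for name, motion in MOTILITY_PANEL.items():
        motions = [(motion, (0.0, 0.0))] * n_per_class
        truth = simulate_trajectories(motions, n_frames, frame_rate, seed=rng)
        correct = 0
        for _, sub in truth.groupby("track_id"):
            track = tirf.Track(
                id=0,
                frames=list(sub["frame"]),
                x=list(sub["x_um"]),
                y=list(sub["y_um"]),
            )
            msd = tirf.compute_msd(track, frame_rate)
            cls = tirf.classify_track(msd, track)
            correct += cls.category == EXPECTED_CATEGORY[name]
        accuracy[name] = correct / n_per_class
    return {"per_class_accuracy": accuracy, "n_per_class": n_per_class}


def velocity_ratio_experiment(
    n_sweeps: int = 3, noise_sd: float = 5.0, seed: int = 0
) -> dict:
    """Velocity-ratio recovery: the generator's velocity scaling puts the
    0.25 µm/ms response at 40% of the reference, emulating currents ~60%
    smaller at slow stimulation."""
    rng = np.random.default_rng(seed)
    proto = FAST_POKING
    gating = GatingParams(noise_sd=noise_sd)
    ref = [simulate_poking_sweep(proto, gating, 8, seed=rng) for _ in range(n_sweeps)]
    test = [
        simulate_poking_sweep(proto, gating, 8, seed=rng, velocity=0.25)
        for _ in range(n_sweeps)
    ]
    result = wholecell.velocity_ratio({1.0: ref, 0.25: test})
    return {
        "ratio": result.ratio,
        "expected": gating.velocity_scaling(0.25),
        "stability_cv": result.stability_cv,
        "excluded": result.excluded,
    }


def responder_false_positive_rate(n_cells: int = 40, seed: int = 0) -> dict:
    """Responder-call false-positive rate on channel-free cells."""
    rng = np.random.default_rng(seed)
    proto = PressureProtocol(
        step_duration=1.0, pre_stimulus_duration=0.2, post_stimulus_duration=0.05
    )
    silent = ChannelParams(n_channels=0)
    fp = 0
    for _ in range(n_cells):
        baselines = [
            simulate_pressure_sweep(proto, silent, 0.0, seed=rng) for _ in range(6)
        ]
        stims = [
            simulate_pressure_sweep(proto, silent, p, seed=rng)
            for p in (-20.0, -40.0, -60.0, -80.0)
        ]
        if stretch.classify_responder(stims, baselines).responded:
            fp += 1
    return {"false_positive_rate": fp / n_cells, "n": n_cells}
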