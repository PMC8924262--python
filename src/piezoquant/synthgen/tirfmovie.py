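"""TIRF movie generator: diffusing Gaussian spots with ground-truth tracks.

Emulates ~10 Hz TIRF imaging of fluorescently tagged channel clusters at a
pixel size of 0.11 µm.  Trajectories follow one of four motion regimes:

* ``diffusion`` — Brownian increments with diffusion coefficient D;
* ``subdiffusion`` — fractional Brownian motion with MSD = 4 D t^alpha
  (Hurst exponent alpha/2), generated by a Cholesky factor of the fBm
  covariance;
* ``confined`` — Brownian motion reflected inside a disc of ``corral_radius``
  centred on the initial position;
* ``directed`` — Brownian motion plus constant drift in a random direction.

Each spot is rendered per frame as a 2D Gaussian of width ``psf_sigma`` on a
constant background with Gaussian photon noise, written as 16-bit frames.
Ground-truth positions are returned alongside the pixels so tracking and
classification stages can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from ..exceptions import InvalidParameterError

MOTION_CATEGORIES = ("diffusion", "subdiffusion", "confined", "directed")


@dataclass(frozen=True)
class MotionModel:
    """One motion regime with its parameters (D µm²/s, radius µm, speed µm/s)."""

    category: str
    D: float = 0.05
    anomalous_exponent: float = 0.5
    corral_radius: float = 0.2
    drift_speed: float = 0.5

    def __post_init__(self) -> None:
        if self.category not in MOTION_CATEGORIES:
            raise InvalidParameterError(
                f"category must be one of {MOTION_CATEGORIES}, got {self.category!r}"
            )
        if self.D < 0 or not math.isfinite(self.D):
            raise InvalidParameterError("D must be >= 0 and finite")
        if self.category == "subdiffusion" and not (0 < self.anomalous_exponent < 1):
            raise InvalidParameterError("subdiffusion requires 0 < alpha < 1")
        if self.category == "confined" and self.corral_radius <= 0:
            raise InvalidParameterError("confined requires corral_radius > 0")


@dataclass(frozen=True)
class TirfMovieConfig:
    """Imaging configuration: frame_rate Hz, pixel_size µm, psf_sigma µm."""

    frame_rate: float = 10.0
    n_frames: int = 100
    pixel_size: float = 0.11
    frame_shape: tuple[int, int] = (128, 128)
    psf_sigma: float = 0.15
    spot_amplitude: float = 800.0
    background: float = 200.0
    photon_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise InvalidParameterError("psf_sigma must be > 0")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be > 0")


@lru_cache(maxsize=16)
def _fbm_cholesky(n_steps: int, alpha: float, dt: float) -> np.ndarray:
    """Lower Cholesky factor of the fBm covariance with unit 2D coefficient.

    Covariance of one axis with E[x(t)^2] = 2 t^alpha (D factored out later):
    C(s, t) = s^alpha + t^alpha - |t - s|^alpha.
    """
    t = (np.arange(1, n_steps + 1) * dt)[:, None]
    s = t.T
    cov = t**alpha + s**alpha - np.abs(t - s) ** alpha
    # small jitter keeps the factorisation stable for alpha near 1
    cov[np.diag_indices_from(cov)] += 1e-12
    return np.linalg.cholesky(cov)


def simulate_trajectory(
    motion: MotionModel,
    start: tuple[float, float],
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ground-truth positions, shape (n_frames, 2), µm."""
    dt = 1.0 / frame_rate
    x0 = np.asarray(start, dtype=float)
    if motion.category == "diffusion" or (motion.category == "directed"):
        step_sd = math.sqrt(2.0 * motion.D * dt)
        steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if motion.category == "directed":
            theta = rng.uniform(0.0, 2.0 * math.pi)
            drift = motion.drift_speed * dt * np.array([math.cos(theta), math.sin(theta)])
            pos = pos + np.arange(n_frames)[:, None] * drift
        return x0 + pos
    if motion.category == "subdiffusion":
        chol = _fbm_cholesky(n_frames - 1, motion.anomalous_exponent, dt)
        z = rng.standard_normal((n_frames - 1, 2))
        pos = math.sqrt(motion.D) * (chol @ z)
        return x0 + np.vstack([np.zeros(2), pos])
    # confined: Brownian reflected in a disc around the start
    step_sd = math.sqrt(2.0 * motion.D * dt)
    pos = np.empty((n_frames, 2))
    pos[0] = x0
    r = motion.corral_radius
    for k in range(1, n_frames):
        p = pos[k - 1] + rng.normal(0.0, step_sd, size=2)
        # radial reflection at the corral boundary (iterate for large steps)
        for _ in range(16):
            d = p - x0
            rho = np.hypot(d[0], d[1])
            if rho <= r:
                break
            p = x0 + d * (2.0 * r - rho) / rho
        else:
            p = x0 + d / rho * r
        pos[k] = p
    return pos


def simulate_trajectories(
    motions: list[tuple[MotionModel, tuple[float, float]]],
    n_frames: int,
    frame_rate: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate many ground-truth tracks.

    Returns a DataFrame with columns
    ``track_id, frame, x_um, y_um, category`` (long format).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for tid, (motion, start) in enumerate(motions):
        pos = simulate_trajectory(motion, start, n_frames, frame_rate, rng)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": np.arange(n_frames),
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "category": motion.category,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um", "category"])
    return pd.concat(rows, ignore_index=True)


def render_frame(
    cfg: TirfMovieConfig,
    positions_um: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one frame: background + Gaussian spots + photon noise, uint16."""
    h, w = cfg.frame_shape
    img = np.full((h, w), cfg.background, dtype=float)
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    half = int(math.ceil(5 * sigma_px))
    for x_um, y_um in positions_um:
        cx = x_um / cfg.pixel_size
        cy = y_um / cfg.pixel_size
        x_lo, x_hi = int(cx) - half, int(cx) + half + 1
        y_lo, y_hi = int(cy) - half, int(cy) + half + 1
        x_lo_c, x_hi_c = max(0, x_lo), min(w, x_hi)
        y_lo_c, y_hi_c = max(0, y_lo), min(h, y_hi)
        if x_lo_c >= x_hi_c or y_lo_c >= y_hi_c:
            continue
        xs = np.arange(x_lo_c, x_hi_c)
        ys = np.arange(y_lo_c, y_hi_c)
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma_px**2))
        img[y_lo_c:y_hi_c, x_lo_c:x_hi_c] += cfg.spot_amplitude * np.outer(gy, gx)
    if cfg.photon_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.photon_noise_sd, size=img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def simulate_tirf_movie(
    cfg: TirfMovieConfig,
    motions: list[tuple[MotionModel, tuple[float, float]]],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a movie and its ground-truth track table.

    Returns
    -------
    stack : ndarray, shape (n_frames, H, W), uint16
    truth : DataFrame with columns track_id, frame, x_um, y_um, category
    """
    h, w = cfg.frame_shape
    for _, (x0, y0) in motions:
        if not (0 <= x0 / cfg.pixel_size < w and 0 <= y0 / cfg.pixel_size < h):
            raise InvalidParameterError(
                f"initial position ({x0}, {y0}) µm lies outside the frame"
            )
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_trajectories(motions, cfg.n_frames, cfg.frame_rate, rng)
    stack = np.empty((cfg.n_frames, h, w), dtype=np.uint16)
    for f in range(cfg.n_frames):
        if len(truth):
            sub = truth[truth["frame"] == f]
            positions = sub[["x_um", "y_um"]].to_numpy()
        else:
            positions = np.empty((0, 2))
        stack[f] = render_frame(cfg, positions, rng)
    return stack, truth
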