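"""TIRF cluster detection, tracking, MSD and motility classification.

The imaging chain mirrors a standard single-particle-tracking workflow:
difference-of-Gaussians spot detection with sub-pixel refinement, linear-
assignment frame-to-frame linking with distance caps and gap closing, a
40-frame minimum track duration, time-averaged MSD, and a transparent
threshold classifier that sorts tracks into directed movement, normal
diffusion, subdiffusion and confined movement from the log-log MSD slope,
path straightness and a confinement ratio.  Cluster diameters are measured
by 2D Gaussian fits (diameter = 2 x the fitted standard deviation) and
cluster density as first-frame spot count over cell area.

Detection quality is the DoG response normalised by a robust noise estimate
of the response image (MAD-based); the absolute scale of third-party
detector quality values is not reproducible, so the threshold is exposed as
configuration with :func:`calibrate_quality_threshold` as a helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.optimize import linear_sum_assignment

from .exceptions import InvalidParameterError, WindowError


# ---------------------------------------------------------------- detection

@dataclass(frozen=True)
class Spot:
    """One detected spot: sub-pixel position in µm, frame index, quality."""

    frame: int
    x: float  # µm
    y: float  # µm
    quality: float
    intensity: float


def _dog_response(image: np.ndarray, sigma_px: float, ratio: float = 1.6) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    g1 = ndimage.gaussian_filter(img, sigma_px)
    g2 = ndimage.gaussian_filter(img, sigma_px * ratio)
    return g1 - g2


def robust_noise_sd(response: np.ndarray) -> float:
    """Robust SD of a response image: 1.4826 x median absolute deviation."""
    med = np.median(response)
    return float(1.4826 * np.median(np.abs(response - med))) or 1e-12


def calibrate_quality_threshold(
    blank_frames: np.ndarray,
    pixel_size_um: float,
    blob_diameter_um: float = 0.7,
    n_sd: float = 5.0,
) -> float:
    """Quality threshold from blank (spot-free) frames: ``n_sd`` times the
    robust spread of the maximal normalised DoG response per frame."""
    maxima = []
    for frame in np.atleast_3d(blank_frames.reshape((-1,) + blank_frames.shape[-2:])):
        sigma_px = blob_diameter_um / 2.0 / math.sqrt(2.0) / pixel_size_um
        resp = _dog_response(frame, sigma_px)
        maxima.append(resp.max() / robust_noise_sd(resp))
    return float(n_sd / 5.0 * np.max(maxima))


def _subpixel_offset(patch3: np.ndarray) -> float:
    """1D quadratic (parabolic) sub-pixel offset from 3 samples."""
    denom = patch3[0] - 2.0 * patch3[1] + patch3[2]
    if denom >= 0:  # not a local maximum of the parabola
        return 0.0
    return float(0.5 * (patch3[0] - patch3[2]) / denom)


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    blob_diameter_um: float = 0.7,
    quality_min: float = 10.0,
    frame: int = 0,
) -> list[Spot]:
    """Difference-of-Gaussians spot detection with sub-pixel refinement.

    The DoG scale matches a blob of ``blob_diameter_um``; local response
    maxima with normalised quality above ``quality_min`` are kept and
    refined by a local quadratic fit.  Coordinates are µm with the origin at
    the top-left pixel center, x rightward, y downward.
    """
    if pixel_size_um <= 0:
        raise InvalidParameterError("pixel size must be > 0")
    if blob_diameter_um / pixel_size_um < 2.0:
        raise InvalidParameterError(
            f"blob diameter {blob_diameter_um} µm is < 2 pixels at "
            f"{pixel_size_um} µm/px"
        )
    sigma_px = blob_diameter_um / 2.0 / math.sqrt(2.0) / pixel_size_um
    resp = _dog_response(image, sigma_px)
    noise = robust_noise_sd(resp)
    quality = resp / noise

    size = max(3, int(round(blob_diameter_um / pixel_size_um)) | 1)
    local_max = ndimage.maximum_filter(quality, size=size) == quality
    candidates = np.argwhere(local_max & (quality >= quality_min))
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    spots = []
    for (r, c) in candidates:
        if 0 < r < h - 1 and 0 < c < w - 1:
            dy = _subpixel_offset(resp[r - 1 : r + 2, c])
            dx = _subpixel_offset(resp[r, c - 1 : c + 2])
        else:
            dy = dx = 0.0
        spots.append(
            Spot(
                frame=frame,
                x=(c + dx) * pixel_size_um,
                y=(r + dy) * pixel_size_um,
                quality=float(quality[r, c]),
                intensity=float(img[r, c]),
            )
        )
    spots.sort(key=lambda s: -s.quality)
    return spots


def detect_movie(
    stack: np.ndarray,
    pixel_size_um: float,
    blob_diameter_um: float = 0.7,
    quality_min: float = 10.0,
) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every frame of a movie."""
    return [
        detect_spots(stack[f], pixel_size_um, blob_diameter_um, quality_min, frame=f)
        for f in range(stack.shape[0])
    ]


# ------------------------------------------------------------------ linking

@dataclass
class Track:
    """A linked trajectory: ordered (frame, x, y) triples, µm."""

    id: int
    frames: list[int]
    x: list[float]
    y: list[float]
    gaps: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise InvalidParameterError("track frames must be strictly increasing")

    @property
    def duration(self) -> int:
        """Span in frames, inclusive."""
        return self.frames[-1] - self.frames[0] + 1

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _assign(
    prev: np.ndarray, cur: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Linear-assignment matching of two point sets with a distance cap."""
    if len(prev) == 0 or len(cur) == 0:
        return []
    d2 = ((prev[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
    big = 1e12
    cost = np.where(d2 <= max_dist**2, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < big]


def link_tracks(
    spots_per_frame: list[list[Spot]],
    link_distance: float = 0.5,
    gap_distance: float = 0.7,
    max_gap: int = 2,
    min_duration: int = 40,
) -> list[Track]:
    """Link per-frame detections into tracks (LAP-style).

    Frame-to-frame links minimise total squared displacement under the
    ``link_distance`` cap (optimal assignment per adjacent frame pair); track
    ends are then merged with later track starts within ``gap_distance`` and
    at most ``max_gap`` missing frames; tracks spanning fewer than
    ``min_duration`` frames are discarded.
    """
    # frame-to-frame linking: open tracks end at the previous frame
    open_tracks: list[dict] = []
    closed: list[dict] = []
    for f, spots in enumerate(spots_per_frame):
        cur = np.array([[s.x, s.y] for s in spots]) if spots else np.empty((0, 2))
        prev = (
            np.array([t["pts"][-1] for t in open_tracks])
            if open_tracks
            else np.empty((0, 2))
        )
        matches = _assign(prev, cur, link_distance)
        matched_prev = {p for p, _ in matches}
        matched_cur = {c for _, c in matches}
        new_open: list[dict] = []
        for p, c in matches:
            tr = open_tracks[p]
            tr["frames"].append(f)
            tr["pts"].append((spots[c].x, spots[c].y))
            new_open.append(tr)
        closed.extend(t for p, t in enumerate(open_tracks) if p not in matched_prev)
        new_open.extend(
            {"frames": [f], "pts": [(s.x, s.y)]}
            for c, s in enumerate(spots)
            if c not in matched_cur
        )
        open_tracks = new_open
    closed.extend(open_tracks)
    segments = [t for t in closed if t["frames"]]

    # gap closing: connect a segment end to a later segment start
    segments.sort(key=lambda t: t["frames"][0])
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(segments):
            best = None
            for j, b in enumerate(segments):
                if i == j:
                    continue
                gap = b["frames"][0] - a["frames"][-1] - 1
                if 1 <= gap <= max_gap:
                    dx = b["pts"][0][0] - a["pts"][-1][0]
                    dy = b["pts"][0][1] - a["pts"][-1][1]
                    dist = math.hypot(dx, dy)
                    if dist <= gap_distance and (best is None or dist < best[0]):
                        best = (dist, j)
            if best is not None:
                j = best[1]
                segments[i] = {
                    "frames": a["frames"] + segments[j]["frames"],
                    "pts": a["pts"] + segments[j]["pts"],
                }
                del segments[j]
                merged = True
                break

    tracks = []
    tid = 0
    for seg in segments:
        duration = seg["frames"][-1] - seg["frames"][0] + 1
        if duration < min_duration:
            continue
        gaps = duration - len(seg["frames"])
        tracks.append(
            Track(
                id=tid,
                frames=list(seg["frames"]),
                x=[p[0] for p in seg["pts"]],
                y=[p[1] for p in seg["pts"]],
                gaps=gaps,
            )
        )
        tid += 1
    return tracks


# --------------------------------------------------------------------- MSD

@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged mean squared displacement per lag."""

    lags: np.ndarray  # s, starting at 0
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray


def compute_msd(
    track: Track, frame_rate: float = 10.0, max_lag_fraction: float = 0.25
) -> MsdCurve:
    """Time-averaged MSD over all overlapping detection pairs per lag.

    Lags run from 0 up to ``max_lag_fraction`` of the track duration; gapped
    frames simply contribute no pairs at the affected lags.
    """
    if track.duration < 4:
        raise WindowError("track too short for MSD (duration < 4 frames)")
    pos = {f: (x, y) for f, x, y in zip(track.frames, track.x, track.y)}
    max_lag = max(1, int(math.floor(max_lag_fraction * track.duration)))
    lags = np.arange(max_lag + 1)
    msd = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=int)
    n_pairs[0] = len(track.frames)
    frames = np.array(track.frames)
    xy = track.positions()
    for lag in range(1, max_lag + 1):
        # pairs of detections separated by exactly `lag` frames
        idx = {f: k for k, f in enumerate(frames)}
        d2s = [
            ((xy[idx[f + lag]] - xy[k]) ** 2).sum()
            for k, f in zip(range(len(frames)), frames)
            if f + lag in idx
        ]
        if d2s:
            msd[lag] = float(np.mean(d2s))
            n_pairs[lag] = len(d2s)
    dt = 1.0 / frame_rate
    return MsdCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


# ----------------------------------------------------------- classification

@dataclass(frozen=True)
class TrackClass:
    """Motility category with the classifier features."""

    category: str  # directed | normal diffusion | subdiffusion | confined
    alpha: float  # log-log MSD slope over the first 5 lags
    D_fit: float  # µm²/s, msd(tau_1) / (4 tau_1)
    straightness: float  # net / total path length
    confinement_ratio: float
    degenerate: bool = False


ALPHA_DIRECTED = 1.5
ALPHA_CONFINED = 0.3
ALPHA_SUBDIFFUSION = 0.85
STRAIGHTNESS_DIRECTED = 0.6
CONFINEMENT_RATIO_MIN = 0.3
CONFINEMENT_LAG_INDEX = 10  # "long" lag used by the confinement ratio


def classify_track(msd: MsdCurve, track: Track) -> TrackClass:
    """Threshold classifier over MSD shape and path geometry.

    alpha is the slope of log(msd) vs log(lag) over the first 5 positive
    lags.  Categories, in order of precedence: directed if alpha >= 1.5 or
    straightness >= 0.6; confined if alpha < 0.3 or confinement ratio < 0.3;
    subdiffusion if 0.3 <= alpha < 0.85; otherwise normal diffusion.  The
    confinement ratio compares the MSD at a long lag with the linear
    (Brownian) extrapolation from the first lag, so it is ~1 for free
    diffusion and << 1 when the MSD saturates.
    """
    usable = np.nonzero(msd.msd[1:] > 0)[0]
    if usable.size < 5:
        if np.all(msd.msd == 0):
            return TrackClass("confined", 0.0, 0.0, 0.0, 0.0, degenerate=True)
        raise WindowError("need >= 5 usable (positive) MSD lags")
    lags = msd.lags[1:][usable]
    values = msd.msd[1:][usable]
    alpha = float(np.polyfit(np.log(lags[:5]), np.log(values[:5]), 1)[0])
    d_fit = float(values[0] / (4.0 * lags[0]))

    xy = track.positions()
    steps = np.diff(xy, axis=0)
    path = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = float(np.hypot(*(xy[-1] - xy[0])))
    straightness = net / path if path > 0 else 0.0

    long_idx = min(CONFINEMENT_LAG_INDEX - 1, len(values) - 1)
    ratio = (values[long_idx] / values[0]) / (lags[long_idx] / lags[0])

    if alpha >= ALPHA_DIRECTED or straightness >= STRAIGHTNESS_DIRECTED:
        category = "directed"
    elif alpha < ALPHA_CONFINED or ratio < CONFINEMENT_RATIO_MIN:
        category = "confined"
    elif alpha < ALPHA_SUBDIFFUSION:
        category = "subdiffusion"
    else:
        category = "normal diffusion"
    return TrackClass(
        category=category,
        alpha=alpha,
        D_fit=d_fit,
        straightness=straightness,
        confinement_ratio=float(ratio),
    )


# ------------------------------------------------------------- cluster size

@dataclass(frozen=True)
class ClusterFit:
    """2D Gaussian cluster fit; diameter = 2 x mean(sigma_x, sigma_y), µm."""

    centroid: tuple[float, float]  # µm
    sigma_x: float  # µm
    sigma_y: float  # µm
    diameter: float  # µm
    amplitude: float
    background: float
    residual: float
    converged: bool


def cluster_diameter(
    patch: np.ndarray, pixel_size_um: float
) -> ClusterFit:
    """Least-squares 2D Gaussian fit of an image patch around one spot.

    The cluster diameter is reported as twice the mean fitted standard
    deviation.  Non-convergence is flagged rather than raised; the flagged
    result carries NaN for the diameter.
    """
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]

    def model(coords, amp, cx, cy, sx, sy, bg):
        x, y = coords
        return (
            amp * np.exp(-((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2))
            + bg
        )

    bg0 = float(np.median(patch))
    amp0 = float(patch.max() - bg0)
    cy0, cx0 = np.unravel_index(np.argmax(patch), patch.shape)
    p0 = (amp0 if amp0 > 0 else 1.0, float(cx0), float(cy0), w / 6.0, h / 6.0, bg0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            (xx.ravel(), yy.ravel()),
            patch.ravel(),
            p0=p0,
            bounds=(
                [0, -1, -1, 0.1, 0.1, -np.inf],
                [np.inf, w, h, w, h, np.inf],
            ),
            maxfev=5000,
        )
    except RuntimeError:
        return ClusterFit(
            centroid=(float("nan"), float("nan")),
            sigma_x=float("nan"), sigma_y=float("nan"), diameter=float("nan"),
            amplitude=float("nan"), background=float("nan"),
            residual=float("nan"), converged=False,
        )
    amp, cx, cy, sx, sy, bg = popt
    resid = patch.ravel() - model((xx.ravel(), yy.ravel()), *popt)
    sigma_x = float(sx * pixel_size_um)
    sigma_y = float(sy * pixel_size_um)
    return ClusterFit(
        centroid=(float(cx * pixel_size_um), float(cy * pixel_size_um)),
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        diameter=sigma_x + sigma_y,  # 2 * mean(sigma_x, sigma_y)
        amplitude=float(amp),
        background=float(bg),
        residual=float(np.sum(resid**2)),
        converged=True,
    )


def cluster_density(first_frame_spots: list[Spot], cell_area_um2: float) -> float:
    """Cluster density: first-frame spot count per µm² of cell area."""
    if cell_area_um2 <= 0:
        raise InvalidParameterError("cell area must be > 0")
    return len(first_frame_spots) / cell_area_um2
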