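"""From raw 4D movies to per-centriole intensity time series.

The processing chain follows the fixed order: maximum-intensity
projection of each z-stack, exponential bleach correction of the
projected movie, rolling-ball background subtraction (default radius 10
px), Laplacian-of-Gaussian spot detection at the centriole diameter
(default 1.1 um), and greedy nearest-neighbour frame-to-frame linking
with no gap closing.  Only tracks covering the whole analysis window
(e.g. cycle start to nuclear envelope breakdown) enter the kinetics;
intensities are measured as the mean pixel value in a disk of the
detection diameter around the sub-pixel spot position.

Coordinates: origin at the image top-left, x rightward, y downward,
pixel centres at (index + 0.5) * pixel_size, positions in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.morphology import disk

from centrikit.series import CentrioleSeries

__all__ = [
    "SpotTrack",
    "max_project",
    "bleach_correct",
    "rolling_ball",
    "detect_spots",
    "link_tracks",
    "extract_intensity",
    "average_centriole_image",
    "normalize_and_align",
]


@dataclass
class SpotTrack:
    """A linked spot trajectory over consecutive frames (no gaps)."""

    frames: np.ndarray  # consecutive frame indices
    x: np.ndarray  # um
    y: np.ndarray  # um
    intensities: Optional[np.ndarray] = None
    complete: bool = False
    track_id: int = -1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the slice axis of one ``(slices, y, x)`` stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (slices, y, x) stack")
    return stack.max(axis=0)


def bleach_correct(movie: np.ndarray, min_frames: int = 5) -> tuple[np.ndarray, dict]:
    """Exponential bleach correction of a projected 2D movie.

    Frame means are fitted with ``a * exp(-b * t) + c`` (t in frames);
    each frame is divided by ``fit(t) / fit(0)``.  If the means do not
    decay the rate is clamped at zero and the movie returned unchanged
    with a warning entry in the returned fit info.
    """

    movie = np.asarray(movie, dtype=float)
    n = movie.shape[0]
    if n < min_frames:
        raise ValueError(f"need at least {min_frames} frames")
    t = np.arange(n, dtype=float)
    means = movie.mean(axis=(1, 2))

    c0 = float(means.min())
    a0 = max(float(means[0] - c0), 1e-12)
    b0 = 1.0 / max(n / 3.0, 1.0)
    model = lambda t, a, b, c: a * np.exp(-b * t) + c
    warning = ""
    try:
        popt, _ = optimize.curve_fit(
            model, t, means, p0=(a0, b0, c0),
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
        a, b, c = (float(v) for v in popt)
    except Exception:
        a, b, c = a0, 0.0, c0
        warning = "fit_failed"
    if b <= 0.0 or means[-1] >= means[0]:
        b = 0.0 if means[-1] >= means[0] else b
    if b == 0.0:
        if not warning:
            warning = "non_decaying"
        return movie.copy(), {"a": a, "b": 0.0, "c": c, "warning": warning}
    fit = model(t, a, b, c)
    corrected = movie * (fit[0] / fit)[:, None, None]
    return corrected, {"a": a, "b": b, "c": c, "warning": warning}


def rolling_ball(image: np.ndarray, radius: int = 10) -> np.ndarray:
    """Rolling-ball background subtraction (default radius 10 px).

    The background is a grayscale opening with a flat disk structuring
    element of the given radius — the morphological form of the rolling
    ball that is exactly idempotent and anti-extensive, so the output is
    in [0, input] everywhere, a constant image maps to zeros, and
    features narrower than the disk are fully preserved.
    """

    if radius < 1:
        raise ValueError("radius must be >= 1")
    image = np.asarray(image, dtype=float)
    background = ndimage.grey_opening(image, footprint=disk(radius), mode="nearest")
    return np.clip(image - background, 0.0, None)


def detect_spots(
    image: np.ndarray,
    diameter: float = 1.1,
    pixel_size: float = 0.2,
    quality_threshold: Optional[float] = None,
) -> list[tuple[float, float, float]]:
    """Laplacian-of-Gaussian spot detection with sub-pixel refinement.

    The LoG scale is ``sigma = diameter / (2 sqrt(2))``; local maxima of
    the scale-normalized response above ``quality_threshold`` (default:
    three robust standard deviations of the response) are refined by
    per-axis quadratic interpolation.  Returns ``(x_um, y_um, quality)``
    tuples.
    """

    if diameter <= 2 * pixel_size:
        raise ValueError("diameter must exceed two pixels")
    image = np.asarray(image, dtype=float)
    sigma_px = diameter / (2.0 * math.sqrt(2.0)) / pixel_size
    resp = -(sigma_px ** 2) * ndimage.gaussian_laplace(image, sigma_px)
    if quality_threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med))
        quality_threshold = float(med + 3.0 * 1.4826 * mad)
    footprint_max = ndimage.maximum_filter(resp, size=3, mode="nearest")
    peaks = (resp == footprint_max) & (resp > quality_threshold)
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False
    out = []
    for iy, ix in zip(*np.nonzero(peaks)):
        dx = dy = 0.0
        den_x = resp[iy, ix - 1] - 2 * resp[iy, ix] + resp[iy, ix + 1]
        if den_x < 0:
            dx = 0.5 * (resp[iy, ix - 1] - resp[iy, ix + 1]) / den_x
        den_y = resp[iy - 1, ix] - 2 * resp[iy, ix] + resp[iy + 1, ix]
        if den_y < 0:
            dy = 0.5 * (resp[iy - 1, ix] - resp[iy + 1, ix]) / den_y
        out.append(
            (
                (ix + 0.5 + np.clip(dx, -0.5, 0.5)) * pixel_size,
                (iy + 0.5 + np.clip(dy, -0.5, 0.5)) * pixel_size,
                float(resp[iy, ix]),
            )
        )
    out.sort(key=lambda d: (-d[2], d[0], d[1]))
    return out


def link_tracks(
    detections: Sequence[Sequence[tuple[float, float, float]]],
    max_disp: float = 0.5,
    full_window: Optional[tuple[int, int]] = None,
) -> list[SpotTrack]:
    """Greedy nearest-neighbour linking with no gap closing.

    Candidate links between frame f and f+1 are sorted by distance
    (ties broken deterministically by lower track then detection index)
    and accepted greedily within ``max_disp``.  Unlinked detections
    start new tracks; a track that misses a frame ends there.  A track
    is ``complete`` when it spans ``full_window`` (default: first to
    last frame of the movie).
    """

    n_frames = len(detections)
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if full_window is None:
        full_window = (0, n_frames - 1)

    tracks: list[dict] = []
    active: list[int] = []
    for i, (x, y, _q) in enumerate(detections[0]):
        tracks.append({"frames": [0], "x": [x], "y": [y]})
        active.append(i)
    for f in range(1, n_frames):
        dets = detections[f]
        candidates = []
        for ai, ti in enumerate(active):
            tx, ty = tracks[ti]["x"][-1], tracks[ti]["y"][-1]
            for di, (x, y, _q) in enumerate(dets):
                dist = math.hypot(x - tx, y - ty)
                if dist <= max_disp:
                    candidates.append((dist, ai, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        next_active: list[int] = []
        for dist, ai, di in candidates:
            if ai in used_tracks or di in used_dets:
                continue
            used_tracks.add(ai)
            used_dets.add(di)
            ti = active[ai]
            tracks[ti]["frames"].append(f)
            tracks[ti]["x"].append(dets[di][0])
            tracks[ti]["y"].append(dets[di][1])
            next_active.append(ti)
        for di, (x, y, _q) in enumerate(dets):
            if di not in used_dets:
                tracks.append({"frames": [f], "x": [x], "y": [y]})
                next_active.append(len(tracks) - 1)
        active = next_active

    out = []
    for tid, tr in enumerate(tracks):
        complete = tr["frames"][0] <= full_window[0] and tr["frames"][-1] >= full_window[1]
        out.append(
            SpotTrack(
                frames=np.asarray(tr["frames"]),
                x=np.asarray(tr["x"]),
                y=np.asarray(tr["y"]),
                complete=complete,
                track_id=tid,
            )
        )
    return out


def extract_intensity(
    movie: np.ndarray,
    track: SpotTrack,
    diameter: float = 1.1,
    pixel_size: float = 0.2,
) -> np.ndarray:
    """Mean pixel value in a disk of ``diameter`` at each track position.

    Requires a complete track; the aperture is centred at the sub-pixel
    position and includes pixels whose centres fall within the radius.
    The result is also stored on ``track.intensities``.
    """

    if not track.complete:
        raise ValueError("intensity extraction requires a complete track")
    movie = np.asarray(movie, dtype=float)
    ny, nx = movie.shape[1:]
    r = diameter / 2.0
    yy = (np.arange(ny) + 0.5) * pixel_size
    xx = (np.arange(nx) + 0.5) * pixel_size
    vals = np.empty(len(track), dtype=float)
    for i, f in enumerate(track.frames):
        mask = (xx[None, :] - track.x[i]) ** 2 + (yy[:, None] - track.y[i]) ** 2 <= r ** 2
        vals[i] = movie[f][mask].mean() if np.any(mask) else 0.0
    track.intensities = vals
    return vals


def average_centriole_image(
    movie: np.ndarray,
    tracks: Sequence[SpotTrack],
    window: int = 15,
    pixel_size: float = 0.2,
) -> np.ndarray:
    """Average centriole-centred crops per timepoint over all tracks.

    Crops of ``window`` pixels (odd) are cut around each complete
    track's nearest-pixel position; the mean over tracks at each frame
    is returned as a ``(n_frames, window, window)`` stack.  Crops that
    would extend past the image edge are skipped for that track/frame.
    """

    if window % 2 == 0:
        raise ValueError("window must be odd")
    complete = [t for t in tracks if t.complete]
    if not complete:
        raise ValueError("no complete tracks")
    movie = np.asarray(movie, dtype=float)
    n_frames, ny, nx = movie.shape
    half = window // 2
    out = np.zeros((n_frames, window, window))
    counts = np.zeros(n_frames)
    for tr in complete:
        for i, f in enumerate(tr.frames):
            # pixel centres sit at (index + 0.5) * pixel_size
            ix = int(round(tr.x[i] / pixel_size - 0.5))
            iy = int(round(tr.y[i] / pixel_size - 0.5))
            if ix - half < 0 or iy - half < 0 or ix + half >= nx or iy + half >= ny:
                continue
            out[f] += movie[f, iy - half : iy + half + 1, ix - half : ix + half + 1]
            counts[f] += 1
    nonzero = counts > 0
    out[nonzero] /= counts[nonzero, None, None]
    return out


def normalize_and_align(
    series: Sequence[CentrioleSeries],
    annotations: dict[str, dict[str, float]],
    anchor: str = "NEB",
    reference: Optional[float] = None,
) -> tuple[list[CentrioleSeries], float]:
    """Normalize to the WT first-timepoint mean and align to an event.

    All intensities are divided by ``reference`` (if None, the mean
    first-timepoint intensity of the given series set — pass the WT set
    first and reuse the returned value for mutants); time axes are
    shifted so the ``anchor`` event of each embryo maps to t = 0.
    Raises ``KeyError`` naming any embryo without an annotation.
    """

    if reference is None:
        firsts = [s.intensities[0] for s in series]
        if not firsts:
            raise ValueError("empty series set")
        reference = float(np.mean(firsts))
    if reference == 0:
        raise ValueError("zero normalization reference")
    out = []
    for s in series:
        if s.embryo_id not in annotations:
            raise KeyError(f"missing event annotations for embryo {s.embryo_id!r}")
        events = annotations[s.embryo_id]
        if anchor not in events:
            raise KeyError(f"missing event {anchor!r} for embryo {s.embryo_id!r}")
        shifted = s.shifted(events[anchor], anchor=anchor)
        out.append(shifted.scaled(1.0 / reference))
    return out, reference
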