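"""Quantification of polarity-spot movies and photobleaching traces.

Implements the measurement pipeline used on two-channel time-lapse movies of
polarizing cells: threshold-based spot segmentation, greedy nearest-neighbor
tracking with optional blink bridging, background-corrected intensity traces
in a circular "vicinity" around each tracked spot, coexistence-time scoring
of multi-spot intermediates, FLIP trace normalization, FRAP recovery
half-time fitting with a double-exponential model, and multi-cluster
frequency scoring across a cell cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import label, regionprops

__all__ = [
    "ImageStack",
    "Spot",
    "SpotTrack",
    "IntensityTrace",
    "CoexistenceOutcome",
    "segment_spots",
    "track_spots",
    "vicinity_trace",
    "coexistence_time",
    "flip_normalize",
    "frap_halftime",
    "cortical_to_internal_ratio",
    "multi_cluster_fraction",
]


@dataclass
class ImageStack:
    """A two-(or one-)channel time-lapse stack.

    ``data`` is indexed (frame, channel, y, x); intensities are arbitrary
    camera units, non-negative.
    """

    data: np.ndarray
    frame_interval: float          # s
    pixel_size: float = 1.0        # um/px
    channel_names: tuple = ("ch1", "ch2")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (frame, channel, y, x)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    # multi-page TIFF (frame-major, channel pages) + sidecar metadata
    def to_tiff(self, path) -> None:
        import json

        import tifffile

        path = Path(path)
        pages = self.data.reshape(-1, *self.data.shape[2:]).astype(np.float32)
        tifffile.imwrite(path, pages)
        meta = {"frame_interval": self.frame_interval,
                "pixel_size": self.pixel_size,
                "n_channels": self.n_channels,
                "channel_names": list(self.channel_names)}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        import json

        import tifffile

        path = Path(path)
        pages = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        nc = int(meta["n_channels"])
        data = pages.reshape(-1, nc, *pages.shape[1:])
        return cls(data, meta["frame_interval"], meta["pixel_size"],
                   tuple(meta["channel_names"]))


@dataclass
class Spot:
    """One segmented spot in one frame."""

    frame: int
    centroid: tuple                # (y, x) px, intensity-weighted
    area: float                    # px^2
    intensity: float               # summed intensity


@dataclass
class SpotTrack:
    """A spot followed through the movie."""

    track_id: int
    spots: dict = field(default_factory=dict)     # frame -> Spot

    @property
    def frames(self) -> list:
        return sorted(self.spots)

    @property
    def birth(self) -> int:
        return min(self.spots)

    @property
    def death(self) -> int:
        return max(self.spots)

    def __len__(self) -> int:
        return len(self.spots)

    def centroid_at(self, frame: int) -> tuple:
        """Centroid at ``frame``, or at the nearest frame where the spot was
        seen (constant extrapolation across gaps and past the ends)."""
        if frame in self.spots:
            return self.spots[frame].centroid
        nearest = min(self.spots, key=lambda f: abs(f - frame))
        return self.spots[nearest].centroid


@dataclass
class IntensityTrace:
    """Background-corrected vicinity intensity per frame and channel."""

    times: np.ndarray              # s
    values: np.ndarray             # (n_frames, n_channels)
    background: np.ndarray         # per-channel background level used
    statistic: str
    normalized: bool = False

    def normalize_percent_max(self) -> "IntensityTrace":
        """Express each channel as percent of its maximum over the trace."""
        peak = np.nanmax(self.values, axis=0)
        peak = np.where(peak > 0, peak, np.nan)
        return IntensityTrace(self.times, 100.0 * self.values / peak,
                              self.background, self.statistic, normalized=True)


def segment_spots(frame: np.ndarray, cell_threshold: float,
                  spot_threshold: float, filter_size_px2: float = 0.0,
                  frame_index: int = 0) -> list[Spot]:
    """Detect polarity spots in a single frame.

    The lower threshold separates cells from background; the higher one
    defines polarity spots within the cell mask.  Connected components of
    the spot mask with area >= ``filter_size_px2`` are returned (the filter
    size excludes small noise speckles), sorted by summed intensity,
    descending.
    """
    if spot_threshold <= cell_threshold:
        raise ValueError("spot_threshold must exceed cell_threshold")
    frame = np.asarray(frame, dtype=float)
    cell_mask = frame > cell_threshold
    spot_mask = (frame > spot_threshold) & cell_mask
    lbl = label(spot_mask, connectivity=2)
    spots = []
    for region in regionprops(lbl, intensity_image=frame):
        if region.area < filter_size_px2:
            continue
        cy, cx = region.centroid_weighted
        spots.append(Spot(frame=frame_index, centroid=(float(cy), float(cx)),
                          area=float(region.area),
                          intensity=float(region.image_intensity.sum())))
    spots.sort(key=lambda s: -s.intensity)
    return spots


def _dist(a: tuple, b: tuple) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def track_spots(frames_spots: list[list[Spot]], target_radius_px: float,
                remove_blinking: bool = False,
                max_gap: int = 2) -> list[SpotTrack]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Each spot at frame t+1 is linked to the nearest active track whose last
    centroid lies within ``target_radius_px``.  Spots are processed in
    descending intensity; conflicts resolve in favour of the brighter spot,
    ties by lowest track id.  With ``remove_blinking``, a track that missed
    up to ``max_gap`` consecutive frames may capture a reappearing spot
    within the same radius; otherwise unmatched spots start new tracks.
    """
    if target_radius_px <= 0:
        raise ValueError("target radius must be positive")
    tracks: list[SpotTrack] = []
    next_id = 0
    for t, spots in enumerate(frames_spots):
        claimed: set[int] = set()
        for spot in sorted(spots, key=lambda s: -s.intensity):
            best = None
            for tr in tracks:
                if tr.track_id in claimed:
                    continue
                last = tr.death
                gap = t - last - 1
                if gap < 0:
                    continue
                allowed_gap = max_gap if remove_blinking else 0
                if gap > allowed_gap:
                    continue
                d = _dist(spot.centroid, tr.spots[last].centroid)
                if d <= target_radius_px:
                    key = (d, tr.track_id)
                    if best is None or key < best[0]:
                        best = (key, tr)
            if best is not None:
                best[1].spots[t] = spot
                claimed.add(best[1].track_id)
            else:
                tr = SpotTrack(track_id=next_id, spots={t: spot})
                next_id += 1
                tracks.append(tr)
                claimed.add(tr.track_id)
    return tracks


def _circle_mask(shape: tuple, center: tuple, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    # a pixel belongs to the circle when its center lies within the radius
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def vicinity_trace(stack: ImageStack, track: SpotTrack, radius_px: float,
                   statistic: str = "mean",
                   cell_threshold: float | None = None,
                   normalize: bool = False) -> IntensityTrace:
    """Per-frame, per-channel intensity in the circular vicinity of a track.

    The statistic ("mean" or "sum") is taken over the non-background pixels
    (above ``cell_threshold`` when given, else all pixels) inside the circle
    centered on the track centroid; across gaps the last known centroid is
    used.  The background — the mean in-cell intensity one frame before the
    spot was first detected, or the per-frame cell-interior median when the
    track exists from frame 0 — is subtracted.  With ``normalize`` the trace
    is returned as percent of its per-channel maximum.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    if len(track) == 0:
        raise ValueError("track has no spots")
    nf, nc = stack.n_frames, stack.n_channels
    shape = stack.data.shape[2:]

    background = np.zeros(nc)
    ref = track.birth - 1
    for c in range(nc):
        if ref >= 0:
            img = stack.data[ref, c]
            mask = img > cell_threshold if cell_threshold is not None else np.ones_like(img, bool)
            background[c] = float(img[mask].mean()) if mask.any() else 0.0
        else:
            img = stack.data[track.birth, c]
            mask = img > cell_threshold if cell_threshold is not None else np.ones_like(img, bool)
            background[c] = float(np.median(img[mask])) if mask.any() else 0.0

    values = np.full((nf, nc), np.nan)
    for t in range(nf):
        center = track.centroid_at(t)
        circ = _circle_mask(shape, center, radius_px)
        for c in range(nc):
            img = stack.data[t, c]
            sel = circ
            if cell_threshold is not None:
                sel = circ & (img > cell_threshold)
            if not sel.any():
                values[t, c] = 0.0
                continue
            vals = img[sel] - background[c]
            values[t, c] = float(vals.mean() if statistic == "mean" else vals.sum())

    times = np.arange(nf) * stack.frame_interval
    trace = IntensityTrace(times, values, background, statistic)
    return trace.normalize_percent_max() if normalize else trace


@dataclass
class CoexistenceOutcome:
    """Coexistence scoring of a per-frame spot-count series."""

    seconds: float | None          # None when undefined or censored
    defined: bool                  # a multi-spot episode occurred
    censored: bool                 # episode never resolved to one spot


def coexistence_time(counts, frame_interval_s: float) -> CoexistenceOutcome:
    """Interval from the first frame with more than one spot to the first
    subsequent frame with exactly one.

    Returns an undefined outcome when no frame has more than one spot, and a
    censored outcome when the multi-spot episode never resolves.
    """
    counts = np.asarray(list(counts), dtype=int)
    multi = np.nonzero(counts > 1)[0]
    if len(multi) == 0:
        return CoexistenceOutcome(seconds=None, defined=False, censored=False)
    start = int(multi[0])
    ones = np.nonzero(counts[start:] == 1)[0]
    if len(ones) == 0:
        return CoexistenceOutcome(seconds=None, defined=True, censored=True)
    return CoexistenceOutcome(
        seconds=float(ones[0]) * frame_interval_s, defined=True, censored=False)


def flip_normalize(I_focus, I_neighbor, I_background):
    """Photobleaching-corrected loss trace:
    ``(I_focus - I_background) / (I_neighbor - I_background)``.

    The neighbor-cell trace corrects for indirect bleaching during repeated
    cytoplasmic bleach pulses.  Frames where the denominator is not positive
    are returned as NaN.
    """
    f = np.asarray(I_focus, dtype=float)
    n = np.asarray(I_neighbor, dtype=float)
    b = np.asarray(I_background, dtype=float)
    den = n - b
    out = np.where(den > 0, (f - b) / np.where(den > 0, den, 1.0), np.nan)
    return out


def frap_halftime(trace, frame_interval_s: float, pre_bleach_frames: int,
                  background: float = 0.0) -> tuple[float, dict]:
    """Recovery half-time from a FRAP trace via a double-exponential fit.

    The trace (including >= 3 pre-bleach frames) is background-subtracted
    and normalized to the pre-bleach mean; the post-bleach recovery is fit
    with ``y0 + A1 (1 - exp(-k1 t)) + A2 (1 - exp(-k2 t))`` with
    ``k1 > k2 > 0`` and the half-time is ``ln2 / k2`` — the slower rate
    reflects membrane exchange, the faster one cytoplasmic recovery inside
    the bleach zone.  Returns ``(half_time_s, diagnostics)``; diagnostics
    flag non-convergence and rate constants at the fit bounds.
    """
    y = np.asarray(trace, dtype=float)
    if pre_bleach_frames < 3:
        raise ValueError("need at least 3 pre-bleach frames")
    if len(y) < pre_bleach_frames + 5:
        raise ValueError("too few post-bleach frames to fit")
    y = y - background
    pre = y[:pre_bleach_frames].mean()
    if pre <= 0:
        raise ValueError("pre-bleach signal must exceed background")
    yn = y / pre
    post = yn[pre_bleach_frames:]
    t = np.arange(len(post)) * frame_interval_s

    def model(t, y0, A1, A2, k_slow, dk):
        return y0 + A1 * (1 - np.exp(-(k_slow + dk) * t)) \
            + A2 * (1 - np.exp(-k_slow * t))

    span = max(t[-1], frame_interval_s)
    k0 = np.log(2.0) / (span / 4.0)
    p0 = [max(post[0], 0.0), 0.3, 0.5, k0, 10.0 * k0]
    lo = [0.0, 0.0, 0.0, 1e-6 / span, 0.0]
    hi = [1.5, 2.0, 2.0, 1e4 / frame_interval_s, 1e4 / frame_interval_s]
    try:
        popt, pcov = curve_fit(model, t, post, p0=p0, bounds=(lo, hi),
                               maxfev=20000)
    except RuntimeError as exc:
        return np.nan, {"converged": False, "message": str(exc)}
    y0, A1, A2, k_slow, dk = popt
    resid = post - model(t, *popt)
    ss_tot = float(((post - post.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan
    half = float(np.log(2.0) / k_slow)
    diag = {
        "converged": True,
        "k_fast": float(k_slow + dk),
        "k_slow": float(k_slow),
        "amplitude_fast": float(A1),
        "amplitude_slow": float(A2),
        "offset": float(y0),
        "r_squared": r2,
        "k_slow_at_bound": bool(np.isclose(k_slow, lo[3]) or np.isclose(k_slow, hi[3])),
    }
    return half, diag


def cortical_to_internal_ratio(frame: np.ndarray, cell_threshold: float,
                               rim_px: int = 2) -> float:
    """Mean rim intensity over mean interior intensity for one cell frame.

    A simple approximation of membrane-versus-cytoplasm partitioning: the
    cell mask's outer shell (``rim_px`` erosions wide) is compared with the
    remaining interior.  No membrane segmentation or geometry correction is
    attempted, so treat the value as a relative index, not a concentration
    ratio.
    """
    from scipy.ndimage import binary_erosion

    frame = np.asarray(frame, dtype=float)
    cell = frame > cell_threshold
    if not cell.any():
        raise ValueError("no pixels above the cell threshold")
    interior = binary_erosion(cell, iterations=rim_px)
    rim = cell & ~interior
    if not interior.any() or not rim.any():
        raise ValueError("cell too small for the requested rim width")
    return float(frame[rim].mean() / frame[interior].mean())


def multi_cluster_fraction(per_cell_multi, confidence: float = 0.95
                           ) -> tuple[float, tuple]:
    """Percent of cells showing more than one polarity cluster, with a
    Wilson binomial confidence interval (percent)."""
    flags = np.asarray(list(per_cell_multi), dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("empty cohort")
    k = int(flags.sum())
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return 100.0 * k / n, (100.0 * float(lo), 100.0 * float(hi))
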