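"""Fiducial ink-mark tracking by per-frame k-means color clustering.

The pipeline mirrors how applicator stability was measured in the clinic: a
small ink mark on the buccal mucosa is imaged by an endoscope fixed to the
light applicator, and the mark's centroid is tracked across the recording.
Per frame:

1. the frame's pixels are clustered in raw RGB space with k-means
   (k = 3 by default: ink mark, healthy tissue, applicator);
2. the cluster whose mean color is nearest (Euclidean, RGB) to a reference
   color — the mean color of a user-supplied region of interest on the first
   frame — is selected as the marker;
3. the largest 4-connected component of that cluster is kept and its
   unweighted pixel centroid recorded, at sub-pixel precision.

Frames where no cluster comes within ``max_color_distance`` of the reference
(e.g. the mark is occluded) are flagged invalid and excluded downstream —
never interpolated. Each frame is clustered independently; there is no
temporal model, warm start, or spatial preprocessing.

Lloyd iteration is delegated to scikit-learn, run on the frame's *unique*
RGB triples weighted by their pixel counts — algebraically identical to
Lloyd on the full pixel multiset, and much faster on quantised images.
Initial centers come from a deterministic k-means++ seeding
(:func:`kmeans_plusplus_init`) driven by the configured seed, so identical
inputs always give identical trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label
from sklearn.cluster import KMeans

from .exceptions import (
    DegenerateClusteringWarning,
    InvalidFrameError,
    InvalidParameterError,
    InvalidRoiError,
    TrackingFailureError,
)
from .frames import FrameSequence


@dataclass
class RoiSeed:
    """Axis-aligned rectangle (or explicit mask) seeding the reference color.

    ``rect`` is ``(x, y, w, h)`` in 0-based pixel coordinates on frame
    ``frame_index`` (normally 0); alternatively supply a boolean ``mask`` of
    the full frame shape.
    """

    rect: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None
    frame_index: int = 0

    def __post_init__(self):
        if (self.rect is None) == (self.mask is None):
            raise InvalidRoiError("provide exactly one of rect or mask")
        if self.rect is not None:
            x, y, w, h = self.rect
            if w <= 0 or h <= 0:
                raise InvalidRoiError(f"ROI rectangle has non-positive size: {self.rect}")

    def pixels(self, frame: np.ndarray) -> np.ndarray:
        """The (n, 3) RGB pixels the seed selects on ``frame``."""
        fh, fw = frame.shape[:2]
        if self.rect is not None:
            x, y, w, h = self.rect
            if x < 0 or y < 0 or x + w > fw or y + h > fh:
                raise InvalidRoiError(
                    f"ROI {self.rect} exceeds frame bounds ({fh}x{fw})")
            region = frame[y:y + h, x:x + w]
            return region.reshape(-1, 3)
        if self.mask.shape != (fh, fw):
            raise InvalidRoiError("ROI mask shape does not match frame")
        pts = frame[self.mask.astype(bool)]
        if pts.size == 0:
            raise InvalidRoiError("ROI mask selects no pixels")
        return pts.reshape(-1, 3)


@dataclass
class ReferenceColor:
    """Per-channel mean RGB over the seed region, plus its pixel count."""

    rgb: tuple[float, float, float]
    n_pixels: int


@dataclass
class ClusterMap:
    """Result of clustering one frame's pixels in color space.

    ``labels`` assigns every pixel to a cluster in ``[0, k)``; clusters are
    numbered in decreasing size order. ``means`` are the exact per-cluster
    averages of member pixel colors (rows of empty clusters are NaN), and
    ``inertia`` is the summed squared RGB distance of pixels to their cluster
    mean. ``degenerate`` is set when the frame had fewer distinct colors than
    k, leaving trailing empty clusters.
    """

    labels: np.ndarray
    means: np.ndarray
    k: int
    inertia: float
    sizes: np.ndarray
    degenerate: bool = False


@dataclass
class MarkerMask:
    """The selected marker cluster after connected-component cleanup."""

    mask: np.ndarray
    matched_cluster: int
    color_distance: float
    valid: bool


@dataclass
class TrackingConfig:
    """Knobs for :func:`track_sequence`; defaults follow the three-region scene."""

    k: int = 3
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-4
    max_color_distance: float = 100.0   # RGB Euclidean; reject weaker matches
    stride: int = 1                     # analyse every nth frame

    def __post_init__(self):
        if self.k < 2:
            raise InvalidParameterError("k must be >= 2")
        if self.stride < 1:
            raise InvalidParameterError("stride must be >= 1")


@dataclass
class Trajectory:
    """Per-frame marker centroids in pixel coordinates, with validity flags.

    ``centroids`` holds (x, y) with NaN rows for invalid frames;
    ``frame_indices`` maps rows back to the source frames when a stride > 1
    was used. The coordinate convention is 0-based, x = column (rightwards),
    y = row (downwards).
    """

    centroids: np.ndarray
    valid: np.ndarray
    match_distance: np.ndarray
    frame_indices: np.ndarray
    timestamps: np.ndarray
    reference: ReferenceColor | None = None
    config: TrackingConfig = field(default_factory=TrackingConfig)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame_indices,
            "time_s": self.timestamps,
            "x_px": self.centroids[:, 0],
            "y_px": self.centroids[:, 1],
            "valid": self.valid,
            "match_distance": self.match_distance,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        required = {"frame", "time_s", "x_px", "y_px", "valid"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidParameterError(f"trajectory table missing columns {sorted(missing)}")
        return cls(
            centroids=df[["x_px", "y_px"]].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            match_distance=(df["match_distance"].to_numpy(float)
                            if "match_distance" in df else
                            np.full(len(df), np.nan)),
            frame_indices=df["frame"].to_numpy(int),
            timestamps=df["time_s"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# reference color
# ---------------------------------------------------------------------------

def extract_reference_color(frames: FrameSequence, roi: RoiSeed) -> ReferenceColor:
    """Mean RGB over the ROI pixels of the seed frame."""
    if not 0 <= roi.frame_index < frames.n_frames:
        raise InvalidRoiError(f"ROI frame index {roi.frame_index} out of range")
    pts = roi.pixels(frames[roi.frame_index]).astype(float)
    if len(pts) == 0:
        raise InvalidRoiError("ROI selects no pixels")
    mean = pts.mean(axis=0)
    return ReferenceColor(tuple(float(v) for v in mean), int(len(pts)))


# ---------------------------------------------------------------------------
# k-means segmentation
# ---------------------------------------------------------------------------

def _histogram_peaks(colors: np.ndarray, counts: np.ndarray, k: int,
                     bin_width: int = 32) -> np.ndarray:
    """Dominant color modes by coarse 3D histogram with non-max suppression.

    Colors are binned at ``bin_width`` per channel; peaks are picked greedily
    by bin weight, suppressing the 3x3x3 bin neighbourhood of each pick so a
    single noisy color class (which can straddle a bin boundary) yields one
    peak, not several. Returns the weighted mean color of up to ``k`` peak
    bins — possibly fewer when the frame has fewer separated modes.
    """
    n_bins = int(np.ceil(256 / bin_width))
    bins = np.minimum((colors // bin_width).astype(np.int64), n_bins - 1)
    keys = (bins[:, 0] * n_bins + bins[:, 1]) * n_bins + bins[:, 2]
    uniq_keys, inverse = np.unique(keys, return_inverse=True)
    bin_w = np.bincount(inverse, weights=counts)
    bin_sum = np.stack(
        [np.bincount(inverse, weights=counts * colors[:, c]) for c in range(3)],
        axis=1)
    coords = np.stack([(uniq_keys // (n_bins * n_bins)) % n_bins,
                       (uniq_keys // n_bins) % n_bins,
                       uniq_keys % n_bins], axis=1)
    peaks = []
    available = bin_w.copy()
    while len(peaks) < k and available.max() > 0:
        top = int(np.argmax(available))
        peaks.append(bin_sum[top] / bin_w[top])
        near = np.abs(coords - coords[top]).max(axis=1) <= 1
        available[near] = 0.0
    return np.asarray(peaks)


def kmeans_plusplus_init(points: np.ndarray, k: int, rng: np.random.Generator,
                         weights: np.ndarray | None = None,
                         n_local_trials: int = 16) -> np.ndarray:
    """Deterministic initial centers: histogram peaks plus greedy k-means++.

    The first centers are the dominant color modes of the frame
    (:func:`_histogram_peaks`) — on an endoscope frame, typically tissue,
    applicator and ink mark. If fewer than ``k`` separated modes exist,
    the remaining centers are chosen k-means++-style: ``n_local_trials``
    candidates drawn with probability proportional to weight times squared
    distance to the nearest chosen center, keeping the candidate that most
    reduces the total potential.

    The mode seeding matters: the ink mark holds a tiny fraction of the
    pixels, and purely sampled seedings regularly leave Lloyd in a local
    optimum that splits the large tissue cluster (or chases the saturated
    highlight atom that uint8 clipping puts next to a bright applicator)
    instead of isolating the mark. Shared with the brute-force Lloyd oracle
    in the test suite so both routes iterate from identical centers.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    peaks = _histogram_peaks(points, w, k)
    centers = np.empty((k, points.shape[1]))
    n_peaks = min(len(peaks), k)
    centers[:n_peaks] = peaks[:n_peaks]
    if n_peaks == 0:
        centers[0] = points[int(np.argmax(w))]
        n_peaks = 1
    d2 = ((points[:, None, :] - centers[None, :n_peaks, :]) ** 2).sum(axis=2).min(axis=1)
    for j in range(n_peaks, k):
        prob = w * d2
        total = prob.sum()
        if total <= 0:        # all remaining points coincide with a center
            centers[j:] = centers[0]
            break
        cand = rng.choice(n, size=n_local_trials, p=prob / total)
        cand_d2 = ((points[cand, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        potentials = (w * np.minimum(d2, cand_d2)).sum(axis=1)
        best = cand[int(np.argmin(potentials))]
        centers[j] = points[best]
        d2 = np.minimum(d2, ((points - centers[j]) ** 2).sum(axis=1))
    return centers


def _unique_colors(frame: np.ndarray):
    """Unique RGB triples of a uint8 frame with counts and an inverse map."""
    flat = frame.reshape(-1, 3).astype(np.int64)
    packed = (flat[:, 0] << 16) | (flat[:, 1] << 8) | flat[:, 2]
    uniq, inverse, counts = np.unique(packed, return_inverse=True, return_counts=True)
    colors = np.stack([(uniq >> 16) & 255, (uniq >> 8) & 255, uniq & 255],
                      axis=1).astype(float)
    return colors, counts.astype(float), inverse


def segment_frame_kmeans(frame: np.ndarray, k: int = 3, seed: int = 0,
                         max_iter: int = 100, tol: float = 1e-4) -> ClusterMap:
    """Cluster one frame's pixels in RGB space by Lloyd's algorithm.

    Deterministic given ``seed``. Labels are renumbered in decreasing
    cluster-size order. If the frame has fewer than ``k`` distinct colors the
    result is flagged degenerate, with empty trailing clusters (NaN means),
    and a :class:`DegenerateClusteringWarning` is emitted.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3 or frame.size == 0:
        raise InvalidParameterError(f"expected a non-empty HxWx3 frame, got {frame.shape}")

    colors, counts, inverse = _unique_colors(frame.astype(np.uint8))
    n_unique = len(colors)
    k_eff = min(k, n_unique)
    degenerate = k_eff < k
    if degenerate:
        warnings.warn(
            f"k={k} exceeds the {n_unique} distinct colors; "
            f"{k - k_eff} empty cluster(s) returned",
            DegenerateClusteringWarning, stacklevel=2)

    rng = np.random.default_rng([seed, 0xC01])
    if k_eff == 1:
        u_labels = np.zeros(n_unique, dtype=np.int32)
    else:
        init = kmeans_plusplus_init(colors, k_eff, rng, weights=counts)
        km = KMeans(n_clusters=k_eff, init=init, n_init=1,
                    max_iter=max_iter, tol=tol, algorithm="lloyd")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # sklearn duplicate-center chatter
            km.fit(colors, sample_weight=counts)
        u_labels = km.labels_.astype(np.int32)

    # exact per-cluster means and sizes over the full pixel multiset
    sizes = np.zeros(k, dtype=np.int64)
    means = np.full((k, 3), np.nan)
    for j in range(k_eff):
        member = u_labels == j
        w = counts[member]
        sizes[j] = int(w.sum())
        if sizes[j] > 0:
            means[j] = (colors[member] * w[:, None]).sum(axis=0) / sizes[j]

    # renumber in decreasing size order (stable for ties)
    order = np.argsort(-sizes[:k_eff], kind="stable")
    remap = np.empty(k_eff, dtype=np.int32)
    remap[order] = np.arange(k_eff, dtype=np.int32)
    u_labels = remap[u_labels]
    full_order = np.concatenate([order, np.arange(k_eff, k)])
    means, sizes = means[full_order], sizes[full_order]

    inertia = 0.0
    for j in range(k_eff):
        member = u_labels == j
        if sizes[j] > 0:
            d2 = ((colors[member] - means[j]) ** 2).sum(axis=1)
            inertia += float((d2 * counts[member]).sum())

    labels = u_labels[inverse].reshape(frame.shape[:2])
    return ClusterMap(labels=labels, means=means, k=k, inertia=inertia,
                      sizes=sizes, degenerate=degenerate)


# ---------------------------------------------------------------------------
# marker selection and centroid
# ---------------------------------------------------------------------------

def select_marker_cluster(cluster_map: ClusterMap, reference: ReferenceColor,
                          max_distance: float = 100.0) -> MarkerMask:
    """Pick the cluster whose mean color is nearest the reference.

    Distance is Euclidean in RGB over non-empty clusters; ties go to the
    lower-index (i.e. larger) cluster. The largest 4-connected component of
    the winning cluster is retained. ``valid`` is False when the best
    distance exceeds ``max_distance`` or the component is empty — a per-frame
    signal, never an exception, so batch tracking can flag and continue.
    """
    ref = np.asarray(reference.rgb, dtype=float)
    nonempty = np.flatnonzero(cluster_map.sizes > 0)
    if len(nonempty) == 0:
        return MarkerMask(np.zeros_like(cluster_map.labels, dtype=bool), -1,
                          np.inf, False)
    dists = np.linalg.norm(cluster_map.means[nonempty] - ref, axis=1)
    best = int(nonempty[int(np.argmin(dists))])   # argmin takes first on ties
    best_dist = float(dists.min())

    mask = cluster_map.labels == best
    comps = _cc_label(mask, connectivity=1)
    if comps.max() > 0:
        largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
        mask = comps == largest
    valid = bool(mask.any()) and best_dist <= max_distance
    return MarkerMask(mask, best, best_dist, valid)


def centroid_of_mask(marker: MarkerMask) -> tuple[float, float]:
    """Unweighted mean pixel coordinate (x, y) of the marker mask, sub-pixel."""
    if not marker.valid or not marker.mask.any():
        raise InvalidFrameError("no valid marker mask to take a centroid of")
    rows, cols = np.nonzero(marker.mask)
    return float(cols.mean()), float(rows.mean())


# ---------------------------------------------------------------------------
# sequence tracking
# ---------------------------------------------------------------------------

def track_sequence(frames: FrameSequence, roi: RoiSeed,
                   config: TrackingConfig | None = None) -> Trajectory:
    """Track the ink mark across a frame sequence (the full pipeline).

    Extracts the reference color once from the ROI, then per analysed frame
    runs k-means segmentation, nearest-color cluster selection and centroid
    computation. Per-frame k-means seeds are split deterministically from
    ``config.seed``. Invalid frames (occlusion, weak color match) are flagged
    and carry NaN centroids. Raises :class:`TrackingFailureError` when more
    than half of the analysed frames are invalid.
    """
    config = config or TrackingConfig()
    reference = extract_reference_color(frames, roi)

    idx = np.arange(0, frames.n_frames, config.stride)
    centroids = np.full((len(idx), 2), np.nan)
    valid = np.zeros(len(idx), dtype=bool)
    distances = np.full(len(idx), np.nan)

    failure_causes: list[str] = []
    for row, i in enumerate(idx):
        cmap = segment_frame_kmeans(frames[i], k=config.k,
                                    seed=int((config.seed + 7919 * int(i)) % (2 ** 31)),
                                    max_iter=config.max_iter, tol=config.tol)
        marker = select_marker_cluster(cmap, reference, config.max_color_distance)
        distances[row] = marker.color_distance
        if marker.valid:
            try:
                centroids[row] = centroid_of_mask(marker)
                valid[row] = True
            except InvalidFrameError:
                failure_causes.append(f"frame {i}: empty marker component")
        else:
            failure_causes.append(
                f"frame {i}: best color distance {marker.color_distance:.1f} "
                f"> {config.max_color_distance:g}" if np.isfinite(marker.color_distance)
                else f"frame {i}: all clusters empty")

    if valid.sum() < 0.5 * len(idx):
        detail = "; ".join(failure_causes[:10])
        raise TrackingFailureError(
            f"{len(idx) - valid.sum()}/{len(idx)} frames invalid: {detail}")

    return Trajectory(centroids=centroids, valid=valid, match_distance=distances,
                      frame_indices=idx, timestamps=frames.timestamps[idx],
                      reference=reference, config=config)
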