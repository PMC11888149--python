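"""Representative-frame selection via CIELAB color histograms and K-means.

Each frame is summarised by a 3-D color histogram in CIELAB (8 bins per
channel by default, 512 bins total), flattened to a feature vector.  K-means
groups the corpus into K clusters of similar color composition; one frame
per cluster, drawn at random, forms the model-fitting subset and the
complement is the evaluation subset.  This spends a tiny annotation budget
(K frames) while still covering the corpus's color variability.

Histograms use fixed absolute bin ranges (L: [0, 100], a/b: [-128, 127]) so
features remain comparable across frames, and are L1-normalised by default
so corpora with mixed resolutions are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .image_io import validate_image

__all__ = [
    "HistogramFeature",
    "ClusterAssignment",
    "ClusteringError",
    "rgb_to_cielab",
    "histogram_3d",
    "cluster_frames",
    "select_representatives",
]

# fixed absolute Lab ranges; per-image ranges would destroy cross-image
# color correspondence
_LAB_RANGES = ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0))


class ClusteringError(RuntimeError):
    """Raised when K-means cannot produce K non-empty, distinct clusters."""


@dataclass(frozen=True)
class HistogramFeature:
    """Flattened 3-D CIELAB histogram of one frame.

    ``counts`` has length ``bins_per_channel ** 3``, flattened L-major
    (then a, then b).  If ``normalized``, entries sum to 1; otherwise to
    the number of counted pixels.
    """

    counts: np.ndarray
    bins_per_channel: int = 8
    normalized: bool = True

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.bins_per_channel**3,):
            raise ValueError(
                f"feature length {counts.shape} != bins^3 = {self.bins_per_channel ** 3}"
            )
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of clustering a corpus of histogram features."""

    labels: np.ndarray  # per-frame cluster index in [0, k)
    k: int
    centroids: np.ndarray  # k x bins^3
    seed: int
    inertia: float = field(default=float("nan"))


def rgb_to_cielab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to CIELAB (sRGB companding, D65 white).

    Returns an H x W x 3 float array with L in [0, 100] and a, b roughly in
    [-128, 127].
    """
    return rgb2lab(validate_image(image))


def histogram_3d(
    lab: np.ndarray,
    bins_per_channel: int = 8,
    fov: np.ndarray | None = None,
    normalize: bool = True,
) -> HistogramFeature:
    """3-D color histogram of a Lab frame over fixed absolute ranges.

    Parameters
    ----------
    lab
        H x W x 3 CIELAB array from :func:`rgb_to_cielab`.
    bins_per_channel
        Uniform bins per channel (>= 2); the feature has ``bins**3`` entries.
    fov
        Optional boolean mask restricting which pixels are counted.
    normalize
        L1-normalise counts so frames of different sizes are comparable.
    """
    if bins_per_channel < 2:
        raise ValueError(f"bins_per_channel must be >= 2, got {bins_per_channel}")
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 Lab array, got {lab.shape}")
    pixels = lab.reshape(-1, 3)
    if fov is not None:
        pixels = pixels[np.asarray(fov, dtype=bool).ravel()]
    # clip into the fixed ranges so out-of-gamut round-off lands in edge bins
    lo = np.array([r[0] for r in _LAB_RANGES])
    hi = np.array([r[1] for r in _LAB_RANGES])
    pixels = np.clip(pixels, lo, hi)
    hist, _ = np.histogramdd(pixels, bins=bins_per_channel, range=_LAB_RANGES)
    counts = hist.ravel(order="C")  # L-major, then a, then b
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return HistogramFeature(counts, bins_per_channel, normalize)


def _feature_matrix(features: list[HistogramFeature]) -> np.ndarray:
    lengths = {f.counts.shape[0] for f in features}
    if len(lengths) != 1:
        raise ValueError(f"features have mixed lengths {sorted(lengths)}")
    return np.stack([f.counts for f in features])


def cluster_frames(
    features: list[HistogramFeature],
    k: int = 20,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterAssignment:
    """K-means over histogram features (k-means++ init, Euclidean metric).

    Deterministic given ``seed``.  Raises :class:`ClusteringError` when the
    corpus cannot support K distinct non-empty clusters (e.g. duplicated
    features), advising a smaller K.
    """
    x = _feature_matrix(features)
    if len(features) < k:
        raise ValueError(f"need at least k={k} frames, got {len(features)}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ClusteringError(
            f"only {np.unique(x, axis=0).shape[0]} distinct features for k={k}; use a smaller k"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(x)
    if np.unique(labels).shape[0] != k:
        raise ClusteringError(f"K-means left an empty cluster at k={k}; use a smaller k")
    return ClusterAssignment(labels=labels, k=k, centroids=km.cluster_centers_, seed=seed, inertia=float(km.inertia_))


def select_representatives(assignment: ClusterAssignment, seed: int = 0) -> list[int]:
    """Pick one frame per cluster, uniformly at random within each cluster.

    Returns K frame indices (the model-fitting subset, in cluster order);
    the complement of the corpus is the evaluation subset.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(assignment.k):
        members = np.flatnonzero(assignment.labels == c)
        chosen.append(int(rng.choice(members)))
    return chosen
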