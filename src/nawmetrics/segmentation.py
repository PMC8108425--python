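"""Tissue classification in standardized bivariate intensity space.

After intensity standardization every voxel's (T1w, FLAIR) pair lives in
the reference intensity space, where CSF, GM, WM and lesion form partially
overlapping clusters around known centroids.  Classification is a
k-means-like iteration: voxels are assigned to the nearest class centroid
under a bin-width-scaled Euclidean distance, CSF/GM/WM centroids are
recomputed from their assignments, and the LESION centroid stays frozen at
its atlas prior (lesions are rare or absent in many subjects; a free
lesion centroid collapses onto WM).  A conservative rule then relabels
FLAIR-hyperintense, ambiguous voxels as lesion, so that the surviving WM
voxels are unconfounded normal-appearing tissue.

Label codes: 0 background, 1 CSF, 2 GM, 3 WM, 4 LESION.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .histogram import ReferenceAtlas
from .io_prep import VolumePair

__all__ = [
    "CLASS_CODES",
    "TissueLabelMap",
    "LesionMetrics",
    "SegmentationOptions",
    "classify_tissues",
    "exclude_lesions",
    "lesion_metrics",
]

CLASS_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4}
_KMEANS_CLASSES = ("csf", "gm", "wm", "lesion")  # assignment order = code order


@dataclass
class TissueLabelMap:
    """Voxelwise class assignment plus an optional analysis-exclusion mask.

    ``excluded`` marks voxels dropped from downstream parameter fitting
    (lesion exclusion) without reassigning their label, so the partition
    into classes is preserved and the exclusion is tracked separately.
    """

    labels: np.ndarray
    class_counts: dict[str, int] = field(default_factory=dict)
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if not self.class_counts:
            self.class_counts = {
                name: int((self.labels == code).sum())
                for name, code in CLASS_CODES.items()
                if name != "background"
            }

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def count(self, name: str) -> int:
        return self.class_counts.get(name, 0)

    def copy(self) -> "TissueLabelMap":
        return TissueLabelMap(
            labels=self.labels.copy(),
            class_counts=dict(self.class_counts),
            excluded=None if self.excluded is None else self.excluded.copy(),
        )


@dataclass
class LesionMetrics:
    """Lesion burden summaries.

    ``lesion_intensity`` is the mean lesion score over lesion voxels,
    u_lv = (1/n_L) * sum_{v in L} u_l(v), where the per-voxel score u_l is
    the voxel's FLAIR elevation above the WM centroid in units of the
    WM-to-lesion-centroid FLAIR gap (clipped at 0).  It is None when the
    subject has no lesion voxels.
    """

    lesion_volume_ml: float
    lesion_intensity: float | None
    n_lesion_voxels: int


@dataclass(frozen=True)
class SegmentationOptions:
    """Iteration and conservative-lesion-rule settings.

    ``lesion_flair_fraction``: a voxel is lesion-eligible when its FLAIR
    intensity exceeds the WM centroid by more than this fraction of the
    WM-to-lesion FLAIR gap.  Lowering it is more conservative (more voxels
    swept into the lesion class).  ``lesion_ambiguity_ratio``: the voxel
    must additionally be ambiguous, i.e. the ratio of its distances to the
    two nearest centroids exceeds this value.
    """

    max_iterations: int = 100
    centroid_tol: float = 1e-3  # bin widths
    lesion_flair_fraction: float = 0.5
    lesion_ambiguity_ratio: float = 0.8
    min_component_voxels: int = 0  # optional 26-connectivity size filter


def _scaled_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n_voxels, n_classes) Euclidean distances in scaled space."""
    diff = points[:, None, :] - centroids[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def classify_tissues(
    pair: VolumePair,
    atlas: ReferenceAtlas,
    opts: SegmentationOptions | None = None,
) -> TissueLabelMap:
    """Assign every in-mask voxel of a standardized pair to a tissue class.

    Deterministic: centroids start at the atlas loci, assignment ties
    break toward the lower class code, and no randomness is involved.
    Emits an empty-class warning when a class ends with zero voxels and a
    non-convergence warning if centroids are still moving at the
    iteration cap.
    """
    opts = opts or SegmentationOptions()
    mask = pair.brain_mask
    scale = np.array([atlas.binning.bin_width_t1, atlas.binning.bin_width_flair])
    pts = np.column_stack([pair.t1w[mask], pair.flair[mask]]) / scale
    centroids = atlas.centroid_array(_KMEANS_CLASSES) / scale

    assign = np.zeros(len(pts), dtype=np.int64)
    converged = False
    for _ in range(opts.max_iterations):
        d = _scaled_distances(pts, centroids)
        assign = np.argmin(d, axis=1)  # ties -> first (lower class code)
        new_centroids = centroids.copy()
        for k, name in enumerate(_KMEANS_CLASSES):
            if name == "lesion":
                continue  # frozen at the atlas prior
            sel = assign == k
            if sel.any():
                new_centroids[k] = pts[sel].mean(axis=0)
        motion = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if motion <= opts.centroid_tol:
            converged = True
            break
    if not converged:
        warnings.warn("tissue classification hit the iteration cap", stacklevel=2)

    # conservative lesion rule: FLAIR-hyperintense AND ambiguous voxels
    # are relabeled lesion so remaining WM is unconfounded NAWM
    wm_fl = centroids[_KMEANS_CLASSES.index("wm"), 1]
    les_fl = centroids[_KMEANS_CLASSES.index("lesion"), 1]
    gap = les_fl - wm_fl
    fl_threshold = wm_fl + opts.lesion_flair_fraction * gap
    d = _scaled_distances(pts, centroids)
    two = np.partition(d, 1, axis=1)[:, :2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(two[:, 1] > 0, two[:, 0] / two[:, 1], 1.0)
    hyper = pts[:, 1] > fl_threshold
    ambiguous = ratio > opts.lesion_ambiguity_ratio
    assign[hyper & ambiguous] = _KMEANS_CLASSES.index("lesion")

    labels = np.zeros(pair.t1w.shape, dtype=np.int16)
    labels[mask] = assign + 1  # class codes are 1-based

    if opts.min_component_voxels > 1:
        labels = _filter_small_lesions(labels, opts.min_component_voxels)

    lm = TissueLabelMap(labels=labels)
    for name in ("csf", "gm", "wm", "lesion"):
        if lm.count(name) == 0:
            warnings.warn(f"empty tissue class: {name}", stacklevel=2)
    return lm


def _filter_small_lesions(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    """Reassign lesion components smaller than min_voxels to WM (26-conn)."""
    from scipy.ndimage import label as cc_label

    lesion = labels == CLASS_CODES["lesion"]
    comp, n = cc_label(lesion, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return labels
    sizes = np.bincount(comp.ravel())
    small = np.isin(comp, np.flatnonzero(sizes < min_voxels)[1:])
    out = labels.copy()
    out[small & lesion] = CLASS_CODES["wm"]
    return out


def exclude_lesions(labels: TissueLabelMap) -> TissueLabelMap:
    """Mark lesion voxels as excluded from analysis without relabeling them."""
    out = labels.copy()
    out.excluded = out.labels == CLASS_CODES["lesion"]
    return out


def lesion_metrics(
    labels: TissueLabelMap,
    pair: VolumePair,
    atlas: ReferenceAtlas,
) -> LesionMetrics:
    """Lesion volume (mL) and the mean standardized lesion score u_lv."""
    lesion = labels.labels == CLASS_CODES["lesion"]
    n = int(lesion.sum())
    volume_ml = n * pair.voxel_volume_mm3 / 1000.0
    if n == 0:
        return LesionMetrics(lesion_volume_ml=0.0, lesion_intensity=None, n_lesion_voxels=0)
    wm_fl = atlas.class_centroids["wm"][1]
    les_fl = atlas.class_centroids["lesion"][1]
    u = np.clip((pair.flair[lesion] - wm_fl) / (les_fl - wm_fl), 0.0, None)
    return LesionMetrics(
        lesion_volume_ml=volume_ml,
        lesion_intensity=float(u.mean()),
        n_lesion_voxels=n,
    )
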