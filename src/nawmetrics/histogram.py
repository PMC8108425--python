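"""Bivariate (T1w x FLAIR) intensity histograms and the normative atlas.

The central object of the standardization technique is the 2D histogram of
paired in-brain (T1w, FLAIR) voxel intensities.  Tissue classes (CSF, GM,
WM) appear as modes of this histogram; in a typical control the marginal
peaks sit near T1w 200/600/1000 (CSF/GM/WM) and FLAIR 200/700/1100
(CSF/WM/GM) scanner units.  A normative reference is the mean of the
normalized histograms of a control cohort, with class centroids located by
seeded mode-finding; subject histograms are later affine-registered to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_prep import PairedIntensities

__all__ = [
    "BinningSpec",
    "BivariateHistogram",
    "ReferenceAtlas",
    "BinningMismatchError",
    "CentroidOrderingError",
    "DEFAULT_CONTROL_LOCI",
    "build_bivariate_histogram",
    "marginalize",
    "build_reference_atlas",
    "save_atlas",
    "load_atlas",
]

#: Normative control peak loci in scanner units, (t1, flair) per class.
#: CSF is dark in both contrasts; WM is brightest on T1w; GM is brightest
#: on FLAIR (fluid-attenuated T2 weighting).
DEFAULT_CONTROL_LOCI: dict[str, tuple[float, float]] = {
    "csf": (200.0, 200.0),
    "gm": (600.0, 1100.0),
    "wm": (1000.0, 700.0),
}

CLASS_NAMES = ("csf", "gm", "wm", "lesion")


class BinningMismatchError(ValueError):
    """Histograms are not on the same bin grid."""


class CentroidOrderingError(ValueError):
    """Recovered class centroids violate the control intensity ordering."""


@dataclass(frozen=True)
class BinningSpec:
    """Frozen bin grid shared by every histogram registered to one atlas.

    ``range_mode='robust_percentile'`` means the ranges were set to
    [0, P99.9] of the pooled control intensities at atlas build time and
    then frozen; 'fixed' means user-supplied.
    """

    n_bins_t1: int = 256
    n_bins_flair: int = 256
    range_t1: tuple[float, float] = (0.0, 2000.0)
    range_flair: tuple[float, float] = (0.0, 2000.0)
    range_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.n_bins_t1 < 32 or self.n_bins_flair < 32:
            raise ValueError("need at least 32 bins per axis")
        if self.range_t1[1] <= self.range_t1[0] or self.range_flair[1] <= self.range_flair[0]:
            raise ValueError("hi must exceed lo on each axis")

    @classmethod
    def from_control_pool(
        cls,
        pool: list[PairedIntensities],
        n_bins_t1: int = 256,
        n_bins_flair: int = 256,
        percentile: float = 99.9,
        padding: float = 1.6,
    ) -> "BinningSpec":
        """Robust-percentile binning from the pooled control intensities.

        The range is [0, padding x P99.9] per contrast.  The head-room
        factor matters: subjects from other scanners can be globally
        brighter than every control, and intensity mass clipped into the
        boundary bin is unrecoverable by the affine registration.
        """
        t1 = np.concatenate([p.t1_values for p in pool])
        fl = np.concatenate([p.flair_values for p in pool])
        return cls(
            n_bins_t1=n_bins_t1,
            n_bins_flair=n_bins_flair,
            range_t1=(0.0, padding * float(np.percentile(t1, percentile))),
            range_flair=(0.0, padding * float(np.percentile(fl, percentile))),
            range_mode="robust_percentile",
        )

    @property
    def edges_t1(self) -> np.ndarray:
        return np.linspace(*self.range_t1, self.n_bins_t1 + 1)

    @property
    def edges_flair(self) -> np.ndarray:
        return np.linspace(*self.range_flair, self.n_bins_flair + 1)

    @property
    def bin_width_t1(self) -> float:
        return (self.range_t1[1] - self.range_t1[0]) / self.n_bins_t1

    @property
    def bin_width_flair(self) -> float:
        return (self.range_flair[1] - self.range_flair[0]) / self.n_bins_flair


@dataclass
class BivariateHistogram:
    """2D count array over (T1w, FLAIR) bins; axis 0 is T1w, axis 1 FLAIR.

    Stored raw (counts summing to ``n_total``); :meth:`normalized` returns
    the probability-mass view on demand so count-conservation stays
    checkable.
    """

    counts: np.ndarray
    bin_edges_t1: np.ndarray
    bin_edges_flair: np.ndarray
    n_total: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.bin_edges_t1 = np.asarray(self.bin_edges_t1, dtype=np.float64)
        self.bin_edges_flair = np.asarray(self.bin_edges_flair, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if (np.diff(self.bin_edges_t1) <= 0).any() or (
            np.diff(self.bin_edges_flair) <= 0
        ).any():
            raise ValueError("bin edges must be strictly increasing")
        expect = 1.0 if self.normalized else float(self.n_total)
        if not np.isclose(self.counts.sum(), expect, rtol=0, atol=1e-6 * max(1.0, expect)):
            raise ValueError(
                f"counts sum {self.counts.sum()} != expected {expect}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def bin_widths(self) -> tuple[float, float]:
        return (
            float(self.bin_edges_t1[1] - self.bin_edges_t1[0]),
            float(self.bin_edges_flair[1] - self.bin_edges_flair[0]),
        )

    @property
    def bin_centers_t1(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_t1[:-1] + self.bin_edges_t1[1:])

    @property
    def bin_centers_flair(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_flair[:-1] + self.bin_edges_flair[1:])

    def normalized_counts(self) -> np.ndarray:
        if self.normalized:
            return self.counts
        return self.counts / self.counts.sum()

    def same_binning(self, other: "BivariateHistogram") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and np.allclose(self.bin_edges_t1, other.bin_edges_t1)
            and np.allclose(self.bin_edges_flair, other.bin_edges_flair)
        )


def build_bivariate_histogram(
    vals: PairedIntensities, spec: BinningSpec
) -> BivariateHistogram:
    """Histogram paired intensities on the spec's grid.

    Out-of-range values (including negatives left over from bias-field
    correction) are clipped into the boundary bins so the voxel count is
    conserved exactly.
    """
    if vals.n_voxels < 1000:
        raise ValueError(f"need >= 1000 voxels, got {vals.n_voxels}")
    # clip strictly inside the range so no mass can fall outside the grid;
    # the shift is < 1e-6 bin widths, invisible at histogram resolution
    t1 = np.clip(
        vals.t1_values, spec.range_t1[0], spec.range_t1[1] - 1e-6 * spec.bin_width_t1
    )
    fl = np.clip(
        vals.flair_values,
        spec.range_flair[0],
        spec.range_flair[1] - 1e-6 * spec.bin_width_flair,
    )
    counts, _, _ = np.histogram2d(
        t1, fl, bins=[spec.edges_t1, spec.edges_flair]
    )
    assert counts.sum() == vals.n_voxels
    return BivariateHistogram(
        counts=counts,
        bin_edges_t1=spec.edges_t1,
        bin_edges_flair=spec.edges_flair,
        n_total=vals.n_voxels,
    )


def marginalize(h: BivariateHistogram, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse to the univariate histogram of one contrast.

    Returns ``(edges, counts)``; the marginal counts sum to the bivariate
    total exactly.
    """
    if axis == "t1":
        return h.bin_edges_t1, h.counts.sum(axis=1)
    if axis == "flair":
        return h.bin_edges_flair, h.counts.sum(axis=0)
    raise ValueError("axis must be 't1' or 'flair'")


@dataclass
class ReferenceAtlas:
    """Normative reference histogram plus class centroids in intensity units."""

    reference_histogram: BivariateHistogram
    class_centroids: dict[str, tuple[float, float]]
    n_controls: int
    binning: BinningSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.reference_histogram.normalized:
            raise ValueError("reference histogram must be normalized")
        _check_centroid_ordering(self.class_centroids)

    def centroid_array(self, classes=CLASS_NAMES) -> np.ndarray:
        return np.array([self.class_centroids[c] for c in classes])


def _check_centroid_ordering(c: dict[str, tuple[float, float]]) -> None:
    t1 = {k: v[0] for k, v in c.items()}
    fl = {k: v[1] for k, v in c.items()}
    ok = (
        t1["csf"] < t1["gm"] < t1["wm"]
        and fl["csf"] < fl["wm"] < fl["gm"]
        and fl["lesion"] > fl["wm"]
    )
    if not ok:
        raise CentroidOrderingError(
            f"class centroids violate control ordering: {c}"
        )


def _refine_centroid(
    smoothed: np.ndarray, seed_idx: tuple[int, int], max_steps: int = 500
) -> tuple[int, int]:
    """Greedy hill-climb on the 8-neighborhood from a seeded bin."""
    i, j = seed_idx
    ni, nj = smoothed.shape
    for _ in range(max_steps):
        i0, i1 = max(i - 1, 0), min(i + 2, ni)
        j0, j1 = max(j - 1, 0), min(j + 2, nj)
        window = smoothed[i0:i1, j0:j1]
        di, dj = np.unravel_index(np.argmax(window), window.shape)
        best = (i0 + di, j0 + dj)
        if best == (i, j):
            break
        i, j = best
    return i, j


def build_reference_atlas(
    control_histograms: list[BivariateHistogram],
    centroid_init: dict[str, tuple[float, float]] | None = None,
    binning: BinningSpec | None = None,
    smoothing_sigma: float = 2.0,
) -> ReferenceAtlas:
    """Average normalized control histograms and locate class centroids.

    The reference is the arithmetic mean of the normalized control
    histograms (each control contributes equally regardless of brain
    size).  CSF/GM/WM centroids are local maxima of the Gaussian-smoothed
    (``smoothing_sigma`` bins) reference, hill-climbed from seeds at the
    normative loci (:data:`DEFAULT_CONTROL_LOCI` by default).  Lesions have
    no control mode; the LESION centroid is placed at
    (midpoint of GM/WM on T1w, GM FLAIR + 1.5 x the GM-WM FLAIR gap)
    unless supplied in ``centroid_init``.
    """
    if len(control_histograms) < 2:
        raise ValueError("need at least 2 control histograms")
    ref0 = control_histograms[0]
    for h in control_histograms[1:]:
        if not ref0.same_binning(h):
            raise BinningMismatchError("control histograms on different bin grids")
    mean = np.mean([h.normalized_counts() for h in control_histograms], axis=0)
    mean = mean / mean.sum()
    reference = BivariateHistogram(
        counts=mean,
        bin_edges_t1=ref0.bin_edges_t1,
        bin_edges_flair=ref0.bin_edges_flair,
        n_total=int(sum(h.n_total for h in control_histograms)),
        normalized=True,
    )

    seeds = dict(DEFAULT_CONTROL_LOCI)
    if centroid_init:
        seeds.update({k: v for k, v in centroid_init.items() if k != "lesion"})

    smoothed = gaussian_filter(mean, smoothing_sigma)
    centers_t1 = reference.bin_centers_t1
    centers_fl = reference.bin_centers_flair
    centroids: dict[str, tuple[float, float]] = {}
    for cls in ("csf", "gm", "wm"):
        si = int(np.clip(np.searchsorted(centers_t1, seeds[cls][0]), 0, len(centers_t1) - 1))
        sj = int(np.clip(np.searchsorted(centers_fl, seeds[cls][1]), 0, len(centers_fl) - 1))
        i, j = _refine_centroid(smoothed, (si, sj))
        centroids[cls] = (float(centers_t1[i]), float(centers_fl[j]))

    if centroid_init and "lesion" in centroid_init:
        centroids["lesion"] = tuple(centroid_init["lesion"])  # type: ignore[assignment]
    else:
        gm, wm = centroids["gm"], centroids["wm"]
        centroids["lesion"] = (
            0.5 * (gm[0] + wm[0]),
            gm[1] + 1.5 * (gm[1] - wm[1]),
        )

    if binning is None:
        binning = BinningSpec(
            n_bins_t1=len(centers_t1),
            n_bins_flair=len(centers_fl),
            range_t1=(float(ref0.bin_edges_t1[0]), float(ref0.bin_edges_t1[-1])),
            range_flair=(float(ref0.bin_edges_flair[0]), float(ref0.bin_edges_flair[-1])),
        )
    return ReferenceAtlas(
        reference_histogram=reference,
        class_centroids=centroids,
        n_controls=len(control_histograms),
        binning=binning,
    )


def save_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    """Serialize the atlas as one .npz archive with a JSON metadata entry."""
    meta = {
        "class_centroids": {k: list(v) for k, v in atlas.class_centroids.items()},
        "n_controls": atlas.n_controls,
        "binning": {
            "n_bins_t1": atlas.binning.n_bins_t1,
            "n_bins_flair": atlas.binning.n_bins_flair,
            "range_t1": list(atlas.binning.range_t1),
            "range_flair": list(atlas.binning.range_flair),
            "range_mode": atlas.binning.range_mode,
        },
    }
    np.savez(
        str(path),
        reference=atlas.reference_histogram.counts,
        edges_t1=atlas.reference_histogram.bin_edges_t1,
        edges_flair=atlas.reference_histogram.bin_edges_flair,
        meta=np.array(json.dumps(meta)),
    )


def load_atlas(path: str | Path) -> ReferenceAtlas:
    with np.load(str(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        reference = BivariateHistogram(
            counts=z["reference"],
            bin_edges_t1=z["edges_t1"],
            bin_edges_flair=z["edges_flair"],
            n_total=0,
            normalized=True,
        )
    b = meta["binning"]
    return ReferenceAtlas(
        reference_histogram=reference,
        class_centroids={k: tuple(v) for k, v in meta["class_centroids"].items()},
        n_controls=int(meta["n_controls"]),
        binning=BinningSpec(
            n_bins_t1=b["n_bins_t1"],
            n_bins_flair=b["n_bins_flair"],
            range_t1=tuple(b["range_t1"]),
            range_flair=tuple(b["range_flair"]),
            range_mode=b["range_mode"],
        ),
    )
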