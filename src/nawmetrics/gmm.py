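"""Univariate Gaussian mixture summaries of standardized intensities.

Each contrast's standardized in-brain intensity distribution is modeled
as a mixture of Gaussians, one per tissue class; each component's mean mu
and standard deviation sigma summarize that tissue's signal level and
within-tissue heterogeneity.  Eight parameters per subject are analyzed:
{T1w, FLAIR} x {GM, WM} x {mu, sigma}; CSF components are fit but not
analyzed.  Fitting is carried out twice, with lesion voxels included and
excluded, because lesion exclusion isolates normal-appearing tissue (its
main effect is to shrink sigma).

EM is written against weighted samples, which gives two equivalent entry
points: the voxel-level fit (unit weights) and a binned fast path
(responsibilities weighted by bin counts).  All initialization comes from
the atlas class loci, never from randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .histogram import ReferenceAtlas
from .io_prep import VolumePair
from .segmentation import CLASS_CODES, LesionMetrics, TissueLabelMap

__all__ = [
    "GaussianComponent",
    "GmmFit",
    "SubjectParameters",
    "DegenerateFitError",
    "fit_univariate_gmm",
    "fit_univariate_gmm_binned",
    "extract_subject_parameters",
    "ANALYZED_PARAMETERS",
]

#: the 8 analyzed per-subject biomarkers
ANALYZED_PARAMETERS = (
    "t1_wm_mu",
    "t1_gm_mu",
    "t1_wm_sigma",
    "t1_gm_sigma",
    "flair_wm_mu",
    "flair_gm_mu",
    "flair_wm_sigma",
    "flair_gm_sigma",
)

#: mu-ordering of tissue classes per contrast in reference space
CLASS_ORDER = {
    "t1": ("csf", "gm", "wm"),
    "flair": ("csf", "wm", "gm"),
    "flair_with_lesion": ("csf", "wm", "gm", "lesion"),
}


class DegenerateFitError(RuntimeError):
    """A mixture component collapsed (vanishing weight or merged seeds)."""


@dataclass
class GaussianComponent:
    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class GmmFit:
    components: list[GaussianComponent]
    log_likelihood_path: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_path[-1])


def _weighted_em(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    pi: np.ndarray,
    max_iter: int,
    tol: float,
    sigma_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """EM for a univariate GMM on weighted samples.

    ``w`` are non-negative sample multiplicities (bin counts, or ones for
    raw voxels).  Convergence: per-sample log-likelihood change < tol.
    """
    n_eff = w.sum()
    ll_path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for stability
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            - 0.5 * np.log(2 * np.pi)
        )
        log_weighted = log_pdf + np.log(pi[None, :])
        m = log_weighted.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_weighted - m).sum(axis=1))
        ll = float((w * log_norm).sum())
        ll_path.append(ll)
        resp = np.exp(log_weighted - log_norm[:, None])
        # M step with sample multiplicities
        wr = resp * w[:, None]
        nk = wr.sum(axis=0)
        if (nk / n_eff < 1e-4).any():
            raise DegenerateFitError(
                f"component weight collapsed below 1e-4 (weights {nk / n_eff})"
            )
        mu = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, sigma_floor**2))
        pi = nk / n_eff
        if len(ll_path) > 1 and (ll_path[-1] - ll_path[-2]) / n_eff < tol:
            converged = True
            break
    return mu, sigma, pi, np.array(ll_path), converged, it


def _finalize(
    mu: np.ndarray,
    sigma: np.ndarray,
    pi: np.ndarray,
    ll_path: np.ndarray,
    converged: bool,
    n_iter: int,
    init_means: np.ndarray,
) -> GmmFit:
    # re-sort by mu and match to the (sorted) seed identity
    order = np.argsort(mu)
    mu, sigma, pi = mu[order], sigma[order], pi[order]
    # nearest-mu sanity check against seeds: two components landing on the
    # same seed indicates an identifiability failure
    nearest = [int(np.argmin(np.abs(init_means - m))) for m in mu]
    merged = len(set(nearest)) < len(mu) or any(
        (mu[i + 1] - mu[i]) < 0.25 * min(sigma[i], sigma[i + 1])
        for i in range(len(mu) - 1)
    )
    if merged:
        warnings.warn(
            "fitted components could not be uniquely matched to seeds "
            "(possible merged components)",
            stacklevel=3,
        )
    if not converged:
        warnings.warn("GMM EM hit the iteration cap", stacklevel=3)
    comps = [
        GaussianComponent(mu=float(m), sigma=float(s), weight=float(p))
        for m, s, p in zip(mu, sigma, pi)
    ]
    return GmmFit(
        components=comps,
        log_likelihood_path=ll_path,
        converged=converged,
        n_iterations=n_iter,
    )


def _initial_sigmas(init_means: np.ndarray) -> np.ndarray:
    gaps = np.diff(np.sort(init_means))
    s0 = max(float(gaps.min()) / 4.0, 1e-6) if len(gaps) else 1.0
    return np.full(len(init_means), s0)


def fit_univariate_gmm(
    values: np.ndarray,
    k: int,
    init_means,
    init_sigmas=None,
    init_weights=None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> GmmFit:
    """Fit a k-component univariate GMM to raw intensity samples.

    Deterministic given the seeds (``init_means`` must be sorted
    ascending); components are returned sorted by mu, so component i
    corresponds to seed i for well-separated fits.  Sigmas are floored at
    1e-3 of the data range.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if len(x) < 100:
        raise ValueError(f"need >= 100 values, got {len(x)}")
    return _fit_weighted(x, np.ones_like(x), k, init_means, init_sigmas, init_weights, max_iter, tol)


def fit_univariate_gmm_binned(
    bin_centers: np.ndarray,
    bin_counts: np.ndarray,
    k: int,
    init_means,
    init_sigmas=None,
    init_weights=None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> GmmFit:
    """Binned fast path: EM with responsibilities weighted by bin counts.

    Agrees with the voxel-level fit to well under 1% on all parameters
    when the binning resolves the component widths.
    """
    centers = np.asarray(bin_centers, dtype=np.float64)
    counts = np.asarray(bin_counts, dtype=np.float64)
    keep = counts > 0
    if counts.sum() < 100:
        raise ValueError("need >= 100 total counts")
    return _fit_weighted(
        centers[keep], counts[keep], k, init_means, init_sigmas, init_weights, max_iter, tol
    )


def _fit_weighted(x, w, k, init_means, init_sigmas, init_weights, max_iter, tol) -> GmmFit:
    if k not in (1, 2, 3, 4):
        raise ValueError("k must be in {1..4}")
    mu0 = np.asarray(init_means, dtype=np.float64).ravel()
    if len(mu0) != k:
        raise ValueError("init_means length must equal k")
    if (np.diff(mu0) < 0).any():
        raise ValueError("init_means must be sorted ascending")
    sigma0 = (
        np.asarray(init_sigmas, dtype=np.float64).ravel()
        if init_sigmas is not None
        else _initial_sigmas(mu0)
    )
    pi0 = (
        np.asarray(init_weights, dtype=np.float64).ravel()
        if init_weights is not None
        else np.full(k, 1.0 / k)
    )
    pi0 = pi0 / pi0.sum()
    data_range = float(x.max() - x.min())
    sigma_floor = max(1e-3 * data_range, 1e-12)
    mu, sigma, pi, ll_path, converged, n_iter = _weighted_em(
        x, w, mu0.copy(), sigma0.copy(), pi0.copy(), max_iter, tol, sigma_floor
    )
    return _finalize(mu, sigma, pi, ll_path, converged, n_iter, mu0)


@dataclass
class SubjectParameters:
    """The analyzed biomarker row for one subject and one lesion variant."""

    subject_id: str
    variant: str  # lesions_included | lesions_excluded
    t1_wm_mu: float
    t1_gm_mu: float
    t1_wm_sigma: float
    t1_gm_sigma: float
    flair_wm_mu: float
    flair_gm_mu: float
    flair_wm_sigma: float
    flair_gm_sigma: float
    csf_components: dict[str, GaussianComponent] = field(default_factory=dict)
    lesion_component: GaussianComponent | None = None
    lesion_metrics: LesionMetrics | None = None

    def analyzed(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ANALYZED_PARAMETERS}

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "variant": self.variant}
        row.update(self.analyzed())
        if self.lesion_metrics is not None:
            row["lesion_volume_ml"] = self.lesion_metrics.lesion_volume_ml
            row["lesion_intensity"] = self.lesion_metrics.lesion_intensity
            row["n_lesion_voxels"] = self.lesion_metrics.n_lesion_voxels
        return row


def _contrast_seeds(atlas: ReferenceAtlas, contrast: str, with_lesion: bool):
    axis = 0 if contrast == "t1" else 1
    order = CLASS_ORDER["flair_with_lesion" if (with_lesion and contrast == "flair") else contrast]
    means = np.array([atlas.class_centroids[c][axis] for c in order])
    return order, means


def extract_subject_parameters(
    pair: VolumePair,
    labels: TissueLabelMap,
    atlas: ReferenceAtlas,
    variant: str = "lesions_excluded",
    lesion_metrics_value: LesionMetrics | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> SubjectParameters:
    """Fit per-contrast GMMs on the in-scope voxels and report the 8 parameters.

    ``lesions_excluded`` drops lesion-labeled voxels and fits k=3 per
    contrast; ``lesions_included`` keeps them, fitting k=4 on FLAIR (the
    lesion component seeded at the atlas lesion locus) and k=3 on T1w,
    where lesion contrast is weak.  Component identity is fixed by the
    atlas mu-ordering (T1: CSF < GM < WM; FLAIR: CSF < WM < GM < lesion),
    never by fit order.
    """
    if variant not in ("lesions_included", "lesions_excluded"):
        raise ValueError(f"unknown variant: {variant}")
    mask = pair.brain_mask
    in_scope = mask.copy()
    if variant == "lesions_excluded":
        in_scope &= labels.labels != CLASS_CODES["lesion"]

    results: dict[str, dict[str, GaussianComponent]] = {}
    for contrast, volume in (("t1", pair.t1w), ("flair", pair.flair)):
        with_lesion = variant == "lesions_included" and contrast == "flair"
        order, means = _contrast_seeds(atlas, contrast, with_lesion)
        values = volume[in_scope]
        try:
            fit = fit_univariate_gmm(
                values, k=len(order), init_means=means, max_iter=max_iter, tol=tol
            )
        except DegenerateFitError as exc:
            if with_lesion:
                # essentially lesion-free subject: the k=4 lesion component
                # collapses; fall back to the k=3 model without it
                warnings.warn(
                    f"{pair.subject_id}: FLAIR lesion component collapsed, "
                    "refitting without it",
                    stacklevel=2,
                )
                order, means = _contrast_seeds(atlas, contrast, with_lesion=False)
                fit = fit_univariate_gmm(
                    values, k=len(order), init_means=means, max_iter=max_iter, tol=tol
                )
            else:
                raise DegenerateFitError(
                    f"{pair.subject_id} {contrast} ({variant}): {exc}"
                ) from exc
        results[contrast] = dict(zip(order, fit.components))

    return SubjectParameters(
        subject_id=pair.subject_id,
        variant=variant,
        t1_wm_mu=results["t1"]["wm"].mu,
        t1_gm_mu=results["t1"]["gm"].mu,
        t1_wm_sigma=results["t1"]["wm"].sigma,
        t1_gm_sigma=results["t1"]["gm"].sigma,
        flair_wm_mu=results["flair"]["wm"].mu,
        flair_gm_mu=results["flair"]["gm"].mu,
        flair_wm_sigma=results["flair"]["wm"].sigma,
        flair_gm_sigma=results["flair"]["gm"].sigma,
        csf_components={c: results[c]["csf"] for c in ("t1", "flair")},
        lesion_component=results["flair"].get("lesion"),
        lesion_metrics=lesion_metrics_value,
    )
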