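"""Synthetic phantoms and cohorts with exact ground truth.

The phantom emulates the statistical structure the pipeline consumes, not
brain anatomy: concentric ellipsoids give plausible class proportions
(CSF ~10%, GM ~45%, WM ~45% of the brain mask), each class draws its
(T1w, FLAIR) intensity pairs from a bivariate Gaussian around the
normative control loci, discrete hyperintense lesions are spheres seeded
inside WM, diffuse normal-appearing-WM pathology is a smooth Gaussian
random field added to WM FLAIR, and scanner-to-scanner intensity
variation is an exactly affine map of the intensity plane (plus an
optional non-affine gamma distortion for stressing the QC gate).

Scanner noise is added *before* the scanner affine, so inverting the
affine recovers the reference-space class distributions exactly; the
generator reports those distributions as ground truth so parameter
recovery is checkable end to end.

The cohort generator adds group structure: each subject carries a latent
severity that drives intensity effects (lower T1w WM mean, wider
within-class distributions, lesion burden), disability (PDDS), simulated
neuroperformance/quality-of-life scores and atrophy covariates.  The
three progressive subtypes share one effect profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .alignment import IntensityAffine
from .histogram import DEFAULT_CONTROL_LOCI
from .io_prep import VolumePair
from .segmentation import CLASS_CODES, TissueLabelMap

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroupEffectProfile",
    "CohortSpec",
    "GeometryOverflowError",
    "generate_phantom",
    "generate_cohort",
    "CohortData",
    "DEFAULT_EFFECT_PROFILES",
]


class GeometryOverflowError(ValueError):
    """Requested lesion load does not fit inside the WM compartment."""


@dataclass(frozen=True)
class LesionSpec:
    """Discrete lesion load: spheres carved out of WM.

    Lesion voxels are hyperintense on FLAIR and mildly hypointense on T1w
    relative to WM.  Lesions are deliberately heterogeneous (wide
    ``intensity_sd``): bright cores grade into milder rims whose FLAIR
    values overlap the upper WM tail, which is exactly why including them
    in the mixture fit inflates the WM sigma.
    """

    count: int = 0
    radius_range: tuple[int, int] = (2, 4)
    flair_elevation: float = 750.0
    t1_depression: float = 200.0
    intensity_sd: float = 120.0


def _default_class_distributions() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    cov = np.diag([40.0**2, 40.0**2])
    return {
        cls: (np.array(loc, dtype=float), cov.copy())
        for cls, loc in DEFAULT_CONTROL_LOCI.items()
    }


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom deterministically.

    ``class_distributions`` maps class -> (mean 2-vector, 2x2 covariance)
    in scanner units; defaults sit at the normative control loci with
    40-unit within-class SD.  ``noise_sd`` is additive scanner noise per
    contrast (applied before the scanner affine).  ``nawm_field_sd`` is
    the SD of the smooth FLAIR field added to WM (0 = healthy control).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    class_distributions: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=_default_class_distributions
    )
    lesion_spec: LesionSpec = field(default_factory=LesionSpec)
    scanner_effect: IntensityAffine = field(default_factory=IntensityAffine.identity)
    noise_sd: tuple[float, float] = (30.0, 30.0)
    nawm_field_sd: float = 0.0
    field_smoothing_voxels: float = 3.0
    gamma: float = 1.0  # optional non-affine distortion, 1.0 = off
    csf_fraction: float = 0.10
    gm_fraction: float = 0.45
    seed: int = 0
    subject_id: str = "phantom"


def _geometry_labels(spec: PhantomSpec) -> np.ndarray:
    """Concentric-ellipsoid class geometry; returns the label volume."""
    shape = spec.shape
    center = (np.array(shape) - 1) / 2.0
    semi = 0.45 * np.array(shape)
    grid = np.indices(shape).astype(np.float64)
    rho = np.sqrt(
        sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    )
    # radii chosen so class volume fractions are csf/gm/wm ~ 10/45/45
    r_csf = spec.csf_fraction ** (1.0 / 3.0)
    r_wm = (1.0 - spec.gm_fraction) ** (1.0 / 3.0)
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= 1.0] = CLASS_CODES["gm"]
    labels[rho <= r_wm] = CLASS_CODES["wm"]
    labels[rho <= r_csf] = CLASS_CODES["csf"]
    return labels


def _place_lesions(
    labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    ls = spec.lesion_spec
    if ls.count == 0:
        return labels
    wm_idx = np.argwhere(labels == CLASS_CODES["wm"])
    max_sphere = 4.0 / 3.0 * np.pi * ls.radius_range[1] ** 3
    if ls.count * max_sphere > len(wm_idx):
        raise GeometryOverflowError(
            f"{ls.count} lesions of radius <= {ls.radius_range[1]} cannot fit "
            f"in {len(wm_idx)} WM voxels"
        )
    out = labels.copy()
    grid = np.indices(labels.shape).astype(np.float64)
    for _ in range(ls.count):
        center = wm_idx[rng.integers(len(wm_idx))]
        radius = float(rng.integers(ls.radius_range[0], ls.radius_range[1] + 1))
        dist2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
        sphere = dist2 <= radius**2
        out[sphere & (labels == CLASS_CODES["wm"])] = CLASS_CODES["lesion"]
    return out


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumePair, TissueLabelMap, dict]:
    """Build one phantom: volumes, ground-truth labels and true parameters.

    The returned ``truth`` dict holds, per class and contrast, the
    reference-space mean and the effective marginal SD (class SD, scanner
    noise and, for WM FLAIR, the NAWM field combined in quadrature), plus
    the scanner affine and lesion voxel count, so every downstream
    estimate has an exact target.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _geometry_labels(spec)
    labels = _place_lesions(labels, spec, rng)
    mask = labels > 0

    t1 = np.zeros(spec.shape)
    fl = np.zeros(spec.shape)
    dists = dict(spec.class_distributions)
    wm_mean = dists["wm"][0]
    lesion_mean = wm_mean + np.array(
        [-spec.lesion_spec.t1_depression, spec.lesion_spec.flair_elevation]
    )
    dists["lesion"] = (lesion_mean, np.diag([spec.lesion_spec.intensity_sd**2] * 2))

    for cls, (mean, cov) in dists.items():
        sel = labels == CLASS_CODES[cls]
        n = int(sel.sum())
        if n == 0:
            continue
        if np.allclose(cov, 0.0):
            samples = np.tile(np.asarray(mean, dtype=float), (n, 1))
        else:
            samples = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        t1[sel] = samples[:, 0]
        fl[sel] = samples[:, 1]

    # scanner noise (reference space, before the scanner affine)
    t1[mask] += rng.normal(0.0, spec.noise_sd[0], size=int(mask.sum()))
    fl[mask] += rng.normal(0.0, spec.noise_sd[1], size=int(mask.sum()))

    # diffuse NAWM heterogeneity: smooth field on WM FLAIR, rescaled to an
    # exact per-voxel SD so the effective sigma is known in closed form
    if spec.nawm_field_sd > 0:
        wm = labels == CLASS_CODES["wm"]
        raw = gaussian_filter(
            rng.standard_normal(spec.shape), spec.field_smoothing_voxels
        )
        vals = raw[wm]
        raw = (raw - vals.mean()) / vals.std()
        fl[wm] += spec.nawm_field_sd * raw[wm]

    # scanner intensity distortion: exactly affine in the intensity plane
    pts = np.column_stack([t1[mask], fl[mask]])
    moved = spec.scanner_effect.apply(pts)
    if spec.gamma != 1.0:
        # optional non-affine distortion for QC stress tests
        top = moved.max(axis=0)
        moved = np.clip(moved, 0.0, None)
        moved = top * (moved / top) ** spec.gamma
    t1[mask] = moved[:, 0]
    fl[mask] = moved[:, 1]
    t1[~mask] = 0.0
    fl[~mask] = 0.0

    truth: dict = {"classes": {}, "scanner_effect": spec.scanner_effect}
    for cls, (mean, cov) in dists.items():
        extra_fl = spec.nawm_field_sd**2 if cls == "wm" else 0.0
        truth["classes"][cls] = {
            "t1_mu": float(mean[0]),
            "flair_mu": float(mean[1]),
            "t1_sigma": float(np.sqrt(cov[0, 0] + spec.noise_sd[0] ** 2)),
            "flair_sigma": float(np.sqrt(cov[1, 1] + spec.noise_sd[1] ** 2 + extra_fl)),
        }
    truth["n_lesion_voxels"] = int((labels == CLASS_CODES["lesion"]).sum())

    pair = VolumePair(
        t1w=t1,
        flair=fl,
        brain_mask=mask,
        voxel_size=(1.0, 1.0, 1.0),
        subject_id=spec.subject_id,
    )
    return pair, TissueLabelMap(labels=labels), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupEffectProfile:
    """Per-unit-severity intensity effects for one clinical group.

    ``severity_mean``/``severity_sd`` define the group's latent severity
    distribution; a subject with severity s gets mean shifts (units x s),
    an NAWM FLAIR field of SD ``nawm_field_per_severity * s``, a T1w WM
    field likewise, class covariances scaled by (1 + sigma_scale_per
    severity * s) and a Poisson lesion count with the stated rate.
    """

    severity_mean: float = 0.0
    severity_sd: float = 0.0
    t1_wm_mu_shift: float = -25.0
    t1_gm_mu_shift: float = +10.0
    flair_wm_mu_shift: float = -10.0
    flair_gm_mu_shift: float = -15.0
    nawm_field_per_severity: float = 18.0
    t1_wm_field_per_severity: float = 12.0
    sigma_scale_per_severity: float = 0.04
    lesion_rate_base: float = 0.3
    lesion_rate_per_severity: float = 3.0


DEFAULT_EFFECT_PROFILES: dict[str, GroupEffectProfile] = {
    "control": GroupEffectProfile(severity_mean=0.0, severity_sd=0.0),
    "RRMS": GroupEffectProfile(severity_mean=1.0, severity_sd=0.35),
    # the three progressive subtypes share one profile
    "SPMS": GroupEffectProfile(severity_mean=2.0, severity_sd=0.45),
    "PPMS": GroupEffectProfile(severity_mean=2.0, severity_sd=0.45),
    "PRMS": GroupEffectProfile(severity_mean=2.0, severity_sd=0.45),
}


@dataclass
class CohortSpec:
    """A multi-group study: phantom per subject plus a clinical table.

    ``scanner_scale_range``/``scanner_offset_range`` give the per-subject
    uniform draws of the diagonal scanner affine the registration step
    must undo.  ``disability_intercept/slope/noise`` map latent severity
    to PDDS (rounded and clipped to 0..8).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "control": 50,
            "RRMS": 50,
            "SPMS": 17,
            "PPMS": 17,
            "PRMS": 16,
        }
    )
    effect_profiles: dict[str, GroupEffectProfile] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILES)
    )
    shape: tuple[int, int, int] = (48, 48, 48)
    scanner_scale_range: tuple[float, float] = (0.85, 1.15)
    scanner_shear_range: tuple[float, float] = (-0.03, 0.03)
    scanner_offset_range: tuple[float, float] = (-50.0, 50.0)
    subject_sigma_jitter: float = 0.04
    subject_mean_jitter_sd: float = 12.0
    disability_intercept: float = 0.5
    disability_slope: float = 1.4
    disability_noise: float = 1.1
    n_npt: int = 3
    n_qol: int = 12
    npt_noise: float = 0.45
    qol_noise: float = 1.3
    seed: int = 0


def _subject_phantom_spec(
    severity: float,
    profile: GroupEffectProfile,
    spec: CohortSpec,
    rng: np.random.Generator,
    seed: int,
    subject_id: str,
) -> PhantomSpec:
    dists = _default_class_distributions()
    shifts = {
        "wm": np.array([profile.t1_wm_mu_shift, profile.flair_wm_mu_shift]),
        "gm": np.array([profile.t1_gm_mu_shift, profile.flair_gm_mu_shift]),
        "csf": np.zeros(2),
    }
    jitter = 1.0 + rng.normal(0.0, spec.subject_sigma_jitter)
    scale = (1.0 + profile.sigma_scale_per_severity * severity) * max(jitter, 0.5)
    for cls in dists:
        mean, cov = dists[cls]
        # biological between-subject variation of class mean intensities
        mean_jitter = rng.normal(0.0, spec.subject_mean_jitter_sd, size=2)
        dists[cls] = (mean + severity * shifts[cls] + mean_jitter, cov * scale**2)

    lesion_count = int(
        rng.poisson(profile.lesion_rate_base + profile.lesion_rate_per_severity * severity)
    )
    sx = rng.uniform(*spec.scanner_scale_range)
    sy = rng.uniform(*spec.scanner_scale_range)
    e1 = rng.uniform(*spec.scanner_shear_range)
    e2 = rng.uniform(*spec.scanner_shear_range)
    b = rng.uniform(*spec.scanner_offset_range, size=2)
    scanner = IntensityAffine(linear=np.array([[sx, e1], [e2, sy]]), offset=b)

    # T1w WM diffuse effect rides on the class covariance (no separate field)
    t1_extra = profile.t1_wm_field_per_severity * severity
    mean, cov = dists["wm"]
    cov = cov.copy()
    cov[0, 0] += t1_extra**2
    dists["wm"] = (mean, cov)

    return PhantomSpec(
        shape=spec.shape,
        class_distributions=dists,
        lesion_spec=LesionSpec(count=lesion_count),
        scanner_effect=scanner,
        nawm_field_sd=profile.nawm_field_per_severity * severity,
        seed=seed,
        subject_id=subject_id,
    )


@dataclass
class CohortData:
    """Clinical table plus lazily generated per-subject phantoms."""

    clinical: pd.DataFrame
    phantom_specs: dict[str, PhantomSpec]
    true_severity: dict[str, float]

    def subjects(self):
        """Yield (subject_id, VolumePair, ground-truth labels, truth dict)."""
        for sid, pspec in self.phantom_specs.items():
            pair, labels, truth = generate_phantom(pspec)
            yield sid, pair, labels, truth


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Sample a full study cohort; deterministic given ``spec.seed``.

    The clinical table has one row per subject: group, PDDS (absent for
    controls), simulated neuroperformance (npt_*) and quality-of-life
    (qol_*) scores driven by the same latent severity, and atrophy-style
    covariates (bpf, gmf, wmf, thalamic_volume).  Phantoms are generated
    lazily from stored per-subject specs to keep memory flat.
    """
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    rows = []
    phantom_specs: dict[str, PhantomSpec] = {}
    true_severity: dict[str, float] = {}
    counter = 0
    for group in GROUP_ORDER:
        n = spec.n_per_group.get(group, 0)
        profile = spec.effect_profiles[group]
        for _ in range(n):
            counter += 1
            sid = f"{group.lower()}_{counter:04d}"
            if profile.severity_sd == 0:
                severity = profile.severity_mean
            else:
                severity = max(
                    0.0, rng.normal(profile.severity_mean, profile.severity_sd)
                )
            child_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            pspec = _subject_phantom_spec(
                severity, profile, spec, rng, child_seed, sid
            )
            phantom_specs[sid] = pspec
            true_severity[sid] = severity

            if group == "control":
                pdds = np.nan
            else:
                raw = (
                    spec.disability_intercept
                    + spec.disability_slope * severity
                    + rng.normal(0.0, spec.disability_noise)
                )
                pdds = float(np.clip(np.round(raw), 0, 8))
            npt = [
                -severity + rng.normal(0.0, spec.npt_noise) for _ in range(spec.n_npt)
            ]
            qol = [
                -severity + rng.normal(0.0, spec.qol_noise) for _ in range(spec.n_qol)
            ]
            row = {
                "subject_id": sid,
                "group": group,
                "pdds": pdds,
                # atrophy-style covariates correlated with severity
                "bpf": 0.85 - 0.012 * severity + rng.normal(0.0, 0.006),
                "gmf": 0.50 - 0.006 * severity + rng.normal(0.0, 0.005),
                "wmf": 0.35 - 0.004 * severity + rng.normal(0.0, 0.005),
                "thalamic_volume": 15.0 - 0.5 * severity + rng.normal(0.0, 0.45),
            }
            row.update({f"npt_{i+1}": v for i, v in enumerate(npt)})
            row.update({f"qol_{i+1}": v for i, v in enumerate(qol)})
            rows.append(row)
    clinical = pd.DataFrame(rows)
    return CohortData(
        clinical=clinical, phantom_specs=phantom_specs, true_severity=true_severity
    )


GROUP_ORDER = ("control", "RRMS", "SPMS", "PPMS", "PRMS")
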