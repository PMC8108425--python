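"""Statistical battery relating imaging biomarkers to group and disability.

The analyses mirror a standard biomarker-evaluation workflow on a
per-subject parameter table:

* one-way ANOVA with group (control, RRMS, SPMS, PPMS, PRMS) as factor,
  Bonferroni-corrected across the 8 analyzed parameters (alpha = 0.05/8 =
  0.00625), with post-hoc pairwise contrasts extracted from the fitted
  model;
* ROC analysis (rank-based AUC with tie correction, Youden-optimal
  operating point) for control-vs-MS and RRMS-vs-progressive
  discrimination;
* per-biomarker linear regressions of the Z-scored biomarker on PDDS, so
  the slopes (beta) are directly comparable across biomarkers;
* PCA composites collapsing multi-measure instruments (neuroperformance
  tests, quality-of-life domains) to their first principal component;
* LASSO regression with a 90/10 hold-out to isolate biomarkers uniquely
  contributing to disability.

PDDS is treated as numeric in regressions (an ordinal scale fit linearly;
a deliberate fidelity-over-purity choice, see the methods notes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "SubjectRecord",
    "AnovaResult",
    "RocResult",
    "RegressionResult",
    "PcaComposite",
    "LassoReport",
    "GROUPS",
    "MS_GROUPS",
    "PROGRESSIVE_GROUPS",
    "BONFERRONI_ALPHA",
    "group_anova",
    "posthoc_contrasts",
    "star_code",
    "roc_analysis",
    "zscore_regression",
    "pca_composite",
    "lasso_disability_model",
    "records_to_frame",
]

GROUPS = ("control", "RRMS", "SPMS", "PPMS", "PRMS")
MS_GROUPS = ("RRMS", "SPMS", "PPMS", "PRMS")
PROGRESSIVE_GROUPS = ("SPMS", "PPMS", "PRMS")

#: 8 analyzed parameters -> Bonferroni-corrected significance level
BONFERRONI_ALPHA = 0.05 / 8

#: star bins for contrast matrices: code -> upper p bound
_STAR_BINS = (
    ("****", 1e-5),
    ("***", 1e-4),
    ("**", 1e-3),
    ("*", 1e-2),
    ("+", 0.05),
)


@dataclass
class SubjectRecord:
    """One subject's clinical row; biomarker names come from a fixed registry."""

    subject_id: str
    group: str
    pdds: float | None = None
    biomarkers: dict[str, float] = field(default_factory=dict)
    npt_scores: list[float] | None = None
    qol_scores: list[float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.pdds is not None and not (0 <= self.pdds <= 8):
            raise ValueError("pdds must be in [0, 8]")


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "pdds": r.pdds}
        row.update(r.biomarkers)
        if r.npt_scores is not None:
            row.update({f"npt_{i+1}": v for i, v in enumerate(r.npt_scores)})
        if r.qol_scores is not None:
            row.update({f"qol_{i+1}": v for i, v in enumerate(r.qol_scores)})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    F: float
    p: float
    significant: bool
    df_between: int
    df_within: int
    mse_within: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]


def group_anova(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
    alpha: float = BONFERRONI_ALPHA,
) -> AnovaResult:
    """One-way ANOVA of a biomarker with group as factor.

    ``significant`` applies the Bonferroni-corrected level for the 8
    analyzed parameters by default.
    """
    df = table[[group_col, parameter]].dropna()
    groups = {g: sub[parameter].to_numpy() for g, sub in df.groupby(group_col, observed=True)}
    usable = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    arrays = list(usable.values())
    F, p = sps.f_oneway(*arrays)
    n = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return AnovaResult(
        F=float(F),
        p=float(p),
        significant=bool(p < alpha),
        df_between=k - 1,
        df_within=n - k,
        mse_within=float(ss_within / (n - k)),
        group_means={g: float(a.mean()) for g, a in usable.items()},
        group_sizes={g: len(a) for g, a in usable.items()},
    )


def star_code(p: float) -> str:
    """Map a contrast p-value to its star-bin code ('' = not significant)."""
    for code, bound in _STAR_BINS:
        if p < bound:
            return code
    return ""


def posthoc_contrasts(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
    groups: tuple[str, ...] = GROUPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise group contrasts extracted from the fitted ANOVA model.

    Contrast t statistics use the pooled within-group variance (the ANOVA
    residual MSE) with N - k degrees of freedom; p-values are unadjusted
    two-sided.  Returns (p-value matrix, star-code matrix), both symmetric
    with NaN/blank diagonal.
    """
    res = group_anova(table, parameter, group_col=group_col)
    if not res.significant:
        warnings.warn(
            f"omnibus ANOVA for {parameter} not significant; "
            "post-hoc contrasts are exploratory",
            stacklevel=2,
        )
    present = [g for g in groups if g in res.group_means]
    p_mat = pd.DataFrame(np.nan, index=present, columns=present)
    star = pd.DataFrame("", index=present, columns=present)
    for a, b in combinations(present, 2):
        se = np.sqrt(
            res.mse_within * (1.0 / res.group_sizes[a] + 1.0 / res.group_sizes[b])
        )
        t = (res.group_means[a] - res.group_means[b]) / se
        p = 2.0 * sps.t.sf(abs(t), df=res.df_within)
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
        star.loc[a, b] = star.loc[b, a] = star_code(p)
    return p_mat, star


@dataclass
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    direction: str  # 'greater': score > threshold calls a case


def rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction: P(case > control) + P(tie)/2."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(values)  # midranks handle ties
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(
    values: np.ndarray,
    labels: np.ndarray,
    direction: str = "auto",
) -> RocResult:
    """AUC plus the Youden-optimal operating point.

    ``direction='auto'`` orients the score so AUC >= 0.5.  The operating
    threshold maximizes Youden's J = sensitivity + specificity - 1; ties
    break toward higher specificity.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    auc = rank_auc(values, labels)
    if direction == "auto":
        direction = "greater" if auc >= 0.5 else "less"
    if direction == "less":
        auc = rank_auc(-values, labels)
        score = -values
    elif direction == "greater":
        auc = rank_auc(values, labels)
        score = values
    else:
        raise ValueError("direction must be auto, greater, or less")

    cases = score[labels]
    controls = score[~labels]
    # candidate thresholds: midpoints between adjacent distinct scores
    uniq = np.unique(score)
    cand = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    sens = (cases[None, :] > cand[:, None]).mean(axis=1)
    spec = (controls[None, :] <= cand[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best_j = j.max()
    # ties toward higher specificity
    tied = np.flatnonzero(np.isclose(j, best_j))
    best = tied[np.argmax(spec[tied])]
    thr = float(cand[best])
    if direction == "less":
        thr = -thr
    return RocResult(
        auc=float(auc),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        threshold=thr,
        direction=direction,
    )


@dataclass
class RegressionResult:
    beta: float
    se: float
    t: float
    p: float
    n: int


def zscore_regression(
    table: pd.DataFrame,
    biomarker: str,
    outcome: str = "pdds",
) -> RegressionResult:
    """OLS of the Z-scored biomarker on the outcome (intercept + slope).

    Z-scoring the biomarker puts all slopes on a common scale so beta
    values are directly comparable across biomarkers.  Complete-case.
    """
    df = table[[biomarker, outcome]].dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    y = df[biomarker].to_numpy(dtype=np.float64)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError(f"biomarker {biomarker!r} has zero variance")
    z = (y - y.mean()) / sd
    x = df[outcome].to_numpy(dtype=np.float64)
    res = sps.linregress(x, z)
    n = len(df)
    return RegressionResult(
        beta=float(res.slope),
        se=float(res.stderr),
        t=float(res.slope / res.stderr),
        p=float(res.pvalue),
        n=n,
    )


@dataclass
class PcaComposite:
    scores: np.ndarray
    variance_explained: float
    loadings: np.ndarray


def pca_composite(scores: np.ndarray | pd.DataFrame) -> PcaComposite:
    """Collapse a subjects x measures matrix to its first principal component.

    Columns are standardized first; the component sign is fixed so the
    largest-magnitude loading is positive.  Complete-case over rows.
    """
    X = np.asarray(scores, dtype=np.float64)
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 measures and >= 3 subjects")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column in composite input")
    Z = (X - X.mean(axis=0)) / sd
    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return PcaComposite(
        scores=Z @ v,
        variance_explained=float(evals[-1] / evals.sum()),
        loadings=v,
    )


@dataclass
class LassoReport:
    selected: dict[str, float]  # feature -> beta (nonzero only)
    coefficients: dict[str, float]  # all features
    holdout_r2: float
    alpha: float
    n_train: int
    n_holdout: int


def lasso_disability_model(
    table: pd.DataFrame,
    features: list[str],
    outcome: str = "pdds",
    holdout_fraction: float = 0.10,
    seed: int = 0,
    penalty_rule: str = "min",
) -> LassoReport:
    """L1-penalized regression of disability on biomarkers with a hold-out.

    Features are Z-scored on the training split only; the penalty is
    chosen by 10-fold cross-validation on the training split (minimum-MSE
    rule by default, '1se' for the one-standard-error rule).  The hold-out
    R^2 is the squared correlation between predicted and observed outcome
    on the unseen 10%.  Fully reproducible given ``seed``.
    """
    df = table[features + [outcome]].dropna()
    if len(df) < 50:
        raise ValueError(f"need >= 50 complete cases, got {len(df)}")
    X = df[features].to_numpy(dtype=np.float64)
    y = df[outcome].to_numpy(dtype=np.float64)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed
    )
    mean = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z_tr = (X_tr - mean) / sd
    Z_ho = (X_ho - mean) / sd

    cv = KFold(n_splits=10, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=50000)
    model.fit(Z_tr, y_tr)
    alpha = float(model.alpha_)
    if penalty_rule == "1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        limit = mse.min() + se[np.argmin(mse)]
        ok = np.flatnonzero(mse <= limit)
        alpha = float(model.alphas_[ok].max())
        from sklearn.linear_model import Lasso

        model = Lasso(alpha=alpha, max_iter=50000)
        model.fit(Z_tr, y_tr)
    elif penalty_rule != "min":
        raise ValueError("penalty_rule must be 'min' or '1se'")

    coefs = dict(zip(features, (float(c) for c in model.coef_)))
    selected = {f: c for f, c in coefs.items() if abs(c) > 1e-10}
    pred = model.predict(Z_ho)
    if np.std(pred) == 0 or np.std(y_ho) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, y_ho)[0, 1] ** 2)
    return LassoReport(
        selected=selected,
        coefficients=coefs,
        holdout_r2=r2,
        alpha=alpha,
        n_train=len(y_tr),
        n_holdout=len(y_ho),
    )
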