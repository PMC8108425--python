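"""Cohort-level statistics on a small synthetic five-group study.

Generates a reduced cohort (controls, RRMS, three progressive subtypes
sharing one effect profile), runs every subject through standardization,
segmentation and GMM extraction, and applies the statistical battery:
group ANOVA with Bonferroni correction, post-hoc contrast matrix, ROC
discrimination and Z-scored disability regressions.
"""

import warnings

from nawmetrics import (
    CohortSpec,
    OptimizerOptions,
    PhantomSpec,
    PipelineConfig,
    build_atlas,
    generate_cohort,
    generate_phantom,
    run_cohort,
)
from nawmetrics.stats import (
    BONFERRONI_ALPHA,
    MS_GROUPS,
    group_anova,
    posthoc_contrasts,
    roc_analysis,
    zscore_regression,
)

config = PipelineConfig(
    n_bins=96,
    optimizer=OptimizerOptions(multistart_scales=((1.0, 1.0), (1.1, 0.9), (0.9, 1.1))),
)

controls = [
    generate_phantom(PhantomSpec(seed=100 + s, subject_id=f"ctl{s}"))[0]
    for s in range(8)
]
atlas = build_atlas(controls, config)

cohort = generate_cohort(
    CohortSpec(
        n_per_group={"control": 15, "RRMS": 15, "SPMS": 6, "PPMS": 6, "PRMS": 6},
        shape=(40, 40, 40),
        seed=3,
    )
)
print(f"processing {len(cohort.clinical)} subjects ...")
subjects = ((sid, pair) for sid, pair, _, _ in cohort.subjects())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    params, qc, _ = run_cohort(subjects, atlas, config)
table = params[params["variant"] == "lesions_excluded"].merge(
    cohort.clinical, on="subject_id"
)

marker = "flair_wm_sigma"
res = group_anova(table, marker)
print(f"\nANOVA for {marker}: F = {res.F:.1f}, p = {res.p:.2e} "
      f"(significant at alpha = {BONFERRONI_ALPHA:.5f}: {res.significant})")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    _, stars = posthoc_contrasts(table, marker)
print("\npost-hoc contrast stars (+ p<0.05, * p<1e-2, ** p<1e-3, ...):")
print(stars.to_string())

is_ms = table["group"].isin(MS_GROUPS).to_numpy()
roc = roc_analysis(table[marker].to_numpy(), is_ms)
print(
    f"\ncontrol vs MS discrimination by {marker}: "
    f"AUC {roc.auc:.2f}, sens {roc.sensitivity:.2f}, spec {roc.specificity:.2f}"
)

ms = table[is_ms]
for biomarker in (marker, "lesion_volume_ml", "bpf"):
    r = zscore_regression(ms, biomarker)
    print(
        f"Z({biomarker}) ~ PDDS: beta = {r.beta:+.3f} "
        f"(t = {r.t:+.1f}, p = {r.p:.2g}, n = {r.n})"
    )
print(
    "\nthe diffuse NAWM marker tracks disability more strongly than raw"
    " lesion volume, mirroring the motivation for non-lesional biomarkers."
)
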