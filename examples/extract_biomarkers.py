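"""Per-subject biomarkers: segmentation, lesion metrics, GMM parameters.

Processes one MS-like phantom (discrete lesions plus a diffuse elevation
of normal-appearing-WM FLAIR variability) through the full pipeline and
prints the 8 analyzed Gaussian-mixture parameters with the generator's
ground truth alongside.  The lesions-included fit shows the wider FLAIR
WM component; excluding lesions isolates normal-appearing tissue.
"""

import warnings

from nawmetrics import (
    LesionSpec,
    OptimizerOptions,
    PhantomSpec,
    PipelineConfig,
    build_atlas,
    generate_phantom,
    process_subject,
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

spec = PhantomSpec(
    seed=11,
    lesion_spec=LesionSpec(count=6),
    nawm_field_sd=25.0,
    subject_id="ms_subject",
)
pair, gt_labels, truth = generate_phantom(spec)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = process_subject(pair, atlas, config)

print("tissue voxel counts:", result.labels.class_counts)
metrics = result.parameters["lesions_excluded"].lesion_metrics
print(
    f"lesion volume {metrics.lesion_volume_ml:.2f} mL over "
    f"{metrics.n_lesion_voxels} voxels (truth: {truth['n_lesion_voxels']}), "
    f"mean lesion score u_lv = {metrics.lesion_intensity:.2f}"
)

print(f"\n{'parameter':>16} {'included':>10} {'excluded':>10} {'truth':>9}")
exc = result.parameters["lesions_excluded"]
inc = result.parameters["lesions_included"]
for name in exc.analyzed():
    contrast, cls, stat = name.split("_")
    true = truth["classes"][cls][f"{contrast}_{stat}"]
    print(
        f"{name:>16} {getattr(inc, name):10.2f} {getattr(exc, name):10.2f} {true:9.2f}"
    )
print(
    "\nthe FLAIR WM sigma of the included fit is consistently (if slightly)"
    "\nwider: the lesion component absorbs most lesion mass, but rim voxels"
    "\nstill share responsibility with the WM component. The excluded fit is"
    "\nthe pure NAWM heterogeneity measure."
)
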