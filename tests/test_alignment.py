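"""Histogram registration: recovery, error functional, QC gate, voxel transform."""

import numpy as np
import pytest

from nawmetrics.alignment import (
    AlignmentResult,
    IntensityAffine,
    alignment_error,
    apply_intensity_transform,
    qc_gate,
    register_histogram,
)
from nawmetrics.histogram import BivariateHistogram, build_bivariate_histogram
from nawmetrics.io_prep import extract_paired_intensities
from nawmetrics.synthetic import PhantomSpec, generate_phantom


class TestIntensityAffine:
    def test_identity_representable_exactly(self):
        t = IntensityAffine.identity()
        pts = np.array([[1.0, 2.0], [300.0, 400.0]])
        np.testing.assert_array_equal(t.apply(pts), pts)

    def test_inverse_and_compose(self):
        t = IntensityAffine(linear=[[1.2, 0.1], [-0.05, 0.9]], offset=[30.0, -20.0])
        comp = t.compose(t.inverse())
        np.testing.assert_allclose(comp.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(comp.offset, 0.0, atol=1e-9)

    def test_orientation_reversing_rejected(self):
        with pytest.raises(ValueError, match="det"):
            IntensityAffine(linear=[[-1.0, 0.0], [0.0, 1.0]])

    def test_json_round_trip(self, tmp_path):
        t = IntensityAffine(linear=[[1.1, 0.0], [0.0, 0.95]], offset=[5.0, -3.0])
        p = tmp_path / "t.json"
        t.to_json(p)
        back = IntensityAffine.from_json(p)
        np.testing.assert_array_equal(back.linear, t.linear)
        np.testing.assert_array_equal(back.offset, t.offset)


class TestErrorFunctional:
    def test_zero_for_identical_histograms_under_identity(self, atlas):
        ref = atlas.reference_histogram
        err = alignment_error(ref, atlas, IntensityAffine.identity())
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_reaches_analytic_bound(self, atlas):
        # all subject mass far from the reference support: SSD of sqrt
        # histograms approaches sum of both masses = 2
        n = atlas.binning.n_bins_t1
        counts = np.zeros((n, atlas.binning.n_bins_flair))
        counts[-1, -1] = 5000
        h = BivariateHistogram(
            counts, atlas.binning.edges_t1, atlas.binning.edges_flair, 5000
        )
        err = alignment_error(h, atlas, IntensityAffine.identity())
        assert err == pytest.approx(2.0, rel=0.05)

    def test_optimum_dominates_identity(self, atlas, fast_config):
        distortion = IntensityAffine(linear=np.diag([1.15, 0.9]), offset=[25.0, -30.0])
        pair, _, _ = generate_phantom(
            PhantomSpec(seed=55, scanner_effect=distortion, subject_id="d")
        )
        h = build_bivariate_histogram(extract_paired_intensities(pair), atlas.binning)
        res = register_histogram(h, atlas, opts=fast_config.optimizer)
        assert res.error <= alignment_error(h, atlas, IntensityAffine.identity())


class TestRegistration:
    def test_self_registration_is_identity(self, atlas, fast_config):
        res = register_histogram(
            atlas.reference_histogram, atlas, opts=fast_config.optimizer
        )
        np.testing.assert_allclose(res.transform.linear, np.eye(2), atol=1e-6)
        np.testing.assert_allclose(res.transform.offset, 0.0, atol=1e-3)
        assert res.error == pytest.approx(0.0, abs=1e-10)

    def test_known_distortion_recovered(self, atlas, fast_config):
        """Distort a control by A=diag(1.2,0.9), b=(30,-20); registration
        must invert it within 2% (linear) and 2 bin widths (offset)."""
        distortion = IntensityAffine(linear=np.diag([1.2, 0.9]), offset=[30.0, -20.0])
        pair, _, _ = generate_phantom(
            PhantomSpec(seed=77, scanner_effect=distortion, subject_id="dist")
        )
        h = build_bivariate_histogram(extract_paired_intensities(pair), atlas.binning)
        res = register_histogram(h, atlas, opts=fast_config.optimizer)
        comp = res.transform.compose(distortion)
        np.testing.assert_allclose(comp.linear, np.eye(2), atol=0.02)
        assert abs(comp.offset[0]) <= 2 * atlas.binning.bin_width_t1
        assert abs(comp.offset[1]) <= 2 * atlas.binning.bin_width_flair

    def test_degenerate_histogram_rejected(self, atlas):
        n = atlas.binning.n_bins_t1
        counts = np.zeros((n, atlas.binning.n_bins_flair))
        counts[5, 5] = 1000
        h = BivariateHistogram(
            counts, atlas.binning.edges_t1, atlas.binning.edges_flair, 1000
        )
        with pytest.raises(ValueError, match="degenerate"):
            register_histogram(h, atlas)

    def test_registration_is_deterministic(self, atlas, fast_config, control_histograms):
        a = register_histogram(control_histograms[1], atlas, opts=fast_config.optimizer)
        b = register_histogram(control_histograms[1], atlas, opts=fast_config.optimizer)
        np.testing.assert_array_equal(a.transform.to_params(), b.transform.to_params())
        assert a.error == b.error


class TestQcGate:
    @staticmethod
    def _results(errors):
        return [
            AlignmentResult(
                transform=IntensityAffine.identity(),
                error=e,
                converged=True,
                n_iterations=1,
                subject_id=f"s{i}",
            )
            for i, e in enumerate(errors)
        ]

    def test_all_below_threshold_keeps_everyone(self):
        kept, excluded, _ = qc_gate(self._results([0.1, 0.2, 0.3]), threshold=1.0)
        assert excluded == [] and len(kept) == 3

    def test_auto_threshold_is_median_plus_4mad(self):
        results = self._results([0.1, 0.1, 0.1, 9.0])
        kept, excluded, thr = qc_gate(results, threshold="auto")
        # median 0.1, MAD 0 -> threshold 0.1: only the outlier is excluded
        assert thr == pytest.approx(0.1)
        assert excluded == ["s3"]
        assert results[3].qc_pass is False and results[0].qc_pass is True

    def test_zero_threshold_excludes_all_positive_errors(self):
        kept, excluded, _ = qc_gate(self._results([0.5, 0.7]), threshold=0.0)
        assert kept == [] and len(excluded) == 2

    def test_plot_written(self, tmp_path):
        qc_gate(self._results([0.1, 0.2, 0.3]), plot_path=tmp_path / "qc.png")
        assert (tmp_path / "qc.png").stat().st_size > 0


class TestApplyTransform:
    def test_identity_leaves_in_mask_voxels_unchanged(self, control_phantom):
        pair, _, _ = control_phantom
        out = apply_intensity_transform(pair, IntensityAffine.identity())
        np.testing.assert_array_equal(
            out.t1w[pair.brain_mask], pair.t1w[pair.brain_mask]
        )
        assert out.t1w[~out.brain_mask].max() == 0.0

    def test_doubling_transform_doubles_intensities(self, control_phantom):
        pair, _, _ = control_phantom
        out = apply_intensity_transform(pair, IntensityAffine(linear=2 * np.eye(2)))
        m = pair.brain_mask
        np.testing.assert_allclose(out.t1w[m], 2 * pair.t1w[m])
        np.testing.assert_allclose(out.flair[m], 2 * pair.flair[m])

    def test_mask_and_voxel_count_preserved(self, control_phantom):
        pair, _, _ = control_phantom
        t = IntensityAffine(linear=[[1.1, 0.02], [0.0, 0.9]], offset=[10.0, -5.0])
        out = apply_intensity_transform(pair, t)
        np.testing.assert_array_equal(out.brain_mask, pair.brain_mask)

    def test_standardized_image_rehistogrammed_matches_reported_error(
        self, atlas, fast_config
    ):
        distortion = IntensityAffine(linear=np.diag([1.1, 0.95]), offset=[15.0, 10.0])
        pair, _, _ = generate_phantom(
            PhantomSpec(seed=88, scanner_effect=distortion, subject_id="c")
        )
        h = build_bivariate_histogram(extract_paired_intensities(pair), atlas.binning)
        res = register_histogram(h, atlas, opts=fast_config.optimizer)
        std = apply_intensity_transform(pair, res.transform)
        h2 = build_bivariate_histogram(extract_paired_intensities(std), atlas.binning)
        err2 = alignment_error(h2, atlas, IntensityAffine.identity())
        assert err2 <= 1.05 * res.error + 1e-6
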