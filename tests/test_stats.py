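"""Statistical battery: ANOVA, contrasts, ROC, regressions, PCA, LASSO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nawmetrics.stats import (
    BONFERRONI_ALPHA,
    group_anova,
    lasso_disability_model,
    pca_composite,
    posthoc_contrasts,
    rank_auc,
    roc_analysis,
    star_code,
    zscore_regression,
)


def _table(groups_values: dict) -> pd.DataFrame:
    rows = []
    for g, vals in groups_values.items():
        rows += [{"group": g, "x": v} for v in vals]
    return pd.DataFrame(rows)


class TestAnova:
    def test_zero_within_group_variance_is_maximally_significant(self):
        t = _table({"control": [1.0] * 5, "RRMS": [2.0] * 5})
        res = group_anova(t, "x")
        assert res.p < 1e-10 and res.significant

    def test_two_groups_f_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        t = _table({"control": a, "RRMS": b})
        res = group_anova(t, "x")
        tt = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(tt.statistic**2)
        assert res.p == pytest.approx(tt.pvalue)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_anova(_table({"control": [1.0, 2.0, 3.0]}), "x")

    def test_null_type_i_error_calibrated(self, rng):
        """Empirical rejection rate at alpha = 0.05/8 under the null sits
        inside the binomial 95% band (small-scale check; the full 1000-rep
        version runs in the end-to-end validation suite)."""
        n_rej = 0
        reps = 400
        for _ in range(reps):
            t = _table({g: rng.normal(0, 1, 20) for g in ("control", "RRMS", "SPMS")})
            if group_anova(t, "x").significant:
                n_rej += 1
        lo, hi = sps.binom.interval(0.95, reps, BONFERRONI_ALPHA)
        assert lo <= n_rej <= hi


class TestPosthoc:
    def test_identical_groups_rarely_significant(self, rng):
        t = _table({g: rng.normal(0, 1, 30) for g in ("control", "RRMS", "SPMS", "PPMS", "PRMS")})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, stars = posthoc_contrasts(t, "x")
        assert (p.values[np.triu_indices(5, 1)] > 0.001).all()

    def test_symmetry(self, rng):
        t = _table(
            {
                "control": rng.normal(0, 1, 20),
                "RRMS": rng.normal(1, 1, 20),
                "SPMS": rng.normal(2, 1, 20),
            }
        )
        p, _ = posthoc_contrasts(t, "x")
        np.testing.assert_allclose(p.values, p.values.T)

    def test_block_structure_of_planted_effects(self, rng):
        """Control != MS and RRMS != progressive, but the progressive
        subtypes are generated identically and stay indistinguishable."""
        t = _table(
            {
                "control": rng.normal(0.0, 1, 60),
                "RRMS": rng.normal(1.5, 1, 60),
                "SPMS": rng.normal(3.0, 1, 40),
                "PPMS": rng.normal(3.0, 1, 40),
                "PRMS": rng.normal(3.0, 1, 40),
            }
        )
        p, stars = posthoc_contrasts(t, "x")
        for ms in ("RRMS", "SPMS", "PPMS", "PRMS"):
            assert p.loc["control", ms] < 1e-5
        for prog in ("SPMS", "PPMS", "PRMS"):
            assert p.loc["RRMS", prog] < 1e-3
        prog_ps = [p.loc[a, b] for a, b in (("SPMS", "PPMS"), ("SPMS", "PRMS"), ("PPMS", "PRMS"))]
        assert all(pv > 0.05 for pv in prog_ps)
        assert all(stars.loc[a, b] == "" for a, b in (("SPMS", "PPMS"), ("PPMS", "PRMS")))

    def test_star_bins(self):
        assert star_code(0.04) == "+"
        assert star_code(0.005) == "*"
        assert star_code(5e-4) == "**"
        assert star_code(5e-5) == "***"
        assert star_code(5e-7) == "****"
        assert star_code(0.2) == ""


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis(np.r_[np.zeros(10), np.ones(10)], np.r_[np.zeros(10), np.ones(10)])
        assert r.auc == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0

    def test_null_auc_near_half(self, rng):
        r = roc_analysis(rng.normal(size=4000), rng.integers(0, 2, 4000))
        assert abs(r.auc - 0.5) < 0.03

    def test_rank_auc_equals_pair_counting_oracle(self, rng):
        """Mann-Whitney AUC == exhaustive concordant-pair fraction, with
        ties counted 1/2, on many small random sets (some with ties)."""
        for _ in range(200):
            n = int(rng.integers(5, 60))
            values = np.round(rng.normal(size=n), rng.integers(0, 3))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            cases = values[labels == 1]
            controls = values[labels == 0]
            gt = (cases[:, None] > controls[None, :]).sum()
            eq = (cases[:, None] == controls[None, :]).sum()
            brute = (gt + 0.5 * eq) / (len(cases) * len(controls))
            assert rank_auc(values, labels) == pytest.approx(brute)

    def test_direction_auto_flips_to_above_half(self, rng):
        x = np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.zeros(50), np.ones(50)]  # cases have LOWER scores
        r = roc_analysis(x, y)
        assert r.direction == "less" and r.auc > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis(np.arange(5.0), np.ones(5))


class TestZscoreRegression:
    def test_exact_linear_relation(self):
        pdds = np.tile(np.arange(9.0), 3)
        t = pd.DataFrame({"pdds": pdds, "b": 10.0 + 2.0 * pdds})
        r = zscore_regression(t, "b")
        # Z(b) on pdds: slope = 1/sd(pdds) since corr = 1
        assert r.beta == pytest.approx(1.0 / pdds.std(ddof=1))
        assert r.p < 1e-12

    def test_matches_pearson_identity(self, rng):
        pdds = rng.integers(0, 9, 20).astype(float)
        b = rng.normal(size=20)
        t = pd.DataFrame({"pdds": pdds, "b": b})
        r = zscore_regression(t, "b")
        rho = np.corrcoef(b, pdds)[0, 1]
        # beta = corr * sd(Z(b)) / sd(pdds) = corr / sd(pdds)
        assert r.beta == pytest.approx(rho / pdds.std(ddof=1))

    def test_null_type_i_error(self, rng):
        n_rej = 0
        reps = 500
        for _ in range(reps):
            t = pd.DataFrame(
                {"pdds": rng.integers(0, 9, 40).astype(float), "b": rng.normal(size=40)}
            )
            if zscore_regression(t, "b").p < 0.05:
                n_rej += 1
        lo, hi = sps.binom.interval(0.95, reps, 0.05)
        assert lo <= n_rej <= hi

    def test_zero_variance_rejected(self):
        t = pd.DataFrame({"pdds": np.arange(12.0) % 9, "b": np.ones(12)})
        with pytest.raises(ValueError, match="zero variance"):
            zscore_regression(t, "b")


class TestPca:
    def test_two_perfectly_correlated_columns(self, rng):
        x = rng.normal(size=50)
        comp = pca_composite(np.column_stack([x, 3 * x + 1]))
        assert comp.variance_explained == pytest.approx(1.0)

    def test_orthogonal_columns_share_variance_equally(self, rng):
        n, k = 200000, 4
        comp = pca_composite(rng.normal(size=(n, k)))
        assert comp.variance_explained == pytest.approx(1 / k, abs=0.01)

    def test_planted_single_factor_structure(self, rng):
        """3 measures = 0.9 x factor + noise: PC1 share matches the
        eigenvalue of the planted correlation matrix."""
        n = 50000
        f = rng.normal(size=n)
        lam = 0.9
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.normal(size=(n, 3))
        comp = pca_composite(X)
        # analytic: corr = lam^2 off-diagonal -> top eigenvalue 1 + 2 lam^2
        expected = (1 + 2 * lam**2) / 3
        assert abs(comp.variance_explained - expected) / expected < 0.03

    def test_sign_convention_and_constant_column(self, rng):
        X = rng.normal(size=(100, 3))
        comp = pca_composite(X)
        assert comp.loadings[np.argmax(np.abs(comp.loadings))] > 0
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="constant"):
            pca_composite(X)


class TestLasso:
    @staticmethod
    def _data(rng, n=500, beta=2.0, n_noise=13):
        X = rng.normal(size=(n, 1 + n_noise))
        y = beta * X[:, 0] + rng.normal(size=n)
        cols = ["signal"] + [f"noise_{i}" for i in range(n_noise)]
        df = pd.DataFrame(X, columns=cols)
        df["pdds"] = y
        return df, cols

    def test_informative_feature_selected_and_noise_suppressed(self, rng):
        df, cols = self._data(rng)
        rep = lasso_disability_model(df, cols, seed=3)
        assert "signal" in rep.selected
        assert rep.holdout_r2 > 0.5

    def test_huge_penalty_zeroes_everything(self, rng):
        from sklearn.linear_model import Lasso

        df, cols = self._data(rng)
        m = Lasso(alpha=1e6).fit(df[cols].to_numpy(), df["pdds"].to_numpy())
        assert (m.coef_ == 0).all()

    def test_seeded_runs_are_identical(self, rng):
        df, cols = self._data(rng)
        a = lasso_disability_model(df, cols, seed=11)
        b = lasso_disability_model(df, cols, seed=11)
        assert a.selected == b.selected and a.holdout_r2 == b.holdout_r2

    def test_lower_noise_duplicate_preferred(self):
        """Of two equally predictive correlated copies, the copy with less
        measurement noise is the one LASSO keeps (majority of seeds)."""
        wins = 0
        n_informative_seeds = 10
        for seed in range(n_informative_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            f = rng.normal(size=n)
            df = pd.DataFrame(
                {
                    "clean": f + rng.normal(0, 0.2, n),
                    "noisy": f + rng.normal(0, 0.8, n),
                    "pdds": 2 * f + rng.normal(0, 1, n),
                }
            )
            rep = lasso_disability_model(df, ["clean", "noisy"], seed=seed)
            if abs(rep.coefficients["clean"]) > abs(rep.coefficients["noisy"]):
                wins += 1
        assert wins >= 0.8 * n_informative_seeds

    def test_insufficient_data_rejected(self, rng):
        df, cols = self._data(rng, n=20)
        with pytest.raises(ValueError, match="complete cases"):
            lasso_disability_model(df, cols)
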