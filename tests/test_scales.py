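"""Elastic-net scale prediction: target-sparsity search, LOSO evaluation,
grid-wide correction, parsimonious selection and stable supports."""

import numpy as np
import pytest

import connstab as cs
from connstab.cohort import CohortSample
from connstab.features import FeatureMatrix
from connstab.scales import (
    ENConfigResult,
    _en_solve,
    fit_en_target_sparsity,
    predict_scales_loso,
)


def _patient_fm(values, n_subjects, runs, scales_per_subject):
    samples = []
    for i in range(n_subjects):
        for r in range(runs):
            samples.append(
                CohortSample(
                    subject_id=f"p{i:03d}",
                    run_id=r + 1,
                    site_id="site01",
                    group="patient",
                    scales=dict(scales_per_subject[i]),
                )
            )
    desc = [(0, j + 1) for j in range(values.shape[1])]
    return FeatureMatrix(values, "link_weight", desc, samples)


class TestUnivariateCorrelations:
    def test_feature_equal_to_scale(self, rng):
        y = rng.integers(0, 6, 40).astype(float)
        X = np.column_stack([y, -y, rng.standard_normal(40)])
        rho = cs.univariate_scale_correlations(X, y)
        assert rho[0] == pytest.approx(1.0)
        assert rho[1] == pytest.approx(-1.0)

    def test_independent_feature_near_zero(self):
        # null band: |rho| < 0.2 at n=200 holds with prob ~0.995 per draw
        rng = np.random.default_rng(4)
        y = rng.integers(0, 6, 200).astype(float)
        X = rng.standard_normal((200, 50))
        rho = cs.univariate_scale_correlations(X, y)
        assert np.mean(np.abs(rho) < 0.2) >= 0.95

    def test_constant_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            cs.univariate_scale_correlations(rng.standard_normal((10, 2)), np.ones(10))


class TestTargetSparsityFit:
    def test_huge_lambda1_all_zero(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        fit = _en_solve(X, y, lambda1=1e6, lambda2=0.1)
        assert len(fit.support) == 0

    def test_single_informative_feature_recovered(self, rng):
        X = rng.standard_normal((60, 15))
        y = 2.0 * X[:, 1]
        fit = fit_en_target_sparsity(X, y, target_nonzero=1, lambda2=0.01)
        assert fit.support.tolist() == [1]

    def test_support_monotone_along_lambda1_path(self, rng):
        X = rng.standard_normal((50, 30))
        y = X[:, :5] @ rng.standard_normal(5) + 0.1 * rng.standard_normal(50)
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
        lams = np.geomspace(lam_max * 1e-3, lam_max, 12)
        sizes = [len(_en_solve(X, y, l1, 0.1).support) for l1 in lams]
        # allow unit-sized path jumps, require the non-increasing trend
        assert all(b <= a + 1 for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] <= sizes[0]

    def test_support_never_exceeds_target(self, rng):
        X = rng.standard_normal((40, 25))
        y = X @ rng.standard_normal(25)
        for target in (3, 10, 20):
            fit = fit_en_target_sparsity(X, y, target, lambda2=0.1)
            assert 1 <= len(fit.support) <= target

    def test_uncorrelated_target_flagged_empty(self):
        X = np.zeros((10, 4))
        fit = fit_en_target_sparsity(X, np.ones(10), 2, 0.1)
        assert fit.empty


class TestLOSOPrediction:
    def _linear_cohort(self, rng, n_subjects=25, runs=3, n_feat=15, noise=0.0):
        subj_signal = rng.standard_normal((n_subjects, 3))
        latent = subj_signal @ np.array([1.0, 0.8, 0.6])
        edges = np.quantile(latent, np.linspace(0, 1, 7)[1:-1])
        scores = np.digitize(latent, edges)
        X = rng.standard_normal((n_subjects * runs, n_feat)) * 0.5
        for j in range(3):
            X[:, j] = np.repeat(subj_signal[:, j], runs) + noise * rng.standard_normal(
                n_subjects * runs
            )
        scales = [{"scale_1": int(s)} for s in scores]
        return _patient_fm(X, n_subjects, runs, scales)

    def test_noiseless_linear_scale_recovered(self):
        rng = np.random.default_rng(2)
        fm = self._linear_cohort(rng, noise=0.0)
        res = predict_scales_loso(fm, "scale_1", [cs.ENConfig(5, 0.01)])
        assert res.entries[0].rho > 0.9

    def test_permuted_scale_in_null_band(self):
        rng = np.random.default_rng(5)
        fm = self._linear_cohort(rng, noise=0.3)
        y = np.array([s.scales["scale_1"] for s in fm.samples], float)
        perm_subjects = rng.permutation(25)
        y_perm = y.reshape(25, 3)[perm_subjects].ravel()
        res = predict_scales_loso(fm, "scale_1", [cs.ENConfig(5, 0.1)], scale_values=y_perm)
        # 95% permutation band for n=75 pooled (25 independent subjects):
        # |rho| < 2/sqrt(25)
        assert abs(res.entries[0].rho) < 0.4

    def test_missing_scale_subject_excluded(self):
        rng = np.random.default_rng(1)
        fm = self._linear_cohort(rng)
        fm.samples[0].scales["scale_1"] = None
        fm.samples[1].scales["scale_1"] = None
        fm.samples[2].scales["scale_1"] = None
        with pytest.warns(UserWarning):
            res = predict_scales_loso(fm, "scale_1", [cs.ENConfig(5, 0.1)])
        assert res.n_subjects == 24

    def test_constant_predictions_flagged(self):
        rng = np.random.default_rng(0)
        scales = [{"scale_1": int(v)} for v in rng.integers(0, 6, 10)]
        fm = _patient_fm(np.zeros((20, 5)), 10, 2, scales)
        res = predict_scales_loso(fm, "scale_1", [cs.ENConfig(2, 0.1)])
        assert res.entries[0].degenerate
        assert res.entries[0].pvalue == 1.0
        assert np.isnan(res.entries[0].rho)


def _entry(scale, target, lam2, rho, p, fdr=True, bon=False):
    e = ENConfigResult(
        scale=scale, target_nonzero=target, lambda2=lam2, rho=rho, pvalue=p, mae=0.5
    )
    e.fdr = fdr
    e.bonferroni = bon
    return e


class TestCorrectionAndSelection:
    def test_single_tiny_p_survives_bonferroni(self):
        entries = [_entry("s", 50, 0.1, 0.1, 0.5) for _ in range(134)]
        entries.append(_entry("s", 50, 0.1, 0.5, 1e-10))
        cs.correct_over_configs(entries, alpha=0.05)
        assert entries[-1].bonferroni and entries[-1].fdr
        assert not any(e.bonferroni for e in entries[:-1])

    def test_all_flat_p_none_survive(self):
        entries = [_entry("s", 50, 0.1, 0.1, 0.5) for _ in range(10)]
        cs.correct_over_configs(entries)
        assert not any(e.fdr or e.bonferroni for e in entries)

    def test_bonferroni_implies_fdr(self, rng):
        entries = [
            _entry("s", 50, 0.1, 0.1, float(p)) for p in rng.random(135) ** 3
        ]
        cs.correct_over_configs(entries)
        assert all(e.fdr for e in entries if e.bonferroni)

    def test_parsimonious_rule_on_published_style_table(self):
        # three significant configs; the middle one is within 5% of the best
        # correlation but far sparser, so it must be chosen
        entries = [
            _entry("SS35", 50, 0.1, 0.30, 1e-3),
            _entry("SS35", 300, 0.1, 0.4670, 2.34e-11),
            _entry("SS35", 700, 0.1, 0.4894, 1.79e-12),
        ]
        chosen = cs.select_parsimonious(entries)
        assert chosen.target_nonzero == 300

    def test_single_config_selected(self):
        e = _entry("s", 100, 0.1, 0.4, 1e-5)
        assert cs.select_parsimonious([e]) is e

    def test_equal_rho_prefers_smallest_support_then_lambda2(self):
        entries = [
            _entry("s", 300, 0.01, 0.4, 1e-5),
            _entry("s", 100, 1.0, 0.4, 1e-5),
            _entry("s", 100, 0.1, 0.4, 1e-5),
        ]
        chosen = cs.select_parsimonious(entries)
        assert (chosen.target_nonzero, chosen.lambda2) == (100, 0.1)

    def test_no_significant_config_returns_none(self):
        entries = [_entry("s", 50, 0.1, 0.3, 0.5, fdr=False)]
        assert cs.select_parsimonious(entries) is None


class TestStableSupport:
    def test_identical_supports(self):
        sup = [np.array([1, 5, 9])] * 3
        idx, desc = cs.stable_en_support(sup, [(i, i + 1) for i in range(10)])
        assert idx.tolist() == [1, 5, 9]
        assert desc == [(1, 2), (5, 6), (9, 10)]

    def test_disjoint_supports_empty(self):
        idx, _ = cs.stable_en_support([np.array([1]), np.array([2])])
        assert len(idx) == 0

    def test_stable_subset_of_every_fold(self, rng):
        sup = [rng.choice(30, size=10, replace=False) for _ in range(6)]
        idx, _ = cs.stable_en_support(sup)
        for s in sup:
            assert set(idx).issubset(set(s.tolist()))


class TestSeverityModel:
    def test_fit_produces_table_and_containment(self, small_link_fm):
        model = cs.SeverityEN(
            small_link_fm,
            scale_names=["scale_1", "scale_2"],
            target_grid=[3, 6],
            lambda2_grid=[0.1],
        )
        res = model.fit()
        df = res.table()
        assert len(df) == 2
        for r in res.per_scale.values():
            src = r.chosen if r.chosen is not None else r.best
            for sup in src.supports:
                assert set(r.stable_support).issubset(set(sup.tolist()))
        assert "configurations tested" in res.summary()
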