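"""Trait preprocessing, covA regressions, BH-FDR, sibship logic."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from ancestra import (
    bh_fdr,
    build_sibships,
    fit_cova_model,
    fit_sibling_model,
    preprocess_trait,
)


def series(values, ids=None, name="t"):
    idx = ids if ids is not None else [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=idx, name=name)


class TestPreprocessTrait:
    def test_extreme_outlier_removed_by_4iqr(self):
        vals = list(range(101)) + [10**6]
        tv = preprocess_trait(series(vals))
        assert tv.n_removed == 1
        assert len(tv.values) == 101

    def test_standardized_output(self):
        rng = np.random.default_rng(0)
        tv = preprocess_trait(series(rng.normal(50, 5, 500)))
        assert abs(tv.values.mean()) < 1e-10
        assert abs(tv.values.std(ddof=0) - 1) < 1e-10

    def test_clean_sample_untouched_up_to_affine(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(0, 1, 300)
        tv = preprocess_trait(series(raw))
        assert tv.n_removed == 0
        r = np.corrcoef(raw, tv.values.to_numpy())[0, 1]
        assert r > 0.999999

    def test_log_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            preprocess_trait(series([1.0, -2.0, 3.0]), log=True)

    def test_log_then_filter_order(self):
        # huge raw value that is NOT an outlier after log
        vals = np.exp(np.linspace(0, 5, 50))
        tv = preprocess_trait(series(vals), log=True)
        assert tv.n_removed == 0

    def test_adjustment_residualizes(self):
        rng = np.random.default_rng(2)
        bmi = rng.normal(25, 3, 400)
        trait = 2.0 * bmi + rng.normal(0, 1, 400)
        tv = preprocess_trait(series(trait), adjust_on=series(bmi))
        r = np.corrcoef(bmi[: len(tv.values)], tv.values.to_numpy())[0, 1]
        assert abs(r) < 0.05

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            preprocess_trait(series([1.0] * 10))


class TestFitCovaModel:
    def test_linear_recovery(self):
        rng = np.random.default_rng(3)
        n = 4000
        cova = series(rng.normal(0, 1, n))
        trait = preprocess_trait(series(0.3 * cova.to_numpy() + rng.normal(0, 1, n)))
        res = fit_cova_model(trait, cova, ancestry="WHG")
        # slope on the standardized trait scale: 0.3 / sd(t)
        expected = 0.3 / np.sqrt(0.3**2 + 1)
        assert abs(res.estimate - expected) < 3 * res.se
        assert res.model == "linear" and res.ancestry == "WHG"

    def test_logistic_recovery(self):
        rng = np.random.default_rng(4)
        n = 6000
        cova = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.5 * cova)))
        y = (rng.random(n) < p).astype(int)
        tv = preprocess_trait(series(y), trait_type="categorical")
        res = fit_cova_model(tv, series(cova), ancestry="EEF")
        log_or = np.log(res.estimate)
        assert abs(log_or - 0.5) < 3 * res.se
        assert res.model == "logistic" and res.estimate > 0

    def test_ordinal_proportional_odds(self):
        rng = np.random.default_rng(5)
        n = 3000
        cova = rng.normal(0, 1, n)
        latent = 0.8 * cova + np.random.default_rng(6).logistic(size=n)
        y = np.digitize(latent, [-1.0, 1.0])  # three ordered categories
        tv = preprocess_trait(series(y), trait_type="ordinal")
        res = fit_cova_model(tv, series(cova), ancestry="SBA")
        assert abs(np.log(res.estimate) - 0.8) < 3 * res.se
        assert res.model == "ordinal"

    def test_null_calibration_small(self):
        rng = np.random.default_rng(7)
        n, reps = 500, 200
        rejections = 0
        for _ in range(reps):
            cova = series(rng.normal(0, 1, n))
            trait = preprocess_trait(series(rng.normal(0, 1, n)))
            res = fit_cova_model(trait, cova)
            rejections += res.pvalue < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se

    def test_collinearity_named(self):
        rng = np.random.default_rng(8)
        n = 100
        cova = series(rng.normal(0, 1, n))
        trait = preprocess_trait(series(rng.normal(0, 1, n)))
        covs = pd.DataFrame(
            {"a": rng.normal(0, 1, n)}, index=cova.index
        )
        covs["b"] = 2 * covs["a"]
        with pytest.raises(ValueError, match="collinearity"):
            fit_cova_model(trait, cova, covariates=covs)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(9)
        n = 800
        cova = series(rng.normal(0, 1, n))
        raw = 0.4 * cova.to_numpy() + rng.normal(0, 1, n)
        import statsmodels.api as sm

        tv_raw = series(raw)
        # unstandardized fits: scaling the trait scales the slope
        X = sm.add_constant(cova.to_numpy())
        b1 = sm.OLS(raw, X).fit().params[1]
        b5 = sm.OLS(5 * raw, X).fit().params[1]
        assert abs(b5 - 5 * b1) < 1e-10
        # the standardized pipeline is scale-free
        r1 = fit_cova_model(preprocess_trait(tv_raw), cova)
        r5 = fit_cova_model(preprocess_trait(series(5 * raw)), cova)
        assert abs(r1.estimate - r5.estimate) < 1e-10


class TestBhFdr:
    def test_step_up_example(self):
        out = bh_fdr([0.01, 0.02, 0.04, 0.8], q=0.05)
        assert list(out["significant"]) == [True, True, False, False]

    def test_all_tiny_all_significant(self):
        out = bh_fdr([0.001] * 10, q=0.05)
        assert out["significant"].all()

    def test_adjusted_monotone_in_sorted_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.0001, 1, 50)
        out = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(out["qvalue"].to_numpy()[order]) >= -1e-12).all()

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_equals_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1, m)
            out = bh_fdr(p, q=0.05)
            ref_flags, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(out["qvalue"], ref_adj, atol=1e-12)
            assert (out["significant"].to_numpy() == ref_flags).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


def kin(id1, id2, k, fs=True):
    return {"id1": id1, "id2": id2, "kinship": k, "full_sib": fs}


class TestBuildSibships:
    def test_valid_pair_kept(self):
        sib = build_sibships(pd.DataFrame([kin("a", "b", 0.25)]))
        assert sib.n_sibships == 1 and set(sib.membership.index) == {"a", "b"}

    def test_kinship_below_bound_excluded(self):
        sib = build_sibships(pd.DataFrame([kin("a", "b", 0.10)]))
        assert sib.n_sibships == 0

    def test_incomplete_triangle_removed(self):
        table = pd.DataFrame(
            [kin("a", "b", 0.25), kin("a", "c", 0.25), kin("b", "c", 0.25, fs=False)]
        )
        sib = build_sibships(table)
        assert sib.n_sibships == 0

    def test_complete_triangle_kept(self):
        table = pd.DataFrame(
            [kin("a", "b", 0.25), kin("a", "c", 0.25), kin("b", "c", 0.2)]
        )
        sib = build_sibships(table)
        assert sib.sizes.iloc[0] == 3

    def test_self_pair_errors(self):
        with pytest.raises(ValueError):
            build_sibships(pd.DataFrame([kin("a", "a", 0.25)]))


def _confounded_sibs(n_sib=300, b=0.4, conf=0.8, seed=12):
    """Sibships whose shared environment tracks the sibship-mean covA."""
    rng = np.random.default_rng(seed)
    ids, covas, traits, sibs = [], [], [], []
    for s in range(n_sib):
        mu = rng.normal(0, 1)
        shared_env = conf * mu + rng.normal(0, 0.3)
        for j in range(2):
            c = mu + rng.normal(0, 1)
            t = b * c + shared_env + rng.normal(0, 1)
            ids.append(f"s{s}_{j}")
            covas.append(c)
            traits.append(t)
            sibs.append(s)
    cova = pd.Series(covas, index=ids)
    trait = pd.Series(traits, index=ids)
    member = pd.Series(sibs, index=ids)
    return cova, trait, member


class TestFitSiblingModel:
    def test_decomposition_identity_and_robustness(self):
        from ancestra.association import SibshipAssignment, TraitVector

        cova, trait, member = _confounded_sibs()
        sibs = SibshipAssignment(membership=member)
        tv = TraitVector(values=trait, trait_type="continuous", name="t")
        within = fit_sibling_model(tv, cova, sibs)
        standard = fit_cova_model(tv, cova)
        b = 0.4
        assert abs(within.estimate - b) < 3 * within.se
        assert abs(standard.estimate - b) > 3 * standard.se  # biased upward

    def test_identical_twins_degenerate(self):
        from ancestra.association import SibshipAssignment, TraitVector

        ids = ["a", "b", "c", "d"]
        cova = pd.Series([1.0, 1.0, -1.0, -1.0], index=ids)
        trait = pd.Series([0.1, 0.2, 0.3, 0.4], index=ids)
        sibs = SibshipAssignment(membership=pd.Series([0, 0, 1, 1], index=ids))
        tv = TraitVector(values=trait, trait_type="continuous", name="t")
        with pytest.raises(ValueError, match="collinearity"):
            fit_sibling_model(tv, cova, sibs)

    def test_all_singletons_error(self):
        from ancestra.association import SibshipAssignment, TraitVector

        sibs = SibshipAssignment(membership=pd.Series({"a": 0, "b": 1}))
        tv = TraitVector(
            values=pd.Series({"a": 0.1, "b": 0.2}), trait_type="continuous", name="t"
        )
        with pytest.raises(ValueError, match="at least two"):
            fit_sibling_model(tv, pd.Series({"a": 1.0, "b": 2.0}), sibs)
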