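"""Test/derived split, site weights and the weighted IRLS fit."""

import numpy as np
import pytest
from scipy.special import expit

from trisskit.derivation import (
    SplitSpec,
    derive_model,
    fit_weighted_logistic,
    site_weights,
    split_test_derived,
)
from trisskit.exceptions import RankDeficiencyError, TrisskitError
from trisskit.registry import PatientRecord


def site_records(n_a, n_b):
    recs = [
        PatientRecord(patient_id=f"A{i}", site="SPBRA", age_years=30,
                      mechanism="blunt")
        for i in range(n_a)
    ]
    recs += [
        PatientRecord(patient_id=f"B{i}", site="SDEUA", age_years=30,
                      mechanism="blunt")
        for i in range(n_b)
    ]
    return recs


class TestSplit:
    def test_published_cohort_arithmetic(self):
        """2416 and 8172 per site minus 300 each -> 2116 and 7872."""
        recs = site_records(2416, 8172)
        test, derived = split_test_derived(recs, SplitSpec(300, seed=1))
        assert len(test) == 600
        by_site = {}
        for r in derived:
            by_site[r.site] = by_site.get(r.site, 0) + 1
        assert by_site == {"SPBRA": 2116, "SDEUA": 7872}

    def test_partition_disjoint_exhaustive_reproducible(self):
        recs = site_records(400, 500)
        t1, d1 = split_test_derived(recs, SplitSpec(100, seed=7))
        t2, d2 = split_test_derived(recs, SplitSpec(100, seed=7))
        assert [r.patient_id for r in t1] == [r.patient_id for r in t2]
        ids_t = {r.patient_id for r in t1}
        ids_d = {r.patient_id for r in d1}
        assert not ids_t & ids_d
        assert len(ids_t | ids_d) == len(recs)

    def test_zero_test_size(self):
        recs = site_records(5, 5)
        test, derived = split_test_derived(recs, SplitSpec(0, seed=0))
        assert test == [] and derived == recs

    def test_small_site_error_names_site(self):
        with pytest.raises(TrisskitError, match="SPBRA"):
            split_test_derived(site_records(10, 400), SplitSpec(300, seed=0))


class TestSiteWeights:
    def test_published_ratio(self):
        recs = site_records(2116, 7872)
        w_pub = site_weights(recs, mode="published")
        w_exact = site_weights(recs, mode="exact")
        assert set(w_pub[:2116]) == {3.72}
        assert set(w_pub[2116:]) == {1.0}
        assert w_exact[0] == pytest.approx(7872 / 2116)
        assert round(7872 / 2116, 2) == 3.72

    def test_equal_counts_all_ones(self):
        assert np.all(site_weights(site_records(50, 50)) == 1.0)

    def test_one_site_warns_all_ones(self):
        with pytest.warns(UserWarning):
            w = site_weights(site_records(10, 0))
        assert np.all(w == 1.0)

    def test_three_sites_rejected(self):
        recs = site_records(5, 5)
        recs.append(PatientRecord(patient_id="C0", site="OTHER", age_years=30,
                                  mechanism="blunt"))
        with pytest.raises(TrisskitError):
            site_weights(recs)


def simulate_logistic(n, beta, seed, k=None):
    rng = np.random.default_rng(seed)
    k = k if k is not None else len(beta) - 1
    X = rng.normal(size=(n, k))
    p = expit(beta[0] + X @ np.asarray(beta[1:]))
    y = (rng.random(n) < p).astype(float)
    return X, y


class TestWeightedFit:
    def test_parameter_recovery_large_n(self):
        beta = np.array([0.5, -1.0, 0.7, 0.3])
        X, y = simulate_logistic(50_000, beta, seed=3)
        res = fit_weighted_logistic(X, y)
        assert res.converged
        est = np.array([res.coefficient_set.intercept, *res.coefficient_set.slopes])
        se = np.array(res.standard_errors)
        assert np.all(np.abs(est - beta) < 3 * se)

    def test_integer_weights_equal_row_replication(self):
        rng = np.random.default_rng(5)
        X, y = simulate_logistic(300, np.array([0.2, -0.8, 0.5]), seed=5)
        w = rng.integers(1, 4, size=300).astype(float)
        res_w = fit_weighted_logistic(X, y, w)
        idx = np.repeat(np.arange(300), w.astype(int))
        res_r = fit_weighted_logistic(X[idx], y[idx])
        a = [res_w.coefficient_set.intercept, *res_w.coefficient_set.slopes]
        b = [res_r.coefficient_set.intercept, *res_r.coefficient_set.slopes]
        assert np.allclose(a, b, atol=1e-8)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check against a reference IRLS implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        X, y = simulate_logistic(2_000, np.array([-0.3, 0.9, -0.6]), seed=11)
        w = rng.uniform(0.5, 4.0, size=2_000)
        res = fit_weighted_logistic(X, y, w)
        glm = sm.GLM(
            y, sm.add_constant(X), family=sm.families.Binomial(), var_weights=w
        ).fit()
        mine = [res.coefficient_set.intercept, *res.coefficient_set.slopes]
        assert np.allclose(mine, glm.params, atol=1e-7)
        assert np.allclose(res.standard_errors, glm.bse, rtol=1e-5)

    def test_constant_outcome_separation_diagnostic(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        res = fit_weighted_logistic(X, np.ones(50))
        assert not res.converged
        assert "separation" in res.diagnostic

    def test_perfectly_separated_data_flagged(self):
        x = np.linspace(-2, 2, 80)[:, None]
        y = (x[:, 0] > 0).astype(float)
        res = fit_weighted_logistic(x, y)
        assert not res.converged
        assert "separation" in res.diagnostic or "converge" in res.diagnostic

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        x0 = rng.normal(size=100)
        X = np.column_stack([x0, 2 * x0])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_weighted_logistic(X, y, column_names=["a", "b"])

    def test_coverage_of_wald_intervals(self):
        """~95% of +-1.96 SE intervals cover the truth over replicates."""
        beta = np.array([0.3, -0.7, 0.5])
        hits = 0
        reps = 200
        for r in range(reps):
            X, y = simulate_logistic(5_000, beta, seed=1000 + r)
            res = fit_weighted_logistic(X, y)
            est = np.array(
                [res.coefficient_set.intercept, *res.coefficient_set.slopes]
            )
            se = np.array(res.standard_errors)
            hits += np.sum(np.abs(est - beta) <= 1.96 * se)
        coverage = hits / (reps * 3)
        assert abs(coverage - 0.95) < 0.04


class TestDeriveModel:
    def test_single_mechanism_stratum_refused(self, small_registry):
        records, _ = small_registry
        blunt_only = [r for r in records if r.mechanism == "blunt"][:500]
        with pytest.warns(UserWarning, match="penetrating"):
            fits = derive_model(blunt_only, "ntriss_like", site_weighting=False)
        assert set(fits) == {"blunt"}
        assert fits["blunt"].converged

    def test_published_vs_exact_weights_negligible_on_large_n(self, small_registry):
        records, _ = small_registry
        f1 = derive_model(records, "ntriss_like", weights_mode="exact")
        f2 = derive_model(records, "ntriss_like", weights_mode="published")
        a = np.array([f1["blunt"].coefficient_set.intercept,
                      *f1["blunt"].coefficient_set.slopes])
        b = np.array([f2["blunt"].coefficient_set.intercept,
                      *f2["blunt"].coefficient_set.slopes])
        assert np.max(np.abs(a - b)) < 1e-2
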