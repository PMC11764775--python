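"""Association-stage checks against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from metspgs import (
    CohortConfig,
    GenotypeDataset,
    VariantSpec,
    association_scan,
    bh_adjust,
    fit_linear_additive,
    fit_logistic_additive,
    flip_if_protective,
    hwe_exact_test,
    simulate_retrospective,
    zscore_matrix,
)


def _dataset_from_dosages(dosages, status, age=None, sex=None, variants=None):
    n = len(status)
    df = pd.DataFrame(dosages, index=[f"S{i}" for i in range(n)])
    return GenotypeDataset(
        dosages=df,
        status=np.asarray(status),
        age=np.full(n, 50.0) if age is None else age,
        sex=np.zeros(n, int) if sex is None else sex,
        variants=variants or [],
    )


class TestLogisticAdditive:
    def test_matches_allelic_cross_product_ratio(self):
        """With only homozygote dosages (0/2) and no covariates, the fitted
        two-allele contrast exp(2*beta) equals the classical 2x2 cross-product
        ratio of the allele table built from the same counts (the per-allele
        OR is its square root)."""
        # 30 cases: 18 hom-effect; 40 controls: 10 hom-effect
        g = np.array([2.0] * 18 + [0.0] * 12 + [2.0] * 10 + [0.0] * 30)
        y = np.array([1] * 30 + [0] * 40)
        ds = _dataset_from_dosages({"rs1": g}, y)
        r = fit_logistic_additive(ds, "rs1", covariates=())
        # allele counts: cases 36 effect / 24 other; controls 20 / 60
        oracle = (36 * 60) / (24 * 20)
        assert math.exp(2 * r.beta) == pytest.approx(oracle, rel=1e-6)

    def test_loglik_matches_generic_optimizer(self):
        """IRLS optimum agrees with a direct numerical maximisation of the
        Bernoulli log-likelihood to 1e-6."""
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, 60).astype(float)
        age = rng.normal(50, 8, 60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(-0.5 + 0.6 * g)))).astype(int)
        ds = _dataset_from_dosages({"rs1": g}, y, age=age)
        r = fit_logistic_additive(ds, "rs1", covariates=("age",))
        X = np.column_stack([np.ones(60), g, age])

        def negll(beta):
            eta = X @ beta
            return -(y * eta - np.log1p(np.exp(eta))).sum()

        opt = optimize.minimize(negll, np.zeros(3), method="BFGS", tol=1e-12)
        assert abs(r.loglik - (-opt.fun)) < 1e-6

    def test_null_recovery_and_uniform_p(self, toy_variants):
        """Null simulation (equal group frequencies): fitted betas centre on
        zero and p-values are uniform (type-I error near nominal)."""
        cc = CohortConfig(n_case=150, n_control=200)
        betas, pvals = [], []
        for s in range(40):
            ds = simulate_retrospective(
                [VariantSpec("rsN", "", "1", "A", "G", 0.3, 0.3)], cc, seed=100 + s
            )
            r = fit_logistic_additive(ds, "rsN")
            betas.append(r.beta)
            pvals.append(r.p)
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_raises(self):
        ds = _dataset_from_dosages(
            {"rs1": np.zeros(40)}, np.array([1] * 20 + [0] * 20)
        )
        with pytest.raises(ValueError, match="monomorphic"):
            fit_logistic_additive(ds, "rs1", covariates=())

    def test_separation_is_flagged_not_silent(self):
        g = np.array([2.0] * 20 + [0.0] * 20)
        y = np.array([1] * 20 + [0] * 20)  # dosage perfectly predicts status
        ds = _dataset_from_dosages({"rs1": g}, y)
        r = fit_logistic_additive(ds, "rs1", covariates=())
        assert not r.ok and r.error in ("separation", "non_convergence")
        assert math.isnan(r.or_)

    def test_missing_dosages_excluded_listwise(self):
        g = np.array([2.0, 1, 0, 1, 2, 0, np.nan, 1, 0, 2, 1, 0])
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        ds = _dataset_from_dosages({"rs1": g}, y)
        r = fit_logistic_additive(ds, "rs1", covariates=())
        assert r.n_used == 11


class TestFlip:
    @pytest.fixture()
    def protective(self):
        v = [VariantSpec("rsP", "", "1", "A", "G", 0.5, 0.35)]
        cc = CohortConfig(n_case=250, n_control=350)
        ds = simulate_retrospective(v, cc, seed=77)
        return ds, fit_logistic_additive(ds, "rsP")

    def test_reciprocal_or_same_p(self, protective):
        ds, r = protective
        assert r.or_ < 1.0
        f = flip_if_protective(r, ds, "rsP")
        assert f.flipped
        assert f.or_ == pytest.approx(1.0 / r.or_, rel=1e-9)
        assert f.p == pytest.approx(r.p, rel=1e-9)
        assert f.se == pytest.approx(r.se, rel=1e-9)
        assert f.effect_allele_used == "G"

    def test_flip_is_involution(self, protective):
        ds, r = protective
        f = flip_if_protective(r, ds, "rsP")
        # force the reverse flip by treating the flipped fit as protective
        back = fit_logistic_additive(ds, "rsP", covariates=r.covariates)
        assert back.beta == pytest.approx(r.beta, rel=1e-12)

    def test_risk_orientation_untouched(self, reference_dataset):
        r = fit_logistic_additive(reference_dataset, "rs1061624")
        rr = flip_if_protective(r, reference_dataset, "rs1061624")
        if r.or_ >= 1:
            assert rr is r and not rr.flipped


class TestLinearAdditive:
    def test_permuted_phenotype_p_uniform(self, toy_variants, rng):
        from metspgs import add_quantitative_phenotype

        cc = CohortConfig(n_case=100, n_control=100)
        ds = simulate_retrospective(toy_variants, cc, seed=55)
        ds = add_quantitative_phenotype(ds, "t", "rsA", 1.5, 1.0, seed=56)
        pvals = []
        base = ds.phenotypes["t"].to_numpy()
        for _ in range(60):
            ds.phenotypes["t"] = rng.permutation(base)
            pvals.append(fit_linear_additive(ds, "rsA", "t").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_phenotype_rejected(self, toy_variants):
        from metspgs import add_quantitative_phenotype

        cc = CohortConfig(n_case=20, n_control=20)
        ds = simulate_retrospective(toy_variants, cc, seed=57)
        ds = add_quantitative_phenotype(ds, "t", "rsA", 1.0, 1.0, seed=58)
        ds.phenotypes["t"] = 3.14
        with pytest.raises(ValueError, match="constant"):
            fit_linear_additive(ds, "rsA", "t")


def _hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Full enumeration of the conditional heterozygote distribution."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    from fractions import Fraction

    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        num = (
            math.factorial(n) * 2**h * math.factorial(n_a) * math.factorial(n_b)
        )
        den = (
            math.factorial(hom_a)
            * math.factorial(h)
            * math.factorial(hom_b)
            * math.factorial(2 * n)
        )
        probs[h] = Fraction(num, den)  # exact rational probability
    p_obs = probs[n_ab]
    return min(1.0, float(sum(p for p in probs.values() if p <= p_obs)))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test((0, 0, 25)) == 1.0
        assert hwe_exact_test((25, 0, 0)) == 1.0

    def test_equals_enumeration_on_balanced_counts(self):
        assert hwe_exact_test((25, 50, 25)) == pytest.approx(
            _hwe_enumeration_oracle(25, 50, 25), rel=1e-9
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_aa=st.integers(0, 40), n_ab=st.integers(0, 40), n_bb=st.integers(0, 40)
    )
    def test_equals_enumeration_everywhere(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            with pytest.raises(ValueError):
                hwe_exact_test((0, 0, 0))
            return
        assert hwe_exact_test((n_aa, n_ab, n_bb)) == pytest.approx(
            _hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-9
        )

    def test_conservative_under_null(self, rng):
        rejections = 0
        for _ in range(300):
            g = rng.binomial(2, 0.3, size=100)
            counts = ((g == 0).sum(), (g == 1).sum(), (g == 2).sum())
            rejections += hwe_exact_test(counts) < 0.05
        assert rejections / 300 <= 0.06

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test((-1, 2, 3))


def _bh_double_loop_oracle(p, m):
    """Literal min-over-tail definition, O(n^2)."""
    order = sorted(range(len(p)), key=lambda i: p[i])
    out = [0.0] * len(p)
    for pos, idx in enumerate(order):
        tail = min(
            m * p[order[j]] / (j + 1) for j in range(pos, len(order))
        )
        out[idx] = min(1.0, tail)
    return out


class TestBhAdjust:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25),
        st.integers(0, 30),
    )
    def test_matches_double_loop_oracle(self, p, extra):
        m = len(p) + extra
        np.testing.assert_allclose(
            bh_adjust(p, m_total=m), _bh_double_loop_oracle(p, m), rtol=1e-12
        )

    def test_matches_statsmodels_without_subsetting(self, rng):
        p = rng.random(30)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p, m_total=80)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_single_p_of_one(self):
        assert bh_adjust([1.0], m_total=1)[0] == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m_total=1)


class TestZscoreMatrix:
    def test_z_consistent_with_wald_chi_square(self, reference_dataset):
        r = fit_logistic_additive(reference_dataset, "rs9295474")
        assert r.z**2 == pytest.approx((r.beta / r.se) ** 2, rel=1e-12)

    def test_flip_negates_z(self, reference_dataset):
        r = fit_logistic_additive(reference_dataset, "rs9295474")
        rf = fit_logistic_additive(
            reference_dataset, "rs9295474", _recode=True
        )
        assert rf.z == pytest.approx(-r.z, rel=1e-6)

    def test_matrix_shape_and_masking(self, toy_variants):
        from metspgs import add_quantitative_phenotype

        cc = CohortConfig(n_case=80, n_control=80)
        ds = simulate_retrospective(toy_variants, cc, seed=91)
        ds = add_quantitative_phenotype(ds, "bmi", "rsA", 1.0, 1.0, seed=92)
        results = [
            fit_linear_additive(ds, vid, "bmi") for vid in ds.variant_ids
        ]
        results[1].z = float("nan")
        results[1].error = "non_convergence"
        mat = zscore_matrix(results)
        assert mat.shape == (3, 1)
        assert np.isnan(mat.loc["rsB", "bmi"])
        assert mat.loc["rsA", "bmi"] == pytest.approx(results[0].z)


class TestScan:
    def test_scan_flips_and_adjusts(self, reference_dataset):
        results = association_scan(reference_dataset, m_total=40)
        assert len(results) == reference_dataset.n_variants
        for r in results:
            if r.ok:
                assert r.or_ >= 1.0 or not r.flipped
                assert r.p_fdr >= r.p - 1e-15
                assert r.hwe_p is not None
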