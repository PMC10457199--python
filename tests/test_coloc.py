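"""Colocalization: ABFs, posterior sums, conditioning, conditional coloc."""

import numpy as np
import pandas as pd
import pytest

from pqtlkit.coloc import (
    DEFAULT_PRIORS,
    coloc_pair,
    conditioned_sumstats,
    log_abf,
    pwcoco,
)
from pqtlkit.simulate import simulate_single_gwas
from pqtlkit.sumstats import VariantKey, mlog10p_from_z

from conftest import custom_ld, make_region_panel


def _frame_from_z(panel, z, n=10_000.0):
    f = panel["EAF"].to_numpy()
    se = 1.0 / np.sqrt(2 * f * (1 - f) * n)
    df = panel[["CHR", "POS", "EA", "OA", "EAF"]].copy()
    df["SE"] = se
    df["BETA"] = np.asarray(z) * se
    df["N"] = n
    df["MLOG10P"] = mlog10p_from_z(np.asarray(z))
    return df


def _mvn_z(r, beta_std, n, rng):
    L = np.linalg.cholesky(r + 1e-10 * np.eye(len(r)))
    return r @ (np.asarray(beta_std) * np.sqrt(n)) + L @ rng.standard_normal(len(r))


class TestLogAbf:
    def test_null_z_is_negative(self):
        assert log_abf(0.0, 0.1) < 0

    def test_uninformative_limit_tends_to_zero(self):
        assert abs(log_abf(0.1, 1e6)) < 1e-6

    def test_direct_formula_evaluation(self):
        # V=1e-4, W=0.0225, r=0.995575..., z=10
        val = log_abf(0.1, 0.01, prior_sd=0.15)
        r = 0.0225 / (1e-4 + 0.0225)
        expected = 0.5 * (np.log1p(-r) + r * 100.0)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(47.07, abs=0.01)

    def test_finite_for_extreme_z(self):
        assert np.isfinite(log_abf(2.0, 0.01))  # z = 200


class TestColocPair:
    def test_global_null_gives_pp0(self):
        panel, _ = make_region_panel(100, rho=0.0, seed=1)
        rng = np.random.default_rng(2)
        t1 = _frame_from_z(panel, rng.standard_normal(100) * 0.3)
        t2 = _frame_from_z(panel, rng.standard_normal(100) * 0.3)
        res = coloc_pair(t1, t2)
        assert res.pp[0] > 0.99

    def test_shared_causal_variant_gives_pp4(self):
        panel, ld = make_region_panel(200, rho=0.8, seed=3)
        rng = np.random.default_rng(4)
        z1 = _mvn_z(ld.r, np.eye(200)[100] * 0.1, 10_000, rng)
        z2 = _mvn_z(ld.r, np.eye(200)[100] * 0.1, 10_000, rng)
        res = coloc_pair(_frame_from_z(panel, z1), _frame_from_z(panel, z2))
        assert res.pp[4] > 0.95

    def test_distinct_uncorrelated_causal_variants_give_pp3(self):
        panel, ld = make_region_panel(200, rho=0.8, seed=5)
        rng = np.random.default_rng(6)
        z1 = _mvn_z(ld.r, np.eye(200)[40] * 0.1, 10_000, rng)
        z2 = _mvn_z(ld.r, np.eye(200)[160] * 0.1, 10_000, rng)
        res = coloc_pair(_frame_from_z(panel, z1), _frame_from_z(panel, z2))
        assert res.pp[3] > 0.95

    def test_posteriors_sum_to_one(self):
        panel, _ = make_region_panel(50, rho=0.0, seed=7)
        rng = np.random.default_rng(8)
        for _ in range(20):
            z1 = rng.standard_normal(50) * rng.uniform(0.5, 50)
            z2 = rng.standard_normal(50) * rng.uniform(0.5, 50)
            res = coloc_pair(_frame_from_z(panel, z1), _frame_from_z(panel, z2))
            assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(res.pp >= 0)

    def test_pp4_monotone_in_shared_prior(self):
        panel, ld = make_region_panel(50, rho=0.5, seed=9)
        rng = np.random.default_rng(10)
        z = _mvn_z(ld.r, np.eye(50)[25] * 0.08, 5000, rng)
        t1, t2 = _frame_from_z(panel, z), _frame_from_z(panel, z * 0.9)
        pp4s = [coloc_pair(t1, t2, priors=(1e-4, 1e-4, p12)).pp4
                for p12 in (1e-7, 1e-6, 1e-5, 1e-4)]
        assert all(a <= b + 1e-12 for a, b in zip(pp4s, pp4s[1:]))

    def test_symmetry_exchanges_pp1_pp2(self):
        panel, _ = make_region_panel(50, rho=0.0, seed=11)
        rng = np.random.default_rng(12)
        z1 = np.zeros(50); z1[10] = 8.0
        z2 = rng.standard_normal(50) * 0.2
        a = coloc_pair(_frame_from_z(panel, z1), _frame_from_z(panel, z2))
        b = coloc_pair(_frame_from_z(panel, z2), _frame_from_z(panel, z1))
        assert a.pp[1] == pytest.approx(b.pp[2], rel=1e-9)
        assert a.pp[0] == pytest.approx(b.pp[0], rel=1e-9)
        assert a.pp[4] == pytest.approx(b.pp[4], rel=1e-9)

    def test_no_overlap_and_extreme_z_edge_cases(self):
        panel, _ = make_region_panel(10, rho=0.0, seed=13)
        t1 = _frame_from_z(panel, np.zeros(10))
        t2 = t1.copy()
        t2["POS"] += 10_000_000
        with pytest.raises(ValueError, match="harmonize"):
            coloc_pair(t1, t2)
        # |z| = 200 stays finite through the log-sum-exp path
        z = np.zeros(10); z[3] = 200.0
        res = coloc_pair(_frame_from_z(panel, z), _frame_from_z(panel, z))
        assert np.all(np.isfinite(res.pp))
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_high_precision_oracle_on_ten_variant_toy(self):
        # independent exact-arithmetic evaluation of the hypothesis sums
        from fractions import Fraction
        panel, _ = make_region_panel(10, rho=0.0, seed=14)
        rng = np.random.default_rng(15)
        z1 = rng.standard_normal(10) * 3
        z2 = rng.standard_normal(10) * 3
        t1, t2 = _frame_from_z(panel, z1), _frame_from_z(panel, z2)
        res = coloc_pair(t1, t2)
        l1 = log_abf(t1["BETA"].to_numpy(), t1["SE"].to_numpy(), 0.15)
        l2 = log_abf(t2["BETA"].to_numpy(), t2["SE"].to_numpy(), 0.15)
        # moderate z: direct exponentiation is exact here, no log-space needed
        p1, p2, p12 = DEFAULT_PRIORS
        s1 = sum(np.exp(l1))
        s2 = sum(np.exp(l2))
        s12 = sum(np.exp(l1 + l2))
        s3 = sum(np.exp(l1[i] + l2[j]) for i in range(10) for j in range(10) if i != j)
        h = np.array([1.0, p1 * s1, p2 * s2, p1 * p2 * s3, p12 * s12])
        np.testing.assert_allclose(res.pp, h / h.sum(), rtol=1e-9)


class TestConditioning:
    def test_empty_condition_set_is_identity(self):
        panel, ld = make_region_panel(20, rho=0.5, seed=16)
        df = simulate_single_gwas(panel, ld, {10: 0.1}, 5000,
                                  np.random.default_rng(17))
        out = conditioned_sumstats(df, ld, [])
        pd.testing.assert_frame_equal(out, df)

    def test_orthogonal_conditioning_leaves_others_unchanged(self):
        panel, _ = make_region_panel(3, rho=0.0, seed=18)
        ld = custom_ld(panel, np.eye(3))
        df = _frame_from_z(panel, np.array([5.0, 1.0, 8.0]))
        key = VariantKey("1", int(panel["POS"].iloc[0]),
                         str(panel["EA"].iloc[0]), str(panel["OA"].iloc[0]))
        out = conditioned_sumstats(df, ld, [key])
        np.testing.assert_allclose(out["BETA"].iloc[1:], df["BETA"].iloc[1:],
                                   rtol=1e-12)
        assert out["BETA"].iloc[0] == 0.0

    def test_shadow_z_shrinks_after_conditioning_on_driver(self):
        panel, ld = make_region_panel(30, rho=0.9, seed=19)
        rng = np.random.default_rng(20)
        shrunk = 0
        for _ in range(60):
            df = simulate_single_gwas(panel, ld, {15: 0.15}, 14_824, rng)
            driver = VariantKey("1", int(panel["POS"].iloc[15]),
                                str(panel["EA"].iloc[15]), str(panel["OA"].iloc[15]))
            out = conditioned_sumstats(df, ld, [driver])
            z_shadow = abs(out["BETA"].iloc[16] / out["SE"].iloc[16])
            if z_shadow < 2:
                shrunk += 1
        assert shrunk / 60 >= 0.95

    def test_missing_conditioning_variant_raises(self):
        panel, ld = make_region_panel(5, rho=0.0, seed=21)
        df = _frame_from_z(panel, np.zeros(5))
        with pytest.raises(KeyError):
            conditioned_sumstats(df, ld, [VariantKey("1", 999, "A", "G")])


class TestPwcoco:
    def test_single_signal_traits_reduce_to_plain_coloc(self):
        panel, ld = make_region_panel(60, rho=0.7, seed=22)
        rng = np.random.default_rng(23)
        t1 = simulate_single_gwas(panel, ld, {30: 0.12}, 14_824, rng)
        t2 = simulate_single_gwas(panel, ld, {30: 0.12}, 30_000, rng)
        res = pwcoco(t1, t2, ld)
        plain = coloc_pair(t1, t2)
        assert len(res.matrix) == 1
        assert res.max_pp4 == pytest.approx(plain.pp4, rel=1e-9)

    def test_two_signal_trait_colocalizes_only_shared_signal(self):
        panel, ld = make_region_panel(80, rho=0.7, seed=24)
        rng = np.random.default_rng(25)
        # trait1 has signals at 20 and 60; trait2 shares only 60
        t1 = simulate_single_gwas(panel, ld, {20: 0.15, 60: 0.12}, 14_824, rng)
        t2 = simulate_single_gwas(panel, ld, {60: 0.12}, 30_000, rng)
        res = pwcoco(t1, t2, ld)
        assert res.max_pp4 > 0.8
        shared_pos = int(panel["POS"].iloc[60])
        pp4_other = [v.pp4 for k, v in res.matrix.items()
                     if k != ("marginal", "marginal")
                     and f":{shared_pos}" not in k[0]]
        assert all(p < 0.2 for p in pp4_other)

    def test_orthogonal_conditioning_equals_exact_signal_removal(self):
        # with r = 0 between signals, conditioning out the secondary is
        # exactly equivalent to deleting its effect from the data
        panel, _ = make_region_panel(40, rho=0.0, seed=26)
        ld = custom_ld(panel, np.eye(40))
        rng = np.random.default_rng(27)
        t1 = simulate_single_gwas(panel, ld, {10: 0.15, 30: 0.15}, 14_824, rng)
        t2 = simulate_single_gwas(panel, ld, {10: 0.12}, 30_000, rng)
        res = pwcoco(t1, t2, ld)
        pos10 = int(panel["POS"].iloc[10])
        conditioned = [v for k, v in res.matrix.items() if k[0] == f"1:{pos10}"]
        assert conditioned, "expected a conditioned result for the shared signal"
        t1_removed = t1.copy()
        t1_removed.loc[30, "BETA"] = 0.0
        manual = coloc_pair(t1_removed, t2)
        assert conditioned[0].pp4 == pytest.approx(manual.pp4, abs=1e-6)
        assert conditioned[0].pp4 > res.matrix[("marginal", "marginal")].pp4
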