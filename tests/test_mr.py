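"""MR: instrument selection, GSMR GLS estimate, HEIDI, FDR, robustness."""

import numpy as np
import pandas as pd
import pytest

from pqtlkit.mr import (
    InstrumentSet,
    MRResult,
    bh_qvalues,
    fdr_and_robustness,
    gsmr_estimate,
    heidi_outlier,
    ld_clump,
    mr_protein_disease,
    select_instruments,
)
from pqtlkit.simulate import (
    PlantedSignal,
    TruthTable,
    simulate_disease_gwas,
    simulate_single_gwas,
)
from pqtlkit.sumstats import VariantKey, mlog10p_from_z

from conftest import custom_ld, make_region_panel


def _instruments(b_zx, se_zx, b_zy, se_zy, r=None):
    k = len(b_zx)
    return InstrumentSet(
        exposure="protein",
        variants=[VariantKey("1", 100 + i, "A", "G") for i in range(k)],
        b_zx=np.asarray(b_zx, float), se_zx=np.asarray(se_zx, float),
        b_zy=np.asarray(b_zy, float), se_zy=np.asarray(se_zy, float),
        r=np.eye(k) if r is None else np.asarray(r, float))


def _exposure_frames(panel, ld, causal, n_exp=14_824, theta=0.3,
                     n_cases=50_000, n_controls=100_000, seed=0,
                     confounder_mode="none", **disease_kw):
    rng = np.random.default_rng(seed)
    exp_df = simulate_single_gwas(panel, ld, causal, n_exp, rng)
    truth = TruthTable(signals=[PlantedSignal("protein", i, b)
                                for i, b in causal.items()])
    out_df = simulate_disease_gwas(panel, ld, truth, theta, confounder_mode,
                                   n_cases, n_controls, rng=rng, **disease_kw)
    return exp_df, out_df


class TestSelectInstruments:
    def test_fewer_than_three_survivors_is_insufficient(self):
        panel, ld = make_region_panel(30, rho=0.8, seed=1)
        exp_df, out_df = _exposure_frames(panel, ld, {15: 0.15}, seed=2)
        assert select_instruments(exp_df, out_df, ld) == "insufficient"

    def test_correlated_pair_clumped_to_lower_p(self):
        panel, _ = make_region_panel(2, rho=0.0, seed=3)
        ld = custom_ld(panel, np.array([[1.0, 0.5], [0.5, 1.0]]))  # r2 = 0.25
        df = panel[["CHR", "POS", "EA", "OA"]].copy()
        df["MLOG10P"] = [12.0, 20.0]
        out = ld_clump(df, ld, r2_max=0.1)
        assert list(out["MLOG10P"]) == [20.0]

    def test_frequency_difference_filter(self):
        panel, ld = make_region_panel(40, rho=0.3, seed=4)
        exp_df, out_df = _exposure_frames(
            panel, ld, {5: 0.2, 20: 0.2, 35: 0.2}, seed=5)
        # corrupt the outcome frequency of one instrument beyond 0.4
        top = exp_df["MLOG10P"].nlargest(3).index
        bad_pos = exp_df.loc[top[0], "POS"]
        out_df.loc[out_df["POS"] == bad_pos, "EAF"] = 0.99
        exp_df.loc[exp_df["POS"] == bad_pos, "EAF"] = 0.01
        with pytest.warns(UserWarning, match="frequency"):
            ins = select_instruments(exp_df, out_df, ld)
        if ins != "insufficient":
            assert bad_pos not in [v.pos for v in ins.variants]

    def test_three_independent_signals_selected(self):
        panel, ld = make_region_panel(40, rho=0.3, seed=6)
        exp_df, out_df = _exposure_frames(
            panel, ld, {5: 0.2, 20: 0.2, 35: 0.2}, seed=7)
        ins = select_instruments(exp_df, out_df, ld)
        assert ins != "insufficient"
        assert len(ins) >= 3
        r_off = ins.r - np.diag(np.diag(ins.r))
        assert np.all(r_off ** 2 <= 0.1 + 1e-12)


class TestGsmrEstimate:
    def test_consensus_instruments_return_common_ratio(self):
        ins = _instruments([0.2, 0.4, 0.5], [0.01] * 3,
                           [0.1, 0.2, 0.25], [0.01] * 3)
        b, se, p = gsmr_estimate(ins)
        assert b == pytest.approx(0.5, rel=1e-10)

    def test_diagonal_covariance_equals_ivw_of_wald_ratios(self):
        rng = np.random.default_rng(8)
        k = 6
        ins = _instruments(rng.uniform(0.1, 0.4, k), rng.uniform(0.005, 0.02, k),
                           rng.normal(0.1, 0.05, k), rng.uniform(0.005, 0.02, k))
        b, se, _ = gsmr_estimate(ins)
        ratio = ins.b_zy / ins.b_zx
        var = (ins.se_zy**2 + ratio**2 * ins.se_zx**2) / ins.b_zx**2
        w = 1 / var
        assert b == pytest.approx(np.sum(w * ratio) / w.sum(), rel=1e-10)
        assert se == pytest.approx(1 / np.sqrt(w.sum()), rel=1e-10)

    def test_planted_theta_recovered_within_three_se(self):
        panel, ld = make_region_panel(40, rho=0.3, seed=9)
        hits, tested = 0, 0
        for seed in range(200):
            exp_df, out_df = _exposure_frames(
                panel, ld, {5: 0.18, 20: 0.18, 35: 0.18}, theta=0.3,
                seed=1000 + seed)
            ins = select_instruments(exp_df, out_df, ld)
            if ins == "insufficient":
                continue
            b, se, _ = gsmr_estimate(ins)
            tested += 1
            if abs(b - 0.3) <= 3 * se:
                hits += 1
        assert tested >= 190
        assert hits / tested >= 0.99


class TestHeidi:
    def test_null_removal_rate_near_filter_size(self):
        rng = np.random.default_rng(10)
        removed_frac = []
        for _ in range(300):
            k = 8
            b_zx = rng.uniform(0.2, 0.4, k)
            se_zx = np.full(k, 0.005)
            theta = 0.3
            se_zy = np.full(k, 0.01)
            b_zy = theta * b_zx + rng.normal(0, se_zy)
            ins = _instruments(b_zx, se_zx, b_zy, se_zy)
            kept, removed = heidi_outlier(ins)
            removed_frac.append(len(removed) / (k - 1))
        assert 0.02 < np.mean(removed_frac) < 0.09

    def test_planted_pleiotropic_instrument_removed(self):
        rng = np.random.default_rng(11)
        removed_count = 0
        for _ in range(100):
            k = 6
            b_zx = rng.uniform(0.25, 0.35, k)
            b_zx[0] = 0.45  # clearly strongest: the HEIDI reference
            se_zx = np.full(k, 0.005)
            se_zy = np.full(k, 0.01)
            b_zy = 0.3 * b_zx + rng.normal(0, se_zy)
            b_zy[3] += 5 * se_zy[3]  # pleiotropic outcome effect 5 SD off
            ins = _instruments(b_zx, se_zx, b_zy, se_zy)
            kept, removed = heidi_outlier(ins)
            if ins.variants[3] in removed:
                removed_count += 1
        assert removed_count >= 80

    def test_reference_never_removed_and_consistent_pair_kept(self):
        ins = _instruments([0.4, 0.3], [0.005, 0.005],
                           [0.12, 0.09], [0.01, 0.01])
        kept, removed = heidi_outlier(ins)
        assert removed == []
        assert len(kept) == 2


class TestFdrRobustness:
    def test_bh_matches_step_up_oracle(self):
        q = bh_qvalues([0.001, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_bh_brute_force_on_random_pvalues(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        q = bh_qvalues(p)
        # brute-force step-up: q_(i) = min_{j >= i} m p_(j) / j
        order = np.argsort(p)
        m = len(p)
        q_oracle = np.empty(m)
        sorted_p = p[order]
        run_min = 1.0
        for i in range(m - 1, -1, -1):
            run_min = min(run_min, m * sorted_p[i] / (i + 1))
            q_oracle[i] = run_min
        np.testing.assert_allclose(q[order], q_oracle, rtol=1e-12)

    def _result(self, p, exposure="protein", outcome="disease"):
        return MRResult(exposure=exposure, outcome=outcome, b_xy=0.3,
                        se_xy=0.05, p_xy=p, mlog10p=-np.log10(p),
                        n_instruments_used=4)

    def test_weak_disease_signal_eliminated(self):
        res = [self._result(1e-8)]
        info = {("protein", "disease"): {"disease_min_p": 0.01}}
        out = fdr_and_robustness(res, info)
        assert out[0].verdict == "eliminated:weak_disease_signal"

    def test_full_robust_path(self):
        res = [self._result(1e-8)]
        info = {("protein", "disease"): {
            "disease_min_p": 1e-6, "r2_sentinel_disease": 0.95,
            "pwcoco_pp4": 0.92}}
        out = fdr_and_robustness(res, info)
        assert out[0].verdict == "robust"

    def test_low_ld_and_no_coloc_verdicts(self):
        res = [self._result(1e-8, outcome="d1"), self._result(1e-8, outcome="d2")]
        info = {("protein", "d1"): {"disease_min_p": 1e-6,
                                    "r2_sentinel_disease": 0.3},
                ("protein", "d2"): {"disease_min_p": 1e-6,
                                    "r2_sentinel_disease": 0.95,
                                    "pwcoco_pp4": 0.1}}
        out = fdr_and_robustness(res, info)
        assert out[0].verdict == "eliminated:low_ld"
        assert out[1].verdict == "eliminated:no_colocalization"

    def test_all_null_grid_rarely_significant(self):
        rng = np.random.default_rng(13)
        res = [self._result(p, outcome=f"d{i}")
               for i, p in enumerate(rng.uniform(size=57 * 14 // 10))]
        out = fdr_and_robustness(res, {})
        n_sig = sum(r.verdict != "not_significant" for r in out)
        assert n_sig <= 1

    def test_or_ci_brackets_point_estimate(self):
        r = self._result(1e-4)
        lo, hi = r.ci95
        assert lo < r.odds_ratio < hi


class TestEndToEndMr:
    def test_vertical_pleiotropy_passes_ld_confounding_flagged(self):
        panel, ld = make_region_panel(40, rho=0.6, seed=14)
        causal = {5: 0.18, 20: 0.18, 35: 0.18}
        ok = 0
        for seed in range(30):
            exp_df, out_df = _exposure_frames(panel, ld, causal, theta=0.3,
                                              seed=2000 + seed)
            res = mr_protein_disease(exp_df, out_df, ld)
            if res is not None and res.p_xy < 1e-4:
                ok += 1
        assert ok >= 27  # vertical pleiotropy: MR succeeds

    def test_ld_confounded_scenario_yields_pp3_over_pp4(self):
        from pqtlkit.coloc import PRIOR_SD_CC, coloc_pair
        panel, ld = make_region_panel(40, rho=0.6, seed=15)
        flagged = 0
        for seed in range(30):
            exp_df, out_df = _exposure_frames(
                panel, ld, {20: 0.2}, theta=0.0, seed=3000 + seed,
                confounder_mode="ld_confounded", confounder_offset=5,
                confounder_beta=0.15)
            res = coloc_pair(exp_df, out_df, prior_sd2=PRIOR_SD_CC)
            if res.pp[3] > res.pp[4]:
                flagged += 1
        assert flagged >= 24
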