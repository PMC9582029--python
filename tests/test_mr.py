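"""Mendelian randomization: instruments, harmonization, estimators, FDR."""

import numpy as np
import pandas as pd
import pytest

from skinmgwas.datatypes import GenotypeMatrix
from skinmgwas.mr import (
    egger,
    fdr_correct,
    harmonize,
    ivw,
    results_table,
    run_mr,
    select_instruments,
    sensitivity_verdict,
    wald_ratio,
    weighted_median,
)
from skinmgwas.sim import SimulationConfig, simulate_mr_summary


def stats_row(snp, beta, se, p=None, ea="A", oa="G", eaf=0.3, pos=1000, n=10000):
    from scipy import stats as sps
    if p is None:
        p = 2 * sps.norm.sf(abs(beta / se))
    return {"SNP": snp, "CHR": "1", "POS": pos, "EA": ea, "OA": oa,
            "EAF": eaf, "BETA": beta, "SE": se, "P": p, "N": n}


def instruments_frame(bx, by, sx=None, sy=None):
    k = len(bx)
    return pd.DataFrame({
        "SNP": [f"v{i}" for i in range(k)],
        "beta_exp": bx, "se_exp": sx if sx is not None else [0.02] * k,
        "beta_out": by, "se_out": sy if sy is not None else [0.02] * k,
    })


class TestSelectInstruments:
    def test_weak_instrument_excluded(self):
        tab = pd.DataFrame([stats_row("v1", 0.3, 0.1, p=1e-6)])
        out = select_instruments(tab)
        assert out.empty  # F = 9 < 10

    def test_clumping_keeps_best_of_correlated_pair(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.3, 500).astype(float)
        dosages = pd.DataFrame({"v1": base, "v2": base}, index=range(500))
        tab = pd.DataFrame([
            stats_row("v1", 0.5, 0.05, p=1e-8, pos=1000),
            stats_row("v2", 0.4, 0.05, p=1e-6, pos=2000),
        ])
        out = select_instruments(tab, g_ref=dosages)
        assert list(out["SNP"]) == ["v1"]

    def test_engineered_four_of_nine(self):
        rng = np.random.default_rng(1)
        n = 500
        dosages = {}
        rows = []
        # 4 good independent instruments, outside each other's clump window
        for i in range(4):
            dosages[f"good{i}"] = rng.binomial(2, 0.3, n).astype(float)
            rows.append(stats_row(f"good{i}", 0.4, 0.05, p=1e-9,
                                  pos=20_000_000 * (i + 1)))
        # 2 fail the p filter
        for i in range(2):
            dosages[f"weakp{i}"] = rng.binomial(2, 0.3, n).astype(float)
            rows.append(stats_row(f"weakp{i}", 0.1, 0.05, p=1e-3,
                                  pos=20_000_000 * (i + 10)))
        # 2 are correlated copies of good0 (clumped away)
        for i in range(2):
            dosages[f"dup{i}"] = dosages["good0"]
            rows.append(stats_row(f"dup{i}", 0.3, 0.05, p=1e-7,
                                  pos=20_000_000 + 1000 * (i + 1)))
        # 1 fails the F filter
        dosages["weakf"] = rng.binomial(2, 0.3, n).astype(float)
        rows.append(stats_row("weakf", 0.29, 0.1, p=9e-6, pos=20_000_000 * 30))
        tab = pd.DataFrame(rows)
        out = select_instruments(tab, g_ref=pd.DataFrame(dosages))

        def oracle():
            # brute force: p filter, then greedy clump by p, then F filter
            cand = [r for r in rows if r["P"] < 1e-5]
            cand.sort(key=lambda r: (r["P"], r["SNP"]))
            kept = []
            for r in cand:
                indep = True
                for q in kept:
                    if abs(r["POS"] - q["POS"]) <= 1e7:  # 10,000 kb window
                        x, y = dosages[r["SNP"]], dosages[q["SNP"]]
                        if np.corrcoef(x, y)[0, 1] ** 2 >= 0.001:
                            indep = False
                            break
                if indep:
                    kept.append(r)
            return sorted(r["SNP"] for r in kept if (r["BETA"] / r["SE"]) ** 2 >= 10)

        assert sorted(out["SNP"]) == oracle()
        assert len(out) == 4

    def test_empty_result_when_nothing_passes(self):
        tab = pd.DataFrame([stats_row("v1", 0.01, 0.05, p=0.5)])
        assert select_instruments(tab).empty


class TestHarmonize:
    def test_sign_flip(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05, ea="A", oa="G", eaf=0.3)])
        out = pd.DataFrame([stats_row("v1", -0.1, 0.05, ea="G", oa="A", eaf=0.7)])
        h = harmonize(exp, out)
        assert h["beta_out"][0] == pytest.approx(0.1)
        assert h["eaf_out"][0] == pytest.approx(0.3)

    def test_identical_alleles_unchanged(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05)])
        out = pd.DataFrame([stats_row("v1", 0.15, 0.05)])
        h = harmonize(exp, out)
        assert h["beta_out"][0] == pytest.approx(0.15)

    def test_ambiguous_palindrome_dropped(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05, ea="A", oa="T", eaf=0.5)])
        out = pd.DataFrame([stats_row("v1", 0.1, 0.05, ea="A", oa="T", eaf=0.5)])
        assert harmonize(exp, out).empty

    def test_unambiguous_palindrome_oriented_by_eaf(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05, ea="A", oa="T", eaf=0.2)])
        out = pd.DataFrame([stats_row("v1", -0.1, 0.05, ea="T", oa="A", eaf=0.8)])
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h["beta_out"][0] == pytest.approx(0.1)

    def test_incompatible_alleles_dropped(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05, ea="A", oa="G")])
        out = pd.DataFrame([stats_row("v1", 0.1, 0.05, ea="A", oa="C")])
        assert harmonize(exp, out).empty

    def test_involution(self):
        exp = pd.DataFrame([stats_row("v1", 0.2, 0.05, ea="A", oa="G", eaf=0.3),
                            stats_row("v2", -0.4, 0.05, ea="C", oa="A", eaf=0.2,
                                      pos=99_000)])
        out = pd.DataFrame([stats_row("v1", -0.1, 0.05, ea="G", oa="A", eaf=0.7),
                            stats_row("v2", 0.3, 0.05, ea="C", oa="A", eaf=0.25,
                                      pos=99_000)])
        h1 = harmonize(exp, out)
        again = h1.rename(columns={"beta_out": "BETA", "se_out": "SE",
                                   "p_out": "P", "eaf_out": "EAF"})
        again["N"] = 1000
        h2 = harmonize(exp, again[["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]])
        np.testing.assert_allclose(h1["beta_out"], h2["beta_out"])


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.05)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.005).beta == 0.0

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.005)

    def test_ivw_single_instrument_reduces_to_wald(self):
        inst = instruments_frame([0.1], [0.02], sx=[0.01], sy=[0.005])
        w = wald_ratio(0.1, 0.01, 0.02, 0.005)
        i = ivw(inst)
        assert i.beta == pytest.approx(w.beta)
        assert i.se == pytest.approx(w.se)


class TestIVW:
    def test_exact_shared_ratio(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3])
        inst = instruments_frame(bx, 0.2 * bx)
        est = ivw(inst)
        assert est.beta == pytest.approx(0.2)

    def test_simulation_recovery(self):
        betas = []
        for seed in range(200):
            cfg = SimulationConfig(seed=seed)
            exp, out = simulate_mr_summary(cfg, causal_beta=0.3, n_instruments=20)
            betas.append(ivw(harmonize(exp, out)).beta)
        assert 0.27 < np.mean(betas) < 0.33

    def test_null_type_one_error(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            k = 15
            bx_true = rng.normal(0.2, 0.05, k)
            sx = np.full(k, 0.01)
            sy = np.full(k, 0.01)
            inst = instruments_frame(bx_true + rng.normal(0, sx),
                                     rng.normal(0, sy), sx=sx, sy=sy)
            rejections += ivw(inst).p < 0.05
        rate = rejections / n_rep
        assert 0.05 - 0.03 <= rate <= 0.05 + 0.03

    def test_estimator_agreement_on_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        inst = instruments_frame(bx, 0.2 * bx)
        assert ivw(inst).beta == pytest.approx(0.2)
        assert egger(inst).beta == pytest.approx(0.2, abs=1e-10)
        assert weighted_median(inst, seed=0).beta == pytest.approx(0.2, abs=1e-10)
        single = inst.iloc[[0]]
        assert wald_ratio(0.1, 0.02, 0.02, 0.02).beta == pytest.approx(0.2)


class TestEgger:
    def test_two_instruments_error(self):
        with pytest.raises(ValueError):
            egger(instruments_frame([0.1, 0.2], [0.02, 0.04]))

    def test_null_intercept_slope_matches_ivw(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            k = 20
            bx = rng.normal(0.2, 0.08, k)
            sy = np.full(k, 0.01)
            by = 0.3 * bx + rng.normal(0, sy)
            inst = instruments_frame(bx, by, sy=sy)
            e, i = egger(inst), ivw(inst)
            if abs(e.beta - i.beta) <= 3 * e.se:
                hits += 1
        assert hits >= 90

    def test_directional_pleiotropy_intercept(self):
        rng = np.random.default_rng(13)
        intercepts = []
        for _ in range(100):
            k = 30
            bx = np.abs(rng.normal(0.25, 0.05, k))
            sy = np.full(k, 0.01)
            by = 0.1 * bx + 0.05 + rng.normal(0, sy)  # delta = 0.05
            intercepts.append(egger(instruments_frame(bx, by, sy=sy)).intercept)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.005)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        # exactly equal inverse-variance weights -> plain median of ratios
        inst = instruments_frame([1.0, 1.0, 1.0], [0.1, 0.2, 0.3],
                                 sx=[0.0, 0.0, 0.0], sy=[0.02, 0.02, 0.02])
        est = weighted_median(inst, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_majority_valid_robustness(self):
        rng = np.random.default_rng(17)
        k_valid, k_invalid = 10, 4
        bx = np.abs(rng.normal(0.3, 0.05, k_valid + k_invalid))
        sy = np.full(k_valid + k_invalid, 0.005)
        by = np.where(np.arange(k_valid + k_invalid) < k_valid,
                      0.3 * bx, 1.0 * bx) + rng.normal(0, sy)
        est = weighted_median(instruments_frame(bx, by, sy=sy), seed=2)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_seeded_se_deterministic(self):
        inst = instruments_frame([0.2, 0.3, 0.25, 0.15], [0.04, 0.07, 0.05, 0.02])
        a = weighted_median(inst, seed=5)
        b = weighted_median(inst, seed=5)
        assert a.se == b.se

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(instruments_frame([0.1, 0.2], [0.02, 0.04]))


class TestSensitivityVerdict:
    def mk(self, p, beta=0.3, method="ivw", intercept_p=0.5):
        from skinmgwas.datatypes import MREstimate
        return MREstimate(method, beta, 0.1, p, 5, intercept_p=intercept_p)

    def test_supporting(self):
        v, _ = sensitivity_verdict(self.mk(0.001), self.mk(0.5, method="egger"),
                                   self.mk(0.02, method="weighted_median"))
        assert v == "supporting"

    def test_discordant_direction(self):
        v, why = sensitivity_verdict(self.mk(0.001, beta=0.3),
                                     self.mk(0.5, method="egger"),
                                     self.mk(0.02, beta=-0.3))
        assert v == "weak_or_inconclusive"
        assert "direction" in why

    def test_significant_egger_slope(self):
        v, why = sensitivity_verdict(self.mk(0.001), self.mk(0.01, method="egger"),
                                     self.mk(0.02))
        assert v == "weak_or_inconclusive"
        assert "Egger" in why

    def test_missing_sensitivity(self):
        v, why = sensitivity_verdict(self.mk(0.001), None, None)
        assert v == "weak_or_inconclusive"


class TestFDR:
    def mk_result(self, p, outcome="eczema"):
        from skinmgwas.datatypes import MREstimate, MRResult
        return MRResult("exp", outcome, MREstimate("ivw", 0.2, 0.1, p, 5))

    def test_single_test_identity(self):
        r = fdr_correct([self.mk_result(0.01)])[0]
        assert r.q_trait == pytest.approx(0.01)
        assert r.q_global == pytest.approx(0.01)

    def test_all_ones(self):
        rs = fdr_correct([self.mk_result(1.0), self.mk_result(1.0, "psoriasis")])
        assert all(r.q_trait == 1.0 and r.q_global == 1.0 for r in rs)

    def test_global_superset_no_smaller_p(self):
        # BH oracle computed by brute force on the enumerated p-vectors
        def bh(ps):
            ps = np.asarray(ps, dtype=float)
            m = len(ps)
            order = np.argsort(ps)
            q = np.empty(m)
            prev = 1.0
            for rank_rev, idx in enumerate(order[::-1]):
                rank = m - rank_rev
                prev = min(prev, ps[idx] * m / rank)
                q[idx] = prev
            return q

        trait_a = [0.01, 0.04, 0.2]
        trait_b = [0.5, 0.8]
        results = ([self.mk_result(p, "a") for p in trait_a]
                   + [self.mk_result(p, "b") for p in trait_b])
        out = fdr_correct(results)
        qa = bh(trait_a)
        q_all = bh(trait_a + trait_b)
        for i in range(3):
            assert out[i].q_trait == pytest.approx(qa[i])
            assert out[i].q_global == pytest.approx(q_all[i])
            # superset adds only larger p-values -> global q >= trait q
            assert out[i].q_global >= out[i].q_trait - 1e-12


class TestRunMR:
    def test_end_to_end_supporting_chain(self):
        cfg = SimulationConfig(seed=4)
        exp, out = simulate_mr_summary(cfg, causal_beta=0.4, n_instruments=25)
        res = run_mr(exp, out, "staph", "eczema", seed=1)
        assert res is not None
        assert res.primary.method == "ivw"
        assert res.egger is not None and res.weighted_median is not None
        assert abs(res.primary.beta - 0.4) < 0.1

    def test_single_instrument_falls_back_to_wald(self):
        cfg = SimulationConfig(seed=6)
        exp, out = simulate_mr_summary(cfg, causal_beta=0.3, n_instruments=1)
        res = run_mr(exp, out, "e", "o", seed=1)
        assert res is not None
        assert res.primary.method == "wald"
        assert res.verdict == "weak_or_inconclusive"

    def test_no_instruments_returns_none(self):
        exp = pd.DataFrame([stats_row("v1", 0.01, 0.05, p=0.9)])
        out = pd.DataFrame([stats_row("v1", 0.01, 0.05, p=0.9)])
        assert run_mr(exp, out, "e", "o") is None

    def test_results_table_columns(self):
        cfg = SimulationConfig(seed=4)
        exp, out = simulate_mr_summary(cfg, causal_beta=0.4, n_instruments=25)
        res = fdr_correct([run_mr(exp, out, "staph", "eczema", seed=1)])
        frame = results_table(res)
        assert {"EXPOSURE", "OUTCOME", "N_SNPS", "METHOD", "BETA", "SE", "P",
                "VERDICT", "Q_TRAIT", "Q_GLOBAL"} <= set(frame.columns)
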