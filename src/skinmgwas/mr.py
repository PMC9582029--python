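"""Two-sample Mendelian randomization.

Instrument selection (p < 1e-5, greedy LD clumping, F >= 10), allele
harmonization with palindrome handling, Wald-ratio / IVW / MR-Egger /
weighted-median estimators, the supporting-evidence verdict and the
per-trait plus global Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from skinmgwas.datatypes import GenotypeMatrix, MREstimate, MRResult

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROME_EAF_BAND = (0.42, 0.58)
DEFAULT_CLUMP_KB = 10_000
DEFAULT_CLUMP_R2 = 0.001


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Outcome rows whose EA equals the exposure OA get their beta sign and
    EAF flipped; strand-flipped allele pairs are complemented first.
    Palindromic (A/T, C/G) variants are kept only when both EAFs fall
    outside the ambiguity band and agree on which allele is minor.
    Incompatible allele sets are dropped and logged.
    """
    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")
    shared = exp.index.intersection(out.index)
    rows = []
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        eea, eoa = str(e["EA"]), str(e["OA"])
        oea, ooa = str(o["EA"]), str(o["OA"])
        beta_o, eaf_o = float(o["BETA"]), float(o["EAF"])
        if _is_palindromic(eea, eoa):
            lo, hi = PALINDROME_EAF_BAND
            eaf_e = float(e["EAF"])
            if lo <= eaf_e <= hi or lo <= eaf_o <= hi:
                logger.info("harmonize: dropped palindromic ambiguous %s", snp)
                continue
            # infer orientation from which side of 0.5 the EAFs fall
            if {oea, ooa} != {eea, eoa} and {oea, ooa} != {
                _COMPLEMENT[eea], _COMPLEMENT[eoa]
            }:
                logger.info("harmonize: dropped incompatible alleles at %s", snp)
                continue
            if (eaf_e < 0.5) != (eaf_o < 0.5):
                beta_o, eaf_o = -beta_o, 1.0 - eaf_o
        else:
            if {oea, ooa} == {_COMPLEMENT[eea], _COMPLEMENT[eoa]} and {oea, ooa} != {
                eea, eoa
            }:
                oea, ooa = _COMPLEMENT[oea], _COMPLEMENT[ooa]
            if {oea, ooa} != {eea, eoa}:
                logger.info("harmonize: dropped incompatible alleles at %s", snp)
                continue
            if oea == eoa:
                beta_o, eaf_o = -beta_o, 1.0 - eaf_o
        rows.append(
            {
                "SNP": snp,
                "EA": eea,
                "OA": eoa,
                "POS": e.get("POS", np.nan),
                "beta_exp": float(e["BETA"]),
                "se_exp": float(e["SE"]),
                "p_exp": float(e["P"]),
                "eaf_exp": float(e["EAF"]),
                "beta_out": beta_o,
                "se_out": float(o["SE"]),
                "p_out": float(o["P"]),
                "eaf_out": eaf_o,
            }
        )
    return pd.DataFrame(rows)


def select_instruments(
    exposure: pd.DataFrame,
    g_ref: GenotypeMatrix | pd.DataFrame | None = None,
    p_max: float = 1e-5,
    clump_kb: float = DEFAULT_CLUMP_KB,
    clump_r2: float = DEFAULT_CLUMP_R2,
    f_min: float = 10.0,
) -> pd.DataFrame:
    """Instrument table after the three filters.

    Keeps exposure variants with p < ``p_max``; greedy clumping by
    ascending p retains a variant only when its r^2 (from the reference
    genotypes) to every previously kept variant within ``clump_kb`` kb is
    below ``clump_r2``; instruments with F = (beta/se)^2 < ``f_min`` are
    dropped.  Without a genotype reference, clumping falls back to the
    distance window alone.
    """
    tab = exposure.copy()
    tab = tab[tab["P"] < p_max]
    tab["F_STAT"] = (tab["BETA"] / tab["SE"]) ** 2
    tab = tab.sort_values(["P", "SNP"], kind="stable")

    dos = None
    if g_ref is not None:
        dos = g_ref.dosages if isinstance(g_ref, GenotypeMatrix) else g_ref
    kept: list[pd.Series] = []
    for _, row in tab.iterrows():
        independent = True
        for prev in kept:
            if abs(float(row["POS"]) - float(prev["POS"])) > clump_kb * 1000:
                continue
            if dos is not None and row["SNP"] in dos.columns and prev["SNP"] in dos.columns:
                x = dos[row["SNP"]].to_numpy(dtype=float)
                y = dos[prev["SNP"]].to_numpy(dtype=float)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    continue
                r2 = float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)
                if r2 >= clump_r2:
                    independent = False
                    break
            else:
                independent = False  # same window, no LD reference: assume linked
                break
        if independent:
            kept.append(row)
    if not kept:
        logger.info("select_instruments: no instruments survive; MR skipped")
        return tab.iloc[0:0]
    out = pd.DataFrame(kept)
    return out[out["F_STAT"] >= f_min].reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp with the
    first-order standard error se_out / |beta_exp|."""
    if beta_exp == 0:
        raise ValueError("exposure effect is zero; Wald ratio undefined")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    z = beta / se
    return MREstimate("wald", beta, se, 2.0 * stats.norm.sf(abs(z)), n_snps=1)


def ivw(instruments: pd.DataFrame) -> MREstimate:
    """Inverse-variance weighted regression through the origin with a
    multiplicative random-effects variance floor (residual scale >= 1)."""
    k = len(instruments)
    if k < 2:
        if k == 1:
            r = instruments.iloc[0]
            est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
            return MREstimate("ivw", est.beta, est.se, est.p, n_snps=1)
        raise ValueError("IVW requires at least one instrument; use wald_ratio")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    sy = instruments["se_out"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    resid = by - beta * bx
    scale = float(np.sum(w * resid**2) / (k - 1)) if k > 1 else 1.0
    scale = max(scale, 1.0)
    se = float(np.sqrt(scale / np.sum(w * bx * bx)))
    z = beta / se
    return MREstimate("ivw", beta, se, 2.0 * stats.norm.sf(abs(z)), n_snps=k)


def egger(instruments: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept; exposure effects are oriented positive first."""
    k = len(instruments)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.sign(instruments["beta_exp"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = instruments["beta_exp"].to_numpy(dtype=float) * sign
    by = instruments["beta_out"].to_numpy(dtype=float) * sign
    sy = instruments["se_out"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    scale = max(float(np.sum(w * resid**2) / (k - 2)), 1.0)
    cov = scale * np.linalg.inv(xtx)
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    # t reference with k - 2 df, as customary for Egger with few instruments
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df=k - 2)
    p_inter = 2.0 * stats.t.sf(abs(inter / se_inter), df=k - 2)
    return MREstimate(
        "egger", float(slope), float(se_slope), float(p_slope), n_snps=k,
        intercept=float(inter), intercept_se=float(se_inter), intercept_p=float(p_inter),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of per-instrument Wald ratios with inverse-variance
    weights; SE from a seeded parametric bootstrap."""
    k = len(instruments)
    if k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    sx = instruments["se_exp"].to_numpy(dtype=float)
    sy = instruments["se_out"].to_numpy(dtype=float)
    ratio = by / bx
    var_ratio = sy**2 / bx**2 + (by**2 * sx**2) / bx**4  # delta method
    w = 1.0 / var_ratio
    beta = _weighted_median(ratio, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.standard_normal(k) * sx
        by_b = by + rng.standard_normal(k) * sy
        ratio_b = by_b / bx_b
        var_b = sy**2 / bx_b**2 + (by_b**2 * sx**2) / bx_b**4
        boots[b] = _weighted_median(ratio_b, 1.0 / var_b)
    se = float(boots.std(ddof=1))
    z = beta / se if se > 0 else np.inf
    return MREstimate("weighted_median", beta, se, 2.0 * stats.norm.sf(abs(z)), n_snps=k)


# ---------------------------------------------------------------------------
# verdicts + FDR
# ---------------------------------------------------------------------------

def sensitivity_verdict(
    primary: MREstimate,
    egger_est: MREstimate | None,
    wmedian: MREstimate | None,
) -> tuple[str, str]:
    """'supporting' iff the Egger slope is non-significant (p > 0.05) and
    the weighted median is significant (p < 0.1) with the same direction as
    the primary estimate."""
    if egger_est is None or wmedian is None:
        return "weak_or_inconclusive", "sensitivity estimates unavailable (<3 instruments)"
    if egger_est.p <= 0.05:
        return "weak_or_inconclusive", "Egger slope significant"
    if wmedian.p >= 0.1:
        return "weak_or_inconclusive", "weighted median not significant"
    if np.sign(wmedian.beta) != np.sign(primary.beta):
        return "weak_or_inconclusive", "weighted median direction discordant"
    return "supporting", ""


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_name: str,
    outcome_name: str,
    g_ref: GenotypeMatrix | pd.DataFrame | None = None,
    p_max: float = 1e-5,
    clump_kb: float = DEFAULT_CLUMP_KB,
    clump_r2: float = DEFAULT_CLUMP_R2,
    f_min: float = 10.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult | None:
    """One exposure-outcome MR: instrument selection on the exposure,
    harmonization, primary estimate (IVW when more than two instruments
    remain, otherwise the Wald ratio of the strongest instrument) and
    sensitivity analyses.  Returns None when no instruments survive."""
    selected = select_instruments(exposure, g_ref, p_max, clump_kb, clump_r2, f_min)
    if selected.empty:
        return None
    harm = harmonize(selected, outcome)
    if harm.empty:
        return None
    k = len(harm)
    egger_est = wmed = None
    if k > 2:
        primary = ivw(harm)
        egger_est = egger(harm)
        wmed = weighted_median(harm, n_boot=n_boot, seed=seed)
    else:
        strongest = harm.loc[(harm["beta_exp"] / harm["se_exp"]).abs().idxmax()]
        primary = wald_ratio(
            strongest["beta_exp"], strongest["se_exp"],
            strongest["beta_out"], strongest["se_out"],
        )
        if k == 2:
            logger.info("run_mr: 2 instruments; IVW logged as %s", ivw(harm))
    verdict, reason = sensitivity_verdict(primary, egger_est, wmed)
    return MRResult(
        exposure=exposure_name, outcome=outcome_name, primary=primary,
        egger=egger_est, weighted_median=wmed, verdict=verdict,
        verdict_reason=reason,
    )


def fdr_correct(results: list[MRResult]) -> list[MRResult]:
    """Benjamini-Hochberg q-values within each outcome trait (q_trait) and
    across all exposure-outcome pairs (q_global)."""
    if not results:
        return results
    ps = np.array([r.primary.p for r in results])
    q_global = multipletests(ps, method="fdr_bh")[1]
    for r, q in zip(results, q_global):
        r.q_global = float(q)
    traits: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        traits.setdefault(r.outcome, []).append(i)
    for idxs in traits.values():
        q_tr = multipletests(ps[idxs], method="fdr_bh")[1]
        for i, q in zip(idxs, q_tr):
            results[i].q_trait = float(q)
    return results


def results_table(results: list[MRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "EXPOSURE": r.exposure,
                "OUTCOME": r.outcome,
                "N_SNPS": r.primary.n_snps,
                "METHOD": r.primary.method,
                "BETA": r.primary.beta,
                "SE": r.primary.se,
                "P": r.primary.p,
                "EGGER_INTERCEPT_P": r.egger.intercept_p if r.egger else np.nan,
                "EGGER_P": r.egger.p if r.egger else np.nan,
                "WMEDIAN_P": r.weighted_median.p if r.weighted_median else np.nan,
                "VERDICT": r.verdict,
                "Q_TRAIT": r.q_trait,
                "Q_GLOBAL": r.q_global,
            }
        )
    return pd.DataFrame(rows)
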