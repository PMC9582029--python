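"""Two-stage covariate-residualized association tests.

Univariate route: zero-truncated non-rarefied counts, 5xIQR outlier
masking on rarefied counts, a negative-binomial GLM with log-total offset
and ML dispersion, randomized-quantile (Dunn-Smyth) residual extraction,
then a per-SNP linear model with a two-sided t-test.

Multivariate route: principal-coordinate decomposition of the Gower-
centered Bray-Curtis matrix, least-squares removal of covariate effects,
then a per-SNP pseudo-F whose p-value comes from a Pearson type III
distribution matched to the exact permutation moments of the statistic
(explicit permutation fallback when moment matching is infeasible).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar

from skinmgwas._moments import PermutationMomentEngine
from skinmgwas.datatypes import AlignmentError, AssociationResult, DistanceMatrix

logger = logging.getLogger(__name__)


class FeatureSkipped(RuntimeError):
    """Feature cannot be modeled (too few samples after truncation)."""


# ---------------------------------------------------------------------------
# sample masking
# ---------------------------------------------------------------------------

def outlier_mask(rarefied_counts: np.ndarray, iqr_mult: float = 5.0) -> np.ndarray:
    """Keep-mask excluding samples deviating more than ``iqr_mult`` x IQR
    from the median; with IQR = 0 only samples equal to the median remain."""
    v = np.asarray(rarefied_counts, dtype=float)
    if v.size == 0:
        raise ValueError("empty abundance vector")
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return np.abs(v - med) <= iqr_mult * iqr


def zero_truncate(counts: np.ndarray, min_samples: int = 50) -> np.ndarray:
    """Keep-mask excluding zero-count samples.

    Raises :class:`FeatureSkipped` when fewer than ``min_samples`` samples
    remain (the feature is dropped from the model stage, with a log entry).
    """
    v = np.asarray(counts)
    mask = v > 0
    if int(mask.sum()) < min_samples:
        logger.info("zero_truncate: %d/%d nonzero samples < %d; feature skipped",
                    int(mask.sum()), v.size, min_samples)
        raise FeatureSkipped(
            f"only {int(mask.sum())} nonzero samples (minimum {min_samples})"
        )
    return mask


# ---------------------------------------------------------------------------
# negative-binomial GLM with ML dispersion
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    """Converged NB regression for one feature."""

    params: np.ndarray
    theta: float  # Var = mu + mu^2 / theta
    mu: np.ndarray
    design: np.ndarray
    offset: np.ndarray
    counts: np.ndarray
    llf: float
    converged: bool
    column_names: list[str]


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + covariate columns as a dense design matrix."""
    x = covariates.to_numpy(dtype=float)
    return np.column_stack([np.ones(len(x)), x])


def nb_glm_fit(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    column_names: list[str] | None = None,
) -> NBFit:
    """Maximum-likelihood NB GLM (log link) with profile dispersion.

    The dispersion theta (Var = mu + mu^2/theta) is profiled by maximizing
    the GLM log-likelihood over log(alpha), alpha = 1/theta, with an IRLS
    fit at each candidate.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    off = np.asarray(offset, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    def fit_at(log_alpha: float):
        fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_alpha)))
        model = sm.GLM(y, X, family=fam, offset=off)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=max_iter, tol=tol)
        return res

    def nll(log_alpha: float) -> float:
        try:
            return -fit_at(log_alpha).llf
        except Exception:
            return np.inf

    opt = minimize_scalar(nll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    res = fit_at(opt.x)
    theta = float(np.exp(-opt.x))
    converged = bool(res.converged) and np.isfinite(res.llf)
    if not converged:
        logger.warning("nb_glm_fit: IRLS failed to converge (theta=%.3g)", theta)
    return NBFit(
        params=np.asarray(res.params),
        theta=theta,
        mu=np.asarray(res.fittedvalues),
        design=X,
        offset=off,
        counts=y,
        llf=float(res.llf),
        converged=converged,
        column_names=column_names or [f"x{i}" for i in range(X.shape[1])],
    )


def pearson_dispersion(fit: NBFit) -> float:
    """Pearson chi-square / df under the fitted NB variance function."""
    var = fit.mu + fit.mu**2 / fit.theta
    resid = (fit.counts - fit.mu) ** 2 / var
    df = len(fit.counts) - fit.design.shape[1]
    return float(resid.sum() / df)


def dunn_smyth_residuals(fit: NBFit, seed: int) -> np.ndarray:
    """Randomized quantile residuals: r_i = Phi^-1(u_i) with u_i uniform on
    (F(y_i - 1), F(y_i)] under the fitted NB distribution.  Standard normal
    when the model is correctly specified."""
    rng = np.random.default_rng(seed)
    theta = fit.theta
    p = theta / (theta + fit.mu)
    y = fit.counts
    upper = stats.nbinom.cdf(y, theta, p)
    lower = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p), 0.0)
    u = lower + rng.uniform(size=len(y)) * (upper - lower)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return stats.norm.ppf(u)


# ---------------------------------------------------------------------------
# per-SNP linear tests on residuals
# ---------------------------------------------------------------------------

def univariate_assoc(
    residuals: np.ndarray,
    dosage: np.ndarray,
    feature: str = "",
    snp: str = "",
    site: str = "",
) -> AssociationResult:
    """OLS of residuals on dosage (with intercept); two-sided t-test."""
    r = np.asarray(residuals, dtype=float)
    d = np.asarray(dosage, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(r)
    r, d = r[ok], d[ok]
    n = len(r)
    if n < 3 or np.ptp(d) == 0:
        return AssociationResult(feature, snp, site, np.nan, np.nan, np.nan, n,
                                 tested=False, note="monomorphic_in_subset")
    dc = d - d.mean()
    rc = r - r.mean()
    sxx = float(dc @ dc)
    beta = float(dc @ rc) / sxx
    resid = rc - beta * dc
    sigma2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tstat = beta / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return AssociationResult(feature, snp, site, beta, se, p, n,
                             stat_type="t", statistic=tstat)


def univariate_scan(residuals: np.ndarray, dosages: np.ndarray) -> pd.DataFrame:
    """Vectorized OLS of one residual vector against many dosage columns.

    ``dosages`` is samples x variants (no missing values).  Returns a frame
    with BETA, SE, P, N, TESTED per variant; variants monomorphic within
    the sample subset are marked untested.
    """
    r = np.asarray(residuals, dtype=float)
    D = np.asarray(dosages, dtype=float)
    n = len(r)
    rc = r - r.mean()
    Dc = D - D.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", Dc, Dc)
    poly = sxx > 0
    sxx_safe = np.where(poly, sxx, 1.0)
    beta = (Dc.T @ rc) / sxx_safe
    syy = float(rc @ rc)
    rss = syy - beta**2 * sxx_safe
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = pd.DataFrame({"BETA": beta, "SE": se, "P": p, "N": n, "TESTED": poly})
    out.loc[~poly, ["BETA", "SE", "P"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# multivariate route: PCoA residualization + moment-matched pseudo-F
# ---------------------------------------------------------------------------

@dataclass
class ResidualCoordMatrix:
    """Ordination coordinates with covariate effects projected out."""

    coords: np.ndarray  # samples x axes
    eigenvalues: np.ndarray
    ids: list[str]


def dbrda_residuals(d: DistanceMatrix, covariates: pd.DataFrame) -> ResidualCoordMatrix:
    """PCoA of the Gower-centered dissimilarity matrix followed by
    least-squares removal of covariate effects.

    Axes with positive eigenvalues are retained (negative eigenvalues are
    dropped, no Lingoes/Cailliez correction).  The returned matrix is
    orthogonal to [1, covariates].
    """
    ids = list(d.ids)
    if list(covariates.index) != ids:
        if set(covariates.index) != set(ids):
            raise AlignmentError("covariates do not cover the distance matrix samples")
        covariates = covariates.loc[ids]
    dm = d.values
    n = dm.shape[0]
    a = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-8 * evals.max())
    coords = evecs[:, pos] * np.sqrt(evals[pos])

    X = build_design(covariates)
    beta, *_ = np.linalg.lstsq(X, coords, rcond=None)
    resid = coords - X @ beta
    return ResidualCoordMatrix(coords=resid, eigenvalues=evals[pos], ids=ids)


def _pearson3_sf(q_std: float, skew: float) -> float:
    """Upper tail of a zero-mean unit-variance Pearson type III variate."""
    if not np.isfinite(skew) or abs(skew) < 1e-8:
        return float(stats.norm.sf(q_std))
    shape = 4.0 / skew**2
    if skew > 0:
        return float(stats.gamma.sf(q_std * np.sqrt(shape) + shape, shape))
    return float(stats.gamma.cdf(-q_std * np.sqrt(shape) + shape, shape))


def permutation_pvalue(
    R: ResidualCoordMatrix | np.ndarray,
    dosage: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Monte-Carlo permutation p-value for the pseudo-F (add-one rule)."""
    coords = R.coords if isinstance(R, ResidualCoordMatrix) else np.asarray(R)
    G = coords @ coords.T
    a = np.asarray(dosage, dtype=float)
    a = a - a.mean()
    rng = np.random.default_rng(seed)
    q_obs = float(a @ G @ a)
    perms = np.array([rng.permutation(a) for _ in range(n_perm)])
    q_null = np.einsum("ij,ij->i", perms @ G, perms)
    return (1.0 + np.sum(q_null >= q_obs - 1e-12)) / (n_perm + 1.0)


class MomentMatchedFTest:
    """Per-feature engine for the multivariate distance pseudo-F.

    Precomputes the Gram matrix and its permutation-pattern sums once, then
    evaluates each dosage vector in microseconds.  ``__call__`` mirrors the
    one-shot :func:`moment_matched_ftest`.
    """

    def __init__(self, R: ResidualCoordMatrix, n_perm_fallback: int = 9999, seed: int = 0):
        self.coords = R.coords
        self.n = R.coords.shape[0]
        self.G = R.coords @ R.coords.T
        self.ss_total = float(np.trace(self.G))
        if self.ss_total <= 0:
            raise ValueError("degenerate residual matrix: zero total sum of squares")
        self.engine = PermutationMomentEngine(self.G)
        self.n_perm_fallback = n_perm_fallback
        self.seed = seed

    def __call__(self, dosage: np.ndarray, feature: str = "beta_diversity",
                 snp: str = "", site: str = "") -> AssociationResult:
        a = np.asarray(dosage, dtype=float)
        n = self.n
        if np.ptp(a[~np.isnan(a)]) == 0:
            return AssociationResult(feature, snp, site, np.nan, np.nan, np.nan, n,
                                     stat_type="pseudo_F", tested=False,
                                     note="monomorphic_in_subset")
        ac = a - np.nanmean(a)
        sxx = float(np.nansum(ac * ac))
        q_obs = float(ac @ self.G @ ac) / sxx
        ss_x = q_obs
        ss_res = self.ss_total - ss_x
        fstat = ss_x / (ss_res / (n - 2))

        mean, var, skew = self.engine.standardized_moments(a)
        mean, var = mean / sxx, var / sxx**2  # moments of Q/sxx (sxx invariant)
        if var <= 0 or not np.isfinite(var) or not np.isfinite(skew):
            p = permutation_pvalue(self.coords, a, self.n_perm_fallback, self.seed)
            note = "permutation_fallback"
        else:
            q_std = (q_obs - mean) / np.sqrt(var)
            p = _pearson3_sf(q_std, skew)
            note = ""
        return AssociationResult(feature, snp, site, np.nan, np.nan, p, n,
                                 stat_type="pseudo_F", statistic=fstat, note=note)


def moment_matched_ftest(
    R: ResidualCoordMatrix,
    dosage: np.ndarray,
    feature: str = "beta_diversity",
    snp: str = "",
    site: str = "",
) -> AssociationResult:
    """Pseudo-F of a single dosage vector on the residual coordinates, with
    a Pearson type III p-value matched to exact permutation moments."""
    return MomentMatchedFTest(R)(dosage, feature=feature, snp=snp, site=site)


# ---------------------------------------------------------------------------
# high-level per-site scans
# ---------------------------------------------------------------------------

def univariate_feature_scan(
    raw_counts: pd.Series,
    rarefied_counts: pd.Series,
    covariates: pd.DataFrame,
    total_counts: pd.Series,
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    feature: str,
    site: str,
    seed: int = 0,
    min_samples: int = 50,
) -> pd.DataFrame:
    """Full univariate two-stage scan of one feature against all variants.

    Sample flow: zero-truncation on raw counts, 5xIQR outlier masking on
    rarefied counts (among retained samples), NB GLM with log-total offset,
    Dunn-Smyth residuals, vectorized per-SNP OLS.  Returns a summary-stats
    frame (FEATURE, SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N, STAT_TYPE).
    """
    samples = raw_counts.index
    mask = pd.Series(False, index=samples)
    nonzero = zero_truncate(raw_counts.to_numpy(), min_samples=min_samples)
    rare = rarefied_counts.reindex(samples)
    keep_outlier = pd.Series(True, index=samples)
    present = rare.notna().to_numpy()
    km = outlier_mask(rare.to_numpy()[present])
    keep_outlier.iloc[np.flatnonzero(present)] = km
    mask[:] = nonzero & keep_outlier.to_numpy()
    if int(mask.sum()) < min_samples:
        raise FeatureSkipped(f"{feature}: {int(mask.sum())} samples after masking")

    kept = samples[mask]
    design = build_design(covariates.loc[kept])
    offset = np.log(total_counts.loc[kept].to_numpy(dtype=float))
    fit = nb_glm_fit(raw_counts.loc[kept].to_numpy(dtype=float), design, offset)
    resid = dunn_smyth_residuals(fit, seed=seed)

    scan = univariate_scan(resid, genotypes.loc[kept].to_numpy(dtype=float))
    scan.index = genotypes.columns
    out = variants.loc[genotypes.columns, ["chrom", "pos", "ea", "oa", "eaf"]].copy()
    out.columns = ["CHR", "POS", "EA", "OA", "EAF"]
    out.insert(0, "SNP", genotypes.columns)
    out.insert(0, "FEATURE", feature)
    out[["BETA", "SE", "P", "N"]] = scan[["BETA", "SE", "P", "N"]]
    out["STAT_TYPE"] = "t"
    return out.reset_index(drop=True)


def beta_diversity_scan(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    site: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Moment-matched pseudo-F scan of community composition vs all variants."""
    R = dbrda_residuals(d, covariates)
    test = MomentMatchedFTest(R, seed=seed)
    G = genotypes.loc[R.ids]
    rows = []
    for snp in G.columns:
        res = test(G[snp].to_numpy(dtype=float), snp=snp, site=site)
        rows.append((res.p, res.n, res.statistic, res.tested))
    p, n, f, tested = zip(*rows)
    out = variants.loc[G.columns, ["chrom", "pos", "ea", "oa", "eaf"]].copy()
    out.columns = ["CHR", "POS", "EA", "OA", "EAF"]
    out.insert(0, "SNP", G.columns)
    out.insert(0, "FEATURE", "beta_diversity")
    out["BETA"] = np.nan
    out["SE"] = np.nan
    out["P"] = p
    out["N"] = n
    out["STAT_TYPE"] = "pseudo_F"
    out["F"] = f
    return out.reset_index(drop=True)
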