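"""Per-SNP association evidence.

Three layers of evidence for "SNP j drives gene k's expression":

* a frequentist scan (:func:`lm_scan`): ordinary least squares of the
  normalized phenotype on additive dosage, one SNP at a time;
* a gene-level permutation FDR (:func:`gene_level_permutation_fdr`) that
  permutes individuals' expression labels while keeping genotype LD intact;
* a single-SNP Bayes factor (:func:`single_snp_bf`): closed-form conjugate
  linear-model BF comparing "this SNP is the causal site" against "no
  causal site", averaged over a grid of effect-size prior SDs.

Plus a genotype-vs-quantitative-signal concordance test used to ask whether
candidate causal SNPs shift an independent molecular readout (e.g. TF
binding read depth) in the same direction as expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io import GenotypeMatrix

__all__ = [
    "ScanResult",
    "FdrTable",
    "lm_scan",
    "gene_level_permutation_fdr",
    "single_snp_bf",
    "bf_scan",
    "genotype_signal_concordance",
    "sign_test",
    "DEFAULT_PRIOR_SDS",
]

P_FLOOR = 1e-300
DEFAULT_PRIOR_SDS = (0.1, 0.2, 0.4, 0.8)


@dataclass
class ScanResult:
    """Per-SNP OLS results for one gene's cis-window."""

    gene_id: str
    table: pd.DataFrame  # columns: snp_id, beta, se, t, p, constant

    @property
    def best_p(self) -> float:
        return float(self.table["p"].min())

    @property
    def second_best_p(self) -> float:
        if len(self.table) < 2:
            return float("nan")
        return float(np.sort(self.table["p"].to_numpy())[1])

    @property
    def best_snp(self) -> str:
        return str(self.table.loc[self.table["p"].idxmin(), "snp_id"])


@dataclass
class FdrTable:
    """Estimated gene-level FDR on a grid of best-P thresholds."""

    table: pd.DataFrame  # columns: threshold, n_observed, mean_null, fdr
    n_perm: int
    seed: int

    def threshold_at_fdr(self, target: float) -> float:
        """Largest (most permissive) threshold whose estimated FDR <= target.

        Returns NaN if no threshold qualifies.
        """
        ok = self.table[self.table["fdr"] <= target]
        if ok.empty:
            return float("nan")
        return float(ok["threshold"].max())


def _scan_stats(dosages: np.ndarray, y: np.ndarray):
    """Vectorized per-column OLS slope test of y on dosage."""
    n = len(y)
    yc = y - y.mean()
    gc = dosages - dosages.mean(axis=0)
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = gc.T @ yc
    syy = float(yc @ yc)
    constant = sgg <= 0
    sgg_safe = np.where(constant, 1.0, sgg)
    beta = sgy / sgg_safe
    rss = np.maximum(syy - beta * sgy, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(np.where(sigma2 > 0, sigma2, 0.0) / sgg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(np.abs(beta) > 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, P_FLOOR, 1.0)
    beta = np.where(constant, 0.0, beta)
    se = np.where(constant, np.nan, se)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    return beta, se, t, p, constant


def lm_scan(g: GenotypeMatrix, y: np.ndarray, gene_id: str = "gene") -> ScanResult:
    """OLS slope test of phenotype on additive dosage for every SNP.

    Two-sided t P-values on n-2 degrees of freedom, floored at 1e-300.
    SNPs that are constant in the analyzed individuals get beta 0, P 1 and
    a ``constant`` flag.
    """
    y = np.asarray(y, dtype=float)
    if g.n_individuals != len(y):
        raise ValueError("phenotype length does not match individuals")
    if len(y) < 3:
        raise ValueError("need at least 3 individuals")
    beta, se, t, p, constant = _scan_stats(g.dosages, y)
    table = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in g.snps],
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "constant": constant,
        }
    )
    return ScanResult(gene_id=gene_id, table=table)


def _best_p_matrix(dosages: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Best (minimum) per-gene P over SNPs for each phenotype column of Y."""
    n = dosages.shape[0]
    gc = dosages - dosages.mean(axis=0)
    sgg = np.einsum("ij,ij->j", gc, gc)
    keep = sgg > 0
    gc = gc[:, keep]
    sgg = sgg[keep]
    if gc.shape[1] == 0:
        return np.ones(Y.shape[1])
    Yc = Y - Y.mean(axis=0)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    sgy = gc.T @ Yc  # M x B
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sgy**2 / (sgg[:, None] * syy[None, :])
    r2 = np.clip(r2, 0.0, 1.0)
    dof = n - 2
    r2max = r2.max(axis=0)
    with np.errstate(divide="ignore"):
        tmax = np.sqrt(dof * r2max / np.maximum(1.0 - r2max, 1e-16))
    p = 2.0 * stats.t.sf(tmax, dof)
    return np.clip(p, P_FLOOR, 1.0)


def gene_level_permutation_fdr(
    genotypes: list,
    phenotypes: list,
    n_perm: int = 100,
    seed: int = 0,
    thresholds=None,
) -> FdrTable:
    """Estimate the gene-level FDR of a cis scan by permutation.

    For each permutation the individual labels of the expression data are
    shuffled once and applied jointly to every gene (preserving both
    genotype LD and gene-gene expression correlation), and every gene is
    rescanned. For a best-P threshold t,

        FDR(t) = mean over permutations of #{genes with best P <= t}
                 / #{observed genes with best P <= t},

    reported as NaN where the denominator is zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = genotypes[0].n_individuals
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    obs_best = np.empty(len(genotypes))
    null_best = np.empty((len(genotypes), n_perm))
    for k, (g, y) in enumerate(zip(genotypes, phenotypes)):
        y = np.asarray(y, dtype=float)
        Y = np.column_stack([y] + [y[perm] for perm in perms])
        best = _best_p_matrix(g.dosages, Y)
        obs_best[k] = best[0]
        null_best[k] = best[1:]
    if thresholds is None:
        thresholds = np.sort(np.unique(obs_best))
    thresholds = np.asarray(thresholds, dtype=float)
    n_obs = (obs_best[None, :] <= thresholds[:, None]).sum(axis=1)
    mean_null = (null_best.reshape(-1)[None, :] <= thresholds[:, None]).sum(axis=1) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, mean_null / np.maximum(n_obs, 1), np.nan)
    table = pd.DataFrame(
        {"threshold": thresholds, "n_observed": n_obs, "mean_null": mean_null, "fdr": fdr}
    )
    return FdrTable(table=table, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


def _log10_bf_from_moments(sgg, sgy, syy, n, prior_sds, weights):
    """log10 BF from centered second moments, averaged over the prior grid.

    Model: y = mu + beta g + eps, eps ~ N(0, sigma^2); prior beta ~
    N(0, w sigma^2) with w = sd^2 (effect scaled by the residual SD), flat
    prior on mu, reference prior p(sigma^2) ~ 1/sigma^2 shared by null and
    alternative. Integrating mu, beta, sigma^2 analytically:

        BF(w) = (1 + w Sgg)^(-1/2) * (1 - w Sgy^2 / ((1 + w Sgg) Syy))^(-(n-1)/2)
    """
    prior_sds = np.asarray(prior_sds, dtype=float)
    if weights is None:
        weights = np.full(prior_sds.shape, 1.0 / len(prior_sds))
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("prior weights must sum to 1")
    w = prior_sds**2
    sgg = np.atleast_1d(np.asarray(sgg, dtype=float))
    sgy = np.atleast_1d(np.asarray(sgy, dtype=float))
    shrink = 1.0 + w[:, None] * sgg[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(
            syy > 0, w[:, None] * sgy[None, :] ** 2 / (shrink * syy), 0.0
        )
    frac = np.clip(frac, 0.0, 1.0 - 1e-15)
    log_bf_w = -0.5 * np.log(shrink) - ((n - 1) / 2.0) * np.log1p(-frac)
    log_bf = logsumexp(log_bf_w + np.log(weights)[:, None], axis=0)
    return log_bf / np.log(10.0)


def single_snp_bf(
    dosage: np.ndarray,
    y: np.ndarray,
    prior_sds=DEFAULT_PRIOR_SDS,
    weights=None,
    standardize: bool = True,
) -> float:
    """log10 Bayes factor for "this SNP is the causal site" vs "no effect".

    The phenotype is standardized to mean 0, variance 1 first (so the
    effect-size prior SDs are on the standardized scale and the BF is
    invariant to affine rescaling of y). A constant dosage carries no
    information: log10 BF = 0.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(dosage) != len(y):
        raise ValueError("dosage and phenotype lengths differ")
    if standardize:
        sd = y.std()
        if sd == 0:
            return 0.0
        y = (y - y.mean()) / sd
    gc = dosage - dosage.mean()
    sgg = float(gc @ gc)
    if sgg <= 0:
        return 0.0
    yc = y - y.mean()
    return float(
        _log10_bf_from_moments(sgg, float(gc @ yc), float(yc @ yc), len(y), prior_sds, weights)[0]
    )


def bf_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    prior_sds=DEFAULT_PRIOR_SDS,
    weights=None,
    gene_id: str = "gene",
) -> pd.DataFrame:
    """Vectorized :func:`single_snp_bf` over every SNP of a cis-window."""
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd > 0:
        y = (y - y.mean()) / sd
    yc = y - y.mean()
    gc = g.dosages - g.dosages.mean(axis=0)
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = gc.T @ yc
    syy = float(yc @ yc)
    log10bf = _log10_bf_from_moments(sgg, sgy, syy, len(y), prior_sds, weights)
    log10bf = np.where(sgg > 0, log10bf, 0.0)
    return pd.DataFrame(
        {"gene_id": gene_id, "snp_id": [s.snp_id for s in g.snps], "log10_bf": log10bf}
    )


# ---------------------------------------------------------------------------
# genotype vs quantitative signal
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    slope: float
    p_slope: float
    concordant: object  # True / False / None when the slope is exactly 0


def genotype_signal_concordance(signal, dosage, expr_beta_sign) -> ConcordanceResult:
    """Regress a per-individual molecular signal on genotype dosage and ask
    whether the slope's sign matches the expression effect's sign.

    Requires at least two distinct genotype classes; a numerically zero
    slope is reported with ``concordant=None``.
    """
    signal = np.asarray(signal, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if len(np.unique(np.round(dosage))) < 2:
        raise ValueError("need at least two genotype classes")
    res = stats.linregress(dosage, signal)
    if res.slope == 0:
        return ConcordanceResult(0.0, float(res.pvalue) if np.isfinite(res.pvalue) else 1.0, None)
    sign = 1 if res.slope > 0 else -1
    want = 1 if expr_beta_sign > 0 else -1
    return ConcordanceResult(float(res.slope), float(res.pvalue), sign == want)


def sign_test(n_concordant: int, n_total: int) -> float:
    """Two-sided exact binomial sign test of concordant/discordant counts."""
    return float(stats.binomtest(n_concordant, n_total, 0.5, alternative="two-sided").pvalue)
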