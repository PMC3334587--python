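"""Expression normalization pipeline.

Raw expression is transformed into the analysis phenotype in five steps:

1. probe-SNP residualization — if a SNP inside an array probe is
   significantly associated with the probe's intensity, use the residual;
2. confounder PC selection — principal components of the expression matrix
   that explain more variance than a within-gene permutation null;
3. covariate regression — population and sex are always removed; the
   selected PCs compete in an elastic net with tuning by leave-one-out
   cross-validation;
4. per-group quantile normalization to standard-normal scores;
5. an expressed-gene filter on a read-depth matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import LeaveOneOut

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationReport",
    "residualize_probe_snp",
    "select_confounder_pcs",
    "regress_out_covariates",
    "quantile_normalize_by_group",
    "expressed_gene_filter",
    "normalize_expression",
]


@dataclass
class NormalizationReport:
    n_pcs_candidate: int = 0
    pcs_selected: list = field(default_factory=list)
    pc_empirical_p: list = field(default_factory=list)
    per_gene_covariates: dict = field(default_factory=dict)
    n_probe_residualized: int = 0

    def to_dict(self) -> dict:
        return {
            "n_pcs_candidate": self.n_pcs_candidate,
            "pcs_selected": list(self.pcs_selected),
            "pc_empirical_p": [float(p) for p in self.pc_empirical_p],
            "per_gene_covariates": {k: list(v) for k, v in self.per_gene_covariates.items()},
            "n_probe_residualized": self.n_probe_residualized,
        }


def residualize_probe_snp(expr, in_probe_dosage, alpha: float = 0.05):
    """Remove in-probe SNP hybridization artifacts.

    Regress the probe's expression on the dosage of the SNP located inside
    the probe; if the slope is significant (P < ``alpha``) return the OLS
    residuals, otherwise return the input unchanged. Returns
    ``(values, was_residualized)``.
    """
    expr = np.asarray(expr, dtype=float)
    dosage = np.asarray(in_probe_dosage, dtype=float)
    if len(expr) != len(dosage):
        raise ValueError("expression and dosage lengths differ")
    if np.ptp(dosage) == 0:
        warnings.warn("constant in-probe dosage; expression returned unchanged")
        return expr.copy(), False
    res = stats.linregress(dosage, expr)
    if res.pvalue < alpha:
        fitted = res.intercept + res.slope * dosage
        return expr - fitted, True
    return expr.copy(), False


def _variance_explained(values: np.ndarray, max_pc: int) -> np.ndarray:
    """Share of total variance along the first ``max_pc`` PCs of a
    genes-as-observations matrix (columns = individuals), already centered."""
    sv = np.linalg.svd(values, compute_uv=False)
    var = sv**2
    total = var.sum()
    if total == 0:
        return np.zeros(min(max_pc, len(var)))
    return (var / total)[:max_pc]


def select_confounder_pcs(
    values: np.ndarray,
    n_perm: int = 100,
    max_pc: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Permutation-calibrated selection of confounder PCs.

    ``values`` is genes x individuals. The matrix is centered within each
    individual (column), then the variance-explained share of each of the
    first ``max_pc`` PCs is compared against a null built by permuting
    every gene's values across individuals (``n_perm`` times). PC i is
    selected iff its empirical P = (1 + #{perm VE_i >= obs VE_i}) /
    (1 + n_perm) is below ``alpha``.

    Returns ``(selected_indices (1-based), scores, report)`` where
    ``scores`` is the individuals x max_pc matrix of PC scores usable as
    regression covariates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    n_genes, n_ind = values.shape
    max_pc = min(max_pc, n_genes, n_ind)
    centered = values - values.mean(axis=0, keepdims=True)  # within-individual
    obs_ve = _variance_explained(centered, max_pc)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(max_pc)
    for _ in range(n_perm):
        perm = np.empty_like(values)
        for i in range(n_genes):
            perm[i] = values[i, rng.permutation(n_ind)]
        perm -= perm.mean(axis=0, keepdims=True)
        null_ve = _variance_explained(perm, max_pc)
        exceed += null_ve >= obs_ve
    emp_p = (1.0 + exceed) / (1.0 + n_perm)
    selected = [i + 1 for i in range(max_pc) if emp_p[i] < alpha]
    # PC scores: right singular vectors scaled by singular values
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    scores = (vt[:max_pc].T * sv[:max_pc])
    report = NormalizationReport(
        n_pcs_candidate=max_pc,
        pcs_selected=selected,
        pc_empirical_p=list(emp_p),
    )
    return selected, scores, report


def _design_from_labels(covariates: pd.DataFrame) -> pd.DataFrame:
    """Indicator-encode categorical columns (population, sex); keep numeric."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float).to_frame())
    if not parts:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(parts, axis=1)


def _drop_degenerate(X: pd.DataFrame) -> pd.DataFrame:
    keep = []
    seen = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.info("dropping constant covariate column %r", col)
            continue
        if any(np.allclose(v, u) for u in seen):
            logger.info("dropping duplicate covariate column %r", col)
            continue
        keep.append(col)
        seen.append(v)
    return X[keep]


def regress_out_covariates(
    gene_expr,
    covariates: pd.DataFrame,
    pc_columns=None,
    l1_ratios=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_alphas: int = 50,
    seed: int = 0,
):
    """Remove population, sex and selected-PC effects from one gene.

    Population and sex (any non-PC column of ``covariates``) are always
    removed, by OLS. The PC columns then compete in an elastic net fitted
    to the OLS residual (mixing parameter over ``l1_ratios`` x an
    ``n_alphas``-point regularization path, tuned by leave-one-out CV);
    PCs with nonzero coefficients are reported as the gene's selected
    covariates. Returns ``(residual, selected_pc_columns)``.
    """
    y = np.asarray(gene_expr, dtype=float)
    if pc_columns is None:
        pc_columns = [c for c in covariates.columns if str(c).upper().startswith("PC")]
    base_cols = [c for c in covariates.columns if c not in pc_columns]
    X_base = _drop_degenerate(_design_from_labels(covariates[base_cols]))
    # stage 1: mandatory covariates by OLS
    if len(X_base.columns):
        A = np.column_stack([np.ones(len(y)), X_base.to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        P = lambda v: v - A @ np.linalg.lstsq(A, v, rcond=None)[0]
    else:
        resid = y - y.mean()
        P = lambda v: v - v.mean()
    X_pc = _drop_degenerate(covariates[list(pc_columns)]) if len(pc_columns) else pd.DataFrame(index=covariates.index)
    if not len(X_pc.columns):
        return resid, []
    # stage 2: PCs (orthogonalized against the mandatory block) via elastic net
    Z = np.column_stack([P(X_pc[c].to_numpy(dtype=float)) for c in X_pc.columns])
    scale = Z.std(axis=0)
    ok = scale > 0
    Z = Z[:, ok] / scale[ok]
    kept_cols = [c for c, k in zip(X_pc.columns, ok) if k]
    if Z.shape[1] == 0:
        return resid, []
    enet = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        alphas=n_alphas,  # length of the automatic regularization path
        cv=LeaveOneOut(),
        random_state=seed,
        max_iter=5000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Z, resid)
    selected = [c for c, b in zip(kept_cols, enet.coef_) if b != 0]
    return resid - Z @ enet.coef_, selected


def quantile_normalize_by_group(values, group) -> np.ndarray:
    """Map values to standard-normal quantiles within each group.

    Within a group of size n the output is Phi^{-1}((rank - 0.5)/n) with
    mid-ranks for ties, so input ranks are preserved and any strictly
    monotone transform of the input yields identical output.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values not allowed")
    group = np.asarray(group)
    out = np.empty_like(values)
    for g in np.unique(group):
        mask = group == g
        r = stats.rankdata(values[mask], method="average")
        out[mask] = stats.norm.ppf((r - 0.5) / mask.sum())
    return out


def expressed_gene_filter(depth: pd.DataFrame, threshold: float = 1e-10) -> list:
    """Genes whose normalized read depth exceeds ``threshold`` in strictly
    more than half the individuals."""
    d = depth.to_numpy(dtype=float)
    if (d < 0).any():
        raise ValueError("depths must be non-negative")
    n = d.shape[1]
    keep = (d > threshold).sum(axis=1) > n / 2
    return [g for g, k in zip(depth.index, keep) if k]


def normalize_expression(
    values: np.ndarray,
    covariates: pd.DataFrame,
    probe_snp_dosages: dict | None = None,
    gene_ids=None,
    n_perm: int = 100,
    max_pc: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
    l1_ratios=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_alphas: int = 50,
):
    """Full pipeline: probe-SNP residualization, PC selection, covariate
    regression, per-population quantile normalization.

    ``values`` is genes x individuals; ``covariates`` must contain a
    ``population`` column (and optionally ``sex``); ``probe_snp_dosages``
    maps gene id -> in-probe SNP dosage vector. Returns ``(normalized
    genes x individuals array, NormalizationReport)``.
    """
    values = np.asarray(values, dtype=float).copy()
    n_genes, n_ind = values.shape
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(n_genes)]
    report = NormalizationReport()
    if probe_snp_dosages:
        for i, gid in enumerate(gene_ids):
            if gid in probe_snp_dosages:
                values[i], did = residualize_probe_snp(values[i], probe_snp_dosages[gid])
                report.n_probe_residualized += int(did)
    selected, scores, pc_report = select_confounder_pcs(
        values, n_perm=n_perm, max_pc=max_pc, alpha=alpha, seed=seed
    )
    report.n_pcs_candidate = pc_report.n_pcs_candidate
    report.pcs_selected = pc_report.pcs_selected
    report.pc_empirical_p = pc_report.pc_empirical_p
    cov = covariates.copy()
    pc_cols = []
    for i in selected:
        col = f"PC{i}"
        cov[col] = scores[:, i - 1]
        pc_cols.append(col)
    population = covariates["population"].to_numpy()
    out = np.empty_like(values)
    for i, gid in enumerate(gene_ids):
        resid, sel = regress_out_covariates(
            values[i], cov, pc_columns=pc_cols, seed=seed,
            l1_ratios=l1_ratios, n_alphas=n_alphas,
        )
        report.per_gene_covariates[gid] = sel
        out[i] = quantile_normalize_by_group(resid, population)
    return out, report
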