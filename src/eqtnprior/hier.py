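"""Bayesian hierarchical model of causal-variant location.

Each gene k has M_k candidate SNPs in its cis-window, a per-SNP Bayes
factor BF_jk measuring association evidence, and binary annotation
indicators delta_jkl. Assuming at most one causal SNP (eQTN) per gene, the
model places a softmax (conditional-logit) prior over which SNP it is,

    pi_jk = exp(x_jk) / sum_j' exp(x_j'k),    x_jk = sum_l lambda_l delta_jkl,

and a shared probability Pi0 that the gene has no eQTN at all. Relative to
the no-eQTN model, the marginal likelihood of gene k's expression is

    L_k / P_k0 = Pi0 + (1 - Pi0) * sum_j pi_jk BF_jk.

Maximizing the joint log relative likelihood over (lambda, Pi0) across all
genes yields enrichment estimates: exp(lambda_l) is the fold enrichment of
eQTNs in annotation l, controlling for the other annotations. Combining
the fitted prior with the Bayes factors gives a posterior probability per
SNP of being the eQTN. Fitting is by EM (default) or direct quasi-Newton;
confidence intervals are profile-likelihood based and may be unbounded
below for annotations whose member SNPs carry no signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HierParams",
    "HierFit",
    "HierData",
    "prior_probabilities",
    "gene_relative_likelihood",
    "fit_hierarchical",
    "posterior_probabilities",
    "enrichment_report",
    "profile_ci",
    "annotation_posterior_mass",
    "model_aic",
    "compare_models",
    "cross_validate",
    "prior_only_ranking",
    "rank_percentile",
    "select_holdout_genes",
]

LAMBDA_CAP = 20.0
LN10 = np.log(10.0)


@dataclass
class HierParams:
    """Fitted (or supplied) parameters: annotation log-odds and Pi0."""

    lambdas: np.ndarray
    pi0: float
    annotation_names: list = field(default_factory=list)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if not np.all(np.isfinite(self.lambdas)):
            raise ValueError("lambda estimates must be finite")


@dataclass
class HierFit:
    params: HierParams
    loglik: float
    n_params: int
    ci: dict = field(default_factory=dict)  # name -> (lo, hi); may be None
    converged: bool = True
    n_iter: int = 0
    backend: str = "em"

    def to_dict(self) -> dict:
        return {
            "lambdas": {n: float(v) for n, v in zip(self.params.annotation_names, self.params.lambdas)},
            "pi0": float(self.params.pi0),
            "loglik": float(self.loglik),
            "n_params": self.n_params,
            "ci": {k: (None if v is None else [float(v[0]), float(v[1])]) for k, v in self.ci.items()},
            "converged": self.converged,
            "n_iter": self.n_iter,
            "backend": self.backend,
        }


class HierData:
    """Flattened per-gene Bayes factors and annotation designs.

    Built from per-gene log10-BF vectors and SNP x annotation indicator
    matrices with identical columns across genes; stored as concatenated
    arrays with gene offsets for fast segmented likelihood evaluation.
    """

    def __init__(self, gene_ids, log10_bfs, deltas, annotation_names=None):
        if len(gene_ids) != len(log10_bfs) or len(gene_ids) != len(deltas):
            raise ValueError("gene_ids, log10_bfs, deltas must align")
        mats = []
        for d in deltas:
            if isinstance(d, pd.DataFrame):
                if annotation_names is None:
                    annotation_names = list(d.columns)
                elif list(d.columns) != list(annotation_names):
                    raise ValueError("annotation columns differ across genes")
                mats.append(d.to_numpy(dtype=float))
            else:
                mats.append(np.asarray(d, dtype=float))
        ncol = {m.shape[1] for m in mats}
        if len(ncol) != 1:
            raise ValueError("annotation column count differs across genes")
        (L,) = ncol
        if annotation_names is None:
            annotation_names = [f"annot{i}" for i in range(L)]
        self.gene_ids = list(gene_ids)
        self.annotation_names = list(annotation_names)
        self.starts = np.concatenate([[0], np.cumsum([len(b) for b in log10_bfs])]).astype(int)
        self.log_bf = np.concatenate([np.asarray(b, dtype=float) * LN10 for b in log10_bfs])
        self.delta = np.vstack(mats)
        if self.delta.shape[0] != len(self.log_bf):
            raise ValueError("BF and delta row counts differ")
        if not np.isin(self.delta, (0.0, 1.0)).all():
            raise ValueError("delta entries must be binary")
        if (np.diff(self.starts) < 1).any():
            raise ValueError("every gene needs at least one SNP")
        empty = self.delta.sum(axis=0) == 0
        if empty.any():
            bad = [annotation_names[i] for i in np.flatnonzero(empty)]
            raise ValueError(f"annotations with zero SNP membership: {bad}")
        self.gene_index = np.repeat(np.arange(self.n_genes), np.diff(self.starts))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_annotations(self) -> int:
        return self.delta.shape[1]

    def gene_slice(self, k: int) -> slice:
        return slice(self.starts[k], self.starts[k + 1])

    def subset_genes(self, indices) -> "HierData":
        indices = np.asarray(indices, dtype=int)
        bfs = [self.log_bf[self.gene_slice(k)] / LN10 for k in indices]
        ds = [self.delta[self.gene_slice(k)] for k in indices]
        return HierData([self.gene_ids[k] for k in indices], bfs, ds, self.annotation_names)

    def select_annotations(self, names) -> "HierData":
        idx = [self.annotation_names.index(n) for n in names]
        bfs = [self.log_bf[self.gene_slice(k)] / LN10 for k in range(self.n_genes)]
        ds = [self.delta[self.gene_slice(k)][:, idx] for k in range(self.n_genes)]
        return HierData(self.gene_ids, bfs, ds, list(names))


def _segment_softmax(x: np.ndarray, starts: np.ndarray):
    """Per-gene (logsumexp, softmax) for a flat score vector."""
    seg_max = np.maximum.reduceat(x, starts[:-1])
    counts = np.diff(starts)
    e = np.exp(x - np.repeat(seg_max, counts))
    sums = np.add.reduceat(e, starts[:-1])
    lse = seg_max + np.log(sums)
    return lse, e / np.repeat(sums, counts)


def prior_probabilities(lambdas, delta) -> np.ndarray:
    """Softmax prior over one gene's SNPs: pi_j from x_j = delta_j . lambda.

    Computed with max-subtraction; adding a constant to every x_j leaves
    pi unchanged, and pi always sums to 1.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2 or delta.shape[0] == 0:
        raise ValueError("delta must be a non-empty SNP x annotation matrix")
    x = delta @ np.asarray(lambdas, dtype=float)
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def gene_relative_likelihood(pi0: float, pi, bf) -> float:
    """Gene marginal likelihood relative to the no-eQTN model:
    Pi0 + (1 - Pi0) * sum_j pi_j BF_j (linear-scale BFs)."""
    pi = np.asarray(pi, dtype=float)
    bf = np.asarray(bf, dtype=float)
    return float(pi0 + (1.0 - pi0) * float(pi @ bf))


def _loglik_parts(lambdas, phi, data: HierData):
    """Log relative likelihood, per-gene eQTN posterior weight w1, and the
    per-SNP posterior allocation, at (lambda, logit(Pi0))."""
    x = data.delta @ lambdas
    lse_x, pi = _segment_softmax(x, data.starts)
    lse_a, p_post = _segment_softmax(x + data.log_bf, data.starts)
    log_s = lse_a - lse_x
    # log Pi0 = -softplus(phi) * ... using logaddexp for stability
    log_pi0 = -np.logaddexp(0.0, -phi)
    log_1m = -np.logaddexp(0.0, phi)
    ll_k = np.logaddexp(log_pi0, log_1m + log_s)
    w1 = np.exp(log_1m + log_s - ll_k)
    return float(ll_k.sum()), w1, p_post, pi, log_s


def _neg_loglik_grad(theta, data: HierData):
    lambdas, phi = theta[:-1], theta[-1]
    ll, w1, p_post, pi, _ = _loglik_parts(lambdas, phi, data)
    r = w1[data.gene_index] * (p_post - pi)
    grad_lam = data.delta.T @ r
    pi0 = 1.0 / (1.0 + np.exp(-phi))
    grad_phi = np.sum((1.0 - pi0) * (1.0 - w1) - pi0 * w1)
    return -ll, -np.concatenate([grad_lam, [grad_phi]])


def _fit_direct(data: HierData, lam0, phi0, tol, max_iter):
    theta0 = np.concatenate([lam0, [phi0]])
    bounds = [(-LAMBDA_CAP, LAMBDA_CAP)] * len(lam0) + [(-35.0, 35.0)]
    res = optimize.minimize(
        _neg_loglik_grad,
        theta0,
        args=(data,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-9},
    )
    lam, phi = res.x[:-1], res.x[-1]
    return lam, phi, -res.fun, res.nit, res.success


def _fit_em(data: HierData, lam0, phi0, tol, max_iter):
    lam = lam0.copy()
    phi = phi0
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        ll, w1, p_post, _, _ = _loglik_parts(lam, phi, data)
        if ll < ll_prev - 1e-8:
            warnings.warn("EM log-likelihood decreased; numerical trouble")
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # M-step, Pi0: closed form
        pi0 = float(np.mean(1.0 - w1))
        pi0 = min(max(pi0, 1e-12), 1.0 - 1e-12)
        phi = float(np.log(pi0 / (1.0 - pi0)))
        # M-step, lambda: weighted conditional-logit objective
        q = w1[data.gene_index] * p_post
        qd = data.delta.T @ q  # sum_j q_j delta_jl

        def neg_q(lmb):
            x = data.delta @ lmb
            lse_x, pi = _segment_softmax(x, data.starts)
            val = q @ x - float(w1 @ lse_x)
            grad = qd - data.delta.T @ (w1[data.gene_index] * pi)
            return -val, -grad

        res = optimize.minimize(
            neg_q,
            lam,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-LAMBDA_CAP, LAMBDA_CAP)] * len(lam),
            options={"maxiter": 200},
        )
        lam = res.x
    ll, *_ = _loglik_parts(lam, phi, data)
    return lam, phi, ll, n_iter, converged


def fit_hierarchical(
    data: HierData,
    init: HierParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    backend: str = "em",
    ci_level: float | None = None,
) -> HierFit:
    """Maximize the joint log relative likelihood over (lambda, Pi0).

    ``backend`` is "em" (default; E-step gives per-gene eQTN posteriors,
    M-step a closed-form Pi0 and a weighted conditional-logit update for
    lambda) or "direct" (quasi-Newton on the marginal likelihood with
    analytic gradient). Lambdas are capped at +/-20 against separation;
    hitting the cap warns. When ``ci_level`` is given, profile-likelihood
    CIs are attached for every annotation.
    """
    if backend not in {"em", "direct"}:
        raise ValueError("backend must be 'em' or 'direct'")
    lam0 = np.zeros(data.n_annotations) if init is None else np.asarray(init.lambdas, dtype=float).copy()
    pi0_init = 0.5 if init is None else min(max(init.pi0, 1e-6), 1 - 1e-6)
    phi0 = float(np.log(pi0_init / (1.0 - pi0_init)))
    if backend == "em":
        lam, phi, ll, n_iter, ok = _fit_em(data, lam0, phi0, tol, max_iter)
    else:
        lam, phi, ll, n_iter, ok = _fit_direct(data, lam0, phi0, tol, max_iter)
    if np.any(np.abs(lam) >= LAMBDA_CAP - 1e-6):
        warnings.warn("lambda estimate hit the +/-20 cap (possible separation)")
    pi0 = 1.0 / (1.0 + np.exp(-phi))
    params = HierParams(lam, float(pi0), list(data.annotation_names))
    fit = HierFit(
        params=params,
        loglik=float(ll),
        n_params=data.n_annotations + 1,
        converged=bool(ok),
        n_iter=int(n_iter),
        backend=backend,
    )
    if ci_level is not None:
        for name in data.annotation_names:
            fit.ci[name] = profile_ci(fit, data, name, level=ci_level)
    return fit


# ---------------------------------------------------------------------------
# posteriors and summaries
# ---------------------------------------------------------------------------


def posterior_probabilities(params: HierParams, log10_bf, delta):
    """Per-SNP posterior probability of being the eQTN for one gene.

    posterior_j = (1-Pi0) pi_j BF_j / (Pi0 + (1-Pi0) sum_j' pi_j' BF_j');
    the per-SNP posteriors sum to the gene-level posterior P(has eQTN).
    Returns ``(per_snp_posterior, gene_posterior)``.
    """
    delta = np.asarray(delta, dtype=float)
    log_bf = np.asarray(log10_bf, dtype=float) * LN10
    if params.pi0 >= 1.0:
        return np.zeros(len(log_bf)), 0.0
    x = delta @ params.lambdas
    a = x + log_bf
    m = a.max()
    ea = np.exp(a - m)
    mx = x.max()
    ex = np.exp(x - mx)
    log_s = (m + np.log(ea.sum())) - (mx + np.log(ex.sum()))
    if params.pi0 <= 0.0:
        w1 = 1.0
    else:
        w1 = float(1.0 / (1.0 + np.exp(np.log(params.pi0 / (1.0 - params.pi0)) - log_s)))
    post = w1 * ea / ea.sum()
    return post, float(w1)


def enrichment_report(fit: HierFit) -> pd.DataFrame:
    """Fold enrichment exp(lambda) per annotation with exponentiated CIs.

    A profile CI unbounded below on the log-odds scale maps to a fold
    lower bound of 0.
    """
    rows = []
    for i, name in enumerate(fit.params.annotation_names):
        lam = fit.params.lambdas[i]
        ci = fit.ci.get(name)
        lo = hi = np.nan
        if ci is not None:
            lo = 0.0 if np.isneginf(ci[0]) else float(np.exp(ci[0]))
            hi = float(np.exp(ci[1])) if np.isfinite(ci[1]) else np.inf
        rows.append((name, lam, float(np.exp(lam)), lo, hi))
    return pd.DataFrame(rows, columns=["annotation", "lambda", "fold", "fold_lo", "fold_hi"])


def _profile_loglik(data: HierData, l_idx: int, value: float, fit: HierFit, tol=1e-8):
    """Max log-likelihood with lambda_l fixed at ``value``."""
    L = data.n_annotations
    free = [i for i in range(L) if i != l_idx]
    pi0 = min(max(fit.params.pi0, 1e-9), 1 - 1e-9)
    theta0 = np.concatenate([fit.params.lambdas[free], [np.log(pi0 / (1 - pi0))]])

    def neg(theta):
        lam = np.empty(L)
        lam[free] = theta[:-1]
        lam[l_idx] = value
        nll, grad = _neg_loglik_grad(np.concatenate([lam, [theta[-1]]]), data)
        return nll, np.concatenate([grad[:-1][free], [grad[-1]]])

    bounds = [(-LAMBDA_CAP, LAMBDA_CAP)] * len(free) + [(-35.0, 35.0)]
    res = optimize.minimize(neg, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": tol, "gtol": 1e-10})
    return -res.fun


def profile_ci(fit: HierFit, data: HierData, annotation, level: float = 0.95):
    """Profile-likelihood CI for one annotation's lambda.

    The interval is {v : 2 (loglik_max - profile(v)) <= chi2_1(level)},
    with the other parameters re-optimized at each v. A likelihood that
    stays within the cutoff down to lambda = -25 is reported as unbounded
    below (-inf); similarly above. ``level -> 0`` collapses to the MLE.
    """
    l_idx = fit.params.annotation_names.index(annotation) if isinstance(annotation, str) else int(annotation)
    lam_hat = float(fit.params.lambdas[l_idx])
    if level <= 0:
        return (lam_hat, lam_hat)
    cutoff = stats.chi2.ppf(level, 1) / 2.0
    target = fit.loglik - cutoff

    def f(v):
        return _profile_loglik(data, l_idx, v, fit) - target

    bounds = []
    for direction in (-1.0, 1.0):
        step = 0.5
        lo_v = lam_hat
        found = None
        while step <= 64.0:
            v = lam_hat + direction * step
            if abs(v) > LAMBDA_CAP + 5:
                break
            if f(v) < 0:
                found = v
                break
            lo_v = v
            step *= 2.0
        if found is None:
            bounds.append(direction * np.inf)
        else:
            a, b = sorted((lo_v, found))
            try:
                root = optimize.brentq(f, a, b, xtol=1e-4)
            except ValueError:
                warnings.warn("profile CI bracketing failed; reporting NaN bound")
                root = np.nan
            bounds.append(root)
    return (bounds[0], bounds[1])


def annotation_posterior_mass(posteriors, delta_columns) -> float:
    """Fraction of total posterior eQTN mass falling inside an annotation.

    ``posteriors`` and ``delta_columns`` are aligned per-gene sequences of
    per-SNP posterior vectors and binary indicator vectors for the
    annotation of interest. Returns NaN when total mass is zero.
    """
    num = 0.0
    den = 0.0
    for post, dcol in zip(posteriors, delta_columns):
        post = np.asarray(post, dtype=float)
        dcol = np.asarray(dcol, dtype=float)
        num += float(post @ dcol)
        den += float(post.sum())
    if den == 0:
        return float("nan")
    return num / den


def model_aic(fit: HierFit) -> float:
    """Akaike information criterion: 2 k - 2 loglik (lower is better)."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def compare_models(fits: dict) -> pd.DataFrame:
    """Rank fitted models by AIC; differences > 2 units are flagged."""
    rows = []
    for name, fit in fits.items():
        if not fit.converged:
            warnings.warn(f"model {name!r} did not converge; excluded from AIC ranking")
            continue
        rows.append((name, fit.loglik, fit.n_params, model_aic(fit)))
    df = pd.DataFrame(rows, columns=["model", "loglik", "n_params", "aic"]).sort_values("aic")
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["significant"] = df["delta_aic"] > 2.0
    return df.reset_index(drop=True)


def cross_validate(data: HierData, model_annotations: dict, k: int = 10, seed: int = 0, **fit_kw) -> pd.DataFrame:
    """Ten-fold (by default) cross-validation over genes.

    Genes are partitioned into ``k`` folds; for each fold and each model
    (a named subset of annotation columns) the parameters are fitted on
    the training genes and the summed log relative likelihood of the test
    genes is evaluated with those parameters fixed. Because nothing is
    estimated from the test data, test log-likelihoods are directly
    comparable across models.
    """
    if k > data.n_genes:
        raise ValueError("more folds than genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n_genes)
    folds = np.array_split(order, k)
    rows = []
    for name, cols in model_annotations.items():
        sub = data.select_annotations(cols)
        for fold_idx, test in enumerate(folds):
            train = np.setdiff1d(order, test)
            fit = fit_hierarchical(sub.subset_genes(train), **fit_kw)
            test_data = sub.subset_genes(test)
            pi0 = min(max(fit.params.pi0, 1e-12), 1 - 1e-12)
            ll, *_ = _loglik_parts(fit.params.lambdas, float(np.log(pi0 / (1 - pi0))), test_data)
            rows.append((name, fold_idx, ll))
    return pd.DataFrame(rows, columns=["model", "fold", "test_loglik"])


# ---------------------------------------------------------------------------
# prior-only ranking and holdout-gene selection
# ---------------------------------------------------------------------------


def prior_only_ranking(params: HierParams, delta) -> pd.DataFrame:
    """Rank a gene's SNPs by prior probability alone (no expression data).

    Ties get mid-ranks; percentile = rank / M (so with all SNPs tied every
    percentile is (M+1)/(2M)).
    """
    pi = prior_probabilities(params.lambdas, delta)
    rank = stats.rankdata(-pi, method="average")
    return pd.DataFrame({"pi": pi, "rank": rank, "percentile": rank / len(pi)})


def rank_percentile(params: HierParams, delta, target_index: int) -> float:
    """Prior-rank percentile of one SNP (smaller = better ranked)."""
    ranking = prior_only_ranking(params, delta)
    return float(ranking["percentile"].iloc[target_index])


def select_holdout_genes(scans, p_max: float = 5e-8, gap_orders: float = 2.0, n: int = 100, seed: int = 0):
    """Genes with a single clear candidate causal SNP, for prior testing.

    A gene qualifies iff its best scan P-value is below ``p_max`` and the
    second-best P exceeds the best by at least ``gap_orders`` orders of
    magnitude. ``n`` genes are sampled from the qualifying set without
    replacement (all of them, with a warning, if fewer qualify).
    """
    qualifying = []
    for scan in scans:
        best, second = scan.best_p, scan.second_best_p
        if np.isnan(second):
            continue
        if best < p_max and second / best >= 10.0**gap_orders:
            qualifying.append(scan.gene_id)
    if len(qualifying) <= n:
        if len(qualifying) < n:
            warnings.warn(f"only {len(qualifying)} genes qualify (requested {n})")
        return list(qualifying)
    rng = np.random.default_rng(seed)
    return list(rng.choice(qualifying, size=n, replace=False))
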