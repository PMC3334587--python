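"""Synthetic eQTL studies with known truth.

Generates complete desk-scale studies — genotypes with linkage
disequilibrium, annotation tracks with planted enrichments, single-eQTN
expression, genotyping error — so that every downstream stage (scans,
Bayes factors, the hierarchical model, prior-only ranking) can be checked
against a known answer.

The genotype generator is a stand-in for real panel genotypes: each
haplotype is a latent Gaussian chain with exponential-decay
(Ornstein-Uhlenbeck) autocorrelation, thresholded at the allele-frequency
quantile; two haplotypes sum to a dosage. The exponential kernel is Markov,
so sampling is exact and O(n_snps). Dichotomization attenuates the latent
correlation; :func:`genotype_corr_from_latent` gives the closed-form
genotype-scale correlation implied by the model, used as the generator's
stated LD target.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .association import _scan_stats
from .io import ExpressionMatrix, GenotypeMatrix, SnpRecord, write_expression_matrix, write_genotype_matrix
from .regions import GeneModel, GenomicInterval, cis_window

__all__ = [
    "SimulationConfig",
    "StudyRegion",
    "Study",
    "simulate_genotypes",
    "genotype_corr_from_latent",
    "simulate_annotations",
    "plant_eqtns",
    "simulate_expression",
    "inject_genotype_error",
    "platform_mix_error_rates",
    "simulate_study",
    "causal_identification_experiment",
    "CausalIdentificationResult",
    "write_study_bundle",
    "read_study_bundle",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the reference study design: 210 individuals, ~1,200
    cis SNPs per gene region (100 kb flanks), MAF >= 1% with a 1/f
    spectrum, single causal SNP per eQTL gene with a mixture-of-normals
    effect size on the standardized phenotype scale, unit residual SD.
    """

    seed: int
    n_individuals: int = 210
    n_genes: int = 200
    snps_per_region: int = 1200
    maf_min: float = 0.01
    maf_max: float = 0.5
    ld_corr_length: float = 15_000.0  # bp; 0 = independent SNPs
    gene_length: int = 10_000
    flank: int = 100_000
    annotation_coverage: dict = field(default_factory=lambda: {"annot_a": 0.05})
    annotation_interval_length: int = 1_000
    disjoint_tracks: bool = False
    true_lambdas: dict = field(default_factory=lambda: {"annot_a": 0.0})
    true_pi0: float = 0.3
    effect_sds: tuple = (0.2, 0.4, 0.8)
    effect_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    resid_sd: float = 1.0
    genotype_error_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.true_pi0 <= 1.0):
            raise ValueError("true_pi0 must be in [0, 1]")
        if self.ld_corr_length < 0:
            raise ValueError("ld_corr_length must be >= 0")
        if not np.isclose(sum(self.effect_weights), 1.0):
            raise ValueError("effect_weights must sum to 1")
        for name, c in self.annotation_coverage.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coverage for {name!r} must be in [0, 1]")
        if set(self.true_lambdas) - set(self.annotation_coverage):
            raise ValueError("true_lambdas refer to tracks without coverage")

    @property
    def region_length(self) -> int:
        return self.gene_length + 2 * self.flank

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_sds"] = list(self.effect_sds)
        d["effect_weights"] = list(self.effect_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["effect_sds"] = tuple(d.get("effect_sds", (0.2, 0.4, 0.8)))
        d["effect_weights"] = tuple(d.get("effect_weights", (1 / 3, 1 / 3, 1 / 3)))
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON (keys mirror the fields)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class StudyRegion:
    gene: GeneModel
    genotypes: GenotypeMatrix
    tracks: dict


@dataclass
class Study:
    config: SimulationConfig
    regions: list
    truth: pd.DataFrame
    expression: ExpressionMatrix


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _sample_mafs(rng, n, maf_min, maf_max):
    """1/f allele-frequency spectrum truncated to [maf_min, maf_max]."""
    u = rng.random(n)
    return maf_min * (maf_max / maf_min) ** u


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    chrom: str = "chr1",
    region_start: int = 0,
) -> GenotypeMatrix:
    """One region's genotypes from the latent-chain LD model.

    SNP positions are uniform over the region; the latent haplotype
    correlation between adjacent SNPs d bp apart is exp(-d / corr_length)
    (independent when corr_length = 0). Dosages are the sum of two
    thresholded haplotype chains; SNPs whose empirical MAF falls below
    ``maf_min``, or that come out monomorphic, are dropped.
    """
    if config.n_individuals < 10:
        raise ValueError("need at least 10 individuals")
    m = config.snps_per_region
    positions = np.sort(
        rng.choice(config.region_length, size=m, replace=False)
    ) + region_start
    mafs = _sample_mafs(rng, m, config.maf_min, config.maf_max)
    thresholds = special.ndtri(mafs)
    n_hap = 2 * config.n_individuals
    if config.ld_corr_length > 0:
        r = np.exp(-np.diff(positions) / config.ld_corr_length)
    else:
        r = np.zeros(m - 1)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    noise = rng.standard_normal((n_hap, m - 1))
    scale = np.sqrt(1.0 - r**2)
    for j in range(1, m):
        z[:, j] = r[j - 1] * z[:, j - 1] + scale[j - 1] * noise[:, j - 1]
    haps = z < thresholds[None, :]
    dosages = (haps[0::2].astype(np.float64) + haps[1::2])
    p = dosages.mean(axis=0) / 2.0
    emp = np.minimum(p, 1.0 - p)
    keep = (emp >= config.maf_min) & (emp > 0)
    dosages = np.ascontiguousarray(dosages[:, keep])
    kept_pos = positions[keep]
    kept_maf = emp[keep]
    individuals = [f"ind{i:03d}" for i in range(config.n_individuals)]
    snps = [
        SnpRecord(f"{chrom}_snp{j:05d}", chrom, int(p), maf=float(f))
        for j, (p, f) in enumerate(zip(kept_pos, kept_maf))
    ]
    return GenotypeMatrix(individuals, snps, dosages)


def genotype_corr_from_latent(f1: float, f2: float, rho: float) -> float:
    """Closed-form genotype correlation implied by the latent model.

    Two thresholded standard normals with latent correlation ``rho`` and
    allele frequencies f1, f2 have binary correlation
    (Phi2(t1, t2; rho) - f1 f2) / sqrt(f1(1-f1) f2(1-f2)); summing two
    independent haplotypes leaves the correlation unchanged.
    """
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    joint = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    return float((joint - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2)))


# ---------------------------------------------------------------------------
# annotations, truth, expression
# ---------------------------------------------------------------------------


def simulate_annotations(config: SimulationConfig, regions, rng: np.random.Generator) -> dict:
    """Interval tracks with configurable genomic coverage per region.

    Each region window is tiled into candidate bins of
    ``annotation_interval_length`` bp; a track with requested coverage c
    occupies a uniform random subset of round(c * n_bins) bins, so the
    intervals are non-overlapping within a track and realized coverage is
    within one bin of the request. With ``disjoint_tracks`` the tracks
    draw from the bin pool without replacement and cannot overlap.
    """
    tracks: dict = {name: [] for name in config.annotation_coverage}
    for window in regions:
        n_bins = window.length // config.annotation_interval_length
        pool = np.arange(n_bins)
        if config.disjoint_tracks:
            pool = rng.permutation(pool)
        offset = 0
        for name, cov in config.annotation_coverage.items():
            k = int(round(cov * n_bins))
            if config.disjoint_tracks:
                chosen = pool[offset : offset + k]
                offset += k
                if offset > n_bins:
                    raise ValueError("disjoint tracks exceed available bins")
            else:
                chosen = rng.choice(n_bins, size=k, replace=False)
            for b in np.sort(chosen):
                s = window.start + int(b) * config.annotation_interval_length
                tracks[name].append(
                    GenomicInterval(window.chrom, s, s + config.annotation_interval_length)
                )
    return tracks


def plant_eqtns(deltas, gene_ids, snp_ids, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose each gene's causal SNP (or none) and its effect size.

    A gene has no eQTN with probability ``true_pi0``; otherwise the causal
    SNP is drawn with the softmax probability implied by ``true_lambdas``
    over the gene's annotation indicators, and the effect size is a draw
    from the configured mixture of normals. Returns the truth table
    (gene_id, causal_index = -1 for none, causal_snp_id, beta).
    """
    names = list(config.annotation_coverage)
    lam = np.array([config.true_lambdas.get(n, 0.0) for n in names])
    sds = np.asarray(config.effect_sds, dtype=float)
    wts = np.asarray(config.effect_weights, dtype=float)
    rows = []
    for gid, delta, sids in zip(gene_ids, deltas, snp_ids):
        if rng.random() < config.true_pi0:
            rows.append((gid, -1, None, 0.0))
            continue
        d = np.asarray(delta, dtype=float)
        x = d @ lam
        x = x - x.max()
        p = np.exp(x)
        p /= p.sum()
        j = int(rng.choice(len(p), p=p))
        comp = int(rng.choice(len(sds), p=wts))
        beta = float(rng.normal(0.0, sds[comp]))
        rows.append((gid, j, sids[j], beta))
    return pd.DataFrame(rows, columns=["gene_id", "causal_index", "causal_snp_id", "beta"])


def simulate_expression(genotypes, truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator) -> ExpressionMatrix:
    """Phenotypes from the single-eQTN linear model.

    y_i = beta * dosage_i + eps_i with eps ~ Normal(0, resid_sd^2); genes
    without an eQTN are pure noise.
    """
    n = config.n_individuals
    values = np.empty((len(truth), n))
    for i, (g, row) in enumerate(zip(genotypes, truth.itertuples())):
        eps = rng.normal(0.0, config.resid_sd, size=n)
        if row.causal_index >= 0:
            values[i] = row.beta * g.dosages[:, row.causal_index] + eps
        else:
            values[i] = eps
    individuals = genotypes[0].individuals
    covariates = pd.DataFrame(
        {
            "population": ["POP1"] * n,
            "sex": [("F" if i % 2 else "M") for i in range(n)],
        },
        index=individuals,
    )
    return ExpressionMatrix(list(truth["gene_id"]), list(individuals), values, covariates)


def inject_genotype_error(g: GenotypeMatrix, rate, rng: np.random.Generator) -> GenotypeMatrix:
    """Corrupt hard genotype calls at the given error rate.

    Each entry is independently replaced, with probability ``rate`` (a
    scalar or per-SNP vector), by one of the two other dosage classes
    chosen uniformly. Fractional dosages are rounded to hard calls first
    with a warning.
    """
    rate = np.asarray(rate, dtype=float)
    if (rate < 0).any() or (rate > 1).any():
        raise ValueError("error rate must be in [0, 1]")
    d = g.dosages
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        warnings.warn("fractional dosages rounded to hard calls before error injection")
        d = np.round(d)
    d = d.astype(int)
    flip = rng.random(d.shape) < rate  # broadcasts per-SNP rates over rows
    shift = rng.integers(1, 3, size=d.shape)  # +1 or +2 mod 3 -> other class
    corrupted = np.where(flip, (d + shift) % 3, d).astype(float)
    return GenotypeMatrix(list(g.individuals), list(g.snps), corrupted).with_recomputed_maf()


def platform_mix_error_rates(n_snps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP genotyping error rates mixing two platforms: half the SNPs
    at 0.5% (array-typed calls), the rest uniform on 1-3% (sequencing-
    derived calls)."""
    rates = np.empty(n_snps)
    array_typed = rng.random(n_snps) < 0.5
    rates[array_typed] = 0.005
    rates[~array_typed] = rng.uniform(0.01, 0.03, size=(~array_typed).sum())
    return rates


# ---------------------------------------------------------------------------
# whole studies and the causal-identification experiment
# ---------------------------------------------------------------------------


def _make_gene(config: SimulationConfig, idx: int) -> GeneModel:
    chrom = f"chr{idx + 1}"
    strand = "+" if idx % 2 == 0 else "-"
    start = config.flank
    end = config.flank + config.gene_length
    exon_len = max(200, config.gene_length // 10)
    exons = (
        GenomicInterval(chrom, start, start + exon_len, strand),
        GenomicInterval(chrom, end - exon_len, end, strand),
    )
    return GeneModel(f"gene{idx:04d}", GenomicInterval(chrom, start, end, strand), exons)


def simulate_study(config: SimulationConfig) -> Study:
    """A complete synthetic study: regions, tracks, truth, expression."""
    rng = np.random.default_rng(config.seed)
    regions = []
    windows = []
    for i in range(config.n_genes):
        gene = _make_gene(config, i)
        g = simulate_genotypes(config, rng, chrom=gene.chrom)
        regions.append(StudyRegion(gene=gene, genotypes=g, tracks={}))
        windows.append(cis_window(gene, config.flank, config.flank))
    tracks = simulate_annotations(config, windows, rng)
    from .annotations import build_indicator_matrix

    deltas, snp_ids = [], []
    for reg in regions:
        reg.tracks = {
            name: [iv for iv in ivs if iv.chrom == reg.gene.chrom]
            for name, ivs in tracks.items()
        }
        delta = build_indicator_matrix(reg.tracks, reg.gene, reg.genotypes.snps)
        deltas.append(delta.to_numpy())
        snp_ids.append([s.snp_id for s in reg.genotypes.snps])
    gene_ids = [reg.gene.gene_id for reg in regions]
    truth = plant_eqtns(deltas, gene_ids, snp_ids, config, rng)
    expression = simulate_expression([r.genotypes for r in regions], truth, config, rng)
    return Study(config=config, regions=regions, truth=truth, expression=expression)


def simulate_hier_dataset(config: SimulationConfig, rng: np.random.Generator | None = None):
    """A Bayes-factor-level dataset for enrichment-recovery experiments.

    Per gene: an LD genotype region, SNP-level annotation membership drawn
    Bernoulli(coverage) per track, a causal SNP planted by the softmax
    prior at ``true_lambdas`` (or none, w.p. ``true_pi0``), expression from
    the linear model, and the per-SNP Bayes factors of the scan. Returns
    ``(HierData, truth_table)`` ready for :func:`eqtnprior.hier.fit_hierarchical`.
    """
    from .association import _log10_bf_from_moments
    from .hier import HierData

    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(config.annotation_coverage)
    covs = np.array([config.annotation_coverage[n] for n in names])
    gene_ids, deltas, snp_ids, genos = [], [], [], []
    for i in range(config.n_genes):
        g = simulate_genotypes(config, rng)
        delta = (rng.random((g.n_snps, len(names))) < covs[None, :]).astype(float)
        if i == 0:  # guarantee nonzero membership for every annotation
            delta[0, :] = 1.0
        gene_ids.append(f"gene{i:04d}")
        deltas.append(delta)
        snp_ids.append([s.snp_id for s in g.snps])
        genos.append(g)
    truth = plant_eqtns(deltas, gene_ids, snp_ids, config, rng)
    expr = simulate_expression(genos, truth, config, rng)
    # matched analysis: BF effect-size prior = the generating mixture
    bfs = []
    for i, g in enumerate(genos):
        y = expr.values[i]
        sd = y.std()
        yc = (y - y.mean()) / (sd if sd > 0 else 1.0)
        gc = g.dosages - g.dosages.mean(axis=0)
        sgg = np.einsum("ij,ij->j", gc, gc)
        log10bf = _log10_bf_from_moments(
            sgg, gc.T @ yc, float(yc @ yc), len(y),
            config.effect_sds, config.effect_weights,
        )
        bfs.append(np.where(sgg > 0, log10bf, 0.0))
    return HierData(gene_ids, bfs, deltas, names), truth


@dataclass
class CausalIdentificationResult:
    n_genes: int
    n_qualifying: int
    n_correct: int
    fraction: float
    ci_low: float
    ci_high: float


def causal_identification_experiment(
    config: SimulationConfig,
    p_max: float = 5e-8,
    gap_orders: float = 2.0,
    error_rates=None,
) -> CausalIdentificationResult:
    """How often do the holdout-gene criteria pick the true causal SNP?

    Per gene: simulate an LD region, plant one causal SNP uniformly at
    random, simulate expression from the linear model with a mixture-drawn
    effect, optionally corrupt the observed genotypes, scan by OLS, and
    keep the gene iff best P < ``p_max`` with at least ``gap_orders``
    orders of magnitude between best and second-best P. Reports the
    fraction of kept genes whose top SNP is the planted causal SNP, with a
    Clopper-Pearson 95% interval.

    ``error_rates``: None (clean genotypes), a scalar rate, or
    "platform_mix" for the half-at-0.5% / half-at-1-3% per-SNP mix.
    """
    rng = np.random.default_rng(config.seed)
    sds = np.asarray(config.effect_sds, dtype=float)
    wts = np.asarray(config.effect_weights, dtype=float)
    gap = 10.0**gap_orders
    n_qual = 0
    n_correct = 0
    for _ in range(config.n_genes):
        g = simulate_genotypes(config, rng)
        m = g.n_snps
        causal = int(rng.integers(m))
        comp = int(rng.choice(len(sds), p=wts))
        beta = float(rng.normal(0.0, sds[comp]))
        y = beta * g.dosages[:, causal] + rng.normal(0.0, config.resid_sd, size=g.n_individuals)
        observed = g
        if error_rates is not None:
            if isinstance(error_rates, str):
                if error_rates != "platform_mix":
                    raise ValueError("error_rates must be None, a number, or 'platform_mix'")
                rates = platform_mix_error_rates(m, rng)
            else:
                rates = error_rates
            observed = inject_genotype_error(g, rates, rng)
        _, _, _, p, _ = _scan_stats(observed.dosages, y)
        order = np.argsort(p, kind="stable")
        best, second = p[order[0]], p[order[1]]
        if best < p_max and second / best >= gap:
            n_qual += 1
            n_correct += int(order[0] == causal)
    if n_qual == 0:
        warnings.warn("no genes qualified; fraction undefined")
        return CausalIdentificationResult(config.n_genes, 0, 0, float("nan"), float("nan"), float("nan"))
    frac = n_correct / n_qual
    lo = stats.beta.ppf(0.025, n_correct, n_qual - n_correct + 1) if n_correct > 0 else 0.0
    hi = stats.beta.ppf(0.975, n_correct + 1, n_qual - n_correct) if n_correct < n_qual else 1.0
    return CausalIdentificationResult(config.n_genes, n_qual, n_correct, frac, float(lo), float(hi))


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------


def write_study_bundle(study: Study, outdir, force: bool = False) -> None:
    """Write a study as plain-text files: genotypes.vcf, expression.tsv,
    covariates.tsv, genes.bed (BED12), <track>.bed per track, truth.json,
    config.json. Re-readable with :func:`read_study_bundle`."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    all_inds = study.regions[0].genotypes.individuals
    snps, cols = [], []
    for reg in study.regions:
        snps.extend(reg.genotypes.snps)
        cols.append(reg.genotypes.dosages)
    merged = GenotypeMatrix(list(all_inds), snps, np.concatenate(cols, axis=1))
    write_genotype_matrix(merged, outdir / "genotypes.vcf", fmt="vcf")
    write_expression_matrix(study.expression, outdir / "expression.tsv", outdir / "covariates.tsv")
    from .io import write_annotation_track, write_gene_models_bed12

    write_gene_models_bed12([reg.gene for reg in study.regions], outdir / "genes.bed")
    track_names = sorted({n for reg in study.regions for n in reg.tracks})
    for name in track_names:
        ivs = [iv for reg in study.regions for iv in reg.tracks.get(name, [])]
        write_annotation_track(ivs, outdir / f"track_{name}.bed")
    study.truth.to_json(outdir / "truth.json", orient="records", indent=2)
    with open(outdir / "config.json", "w") as fh:
        json.dump(study.config.to_dict(), fh, indent=2)


def read_study_bundle(outdir) -> Study:
    """Reload a study bundle written by :func:`write_study_bundle`."""
    from .io import read_annotation_track, read_expression_matrix, read_gene_models, read_genotype_matrix

    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        config = SimulationConfig.from_dict(json.load(fh))
    genotypes = read_genotype_matrix(outdir / "genotypes.vcf", fmt="vcf")
    genes = read_gene_models(outdir / "genes.bed", fmt="bed12")
    tracks = {
        p.stem.removeprefix("track_"): read_annotation_track(p)
        for p in sorted(outdir.glob("track_*.bed"))
    }
    regions = []
    for gene in genes:
        window = cis_window(gene, config.flank, config.flank)
        regions.append(
            StudyRegion(
                gene=gene,
                genotypes=genotypes.restrict(window).with_recomputed_maf(),
                tracks={n: [iv for iv in ivs if iv.chrom == gene.chrom] for n, ivs in tracks.items()},
            )
        )
    truth = pd.read_json(outdir / "truth.json", orient="records")
    truth["causal_snp_id"] = truth["causal_snp_id"].where(truth["causal_index"] >= 0, None)
    expression = read_expression_matrix(outdir / "expression.tsv", outdir / "covariates.tsv")
    return Study(config=config, regions=regions, truth=truth, expression=expression)
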