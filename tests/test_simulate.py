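"""The synthetic-data generator: LD genotypes, annotation tracks, planted
eQTNs, expression, genotyping error, bundles, and end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from eqtnprior.hier import HierParams, fit_hierarchical, prior_only_ranking, profile_ci
from eqtnprior.simulate import (
    SimulationConfig,
    causal_identification_experiment,
    genotype_corr_from_latent,
    inject_genotype_error,
    plant_eqtns,
    read_study_bundle,
    simulate_annotations,
    simulate_genotypes,
    simulate_hier_dataset,
    simulate_study,
    write_study_bundle,
)
from eqtnprior.regions import GenomicInterval


def small_config(**kw):
    base = dict(
        seed=9, n_genes=5, n_individuals=120, snps_per_region=150,
        flank=20_000, gene_length=4_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        a = simulate_genotypes(cfg, np.random.default_rng(1))
        b = simulate_genotypes(cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_zero_corr_length_gives_independent_snps(self):
        cfg = small_config(ld_corr_length=0.0, n_individuals=300, snps_per_region=200)
        g = simulate_genotypes(cfg, np.random.default_rng(2))
        r = np.corrcoef(g.dosages.T)
        adj = np.array([r[i, i + 1] for i in range(g.n_snps - 1)])
        assert abs(adj.mean()) < 0.02
        assert (adj**2).mean() < 0.02

    def test_ld_matches_closed_form_target(self):
        """Mean adjacent-SNP correlation tracks the thresholded-Gaussian
        prediction of the generator's own LD model."""
        cfg = small_config(n_individuals=250, snps_per_region=120, ld_corr_length=8_000.0)
        rng = np.random.default_rng(3)
        obs, pred = [], []
        for _ in range(25):
            g = simulate_genotypes(cfg, rng)
            d = g.dosages
            f = g.maf()
            pos = g.positions()
            r = np.corrcoef(d.T)
            for i in range(g.n_snps - 1):
                rho = np.exp(-(pos[i + 1] - pos[i]) / cfg.ld_corr_length)
                # use the model's alt-allele frequencies
                p1 = d[:, i].mean() / 2
                p2 = d[:, i + 1].mean() / 2
                pred.append(genotype_corr_from_latent(p1, p2, rho))
                obs.append(r[i, i + 1])
        assert abs(np.mean(obs) - np.mean(pred)) < 0.05

    def test_maf_floor_enforced(self):
        cfg = small_config(maf_min=0.05)
        g = simulate_genotypes(cfg, np.random.default_rng(4))
        assert (g.maf() >= 0.05).all()

    def test_negative_ld_parameter_rejected(self):
        with pytest.raises(ValueError):
            small_config(ld_corr_length=-1.0)


class TestAnnotations:
    def test_requested_coverage_realized(self):
        cfg = small_config(annotation_coverage={"t": 0.01}, true_lambdas={"t": 0.0})
        regions = [GenomicInterval("chr1", 0, 10_000_000)]
        tracks = simulate_annotations(cfg, regions, np.random.default_rng(5))
        covered = sum(iv.length for iv in tracks["t"])
        assert covered / 10_000_000 == pytest.approx(0.01, rel=0.2)

    def test_zero_coverage_empty(self):
        cfg = small_config(annotation_coverage={"t": 0.0}, true_lambdas={"t": 0.0})
        tracks = simulate_annotations(cfg, [GenomicInterval("chr1", 0, 100_000)], np.random.default_rng(6))
        assert tracks["t"] == []

    def test_disjoint_tracks_do_not_overlap(self):
        cfg = small_config(
            annotation_coverage={"a": 0.1, "b": 0.1},
            true_lambdas={"a": 0.0, "b": 0.0},
            disjoint_tracks=True,
        )
        tracks = simulate_annotations(cfg, [GenomicInterval("chr1", 0, 200_000)], np.random.default_rng(7))
        in_a = set()
        for iv in tracks["a"]:
            in_a.update(range(iv.start, iv.end))
        assert not any(p in in_a for iv in tracks["b"] for p in range(iv.start, iv.end))

    def test_intervals_disjoint_within_track(self):
        cfg = small_config(annotation_coverage={"t": 0.3}, true_lambdas={"t": 0.0})
        tracks = simulate_annotations(cfg, [GenomicInterval("chr1", 0, 50_000)], np.random.default_rng(8))
        ivs = sorted(tracks["t"], key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))


class TestPlanting:
    def _deltas(self, rng, n_genes, m, coverage, n_annot=1):
        out = []
        for _ in range(n_genes):
            out.append((rng.random((m, n_annot)) < coverage).astype(float))
        return out

    def test_uniform_when_lambda_zero(self, rng):
        cfg = small_config(n_genes=2000, true_pi0=0.0, annotation_coverage={"a": 0.5},
                           true_lambdas={"a": 0.0})
        m = 10
        deltas = self._deltas(rng, 2000, m, 0.5)
        ids = [f"g{k}" for k in range(2000)]
        sids = [[f"s{j}" for j in range(m)] for _ in range(2000)]
        truth = plant_eqtns(deltas, ids, sids, cfg, rng)
        counts = truth["causal_index"].value_counts().reindex(range(m), fill_value=0)
        chi2 = ((counts - 200) ** 2 / 200).sum()
        assert stats.chi2.sf(chi2, m - 1) > 0.01

    def test_softmax_enrichment_expectation(self, rng):
        """lambda = ln 4 on a 5%-membership annotation puts ~17.4% of causal
        SNPs inside it (4*5 / (4*5 + 95))."""
        cfg = small_config(n_genes=4000, true_pi0=0.0,
                           annotation_coverage={"a": 0.05}, true_lambdas={"a": np.log(4.0)})
        m = 40
        deltas = self._deltas(rng, 4000, m, 0.05)
        ids = [f"g{k}" for k in range(4000)]
        sids = [[f"s{j}" for j in range(m)] for _ in range(4000)]
        truth = plant_eqtns(deltas, ids, sids, cfg, rng)
        inside = [
            deltas[k][row.causal_index, 0]
            for k, row in enumerate(truth.itertuples())
        ]
        assert np.mean(inside) == pytest.approx(0.174, abs=0.025)

    def test_pi0_one_plants_nothing(self, rng):
        cfg = small_config(true_pi0=1.0)
        deltas = self._deltas(rng, 5, 10, 0.5)
        truth = plant_eqtns(deltas, list("abcde"), [[str(j) for j in range(10)]] * 5, cfg, rng)
        assert (truth["causal_index"] == -1).all()


class TestExpression:
    def test_r2_matches_variance_decomposition(self, rng):
        """beta = 0.8, MAF 0.3, sigma = 1: E[R^2] = b^2 var(g) / (b^2 var(g) + 1)."""
        n, beta = 210, 0.8
        r2s, expects = [], []
        for _ in range(200):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = beta * g + rng.standard_normal(n)
            r2s.append(np.corrcoef(g, y)[0, 1] ** 2)
            vg = g.var()
            expects.append(beta**2 * vg / (beta**2 * vg + 1.0))
        assert np.mean(r2s) == pytest.approx(np.mean(expects), abs=0.03)
        # the analytic value with exact var(g) = 2 f (1-f)
        assert np.mean(expects) == pytest.approx(0.215, abs=0.02)

    def test_genotype_group_means_differ_by_beta(self, rng):
        n, beta = 5000, 0.7
        g = rng.binomial(2, 0.4, n).astype(float)
        y = beta * g + rng.standard_normal(n)
        m0, m1, m2 = (y[g == k].mean() for k in (0, 1, 2))
        assert m1 - m0 == pytest.approx(beta, abs=0.1)
        assert m2 - m1 == pytest.approx(beta, abs=0.1)


class TestGenotypeError:
    def _geno(self, rng, n=1000, m=1000):
        from eqtnprior.io import GenotypeMatrix, SnpRecord

        snps = [SnpRecord(f"rs{i}", "chr1", i * 10) for i in range(m)]
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        return GenotypeMatrix([f"i{k}" for k in range(n)], snps, dos)

    def test_zero_rate_identity(self, rng):
        g = self._geno(rng, 50, 50)
        out = inject_genotype_error(g, 0.0, rng)
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_changed_fraction_within_binomial_bounds(self, rng):
        g = self._geno(rng)  # 1e6 entries
        out = inject_genotype_error(g, 0.01, rng)
        changed = (out.dosages != g.dosages).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 1_000_000, 0.01)
        assert lo <= changed <= hi

    def test_outputs_remain_hard_calls(self, rng):
        g = self._geno(rng, 100, 100)
        out = inject_genotype_error(g, 0.3, rng)
        assert np.isin(out.dosages, (0.0, 1.0, 2.0)).all()

    def test_invalid_rate_rejected(self, rng):
        g = self._geno(rng, 10, 10)
        with pytest.raises(ValueError):
            inject_genotype_error(g, 1.5, rng)


class TestBundle:
    def test_round_trip_and_determinism(self, tmp_path, small_study):
        out = tmp_path / "bundle"
        write_study_bundle(small_study, out)
        expected = {"genotypes.vcf", "expression.tsv", "covariates.tsv",
                    "genes.bed", "truth.json", "config.json", "track_open_chromatin.bed"}
        assert expected <= {p.name for p in out.iterdir()}
        reread = read_study_bundle(out)
        for reg, reg2 in zip(small_study.regions, reread.regions):
            np.testing.assert_allclose(reg.genotypes.dosages, reg2.genotypes.dosages)
            assert [s.pos for s in reg.genotypes.snps] == [s.pos for s in reg2.genotypes.snps]
        assert list(reread.truth["causal_index"]) == list(small_study.truth["causal_index"])
        np.testing.assert_allclose(reread.expression.values, small_study.expression.values, atol=5e-7)
        # same config, fresh simulation: identical files
        from eqtnprior.simulate import simulate_study

        study2 = simulate_study(small_study.config)
        out2 = tmp_path / "bundle2"
        write_study_bundle(study2, out2)
        assert (out / "genotypes.vcf").read_text() == (out2 / "genotypes.vcf").read_text()
        assert (out / "truth.json").read_text() == (out2 / "truth.json").read_text()

    def test_config_loads_from_yaml_and_json(self, tmp_path):
        cfg = small_config(true_pi0=0.4)
        (tmp_path / "c.yaml").write_text(
            "seed: 9\nn_genes: 5\nn_individuals: 120\nsnps_per_region: 150\n"
            "flank: 20000\ngene_length: 4000\ntrue_pi0: 0.4\n"
        )
        from_yaml = SimulationConfig.from_file(tmp_path / "c.yaml")
        assert from_yaml == cfg
        import json

        (tmp_path / "c.json").write_text(json.dumps(cfg.to_dict()))
        assert SimulationConfig.from_file(tmp_path / "c.json") == cfg

    def test_refuses_to_overwrite(self, tmp_path, small_study):
        out = tmp_path / "b"
        write_study_bundle(small_study, out)
        with pytest.raises(FileExistsError):
            write_study_bundle(small_study, out)


class TestCausalIdentification:
    def test_ld_free_genotypes_near_perfect(self):
        cfg = SimulationConfig(
            seed=21, n_genes=120, n_individuals=210, snps_per_region=300,
            flank=20_000, gene_length=4_000, ld_corr_length=0.0,
        )
        res = causal_identification_experiment(cfg)
        assert res.n_qualifying >= 10
        assert res.fraction >= 0.99

    def test_fraction_non_increasing_in_error_rate(self):
        fracs = []
        for rate in (0.0, 0.005, 0.03):
            cfg = SimulationConfig(
                seed=22, n_genes=250, n_individuals=210, snps_per_region=250,
                flank=20_000, gene_length=4_000, ld_corr_length=0.0,
            )
            res = causal_identification_experiment(cfg, error_rates=rate or None)
            fracs.append(res.fraction)
        # allow slight Monte-Carlo slack around equality
        assert fracs[1] <= fracs[0] + 0.02
        assert fracs[2] <= fracs[0] + 0.02
        assert fracs[2] <= fracs[1] + 0.03


class TestEndToEndRecovery:
    def test_lambda_recovered_within_ci(self):
        """Headline check: fitting the hierarchical model on a synthetic
        study with a planted enrichment recovers it within the profile CI."""
        cfg = SimulationConfig(
            seed=31, n_genes=800, n_individuals=210, snps_per_region=40,
            flank=10_000, gene_length=2_000,
            annotation_coverage={"a": 0.05}, true_lambdas={"a": 1.5}, true_pi0=0.3,
        )
        data, _ = simulate_hier_dataset(cfg)
        fit = fit_hierarchical(data)
        lo, hi = profile_ci(fit, data, "a")
        assert lo <= 1.5 <= hi
        assert abs(fit.params.pi0 - 0.3) < 0.1

    def test_prior_ranking_improves_with_enrichment(self):
        """Prior-rank percentiles of the true causal SNPs improve as the
        planted enrichment grows (strictly in the mean; members of a single
        binary annotation are tied, so the median moves in steps)."""
        medians, means = [], []
        for lam in (0.0, 1.5, 3.0):
            cfg = SimulationConfig(
                seed=32, n_genes=300, n_individuals=60, snps_per_region=30,
                flank=8_000, gene_length=2_000,
                annotation_coverage={"a": 0.25}, true_lambdas={"a": lam}, true_pi0=0.0,
            )
            data, truth = simulate_hier_dataset(cfg)
            params = HierParams([lam], 0.0, ["a"])
            pcts = []
            for k, row in enumerate(truth.itertuples()):
                delta = data.delta[data.gene_slice(k)]
                ranking = prior_only_ranking(params, delta)
                pcts.append(ranking["percentile"].iloc[row.causal_index])
            medians.append(np.median(pcts))
            means.append(np.mean(pcts))
        assert medians[0] == pytest.approx(0.5, abs=0.05)
        assert medians[1] < medians[0] - 0.2 and medians[2] < medians[0] - 0.2
        assert means[2] < means[1] < means[0]
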