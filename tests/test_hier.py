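"""The hierarchical enrichment model: priors, likelihood, fitting,
posteriors, CIs, model comparison, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from eqtnprior.association import ScanResult
from eqtnprior.hier import (
    HierData,
    HierFit,
    HierParams,
    _loglik_parts,
    annotation_posterior_mass,
    compare_models,
    cross_validate,
    enrichment_report,
    fit_hierarchical,
    gene_relative_likelihood,
    model_aic,
    posterior_probabilities,
    prior_only_ranking,
    prior_probabilities,
    profile_ci,
    select_holdout_genes,
)


def random_data(rng, n_genes=12, max_snps=4, n_annot=1, bf_scale=1.0):
    bfs, ds = [], []
    for _ in range(n_genes):
        m = int(rng.integers(2, max_snps + 1))
        bfs.append(bf_scale * rng.normal(0.2, 0.6, m))
        d = (rng.random((m, n_annot)) < 0.4).astype(float)
        ds.append(d)
    ds[0][0, :] = 1.0
    return HierData([f"g{k}" for k in range(n_genes)], bfs, ds)


class TestPrior:
    def test_uniform_when_lambdas_zero(self):
        pi = prior_probabilities([0.0], np.zeros((5, 1)))
        np.testing.assert_allclose(pi, 0.2)

    def test_ln2_single_member(self):
        delta = np.array([[1.0], [0.0], [0.0]])
        pi = prior_probabilities([np.log(2.0)], delta)
        np.testing.assert_allclose(pi, [0.5, 0.25, 0.25])

    def test_shift_invariance_and_normalization(self, rng):
        for _ in range(20):
            m, L = int(rng.integers(1, 8)), int(rng.integers(1, 4))
            delta = (rng.random((m, L)) < 0.5).astype(float)
            lam = rng.normal(0, 2, L)
            pi = prior_probabilities(lam, delta)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            # adding a constant to every score leaves pi unchanged
            shifted = np.column_stack([delta, np.ones(m)])
            pi2 = prior_probabilities(np.append(lam, 3.7), shifted)
            np.testing.assert_allclose(pi, pi2, atol=1e-12)

    def test_empty_snp_set_errors(self):
        with pytest.raises(ValueError):
            prior_probabilities([0.0], np.zeros((0, 1)))


class TestGeneRelativeLikelihood:
    def test_null_equivalent_data(self):
        assert gene_relative_likelihood(0.3, [0.5, 0.5], [1.0, 1.0]) == pytest.approx(1.0)

    def test_pi0_one_ignores_bfs(self):
        assert gene_relative_likelihood(1.0, [0.5, 0.5], [100.0, 7.0]) == pytest.approx(1.0)

    def test_arithmetic_instance(self):
        assert gene_relative_likelihood(0.5, [0.5, 0.5], [3.0, 1.0]) == pytest.approx(1.5)


class TestPosterior:
    def test_symmetric_case_uniform(self):
        m, bf, pi0 = 4, 5.0, 0.4
        post, gene_post = posterior_probabilities(
            HierParams([0.0], pi0, ["a"]), np.full(m, np.log10(bf)), np.zeros((m, 1))
        )
        expected_gene = (1 - pi0) * bf / (pi0 + (1 - pi0) * bf)
        np.testing.assert_allclose(post, expected_gene / m)
        assert gene_post == pytest.approx(expected_gene)

    def test_dominant_bf_takes_all(self):
        post, gene_post = posterior_probabilities(
            HierParams([0.0], 0.5, ["a"]), np.array([10.0, 0.0, 0.0]), np.zeros((3, 1))
        )
        assert post[0] == pytest.approx(1.0, abs=1e-6)

    def test_pi0_one_zeroes_posteriors(self):
        post, gene_post = posterior_probabilities(
            HierParams([0.0], 1.0, ["a"]), np.array([3.0, 1.0]), np.zeros((2, 1))
        )
        assert gene_post == 0.0 and (post == 0).all()

    def test_conservation_identity(self, rng):
        """Sum of per-SNP posteriors equals the gene posterior, which equals
        (1-Pi0) S / (Pi0 + (1-Pi0) S) with S = sum pi_j BF_j, to machine
        precision."""
        for _ in range(30):
            m = int(rng.integers(1, 9))
            log10bf = rng.normal(0, 1.5, m)
            delta = (rng.random((m, 2)) < 0.5).astype(float)
            params = HierParams(rng.normal(0, 1, 2), float(rng.uniform(0.01, 0.99)), ["a", "b"])
            post, gene_post = posterior_probabilities(params, log10bf, delta)
            assert post.sum() == pytest.approx(gene_post, rel=1e-12)
            pi = prior_probabilities(params.lambdas, delta)
            s = float(pi @ 10.0**log10bf)
            expected = (1 - params.pi0) * s / (params.pi0 + (1 - params.pi0) * s)
            assert gene_post == pytest.approx(expected, rel=1e-9)
            assert 0.0 <= gene_post <= 1.0


def grid_oracle(data, lam_lo=-6.0, lam_hi=6.0):
    """Exhaustive staged grid over lambda with inner Pi0 optimization."""

    def profile(lam):
        def neg(phi):
            ll, *_ = _loglik_parts(np.array([lam]), phi, data)
            return -ll

        res = optimize.minimize_scalar(neg, bounds=(-30, 30), method="bounded",
                                       options={"xatol": 1e-10})
        return -res.fun

    grid = np.arange(lam_lo, lam_hi + 1e-9, 0.01)
    vals = [profile(l) for l in grid]
    best = grid[int(np.argmax(vals))]
    fine = np.arange(best - 0.02, best + 0.02 + 1e-12, 1e-4)
    vals = [profile(l) for l in fine]
    return float(fine[int(np.argmax(vals))])


class TestFit:
    def test_matches_grid_oracle_on_tiny_instances(self, rng):
        checked = 0
        trials = 0
        while checked < 5 and trials < 30:
            trials += 1
            data = random_data(rng, n_genes=10, max_snps=3)
            fit = fit_hierarchical(data, backend="direct", tol=1e-12)
            if abs(fit.params.lambdas[0]) > 4:  # near-flat direction; ill-posed
                continue
            lam_grid = grid_oracle(data)
            assert abs(fit.params.lambdas[0] - lam_grid) < 1e-3
            checked += 1
        assert checked == 5

    def test_em_and_direct_agree(self, rng):
        data = random_data(rng, n_genes=40, max_snps=6)
        em = fit_hierarchical(data, backend="em", tol=1e-10, max_iter=3000)
        direct = fit_hierarchical(data, backend="direct", tol=1e-12)
        assert em.loglik == pytest.approx(direct.loglik, abs=1e-4)
        np.testing.assert_allclose(em.params.lambdas, direct.params.lambdas, atol=5e-3)

    def test_em_loglik_monotone(self, rng):
        data = random_data(rng, n_genes=25, max_snps=5)
        lls = [
            fit_hierarchical(data, backend="em", max_iter=k, tol=0.0).loglik
            for k in (1, 2, 4, 8, 16)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_zero_membership_annotation_rejected(self, rng):
        bfs = [rng.normal(0, 1, 3)]
        with pytest.raises(ValueError, match="zero SNP membership"):
            HierData(["g"], bfs, [np.zeros((3, 1))])


class TestProfileCi:
    def test_against_curvature_standard_error(self, rng):
        """On a well-behaved dataset the profile interval approximates the
        Wald interval from the observed information."""
        from eqtnprior.simulate import SimulationConfig, simulate_hier_dataset

        cfg = SimulationConfig(
            seed=42, n_genes=400, n_individuals=100, snps_per_region=25,
            flank=6000, gene_length=2000,
            annotation_coverage={"a": 0.2}, true_lambdas={"a": 1.0}, true_pi0=0.3,
        )
        data, _ = simulate_hier_dataset(cfg)
        fit = fit_hierarchical(data)
        lo, hi = profile_ci(fit, data, "a")
        lam_hat = fit.params.lambdas[0]
        pi0 = fit.params.pi0
        phi = np.log(pi0 / (1 - pi0))
        h = 1e-4

        def ll(lam):
            # re-optimize phi at each lambda (profile curvature)
            res = optimize.minimize_scalar(
                lambda p: -_loglik_parts(np.array([lam]), p, data)[0],
                bounds=(phi - 3, phi + 3), method="bounded",
            )
            return -res.fun

        curv = (ll(lam_hat + h) - 2 * ll(lam_hat) + ll(lam_hat - h)) / h**2
        se = 1.0 / np.sqrt(-curv)
        assert lo == pytest.approx(lam_hat - 1.96 * se, abs=0.25 * se)
        assert hi == pytest.approx(lam_hat + 1.96 * se, abs=0.25 * se)

    def test_no_signal_annotation_unbounded_below(self, rng):
        # annotation members carry no BF signal in any gene
        bfs, ds = [], []
        for _ in range(20):
            m = 5
            bf = np.zeros(m)
            bf[0] = 2.0  # signal on a non-member SNP
            d = np.zeros((m, 1))
            d[-1, 0] = 1.0
            bfs.append(bf)
            ds.append(d)
        data = HierData([f"g{k}" for k in range(20)], bfs, ds)
        fit = fit_hierarchical(data, backend="direct")
        lo, hi = profile_ci(fit, data, 0)
        assert np.isneginf(lo)
        assert np.isfinite(hi)

    def test_level_zero_collapses_to_mle(self, rng):
        data = random_data(rng, n_genes=15)
        fit = fit_hierarchical(data, backend="direct")
        lo, hi = profile_ci(fit, data, 0, level=0.0)
        assert lo == hi == fit.params.lambdas[0]


class TestEnrichmentAndAic:
    def test_fold_is_exp_lambda(self):
        fit = HierFit(HierParams([0.0, np.log(4.0)], 0.5, ["x", "y"]), -10.0, 3)
        rep = enrichment_report(fit)
        assert rep.loc[rep.annotation == "x", "fold"].iloc[0] == pytest.approx(1.0)
        assert rep.loc[rep.annotation == "y", "fold"].iloc[0] == pytest.approx(4.0)

    def test_unbounded_ci_maps_to_zero_fold(self):
        fit = HierFit(HierParams([0.2], 0.5, ["x"]), -10.0, 2, ci={"x": (-np.inf, 0.5)})
        rep = enrichment_report(fit)
        assert rep["fold_lo"].iloc[0] == 0.0
        assert rep["fold_hi"].iloc[0] == pytest.approx(np.exp(0.5))

    def test_aic_formula(self):
        fit = HierFit(HierParams([0.0, 0.0], 0.5, ["a", "b"]), -100.0, 3)
        assert model_aic(fit) == pytest.approx(206.0)

    def test_compare_models_flags_delta(self):
        f1 = HierFit(HierParams([0.0], 0.5, ["a"]), -100.0, 2)
        f2 = HierFit(HierParams([0.0], 0.5, ["a"]), -110.0, 2)
        df = compare_models({"good": f1, "bad": f2})
        assert df.iloc[0]["model"] == "good"
        assert bool(df.iloc[1]["significant"])


class TestPosteriorMass:
    def test_all_mass_inside(self):
        posts = [np.array([0.5, 0.0]), np.array([0.3, 0.0])]
        cols = [np.array([1.0, 0.0]), np.array([1.0, 1.0])]
        assert annotation_posterior_mass(posts, cols) == pytest.approx(1.0)

    def test_empty_annotation_zero(self):
        posts = [np.array([0.5, 0.2])]
        cols = [np.zeros(2)]
        assert annotation_posterior_mass(posts, cols) == 0.0

    def test_nan_when_no_mass(self):
        assert np.isnan(annotation_posterior_mass([np.zeros(3)], [np.ones(3)]))


class TestCrossValidate:
    def test_folds_partition_and_determinism(self, rng):
        data = random_data(rng, n_genes=30)
        a = cross_validate(data, {"m": ["annot0"]}, k=5, seed=3, backend="direct")
        b = cross_validate(data, {"m": ["annot0"]}, k=5, seed=3, backend="direct")
        pd.testing.assert_frame_equal(a, b)
        assert sorted(a["fold"].unique()) == list(range(5))

    def test_too_many_folds_errors(self, rng):
        with pytest.raises(ValueError):
            cross_validate(random_data(rng, n_genes=4), {"m": ["annot0"]}, k=10)


class TestPriorRanking:
    def test_all_tied_midrank_percentile(self):
        params = HierParams([0.0], 0.3, ["a"])
        ranking = prior_only_ranking(params, np.zeros((7, 1)))
        np.testing.assert_allclose(ranking["percentile"], (7 + 1) / (2 * 7))

    def test_sole_member_of_positive_annotation_ranks_first(self):
        params = HierParams([2.0], 0.3, ["a"])
        delta = np.zeros((10, 1))
        delta[4, 0] = 1.0
        ranking = prior_only_ranking(params, delta)
        assert ranking["rank"].iloc[4] == 1.0


def scan_stub(gene_id, best, second):
    table = pd.DataFrame(
        {"snp_id": ["s1", "s2"], "beta": [0, 0], "se": [1, 1], "t": [0, 0],
         "p": [best, second], "constant": [False, False]}
    )
    return ScanResult(gene_id=gene_id, table=table)


class TestHoldoutSelection:
    def test_three_order_gap_qualifies(self):
        assert select_holdout_genes([scan_stub("g", 1e-10, 1e-7)], n=10) == ["g"]

    def test_one_order_gap_excluded(self):
        assert select_holdout_genes([scan_stub("g", 1e-9, 1e-8)], n=10) == []

    def test_fewer_qualifying_than_requested_warns(self):
        scans = [scan_stub(f"g{i}", 1e-12, 1e-9) for i in range(3)]
        with pytest.warns(UserWarning, match="3 genes qualify"):
            out = select_holdout_genes(scans, n=100)
        assert sorted(out) == ["g0", "g1", "g2"]

    def test_sampling_is_seeded(self):
        scans = [scan_stub(f"g{i}", 1e-12, 1e-9) for i in range(50)]
        a = select_holdout_genes(scans, n=10, seed=4)
        b = select_holdout_genes(scans, n=10, seed=4)
        assert a == b
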