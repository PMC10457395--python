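import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mixproject.datatypes import AbundanceMatrix, ExpressionMatrix, GenePanel, MixtureSet
from mixproject.deconvolve import (
    AbundanceConfig,
    contamination_score,
    estimate_abundances,
    init_abundances_linear,
    initial_projections,
    per_type_log_likelihood,
    predict_cell_type,
)


@pytest.fixture(scope="module")
def projections(toy_bundle, toy_problem):
    return initial_projections(toy_bundle, toy_problem["mixtures"])


def mixture_from_profiles(profiles, sample_ids, gene_ids):
    expr = ExpressionMatrix(np.asarray(profiles).T, gene_ids, sample_ids, "scaled")
    return MixtureSet(expr=expr, panel=GenePanel.symmetric(gene_ids))


class TestInitialProjections:
    def test_tensor_shape_and_stage(self, projections, toy_problem, toy_bundle):
        n = toy_problem["mixtures"].n_samples
        k = len(toy_bundle.labels)
        g = len(toy_bundle.panel.full_genes)
        assert projections.x.shape == (n, k, g)
        assert projections.var.shape == (n, k)
        assert projections.stage == "initial"

    def test_projection_is_decode_encode_composition(self, toy_bundle, toy_problem):
        atlas = toy_problem["train_atlas"]
        cell = atlas.expr.values.T[:1]
        mix = mixture_from_profiles(cell, ["m0"], atlas.expr.gene_ids)
        proj = initial_projections(toy_bundle, mix)
        for j, lab in enumerate(toy_bundle.labels):
            mu, var = toy_bundle[lab].reconstruct(cell)
            np.testing.assert_array_equal(proj.x[0, j], mu[0])
            np.testing.assert_array_equal(proj.var[0, j], var[0])

    def test_gene_order_mismatch_rejected(self, toy_bundle, toy_problem):
        m = toy_problem["mixtures"]
        reordered = ExpressionMatrix(
            m.expr.values[::-1], m.expr.gene_ids[::-1], m.expr.obs_ids, m.expr.layer_tag
        )
        bad = MixtureSet(
            expr=reordered, panel=GenePanel.symmetric(reordered.gene_ids)
        )
        with pytest.raises(ValueError, match="gene order"):
            initial_projections(toy_bundle, bad)

    def test_projection_tracks_own_contributor_better(self, projections, toy_problem):
        from scipy.stats import spearmanr

        atlas, truth = toy_problem["atlas"], toy_problem["truth"]
        cell_idx = {c: i for i, c in enumerate(atlas.expr.obs_ids)}
        x_atlas = atlas.expr.values.T
        labels = projections.labels
        wins = 0
        n = projections.x.shape[0]
        for i, mid in enumerate(projections.sample_ids):
            ok = True
            for j, lab in enumerate(labels):
                own = x_atlas[cell_idx[truth.contributors.loc[mid, lab]]]
                other_lab = labels[1 - j]
                other = x_atlas[cell_idx[truth.contributors.loc[mid, other_lab]]]
                if (
                    spearmanr(projections.x[i, j], own).statistic
                    <= spearmanr(projections.x[i, j], other).statistic
                ):
                    ok = False
            wins += ok
        assert wins / n >= 0.8


class TestLinearInitialization:
    def test_exact_recovery_of_constructed_mixture(self, projections, toy_problem):
        # build a sample exactly as 0.3 x_1 + 0.7 x_2 from the projections
        x = projections.x[0]  # K x G
        b = 0.3 * x[0] + 0.7 * x[1]
        mix = mixture_from_profiles([b], ["m0"], list(projections.gene_ids))
        proj_one = type(projections)(
            x=x[None], var=projections.var[:1], labels=list(projections.labels),
            sample_ids=["m0"], gene_ids=list(projections.gene_ids), stage="initial",
        )
        ab = init_abundances_linear(mix, proj_one)
        np.testing.assert_allclose(ab.alpha[0], [0.3, 0.7], atol=1e-6)

    def test_identical_projections_share_weight_uniformly(self, projections):
        x = projections.x[0].copy()
        x[1] = x[0]
        b = x[0].copy()
        mix = mixture_from_profiles([b], ["m0"], list(projections.gene_ids))
        proj_one = type(projections)(
            x=x[None], var=projections.var[:1], labels=list(projections.labels),
            sample_ids=["m0"], gene_ids=list(projections.gene_ids), stage="initial",
        )
        ab = init_abundances_linear(mix, proj_one)
        np.testing.assert_allclose(ab.alpha[0], [0.5, 0.5])

    def test_zero_projections_fall_back_to_uniform(self, projections):
        x = np.zeros_like(projections.x[:1])
        proj_one = type(projections)(
            x=x, var=projections.var[:1], labels=list(projections.labels),
            sample_ids=["m0"], gene_ids=list(projections.gene_ids), stage="initial",
        )
        b = np.ones(x.shape[2])
        mix = mixture_from_profiles([b], ["m0"], list(projections.gene_ids))
        with pytest.warns(UserWarning, match="uniform"):
            ab = init_abundances_linear(mix, proj_one)
        np.testing.assert_allclose(ab.alpha[0], 0.5)

    def test_rows_on_simplex_for_real_mixtures(self, projections, toy_problem):
        ab = init_abundances_linear(toy_problem["mixtures"], projections)
        assert (ab.alpha >= 0).all()
        np.testing.assert_allclose(ab.alpha.sum(axis=1), 1.0, atol=1e-9)


class TestEstimateAbundances:
    def test_recovers_noiseless_mixture_fractions(self, projections):
        # mixtures constructed exactly from the projections: the likelihood
        # optimum is the generating alpha, reachable from a perturbed start
        rng = np.random.default_rng(0)
        n_use = 12
        alphas = rng.dirichlet([1.0, 1.0], size=n_use)
        profiles = np.einsum("nk,nkg->ng", alphas, projections.x[:n_use])
        ids = [f"m{i}" for i in range(n_use)]
        mix = mixture_from_profiles(profiles, ids, list(projections.gene_ids))
        proj = type(projections)(
            x=projections.x[:n_use], var=projections.var[:n_use],
            labels=list(projections.labels), sample_ids=ids,
            gene_ids=list(projections.gene_ids), stage="initial",
        )
        start = AbundanceMatrix(
            np.full((n_use, 2), 0.5), list(projections.labels), ids
        )
        ab, noise = estimate_abundances(
            mix, proj, start, AbundanceConfig(seed=0, max_steps=4000, patience=400)
        )
        rmse = np.sqrt(np.mean((ab.alpha - alphas) ** 2))
        assert rmse <= 0.05

    def test_symmetric_mixture_recovers_equal_fractions(self, projections):
        b = 0.5 * projections.x[0, 0] + 0.5 * projections.x[0, 1]
        ids = ["m0"]
        mix = mixture_from_profiles([b], ids, list(projections.gene_ids))
        proj = type(projections)(
            x=projections.x[:1], var=projections.var[:1],
            labels=list(projections.labels), sample_ids=ids,
            gene_ids=list(projections.gene_ids), stage="initial",
        )
        start = AbundanceMatrix(np.array([[0.8, 0.2]]), list(projections.labels), ids)
        ab, _ = estimate_abundances(
            mix, proj, start, AbundanceConfig(seed=0, max_steps=4000, patience=400)
        )
        np.testing.assert_allclose(ab.alpha[0], 0.5, atol=0.05)

    def test_objective_decreases_over_optimization(self, projections, toy_problem):
        ab0 = init_abundances_linear(toy_problem["mixtures"], projections)
        ab, _ = estimate_abundances(
            toy_problem["mixtures"], projections, ab0, AbundanceConfig(seed=0)
        )
        hist = np.array(ab.opt_history)
        smooth = np.convolve(hist, np.ones(10) / 10, mode="valid")
        assert smooth[-1] <= smooth[0]

    def test_simplex_preserved_and_noise_variance_positive(
        self, projections, toy_problem
    ):
        ab0 = init_abundances_linear(toy_problem["mixtures"], projections)
        ab, noise = estimate_abundances(
            toy_problem["mixtures"], projections, ab0, AbundanceConfig(seed=0)
        )
        np.testing.assert_allclose(ab.alpha.sum(axis=1), 1.0, atol=1e-6)
        var = noise.predict(projections.var, ab.alpha)
        assert (var > 0).all()


class TestLikelihoodDiagnostics:
    def test_out_of_atlas_mixtures_score_lower(self, toy_bundle, toy_problem):
        # held-out cells of modeled types vs profiles far from both manifolds
        held = toy_problem["heldout_atlas"].expr.values.T
        rng = np.random.default_rng(1)
        alien = held + rng.uniform(-3, 3, size=held.shape)
        ids_in = [f"in{i}" for i in range(held.shape[0])]
        ids_out = [f"out{i}" for i in range(alien.shape[0])]
        genes = toy_problem["atlas"].expr.gene_ids
        ll_in = per_type_log_likelihood(
            toy_bundle, mixture_from_profiles(held, ids_in, genes)
        ).max(axis=1)
        ll_out = per_type_log_likelihood(
            toy_bundle, mixture_from_profiles(alien, ids_out, genes)
        ).max(axis=1)
        assert mannwhitneyu(ll_out, ll_in, alternative="less").pvalue < 1e-4

    def test_confidence_fills_when_bundle_given(self, toy_bundle, toy_problem, projections):
        ab0 = init_abundances_linear(toy_problem["mixtures"], projections)
        ab, _ = estimate_abundances(
            toy_problem["mixtures"], projections, ab0,
            AbundanceConfig(seed=0, max_steps=50), bundle=toy_bundle,
        )
        assert ab.per_sample_loglik.shape == ab.alpha.shape
        assert ab.confidence.shape == (ab.alpha.shape[0],)
        assert ((ab.confidence >= 0) & (ab.confidence <= 1)).all()


class TestCellTypeCalls:
    def test_argmax_label(self):
        ab = AbundanceMatrix(
            np.array([[0.1, 0.7, 0.2]]), ["a", "b", "c"], ["s0"]
        )
        out = predict_cell_type(ab)
        assert out.loc["s0", "cell_type"] == "b"
        assert not out.loc["s0", "tie"]

    def test_exact_tie_takes_first_label_and_flags(self):
        ab = AbundanceMatrix(np.array([[0.5, 0.5]]), ["a", "b"], ["s0"])
        out = predict_cell_type(ab)
        assert out.loc["s0", "cell_type"] == "a"
        assert bool(out.loc["s0", "tie"])

    def test_single_contributor_mixtures_called_correctly(
        self, toy_bundle, toy_problem
    ):
        # single cells presented as mixtures: dominant type must be their own
        atlas = toy_problem["heldout_atlas"]
        x = atlas.expr.values.T
        ids = [f"c{i}" for i in range(x.shape[0])]
        mix = mixture_from_profiles(x, ids, atlas.expr.gene_ids)
        proj = initial_projections(toy_bundle, mix)
        ab = init_abundances_linear(mix, proj)
        calls = predict_cell_type(ab)["cell_type"].to_numpy()
        assert (calls == np.array(atlas.cell_types)).mean() >= 0.95


class TestContamination:
    @pytest.fixture
    def ab(self):
        return AbundanceMatrix(
            np.array([[0.6, 0.25, 0.15], [0.9, 0.05, 0.05]]),
            ["neuron", "glia", "endo"],
            ["s0", "s1"],
        )

    def test_no_contaminants_scores_zero(self, ab):
        assert (contamination_score(ab, []) == 0).all()

    def test_all_types_score_one(self, ab):
        np.testing.assert_allclose(
            contamination_score(ab, ["neuron", "glia", "endo"]), 1.0
        )

    def test_additive_over_contaminant_types(self, ab):
        np.testing.assert_allclose(
            contamination_score(ab, ["glia", "endo"]).to_numpy(), [0.40, 0.10]
        )

    def test_unknown_type_rejected(self, ab):
        with pytest.raises(KeyError):
            contamination_score(ab, ["astro"])
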