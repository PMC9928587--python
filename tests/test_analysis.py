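"""Differential GP test and decoder diagnostics."""

import numpy as np
import pytest

from progmap.analysis import (
    bayes_factor,
    directed_scores,
    gene_importance,
    gp_direction,
    normalized_entropy,
    pairwise_h0_prob,
    rank_gps,
)
from progmap.model import PosteriorParams

rng = np.random.default_rng(17)


class TestPairwiseH0:
    def test_equal_posteriors_give_half(self):
        assert pairwise_h0_prob(1.3, 0.2, 1.3, 0.2) == pytest.approx(0.5)

    def test_large_separation_saturates(self):
        assert pairwise_h0_prob(100.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)
        assert pairwise_h0_prob(-100.0, 1.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_mean_difference_and_strictly_inside_unit_interval(self):
        mus = np.linspace(-5, 5, 21)
        p = pairwise_h0_prob(mus, 1.0, 0.0, 1.0)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_matches_monte_carlo_pair_sampling(self):
        gen = np.random.default_rng(0)
        for _ in range(5):
            mu1, mu2 = gen.normal(0, 2, 2)
            s1, s2 = gen.uniform(0.2, 3, 2)
            n = 1_000_000
            z1 = mu1 + np.sqrt(s1) * gen.standard_normal(n)
            z2 = mu2 + np.sqrt(s2) * gen.standard_normal(n)
            p_hat = (z1 > z2).mean()
            se = max(np.sqrt(p_hat * (1 - p_hat) / n), 1e-6)
            assert abs(pairwise_h0_prob(mu1, s1, mu2, s2) - p_hat) < 4 * se

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_h0_prob(0.0, 0.0, 0.0, 1.0)


def _fake_model(n_programs=3, n_genes=5, seed=0):
    """Minimal model stub: only W and program names are used by the tests."""
    from progmap.gene_sets import GPMask
    from progmap.model import GPModel, ModelSpec

    gen = np.random.default_rng(seed)
    names = [f"p{j}" for j in range(n_programs)]
    B = np.ones((n_genes, n_programs), np.int8)
    mask = GPMask(names, [f"g{i}" for i in range(n_genes)], B,
                  (1 - B).astype(np.int8), ["hard"] * n_programs)
    spec = ModelSpec(n_genes=n_genes, n_programs=n_programs, n_conditions=1,
                     hidden_sizes=(4,))
    model = GPModel.initialise(spec, mask, ["c0"], seed=seed)
    model.params["dec.W"] = gen.normal(size=(n_genes, n_programs))
    return model


class TestBayesFactor:
    def test_same_group_gives_log_k_zero(self):
        model = _fake_model()
        post = PosteriorParams(mu=rng.normal(size=(40, 3)), sigma2=np.full((40, 3), 0.5))
        res = bayes_factor(model, post, post, "p0")
        assert res.p_h0 == pytest.approx(0.5)
        assert res.log_bayes_factor == pytest.approx(0.0)

    def test_swapping_groups_flips_sign_exactly(self):
        model = _fake_model()
        pa = PosteriorParams(mu=rng.normal(1, 1, (30, 3)), sigma2=np.full((30, 3), 0.4))
        pb = PosteriorParams(mu=rng.normal(0, 1, (25, 3)), sigma2=np.full((25, 3), 0.7))
        ab = bayes_factor(model, pa, pb, "p1")
        ba = bayes_factor(model, pb, pa, "p1")
        assert ab.log_bayes_factor == pytest.approx(-ba.log_bayes_factor, abs=1e-12)

    def test_sampling_agrees_with_closed_form(self):
        model = _fake_model()
        pa = PosteriorParams(mu=rng.normal(0.8, 1, (50, 3)), sigma2=np.full((50, 3), 0.6))
        pb = PosteriorParams(mu=rng.normal(0, 1, (50, 3)), sigma2=np.full((50, 3), 0.6))
        closed = bayes_factor(model, pa, pb, "p2", method="closed_form", n_pairs=2500)
        sampled = bayes_factor(model, pa, pb, "p2", method="sampling",
                               n_pairs=2500, mc_draws=500, seed=4)
        n_draws = 2500 * 500
        se = np.sqrt(closed.p_h0 * (1 - closed.p_h0) / n_draws)
        # pairs are shared, only the within-pair MC adds noise
        assert abs(sampled.p_h0 - closed.p_h0) < 10 * se + 1e-3

    def test_clipping_keeps_log_k_finite(self):
        model = _fake_model()
        pa = PosteriorParams(mu=np.full((10, 3), 100.0), sigma2=np.full((10, 3), 0.1))
        pb = PosteriorParams(mu=np.zeros((10, 3)), sigma2=np.full((10, 3), 0.1))
        res = bayes_factor(model, pa, pb, "p0", clip=1e-7)
        assert np.isfinite(res.log_bayes_factor)
        assert res.log_bayes_factor == pytest.approx(np.log((1 - 1e-7) / 1e-7))

    def test_unknown_program_rejected(self):
        model = _fake_model()
        post = PosteriorParams(mu=np.zeros((5, 3)), sigma2=np.ones((5, 3)))
        with pytest.raises(KeyError):
            bayes_factor(model, post, post, "nope")


class TestRankGps:
    def _posteriors(self, shift_program=1, shift=2.0, n=400):
        gen = np.random.default_rng(8)
        mu_a = gen.normal(0, 1, (n, 3))
        mu_b = gen.normal(0, 1, (n, 3))
        mu_a[:, shift_program] += shift
        s = np.full((n, 3), 0.01)
        return PosteriorParams(mu_a, s), PosteriorParams(mu_b, s)

    def test_planted_two_sd_shift_ranks_first_and_enriched(self):
        """A +2 SD latent shift gives log K above the 2.3 enrichment bar."""
        model = _fake_model()
        pa, pb = self._posteriors()
        res = rank_gps(model, pa, pb, n_pairs=200_000, seed=0)
        assert res[0].program_name == "p1"
        assert res[0].log_bayes_factor >= 2.3
        assert res[0].enriched

    def test_infinite_threshold_enriches_nothing(self):
        model = _fake_model()
        pa, pb = self._posteriors()
        res = rank_gps(model, pa, pb, threshold=np.inf, seed=0)
        assert not any(r.enriched for r in res)

    def test_sorted_by_absolute_log_k(self):
        model = _fake_model()
        pa, pb = self._posteriors()
        res = rank_gps(model, pa, pb, seed=0)
        mags = [abs(r.log_bayes_factor) for r in res]
        assert mags == sorted(mags, reverse=True)

    def test_deactivated_programs_excluded(self):
        model = _fake_model()
        model.params["dec.W"][:, 2] = 0.0
        pa, pb = self._posteriors()
        res = rank_gps(model, pa, pb, seed=0)
        assert all(r.program_name != "p2" for r in res)

    def test_null_comparisons_rarely_enriched(self):
        """Random splits with no effect stay below the enrichment bar."""
        model = _fake_model()
        gen = np.random.default_rng(21)
        mu = gen.normal(0, 1, (600, 3))
        s = np.full((600, 3), 0.3)
        n_enriched = n_total = 0
        for trial in range(20):
            sel = gen.random(600) < 0.5
            pa = PosteriorParams(mu[sel], s[sel])
            pb = PosteriorParams(mu[~sel], s[~sel])
            res = rank_gps(model, pa, pb, n_pairs=5000, seed=trial)
            n_enriched += sum(r.enriched for r in res)
            n_total += len(res)
        assert n_enriched / n_total <= 0.05


class TestDecoderDiagnostics:
    def test_gene_importance_ranking_and_ties(self):
        model = _fake_model(n_programs=1, n_genes=3)
        model.params["dec.W"][:, 0] = [0.5, -2.0, 0.0]
        ranked = gene_importance(model, "p0")
        assert ranked == [("g1", 2.0), ("g0", 0.5), ("g2", 0.0)]
        model.params["dec.W"][:, 0] = [1.0, 1.0, 1.0]
        assert [g for g, _ in gene_importance(model, "p0")] == ["g0", "g1", "g2"]

    def test_deactivated_column_all_zero_scores(self):
        model = _fake_model(n_programs=1, n_genes=4)
        model.params["dec.W"][:] = 0.0
        assert all(s == 0.0 for _, s in gene_importance(model, "p0"))

    @pytest.mark.parametrize(
        "col, method, expected",
        [
            ([1, 2, -0.5], "sum", 1),
            ([1, -2, -0.5], "counts", -1),
            ([1, -1], "sum", 1),  # exact-zero aggregate -> +1 by convention
            ([-1, -2], "sum", -1),
        ],
    )
    def test_direction_heuristics(self, col, method, expected):
        assert gp_direction(col, method=method) == expected

    def test_directed_scores_columnwise_flip(self):
        Z = rng.normal(size=(6, 3))
        d = np.array([1, -1, 1])
        out = directed_scores(Z, d)
        np.testing.assert_array_equal(out, Z * d)
        np.testing.assert_array_equal(directed_scores(out, d), Z)
        np.testing.assert_array_equal(directed_scores(Z, np.ones(3)), Z)


class TestNormalizedEntropy:
    def test_uniform_is_one_onehot_is_zero(self):
        assert normalized_entropy(np.full(7, 0.3)) == pytest.approx(1.0)
        assert normalized_entropy([0, 0, 5.0]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # H(0.5, 0.25, 0.25) = 1.5 bits; / log2(3) = 0.946...
        expected = 1.5 / np.log2(3)
        assert normalized_entropy([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy([1.0])
        with pytest.raises(ValueError):
            normalized_entropy([0.0, 0.0])
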