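"""Variable-rate Brownian Bayesian placement: likelihood, prior, MCMC,
weights and convergence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from phyplace.bayes import (
    BranchLengthPrior,
    McmcSettings,
    burnin_protocol,
    classify_placement,
    ess,
    geweke,
    mcmc_place,
    ml_branch_lengths,
    random_topology,
    reml_char_weights,
    reml_loglik,
    summarize_placements,
    unroot,
    zscore_transform,
    _child_side_map,
)
from phyplace.synthetic import SyntheticConfig, make_fixture, simulate_tree
from phyplace.treespace import Backbone, Placement, apply_placement, parse_newick

from conftest import covariance_from_tree, dense_bm_loglik


class TestRemlLoglik:
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_dense_mvn_reml(self, trial):
        rng = np.random.default_rng(40 + trial)
        from conftest import random_binary_tree

        tree = random_binary_tree(rng, 5)
        X = pd.DataFrame(rng.normal(size=(5, 3)), index=tree.tip_labels)
        V, labels = covariance_from_tree(tree)
        x = X.loc[labels].to_numpy(float)
        dense = sum(dense_bm_loglik(V, x[:, c], reml=True) for c in range(3))
        assert reml_loglik(tree, X) == pytest.approx(dense, abs=1e-8)

    def test_weights_scale_per_character_contributions(self, rng):
        from conftest import random_binary_tree

        tree = random_binary_tree(rng, 6)
        X = pd.DataFrame(rng.normal(size=(6, 4)), index=tree.tip_labels)
        per_char = reml_loglik(tree, X, per_character=True)
        w = np.array([0.0, 0.5, 1.0, 2.0])
        assert reml_loglik(tree, X, weights=w) == pytest.approx(float(w @ per_char))


class TestMlBranchLengths:
    def test_scale_equivariance(self, rng):
        tree = simulate_tree(SyntheticConfig(n_tips=6, seed=3))
        tree.set_lengths_from_ages()
        X = pd.DataFrame(rng.normal(size=(6, 20)), index=tree.tip_labels)
        fit1, _ = ml_branch_lengths(tree, X, max_sweeps=6)
        fit2, _ = ml_branch_lengths(tree, 2.0 * X, max_sweeps=6)
        l1 = np.array(sorted(n.length for n in fit1.postorder() if n is not fit1.root))
        l2 = np.array(sorted(n.length for n in fit2.postorder() if n is not fit2.root))
        keep = l1 > 1e-4
        assert np.allclose(l2[keep] / l1[keep], 4.0, rtol=0.05)

    def test_three_tip_closed_form(self):
        # unrooted 3-tip star: pairwise contrast variances are sums of
        # pendant lengths, giving closed-form estimates
        tree = parse_newick("(A:1,B:1,C:1);")
        rng = np.random.default_rng(5)
        true = {"A": 0.5, "B": 1.5, "C": 2.5}
        n_chars = 4000
        x = {}
        root_vals = np.zeros(n_chars)
        for lbl, v in true.items():
            x[lbl] = root_vals + rng.normal(0, math.sqrt(v), n_chars)
        X = pd.DataFrame(x).T
        X.index = ["A", "B", "C"]
        fit, _ = ml_branch_lengths(tree, X, max_sweeps=8)
        got = {n.label: n.length for n in fit.postorder() if n.is_tip}
        # closed form from sample contrast variances
        sAB = np.var(X.loc["A"] - X.loc["B"], ddof=0)
        sAC = np.var(X.loc["A"] - X.loc["C"], ddof=0)
        sBC = np.var(X.loc["B"] - X.loc["C"], ddof=0)
        expect = {
            "A": (sAB + sAC - sBC) / 2,
            "B": (sAB + sBC - sAC) / 2,
            "C": (sAC + sBC - sAB) / 2,
        }
        for lbl in "ABC":
            assert got[lbl] == pytest.approx(expect[lbl], abs=2e-3 + 0.02 * expect[lbl])

    def test_parameter_recovery_within_rmse(self):
        tree = simulate_tree(SyntheticConfig(n_tips=8, seed=21))
        tree.set_lengths_from_ages()
        rng = np.random.default_rng(2)
        # simulate BM at unit rate on the tree's own lengths
        n_chars = 500
        vals = {id(tree.root): np.zeros(n_chars)}
        for node in reversed(list(tree.postorder())):
            if node is tree.root:
                continue
            vals[id(node)] = vals[id(node.parent)] + rng.normal(
                0, math.sqrt(node.length), n_chars)
        X = pd.DataFrame({t.label: vals[id(t)] for t in tree.tips()}).T
        fit, _ = ml_branch_lengths(tree, X, max_sweeps=6)
        # compare unrooted branch lengths via bipartition keys
        ref = unroot(tree)
        ref_len = {ref.edge_key(n): n.length for n in ref.postorder() if n is not ref.root}
        fit_len = {fit.edge_key(n): n.length for n in fit.postorder() if n is not fit.root}
        truth = np.array([ref_len[k] for k in ref_len])
        est = np.array([fit_len[k] for k in ref_len])
        rmse = math.sqrt(np.mean((est - truth) ** 2)) / np.mean(truth)
        assert rmse < 0.30

    def test_all_zero_weights_rejected(self, rng):
        tree = simulate_tree(SyntheticConfig(n_tips=5, seed=3))
        tree.set_lengths_from_ages()
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=tree.tip_labels)
        with pytest.raises(ValueError):
            ml_branch_lengths(tree, X, weights=np.zeros(2))


class TestCharacterWeights:
    def test_strong_signal_character_wins_almost_always(self):
        fx = make_fixture(SyntheticConfig(n_tips=10, seed=31, n_continuous=6,
                                          branch_rate_sd=0.0,
                                          intraspecific_sd_frac=0.0,
                                          missing_fraction=0.0))
        X = fx.matrix.cont_mean.drop(index=list(fx.query_labels))
        cw = reml_char_weights(fx.tree, X, n_random=25, seed=7, max_sweeps=2)
        assert cw.table["fraction"].mean() > 0.8

    def test_noise_character_is_not_preferred(self):
        fx = make_fixture(SyntheticConfig(n_tips=10, seed=31, n_continuous=6,
                                          branch_rate_sd=0.0,
                                          intraspecific_sd_frac=0.0,
                                          missing_fraction=0.0))
        X = fx.matrix.cont_mean.drop(index=list(fx.query_labels))
        rng = np.random.default_rng(0)
        X["noise"] = rng.normal(size=len(X))  # no tree structure at all
        cw = reml_char_weights(fx.tree, X, n_random=25, seed=7, max_sweeps=2)
        real = cw.table["fraction"].drop("noise")
        assert cw.table.loc["noise", "fraction"] < real.mean()

    def test_binary_mode_applies_cutoff(self):
        tbl = pd.DataFrame({"fraction": [0.99, 0.96, 0.94, 0.5]},
                           index=list("abcd"))
        from phyplace.bayes import CharacterWeights

        weights = (tbl["fraction"] >= 0.95).astype(float)
        cw = CharacterWeights(table=tbl.assign(weight=weights), mode="binary",
                              n_random=100)
        assert cw.weights.tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_weights_serialize_roundtrip(self, tmp_path):
        from phyplace.bayes import CharacterWeights

        tbl = pd.DataFrame({"fraction": [0.7, 1.0], "weight": [0.7, 1.0]},
                           index=["c1", "c2"])
        cw = CharacterWeights(table=tbl, mode="fractional", n_random=50)
        path = tmp_path / "w.json"
        cw.to_json(path)
        back = CharacterWeights.from_json(path)
        assert back.mode == "fractional"
        assert np.allclose(back.weights, cw.weights)

    def test_random_topologies_are_valid_and_varied(self, rng):
        labels = [f"t{i}" for i in range(8)]
        seen = set()
        for _ in range(10):
            topo = random_topology(labels, rng)
            assert sorted(topo.tip_labels) == sorted(labels)
            seen.add(frozenset(topo.bipartitions()))
        assert len(seen) > 3


class TestZscore:
    def test_unit_variance_and_roundtrip(self, rng):
        X = pd.DataFrame(rng.normal(2.0, 3.0, size=(10, 4)))
        Z, loc, scale = zscore_transform(X)
        assert np.allclose(Z.std(ddof=1), 1.0)
        assert np.allclose(Z * scale + loc, X, atol=1e-10)
        Z2, _, _ = zscore_transform(Z)
        assert np.allclose(Z2.to_numpy(), Z.to_numpy(), atol=1e-12)


class TestPrior:
    def test_log_density_matches_manual_formula(self):
        prior = BranchLengthPrior(ml_tree_length=2.0)
        lengths = np.array([0.5, 0.25, 0.25, 1.0])
        T, m = 2.0, 4
        rate = 0.5
        expected = (math.log(rate) - rate * T          # Gamma(1, rate) at T
                    + math.lgamma(m) - (m - 1) * math.log(T))
        assert prior.log_density(lengths) == pytest.approx(expected, abs=1e-12)

    def test_literal_beta_switch(self):
        assert BranchLengthPrior(2.0).rate == pytest.approx(0.5)
        assert BranchLengthPrior(2.0, literal_beta=True).rate == pytest.approx(2.0)

    def test_negative_lengths_impossible(self):
        prior = BranchLengthPrior(1.0)
        assert prior.log_density(np.array([0.5, -0.1])) == -np.inf


def quick_fixture(seed=2, n_tips=8, n_chars=5):
    return make_fixture(SyntheticConfig(n_tips=n_tips, seed=seed,
                                        n_continuous=n_chars,
                                        missing_fraction=0.0))


class TestMcmc:
    def test_chain_is_reproducible_from_seed(self):
        fx = quick_fixture()
        X = fx.matrix.cont_mean
        prior = BranchLengthPrior(1.0)
        settings = McmcSettings(generations=2000, sample_interval=50)
        r1 = mcmc_place(fx.tree, X, None, prior, [fx.query_labels[0]],
                        settings=settings, seed=9)
        r2 = mcmc_place(fx.tree, X, None, prior, [fx.query_labels[0]],
                        settings=settings, seed=9)
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_zero_weights_make_posterior_proportional_to_prior(self):
        fx = quick_fixture(seed=5)
        X = fx.matrix.cont_mean
        prior = BranchLengthPrior(1.5)
        run = mcmc_place(fx.tree, X, np.zeros(X.shape[1]), prior,
                         [fx.query_labels[0]],
                         settings=McmcSettings(generations=30000, sample_interval=25),
                         seed=3)
        assert (run.samples["loglik"] == 0.0).all()
        T = run.samples["tree_length"].to_numpy()[200:]
        assert abs(T.mean() - 1.5) < 0.35  # Exp(1/1.5) mean within MC error

    def test_posterior_concentrates_on_true_edge_with_strong_signal(self):
        fx = make_fixture(SyntheticConfig(n_tips=15, seed=9, n_continuous=60,
                                          branch_rate_sd=0.0,
                                          intraspecific_sd_frac=0.0,
                                          missing_fraction=0.0,
                                          query_age_frac=0.9,
                                          query_host_edge="pendant"))
        X, _, _ = zscore_transform(fx.matrix.cont_mean,
                                   reference_rows=fx.matrix.extant)
        q = fx.query_labels[0]
        fit, _ = ml_branch_lengths(fx.tree, X.drop(index=q), max_sweeps=3)
        prior = BranchLengthPrior(max(fit.total_length(), 1e-6))
        run = mcmc_place(fx.tree, X, None, prior, [q],
                         settings=McmcSettings(generations=60000), seed=4)
        post = summarize_placements(run)
        top = post.iloc[0]
        assert top["edges"][0] == fx.truth.edges[0]
        assert top["posterior"] > 0.8

    def test_two_seeds_agree_on_edge_posteriors(self):
        fx = make_fixture(SyntheticConfig(n_tips=10, seed=13, n_continuous=40,
                                          branch_rate_sd=0.0,
                                          intraspecific_sd_frac=0.0,
                                          missing_fraction=0.0,
                                          query_age_frac=0.9,
                                          query_host_edge="pendant"))
        X, _, _ = zscore_transform(fx.matrix.cont_mean,
                                   reference_rows=fx.matrix.extant)
        q = fx.query_labels[0]
        prior = BranchLengthPrior(2.0)
        posts = []
        for seed in (1, 2):
            run = mcmc_place(fx.tree, X, None, prior, [q],
                             settings=McmcSettings(generations=60000), seed=seed)
            post = summarize_placements(run)
            posts.append({tuple(sorted(map(tuple, map(sorted, p["edges"])))): p["posterior"]
                          for _, p in post.iterrows()})
        keys = set(posts[0]) | set(posts[1])
        tv = 0.5 * sum(abs(posts[0].get(k, 0) - posts[1].get(k, 0)) for k in keys)
        assert tv < 0.1

    def test_two_query_chain_visits_and_classifies_all_modes(self):
        fx = make_fixture(SyntheticConfig(n_tips=8, seed=3, n_continuous=4,
                                          n_queries=2, missing_fraction=0.0))
        X = fx.matrix.cont_mean
        prior = BranchLengthPrior(1.0)
        run = mcmc_place(fx.tree, X, np.zeros(X.shape[1]), prior,
                         list(fx.query_labels),
                         settings=McmcSettings(generations=30000, sample_interval=10),
                         seed=8)
        modes = set(run.samples["mode"])
        assert {"cherry", "sequential", "pair"} <= modes
        post = summarize_placements(run)
        assert post["posterior"].sum() == pytest.approx(1.0, abs=1e-9)


class TestClassification:
    def test_each_mode_roundtrips_through_classification(self, rng):
        from conftest import random_binary_tree

        tree = random_binary_tree(rng, 8)
        bb_edges = tree.edges(unrooted=True)
        child_side = _child_side_map(tree)
        bb = Backbone(tree, bb_edges[0][0], "")
        e1, e2 = bb_edges[2][0], bb_edges[5][0]
        cases = [
            Placement("cherry", (e1,), ("q1", "q2")),
            Placement("sequential", (e1,), ("q1", "q2"), order="q1"),
            Placement("sequential", (e1,), ("q1", "q2"), order="q2"),
            Placement("pair", (e1, e2), ("q1", "q2")),
        ]
        for placement in cases:
            placed = apply_placement(bb, placement, pendant_length=0.1)
            got = classify_placement(placed, ("q1", "q2"), child_side)
            assert got.mode == placement.mode
            assert set(got.edges) == set(placement.edges)
            if placement.mode == "sequential":
                assert got.order == placement.order

    def test_single_query_classification(self, rng):
        from conftest import random_binary_tree

        tree = random_binary_tree(rng, 7)
        edges = tree.edges(unrooted=True)
        bb = Backbone(tree, edges[0][0], "")
        child_side = _child_side_map(tree)
        target = edges[3][0]
        placed = apply_placement(bb, Placement("single", (target,), ("q",)),
                                 pendant_length=0.2)
        got = classify_placement(placed, ("q",), child_side)
        assert got.edges[0] == target


class TestDiagnostics:
    def test_iid_normal_geweke_calibration_and_ess(self):
        rng = np.random.default_rng(77)
        inside = 0
        trials = 400
        for _ in range(trials):
            z = geweke(rng.normal(size=500))
            inside += abs(z) < 1.96
        # ~95% coverage, binomial sd ~ 1%
        assert 0.91 <= inside / trials <= 0.985
        series = rng.normal(size=4000)
        assert ess(series) > 0.6 * len(series)

    def test_trending_series_flagged(self):
        rng = np.random.default_rng(3)
        series = np.linspace(0, 5, 1000) + rng.normal(0, 0.1, 1000)
        assert abs(geweke(series)) > 5

    def test_ar1_ess_closed_form(self):
        rng = np.random.default_rng(11)
        phi, n = 0.9, 200_000
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert ess(x) == pytest.approx(expected, rel=0.2)

    def test_constant_series_gives_nan_not_error(self):
        assert math.isnan(geweke(np.ones(500)))
        assert math.isnan(ess(np.ones(500)))

    def test_burnin_protocol_paths(self):
        rng = np.random.default_rng(5)
        settings = McmcSettings(generations=100, sample_interval=1)

        def fake_run(series):
            samples = pd.DataFrame({
                "generation": np.arange(len(series)),
                "loglik": series,
                "log_prior": 0.0, "tree_length": 1.0,
                "mode": "single", "edges": [()] * len(series), "order": None,
            })
            from phyplace.bayes import McmcRun

            return McmcRun(samples=samples, settings=settings, seed=0,
                           n_queries=1, acceptance={})

        white = fake_run(rng.normal(size=2000))
        rep = burnin_protocol(white, min_ess=100)
        assert rep.converged and rep.burnin_frac == pytest.approx(0.1)

        transient = np.concatenate([np.linspace(-60, 0, 500) + rng.normal(0, 0.5, 500),
                                    rng.normal(size=1500)])
        rep2 = burnin_protocol(fake_run(transient), min_ess=100)
        assert rep2.converged and rep2.burnin_frac > 0.1 + 1e-9

        walk = np.cumsum(rng.normal(size=2000))
        rep3 = burnin_protocol(fake_run(walk), min_ess=100)
        assert rep3.rerun_flag and not rep3.converged
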