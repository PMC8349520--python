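"""Parsimony kernels against exhaustive oracles; weighting; bootstrap."""

import numpy as np
import pandas as pd
import pytest

from phyplace.characters import CharacterMatrix
from phyplace.parsimony import (
    CostScheme,
    ScoredData,
    bootstrap_support,
    character_lengths,
    extended_k,
    placement_search,
    tree_score,
)
from phyplace.synthetic import SyntheticConfig, make_fixture
from phyplace.treespace import Backbone, parse_newick, prune_query

from conftest import brute_force_interval, brute_force_unordered, random_binary_tree


def matrix_from_cells(species, disc_cells=None, intervals=None, ordered=False):
    """Assemble a one-character matrix from explicit cells."""
    species = list(species)
    if disc_cells is not None:
        disc = pd.DataFrame({"d": [None if c is None else frozenset(c)
                                   for c in disc_cells]}, index=species, dtype=object)
        empty = pd.DataFrame(index=species)
        return CharacterMatrix(
            cont_mean=empty.copy(), cont_lo=empty.copy(), cont_hi=empty.copy(),
            cont_n=empty.copy(), disc=disc,
            ordered=pd.Series({"d": ordered}),
        )
    lo = pd.DataFrame({"c": [np.nan if iv is None else iv[0] for iv in intervals]},
                      index=species)
    hi = pd.DataFrame({"c": [np.nan if iv is None else iv[1] for iv in intervals]},
                      index=species)
    mean = (lo + hi) / 2
    n = pd.DataFrame({"c": [2] * len(species)}, index=species)
    return CharacterMatrix(
        cont_mean=mean, cont_lo=lo, cont_hi=hi, cont_n=n,
        disc=pd.DataFrame(index=species), ordered=pd.Series(dtype=bool),
    )


def lengths_of(tree, matrix, ci=True):
    data = ScoredData(matrix, CostScheme("equal", scaling="raw", ci=ci))
    return character_lengths(tree, data)


class TestUnorderedLength:
    def test_two_state_split_one_step(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", disc_cells=[{0}, {0}, {1}, {1}])
        assert lengths_of(tree, m)[0] == 1

    def test_polymorphic_tip_adds_no_step(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", disc_cells=[{0, 1}, {0}, {0}, {0}])
        assert lengths_of(tree, m)[0] == 0

    def test_missing_cell_is_free(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", disc_cells=[None, {0}, {1}, {1}])
        assert lengths_of(tree, m)[0] == 1

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_assignment_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_tips = int(rng.integers(4, 8))
        tree = random_binary_tree(rng, n_tips, with_lengths=False)
        cells = []
        for _ in range(n_tips):
            if rng.random() < 0.15:
                cells.append(None)
            else:
                size = 1 + (rng.random() < 0.25)
                cells.append(set(rng.choice(3, size=size, replace=False).tolist()))
        m = matrix_from_cells(tree.tip_labels, disc_cells=cells)
        got = lengths_of(tree, m)[0]
        oracle = brute_force_unordered(
            tree, {t: frozenset(c) if c else frozenset() for t, c in
                   zip(tree.tip_labels, cells)}, 3)
        assert got == oracle

    def test_polytomies_scored_exactly(self):
        tree = parse_newick("((A,B,C),(D,E),F);")
        cells = [{0}, {1}, {2}, {1}, {1}, {0}]
        m = matrix_from_cells("ABCDEF", disc_cells=cells)
        oracle = brute_force_unordered(
            tree, {t: frozenset(c) for t, c in zip("ABCDEF", cells)}, 3)
        assert lengths_of(tree, m)[0] == oracle


class TestIntervalLength:
    def test_two_cherry_gap(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", intervals=[(0, 1), (2, 3), (0, 1), (2, 3)])
        assert lengths_of(tree, m)[0] == pytest.approx(2.0)

    def test_shared_point_value_costs_nothing(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", intervals=[(1.3, 1.3)] * 4)
        assert lengths_of(tree, m)[0] == 0.0

    def test_missing_interval_contributes_zero(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", intervals=[None, (0, 0), (5, 5), (5, 5)])
        assert lengths_of(tree, m)[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_breakpoint_dp_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        n_tips = int(rng.integers(4, 9))
        tree = random_binary_tree(rng, n_tips, with_lengths=False)
        intervals = []
        for _ in range(n_tips):
            if rng.random() < 0.15:
                intervals.append(None)
            else:
                a, b = sorted(rng.uniform(0, 10, size=2))
                if rng.random() < 0.3:
                    b = a
                intervals.append((a, b))
        m = matrix_from_cells(tree.tip_labels, intervals=intervals)
        got = lengths_of(tree, m)[0]
        oracle = brute_force_interval(
            tree, dict(zip(tree.tip_labels, intervals)))
        assert got == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("trial", range(8))
    def test_integer_points_match_ordered_sankoff(self, trial):
        """Degenerate integer intervals reproduce additive (|i-j| cost)
        discrete lengths."""
        rng = np.random.default_rng(500 + trial)
        tree = random_binary_tree(rng, 6, with_lengths=False)
        states = rng.integers(0, 4, size=6)
        intervals = [(float(s), float(s)) for s in states]
        m = matrix_from_cells(tree.tip_labels, intervals=intervals)
        got = lengths_of(tree, m)[0]
        oracle = brute_force_interval(tree, dict(zip(tree.tip_labels, intervals)))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_polytomy_interval_parsimony(self):
        tree = parse_newick("(A,B,C,D,E);")
        intervals = [(0, 1), (4, 5), (2, 2), (9, 9), (2, 3)]
        m = matrix_from_cells("ABCDE", intervals=intervals)
        oracle = brute_force_interval(tree, dict(zip("ABCDE", intervals)))
        assert lengths_of(tree, m)[0] == pytest.approx(oracle, abs=1e-9)

    def test_ci_vs_means_switch(self):
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", intervals=[(0, 1), (2, 3), (0, 1), (2, 3)])
        assert lengths_of(tree, m, ci=False)[0] == pytest.approx(4.0)  # point means


class TestMinStepsAndWeights:
    def test_min_steps_interval_gap(self):
        m = matrix_from_cells("ABCD", intervals=[(0, 1), (2, 3), (0, 1), (2, 3)])
        data = ScoredData(m, CostScheme("equal", scaling="raw", ci=True))
        assert data.min_steps[0] == pytest.approx(1.0)  # max-lo 2 - min-hi 1

    def test_min_steps_constant_zero(self):
        m = matrix_from_cells("ABCD", disc_cells=[{0}] * 4)
        data = ScoredData(m, CostScheme("equal", scaling="raw", ci=True))
        assert data.min_steps[0] == 0.0

    def test_min_steps_three_fixed_states(self):
        m = matrix_from_cells("ABCD", disc_cells=[{0}, {1}, {2}, {2}])
        data = ScoredData(m, CostScheme("equal", scaling="raw", ci=True))
        assert data.min_steps[0] == 2.0

    def test_extended_k_limits(self):
        assert extended_k(75.0, 0.0, [0.0, 0.5, 0.9]) == pytest.approx([75.0] * 3)
        assert extended_k(75.0, 0.7, [0.0])[0] == pytest.approx(75.0)

    def test_extended_k_monotone_in_missing_fraction(self):
        mf = np.linspace(0.0, 0.95, 30)
        for R in (0.25, 0.5, 1.0):
            kc = extended_k(10.0, R, mf)
            assert np.all(np.diff(kc) < 0)

    def test_extended_k_validation(self):
        with pytest.raises(ValueError):
            extended_k(10.0, 1.5, [0.1])
        with pytest.raises(ValueError):
            extended_k(10.0, 0.5, [1.0])


class TestTreeScore:
    def four_tip(self):
        tree = parse_newick("((A,B),(C,D));")
        return tree, matrix_from_cells("ABCD", disc_cells=[{0}, {0}, {1}, {1}])

    def test_homoplasy_free_matrix_scores_zero_under_implied(self):
        tree, m = self.four_tip()
        assert tree_score(tree, m, CostScheme("implied", k=10.0)) == pytest.approx(0.0)

    def test_single_character_h_equals_k_scores_half(self):
        # 0,1,0,1 on ((A,C'),(B',D)) arrangement: length 2, min 1 -> h = 1
        tree = parse_newick("((A,B),(C,D));")
        m = matrix_from_cells("ABCD", disc_cells=[{0}, {1}, {0}, {1}])
        score = tree_score(tree, m, CostScheme("implied", k=1.0))
        assert score == pytest.approx(0.5)

    def test_equal_weight_sum(self):
        tree, m = self.four_tip()
        assert tree_score(tree, m, CostScheme("equal")) == pytest.approx(1.0)

    def test_implied_converges_to_equal_rank_order(self, rng):
        """As k grows, implied-weight ranking of single placements matches
        equal weights."""
        fx = make_fixture(SyntheticConfig(n_tips=8, seed=11, n_continuous=6,
                                          n_discrete=12, missing_fraction=0.0))
        bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
        t_eq = placement_search(bb, fx.matrix, fx.query_labels,
                                CostScheme("equal", scaling="zscore"))
        t_iw = placement_search(bb, fx.matrix, fx.query_labels,
                                CostScheme("implied", k=1e7, scaling="zscore"))
        assert np.array_equal(np.argsort(t_eq.scores, kind="stable"),
                              np.argsort(t_iw.scores, kind="stable"))


class TestPlacementSearch:
    def test_scores_consistent_with_tree_score(self):
        fx = make_fixture(SyntheticConfig(n_tips=8, seed=2, n_continuous=5,
                                          n_discrete=8, missing_fraction=0.0))
        bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
        scheme = CostScheme("implied", k=3.0, scaling="zscore", ci=True)
        table = placement_search(bb, fx.matrix, fx.query_labels, scheme)
        from phyplace.treespace import apply_placement

        scaled, _ = fx.matrix.scale("zscore")
        for i in (0, len(table.placements) // 2, -1):
            placed = apply_placement(bb, table.placements[i])
            assert table.scores[i] == pytest.approx(
                tree_score(placed, scaled, scheme), abs=1e-10)

    def test_clean_signal_recovers_true_edge(self):
        recovered = 0
        for seed in range(5):
            # clear-signal fixture: short pendant, non-degenerate host edge
            fx = make_fixture(SyntheticConfig(
                n_tips=15, seed=seed, n_continuous=30, n_discrete=50,
                missing_fraction=0.0, polymorphism_prob=0.0,
                intraspecific_sd_frac=0.0, branch_rate_sd=0.0,
                query_age_frac=0.9, query_host_edge="pendant"))
            bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
            table = placement_search(bb, fx.matrix, fx.query_labels,
                                     CostScheme("equal", scaling="zscore"))
            if any(p.edges[0] == bb.true_edge for p in table.best_placements):
                recovered += 1
        assert recovered >= 4

    def test_all_missing_query_refused(self):
        fx = make_fixture(SyntheticConfig(n_tips=8, seed=2, n_continuous=4,
                                          n_discrete=4))
        m = fx.matrix.copy()
        q = fx.query_labels[0]
        m.cont_mean.loc[q] = np.nan
        m.cont_lo.loc[q] = np.nan
        m.cont_hi.loc[q] = np.nan
        m.cont_n.loc[q] = 0
        m.disc.loc[q] = None
        bb = Backbone(fx.tree, fx.truth.edges[0], q)
        with pytest.raises(ValueError, match="no scored data"):
            placement_search(bb, m, [q], CostScheme("equal"))


class TestBootstrap:
    def test_single_informative_character_gives_total_support(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        bb = prune_query(tree, "E")
        species = bb.tree.tip_labels + ["q"]
        m = matrix_from_cells(species,
                              disc_cells=[{0}, {0}, {1}, {1}, {1}])
        table = bootstrap_support(bb, m, ["q"], CostScheme("equal"),
                                  n_reps=200, seed=1)
        # the character cannot separate edges within the 1-side, so mass is
        # shared among its co-optimal placements but stays off the 0-side
        total = table.table["support_pct"].sum()
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_frequencies_conserved(self):
        fx = make_fixture(SyntheticConfig(n_tips=10, seed=6, n_continuous=6,
                                          n_discrete=10))
        bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
        table = bootstrap_support(bb, fx.matrix, fx.query_labels,
                                  CostScheme("equal", scaling="zscore"),
                                  n_reps=300, seed=5)
        assert table.table["support_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        fx = make_fixture(SyntheticConfig(n_tips=10, seed=6, n_continuous=6,
                                          n_discrete=10))
        bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
        scheme = CostScheme("equal", scaling="zscore")
        t1 = bootstrap_support(bb, fx.matrix, fx.query_labels, scheme,
                               n_reps=2000, seed=1)
        t2 = bootstrap_support(bb, fx.matrix, fx.query_labels, scheme,
                               n_reps=2000, seed=2)
        merged = t1.table.merge(
            t2.table, on=["edge", "mode"], how="outer", suffixes=("_1", "_2")
        ).fillna(0.0)
        # ~4 binomial sd at p<=0.5, n=2000 is ~4.5 percentage points
        assert (merged["support_pct_1"] - merged["support_pct_2"]).abs().max() < 5.0

    def test_branch_aggregation_recountable(self):
        fx = make_fixture(SyntheticConfig(n_tips=8, seed=3, n_continuous=5,
                                          n_discrete=6))
        bb = Backbone(fx.tree, fx.truth.edges[0], fx.query_labels[0])
        table = bootstrap_support(bb, fx.matrix, fx.query_labels,
                                  CostScheme("equal", scaling="zscore"),
                                  n_reps=100, seed=9)
        agg = table.branch_support()
        assert agg["support_pct"].sum() == pytest.approx(100.0, abs=1e-9)
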