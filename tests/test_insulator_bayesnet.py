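import itertools

import numpy as np
import pandas as pd
import pytest

from tandemloop.insulator_bayesnet import (
    VARIABLES,
    bdeu_log_marginal,
    compute_promoter_factors,
    discretize_by_rank,
    family_log_marginal,
    insulator_signal_interval,
    learn_structure,
    ranks_to_samples,
)
from tandemloop.insulator_bayesnet import _all_dags
from tandemloop.synthetic_data import gen_ep_contact_table


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "promoter", "condition", "promoter_start", "promoter_end",
        "enhancer_start", "enhancer_end", "loop_count", "enhancer_strength",
        "ctcf_signal", "expression",
    ])


class TestPromoterFactors:
    def test_single_enhancer_is_identity(self):
        table = make_table([
            (0, "d0", 100, 2000, 50_000, 52_000, 7.0, 4.0, 2.5, 9.0),
        ])
        f = compute_promoter_factors(table).values
        row = f.iloc[0]
        assert row["enhancer"] == 4.0
        assert row["loop"] == 7.0
        assert row["insulator"] == 2.5
        assert row["promoter_expr"] == 9.0

    def test_weighted_mean_of_two_enhancers(self):
        table = make_table([
            (0, "d0", 100, 2000, 50_000, 52_000, 3.0, 2.0, 1.0, 5.0),
            (0, "d0", 100, 2000, 90_000, 92_000, 6.0, 1.0, 4.0, 5.0),
        ])
        f = compute_promoter_factors(table).values.iloc[0]
        assert f["enhancer"] == 3.0
        assert f["loop"] == pytest.approx((2 * 3 + 1 * 6) / 3)  # = 4
        assert f["insulator"] == pytest.approx((2 * 1 + 1 * 4) / 3)

    def test_overlapping_fragments_zero_insulator_signal(self):
        # separating interval is empty after the +-500 bp margin
        assert insulator_signal_interval((100, 2000), (2300, 4000)) is None
        table = make_table([
            (0, "d0", 100, 2000, 2300, 4000, 1.0, 1.0, 99.0, 1.0),
        ])
        f = compute_promoter_factors(table).values.iloc[0]
        assert f["insulator"] == 0.0

    def test_margin_boundary_is_inclusive(self):
        # min(t) + 500 == max(s) - 500 exactly: a single-point interval counts
        assert insulator_signal_interval((0, 1000), (2000, 3000)) == (1500, 1500)

    def test_zero_enhancer_strength_promoter_excluded(self):
        table = make_table([
            (0, "d0", 100, 2000, 50_000, 52_000, 1.0, 0.0, 1.0, 1.0),
            (1, "d0", 100, 2000, 50_000, 52_000, 1.0, 2.0, 1.0, 1.0),
        ])
        f = compute_promoter_factors(table).values
        assert set(f["promoter"]) == {1}


class TestRankDiscretization:
    def test_printed_example(self):
        # day-3 value < day-0 value < day-6 value maps to ranks (2, 1, 3)
        rows = []
        for cond, (expr, e) in zip(("d0", "d3", "d6"),
                                   [(5.0, 1.0), (2.0, 2.0), (9.0, 3.0)]):
            rows.append((0, cond, 100, 2000, 50_000, 52_000, 1.0, e, 1.0, expr))
        f = discretize_by_rank(compute_promoter_factors(make_table(rows)))
        ranks = f.ranks.set_index("condition")["promoter_expr"]
        assert ranks["d0"] == 2 and ranks["d3"] == 1 and ranks["d6"] == 3

    def test_strictly_increasing_values(self):
        rows = [(0, c, 100, 2000, 50_000, 52_000, v + 0.5, v, v + 0.1, v)
                for c, v in zip(("a", "b", "c"), (1.0, 2.0, 3.0))]
        f = discretize_by_rank(compute_promoter_factors(make_table(rows)))
        assert f.ranks.sort_values("condition")["enhancer"].tolist() == [1, 2, 3]
        assert not f.tie_broken

    def test_ties_broken_by_condition_order_and_flagged(self):
        rows = [(0, c, 100, 2000, 50_000, 52_000, 1.0, 1.0, 1.0, 7.0)
                for c in ("a", "b", "c")]
        f = discretize_by_rank(compute_promoter_factors(make_table(rows)))
        assert f.tie_broken
        assert f.ranks.sort_values("condition")["promoter_expr"].tolist() == [1, 2, 3]


class TestDirichletMarginal:
    def test_single_binary_variable_two_observations(self):
        # alpha_ijk = 1 per state: marginal = 1! 1! / 3! = 1/6
        data = np.array([[0], [1]])
        lm = bdeu_log_marginal(data, {"x": ()}, arities=[2], variables=("x",))
        assert np.exp(lm) == pytest.approx(1 / 6)

    def test_empty_dataset_scores_zero(self):
        data = np.empty((0, 2), dtype=int)
        lm = bdeu_log_marginal(data, {"a": (), "b": ("a",)}, arities=[2, 3],
                               variables=("a", "b"))
        assert lm == 0.0

    def test_matches_sequential_predictive_oracle_over_all_orderings(self):
        """Exchangeability: every row ordering gives the same sequential
        predictive probability, and it equals the closed form."""
        rng = np.random.default_rng(4)
        data = rng.integers(0, 2, size=(5, 3))
        variables = ("a", "b", "c")
        parents = {"a": (), "b": ("a",), "c": ("b",)}
        arities = np.array([2, 2, 2])
        col = {v: i for i, v in enumerate(variables)}

        def sequential(order):
            counts = {}
            logp = 0.0
            for l in order:
                row = data[l]
                for v in variables:
                    ci = col[v]
                    pcols = tuple(col[p] for p in parents[v])
                    others = [k for k in range(3)
                              if k != ci and k not in pcols]
                    a_ijk = float(np.prod(arities[others])) if others else 1.0
                    key = (ci, tuple(row[c] for c in pcols))
                    cnt = counts.setdefault(key, np.zeros(arities[ci]))
                    logp += np.log((a_ijk + cnt[row[ci]])
                                   / (a_ijk * arities[ci] + cnt.sum()))
                    cnt[row[ci]] += 1
            return logp

        values = [sequential(o) for o in itertools.permutations(range(5))]
        assert np.allclose(values, values[0])
        closed = bdeu_log_marginal(data, parents, arities=arities,
                                   variables=variables)
        assert closed == pytest.approx(values[0])

    def test_score_decomposes_over_families(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 3, size=(50, 4))
        arities = np.full(4, 3)
        base = {v: () for v in VARIABLES}
        with_edge = dict(base)
        with_edge["promoter"] = ("insulator",)
        s0 = bdeu_log_marginal(data, base, arities=arities)
        s1 = bdeu_log_marginal(data, with_edge, arities=arities)
        col = {v: i for i, v in enumerate(VARIABLES)}
        f0 = family_log_marginal(data, col["promoter"], (), arities)
        f1 = family_log_marginal(data, col["promoter"], (col["insulator"],),
                                 arities)
        assert s1 - s0 == pytest.approx(f1 - f0)

    def test_markov_equivalent_structures_score_equally(self):
        rng = np.random.default_rng(6)
        data = rng.integers(0, 3, size=(80, 2))
        arities = [3, 3]
        fwd = bdeu_log_marginal(data, {"a": (), "b": ("a",)}, arities=arities,
                                variables=("a", "b"))
        rev = bdeu_log_marginal(data, {"a": ("b",), "b": ()}, arities=arities,
                                variables=("a", "b"))
        assert fwd == pytest.approx(rev)

    def test_cyclic_structure_rejected(self):
        data = np.zeros((3, 2), dtype=int)
        with pytest.raises(ValueError):
            bdeu_log_marginal(data, {"a": ("b",), "b": ("a",)},
                              arities=[2, 2], variables=("a", "b"))


class TestStructureLearning:
    def test_dag_count_over_four_nodes(self):
        assert sum(1 for _ in _all_dags(VARIABLES)) == 543

    def test_exhaustive_refuses_many_variables(self):
        data = np.zeros((5, 7), dtype=int)
        with pytest.raises(ValueError):
            learn_structure(data, method="exhaustive",
                            variables=tuple("abcdefg"))

    def test_independent_data_yields_empty_graph(self):
        table, _ = gen_ep_contact_table(n_promoters=1200, planted_edges=[],
                                        seed=0)
        data = ranks_to_samples(discretize_by_rank(compute_promoter_factors(table)))
        model = learn_structure(data, method="exhaustive")
        assert model.edges == ()

    def test_mmhc_matches_exhaustive_on_easy_data(self):
        table, _ = gen_ep_contact_table(
            n_promoters=1200, planted_edges=[("insulator", "promoter", -1.5)],
            seed=1,
        )
        data = ranks_to_samples(discretize_by_rank(compute_promoter_factors(table)))
        exh = learn_structure(data, method="exhaustive")
        mmhc = learn_structure(data, method="mmhc")
        assert mmhc.log_score <= exh.log_score + 1e-9
        assert mmhc.log_score == pytest.approx(exh.log_score)
        assert mmhc.skeleton() == exh.skeleton()

    def test_planted_edge_in_learned_skeleton(self):
        table, _ = gen_ep_contact_table(
            n_promoters=1000, planted_edges=[("insulator", "promoter", -1.5)],
            seed=2,
        )
        data = ranks_to_samples(discretize_by_rank(compute_promoter_factors(table)))
        model = learn_structure(data, method="exhaustive")
        assert frozenset(("insulator", "promoter")) in model.skeleton()

    def test_model_export_round_trip(self):
        table, _ = gen_ep_contact_table(n_promoters=300, seed=3)
        data = ranks_to_samples(discretize_by_rank(compute_promoter_factors(table)))
        model = learn_structure(data, method="mmhc")
        d = model.to_json_dict()
        assert d["variables"] == list(VARIABLES)
        assert np.isfinite(d["log_score"])
        g = model.graph()
        assert set(g.nodes) == set(VARIABLES)
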