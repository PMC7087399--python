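"""Promoter-level insulator/enhancer/loop factors and Bayesian-network
structure learning over them.

Each instance is a promoter observed under several conditions. From its
enhancer contacts the pipeline derives, per condition,

    E_i = sum_j e_j                    (total enhancer strength),
    L_i = sum_j e_j l_ij / E_i         (enhancer-weighted mean loop strength),
    U_i = sum_j e_j u_ij / E_i         (enhancer-weighted mean insulator strength),

plus the promoter expression f_i; the CTCF (insulator) signal of a loop counts
only when the separating interval ``[min(t_i,t_j)+a, max(s_i,s_j)-a]`` is
nonempty (``a`` = 500 bp keeps promoter/enhancer-internal CTCF out). Values
are discretized by ranking each variable across conditions within a promoter,
and the network over {enhancer, insulator, loop, promoter} is scored by the
exact Dirichlet marginal likelihood with a uniform unit mass over joint
states (``alpha_x = 1``), searched either exhaustively (all DAGs; 543 for four
nodes) or by max-min hill-climbing (MMHC).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "VARIABLES",
    "PromoterFactors",
    "BayesNetModel",
    "insulator_signal_interval",
    "compute_promoter_factors",
    "discretize_by_rank",
    "ranks_to_samples",
    "bdeu_log_marginal",
    "family_log_marginal",
    "learn_structure",
]

VARIABLES = ("enhancer", "insulator", "loop", "promoter")


# ---------------------------------------------------------------------------
# promoter factors
# ---------------------------------------------------------------------------

def insulator_signal_interval(promoter: tuple[int, int], enhancer: tuple[int, int],
                              margin: int = 500) -> tuple[int, int] | None:
    """Interval between two fragments, shrunk by ``margin`` bp on both sides.

    Returns None when ``min(t_i, t_j) + margin > max(s_i, s_j) - margin``
    (overlapping or nearly adjacent fragments), in which case the insulator
    signal of the pair is zero.
    """
    s_i, t_i = promoter
    s_j, t_j = enhancer
    if not (s_i < t_i and s_j < t_j):
        raise ValueError("fragment coordinates must satisfy start < end")
    lo = min(t_i, t_j) + margin
    hi = max(s_i, s_j) - margin
    return (lo, hi) if lo <= hi else None


@dataclass
class PromoterFactors:
    """Per-promoter, per-condition derived factors and their rank categories."""

    values: pd.DataFrame  # promoter, condition, enhancer, loop, insulator, promoter_expr
    ranks: pd.DataFrame | None = None
    tie_broken: bool = False


def compute_promoter_factors(table: pd.DataFrame, margin: int = 500) -> PromoterFactors:
    """Aggregate an enhancer-promoter contact table into promoter factors.

    ``table`` columns: promoter, condition, promoter_start, promoter_end,
    enhancer_start, enhancer_end, loop_count, enhancer_strength, ctcf_signal,
    expression. ``ctcf_signal`` is the CTCF ChIP total measured between the
    fragments; it is zeroed whenever the margin-shrunk separating interval is
    empty. Promoters with zero total enhancer strength are excluded (logged).
    """
    required = {"promoter", "condition", "promoter_start", "promoter_end",
                "enhancer_start", "enhancer_end", "loop_count",
                "enhancer_strength", "ctcf_signal", "expression"}
    if not required.issubset(table.columns):
        raise ValueError(f"contact table needs columns {sorted(required)}")
    rows = []
    for (promoter, condition), group in table.groupby(["promoter", "condition"]):
        e = group["enhancer_strength"].to_numpy(float)
        l = group["loop_count"].to_numpy(float)
        u = np.empty(len(group))
        for pos, row in enumerate(group.itertuples(index=False)):
            interval = insulator_signal_interval(
                (int(row.promoter_start), int(row.promoter_end)),
                (int(row.enhancer_start), int(row.enhancer_end)),
                margin,
            )
            u[pos] = float(row.ctcf_signal) if interval is not None else 0.0
        E = float(e.sum())
        if E == 0:
            logger.warning("promoter %s (%s): zero enhancer strength; excluded",
                           promoter, condition)
            continue
        expr = group["expression"].iloc[0]
        rows.append({
            "promoter": promoter, "condition": condition,
            "enhancer": E,
            "loop": float(np.sum(e * l) / E),
            "insulator": float(np.sum(e * u) / E),
            "promoter_expr": float(expr),
        })
    return PromoterFactors(values=pd.DataFrame(rows))


def discretize_by_rank(factors: PromoterFactors) -> PromoterFactors:
    """Replace condition values by their rank (1 = smallest) per promoter.

    Ranks are computed per promoter and variable across conditions; ties are
    broken deterministically by condition order (first condition gets the
    lower rank) and flagged on the result.
    """
    df = factors.values
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("rank discretization needs at least two conditions")
    columns = ["enhancer", "loop", "insulator", "promoter_expr"]
    tie_seen = False
    out_rows = []
    for promoter, group in df.groupby("promoter"):
        group = group.set_index("condition").loc[
            [c for c in conditions if c in group["condition"].values]
        ]
        ranked = {"promoter": promoter}
        for col in columns:
            vals = group[col].to_numpy()
            if len(np.unique(vals)) < len(vals):
                tie_seen = True
            order = np.argsort(vals, kind="stable")  # stable = condition order ties
            ranks = np.empty(len(vals), dtype=int)
            ranks[order] = np.arange(1, len(vals) + 1)
            ranked[col] = ranks
        for pos, condition in enumerate(group.index):
            out_rows.append({
                "promoter": promoter, "condition": condition,
                "enhancer": ranked["enhancer"][pos],
                "loop": ranked["loop"][pos],
                "insulator": ranked["insulator"][pos],
                "promoter_expr": ranked["promoter_expr"][pos],
            })
    ranks = pd.DataFrame(out_rows)
    return PromoterFactors(values=df, ranks=ranks, tie_broken=tie_seen)


def ranks_to_samples(factors: PromoterFactors) -> np.ndarray:
    """Rank table -> integer sample matrix (rows = promoter-condition pairs).

    Columns follow :data:`VARIABLES`; categories are 0-based.
    """
    if factors.ranks is None:
        raise ValueError("factors not discretized; call discretize_by_rank first")
    cols = {"enhancer": "enhancer", "insulator": "insulator",
            "loop": "loop", "promoter": "promoter_expr"}
    data = np.column_stack([
        factors.ranks[cols[v]].to_numpy(int) - 1 for v in VARIABLES
    ])
    return data


# ---------------------------------------------------------------------------
# Dirichlet marginal likelihood
# ---------------------------------------------------------------------------

def _validate_structure(parents: dict, variables) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(p, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structure contains a directed cycle")


def family_log_marginal(data: np.ndarray, child: int, parent_cols: tuple[int, ...],
                        arities, alpha: float = 1.0) -> float:
    """Log marginal likelihood contribution of one (child, parents) family.

    Hyperparameters follow the uniform joint-state construction: a mass
    ``alpha`` on every joint state of all variables gives
    ``alpha_ijk = alpha * prod_{v not in {child} ∪ parents} r_v``.
    """
    arities = np.asarray(arities, dtype=int)
    n_vars = arities.size
    r_child = int(arities[child])
    others = [v for v in range(n_vars) if v != child and v not in parent_cols]
    alpha_ijk = alpha * float(np.prod(arities[others])) if others else alpha
    q = int(np.prod(arities[list(parent_cols)])) if parent_cols else 1
    # index parent configurations
    if parent_cols:
        idx = np.zeros(data.shape[0], dtype=np.int64)
        for col in parent_cols:
            idx = idx * arities[col] + data[:, col]
    else:
        idx = np.zeros(data.shape[0], dtype=np.int64)
    joint = idx * r_child + data[:, child]
    counts = np.bincount(joint, minlength=q * r_child).reshape(q, r_child)
    n_ij = counts.sum(axis=1)
    alpha_ij = alpha_ijk * r_child
    ll = float(np.sum(gammaln(alpha_ij) - gammaln(alpha_ij + n_ij)))
    ll += float(np.sum(gammaln(alpha_ijk + counts) - gammaln(alpha_ijk)))
    return ll


def bdeu_log_marginal(data: np.ndarray, parents: dict, arities=None,
                      alpha: float = 1.0,
                      variables=VARIABLES) -> float:
    """Exact log marginal likelihood of a discrete network structure.

    ``data`` is (samples, variables) with 0-based categories; ``parents`` maps
    each variable name to a tuple of parent names. The score decomposes over
    families and, with the uniform joint-state prior, is identical on
    Markov-equivalent structures.
    """
    data = np.asarray(data, dtype=int)
    variables = tuple(variables)
    _validate_structure(parents, variables)
    name_to_col = {v: i for i, v in enumerate(variables)}
    if arities is None:
        arities = data.max(axis=0) + 1 if data.size else np.ones(len(variables), int)
    arities = np.asarray(arities, dtype=int)
    total = 0.0
    for child in variables:
        parent_cols = tuple(sorted(name_to_col[p] for p in parents.get(child, ())))
        total += family_log_marginal(data, name_to_col[child], parent_cols,
                                     arities, alpha)
    return total


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

@dataclass
class BayesNetModel:
    """Learned network: edges, decomposed score, and the search method used."""

    variables: tuple
    edges: tuple  # tuple of (parent, child)
    log_score: float
    alpha: float
    method: str

    def parent_map(self) -> dict:
        parents: dict = {v: () for v in self.variables}
        for p, c in self.edges:
            parents[c] = tuple(sorted(set(parents[c]) | {p}))
        return parents

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def skeleton(self) -> set:
        return {frozenset(e) for e in self.edges}

    def to_json_dict(self) -> dict:
        return {"variables": list(self.variables),
                "edges": [list(e) for e in self.edges],
                "log_score": self.log_score,
                "alpha": self.alpha,
                "method": self.method}


def _all_dags(variables):
    """Every DAG over the variables, as edge tuples (543 for four nodes)."""
    pairs = list(itertools.combinations(variables, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        g = nx.DiGraph()
        g.add_nodes_from(variables)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield tuple(edges)


class _ScoreCache:
    """Cache of per-family scores over an all-configurations count index."""

    def __init__(self, data, variables, arities, alpha):
        self.data = np.asarray(data, dtype=int)
        self.variables = tuple(variables)
        self.name_to_col = {v: i for i, v in enumerate(self.variables)}
        self.arities = np.asarray(arities, dtype=int)
        self.alpha = alpha
        self._cache: dict = {}

    def family(self, child: str, parents: tuple) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            cols = tuple(sorted(self.name_to_col[p] for p in parents))
            self._cache[key] = family_log_marginal(
                self.data, self.name_to_col[child], cols, self.arities, self.alpha
            )
        return self._cache[key]

    def total(self, parent_map: dict) -> float:
        return sum(self.family(v, tuple(parent_map.get(v, ()))) for v in self.variables)


def _mmpc_candidates(cache: _ScoreCache) -> dict:
    """Score-based max-min parents-children: candidate neighbour sets.

    The association of Y with X given a conditioning set S is the family-score
    gain of adding Y to parents S of X; Y joins the candidate set of X when its
    minimum gain over subsets of the current set stays positive, and is pruned
    again in a backward pass.
    """
    variables = cache.variables

    def assoc(x, y, cond):
        return cache.family(x, tuple(cond) + (y,)) - cache.family(x, tuple(cond))

    def min_assoc(x, y, cpc):
        subsets = itertools.chain.from_iterable(
            itertools.combinations(cpc, r) for r in range(len(cpc) + 1)
        )
        return min(assoc(x, y, s) for s in subsets)

    candidates: dict = {}
    for x in variables:
        cpc: list = []
        remaining = [v for v in variables if v != x]
        while True:
            gains = [(min_assoc(x, y, cpc), y) for y in remaining]
            if not gains:
                break
            best_gain, best_y = max(gains)
            if best_gain <= 0:
                break
            cpc.append(best_y)
            remaining.remove(best_y)
        # backward pruning
        for y in list(cpc):
            others = [z for z in cpc if z != y]
            if min_assoc(x, y, others) <= 0:
                cpc.remove(y)
        candidates[x] = set(cpc)
    # symmetrize: keep Y in CPC(X) only if X in CPC(Y)
    sym = {x: {y for y in candidates[x] if x in candidates[y]}
           for x in variables}
    return sym


def _hill_climb(cache: _ScoreCache, allowed_pairs) -> tuple[tuple, float]:
    variables = cache.variables
    parent_map: dict = {v: () for v in variables}
    edges: set = set()

    def score():
        return cache.total(parent_map)

    def acyclic(candidate_edges):
        g = nx.DiGraph()
        g.add_nodes_from(variables)
        g.add_edges_from(candidate_edges)
        return nx.is_directed_acyclic_graph(g)

    current = score()
    improved = True
    while improved:
        improved = False
        best_move, best_score = None, current
        # additions
        for u, v in itertools.permutations(variables, 2):
            if (u, v) in edges or frozenset((u, v)) not in allowed_pairs:
                continue
            if not acyclic(edges | {(u, v)}):
                continue
            trial = dict(parent_map)
            trial[v] = tuple(sorted(set(parent_map[v]) | {u}))
            s = cache.total(trial)
            if s > best_score + 1e-12:
                best_move, best_score = ("add", (u, v)), s
        # deletions
        for u, v in list(edges):
            trial = dict(parent_map)
            trial[v] = tuple(p for p in parent_map[v] if p != u)
            s = cache.total(trial)
            if s > best_score + 1e-12:
                best_move, best_score = ("delete", (u, v)), s
        # reversals
        for u, v in list(edges):
            if not acyclic((edges - {(u, v)}) | {(v, u)}):
                continue
            trial = dict(parent_map)
            trial[v] = tuple(p for p in parent_map[v] if p != u)
            trial[u] = tuple(sorted(set(parent_map[u]) | {v}))
            s = cache.total(trial)
            if s > best_score + 1e-12:
                best_move, best_score = ("reverse", (u, v)), s
        if best_move is not None:
            op, (u, v) = best_move
            if op == "add":
                edges.add((u, v))
            elif op == "delete":
                edges.discard((u, v))
            else:
                edges.discard((u, v))
                edges.add((v, u))
            parent_map = {w: () for w in variables}
            for a, b in edges:
                parent_map[b] = tuple(sorted(set(parent_map[b]) | {a}))
            assert best_score >= current  # hill climbing never decreases
            current = best_score
            improved = True
    return tuple(sorted(edges)), current


def learn_structure(data: np.ndarray, method: str = "exhaustive",
                    alpha: float = 1.0, variables=VARIABLES,
                    arities=None) -> BayesNetModel:
    """Learn the best-scoring DAG over discrete variables.

    ``exhaustive`` enumerates every DAG (refused above 6 variables);
    ``mmhc`` restricts candidate edges by score-based max-min parents-children
    and hill-climbs with add/delete/reverse moves.
    """
    data = np.asarray(data, dtype=int)
    variables = tuple(variables)
    if arities is None:
        arities = data.max(axis=0) + 1
    cache = _ScoreCache(data, variables, arities, alpha)
    if method == "exhaustive":
        if len(variables) > 6:
            raise ValueError("exhaustive search refused for more than 6 variables")
        best_edges, best_score = None, -np.inf
        for edges in _all_dags(variables):
            parent_map = {v: () for v in variables}
            for u, v in edges:
                parent_map[v] = tuple(sorted(set(parent_map[v]) | {u}))
            s = cache.total(parent_map)
            if s > best_score:
                best_edges, best_score = tuple(sorted(edges)), s
        return BayesNetModel(variables=variables, edges=best_edges,
                             log_score=best_score, alpha=alpha, method="exhaustive")
    if method == "mmhc":
        allowed = set()
        candidates = _mmpc_candidates(cache)
        for x, neigh in candidates.items():
            for y in neigh:
                allowed.add(frozenset((x, y)))
        edges, score = _hill_climb(cache, allowed)
        return BayesNetModel(variables=variables, edges=edges,
                             log_score=score, alpha=alpha, method="mmhc")
    raise ValueError(f"unknown method {method!r}")
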