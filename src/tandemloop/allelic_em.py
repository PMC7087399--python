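"""EM decomposition of single-cell expressed gene sets into allelic subsets.

A cell's observed expressed set R (over a universe of G clustered genes) is
modelled as the union of two sets S and T drawn independently — one per
chromosomal allele — from a common distribution over subsets of size at most
H. The per-allele distribution P is the maximum-likelihood solution of the
observed union counts N_R, obtained by EM over the hidden per-allele counts
N_{S,T}:

    M-step:  P(S) ∝ sum_T N_{S,T}
    E-step:  N_{S,T} ∝ P(S) P(T), constrained so that the N_{S,T} with
             S ∪ T = R total N_R for every observed R,

initialized with N_{S,T} = N_R / |pairs(R)| (the uniform split).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "AlleleDistribution",
    "ExpressionDataset",
    "enumerate_allele_sets",
    "union_pairs",
    "union_distribution",
    "em_decompose",
    "EMResult",
]


def enumerate_allele_sets(n_genes: int, max_per_allele: int) -> list[frozenset]:
    """All subsets of {0..G-1} with at most H elements, smallest first.

    Deterministic order: by size, then lexicographically by sorted members.
    The count is sum_{k=0}^{H} C(G, k).
    """
    if not 0 <= max_per_allele <= n_genes:
        raise ValueError(
            f"need 0 <= H <= G, got H={max_per_allele}, G={n_genes}"
        )
    sets: list[frozenset] = []
    for k in range(max_per_allele + 1):
        for combo in itertools.combinations(range(n_genes), k):
            sets.append(frozenset(combo))
    assert len(sets) == sum(comb(n_genes, k) for k in range(max_per_allele + 1))
    return sets


@dataclass
class AlleleDistribution:
    """Probability mass over per-allele gene subsets of size <= H."""

    n_genes: int
    max_per_allele: int
    probabilities: dict  # frozenset -> float

    def __post_init__(self) -> None:
        support = set(enumerate_allele_sets(self.n_genes, self.max_per_allele))
        probs = {frozenset(k): float(v) for k, v in self.probabilities.items()}
        if not set(probs) <= support:
            raise ValueError("distribution supported outside the allowed subsets")
        if any(v < 0 for v in probs.values()):
            raise ValueError("probabilities must be nonnegative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        # fill missing subsets with zero mass
        self.probabilities = {s: probs.get(s, 0.0) for s in support}

    def as_array(self) -> tuple[list[frozenset], np.ndarray]:
        sets = enumerate_allele_sets(self.n_genes, self.max_per_allele)
        return sets, np.array([self.probabilities[s] for s in sets])

    def total_variation(self, other: "AlleleDistribution") -> float:
        keys = set(self.probabilities) | set(other.probabilities)
        return 0.5 * sum(
            abs(self.probabilities.get(k, 0.0) - other.probabilities.get(k, 0.0))
            for k in keys
        )


@dataclass
class ExpressionDataset:
    """Observed per-cell expressed gene sets, aggregated into union counts."""

    n_genes: int
    union_counts: dict  # frozenset -> int

    @classmethod
    def from_cells(cls, n_genes: int, cells) -> "ExpressionDataset":
        counts: dict = {}
        for cell in cells:
            key = frozenset(int(g) for g in cell)
            if key and max(key) >= n_genes:
                raise ValueError("cell expresses a gene outside the universe")
            counts[key] = counts.get(key, 0) + 1
        return cls(n_genes=n_genes, union_counts=counts)

    @classmethod
    def from_binary_matrix(cls, matrix) -> "ExpressionDataset":
        """Cells x genes 0/1 (or count) matrix; positive entries = expressed."""
        m = np.asarray(matrix)
        cells = [np.flatnonzero(row > 0) for row in m]
        return cls.from_cells(m.shape[1], cells)

    @property
    def n_cells(self) -> int:
        return sum(self.union_counts.values())


def union_pairs(observed: frozenset, max_per_allele: int) -> list[tuple[frozenset, frozenset]]:
    """All ordered pairs (S, T) with |S|, |T| <= H and S ∪ T = observed."""
    members = sorted(observed)
    pairs = []
    for r in range(len(members) + 1):
        for s_combo in itertools.combinations(members, r):
            S = frozenset(s_combo)
            if len(S) > max_per_allele:
                continue
            remainder = observed - S
            # T must contain remainder; the rest of T is any subset of S
            for t_extra in range(len(s_combo) + 1):
                for extra in itertools.combinations(s_combo, t_extra):
                    T = remainder | frozenset(extra)
                    if len(T) <= max_per_allele:
                        pairs.append((S, T))
    return pairs


def union_distribution(dist: AlleleDistribution) -> dict:
    """Exact distribution of S ∪ T for independent S, T ~ dist (convolution)."""
    sets, probs = dist.as_array()
    out: dict = {}
    for S, ps in zip(sets, probs):
        if ps == 0:
            continue
        for T, pt in zip(sets, probs):
            if pt == 0:
                continue
            key = S | T
            out[key] = out.get(key, 0.0) + ps * pt
    return out


@dataclass
class EMResult:
    distribution: AlleleDistribution
    log_likelihood: float
    trace: np.ndarray
    n_iter: int
    converged: bool


def em_decompose(dataset: ExpressionDataset, max_per_allele: int,
                 tol: float = 1e-9, max_iter: int = 10_000) -> EMResult:
    """Maximum-likelihood per-allele distribution from union counts via EM.

    Raises if any observed set exceeds 2H genes (impossible under the model).
    The observed-data log-likelihood is tracked every iteration; EM guarantees
    it never decreases.
    """
    G = dataset.n_genes
    H = max_per_allele
    observed = {frozenset(k): int(v) for k, v in dataset.union_counts.items()}
    for R in observed:
        if len(R) > 2 * H:
            raise ValueError(
                f"observed set {sorted(R)} has {len(R)} genes > 2H = {2 * H}; "
                "the two-allele model cannot produce it"
            )
    pair_lists = {R: union_pairs(R, H) for R in observed}

    all_sets = enumerate_allele_sets(G, H)
    set_index = {s: i for i, s in enumerate(all_sets)}
    n_sets = len(all_sets)

    # hidden counts stored per observed union set, aligned with pair_lists[R]
    hidden = {R: np.full(len(pair_lists[R]), observed[R] / len(pair_lists[R]))
              for R in observed}
    pair_idx = {R: np.array([(set_index[S], set_index[T])
                             for S, T in pair_lists[R]], dtype=np.int64).reshape(-1, 2)
                for R in observed}

    def m_step() -> np.ndarray:
        counts = np.zeros(n_sets)
        for R, h in hidden.items():
            np.add.at(counts, pair_idx[R][:, 0], h)
        total = counts.sum()
        return counts / total if total > 0 else np.full(n_sets, 1.0 / n_sets)

    def log_likelihood(p: np.ndarray) -> float:
        ll = 0.0
        for R, n_r in observed.items():
            idx = pair_idx[R]
            mass = float(np.sum(p[idx[:, 0]] * p[idx[:, 1]]))
            ll += n_r * (np.log(mass) if mass > 0 else -np.inf)
        return ll

    p = m_step()
    trace = [log_likelihood(p)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: N_{S,T} ∝ P(S) P(T) within each observed union set
        for R, n_r in observed.items():
            idx = pair_idx[R]
            mass = p[idx[:, 0]] * p[idx[:, 1]]
            total = mass.sum()
            if total > 0:
                hidden[R] = n_r * mass / total
            else:
                hidden[R] = np.full(len(mass), n_r / len(mass))
        p_new = m_step()
        trace.append(log_likelihood(p_new))
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < tol:
            converged = True
            break

    dist = AlleleDistribution(
        n_genes=G, max_per_allele=H,
        probabilities={s: float(p[i]) for s, i in set_index.items()},
    )
    return EMResult(distribution=dist, log_likelihood=trace[-1],
                    trace=np.asarray(trace), n_iter=n_iter, converged=converged)
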