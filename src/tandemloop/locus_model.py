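"""Coarse-grained representation of a chromatin locus.

A locus is modelled as a 1D lattice of fixed-width genomic bins ("monomers").
Oriented CTCF-binding sites (CBS) inside a bin turn into per-bin, per-direction
cohesin stalling probabilities; NIPBL-like coverage turns into a cohesin loading
distribution. These quantities drive the lattice loop-extrusion simulation in
:mod:`tandemloop.extrusion_1d`.

Orientation convention
----------------------
A *forward* CBS stalls a cohesin head translocating toward decreasing bin index,
and a *reverse* CBS stalls a head translocating toward increasing bin index.
With this convention a forward ... reverse pair is convergent and anchors a
chromatin loop between the two sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "StallParams",
    "LocusModel",
    "bin_interval",
    "stall_probability",
    "array_permeability",
    "loading_distribution",
    "assemble_locus",
    "read_cbs_bed",
    "read_bedgraph",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class StallParams:
    """Parameters of the logistic map from ChIP fold enrichment to stalling.

    An enrichment ``x > 0`` stalls an opposing cohesin head with probability
    ``1 / (1 + exp(-x/zeta - mu))``; a bin with no CBS (``x = 0``) never stalls.
    """

    zeta: float = 40.0
    mu: float = 4.0

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")


def bin_interval(
    chrom: str, start: int, end: int, bin_bp: int
) -> tuple[int, pd.DataFrame]:
    """Tile a 0-based half-open genomic interval with fixed-width bins.

    Returns the bin count ``ceil((end - start) / bin_bp)`` and a table with
    columns ``chrom, start, end, bin``. The final bin may be shorter than
    ``bin_bp``; it is kept.
    """
    if end <= start:
        raise ValueError(f"end must exceed start, got [{start}, {end})")
    if bin_bp <= 0:
        raise ValueError(f"bin_bp must be positive, got {bin_bp}")
    n_bins = math.ceil((end - start) / bin_bp)
    starts = start + bin_bp * np.arange(n_bins, dtype=np.int64)
    ends = np.minimum(starts + bin_bp, end)
    table = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "bin": np.arange(n_bins)}
    )
    return n_bins, table


def stall_probability(
    x: float | np.ndarray, params: StallParams | None = None
) -> float | np.ndarray:
    """Cohesin stalling probability of a CBS with ChIP fold enrichment ``x``.

    Zero exactly at ``x = 0`` (no site), logistic ``1/(1+exp(-x/zeta-mu))``
    for ``x > 0``. Accepts scalars or arrays.
    """
    params = params or StallParams()
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("enrichment must be nonnegative")
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-arr / params.zeta - params.mu))
    prob = np.where(arr == 0, 0.0, prob)
    if np.isscalar(x) or arr.ndim == 0:
        return float(prob)
    return prob


def array_permeability(pass_probs) -> float:
    """Overall permeability of an oriented CBS array to cohesin sliding.

    ``pass_probs`` lists per-site pass probabilities in distal-to-proximal
    order. A blocked head retries every step, so the mean number of attempts
    to clear the whole array satisfies the recursion
    ``x_n = p_n * x_{n-1} + (1 - p_n) * (1 + x_n)`` with ``x_0 = 1``, whose
    closed form is ``x_n = sum(1/p_i) - n + 1``; the permeability is ``1/x_n``.
    """
    p = np.asarray(list(pass_probs), dtype=float)
    if p.size == 0:
        return 1.0
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("pass probabilities must lie in (0, 1]")
    x_n = float(np.sum(1.0 / p) - p.size + 1)
    return 1.0 / x_n


def loading_distribution(
    nipbl_coverage, targeted_fraction: float = 0.8
) -> np.ndarray:
    """Per-bin cohesin loading probabilities from NIPBL-like coverage.

    A fraction ``targeted_fraction`` of loading events is distributed
    proportionally to coverage and the remainder uniformly:
    ``prob_b = targeted_fraction * c_b / sum(c) + (1 - targeted_fraction) / L``.
    """
    c = np.asarray(nipbl_coverage, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("coverage must be a nonempty 1D array")
    if np.any(c < 0):
        raise ValueError("coverage must be nonnegative")
    if not 0 <= targeted_fraction <= 1:
        raise ValueError("targeted_fraction must lie in [0, 1]")
    total = c.sum()
    if total == 0:
        if targeted_fraction > 0:
            raise ValueError(
                "all-zero coverage cannot receive targeted loading"
            )
        targeted = np.zeros_like(c)
    else:
        targeted = c / total
    return targeted_fraction * targeted + (1.0 - targeted_fraction) / c.size


@dataclass
class LocusModel:
    """Binned chromatin fiber with stalling and loading probabilities.

    ``forward_stall[b]`` is the probability that a head moving toward
    decreasing bin index is stalled when attempting to enter bin ``b``;
    ``reverse_stall[b]`` the analogue for increasing bin index.
    """

    n_bins: int
    bin_bp: int
    forward_stall: np.ndarray
    reverse_stall: np.ndarray
    loading_prob: np.ndarray
    interval: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        self.forward_stall = np.asarray(self.forward_stall, dtype=float)
        self.reverse_stall = np.asarray(self.reverse_stall, dtype=float)
        self.loading_prob = np.asarray(self.loading_prob, dtype=float)
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        for name in ("forward_stall", "reverse_stall", "loading_prob"):
            arr = getattr(self, name)
            if arr.shape != (self.n_bins,):
                raise ValueError(f"{name} must have length n_bins={self.n_bins}")
        for name in ("forward_stall", "reverse_stall"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if abs(self.loading_prob.sum() - 1.0) > 1e-12:
            raise ValueError("loading_prob must sum to 1")
        if self.interval is not None:
            chrom, start, end = self.interval
            expected = math.ceil((end - start) / self.bin_bp)
            if expected != self.n_bins:
                raise ValueError(
                    f"interval implies {expected} bins, model has {self.n_bins}"
                )

    def to_json(self, path) -> None:
        payload = {
            "n_bins": int(self.n_bins),
            "bin_bp": int(self.bin_bp),
            "interval": list(self.interval) if self.interval else None,
            "forward_stall": self.forward_stall.tolist(),
            "reverse_stall": self.reverse_stall.tolist(),
            "loading_prob": self.loading_prob.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LocusModel":
        with open(path) as fh:
            payload = json.load(fh)
        interval = payload.get("interval")
        return cls(
            n_bins=payload["n_bins"],
            bin_bp=payload["bin_bp"],
            forward_stall=np.asarray(payload["forward_stall"]),
            reverse_stall=np.asarray(payload["reverse_stall"]),
            loading_prob=np.asarray(payload["loading_prob"]),
            interval=tuple(interval) if interval else None,
        )


def assemble_locus(
    n_bins: int,
    bin_bp: int,
    cbs_list,
    nipbl_profile,
    stall_params: StallParams | None = None,
    targeted_fraction: float = 0.8,
    interval: tuple[str, int, int] | None = None,
) -> LocusModel:
    """Build a :class:`LocusModel` from oriented CBS annotations and coverage.

    ``cbs_list`` holds ``(bin_index, orientation, enrichment)`` triples with
    orientation in {"forward", "reverse"}. When several same-orientation sites
    fall in one bin they are combined into a single effective barrier whose
    pass probability follows :func:`array_permeability` over the individual
    pass probabilities.
    """
    params = stall_params or StallParams()
    per_bin: dict[tuple[int, str], list[float]] = {}
    for bin_idx, orientation, enrichment in cbs_list:
        bin_idx = int(bin_idx)
        if not 0 <= bin_idx < n_bins:
            raise ValueError(f"CBS bin index {bin_idx} outside [0, {n_bins})")
        if orientation not in (FORWARD, REVERSE):
            raise ValueError(f"unknown CBS orientation {orientation!r}")
        if enrichment < 0:
            raise ValueError("CBS enrichment must be nonnegative")
        per_bin.setdefault((bin_idx, orientation), []).append(float(enrichment))

    forward = np.zeros(n_bins)
    reverse = np.zeros(n_bins)
    for (bin_idx, orientation), enrichments in per_bin.items():
        stalls = np.atleast_1d(stall_probability(np.asarray(enrichments), params))
        passes = 1.0 - stalls
        if np.any(passes == 0):
            effective_stall = 1.0
        else:
            effective_stall = 1.0 - array_permeability(passes)
        target = forward if orientation == FORWARD else reverse
        target[bin_idx] = effective_stall

    loading = loading_distribution(nipbl_profile, targeted_fraction)
    return LocusModel(
        n_bins=n_bins,
        bin_bp=bin_bp,
        forward_stall=forward,
        reverse_stall=reverse,
        loading_prob=loading,
        interval=interval,
    )


def read_cbs_bed(path) -> list[tuple[int, str, float, int]]:
    """Read CBS annotations from a BED-like TSV.

    Expected columns (no header): chrom, start, end, name, enrichment, strand,
    with 0-based half-open coordinates and strand ``+`` (forward) or ``-``
    (reverse). Returns ``(start, orientation, enrichment, end)`` tuples in
    genomic coordinates; map to bins with :func:`bin_interval` output.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "enrichment", "strand"],
    )
    records = []
    for row in table.itertuples(index=False):
        orientation = FORWARD if row.strand == "+" else REVERSE
        records.append((int(row.start), orientation, float(row.enrichment), int(row.end)))
    return records


def read_bedgraph(path, n_bins: int, locus_start: int, bin_bp: int) -> np.ndarray:
    """Read a bedGraph-like coverage TSV and accumulate it onto locus bins.

    Coverage of each record is apportioned to overlapping bins by overlap
    length (in bp) times the record value.
    """
    table = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )
    coverage = np.zeros(n_bins)
    locus_end = locus_start + n_bins * bin_bp
    for row in table.itertuples(index=False):
        lo = max(int(row.start), locus_start)
        hi = min(int(row.end), locus_end)
        if hi <= lo:
            continue
        first = (lo - locus_start) // bin_bp
        last = (hi - 1 - locus_start) // bin_bp
        for b in range(first, last + 1):
            b_lo = locus_start + b * bin_bp
            b_hi = b_lo + bin_bp
            overlap = min(hi, b_hi) - max(lo, b_lo)
            coverage[b] += overlap * float(row.value)
    return coverage
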