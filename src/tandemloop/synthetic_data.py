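"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and an explicit seed, and
returns both the dataset and a :class:`GroundTruth` record sufficient to score
recovery downstream. Count-like noise is multiplicative lognormal throughout,
matching the geometric-standard-deviation machinery of the 4C rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .allelic_em import AlleleDistribution, ExpressionDataset, union_distribution
from .fivec_qc import FiveCDataset
from .locus_model import LocusModel, StallParams, assemble_locus

__all__ = [
    "SyntheticLocusSpec",
    "GroundTruth",
    "gen_synthetic_locus",
    "gen_4c_profiles",
    "gen_single_cell_expression",
    "gen_5c_dataset",
    "gen_ep_contact_table",
]


@dataclass
class GroundTruth:
    """Record of the parameters a generator actually used."""

    generator: str
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"cannot serialize {type(o)}")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=default)


# ---------------------------------------------------------------------------
# locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Description of a synthetic binned locus with oriented CBS elements.

    ``cbs_list`` holds (bin index, orientation, enrichment) triples;
    ``nipbl_profile`` is nonnegative coverage per bin.
    """

    n_bins: int
    bin_bp: int
    cbs_list: tuple = ()
    nipbl_profile: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins <= 0 or self.bin_bp <= 0:
            raise ValueError("n_bins and bin_bp must be positive")
        for bin_idx, _orientation, enrichment in self.cbs_list:
            if not 0 <= bin_idx < self.n_bins:
                raise ValueError(f"CBS bin {bin_idx} outside [0, {self.n_bins})")
            if enrichment < 0:
                raise ValueError("CBS enrichment must be nonnegative")
        if self.nipbl_profile is not None and len(self.nipbl_profile) != self.n_bins:
            raise ValueError("nipbl_profile length must equal n_bins")


def gen_synthetic_locus(spec: SyntheticLocusSpec,
                        stall_params: StallParams | None = None,
                        targeted_fraction: float = 0.8) -> LocusModel:
    """Materialize a :class:`LocusModel` from a synthetic locus description.

    With no NIPBL profile supplied, a mildly rough lognormal coverage is drawn
    from the locus description's seed (so loading is reproducible but not flat).
    """
    if spec.nipbl_profile is not None:
        coverage = np.asarray(spec.nipbl_profile, dtype=float)
    else:
        rng = np.random.default_rng(spec.seed)
        coverage = rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_bins)
    return assemble_locus(
        n_bins=spec.n_bins, bin_bp=spec.bin_bp, cbs_list=spec.cbs_list,
        nipbl_profile=coverage, stall_params=stall_params,
        targeted_fraction=targeted_fraction,
    )


# ---------------------------------------------------------------------------
# 4C viewpoint profiles
# ---------------------------------------------------------------------------

def gen_4c_profiles(n_viewpoints: int, n_partners: int, alpha: float = 1.0,
                    k_scales=None, noise_gsd: float = 1.2, replicates: int = 2,
                    seed: int = 0, min_distance: float = 600.0,
                    max_distance: float = 600_000.0):
    """Power-law decaying viewpoint contact profiles with lognormal noise.

    Frequencies follow ``u_ij = k_i * s_ij^(-alpha) * eps`` where ``eps`` is
    lognormal with geometric standard deviation ``noise_gsd`` (``noise_gsd=1``
    is noiseless). Replicates share ``k_i`` and ``alpha``; only the noise
    differs. Returns ``(profiles DataFrame, GroundTruth)``.
    """
    if alpha <= 0:
        raise ValueError("decay exponent alpha must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_gsd < 1:
        raise ValueError("geometric SD must be >= 1")
    if min_distance <= 0:
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    if k_scales is None:
        k_scales = np.concatenate([[1.0], rng.uniform(0.3, 3.0, n_viewpoints - 1)])
    k_scales = np.asarray(k_scales, dtype=float)
    if k_scales.shape != (n_viewpoints,) or np.any(k_scales <= 0):
        raise ValueError("k_scales must be positive, one per viewpoint")
    log_sigma = np.log(noise_gsd)
    rows = []
    distances = {}
    for vp in range(n_viewpoints):
        s = np.exp(rng.uniform(np.log(min_distance), np.log(max_distance),
                               size=n_partners))
        distances[vp] = s
        base = k_scales[vp] * s ** (-alpha)
        for rep in range(replicates):
            noise = (rng.lognormal(mean=0.0, sigma=log_sigma, size=n_partners)
                     if log_sigma > 0 else np.ones(n_partners))
            for j in range(n_partners):
                rows.append({"viewpoint": vp, "partner": j,
                             "distance": s[j], "frequency": base[j] * noise[j],
                             "replicate": rep})
    profiles = pd.DataFrame(rows)
    truth = GroundTruth("gen_4c_profiles", {
        "alpha": float(alpha), "k_scales": k_scales,
        "noise_gsd": float(noise_gsd), "replicates": replicates,
        "seed": seed,
    })
    return profiles, truth


# ---------------------------------------------------------------------------
# single-cell expression
# ---------------------------------------------------------------------------

def gen_single_cell_expression(allele_dist: AlleleDistribution, n_cells: int,
                               seed: int = 0):
    """Cells whose expressed set is the union of two independent allele draws.

    Returns ``(ExpressionDataset, GroundTruth)``; the truth records the
    per-allele distribution and its exact self-convolution over unions.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    sets, probs = allele_dist.as_array()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(sets), size=(n_cells, 2), p=probs)
    counts: dict = {}
    for a, b in draws:
        key = sets[a] | sets[b]
        counts[key] = counts.get(key, 0) + 1
    dataset = ExpressionDataset(n_genes=allele_dist.n_genes, union_counts=counts)
    truth = GroundTruth("gen_single_cell_expression", {
        "allele_probabilities": {tuple(sorted(s)): p
                                 for s, p in allele_dist.probabilities.items()},
        "union_distribution": {tuple(sorted(k)): v
                               for k, v in union_distribution(allele_dist).items()},
        "n_cells": n_cells, "seed": seed,
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# 5C matrices
# ---------------------------------------------------------------------------

def gen_5c_dataset(n_forward: int = 40, n_reverse: int = 40,
                   decay_scale: float = 1e5, decay_alpha: float = 0.5,
                   primer_bias: dict | None = None, n_singletons: int = 3,
                   n_datasets: int = 2, noise_gsd: float = 1.05,
                   singleton_fold: float = 20.0, primer_spacing: int = 4000,
                   seed: int = 0):
    """Forward x reverse 5C count matrices with planted biases and singletons.

    Frequencies decay as a power law of primer-pair distance with per-primer
    multiplicative biases and lognormal noise; the BAC control shares the
    primer biases but has no distance decay. ``n_singletons`` entries per
    dataset are inflated ``singleton_fold``-fold at recorded coordinates.
    Returns ``(datasets, bac, GroundTruth)``.
    """
    if n_forward < 2 or n_reverse < 2:
        raise ValueError("need at least two primers per orientation")
    if n_singletons > n_forward * n_reverse:
        raise ValueError("more singletons than matrix entries")
    rng = np.random.default_rng(seed)
    fwd = [f"syn_for_{i}" for i in range(n_forward)]
    rev = [f"syn_rev_{j}" for j in range(n_reverse)]
    # alternating forward/reverse primers along the region, irregularly spaced
    # (restriction sites are not evenly distributed)
    fwd_pos = (np.arange(n_forward) * 2 * primer_spacing
               + rng.uniform(-0.25, 0.25, n_forward) * primer_spacing)
    rev_pos = (np.arange(n_reverse) * 2 * primer_spacing + primer_spacing
               + rng.uniform(-0.25, 0.25, n_reverse) * primer_spacing)
    bias = {p: 1.0 for p in fwd + rev}
    if primer_bias:
        unknown = set(primer_bias) - set(bias)
        if unknown:
            raise ValueError(f"unknown primers in primer_bias: {sorted(unknown)}")
        bias.update({p: float(v) for p, v in primer_bias.items()})
    log_sigma = np.log(noise_gsd)

    def base_frame():
        rows = []
        for i, f in enumerate(fwd):
            for j, r in enumerate(rev):
                dist = abs(float(fwd_pos[i] - rev_pos[j]))
                rows.append({"forward": f, "reverse": r, "distance": dist})
        return pd.DataFrame(rows)

    frame = base_frame()
    bias_f = frame["forward"].map(bias).to_numpy()
    bias_r = frame["reverse"].map(bias).to_numpy()
    datasets = []
    singleton_records = []
    for d in range(n_datasets):
        decayed = decay_scale * frame["distance"].to_numpy() ** (-decay_alpha)
        noise = (rng.lognormal(0.0, log_sigma, size=len(frame))
                 if log_sigma > 0 else np.ones(len(frame)))
        freq = decayed * bias_f * bias_r * noise
        chosen = rng.choice(len(frame), size=n_singletons, replace=False)
        freq[chosen] *= singleton_fold
        pairs = frame.copy()
        pairs["frequency"] = freq
        datasets.append(FiveCDataset(pairs=pairs, name=f"synthetic_{d}"))
        singleton_records.append([
            (frame["forward"].iloc[c], frame["reverse"].iloc[c]) for c in chosen
        ])
    bac_noise = (rng.lognormal(0.0, log_sigma, size=len(frame))
                 if log_sigma > 0 else np.ones(len(frame)))
    bac_pairs = frame.copy()
    bac_pairs["frequency"] = decay_scale * bias_f * bias_r * bac_noise
    bac = FiveCDataset(pairs=bac_pairs, name="bac_control")
    truth = GroundTruth("gen_5c_dataset", {
        "decay_alpha": decay_alpha, "decay_scale": decay_scale,
        "primer_bias": {p: v for p, v in bias.items() if v != 1.0},
        "singletons": singleton_records, "singleton_fold": singleton_fold,
        "noise_gsd": noise_gsd, "seed": seed,
    })
    return datasets, bac, truth


# ---------------------------------------------------------------------------
# enhancer-promoter contact tables
# ---------------------------------------------------------------------------

_EDGE_VARS = ("enhancer", "insulator", "loop", "promoter")


def gen_ep_contact_table(n_promoters: int = 500, planted_edges=(),
                         n_conditions: int = 3, n_enhancers: int = 3,
                         noise_gsd: float = 1.1, seed: int = 0):
    """Enhancer-promoter contact tables with a planted dependency structure.

    ``planted_edges`` lists ``(parent, child, effect)`` triples over the
    variables {enhancer, insulator, loop, promoter}; a positive effect makes
    the child increase with the parent across conditions, a negative effect
    makes it decrease (e.g. ``("insulator", "promoter", -1.5)`` plants the
    inverse insulator-expression relationship). Variables without parents vary
    independently across conditions. Returns ``(table, GroundTruth)``.
    """
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    parents: dict = {v: [] for v in _EDGE_VARS}
    for parent, child, effect in planted_edges:
        if parent not in _EDGE_VARS or child not in _EDGE_VARS:
            raise ValueError(f"unknown edge {(parent, child)}; "
                             f"variables are {_EDGE_VARS}")
        parents[child].append((parent, float(effect)))
    # topological generation order
    order = []
    pending = dict(parents)
    while pending:
        ready = [v for v, ps in pending.items()
                 if all(p not in pending for p, _ in ps)]
        if not ready:
            raise ValueError("planted edges contain a cycle")
        for v in ready:
            order.append(v)
            del pending[v]

    rng = np.random.default_rng(seed)
    log_sigma = np.log(noise_gsd)
    rows = []
    latent_log = {}
    for prom in range(n_promoters):
        latents: dict = {}
        for v in order:
            base = rng.normal(0.0, 1.0, size=n_conditions)
            for parent, effect in parents[v]:
                base = base + effect * latents[parent]
            latents[v] = base
        latent_log[prom] = {v: latents[v].tolist() for v in _EDGE_VARS}
        prom_start = 1_000_000 + prom * 100_000
        prom_end = prom_start + 2_000
        enh_strength_base = np.exp(rng.normal(0.0, 0.3, size=n_enhancers))
        for c in range(n_conditions):
            scale_e = np.exp(latents["enhancer"][c])
            scale_u = np.exp(latents["insulator"][c])
            scale_l = np.exp(latents["loop"][c])
            expr = float(np.exp(latents["promoter"][c]))
            for e_idx in range(n_enhancers):
                enh_start = prom_end + 20_000 * (e_idx + 1)
                enh_end = enh_start + 2_000
                eps = rng.lognormal(0.0, log_sigma, size=3)
                rows.append({
                    "promoter": prom, "condition": c,
                    "promoter_start": prom_start, "promoter_end": prom_end,
                    "enhancer_start": enh_start, "enhancer_end": enh_end,
                    "loop_count": 10.0 * scale_l * eps[0],
                    "enhancer_strength": enh_strength_base[e_idx] * scale_e * eps[1],
                    "ctcf_signal": 5.0 * scale_u * eps[2],
                    "expression": expr,
                })
    table = pd.DataFrame(rows)
    truth = GroundTruth("gen_ep_contact_table", {
        "planted_edges": [list(e) for e in planted_edges],
        "n_conditions": n_conditions, "n_promoters": n_promoters,
        "noise_gsd": noise_gsd, "seed": seed,
    })
    return table, truth
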