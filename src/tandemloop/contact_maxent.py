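"""Contact maps, 4C rescaling, relative maximum-entropy correction, and the
four-CBS toy ("hulu"/gourd) demonstration.

The relative maximum-entropy step picks the conformation distribution closest
in KL divergence to the loop-extrusion prior among those reproducing observed
mean contact probabilities. With Gaussian slack of variance ``sigma^2`` per
constrained pair, the Lagrange multipliers minimize the strictly convex dual

    Gamma(lambda) = log mean_n exp(-sum_m lambda_m c_m(q_n))
                    + sum_m lambda_m xi_m + 1/2 sum_m lambda_m^2 sigma_m^2,

whose gradient is ``xi_m - <c_m>_lambda + lambda_m sigma_m^2`` and whose
Hessian is the reweighted contact covariance plus ``diag(sigma^2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.isotonic import IsotonicRegression

from . import _kernels
from .extrusion_1d import ExtrusionParams
from .locus_model import LocusModel, assemble_locus
from .polymer_3d import ConformationEnsemble, ForceField, Schedule, simulate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMap",
    "RescaledProfiles",
    "MaxEntModel",
    "HuluConfig",
    "HuluResult",
    "contact_map_from_ensemble",
    "regrid_to_bins",
    "rescale_viewpoint_profiles",
    "fit_contact_multiplier",
    "compute_targets",
    "maxent_fit",
    "reweight_ensemble",
    "grid_optimize_parameters",
    "run_hulu_demo",
    "hulu_anchor_enrichment",
    "nmds_embed",
]


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric matrix of pairwise contact probabilities at a capture radius."""

    probabilities: np.ndarray
    capture_radius: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("contact map must be square")
        self.probabilities = p

    @property
    def median_background(self) -> float:
        """Median contact probability over all distinct locus pairs (p-hat)."""
        iu = np.triu_indices(self.probabilities.shape[0], k=1)
        return float(np.median(self.probabilities[iu]))

    def viewpoint_profile(self, viewpoint_bin: int) -> np.ndarray:
        return self.probabilities[viewpoint_bin].copy()


def contact_map_from_ensemble(ensemble: ConformationEnsemble,
                              capture_radius: float) -> ContactMap:
    """p_ij = weighted fraction of conformations with min-image distance <= radius."""
    if ensemble.n_samples == 0:
        raise ValueError("empty ensemble")
    if capture_radius <= 0:
        raise ValueError("capture radius must be positive")
    n = ensemble.n_monomers
    weights = ensemble.weights
    if weights is None:
        weights = np.full(ensemble.n_samples, 1.0 / ensemble.n_samples)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    out = np.zeros((n, n))
    _kernels.accumulate_contact_map(
        np.ascontiguousarray(ensemble.positions), ensemble.box,
        float(capture_radius), weights, out,
    )
    np.fill_diagonal(out, 1.0)
    return ContactMap(probabilities=out, capture_radius=capture_radius)


def regrid_to_bins(fragments: pd.DataFrame, bin_table: pd.DataFrame) -> pd.DataFrame:
    """Re-grid a restriction-fragment profile onto coarse bins.

    ``fragments`` needs columns ``start, end, frequency``; ``bin_table`` is the
    output of :func:`tandemloop.locus_model.bin_interval`. Fragment frequency
    is apportioned to overlapping bins proportionally to overlap length.
    Fragments entirely outside the locus are dropped with a logged warning.
    """
    freq = np.zeros(len(bin_table))
    if len(fragments) == 0:
        return pd.DataFrame({"bin": bin_table["bin"], "frequency": freq})
    locus_start = int(bin_table["start"].iloc[0])
    locus_end = int(bin_table["end"].iloc[-1])
    bin_bp = int(bin_table["end"].iloc[0] - bin_table["start"].iloc[0])
    for row in fragments.itertuples(index=False):
        lo, hi = int(row.start), int(row.end)
        if hi <= lo:
            raise ValueError(f"degenerate fragment [{lo}, {hi})")
        clip_lo, clip_hi = max(lo, locus_start), min(hi, locus_end)
        if clip_hi <= clip_lo:
            logger.warning("fragment [%d, %d) outside locus; dropped", lo, hi)
            continue
        length = hi - lo
        first = (clip_lo - locus_start) // bin_bp
        last = (clip_hi - 1 - locus_start) // bin_bp
        for b in range(first, last + 1):
            b_lo = locus_start + b * bin_bp
            b_hi = min(b_lo + bin_bp, locus_end)
            overlap = min(clip_hi, b_hi) - max(clip_lo, b_lo)
            freq[b] += row.frequency * overlap / length
    return pd.DataFrame({"bin": bin_table["bin"], "frequency": freq})


# ---------------------------------------------------------------------------
# multi-viewpoint 4C rescaling
# ---------------------------------------------------------------------------

@dataclass
class RescaledProfiles:
    """Cross-viewpoint rescaling of 4C contact profiles.

    The model ``u_ij ~ k_i * s_ij^(-alpha)`` is fitted by minimizing the
    geometric standard deviation of ``u_ij / (k_i s_ij^(-alpha))`` over all
    viewpoints jointly, with ``k_1 = 1`` fixed to remove the scale redundancy.
    """

    alpha: float
    scales: dict
    gsd: float
    table: pd.DataFrame  # original rows plus a `rescaled` column (u / k_i)

    def replicate_stats(self) -> pd.DataFrame:
        grouped = self.table.groupby(["viewpoint", "partner"], sort=True)
        stats = grouped["rescaled"].agg(mean="mean", var="var").reset_index()
        stats["var"] = stats["var"].fillna(0.0)
        dist = grouped["distance"].first().reset_index(drop=True)
        stats["distance"] = dist
        return stats


def rescale_viewpoint_profiles(profiles: pd.DataFrame) -> RescaledProfiles:
    """Fit the shared decay exponent and per-viewpoint scales, rescale frequencies.

    ``profiles`` needs columns ``viewpoint, partner, distance, frequency`` and
    optionally ``replicate``. Pairs with zero mean frequency across replicates
    are excluded from the fit and from the output.
    """
    required = {"viewpoint", "partner", "distance", "frequency"}
    if not required.issubset(profiles.columns):
        raise ValueError(f"profiles must have columns {sorted(required)}")
    df = profiles.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0
    if np.any(df["distance"] <= 0):
        raise ValueError("distances must be positive")
    mean_u = df.groupby(["viewpoint", "partner"])["frequency"].transform("mean")
    df = df[mean_u > 0].copy()
    if len(df) == 0:
        raise ValueError("no pairs with positive mean frequency")
    if np.any(df["frequency"] <= 0):
        raise ValueError("frequencies of retained pairs must be positive")

    viewpoints = sorted(df["viewpoint"].unique())
    vp_index = {v: i for i, v in enumerate(viewpoints)}
    n_rows = len(df)
    log_u = np.log(df["frequency"].to_numpy(float))
    log_s = np.log(df["distance"].to_numpy(float))
    # columns: intercept (beta), -log s (alpha), dummies for viewpoints 2..I (log k_i)
    n_extra = len(viewpoints) - 1
    design = np.zeros((n_rows, 2 + n_extra))
    design[:, 0] = 1.0
    design[:, 1] = -log_s
    vp_col = df["viewpoint"].map(vp_index).to_numpy()
    for i in range(1, len(viewpoints)):
        design[vp_col == i, 2 + i - 1] = 1.0
    coef, _, rank, _ = np.linalg.lstsq(design, log_u, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rescaling system is singular (e.g., all distances equal)")
    alpha = float(coef[1])
    log_k = np.concatenate([[0.0], coef[2:]])
    scales = {v: float(np.exp(log_k[i])) for v, i in vp_index.items()}
    k_rows = np.exp(log_k[vp_col])
    residuals = log_u - design @ coef
    gsd = float(np.exp(np.sqrt(np.mean(residuals**2))))
    df["rescaled"] = df["frequency"].to_numpy(float) / k_rows
    return RescaledProfiles(alpha=alpha, scales=scales, gsd=gsd, table=df)


# ---------------------------------------------------------------------------
# relative maximum entropy
# ---------------------------------------------------------------------------

def fit_contact_multiplier(u_bar, p_pairs, p_hat: float) -> float:
    """Closed-form multiplier matching 4C frequencies to contact probabilities.

    Minimizes ``sum (u_bar - max(0, p - p_hat) / k)^2`` over ``k > 0``:
    ``k = sum(m^2) / sum(u_bar * m)`` with ``m = max(0, p - p_hat)``. The
    median background ``p_hat`` is subtracted because the small periodic box
    inflates baseline contact probabilities.
    """
    u_bar = np.asarray(u_bar, dtype=float)
    m = np.maximum(0.0, np.asarray(p_pairs, dtype=float) - p_hat)
    if np.all(m == 0):
        raise ValueError("degenerate background: no pair exceeds the median p-hat")
    denom = float(np.sum(u_bar * m))
    if denom <= 0:
        raise ValueError("cannot fit a positive multiplier (sum u*m <= 0)")
    return float(np.sum(m * m)) / denom


def compute_targets(u_bar, p_pairs, p_hat: float, k: float) -> np.ndarray:
    """Constraint targets ``xi = min(1, k * u_bar + min(p, p_hat))``."""
    u_bar = np.asarray(u_bar, dtype=float)
    p_pairs = np.asarray(p_pairs, dtype=float)
    return np.minimum(1.0, k * u_bar + np.minimum(p_pairs, p_hat))


@dataclass
class MaxEntModel:
    """Fitted relative maximum-entropy correction."""

    lambdas: np.ndarray
    targets: np.ndarray
    sigma2: np.ndarray
    gamma: float
    converged: bool
    n_iter: int
    grad_norm: float
    pairs: np.ndarray | None = None
    capture_radius: float | None = None
    multiplier: float | None = None


def _gamma_value(lam, C, xi, sigma2):
    logits = -C @ lam
    return float(logsumexp(logits) - math.log(C.shape[0])
                 + xi @ lam + 0.5 * np.sum(lam * lam * sigma2))


def maxent_fit(contacts, targets, variances=None, sigma_min2: float = 0.01,
               pairs=None, capture_radius: float | None = None,
               max_iter: int = 500, grad_tol: float = 1e-8) -> MaxEntModel:
    """Fit Lagrange multipliers of the relative maximum-entropy correction.

    ``contacts`` is the (n_conformations, n_pairs) 0/1 matrix of per-sample
    contact indicators under the prior ensemble; ``targets`` the desired mean
    contact probabilities ``xi``; ``variances`` the replicate variances of the
    transformed frequencies (floored at ``sigma_min2``). Optimization is a
    trust-region Newton method on the strictly convex dual; non-convergence is
    reported on the returned model rather than raised.
    """
    C = np.asarray(contacts, dtype=float)
    if C.ndim != 2:
        raise ValueError("contacts must be 2D (conformations x pairs)")
    xi = np.asarray(targets, dtype=float)
    if np.any((xi < 0) | (xi > 1)):
        raise ValueError("targets must lie in [0, 1]")
    if variances is None:
        sigma2 = np.full(xi.shape, sigma_min2)
    else:
        sigma2 = np.maximum(sigma_min2, np.asarray(variances, dtype=float))

    def fun(lam):
        return _gamma_value(lam, C, xi, sigma2)

    def grad(lam):
        w = softmax(-C @ lam)
        mean_c = w @ C
        return xi - mean_c + lam * sigma2

    def hess(lam):
        w = softmax(-C @ lam)
        mean_c = w @ C
        second = C.T @ (w[:, None] * C)
        return second - np.outer(mean_c, mean_c) + np.diag(sigma2)

    x0 = np.zeros(xi.shape[0])
    res = minimize(fun, x0, jac=grad, hess=hess, method="trust-exact",
                   options={"maxiter": max_iter, "gtol": grad_tol})
    gnorm = float(np.linalg.norm(grad(res.x), ord=np.inf))
    converged = bool(gnorm <= max(grad_tol * 10, 1e-6))
    return MaxEntModel(
        lambdas=res.x, targets=xi, sigma2=sigma2, gamma=float(res.fun),
        converged=converged, n_iter=int(res.nit), grad_norm=gnorm,
        pairs=None if pairs is None else np.asarray(pairs, dtype=np.int64),
        capture_radius=capture_radius,
    )


def reweight_ensemble(ensemble: ConformationEnsemble, model: MaxEntModel):
    """Weight conformations by ``exp(-sum lambda_m c_m(q))`` and rebuild the map.

    The model must carry its constrained ``pairs`` and ``capture_radius``. The
    fitted multipliers may come from a different (e.g. wild-type) sample than
    the ensemble being reweighted, reproducing cross-sample correction.
    Returns ``(weighted_ensemble, corrected_map)``.
    """
    if model.pairs is None or model.capture_radius is None:
        raise ValueError("model lacks pairs/capture_radius; fit via ensemble helpers")
    C = _kernels.pair_contact_matrix(
        np.ascontiguousarray(ensemble.positions), ensemble.box,
        float(model.capture_radius), model.pairs,
    ).astype(float)
    logits = -C @ model.lambdas
    logits -= logits.max()
    weights = np.exp(logits)
    total = weights.sum()
    if total == 0 or not np.isfinite(total):
        raise FloatingPointError("degenerate reweighting: all weights underflow")
    weights /= total
    weighted = ConformationEnsemble(positions=ensemble.positions,
                                    box=ensemble.box, weights=weights)
    corrected = contact_map_from_ensemble(weighted, model.capture_radius)
    return weighted, corrected


def ensemble_pair_contacts(ensemble: ConformationEnsemble, pairs,
                           capture_radius: float) -> np.ndarray:
    """Per-conformation 0/1 contact indicators for the given pairs."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return _kernels.pair_contact_matrix(
        np.ascontiguousarray(ensemble.positions), ensemble.box,
        float(capture_radius), pairs,
    )


# ---------------------------------------------------------------------------
# parameter grid optimization
# ---------------------------------------------------------------------------

def grid_optimize_parameters(locus: LocusModel, u_bar, pairs, variances=None,
                             grid=((100, 100), (100, 200), (200, 200)),
                             radii=(2.0, 3.0, 4.0),
                             schedule: Schedule | None = None,
                             sigma_min2: float = 0.01, rho: float = 0.2,
                             dt: float = 0.05, seed: int = 0):
    """Select (processivity, separation) maximizing the mean converged dual.

    For each grid cell an ensemble is simulated and the relative max-ent dual
    minimum ``Gamma`` (which approximates the negative KL divergence to the
    data-consistent distribution) is computed per capture radius; the cell with
    the largest mean ``Gamma`` across radii wins. Failed cells are skipped with
    a warning. Returns ``(best_processivity, best_separation, results)`` where
    results maps cells to per-radius ``Gamma`` values.
    """
    schedule = schedule or Schedule.reduced()
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    u_bar = np.asarray(u_bar, dtype=float)
    results: dict = {}
    best_cell, best_score = None, -np.inf
    for cell_idx, (proc, sep) in enumerate(grid):
        try:
            params = ExtrusionParams(processivity=proc, separation=sep,
                                     seed=seed + cell_idx)
            ens = simulate_ensemble(locus, params, schedule, rho=rho, dt=dt,
                                    seed=seed + cell_idx)
            gammas = []
            for radius in radii:
                cmap = contact_map_from_ensemble(ens, radius)
                p_hat = cmap.median_background
                p_pairs = cmap.probabilities[pairs[:, 0], pairs[:, 1]]
                k = fit_contact_multiplier(u_bar, p_pairs, p_hat)
                xi = compute_targets(u_bar, p_pairs, p_hat, k)
                C = ensemble_pair_contacts(ens, pairs, radius)
                model = maxent_fit(C, xi, variances, sigma_min2=sigma_min2)
                gammas.append(model.gamma)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("grid cell (%s, %s) skipped: %s", proc, sep, exc)
            continue
        results[(proc, sep)] = gammas
        score = float(np.mean(gammas))
        if score > best_score:
            best_score, best_cell = score, (proc, sep)
    if best_cell is None:
        raise RuntimeError("all grid cells failed")
    return best_cell[0], best_cell[1], results


# ---------------------------------------------------------------------------
# hulu (gourd) toy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HuluConfig:
    """Four tandem CBS (forward, forward, reverse, reverse) spaced 100 bins.

    Cohesins load 30x faster between the inner convergent pair; stalling
    probability 0.97 at every site; processivity and separation 400 bins;
    contacts scored at capture radius 2.
    """

    spacing: int = 100
    flank: int = 50
    stall: float = 0.97
    loading_fold: float = 30.0
    processivity: float = 400.0
    separation: int = 400
    capture_radius: float = 2.0
    rho: float = 0.2
    dt: float = 0.05

    @property
    def cbs_bins(self) -> tuple[int, int, int, int]:
        f = self.flank
        s = self.spacing
        return (f, f + s, f + 2 * s, f + 3 * s)

    @property
    def n_bins(self) -> int:
        return 2 * self.flank + 3 * self.spacing + 1

    def build_locus(self) -> LocusModel:
        b1, b2, b3, b4 = self.cbs_bins
        n = self.n_bins
        forward = np.zeros(n)
        reverse = np.zeros(n)
        forward[[b1, b2]] = self.stall
        reverse[[b3, b4]] = self.stall
        loading = np.ones(n)
        loading[b2 + 1:b3] = self.loading_fold
        loading /= loading.sum()
        return LocusModel(n_bins=n, bin_bp=600, forward_stall=forward,
                          reverse_stall=reverse, loading_prob=loading)


@dataclass
class HuluResult:
    contact_map: ContactMap
    embedding: np.ndarray
    stress: float
    ensemble: ConformationEnsemble
    config: HuluConfig


def hulu_anchor_enrichment(result: "HuluResult", window: int = 2) -> dict:
    """Observed/expected contact enrichment of the four CBS anchor pairs.

    The expected level at each genomic separation is the mean contact
    probability over all pairs at that separation, excluding pairs near any
    CBS bin so anchored loops do not contaminate their own baseline. For the
    inner-inner, outer-outer and the two mismatched inner-outer pairs the
    peak (window maximum) probability, its enrichment over expected, and the
    anchored-vs-mismatched contrasts in binomial standard errors are
    returned. Enrichment over expected removes the distance-decay confound:
    mismatched pairs are genomically closer than the outer-outer pair.
    """
    p = result.contact_map.probabilities
    n_conf = result.ensemble.n_samples
    L = p.shape[0]
    b1, b2, b3, b4 = result.config.cbs_bins
    near_cbs = np.zeros(L, dtype=bool)
    for b in (b1, b2, b3, b4):
        near_cbs[max(0, b - 2 * window):b + 2 * window + 1] = True
    iu = np.triu_indices(L, k=1)
    sep = iu[1] - iu[0]
    clean = ~(near_cbs[iu[0]] | near_cbs[iu[1]])
    expected = np.full(L, np.nan)
    pv = p[iu]
    for s in range(1, L):
        mask = clean & (sep == s)
        if mask.any():
            expected[s] = pv[mask].mean()

    def peak(a, b):
        block = p[a - window:a + window + 1, b - window:b + window + 1]
        seps = np.abs(np.subtract.outer(
            np.arange(a - window, a + window + 1),
            np.arange(b - window, b + window + 1)))
        idx = np.unravel_index(np.argmax(block), block.shape)
        obs = float(block[idx])
        exp = float(expected[seps[idx]])
        return obs, exp

    pairs = {"inner": (b2, b3), "outer": (b1, b4),
             "mismatched_1": (b1, b3), "mismatched_2": (b2, b4)}
    stats = {}
    for name, (a, b) in pairs.items():
        obs, exp = peak(a, b)
        stats[name] = {"observed": obs, "expected": exp,
                       "enrichment": obs / exp if exp > 0 else np.inf,
                       "se": math.sqrt(obs * (1 - obs) / n_conf)}
    worst_mis = max(("mismatched_1", "mismatched_2"),
                    key=lambda k: stats[k]["enrichment"])
    for name in ("inner", "outer"):
        a, m = stats[name], stats[worst_mis]
        gap = a["enrichment"] - m["enrichment"]
        se_gap = math.sqrt((a["se"] / a["expected"]) ** 2
                           + (m["se"] / m["expected"]) ** 2)
        stats[f"{name}_vs_mismatched_se"] = gap / se_gap if se_gap > 0 else np.inf
    return stats


def run_hulu_demo(n_conformations: int = 2000, seed: int = 0,
                  config: HuluConfig | None = None,
                  schedule: Schedule | None = None) -> HuluResult:
    """Simulate the four-CBS toy region and embed its contact topology in 3D.

    The contact map is transformed to dissimilarities ``d_ij = 1 / h_ij``
    (zero-contact pairs get 10x the largest finite dissimilarity) and embedded
    by non-metric MDS.
    """
    cfg = config or HuluConfig()
    locus = cfg.build_locus()
    # thorough 3D annealing is essential: it erases the compact-start memory
    # and flattens the box background so anchored-loop contacts stand out
    schedule = schedule or Schedule.reduced(
        n_1d_anneal=20_000, n_3d_anneal_blocks=2000, steps_per_block=100,
        n_sample_blocks=n_conformations,
    )
    if schedule.n_sample_blocks != n_conformations:
        raise ValueError("schedule sample count must equal n_conformations")
    params = ExtrusionParams(processivity=cfg.processivity,
                             separation=cfg.separation, seed=seed)
    ens = simulate_ensemble(locus, params, schedule, rho=cfg.rho, dt=cfg.dt,
                            seed=seed)
    cmap = contact_map_from_ensemble(ens, cfg.capture_radius)
    h = cmap.probabilities
    with np.errstate(divide="ignore"):
        d = 1.0 / h
    finite = np.isfinite(d)
    if not np.all(finite):
        d[~finite] = 10.0 * d[finite & (d > 0)].max()
    np.fill_diagonal(d, 0.0)
    coords, stress, _ = nmds_embed(d, dim=3, seed=seed)
    return HuluResult(contact_map=cmap, embedding=coords, stress=stress,
                      ensemble=ens, config=cfg)


# ---------------------------------------------------------------------------
# non-metric MDS
# ---------------------------------------------------------------------------

def kruskal_stress(distances: np.ndarray, disparities: np.ndarray) -> float:
    """Kruskal's normalized stress-1, sqrt(sum (d - dhat)^2 / sum d^2)."""
    return float(np.sqrt(np.sum((distances - disparities) ** 2)
                         / np.sum(distances**2)))


def nmds_embed(dissimilarities: np.ndarray, dim: int = 3, seed: int = 0,
               max_iter: int = 300, tol: float = 1e-9):
    """Non-metric MDS minimizing Kruskal's stress-1.

    Alternates isotonic (monotone) regression of the embedded distances on the
    dissimilarity order (ties pooled; Kruskal's secondary approach) with a
    Guttman majorization update. Initialization is classical metric MDS of
    the dissimilarities. Returns ``(coords, stress, trace)``.
    """
    D = np.asarray(dissimilarities, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, rtol=0, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(D < 0) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("dissimilarities must be nonnegative with zero diagonal")
    iu = np.triu_indices(n, k=1)
    delta = D[iu]

    # classical (metric) MDS of the dissimilarities as the start; exact for
    # perfectly Euclidean input, a good monotone-order guess otherwise
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dim]
    X = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))
    if np.allclose(X, 0):
        X = np.random.default_rng(seed).normal(size=(n, dim))

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        diffs = X[:, None, :] - X[None, :, :]
        dmat = np.sqrt(np.sum(diffs**2, axis=-1))
        d = dmat[iu]
        dhat = iso.fit(delta, d).predict(delta)
        stress = kruskal_stress(d, dhat)
        trace.append(stress)
        if stress < 1e-12:
            break
        if np.isfinite(prev) and abs(prev - stress) <= tol * max(prev, 1e-12):
            break
        prev = stress
        # Guttman transform with weights 1
        Bmat = np.zeros((n, n))
        ratio = np.zeros_like(d)
        nonzero = d > 0
        ratio[nonzero] = dhat[nonzero] / d[nonzero]
        Bmat[iu] = -ratio
        Bmat += Bmat.T
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = Bmat @ X / n
    return X, trace[-1], np.asarray(trace)
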