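"""5C matrix quality control and normalization.

Pipeline order (logged): depth-normalize to 1e6 reads per sample → Loess
distance-decay fit with hat-matrix standard deviations and Z scores → primer
filtering (per-primer decay curve vs the global one) → singleton removal
(Z > 12) → BAC control normalization → replicate-mean log2 ratio maps.

The Loess smoother fits a local weighted polynomial (tricube weights over the
``ceil(span * n)`` nearest predictors) at each data point. Collecting the
local fits into the smoother matrix L, the residual covariance is
``sigma^2 (I - L)(I - L)^T`` under homoscedastic Gaussian errors, with
``sigma^2`` estimated as ``eps' eps / tr[(I - L)(I - L)^T]`` from all
residuals; the per-point SD is the square root of the corresponding diagonal
entry and standardizes each residual into a Z score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FiveCDataset",
    "LoessFit",
    "loess_fit",
    "tricube_weight",
    "compute_z_scores",
    "filter_primers",
    "remove_singletons",
    "normalize_depth",
    "normalize_bac",
    "log2_comparison",
    "normalize_5c",
]


@dataclass
class FiveCDataset:
    """One 5C sample: long-format pair table plus primer metadata.

    ``pairs`` has columns ``forward, reverse, distance, frequency``; distances
    are genomic separations of the primer pair midpoints (positive).
    """

    pairs: pd.DataFrame
    name: str = "sample"

    def __post_init__(self) -> None:
        required = {"forward", "reverse", "distance", "frequency"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pairs table needs columns {sorted(required)}")
        if np.any(self.pairs["distance"] <= 0):
            raise ValueError("pair distances must be positive")

    def matrix(self) -> pd.DataFrame:
        return self.pairs.pivot_table(index="forward", columns="reverse",
                                      values="frequency", aggfunc="first")

    def copy_with(self, pairs: pd.DataFrame) -> "FiveCDataset":
        return FiveCDataset(pairs=pairs.reset_index(drop=True), name=self.name)


@dataclass
class LoessFit:
    """Loess fit evaluated at the input points, with per-point residual SDs."""

    x: np.ndarray
    fitted: np.ndarray
    sd: np.ndarray
    span: float
    degree: int

    def predict_sd_floor(self) -> np.ndarray:
        floored = np.maximum(self.sd, 1e-12)
        if np.any(self.sd < 1e-12):
            logger.warning("Loess SD floored at 1e-12 for %d points",
                           int(np.sum(self.sd < 1e-12)))
        return floored


def tricube_weight(x, center, bandwidth):
    """Tricube kernel (1 - (|x - center| / d)^3)^3, zero beyond the bandwidth."""
    u = np.abs(np.asarray(x, dtype=float) - center) / bandwidth
    w = np.where(u <= 1.0, (1.0 - u**3) ** 3, 0.0)
    return w


def loess_fit(x, y, span: float = 0.01, degree: int = 2) -> LoessFit:
    """Local weighted polynomial regression with hat-matrix residual SDs.

    At each point the ``ceil(span * n)`` nearest predictors (ties broken
    stably by index) are fitted with a degree-``degree`` polynomial under
    tricube weights. Windows too small for the polynomial are widened with a
    log message, as is a span that admits fewer points than coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    n_terms = degree + 1
    if n < n_terms:
        raise ValueError(f"need at least {n_terms} points for degree {degree}")
    m = int(np.ceil(span * n))
    if m < n_terms + 1:
        new_m = min(n, n_terms + 1)
        logger.warning("span %.4g admits %d points < %d; window widened to %d",
                       span, m, n_terms + 1, new_m)
        m = new_m

    order = np.argsort(x, kind="stable")
    xs = x[order]
    fitted = np.empty(n)
    # per-point pieces of the n x n smoother matrix L (row i is nonzero only
    # on i's window): diag entry and squared row norm, for the residual
    # covariance sigma^2 (I - L)(I - L)^T
    l_diag = np.empty(n)
    l_rowsq = np.empty(n)
    for i in range(n):
        xc = x[i]
        # window of the m nearest predictors around xc (in sorted order)
        left = np.searchsorted(xs, xc, side="left")
        lo = max(0, left - m)
        hi = min(n, left + m)
        window = order[lo:hi]
        dists = np.abs(x[window] - xc)
        nearest = np.argsort(dists, kind="stable")[:m]
        idx = window[nearest]
        if i not in idx:  # tied distances can crowd out the point itself
            idx[-1] = i
        d = np.abs(x[idx] - xc).max()
        if d == 0:
            d = 1.0  # all predictors coincide; uniform weights
        w = tricube_weight(x[idx], xc, d)
        w = np.where(w > 0, w, 1e-12)
        X = np.vander(x[idx] - xc, N=n_terms, increasing=True)
        XtW = X.T * w
        try:
            beta_mat = np.linalg.solve(XtW @ X, XtW)
        except np.linalg.LinAlgError:
            beta_mat = np.linalg.pinv(XtW @ X) @ XtW
        row = beta_mat[0]  # fitted value at xc is the constant coefficient
        fitted[i] = row @ y[idx]
        self_pos = int(np.flatnonzero(idx == i)[0])
        l_diag[i] = row[self_pos]
        l_rowsq[i] = float(row @ row)
    resid = y - fitted
    shape_diag = np.maximum(1.0 - 2.0 * l_diag + l_rowsq, 0.0)
    tr = float(shape_diag.sum())
    sigma2 = float(resid @ resid) / tr if tr > 0 else 0.0
    sd = np.sqrt(sigma2 * shape_diag)
    return LoessFit(x=x, fitted=fitted, sd=sd, span=span, degree=degree)


def compute_z_scores(y, fit: LoessFit) -> np.ndarray:
    """Z_i = (y_i - g(x_i)) / SD_i with the SD floored at 1e-12."""
    y = np.asarray(y, dtype=float)
    if y.shape != fit.fitted.shape:
        raise ValueError("y must align with the fit")
    return (y - fit.fitted) / fit.predict_sd_floor()


def _primer_median_ratio(dataset: FiveCDataset, global_fit: LoessFit,
                         primer: str, axis: str, primer_span: float,
                         min_pairs: int) -> float | None:
    sub = dataset.pairs[dataset.pairs[axis] == primer]
    if len(sub) < min_pairs:
        logger.warning("primer %s has %d pairs < %d; excluded from flagging",
                       primer, len(sub), min_pairs)
        return None
    own = loess_fit(sub["distance"].to_numpy(), sub["frequency"].to_numpy(),
                    span=primer_span, degree=2)
    global_at = np.interp(sub["distance"].to_numpy(),
                          np.sort(global_fit.x),
                          global_fit.fitted[np.argsort(global_fit.x, kind="stable")])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = own.fitted / global_at
    ratio = ratio[np.isfinite(ratio)]
    if ratio.size == 0:
        return None
    return float(np.median(ratio))


def filter_primers(datasets, ratio: float = 0.85, flag_fraction: float = 0.40,
                   span: float = 0.01, primer_span: float = 0.4,
                   min_pairs: int = 4):
    """Flag primers whose own decay curve deviates from the global one.

    Per dataset, a primer is flagged when the median ratio of its own Loess
    curve (``primer_span`` over its handful of pairs) to the global Loess,
    evaluated at the primer's pair distances, falls below ``ratio`` or above
    ``1 / ratio`` (symmetric multiplicative band). Primers flagged in more
    than ``flag_fraction`` of the datasets are removed from every dataset.
    Returns ``(filtered_datasets, removed, flags)``.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    flags: dict = {}
    for ds in datasets:
        gfit = loess_fit(ds.pairs["distance"].to_numpy(),
                         ds.pairs["frequency"].to_numpy(), span=span, degree=2)
        for axis in ("forward", "reverse"):
            for primer in ds.pairs[axis].unique():
                med = _primer_median_ratio(ds, gfit, primer, axis,
                                           primer_span, min_pairs)
                if med is None:
                    continue
                flagged = med < ratio or med > 1.0 / ratio
                flags.setdefault(primer, []).append(flagged)
    removed = sorted(
        p for p, hits in flags.items()
        if np.mean(hits) > flag_fraction
    )
    removed_set = set(removed)
    filtered = []
    for ds in datasets:
        keep = ~(ds.pairs["forward"].isin(removed_set)
                 | ds.pairs["reverse"].isin(removed_set))
        filtered.append(ds.copy_with(ds.pairs[keep]))
    return filtered, removed, flags


def remove_singletons(dataset: FiveCDataset, z_threshold: float = 12.0,
                      span: float = 0.01, max_rounds: int = 10):
    """Remove PCR-blowout singletons with Loess Z score strictly above 12.

    Singletons are removed one at a time (largest Z first), refitting the
    Loess and residual variance after each removal: a dominant blowout both
    inflates the global residual variance (masking smaller ones) and makes the
    local quadratic ring around the spike (faking neighbours' Z scores), so
    simultaneous removal is unreliable. Returns ``(cleaned_dataset,
    removal_log)`` where the log lists the removed (forward, reverse)
    coordinates with their Z scores and removal round.
    """
    pairs = dataset.pairs
    logs = []
    for round_idx in range(max_rounds):
        fit = loess_fit(pairs["distance"].to_numpy(),
                        pairs["frequency"].to_numpy(), span=span, degree=2)
        z = compute_z_scores(pairs["frequency"].to_numpy(), fit)
        if not np.any(z > z_threshold):
            break
        worst = int(np.argmax(z))
        mask = np.zeros(len(pairs), dtype=bool)
        mask[worst] = True
        removed = pairs.loc[mask, ["forward", "reverse"]].copy()
        removed["z"] = z[mask]
        removed["round"] = round_idx
        logs.append(removed)
        pairs = pairs[~mask]
    removal_log = (pd.concat(logs, ignore_index=True) if logs
                   else pd.DataFrame(columns=["forward", "reverse", "z", "round"]))
    return dataset.copy_with(pairs), removal_log


def normalize_depth(dataset: FiveCDataset, total: float = 1_000_000.0) -> FiveCDataset:
    """Scale a sample so its total interaction frequency equals ``total``."""
    current = float(dataset.pairs["frequency"].sum())
    if current <= 0:
        raise ValueError("cannot depth-normalize an all-zero sample")
    pairs = dataset.pairs.copy()
    pairs["frequency"] = pairs["frequency"] * (total / current)
    return dataset.copy_with(pairs)


def normalize_bac(dataset: FiveCDataset, bac: FiveCDataset) -> FiveCDataset:
    """Divide entrywise by the BAC control; zero-BAC pairs are masked."""
    merged = dataset.pairs.merge(
        bac.pairs[["forward", "reverse", "frequency"]],
        on=["forward", "reverse"], suffixes=("", "_bac"),
    )
    zero = merged["frequency_bac"] <= 0
    if zero.any():
        logger.warning("%d pairs masked: zero BAC control", int(zero.sum()))
        merged = merged[~zero]
    merged["frequency"] = merged["frequency"] / merged["frequency_bac"]
    return dataset.copy_with(merged.drop(columns="frequency_bac"))


def log2_comparison(mutant_reps, wildtype_reps) -> pd.DataFrame:
    """log2 of (mean mutant frequency / mean wild-type frequency) per pair."""
    def mean_table(reps):
        stacked = pd.concat([ds.pairs for ds in reps], ignore_index=True)
        return stacked.groupby(["forward", "reverse"], sort=True).agg(
            frequency=("frequency", "mean"), distance=("distance", "first")
        ).reset_index()

    mut = mean_table(mutant_reps)
    wt = mean_table(wildtype_reps)
    merged = mut.merge(wt, on=["forward", "reverse"], suffixes=("_mut", "_wt"))
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["log2_ratio"] = np.log2(merged["frequency_mut"]
                                       / merged["frequency_wt"])
    return merged[["forward", "reverse", "log2_ratio"]]


def normalize_5c(datasets, bac: FiveCDataset, span: float = 0.01,
                 ratio: float = 0.85, flag_fraction: float = 0.40,
                 z_threshold: float = 12.0, min_pairs: int = 4):
    """Full QC pipeline over a collection of samples sharing one primer set.

    Order: depth normalization → primer filtering → singleton removal → BAC
    normalization. Returns ``(normalized_datasets, report)`` with the removed
    primers and per-sample singleton logs in the report.
    """
    logger.info("5C pipeline: depth -> primer filter -> singletons -> BAC")
    depth_normed = [normalize_depth(ds) for ds in datasets]
    filtered, removed_primers, flags = filter_primers(
        depth_normed, ratio=ratio, flag_fraction=flag_fraction,
        span=span, min_pairs=min_pairs,
    )
    bac_filtered = bac.copy_with(
        bac.pairs[~(bac.pairs["forward"].isin(removed_primers)
                    | bac.pairs["reverse"].isin(removed_primers))]
    )
    cleaned, singleton_logs = [], {}
    for ds in filtered:
        out, log = remove_singletons(ds, z_threshold=z_threshold, span=span)
        cleaned.append(out)
        singleton_logs[ds.name] = log
    normalized = [normalize_bac(ds, bac_filtered) for ds in cleaned]
    report = {"removed_primers": removed_primers,
              "primer_flags": flags,
              "singletons": singleton_logs}
    return normalized, report
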