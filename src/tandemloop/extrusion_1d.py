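"""Stochastic two-headed cohesin loop extrusion on the binned lattice.

Each cohesin is a pair of heads ``(left, right)`` on the lattice of bins. At
every step a cohesin first tests drop-off with probability ``2 / processivity``
(a dropped cohesin is immediately replaced by one loaded from the NIPBL-derived
loading distribution, keeping the cohesin count at ``floor(L / separation)``),
then every surviving head attempts to advance one bin outward. An attempt
fails when the target bin hosts a head of another cohesin, or — when the target
bin carries a CBS barrier oriented against the moving head — with the bin's
stalling probability, independently re-tried each step (geometric waiting).

Update order within a step: drop-off/reload for all cohesins first, then head
moves in a fresh random permutation of all heads, which removes index bias when
two heads contend for the same bin. Cohesins loaded during the current step
only start moving at the next step. Fiber ends are reflecting by default; a
periodic mode (unwrapped head coordinates, occupancy modulo ``L``) is available
for steady-state property checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus_model import LocusModel

__all__ = ["ExtrusionParams", "ExtrusionState", "init_cohesin_system",
           "extrusion_step", "run_extrusion"]


@dataclass(frozen=True)
class ExtrusionParams:
    """Loop-extrusion control parameters.

    processivity: mean extruded loop size in bins (sets drop-off rate 2/processivity).
    separation: mean genomic distance between bound cohesins in bins
        (sets the cohesin count ``floor(L / separation)``).
    """

    processivity: float
    separation: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.processivity <= 0:
            raise ValueError("processivity must be positive")
        if self.separation < 1:
            raise ValueError("separation must be at least 1")


class ExtrusionState:
    """Mutable state of the lattice extrusion simulation."""

    def __init__(self, cohesins: np.ndarray, n_bins: int, rng: np.random.Generator,
                 periodic: bool = False):
        self.cohesins = cohesins  # (n, 2) int64, unwrapped in periodic mode
        self.n_bins = n_bins
        self.rng = rng
        self.periodic = periodic
        self.step_count = 0
        # moved_this_step guards freshly reloaded cohesins from moving
        self._frozen = np.zeros(len(cohesins), dtype=bool)
        self._occ = np.full(n_bins, -1, dtype=np.int64)
        for cid, (lo, hi) in enumerate(cohesins):
            self._occ[lo % n_bins] = cid
            self._occ[hi % n_bins] = cid

    # -- occupancy helpers -------------------------------------------------
    def _bin(self, pos: int) -> int:
        return pos % self.n_bins if self.periodic else pos

    def occupied_by(self, pos: int) -> int:
        return int(self._occ[self._bin(pos)])

    def _clear_cohesin(self, cid: int) -> None:
        lo, hi = self.cohesins[cid]
        self._occ[self._bin(lo)] = -1
        self._occ[self._bin(hi)] = -1

    def _place_cohesin(self, cid: int, lo: int, hi: int) -> None:
        self.cohesins[cid, 0] = lo
        self.cohesins[cid, 1] = hi
        self._occ[self._bin(lo)] = cid
        self._occ[self._bin(hi)] = cid

    def loop_sizes(self) -> np.ndarray:
        return self.cohesins[:, 1] - self.cohesins[:, 0]

    def snapshot(self) -> np.ndarray:
        return self.cohesins.copy()


def _draw_load_site(state: ExtrusionState, locus: LocusModel) -> tuple[int, int]:
    """Draw a loading position and head geometry avoiding occupied bins."""
    rng = state.rng
    free = state._occ < 0
    probs = locus.loading_prob * free
    total = probs.sum()
    if total <= 0:
        raise RuntimeError("no free bin with positive loading probability")
    probs = probs / total
    b = int(rng.choice(locus.n_bins, p=probs))
    if rng.random() < 0.5:
        return b, b  # heads co-located
    # adjacent heads: pick a free neighbouring bin, random side first
    sides = [1, -1] if rng.random() < 0.5 else [-1, 1]
    for side in sides:
        nb = b + side
        if state.periodic:
            if state._occ[nb % state.n_bins] < 0:
                return (b, nb) if side == 1 else (nb, b)
        elif 0 <= nb < state.n_bins and state._occ[nb] < 0:
            return (b, nb) if side == 1 else (nb, b)
    return b, b  # both neighbours blocked: fall back to co-located


def init_cohesin_system(locus: LocusModel, params: ExtrusionParams,
                        periodic: bool = False,
                        rng: np.random.Generator | None = None) -> ExtrusionState:
    """Place ``floor(L / separation)`` cohesins by the loading distribution.

    Each cohesin's heads are co-located or on adjacent bins with probability
    0.5 each.
    """
    n_cohesins = locus.n_bins // params.separation
    if n_cohesins < 1:
        raise ValueError(
            f"separation {params.separation} admits no cohesin on {locus.n_bins} bins"
        )
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    state = ExtrusionState(
        np.zeros((n_cohesins, 2), dtype=np.int64), locus.n_bins, rng, periodic
    )
    state._occ[:] = -1
    for cid in range(n_cohesins):
        lo, hi = _draw_load_site(state, locus)
        state._place_cohesin(cid, lo, hi)
    return state


def _try_move_head(state: ExtrusionState, locus: LocusModel, cid: int,
                   which: int) -> None:
    """Attempt to advance one head outward by one bin."""
    pos = int(state.cohesins[cid, which])
    direction = -1 if which == 0 else 1
    target = pos + direction
    if not state.periodic and not (0 <= target < state.n_bins):
        return  # reflecting fiber end
    target_bin = state._bin(target)
    occupant = state._occ[target_bin]
    if occupant >= 0:
        return  # blocked by a cohesin head (own or foreign)
    stall = (locus.forward_stall if direction == -1 else locus.reverse_stall)[target_bin]
    if stall > 0 and state.rng.random() < stall:
        return  # stalled by an opposing CBS; retried next step
    # vacate old bin unless the partner head still sits there
    partner = int(state.cohesins[cid, 1 - which])
    if state._bin(partner) != state._bin(pos):
        state._occ[state._bin(pos)] = -1
    state.cohesins[cid, which] = target
    state._occ[target_bin] = cid


def extrusion_step(state: ExtrusionState, locus: LocusModel,
                   params: ExtrusionParams) -> ExtrusionState:
    """Advance the extrusion system by one lattice step (in place)."""
    rng = state.rng
    n = len(state.cohesins)
    p_drop = min(1.0, 2.0 / params.processivity)
    state._frozen[:] = False
    drops = rng.random(n) < p_drop
    for cid in np.flatnonzero(drops):
        state._clear_cohesin(cid)
        lo, hi = _draw_load_site(state, locus)
        state._place_cohesin(cid, lo, hi)
        state._frozen[cid] = True
    heads = [(cid, w) for cid in range(n) if not state._frozen[cid] for w in (0, 1)]
    if heads:
        order = rng.permutation(len(heads))
        for idx in order:
            cid, which = heads[idx]
            _try_move_head(state, locus, cid, which)
    state.step_count += 1
    return state


def run_extrusion(locus: LocusModel, params: ExtrusionParams, n_steps: int,
                  record_every: int = 1, periodic: bool = False,
                  rng: np.random.Generator | None = None):
    """Run ``n_steps`` of extrusion, recording head pairs every ``record_every``.

    Returns ``(trajectory, state)`` where trajectory is a list of ``(n, 2)``
    arrays of head positions (after steps ``record_every, 2*record_every, ...``).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    state = init_cohesin_system(locus, params, periodic=periodic, rng=rng)
    trajectory = []
    for step in range(1, n_steps + 1):
        extrusion_step(state, locus, params)
        if step % record_every == 0:
            trajectory.append(state.snapshot())
    return trajectory, state
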