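"""Langevin dynamics of the coarse-grained chromatin fiber in reduced units.

The fiber is a chain of ``L`` monomers in a periodic cubic box of side
``(L / rho)^(1/3)`` at monomer density ``rho``. Monomer mass, diameter and
thermal energy are the units of mass, length and energy; the time unit is
``(sigma^2 m / k_B T)^(1/2)``. The force field combines a truncated purely
repulsive excluded-volume pair term, harmonic backbone and cohesin bonds, and
a bending stiffness ``2 (1 - cos(theta))``; chains may cross (no topological
constraint), as the repulsive barrier is finite.

The 3D dynamics is interleaved with the 1D lattice extrusion: per block one
lattice step updates the cohesin bond list, then a fixed number of Langevin
velocity-Verlet steps relaxes the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .extrusion_1d import ExtrusionParams, extrusion_step, init_cohesin_system
from .locus_model import LocusModel

__all__ = [
    "ReducedUnits",
    "ForceField",
    "Conformation",
    "ConformationEnsemble",
    "Schedule",
    "box_side",
    "init_compact_conformation",
    "compute_forces",
    "langevin_verlet_step",
    "simulate_ensemble",
]

_KB = 1.380649e-23  # J / K
_DALTON = 1.66053906660e-27  # kg


@dataclass(frozen=True)
class ReducedUnits:
    """Physical scales defining the reduced-unit system.

    Defaults: monomer mass 100 Da, diameter 1 nm, temperature 300 K, friction
    0.01 / ps. ``alpha_gamma`` is the dimensionless friction per reduced time
    unit entering the integrator.
    """

    mass_da: float = 100.0
    sigma_nm: float = 1.0
    temperature_k: float = 300.0
    gamma_per_ps: float = 0.01

    def __post_init__(self) -> None:
        if min(self.mass_da, self.sigma_nm, self.temperature_k) <= 0:
            raise ValueError("mass, sigma and temperature must be positive")
        if self.gamma_per_ps < 0:
            raise ValueError("friction must be nonnegative")

    @property
    def time_unit_ps(self) -> float:
        m = self.mass_da * _DALTON
        sigma = self.sigma_nm * 1e-9
        kbt = _KB * self.temperature_k
        return math.sqrt(sigma * sigma * m / kbt) / 1e-12

    @property
    def alpha_gamma(self) -> float:
        return self.gamma_per_ps * self.time_unit_ps


@dataclass(frozen=True)
class ForceField:
    """Reduced-unit force-field constants.

    ``rep_emin`` is the depth ``|min_{x>0} x^12 (x^2 - 1)| = 6^6 / 7^7`` of the
    untruncated pair polynomial; the repulsive term is truncated at
    ``r = rep_sigma`` where both energy and radial force vanish. ``force_cap``
    bounds the repulsive pair force so overlapping monomers from the lattice
    start do not blow up the integrator.
    """

    rep_e: float = 1.5
    rep_rmin: float = math.sqrt(6.0 / 7.0)
    rep_sigma: float = 1.05
    rep_emin: float = 46656.0 / 823543.0
    backbone_k: float = 100.0
    backbone_d: float = 1.0
    cohesin_k: float = 25.0
    cohesin_d: float = 0.5
    stiffness_amplitude: float = 2.0
    force_cap: float = 200.0


@dataclass
class Conformation:
    """Monomer positions/velocities (reduced units) in a periodic box."""

    positions: np.ndarray  # (L, 3)
    velocities: np.ndarray  # (L, 3)
    box: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must share an (L, 3) shape")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")


@dataclass
class ConformationEnsemble:
    """Sampled conformations (n_samples, L, 3) with optional weights."""

    positions: np.ndarray
    box: float
    weights: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class Schedule:
    """Annealing/sampling schedule of the interleaved 1D+3D simulation.

    The full-scale reference schedule anneals the lattice extrusion for 1e6
    steps, anneals the 3D dynamics for 2000 blocks of (1 lattice step + 1250
    MD steps), then samples one conformation per block for 50,000 blocks.
    Use :meth:`reduced` for desk-scale runs.
    """

    n_1d_anneal: int = 1_000_000
    n_3d_anneal_blocks: int = 2000
    steps_per_block: int = 1250
    n_sample_blocks: int = 50_000

    @classmethod
    def reduced(cls, n_1d_anneal: int = 20_000, n_3d_anneal_blocks: int = 200,
                steps_per_block: int = 40, n_sample_blocks: int = 2000) -> "Schedule":
        return cls(n_1d_anneal, n_3d_anneal_blocks, steps_per_block, n_sample_blocks)


def box_side(n_monomers: int, rho: float) -> float:
    """Periodic box side ``(L / rho)^(1/3)`` at monomer density ``rho``."""
    if rho <= 0:
        raise ValueError("density must be positive")
    return (n_monomers / rho) ** (1.0 / 3.0)


def init_compact_conformation(n_monomers: int, rho: float,
                              seed: int | np.random.Generator = 0) -> Conformation:
    """Compact start: a boustrophedon self-avoiding walk on a cubic lattice.

    Consecutive monomers sit at unit spacing; velocities follow the reduced
    Maxwell-Boltzmann law (unit variance per component).
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if not 0 < rho < 1:
        raise ValueError("density must lie in (0, 1)")
    box = box_side(n_monomers, rho)
    k = math.ceil(n_monomers ** (1.0 / 3.0))
    if k > box:
        raise ValueError("periodic box too small to host the compact lattice")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.empty((n_monomers, 3))
    i = 0
    for z in range(k):
        ys = range(k) if z % 2 == 0 else range(k - 1, -1, -1)
        for yi, y in enumerate(ys):
            serpentine_flip = (z * k + yi) % 2
            xs = range(k) if serpentine_flip == 0 else range(k - 1, -1, -1)
            for x in xs:
                if i < n_monomers:
                    pos[i] = (x + 0.5, y + 0.5, z + 0.5)
                    i += 1
    vel = rng.normal(0.0, 1.0, size=(n_monomers, 3))
    return Conformation(positions=pos, velocities=vel, box=box)


def _cohesin_bond_array(cohesins: np.ndarray, n_bins: int, periodic: bool) -> np.ndarray:
    if len(cohesins) == 0:
        return np.empty((0, 2), dtype=np.int64)
    bonds = np.mod(cohesins, n_bins) if periodic else cohesins
    return np.ascontiguousarray(bonds, dtype=np.int64)


def compute_forces(conf: Conformation, cohesin_bonds=None,
                   force_field: ForceField | None = None):
    """Per-monomer force vectors and total potential energy."""
    ff = force_field or ForceField()
    bonds = (np.asarray(cohesin_bonds, dtype=np.int64).reshape(-1, 2)
             if cohesin_bonds is not None and len(cohesin_bonds)
             else np.empty((0, 2), dtype=np.int64))
    f, pe = _kernels.forces_and_energy(
        conf.positions, conf.box, bonds,
        ff.rep_e, ff.rep_rmin, ff.rep_sigma, ff.rep_emin,
        ff.backbone_k, ff.backbone_d, ff.cohesin_k, ff.cohesin_d,
        ff.stiffness_amplitude, ff.force_cap,
    )
    return f, pe


def langevin_verlet_step(conf: Conformation, dt: float, alpha_gamma: float,
                         rng: np.random.Generator, cohesin_bonds=None,
                         force_field: ForceField | None = None,
                         forces: np.ndarray | None = None) -> np.ndarray:
    """One Langevin velocity-Verlet step (in place); returns the new forces.

    Scheme: ``v += (dt/2) f + b dW1``; ``r += c v`` (wrapped); recompute
    ``f(r)``; ``v = a v + b dW2 + (dt/2) f`` with
    ``a = (2 - ag dt)/(2 + ag dt)`` and ``c = 2 dt / (2 + ag dt)``. The kick
    amplitude ``b = sqrt(ag dt)`` is fixed by fluctuation-dissipation so the
    stationary velocity variance is the reduced temperature (1) per component.
    With ``alpha_gamma = 0`` this reduces to deterministic velocity Verlet.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ff = force_field or ForceField()
    bonds = (np.asarray(cohesin_bonds, dtype=np.int64).reshape(-1, 2)
             if cohesin_bonds is not None and len(cohesin_bonds)
             else np.empty((0, 2), dtype=np.int64))
    if forces is None:
        forces, _ = compute_forces(conf, bonds, ff)
    n = conf.positions.shape[0]
    if alpha_gamma > 0:
        noise1 = rng.normal(size=(1, n, 3))
        noise2 = rng.normal(size=(1, n, 3))
    else:
        noise1 = np.zeros((1, n, 3))
        noise2 = np.zeros((1, n, 3))
    f = np.ascontiguousarray(forces)
    f = _kernels.run_md_block(
        conf.positions, conf.velocities, f, conf.box, bonds, noise1, noise2,
        dt, alpha_gamma,
        ff.rep_e, ff.rep_rmin, ff.rep_sigma, ff.rep_emin,
        ff.backbone_k, ff.backbone_d, ff.cohesin_k, ff.cohesin_d,
        ff.stiffness_amplitude, ff.force_cap,
    )
    if not np.all(np.isfinite(conf.positions)):
        raise FloatingPointError(
            "integrator blow-up: non-finite positions (reduce dt or raise force_cap)"
        )
    return f


def simulate_ensemble(locus: LocusModel, ext_params: ExtrusionParams,
                      schedule: Schedule, force_field: ForceField | None = None,
                      rho: float = 0.2, dt: float = 0.05,
                      units: ReducedUnits | None = None,
                      seed: int = 0, periodic_fiber: bool = False) -> ConformationEnsemble:
    """Sample a conformation ensemble under interleaved 1D+3D dynamics.

    Runs ``n_1d_anneal`` lattice extrusion steps, then per block one lattice
    step (re-pointing cohesin bonds to the monomers hosting the heads) and
    ``steps_per_block`` MD steps; after ``n_3d_anneal_blocks`` warm-up blocks,
    one conformation is recorded per sampling block.
    """
    ff = force_field or ForceField()
    units = units or ReducedUnits()
    ag = units.alpha_gamma
    seq = np.random.SeedSequence(seed)
    rng_1d, rng_3d, rng_vel = (np.random.default_rng(s) for s in seq.spawn(3))

    state = init_cohesin_system(locus, ext_params, periodic=periodic_fiber, rng=rng_1d)
    for _ in range(schedule.n_1d_anneal):
        extrusion_step(state, locus, ext_params)

    conf = init_compact_conformation(locus.n_bins, rho, seed=rng_vel)
    n = locus.n_bins
    samples = np.empty((schedule.n_sample_blocks, n, 3))
    bonds = _cohesin_bond_array(state.cohesins, n, periodic_fiber)
    forces, _ = compute_forces(conf, bonds, ff)
    total_blocks = schedule.n_3d_anneal_blocks + schedule.n_sample_blocks
    for block in range(total_blocks):
        extrusion_step(state, locus, ext_params)
        bonds = _cohesin_bond_array(state.cohesins, n, periodic_fiber)
        # bonds were re-pointed: refresh forces before the first half-kick
        forces, _ = compute_forces(conf, bonds, ff)
        nsteps = schedule.steps_per_block
        noise1 = rng_3d.normal(size=(nsteps, n, 3))
        noise2 = rng_3d.normal(size=(nsteps, n, 3))
        forces = _kernels.run_md_block(
            conf.positions, conf.velocities, np.ascontiguousarray(forces),
            conf.box, bonds, noise1, noise2, dt, ag,
            ff.rep_e, ff.rep_rmin, ff.rep_sigma, ff.rep_emin,
            ff.backbone_k, ff.backbone_d, ff.cohesin_k, ff.cohesin_d,
            ff.stiffness_amplitude, ff.force_cap,
        )
        if not np.all(np.isfinite(conf.positions)):
            raise FloatingPointError(
                f"integrator blow-up in block {block} (reduce dt or raise force_cap)"
            )
        if block >= schedule.n_3d_anneal_blocks:
            samples[block - schedule.n_3d_anneal_blocks] = conf.positions
    return ConformationEnsemble(positions=samples, box=conf.box)
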