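"""Langevin-dynamics toy simulator on model potentials, and synthetic-data generators.

This module plays the role the all-atom force field and solvent model play in
a production MD study, at bead scale: a small "protein" (tethered anchor
beads forming a binding pocket, plus one mobile loop bead) and a "ligand"
(a core bead carrying three peripheral moiety beads) move under Langevin
dynamics on an analytic energy landscape whose unbinding coordinate has a
bound well, an optional metastable intermediate well, and a flat unbound
region.  Everything downstream — the ratchet bias, plateau detection, the
search protocol, contact analysis — is exercised against ground truth
planted here.

Also provided are direct fixture generators: multichannel time series with
planted plateaus (:func:`synth_series`) and bead trajectories with planted
atom-pair contact frequencies (:func:`synth_contact_trajectory`).

Units: kcal/mol, Angstrom, ps, amu, Kelvin.  The integrator is the BAOAB
splitting, which stays accurate in the strongly damped regime used here
(friction 60 ps^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_model import Atom, GroupConfig, Topology, Trajectory
from .units import ACC_CONVERSION, KB

__all__ = [
    "SimulationError",
    "LangevinParams",
    "LangevinState",
    "ToyPotential",
    "HarmonicWell",
    "DoubleWell1D",
    "FunnelRadial",
    "FlatBottomPair",
    "RelativeTether",
    "RadialDoubleWell",
    "RestraintSet",
    "flat_bottom_energy",
    "flat_bottom_force",
    "langevin_step",
    "run_langevin",
    "ToyLandscapeSpec",
    "ToyComplex",
    "make_toy_complex",
    "ContactPlanEntry",
    "synth_contact_trajectory",
    "synth_series",
]


class SimulationError(RuntimeError):
    """Raised when the dynamics produce a non-finite energy or force."""


# ---------------------------------------------------------------------------
# potential terms


def flat_bottom_energy(d, r_min: float, r_max: float, k: float):
    """Flat-bottom restraint energy: 0 in [r_min, r_max], half-harmonic outside.

    The functional form is the standard NOE-style flat-bottom harmonic:
    1/2*k*(d-r_max)^2 above the window, 1/2*k*(r_min-d)^2 below, continuous
    with continuous first derivative at both edges.
    """
    if k < 0:
        raise ValueError("flat-bottom restraint: k must be >= 0")
    if r_min > r_max:
        raise ValueError("flat-bottom restraint: R_min must be <= R_max")
    d = np.asarray(d, dtype=float)
    above = np.clip(d - r_max, 0.0, None)
    below = np.clip(r_min - d, 0.0, None)
    e = 0.5 * k * (above**2 + below**2)
    return float(e) if e.ndim == 0 else e


def flat_bottom_force(d, r_min: float, r_max: float, k: float):
    """Radial derivative dE/dd of :func:`flat_bottom_energy` (negated force)."""
    if k < 0:
        raise ValueError("flat-bottom restraint: k must be >= 0")
    d = np.asarray(d, dtype=float)
    g = k * (np.clip(d - r_max, 0.0, None) - np.clip(r_min - d, 0.0, None))
    return float(g) if g.ndim == 0 else g


class _Term:
    """A potential-energy term: adds its gradient in place, returns its energy."""

    def energy_and_grad(self, x: np.ndarray, grad: np.ndarray) -> float:
        raise NotImplementedError


@dataclass
class HarmonicWell(_Term):
    """Isotropic harmonic tether of one atom to a fixed point."""

    index: int
    center: np.ndarray
    k: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def energy_and_grad(self, x, grad):
        dr = x[self.index] - self.center
        grad[self.index] += self.k * dr
        return 0.5 * self.k * float(dr @ dr)


@dataclass
class DoubleWell1D(_Term):
    """Symmetric quartic double well on one Cartesian coordinate.

    V(q) = h * ((q - q0)^2 - b^2)^2 / b^4 has minima at q0 +/- b and a
    barrier of height h at q0.
    """

    index: int
    dim: int
    q0: float
    half_separation: float
    barrier: float

    def energy_and_grad(self, x, grad):
        b2 = self.half_separation**2
        q = x[self.index, self.dim] - self.q0
        u = q * q - b2
        grad[self.index, self.dim] += self.barrier * 4.0 * u * q / (b2 * b2)
        return self.barrier * u * u / (b2 * b2)

    def density(self, q_grid: np.ndarray, temperature: float) -> np.ndarray:
        """Normalized Boltzmann density on a grid (analytic reference)."""
        b2 = self.half_separation**2
        v = self.barrier * ((q_grid - self.q0) ** 2 - b2) ** 2 / (b2 * b2)
        p = np.exp(-v / (KB * temperature))
        return p / np.trapezoid(p, q_grid)


@dataclass
class FunnelRadial(_Term):
    """Harmonic confinement of atoms to an axis (the unbinding funnel)."""

    indices: tuple[int, ...]
    origin: np.ndarray
    axis: np.ndarray
    k: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        self.axis = a / np.linalg.norm(a)
        self._idx = np.asarray(self.indices, dtype=int)

    def energy_and_grad(self, x, grad):
        dr = x[self._idx] - self.origin
        proj = dr @ self.axis
        perp = dr - proj[:, None] * self.axis
        grad[self._idx] += self.k * perp
        return 0.5 * self.k * float((perp * perp).sum())


@dataclass
class FlatBottomPair(_Term):
    """Flat-bottom distance restraint between two atoms."""

    i: int
    j: int
    r_min: float
    r_max: float
    k: float

    def energy_and_grad(self, x, grad):
        dr = x[self.j] - x[self.i]
        d = float(np.linalg.norm(dr))
        if d < 1e-12:
            raise SimulationError(f"FlatBottomPair({self.i},{self.j}): coincident atoms")
        g = flat_bottom_force(d, self.r_min, self.r_max, self.k)
        u = dr / d
        grad[self.j] += g * u
        grad[self.i] -= g * u
        return flat_bottom_energy(d, self.r_min, self.r_max, self.k)


@dataclass
class RelativeTether(_Term):
    """Vector spring on (r_j - r_i - offset): fixes internal geometry and
    orientation of a bead cluster while leaving its translation free."""

    i: int
    j: int
    offset: np.ndarray
    k: float

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)

    def energy_and_grad(self, x, grad):
        dr = x[self.j] - x[self.i] - self.offset
        grad[self.j] += self.k * dr
        grad[self.i] -= self.k * dr
        return 0.5 * self.k * float(dr @ dr)


@dataclass
class HarmonicWellBlock(_Term):
    """Vectorized block of harmonic tethers (one array op for all anchors)."""

    indices: np.ndarray
    centers: np.ndarray
    ks: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        self.ks = np.asarray(self.ks, dtype=float)

    def energy_and_grad(self, x, grad):
        dr = x[self.indices] - self.centers
        kdr = self.ks[:, None] * dr
        grad[self.indices] += kdr
        return 0.5 * float((kdr * dr).sum())


@dataclass
class RelativeTetherBlock(_Term):
    """Vectorized block of lab-frame vector springs from one hub atom."""

    hub: int
    indices: np.ndarray
    offsets: np.ndarray
    ks: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.ks = np.asarray(self.ks, dtype=float)

    def energy_and_grad(self, x, grad):
        dr = x[self.indices] - x[self.hub] - self.offsets
        kdr = self.ks[:, None] * dr
        grad[self.indices] += kdr
        grad[self.hub] -= kdr.sum(axis=0)
        return 0.5 * float((kdr * dr).sum())


@dataclass
class RadialDoubleWell(_Term):
    """Unbinding landscape along the distance between two atoms.

    Two negative Gaussian wells (bound and, optionally, intermediate) plus a
    half-harmonic inner wall; the unbound region is asymptotically flat at
    zero energy, so the barrier tops sit above both well bottoms by
    construction.
    """

    i: int
    j: int
    bound_rho: float
    bound_depth: float
    intermediate_rho: float
    intermediate_depth: float
    width: float
    wall_rho: float
    wall_k: float = 25.0

    def profile(self, d):
        """Radial energy profile V(d) in kcal/mol."""
        d = np.asarray(d, dtype=float)
        w2 = 2.0 * self.width**2
        v = -self.bound_depth * np.exp(-((d - self.bound_rho) ** 2) / w2)
        if self.intermediate_depth > 0:
            v = v - self.intermediate_depth * np.exp(
                -((d - self.intermediate_rho) ** 2) / w2)
        v = v + 0.5 * self.wall_k * np.clip(self.wall_rho - d, 0.0, None) ** 2
        return float(v) if v.ndim == 0 else v

    def dprofile(self, d):
        d = np.asarray(d, dtype=float)
        w2 = self.width**2
        g = (self.bound_depth * (d - self.bound_rho) / w2
             * np.exp(-((d - self.bound_rho) ** 2) / (2 * w2)))
        if self.intermediate_depth > 0:
            g = g + (self.intermediate_depth * (d - self.intermediate_rho) / w2
                     * np.exp(-((d - self.intermediate_rho) ** 2) / (2 * w2)))
        g = g - self.wall_k * np.clip(self.wall_rho - d, 0.0, None)
        return float(g) if g.ndim == 0 else g

    def energy_and_grad(self, x, grad):
        from math import exp, sqrt

        dr = x[self.j] - x[self.i]
        d = sqrt(dr[0] * dr[0] + dr[1] * dr[1] + dr[2] * dr[2])
        if d < 1e-12:
            raise SimulationError(f"RadialDoubleWell({self.i},{self.j}): coincident atoms")
        # scalar fast path equivalent to profile()/dprofile()
        w2 = self.width * self.width
        ub = d - self.bound_rho
        eb = exp(-ub * ub / (2.0 * w2))
        e = -self.bound_depth * eb
        g = self.bound_depth * ub / w2 * eb
        if self.intermediate_depth > 0:
            ui = d - self.intermediate_rho
            ei = exp(-ui * ui / (2.0 * w2))
            e -= self.intermediate_depth * ei
            g += self.intermediate_depth * ui / w2 * ei
        if d < self.wall_rho:
            e += 0.5 * self.wall_k * (self.wall_rho - d) ** 2
            g -= self.wall_k * (self.wall_rho - d)
        gu = (g / d) * dr
        grad[self.j] += gu
        grad[self.i] -= gu
        return e


@dataclass
class ToyPotential:
    """Sum of analytic terms; exposes energy, gradient and force."""

    terms: list[_Term] = field(default_factory=list)

    def energy(self, x: np.ndarray) -> float:
        grad = np.zeros_like(x)
        return self.energy_and_gradient(x, grad)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        grad = np.zeros_like(x)
        self.energy_and_gradient(x, grad)
        return grad

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.gradient(x)

    def energy_and_gradient(self, x: np.ndarray, grad: np.ndarray) -> float:
        e = 0.0
        for term in self.terms:
            e += term.energy_and_grad(x, grad)
        if not np.isfinite(e) or not np.all(np.isfinite(grad)):
            for term in self.terms:  # identify the offender for the error message
                g = np.zeros_like(x)
                et = term.energy_and_grad(x, g)
                if not np.isfinite(et) or not np.all(np.isfinite(g)):
                    raise SimulationError(f"non-finite energy/force from term {term!r}")
            raise SimulationError("non-finite total energy/force")
        return e


@dataclass(frozen=True)
class RestraintSet:
    """Named set of flat-bottom pair restraints (NOE-style)."""

    restraints: tuple[FlatBottomPair, ...]

    def __post_init__(self):
        for r in self.restraints:
            if r.r_min > r.r_max or r.k < 0:
                raise ValueError("restraint requires R_min <= R_max and k >= 0")

    def as_terms(self) -> list[_Term]:
        return list(self.restraints)


# ---------------------------------------------------------------------------
# Langevin integration (BAOAB)


@dataclass
class LangevinParams:
    temperature: float = 300.0
    friction: float = 60.0  # ps^-1
    dt: float = 0.002  # ps
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class LangevinState:
    coords: np.ndarray
    velocities: np.ndarray
    force: np.ndarray | None = None
    rng: np.random.Generator | None = None
    step: int = 0


def maxwell_velocities(masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * ACC_CONVERSION / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def langevin_step(state: LangevinState, potential: ToyPotential,
                  params: LangevinParams, masses: np.ndarray,
                  external_force: Callable[[np.ndarray, int], np.ndarray] | None = None,
                  ) -> LangevinState:
    """Advance one BAOAB step in place and return the state.

    Deterministic given the state's RNG stream; with temperature 0 the O-step
    noise vanishes and with friction -> 0 the scheme reduces to velocity
    Verlet.
    """
    if state.rng is None:
        state.rng = np.random.default_rng(params.seed)
    x, v = state.coords, state.velocities
    m = masses[:, None]
    dt = params.dt
    c1 = np.exp(-params.friction * dt)
    sigma = np.sqrt((1.0 - c1 * c1) * KB * params.temperature * ACC_CONVERSION / masses)[:, None]

    def total_force(xx):
        f = potential.force(xx)
        if external_force is not None:
            f = f + external_force(xx, state.step)
        return f

    if state.force is None:
        state.force = total_force(x)
    # B
    v += 0.5 * dt * ACC_CONVERSION * state.force / m
    # A
    x += 0.5 * dt * v
    # O
    noise = state.rng.standard_normal(x.shape)
    v *= c1
    v += sigma * noise
    # A
    x += 0.5 * dt * v
    # B
    state.force = total_force(x)
    v += 0.5 * dt * ACC_CONVERSION * state.force / m
    state.step += 1
    return state


@dataclass
class RunResult:
    positions: np.ndarray  # (n_recorded, n_atoms, 3)
    times: np.ndarray  # ps, matching positions
    state: LangevinState
    record_every: int


def run_langevin(potential: ToyPotential, masses: np.ndarray,
                 params: LangevinParams, coords0: np.ndarray,
                 n_steps: int,
                 velocities0: np.ndarray | None = None,
                 external_force=None,
                 record_every: int = 1,
                 callback: Callable[[LangevinState], bool] | None = None,
                 rng: np.random.Generator | None = None) -> RunResult:
    """Integrate ``n_steps`` BAOAB steps, recording every ``record_every``-th frame.

    ``callback`` (called after each step) may return True to stop early.
    The initial frame is always recorded.
    """
    masses = np.asarray(masses, dtype=float)
    x = np.array(coords0, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if velocities0 is None:
        if params.temperature > 0:
            v = maxwell_velocities(masses, params.temperature, rng)
        else:
            v = np.zeros_like(x)
    else:
        v = np.array(velocities0, dtype=float)
    state = LangevinState(coords=x, velocities=v, rng=rng)
    recorded = [x.copy()]
    times = [0.0]
    # inlined BAOAB loop with precomputed constants (hot path); the
    # per-step algebra matches langevin_step exactly
    dt = params.dt
    half_dt = 0.5 * dt
    inv_m = ACC_CONVERSION / masses[:, None]
    c1 = np.exp(-params.friction * dt)
    sigma = np.sqrt((1.0 - c1 * c1) * KB * params.temperature
                    * ACC_CONVERSION / masses)[:, None]
    shape = x.shape
    normal = rng.standard_normal
    grad = np.empty_like(x)

    def total_force(xx, step):
        grad.fill(0.0)
        e = potential.energy_and_gradient(xx, grad)
        f = -grad
        if external_force is not None:
            f += external_force(xx, step)
        return f

    f = total_force(x, 0)
    for step in range(n_steps):
        v += half_dt * f * inv_m
        x += half_dt * v
        v *= c1
        v += sigma * normal(shape)
        x += half_dt * v
        f = total_force(x, step + 1)
        v += half_dt * f * inv_m
        state.step = step + 1
        if state.step % record_every == 0:
            recorded.append(x.copy())
            times.append(state.step * dt)
        if callback is not None and callback(state):
            if state.step % record_every != 0:
                recorded.append(x.copy())
                times.append(state.step * dt)
            break
    state.force = f
    return RunResult(positions=np.array(recorded), times=np.array(times),
                     state=state, record_every=record_every)


# ---------------------------------------------------------------------------
# the toy protein-ligand complex


@dataclass
class ToyLandscapeSpec:
    """Parameters of the toy unbinding landscape.

    Defaults place the bound well at rho=5 A and a metastable intermediate at
    rho=9 A (about 4 A outward, the displacement scale seen for a
    pocket-to-core distance between bound and intermediate states).  Depths
    are in kcal/mol at 300 K: the bound well (6.5, ~11 kT) is effectively
    inescapable without bias on the ns scale, the intermediate (3.2, ~5 kT)
    holds the ligand for hundreds of ps under a weak ratchet.
    """

    bound_rho: float = 5.0
    intermediate_rho: float = 9.0
    bound_depth: float = 6.0
    intermediate_depth: float = 4.0
    well_width: float = 0.6
    funnel_k: float = 2.0
    anchor_k: float = 20.0
    loop_k: float = 1.5
    ligand_bond_k: float = 10.0

    def __post_init__(self):
        if self.intermediate_depth > 0:
            if self.intermediate_rho <= self.bound_rho:
                raise ValueError("wells must be ordered bound < intermediate")
            if self.intermediate_rho - self.bound_rho < 3.0 * self.well_width:
                raise ValueError("overlapping wells: separation must exceed 3 widths")


@dataclass
class ToyComplex:
    topology: Topology
    potential: ToyPotential
    coords: np.ndarray  # bound-state coordinates
    masses: np.ndarray
    rc_pair: tuple[int, int]
    landscape: RadialDoubleWell
    spec: ToyLandscapeSpec
    kernel_spec: dict | None = None  # static arguments of the compiled kernel


@dataclass
class ToyRunResult:
    """Output of a (possibly biased) toy-complex run."""

    positions: np.ndarray  # recorded frames
    times: np.ndarray      # ps, per recorded frame
    rho: np.ndarray        # rc distance per integration step
    rho_max: np.ndarray
    bias_energy: np.ndarray  # kcal/mol per step
    final_coords: np.ndarray
    stopped_unbound: bool
    steps_done: int


def run_toy(system: "ToyComplex", params: LangevinParams, coords0: np.ndarray,
            n_steps: int, rng: np.random.Generator, record_every: int = 1,
            alpha: float = 0.0, rho_max0: float | None = None,
            unbound_rho: float = np.inf) -> ToyRunResult:
    """Langevin run of the toy complex with an optional ratchet bias.

    Uses the compiled kernel when numba is available, otherwise the generic
    integrator; both consume the same noise stream in the same order.
    ``alpha`` is in pN/Angstrom; ``rho_max0`` defaults to the starting rc
    distance so the bias is zero at t = 0.
    """
    from ._kernel import HAVE_NUMBA, baoab_toy
    from .units import alpha_to_kcal

    i, j = system.rc_pair
    x = np.array(coords0, dtype=float)
    d0 = float(np.linalg.norm(x[i] - x[j]))
    if d0 < 1e-9:
        raise ValueError("rc atoms are coincident in the starting frame")
    rho_max = max(rho_max0 if rho_max0 is not None else d0, d0)
    masses = system.masses
    if params.temperature > 0:
        v = maxwell_velocities(masses, params.temperature, rng)
    else:
        v = np.zeros_like(x)
    alpha_k = alpha_to_kcal(alpha)

    if HAVE_NUMBA and system.kernel_spec is not None:
        ks = system.kernel_spec
        dt = params.dt
        c1 = float(np.exp(-params.friction * dt))
        sigma = np.sqrt((1.0 - c1 * c1) * KB * params.temperature
                        * ACC_CONVERSION / masses)
        noise = rng.standard_normal((n_steps, len(masses), 3))
        n_rec_max = n_steps // record_every + 2
        frames = np.zeros((n_rec_max, len(masses), 3))
        frames[0] = x
        rho_tr = np.zeros(n_steps + 1)
        rhomax_tr = np.zeros(n_steps + 1)
        ebias_tr = np.zeros(n_steps + 1)
        rho_tr[0], rhomax_tr[0] = d0, rho_max
        steps, rec = baoab_toy(
            x, v, noise, dt, c1, sigma, ACC_CONVERSION / masses,
            ks["tether_idx"], ks["tether_c"], ks["tether_k"],
            ks["funnel_i"], ks["funnel_ox"], ks["funnel_oy"], ks["funnel_k"],
            ks["hub"], ks["rel_idx"], ks["rel_off"], ks["rel_k"],
            ks["rdw_i"], ks["rdw_j"], ks["rdw_brho"], ks["rdw_bd"],
            ks["rdw_irho"], ks["rdw_id"], ks["rdw_w"], ks["rdw_wall"],
            ks["rdw_wallk"],
            i, j, alpha_k, rho_max, unbound_rho,
            record_every, frames, rho_tr, rhomax_tr, ebias_tr)
        n_frames = rec + 1
        times = np.empty(n_frames)
        times[0] = 0.0
        full = np.arange(1, steps // record_every + 1) * (record_every * dt)
        times[1:1 + len(full)] = full
        if n_frames - 1 > len(full):  # early-stop extra frame
            times[-1] = steps * dt
        return ToyRunResult(
            positions=frames[:n_frames].copy(), times=times,
            rho=rho_tr[:steps + 1], rho_max=rhomax_tr[:steps + 1],
            bias_energy=ebias_tr[:steps + 1], final_coords=x.copy(),
            stopped_unbound=bool(rho_tr[steps] >= unbound_rho),
            steps_done=steps)

    # generic fallback: bias as external force, ratchet updated per step
    holder = {"rho_max": rho_max, "n": 0}
    n_atoms = len(masses)
    rho_tr = np.zeros(n_steps + 1)
    rhomax_tr = np.zeros(n_steps + 1)
    ebias_tr = np.zeros(n_steps + 1)
    rho_tr[0], rhomax_tr[0] = d0, rho_max

    def external_force(xx, step):
        f = np.zeros((n_atoms, 3))
        dr = xx[i] - xx[j]
        d = float(np.sqrt((dr * dr).sum()))
        gap = holder["rho_max"] - d
        if alpha_k > 0.0 and gap > 0.0:
            g = alpha_k * gap / d
            f[i] = g * dr
            f[j] = -g * dr
        return f

    def callback(state):
        xx = state.coords
        dr = xx[i] - xx[j]
        d = float(np.sqrt((dr * dr).sum()))
        holder["rho_max"] = max(holder["rho_max"], d)
        n = state.step
        rho_tr[n] = d
        rhomax_tr[n] = holder["rho_max"]
        gap = holder["rho_max"] - d
        ebias_tr[n] = 0.5 * alpha_k * gap * gap if gap > 0 else 0.0
        holder["n"] = n
        return d >= unbound_rho

    result = run_langevin(system.potential, masses, params, x, n_steps,
                          velocities0=v, external_force=external_force,
                          record_every=record_every, callback=callback,
                          rng=rng)
    n = holder["n"]
    return ToyRunResult(
        positions=result.positions, times=result.times,
        rho=rho_tr[:n + 1], rho_max=rhomax_tr[:n + 1],
        bias_energy=ebias_tr[:n + 1], final_coords=result.state.coords.copy(),
        stopped_unbound=bool(rho_tr[n] >= unbound_rho), steps_done=n)


def _toy_atoms() -> list[Atom]:
    prot = [
        Atom(1, "CA", "C", 60.0, 5, "GLU"),
        Atom(2, "CA", "C", 60.0, 54, "GLU"),
        Atom(3, "CA", "C", 60.0, 56, "ILE"),
        Atom(4, "CA", "C", 60.0, 82, "TYR"),
        Atom(5, "CA", "C", 60.0, 89, "GLY"),
    ]
    lig = [
        Atom(6, "C1", "C", 60.0, 200, "LIG"),
        Atom(7, "C2", "C", 50.0, 200, "LIG"),
        Atom(8, "C3", "C", 70.0, 200, "LIG"),
        Atom(9, "C4", "C", 30.0, 200, "LIG"),
    ]
    return prot + lig


def make_toy_complex(spec: ToyLandscapeSpec | None = None) -> ToyComplex:
    """Build the toy protein-ligand complex on the requested landscape.

    The pocket is four anchored beads arranged symmetrically about the z
    axis (plus one weakly tethered mobile "loop" bead); the ligand is a core
    bead carrying three moiety beads held semi-rigidly.  The reaction
    coordinate is the core-to-anchor distance along z.  The planted well
    positions are verified by local minimization of the radial profile.
    """
    from scipy.optimize import minimize_scalar

    spec = spec if spec is not None else ToyLandscapeSpec()
    atoms = _toy_atoms()
    # protein bead positions: P1 on the axis, P2-P4 a symmetric ring, loop bead off-axis
    ring_r, ring_z = 2.5, 1.0
    positions = np.array([
        [0.0, 0.0, 0.0],                                         # P1 (rc anchor)
        [ring_r * np.cos(np.pi / 2), ring_r * np.sin(np.pi / 2), ring_z],
        [ring_r * np.cos(7 * np.pi / 6), ring_r * np.sin(7 * np.pi / 6), ring_z],
        [ring_r * np.cos(11 * np.pi / 6), ring_r * np.sin(11 * np.pi / 6), ring_z],
        [4.0, 0.0, 1.5],                                         # mobile loop bead
        [0.0, 0.0, spec.bound_rho],                              # ligand core
        [1.8, 0.0, spec.bound_rho + 0.6],                        # iBu analogue
        [-0.9, 1.56, spec.bound_rho + 0.6],                      # Tol analogue
        [-0.9, -1.56, spec.bound_rho + 0.6],                     # Ethe analogue
    ])
    core, ibu, tol, eth = 5, 6, 7, 8
    landscape = RadialDoubleWell(
        i=0, j=core,
        bound_rho=spec.bound_rho, bound_depth=spec.bound_depth,
        intermediate_rho=spec.intermediate_rho,
        intermediate_depth=spec.intermediate_depth,
        width=spec.well_width, wall_rho=spec.bound_rho - 1.5)
    terms: list[_Term] = [landscape]
    terms.append(HarmonicWellBlock(
        indices=np.arange(5), centers=positions[:5].copy(),
        ks=np.array([spec.anchor_k] * 4 + [spec.loop_k])))
    terms.append(FunnelRadial((core,), positions[0].copy(), np.array([0.0, 0.0, 1.0]),
                              spec.funnel_k))
    terms.append(RelativeTetherBlock(
        hub=core, indices=np.array([ibu, tol, eth]),
        offsets=positions[[ibu, tol, eth]] - positions[core],
        ks=np.full(3, spec.ligand_bond_k)))
    potential = ToyPotential(terms)

    # verify planted minima by local minimization of the radial profile
    lo = minimize_scalar(landscape.profile,
                         bounds=(spec.bound_rho - 1.0, spec.bound_rho + 1.0),
                         method="bounded")
    if abs(lo.x - spec.bound_rho) > 1e-3:
        raise ValueError(f"bound-well minimum off target: {lo.x:.4f}")
    if spec.intermediate_depth > 0:
        li = minimize_scalar(landscape.profile,
                             bounds=(spec.intermediate_rho - 1.0,
                                     spec.intermediate_rho + 1.0),
                             method="bounded")
        if abs(li.x - spec.intermediate_rho) > 1e-3:
            raise ValueError(f"intermediate-well minimum off target: {li.x:.4f}")

    groups = {
        "core": (core,), "iBu": (ibu,), "Tol": (tol,), "Ethe": (eth,),
        "pocket": (0, 1, 2, 3),
        "80s_loop": (4,), "loop_tip": (4,),
        "nonloop": (0, 1, 2, 3),
        "calpha": (0, 1, 2, 3, 4),
        "protein": (0, 1, 2, 3, 4),
        "ligand": (core, ibu, tol, eth),
        "solvent": (),
    }
    topology = Topology(atoms=atoms, groups=groups)
    kernel_spec = {
        "tether_idx": np.arange(5), "tether_c": positions[:5].copy(),
        "tether_k": np.array([spec.anchor_k] * 4 + [spec.loop_k]),
        "funnel_i": core, "funnel_ox": 0.0, "funnel_oy": 0.0,
        "funnel_k": spec.funnel_k,
        "hub": core, "rel_idx": np.array([ibu, tol, eth]),
        "rel_off": positions[[ibu, tol, eth]] - positions[core],
        "rel_k": np.full(3, spec.ligand_bond_k),
        "rdw_i": 0, "rdw_j": core, "rdw_brho": spec.bound_rho,
        "rdw_bd": spec.bound_depth, "rdw_irho": spec.intermediate_rho,
        "rdw_id": spec.intermediate_depth, "rdw_w": spec.well_width,
        "rdw_wall": spec.bound_rho - 1.5, "rdw_wallk": landscape.wall_k,
    }
    return ToyComplex(topology=topology, potential=potential,
                      coords=positions, masses=topology.masses,
                      rc_pair=(core, 0), landscape=landscape, spec=spec,
                      kernel_spec=kernel_spec)


def toy_group_config() -> GroupConfig:
    """GroupConfig whose selectors resolve against the toy complex topology."""
    return GroupConfig(
        reaction_coordinate=("LIG 200 C1", "GLU 5 CA"),
        pocket_residues=[5, 54, 56, 82],
        moiety_definitions={
            "core": ["LIG 200 C1"], "iBu": ["LIG 200 C2"],
            "Tol": ["LIG 200 C3"], "Ethe": ["LIG 200 C4"],
        },
        region_definitions={"80s_loop": ["GLY 89 CA"], "loop_tip": ["GLY 89 CA"]},
        ligand_resnames=["LIG"],
    )


# ---------------------------------------------------------------------------
# fixture generators


@dataclass
class ContactPlanEntry:
    """One planted ligand-protein atom pair with a target contact frequency."""

    frequency: float
    mean: float  # Angstrom, in-contact mean distance
    sd: float
    moiety: str = "core"
    residue_name: str = "VAL"
    residue_number: int = 55

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("contact frequency must be in [0, 1]")


def _normalize_plan(plan: Sequence) -> list[ContactPlanEntry]:
    out = []
    for entry in plan:
        if isinstance(entry, ContactPlanEntry):
            out.append(entry)
        else:
            freq, mean, sd = entry[:3]
            out.append(ContactPlanEntry(frequency=freq, mean=mean, sd=sd))
    return out


def synth_contact_trajectory(plan: Sequence, n_frames: int, seed: int,
                             dt: float = 1.0, cutoff: float = 4.0) -> Trajectory:
    """Generate a bead trajectory with planted per-pair contact statistics.

    Each plan entry becomes a (ligand atom, protein atom) pair laid out on
    its own well-separated lane; frame-by-frame the pair is in contact with
    the planted Bernoulli frequency, with in-contact distances drawn from a
    Gaussian of the planted mean/SD (truncated below the cutoff) and
    out-of-contact distances safely beyond it.
    """
    entries = _normalize_plan(plan)
    for e in entries:
        if e.frequency > 0 and e.mean >= cutoff:
            raise ValueError(
                f"infeasible plan: mean {e.mean} A >= cutoff with frequency {e.frequency}")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    groups: dict[str, set[int]] = {}
    n_pairs = len(entries)
    coords = np.zeros((n_frames, 2 * n_pairs, 3))
    for k, e in enumerate(entries):
        li, pi = 2 * k, 2 * k + 1
        atoms.append(Atom(li + 1, f"L{k}", "C", 12.011, 200, "LIG"))
        atoms.append(Atom(pi + 1, f"P{k}", "C", 12.011, e.residue_number,
                          e.residue_name))
        groups.setdefault(e.moiety, set()).add(li)
        groups.setdefault("ligand", set()).add(li)
        groups.setdefault("protein", set()).add(pi)
        lane_y = 100.0 * k
        in_contact = rng.random(n_frames) < e.frequency
        d = np.empty(n_frames)
        if e.frequency > 0:
            if e.sd > 0:
                dc = rng.normal(e.mean, e.sd, size=n_frames)
                # truncate below the cutoff so planted contacts stay contacts
                bad = dc >= cutoff
                while np.any(bad):
                    dc[bad] = rng.normal(e.mean, e.sd, size=int(bad.sum()))
                    bad = dc >= cutoff
            else:
                dc = np.full(n_frames, e.mean)
        else:
            dc = np.zeros(n_frames)
        far_mean = max(e.mean + 3.0, cutoff + 2.0)
        df = np.abs(rng.normal(far_mean, 0.3, size=n_frames))
        df = np.clip(df, cutoff + 0.05, None)
        d[in_contact] = dc[in_contact]
        d[~in_contact] = df[~in_contact]
        coords[:, li] = [0.0, lane_y, 0.0]
        coords[:, pi, 0] = d
        coords[:, pi, 1] = lane_y
    topo = Topology(atoms=atoms,
                    groups={k: tuple(sorted(v)) for k, v in groups.items()})
    topo.groups.setdefault("solvent", ())
    return Trajectory(topology=topo, frames=coords, dt=dt)


def synth_series(plateaus: Sequence[tuple], total: float, dt: float,
                 seed: int = 0, edge_slope: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Generate multichannel time traces with planted plateaus.

    ``plateaus`` is a list of ``(start_ps, end_ps, level, noise_sd)``; the
    level may be a scalar (one channel) or a sequence (one level per
    channel).  Between plateaus the series ramps linearly from one level to
    the next; outside the first/last plateau it drifts away at
    ``edge_slope`` A/ps so that only the planted intervals are stable.

    Returns ``(times, series)`` with ``series`` of shape (n_frames, n_channels).
    """
    if not plateaus:
        raise ValueError("at least one plateau is required")
    plat = sorted(plateaus, key=lambda p: p[0])
    for (s1, e1, *_), (s2, e2, *_) in zip(plat, plat[1:]):
        if e1 > s2:
            raise ValueError("plateau intervals overlap")
    for s, e, *_ in plat:
        if s < 0 or e > total or e <= s:
            raise ValueError("plateau interval outside [0, total]")
    levels = [np.atleast_1d(np.asarray(p[2], dtype=float)) for p in plat]
    n_channels = len(levels[0])
    if any(len(l) != n_channels for l in levels):
        raise ValueError("all plateaus must have the same number of channels")
    noises = [float(p[3]) if len(p) > 3 else 0.0 for p in plat]

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, total + 0.5 * dt, dt)
    series = np.empty((len(times), n_channels))
    for c in range(n_channels):
        y = np.empty(len(times))
        for ti, t in enumerate(times):
            k = next((j for j, p in enumerate(plat) if p[0] <= t <= p[1]), None)
            if k is not None:
                y[ti] = levels[k][c]
            elif t < plat[0][0]:
                y[ti] = levels[0][c] + edge_slope * (plat[0][0] - t)
            elif t > plat[-1][1]:
                y[ti] = levels[-1][c] + edge_slope * (t - plat[-1][1])
            else:
                j = next(j for j, p in enumerate(plat) if t < p[0]) - 1
                s_prev, e_prev = plat[j][1], plat[j + 1][0]
                frac = (t - s_prev) / (e_prev - s_prev)
                y[ti] = levels[j][c] + frac * (levels[j + 1][c] - levels[j][c])
        series[:, c] = y
    # per-frame noise, drawn channel-major for seed determinism
    for c in range(n_channels):
        for ti, t in enumerate(times):
            k = next((j for j, p in enumerate(plat) if p[0] <= t <= p[1]), None)
            sd = noises[k] if k is not None else (noises[0] if noises else 0.0)
            if sd > 0:
                series[ti, c] += rng.normal(0.0, sd)
    return times, series
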