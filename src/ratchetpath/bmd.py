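"""Biased Molecular Dynamics: the ratchet-and-pawl bias and its force schedule.

The bias acts on one reaction-coordinate (rc) distance rho between a ligand
anchor atom and a protein anchor atom.  A half-quadratic penalty
1/2*alpha*(rho_max - rho)^2 is applied only while rho sits below the largest
value rho_max it has reached; whenever rho exceeds rho_max, no perturbation
is applied and rho_max advances to the new value.  The ratchet therefore
never pushes the ligand out directly — it converts spontaneous outward
fluctuations into irreversible progress, which is why it perturbs the
dynamics far less than a pulling force.

alpha is quoted in pN/Angstrom as is conventional for this bias and
converted to kcal/mol/Angstrom^2 internally.  The schedule starts at
300 pN/Angstrom (strong enough to unbind within the run limit) and is
lowered in steps of 25 within the range 50-250 to extend the lifetime of
metastable states encountered on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_model import Trajectory
from .toysim import LangevinParams, ToyComplex, run_langevin
from .units import alpha_to_kcal

__all__ = [
    "ScheduleExhausted",
    "BiasState",
    "bias_energy",
    "bias_force_magnitude",
    "update_rho_max",
    "next_alpha",
    "ALPHA_INITIAL",
    "ALPHA_STEP",
    "ALPHA_MIN",
    "ALPHA_MAX_STEP2",
    "BMDResult",
    "run_bmd",
]

#: Bias schedule (pN/Angstrom): initial value, decrement, and allowed range
#: for the lifetime-extension stage.
ALPHA_INITIAL = 300.0
ALPHA_STEP = 25.0
ALPHA_MIN = 50.0
ALPHA_MAX_STEP2 = 250.0


class ScheduleExhausted(Exception):
    """The alpha schedule has reached its lower bound."""


@dataclass
class BiasState:
    """Ratchet state: rc atom pair, running maximum rho_max, and alpha."""

    rc_atoms: tuple[int, int]
    rho_max: float
    alpha: float  # pN/Angstrom

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def bias_energy(rho: float, rho_max: float, alpha: float) -> float:
    """Ratchet bias energy in kcal/mol; exactly 0 whenever rho >= rho_max."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if rho >= rho_max:
        return 0.0
    return 0.5 * alpha_to_kcal(alpha) * (rho_max - rho) ** 2


def bias_force_magnitude(rho: float, rho_max: float, alpha: float) -> float:
    """Outward force magnitude (kcal/mol/Angstrom) along the rc separation."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if rho >= rho_max:
        return 0.0
    return alpha_to_kcal(alpha) * (rho_max - rho)


def update_rho_max(rho: float, state: BiasState) -> BiasState:
    """Advance the ratchet: rho_max becomes max(rho_max, rho)."""
    return replace(state, rho_max=max(state.rho_max, rho))


def next_alpha(alpha: float) -> float:
    """Step the schedule down by 25 pN/Angstrom within [50, 250].

    From the initial 300 the first lowered value is 250 (the top of the
    allowed range).  At 50 the schedule is exhausted.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if alpha <= ALPHA_MIN:
        raise ScheduleExhausted(f"alpha schedule exhausted at {alpha} pN/A")
    return max(ALPHA_MIN, min(alpha - ALPHA_STEP, ALPHA_MAX_STEP2))


@dataclass
class BMDResult:
    trajectory: Trajectory
    times: np.ndarray       # ps, one entry per integration step
    rho: np.ndarray         # rc distance per step
    rho_max: np.ndarray     # running maximum per step
    bias_energy: np.ndarray  # kcal/mol per step
    final_state: BiasState
    stopped_unbound: bool
    final_coords: np.ndarray


def run_bmd(system: ToyComplex, params: LangevinParams, bias: BiasState,
            time_limit: float, unbound_rho: float,
            coords0: np.ndarray | None = None,
            record_every: int = 25,
            rng: np.random.Generator | None = None) -> BMDResult:
    """Run ratchet-biased Langevin dynamics until unbinding or the time limit.

    The bias force acts only on the two rc atoms, applied equally and
    oppositely along their separation vector.  With alpha = 0 the run is
    bit-identical to an unbiased run at the same seed (the bias contributes
    exact zeros and draws no randomness).  rho_max is initialized at the
    starting frame's rc distance so the bias is zero at t = 0, and is
    updated once per step from the post-step coordinates.
    """
    from .toysim import run_toy

    x0 = np.array(coords0 if coords0 is not None else system.coords, dtype=float)
    if bias.rc_atoms != system.rc_pair:
        raise ValueError("bias rc atoms do not match the system rc pair")
    n_steps = int(round(time_limit / params.dt))
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    result = run_toy(system, params, x0, n_steps, rng,
                     record_every=record_every, alpha=bias.alpha,
                     rho_max0=bias.rho_max if bias.rho_max > 0 else None,
                     unbound_rho=unbound_rho)
    n = result.steps_done
    traj = Trajectory(topology=system.topology, frames=result.positions,
                      dt=params.dt * record_every)
    final = BiasState(rc_atoms=bias.rc_atoms,
                      rho_max=float(result.rho_max[n]), alpha=bias.alpha)
    return BMDResult(
        trajectory=traj,
        times=np.arange(n + 1) * params.dt,
        rho=result.rho,
        rho_max=result.rho_max,
        bias_energy=result.bias_energy,
        final_state=final,
        stopped_unbound=result.stopped_unbound,
        final_coords=result.final_coords,
    )
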