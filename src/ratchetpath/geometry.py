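"""Superposition-based RMSD (alignments A1/A2), COM distances, RMSF, series summaries.

Two alignment modes are used throughout the analysis.  A1 superposes all
C-alpha (here: all fit-set) atoms onto their reference positions; A2
superposes all of them *except* a chosen group G, so that the RMSD of G then
measures its displacement relative to the rest of the structure (e.g. the
distortion of a mobile loop).  Superposition uses the Kabsch/quaternion
closed form via scipy, constrained to proper rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .io_model import Topology, Trajectory

__all__ = [
    "AlignmentSpec",
    "SeriesSummary",
    "superpose",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "com",
    "com_distance",
    "rmsf",
    "summarize_series",
]


@dataclass(frozen=True)
class AlignmentSpec:
    """Which atoms to fit and which to measure.

    ``mode`` "A1" fits on ``fit_group``; "A2" fits on ``fit_group`` minus
    ``excluded_group`` (G), whose displacement the measured RMSD then
    reports.  ``measure_group`` defaults to the excluded group for A2 and to
    the fit group for A1.
    """

    mode: str = "A1"
    fit_group: str = "calpha"
    excluded_group: str | None = None
    measure_group: str | None = None

    def __post_init__(self):
        if self.mode not in ("A1", "A2"):
            raise ValueError("alignment mode must be 'A1' or 'A2'")
        if self.mode == "A2" and not self.excluded_group:
            raise ValueError("A2 alignment requires an excluded group G")

    def resolve(self, topology: Topology) -> tuple[list[int], list[int]]:
        fit = list(topology.group(self.fit_group))
        if self.mode == "A2":
            excl = set(topology.group(self.excluded_group))
            if not excl:
                raise ValueError("A2 excluded group is empty")
            fit = [i for i in fit if i not in excl]
        measure_name = self.measure_group or (
            self.excluded_group if self.mode == "A2" else self.fit_group)
        measure = list(topology.group(measure_name))
        if not measure:
            raise ValueError(f"measure group {measure_name!r} is empty")
        if len(fit) < 3:
            raise ValueError("fit set must contain at least 3 atoms")
        return fit, measure


def _check_non_degenerate(x: np.ndarray) -> None:
    if len(x) < 3:
        raise ValueError("superposition requires at least 3 fit atoms")
    c = x - x.mean(axis=0)
    # rank < 2 means collinear (or coincident) points: rotation underdetermined
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear or coincident")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              fit_atoms: Sequence[int] | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fit_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the fit
    atoms.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = list(fit_atoms) if fit_atoms is not None else list(range(len(mobile)))
    mob = mobile[idx]
    ref = reference[idx]
    _check_non_degenerate(mob)
    _check_non_degenerate(ref)
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - mob_c @ R.T
    fitted = mob @ R.T + t
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, fit_rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd(frame: np.ndarray, reference: np.ndarray, spec: AlignmentSpec,
         topology: Topology) -> float:
    """RMSD of the spec's measure group after superposing on its fit set."""
    fit, measure = spec.resolve(topology)
    R, t, _ = superpose(frame, reference, fit)
    moved = apply_transform(frame[measure], R, t)
    return float(np.sqrt(np.mean(np.sum((moved - reference[measure]) ** 2, axis=1))))


def rmsd_series(trajectory: Trajectory, reference: np.ndarray,
                spec: AlignmentSpec) -> np.ndarray:
    """Per-frame RMSD trace for one alignment spec."""
    return np.array([rmsd(f, reference, spec, trajectory.topology)
                     for f in trajectory.frames])


def com(coords: np.ndarray, indices: Sequence[int], masses: np.ndarray) -> np.ndarray:
    idx = list(indices)
    if not idx:
        raise ValueError("group is empty")
    m = np.asarray(masses, dtype=float)[idx]
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    return (np.asarray(coords, dtype=float)[idx] * m[:, None]).sum(axis=0) / m.sum()


def com_distance(frame: np.ndarray, group_a: Sequence[int],
                 group_b: Sequence[int], masses: np.ndarray) -> float:
    """Distance between the mass-weighted centroids of two groups (Angstrom)."""
    return float(np.linalg.norm(com(frame, group_a, masses)
                                - com(frame, group_b, masses)))


def rmsf(trajectory: Trajectory, selection: Sequence[int],
         alignment: AlignmentSpec | None = None,
         reference: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Each frame is first superposed onto the reference (the first frame by
    default) over the alignment's fit set; with no alignment the raw frames
    are used, which is only meaningful for tethered systems.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    sel = list(selection)
    ref = reference if reference is not None else trajectory.frames[0]
    if alignment is not None:
        fit, _ = alignment.resolve(trajectory.topology)
        frames = np.empty((trajectory.n_frames, len(sel), 3))
        for fi, frame in enumerate(trajectory.frames):
            R, t, _ = superpose(frame, ref, fit)
            frames[fi] = apply_transform(frame[sel], R, t)
    else:
        frames = trajectory.frames[:, sel]
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


@dataclass(frozen=True)
class SeriesSummary:
    """Within- and across-simulation statistics of a monitored series.

    ``fluctuation`` is the (pooled) within-simulation sample SD; ``ensemble_sd``
    the sample SD of the per-simulation means across simulations (0 for a
    single simulation).  Sample (n-1) SDs are used throughout: the ensembles
    are small.
    """

    mean: float
    sd: float
    fluctuation: float
    ensemble_sd: float


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_series(series_per_simulation: Sequence[np.ndarray]) -> SeriesSummary:
    """Summarize one monitored quantity over one or more simulations."""
    series = [np.asarray(s, dtype=float) for s in series_per_simulation]
    if not series:
        raise ValueError("at least one simulation is required")
    pooled = np.concatenate(series)
    per_sim_means = np.array([s.mean() for s in series])
    within = [np.std(s, ddof=1) for s in series if len(s) > 1]
    fluctuation = float(np.sqrt(np.mean(np.square(within)))) if within else 0.0
    return SeriesSummary(
        mean=float(pooled.mean()),
        sd=_sample_sd(pooled),
        fluctuation=fluctuation,
        ensemble_sd=_sample_sd(per_sim_means) if len(series) > 1 else 0.0,
    )
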