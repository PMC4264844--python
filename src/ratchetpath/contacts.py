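"""Contact census and classification, moiety-residue contact maps, bridging
waters, and hydrogen-bond geometry.

Conventions (tested at the boundaries): an atom pair is *in contact* on a
frame iff its distance is strictly below the 4 Angstrom cutoff; a pair is a
*candidate* contact iff its contact frequency strictly exceeds 0.5 in at
least one simulation; a candidate is *permanent* iff it is in contact in
every frame of every simulation and its pooled distance SD is below
0.25 Angstrom — otherwise it is *transient*.  The census uses heavy atoms
only (hydrogens enter only through the explicit H-bond geometry analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_model import Topology, Trajectory

__all__ = [
    "ContactRecord",
    "ContactMap",
    "HBondGeometry",
    "CONTACT_CUTOFF",
    "MIN_FREQUENCY",
    "PERMANENT_SD",
    "candidate_contacts",
    "classify",
    "contact_map",
    "bridging_waters",
    "water_bin_label",
    "hbond_stats",
]

CONTACT_CUTOFF = 4.0   # Angstrom, strict '<'
MIN_FREQUENCY = 0.5    # fraction of frames, strict '>'
PERMANENT_SD = 0.25    # Angstrom, strict '<'


@dataclass
class ContactRecord:
    """Distance statistics for one (ligand atom, protein atom) pair."""

    ligand_index: int
    protein_index: int
    frequencies: tuple[float, ...]  # one per simulation
    pooled_mean: float
    pooled_sd: float
    all_frames_in_contact: bool
    contact_class: str = "transient"  # 'permanent' | 'transient'

    @property
    def pair_label(self) -> tuple[int, int]:
        return (self.ligand_index, self.protein_index)


@dataclass
class ContactMap:
    """Ensemble-average contact counts per (ligand group, protein residue)."""

    row_names: list[str]
    residue_labels: list[str]
    counts: np.ndarray        # (n_rows, n_residues) ensemble average
    water_counts: np.ndarray | None = None  # same layout, bridging waters


@dataclass(frozen=True)
class HBondGeometry:
    donor: int
    hydrogen: int
    acceptor: int
    mean_distance: float  # H...A, Angstrom
    sd_distance: float
    mean_angle: float     # D-H...A, degrees
    sd_angle: float
    formed: bool


def _is_heavy(topology: Topology, index: int) -> bool:
    el = (topology.atoms[index].element or topology.atoms[index].name[:1]).upper()
    return el != "H"


def _pair_distances(traj: Trajectory, ligand: Sequence[int],
                    protein: Sequence[int]) -> np.ndarray:
    """Distances of all ligand x protein pairs, shape (n_frames, n_lig, n_prot)."""
    lc = traj.frames[:, list(ligand)]
    pc = traj.frames[:, list(protein)]
    diff = lc[:, :, None, :] - pc[:, None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def candidate_contacts(trajectories: Sequence[Trajectory],
                       ligand_atoms: Sequence[int],
                       protein_atoms: Sequence[int],
                       cutoff: float = CONTACT_CUTOFF,
                       min_freq: float = MIN_FREQUENCY,
                       heavy_only: bool = True) -> list[ContactRecord]:
    """Census of candidate contacts over a set of simulations.

    A pair is retained iff its per-simulation contact frequency exceeds
    ``min_freq`` (strict) in at least one simulation.  Distance statistics
    are pooled over all frames of all simulations.  Records are returned
    already classified (see :func:`classify`).
    """
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    topo = trajectories[0].topology
    ligand = [i for i in ligand_atoms if not heavy_only or _is_heavy(topo, i)]
    protein = [i for i in protein_atoms if not heavy_only or _is_heavy(topo, i)]
    if not ligand or not protein:
        raise ValueError("empty ligand or protein atom set")

    per_sim_freq = []
    all_d = []
    for traj in trajectories:
        d = _pair_distances(traj, ligand, protein)
        per_sim_freq.append((d < cutoff).mean(axis=0))
        all_d.append(d)
    freq = np.stack(per_sim_freq)          # (n_sims, n_lig, n_prot)
    pooled = np.concatenate(all_d, axis=0)  # (total_frames, n_lig, n_prot)

    records = []
    keep = (freq > min_freq).any(axis=0)
    for li in range(len(ligand)):
        for pi in range(len(protein)):
            if not keep[li, pi]:
                continue
            dist = pooled[:, li, pi]
            rec = ContactRecord(
                ligand_index=ligand[li],
                protein_index=protein[pi],
                frequencies=tuple(float(f) for f in freq[:, li, pi]),
                pooled_mean=float(dist.mean()),
                pooled_sd=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
                all_frames_in_contact=bool(np.all(dist < cutoff)),
            )
            rec.contact_class = classify(rec)
            records.append(rec)
    records.sort(key=lambda r: (r.ligand_index, r.protein_index))
    return records


def classify(record: ContactRecord, sd_threshold: float = PERMANENT_SD) -> str:
    """'permanent' iff in contact on every frame of every simulation with
    pooled distance SD strictly below the threshold; else 'transient'."""
    if record.all_frames_in_contact and record.pooled_sd < sd_threshold:
        return "permanent"
    return "transient"


def _residue_groups(topology: Topology, protein_atoms: Sequence[int]
                    ) -> tuple[list[str], list[list[int]]]:
    labels: list[str] = []
    members: list[list[int]] = []
    seen: dict[tuple[str, int], int] = {}
    for i in protein_atoms:
        a = topology.atoms[i]
        key = (a.residue_name, a.residue_number)
        if key not in seen:
            seen[key] = len(labels)
            labels.append(f"{a.residue_name}{a.residue_number}")
            members.append([])
        members[seen[key]].append(i)
    return labels, members


def contact_map(trajectories: Sequence[Trajectory],
                row_groups: dict[str, Sequence[int]],
                protein_atoms: Sequence[int],
                cutoff: float = CONTACT_CUTOFF,
                heavy_only: bool = True) -> ContactMap:
    """Ensemble-average contact counts per (ligand group, protein residue).

    Per frame a cell counts the atom pairs within the cutoff; the per-
    simulation time average is taken first, then the mean across
    simulations (the ensemble average is the mean of per-simulation
    averages, so simulations of unequal length carry equal weight).
    """
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    topo = trajectories[0].topology
    protein = [i for i in protein_atoms if not heavy_only or _is_heavy(topo, i)]
    res_labels, res_members = _residue_groups(topo, protein)
    row_names = list(row_groups)
    per_sim = []
    for traj in trajectories:
        counts = np.zeros((len(row_names), len(res_labels)))
        for ri, rn in enumerate(row_names):
            idx = [i for i in row_groups[rn]
                   if not heavy_only or _is_heavy(topo, i)]
            if not idx:
                continue
            d = _pair_distances(traj, idx, protein)  # (F, n_idx, n_prot)
            contact = d < cutoff
            for ci, members in enumerate(res_members):
                cols = [protein.index(m) for m in members]
                counts[ri, ci] = contact[:, :, cols].sum(axis=(1, 2)).mean()
        per_sim.append(counts)
    return ContactMap(row_names=row_names, residue_labels=res_labels,
                      counts=np.mean(per_sim, axis=0))


def bridging_waters(trajectories: Sequence[Trajectory],
                    row_groups: dict[str, Sequence[int]],
                    protein_atoms: Sequence[int],
                    solvent_atoms: Sequence[int],
                    cutoff: float = CONTACT_CUTOFF,
                    oxygen_only: bool = False) -> np.ndarray:
    """Ensemble-average count of distinct bridging water molecules per cell.

    A water bridges a (ligand group, residue) cell on a frame iff at least
    one of its atoms lies within the cutoff of the group AND at least one
    within the cutoff of the residue.  Averaged as in :func:`contact_map`.
    Returns an all-zero layer (with a warning) when no solvent is present.
    """
    import warnings

    if not trajectories:
        raise ValueError("at least one trajectory is required")
    topo = trajectories[0].topology
    protein = list(protein_atoms)
    res_labels, res_members = _residue_groups(topo, protein)
    row_names = list(row_groups)
    shape = (len(row_names), len(res_labels))
    solvent = [i for i in solvent_atoms
               if not oxygen_only or
               (topo.atoms[i].element or topo.atoms[i].name[:1]).upper() == "O"]
    if not solvent:
        warnings.warn("no solvent atoms: bridging-water layer is all zero")
        return np.zeros(shape)
    # group solvent atoms into water molecules by residue
    _, water_members = _residue_groups(topo, solvent)

    per_sim = []
    for traj in trajectories:
        counts = np.zeros(shape)
        for ri, rn in enumerate(row_names):
            gidx = list(row_groups[rn])
            if not gidx:
                continue
            for ci, members in enumerate(res_members):
                per_frame = np.zeros(traj.n_frames)
                for wat in water_members:
                    dg = _pair_distances(traj, wat, gidx)   # (F, nw, ng)
                    dr = _pair_distances(traj, wat, members)
                    bridges = ((dg < cutoff).any(axis=(1, 2))
                               & (dr < cutoff).any(axis=(1, 2)))
                    per_frame += bridges
                counts[ri, ci] = per_frame.mean()
        per_sim.append(counts)
    return np.mean(per_sim, axis=0)


def water_bin_label(value: float) -> str | None:
    """Display bin for a bridging-water average: left-open, right-closed
    intervals ]0.5;1], ]1;1.5], ]1.5;2]; None when unbinned (<= 0.5 or > 2)."""
    for lo, hi in ((0.5, 1.0), (1.0, 1.5), (1.5, 2.0)):
        if lo < value <= hi:
            return f"]{lo:g};{hi:g}]"
    return None


def hbond_stats(trajectories: Sequence[Trajectory], donor: int, hydrogen: int,
                acceptor: int, dist_max: float = 2.5,
                angle_min: float = 135.0) -> HBondGeometry:
    """Per-frame H...A distance and D-H...A angle statistics.

    The bond is flagged as formed iff the mean distance is at most
    ``dist_max`` and the mean angle at least ``angle_min`` (defaults chosen
    as conventional geometric criteria for a formed hydrogen bond).
    """
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor must be distinct atoms")
    dists, angles = [], []
    for traj in trajectories:
        h = traj.frames[:, hydrogen]
        d = traj.frames[:, donor]
        a = traj.frames[:, acceptor]
        ha = a - h
        hd = d - h
        r = np.linalg.norm(ha, axis=1)
        cosang = np.sum(ha * hd, axis=1) / (
            r * np.linalg.norm(hd, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        dists.append(r)
    dist = np.concatenate(dists)
    ang = np.concatenate(angles)
    mean_d, mean_a = float(dist.mean()), float(ang.mean())
    return HBondGeometry(
        donor=donor, hydrogen=hydrogen, acceptor=acceptor,
        mean_distance=mean_d,
        sd_distance=float(dist.std(ddof=1)) if len(dist) > 1 else 0.0,
        mean_angle=mean_a,
        sd_angle=float(ang.std(ddof=1)) if len(ang) > 1 else 0.0,
        formed=bool(mean_d <= dist_max and mean_a >= angle_min),
    )
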