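"""Data model and file I/O: structures (PDB), trajectories (DCD/XYZ), group configs.

The in-memory model is deliberately small: an ordered list of atoms with
residue/chain assignment (:class:`Topology`), coordinate frames tied to a
topology (:class:`Trajectory`), and a declarative description of the atom
groups the analysis needs — ligand moieties, protein regions, the
binding-pocket residue set and the reaction-coordinate atom pair
(:class:`GroupConfig`).

PDB parsing is delegated to Bio.PDB (highest-occupancy altloc retained);
trajectory reading/writing to the MDAnalysis DCD and XYZ readers/writers.
Coordinates are Angstrom throughout, times in ps, masses in amu.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "GroupConfig",
    "Restraint",
    "ParseError",
    "TrajectoryError",
    "GroupResolutionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_groups",
    "load_group_config",
]


class ParseError(ValueError):
    """A structure file could not be parsed."""


class TrajectoryError(ValueError):
    """A trajectory file is inconsistent with its topology or truncated."""


class GroupResolutionError(ValueError):
    """A group selector did not resolve uniquely against the topology."""


#: Atomic masses (amu) for the elements that occur in protein/ligand/solvent
#: PDB files handled here.  Unknown elements fall back to carbon with a warning.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971, "MN": 54.938,
}

DEFAULT_SOLVENT_RESNAMES = ("HOH", "TIP3", "WAT", "SOL")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    mass: float
    residue_number: int
    residue_name: str
    chain: str = "A"

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial} ({self.name}): mass must be > 0")


@dataclass
class Topology:
    """Ordered atom list plus named atom-index groups.

    Groups include ligand moieties (``core``, ``iBu``, ``Tol``, ``Ethe``),
    protein regions (``80s_loop``, ``loop_tip``, ``pocket``) and the
    ``ligand``/``protein``/``solvent`` partition.
    """

    atoms: list[Atom]
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique within the topology")
        n = len(self.atoms)
        for name, idx in self.groups.items():
            for i in idx:
                if not (0 <= i < n):
                    raise ValueError(f"group {name!r}: index {i} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def group(self, name: str) -> tuple[int, ...]:
        try:
            return self.groups[name]
        except KeyError:
            raise GroupResolutionError(f"no group named {name!r} in topology")

    def select(self, residue_name: str | None = None,
               residue_number: int | None = None,
               atom_name: str | None = None) -> list[int]:
        """Indices of atoms matching the given residue/atom fields."""
        out = []
        for i, a in enumerate(self.atoms):
            if residue_name is not None and a.residue_name.upper() != residue_name.upper():
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if atom_name is not None and a.name.upper() != atom_name.upper():
                continue
            out.append(i)
        return out


@dataclass
class Trajectory:
    """Time-ordered coordinate frames (Angstrom) linked to a Topology."""

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float  # ps between stored frames

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}")
        if self.dt <= 0:
            raise TrajectoryError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class Restraint:
    pair: tuple[str, str]  # two atom selectors
    r_min: float
    r_max: float
    k: float

    def __post_init__(self):
        if self.r_min > self.r_max:
            raise ValueError("restraint: R_min must be <= R_max")
        if self.k < 0:
            raise ValueError("restraint: k must be >= 0")


@dataclass
class GroupConfig:
    """Declarative group definitions resolved against a Topology.

    Selector syntax is ``"RESNAME RESNUM"`` (all atoms of a residue) or
    ``"RESNAME RESNUM ATOMNAME"`` (a single atom), with 1-based residue
    numbers taken verbatim from the input file.
    """

    reaction_coordinate: tuple[str, str]
    pocket_residues: list[int]
    moiety_definitions: dict[str, list[str]] = field(default_factory=dict)
    region_definitions: dict[str, list[str]] = field(default_factory=dict)
    restraint_sets: dict[str, list[Restraint]] = field(default_factory=dict)
    ligand_resnames: list[str] = field(default_factory=list)
    solvent_resnames: list[str] = field(
        default_factory=lambda: list(DEFAULT_SOLVENT_RESNAMES))


# Residues named in the analysis of the binding pocket; the pocket residue
# set itself is a documented default, not an experimentally defined list.
DEFAULT_POCKET_RESIDUES = [26, 36, 46, 53, 54, 55, 56, 59, 82, 87, 90, 91]


def _mass_for_element(element: str, name: str) -> float:
    key = element.upper().strip()
    if not key:
        # fall back on the first letter of the atom name
        key = "".join(c for c in name if c.isalpha())[:1].upper()
    if key not in ELEMENT_MASSES:
        warnings.warn(f"unknown element {element!r} for atom {name!r}; "
                      "assigning carbon mass")
        return ELEMENT_MASSES["C"]
    return ELEMENT_MASSES[key]


def _scan_pdb_for_bad_record(path: str) -> int | None:
    """Return the 1-based line number of the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return lineno
    return None


def read_structure(path: str) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus single-frame coordinates (Angstrom).

    For disordered atoms the highest-occupancy alternate location is kept.
    Raises :class:`ParseError` for empty or malformed files (naming the
    offending line where one can be identified).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    bad = _scan_pdb_for_bad_record(path)
    if bad is not None:
        raise ParseError(f"{path}: malformed ATOM/HETATM record at line {bad}")
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    try:
        structure = parser.get_structure("s", path)
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise ParseError(f"{path}: no models found")
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    children = atom.disordered_get_list()
                    atom = max(children, key=lambda a: (a.get_occupancy() or 0.0))
                element = (atom.element or "").strip()
                atoms.append(Atom(
                    serial=atom.get_serial_number(),
                    name=atom.get_name(),
                    element=element,
                    mass=_mass_for_element(element, atom.get_name()),
                    residue_number=residue.id[1],
                    residue_name=residue.get_resname().strip(),
                    chain=chain.id if chain.id.strip() else "A",
                ))
                coords.append(np.asarray(atom.get_coord(), dtype=float))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return Topology(atoms=atoms), np.array(coords, dtype=float)


def _mda_universe(topology: Topology, coords: np.ndarray):
    """Build an in-memory MDAnalysis Universe mirroring our topology."""
    import MDAnalysis as mda

    n = topology.n_atoms
    # map residues in order of first appearance
    res_keys: list[tuple[str, int, str]] = []
    resindex = np.empty(n, dtype=int)
    for i, a in enumerate(topology.atoms):
        key = (a.chain, a.residue_number, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            if key in res_keys:  # non-contiguous residue: still map to it
                resindex[i] = res_keys.index(key)
                continue
            res_keys.append(key)
        resindex[i] = len(res_keys) - 1
    n_res = len(res_keys)
    segids = sorted({k[0] for k in res_keys})
    seg_of_res = np.array([segids.index(k[0]) for k in res_keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=resindex,
                               residue_segindex=seg_of_res, trajectory=True)
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element or "C" for a in topology.atoms])
        u.add_TopologyAttr("masses", [a.mass for a in topology.atoms])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("segids", segids)
        u.add_TopologyAttr("chainIDs", [topology.atoms[i].chain for i in range(n)])
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.add_TopologyAttr("altLocs", [""] * n)
        u.atoms.positions = np.asarray(coords, dtype=float)
    return u


def write_structure(path: str, topology: Topology, coords: np.ndarray) -> None:
    """Write a single-frame PDB file."""
    u = _mda_universe(topology, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)


def write_trajectory(path: str, trajectory: Trajectory) -> None:
    """Write a trajectory as DCD (binary) or XYZ (text), chosen by extension."""
    import MDAnalysis as mda

    ext = os.path.splitext(path)[1].lower()
    if ext not in (".dcd", ".xyz"):
        raise TrajectoryError(f"unsupported trajectory format {ext!r}")
    u = _mda_universe(trajectory.topology, trajectory.frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, trajectory.topology.n_atoms,
                        dt=trajectory.dt) as w:
            for frame in trajectory.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def _validate_xyz(path: str, n_atoms: int) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise TrajectoryError(f"{path}: bad XYZ frame header at line {i + 1}")
        if n != n_atoms:
            raise TrajectoryError(
                f"{path}: frame declares {n} atoms, topology has {n_atoms}")
        if i + 2 + n > len(lines):
            raise TrajectoryError(f"{path}: truncated final frame (expected "
                                  f"{n} atom lines after line {i + 2})")
        for j in range(i + 2, i + 2 + n):
            if len(lines[j].split()) < 4:
                raise TrajectoryError(f"{path}: truncated atom record at line {j + 1}")
        i += 2 + n


def read_trajectory(path: str, topology: Topology,
                    dt: float | None = None) -> Trajectory:
    """Read a DCD or XYZ trajectory; ``dt`` (ps/frame) overrides the header.

    Raises :class:`TrajectoryError` on atom-count mismatch or a truncated
    final frame (earlier frames are never silently returned).
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XYZ import XYZReader

    ext = os.path.splitext(path)[1].lower()
    frames = []
    header_dt = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ext == ".dcd":
            reader = DCDReader(path)
        elif ext == ".xyz":
            _validate_xyz(path, topology.n_atoms)
            reader = XYZReader(path)
        else:
            raise TrajectoryError(f"unsupported trajectory format {ext!r}")
        with reader:
            if reader.n_atoms != topology.n_atoms:
                raise TrajectoryError(
                    f"{path}: expected {topology.n_atoms} atoms, found {reader.n_atoms}")
            for ts in reader:
                frames.append(ts.positions.astype(float).copy())
                if header_dt is None:
                    try:
                        header_dt = float(ts.dt)
                    except Exception:
                        header_dt = None
    if not frames:
        raise TrajectoryError(f"{path}: no frames")
    eff_dt = dt if dt is not None else header_dt
    if eff_dt is None or eff_dt <= 0:
        raise TrajectoryError(f"{path}: no usable dt in header; pass dt explicitly")
    return Trajectory(topology=topology, frames=np.array(frames), dt=eff_dt)


def _resolve_selector(selector: str, topology: Topology,
                      expect_single: bool = False) -> list[int]:
    tokens = selector.split()
    if len(tokens) == 3:
        resname, resnum, atname = tokens[0], int(tokens[1]), tokens[2]
        idx = topology.select(residue_name=resname, residue_number=resnum,
                              atom_name=atname)
    elif len(tokens) == 2:
        resname, resnum = tokens[0], int(tokens[1])
        idx = topology.select(residue_name=resname, residue_number=resnum)
    else:
        raise GroupResolutionError(
            f"selector {selector!r}: expected 'RESNAME RESNUM [ATOMNAME]'")
    if not idx:
        raise GroupResolutionError(f"selector {selector!r} matched no atoms")
    if expect_single and len(idx) != 1:
        raise GroupResolutionError(
            f"selector {selector!r} is ambiguous: matched {len(idx)} atoms")
    return idx


def resolve_groups(config: GroupConfig, topology: Topology) -> dict[str, tuple[int, ...]]:
    """Resolve a GroupConfig into named atom-index sets.

    Returns a dict with keys ``rc_pair`` (two indices), one key per moiety
    and region, ``pocket``, and the complete ``ligand``/``protein``/``solvent``
    partition.  Unresolved or ambiguous selectors raise, never resolve empty.
    """
    groups: dict[str, tuple[int, ...]] = {}

    a = _resolve_selector(config.reaction_coordinate[0], topology, expect_single=True)
    b = _resolve_selector(config.reaction_coordinate[1], topology, expect_single=True)
    groups["rc_pair"] = (a[0], b[0])

    moiety_sets: dict[str, set[int]] = {}
    for name, selectors in config.moiety_definitions.items():
        s: set[int] = set()
        for sel in selectors:
            s.update(_resolve_selector(sel, topology))
        if not s:
            raise GroupResolutionError(f"moiety {name!r} resolved empty")
        moiety_sets[name] = s
    names = list(moiety_sets)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            overlap = moiety_sets[n1] & moiety_sets[n2]
            if overlap:
                raise GroupResolutionError(
                    f"moieties {n1!r} and {n2!r} overlap on atoms {sorted(overlap)}")
    for name, s in moiety_sets.items():
        groups[name] = tuple(sorted(s))

    for name, selectors in config.region_definitions.items():
        s = set()
        for sel in selectors:
            s.update(_resolve_selector(sel, topology))
        groups[name] = tuple(sorted(s))

    solvent = {i for i, at in enumerate(topology.atoms)
               if at.residue_name.upper() in
               {r.upper() for r in config.solvent_resnames}}
    if config.ligand_resnames:
        ligand = {i for i, at in enumerate(topology.atoms)
                  if at.residue_name.upper() in
                  {r.upper() for r in config.ligand_resnames}}
    else:
        ligand = set().union(*moiety_sets.values()) if moiety_sets else set()
    protein = set(range(topology.n_atoms)) - solvent - ligand
    groups["ligand"] = tuple(sorted(ligand))
    groups["protein"] = tuple(sorted(protein))
    groups["solvent"] = tuple(sorted(solvent))

    pocket = set()
    for resnum in config.pocket_residues:
        idx = [i for i in topology.select(residue_number=resnum) if i in protein]
        if not idx:
            raise GroupResolutionError(f"pocket residue {resnum} matched no protein atoms")
        pocket.update(idx)
    groups["pocket"] = tuple(sorted(pocket))
    return groups


def load_group_config(path: str) -> GroupConfig:
    """Load a GroupConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    restraints = {}
    for name, entries in (raw.get("restraints") or {}).items():
        restraints[name] = [
            Restraint(pair=tuple(e["pair"]), r_min=float(e["r_min"]),
                      r_max=float(e["r_max"]), k=float(e["k"]))
            for e in entries
        ]
    return GroupConfig(
        reaction_coordinate=tuple(raw["reaction_coordinate"]),
        pocket_residues=list(raw.get("pocket_residues", DEFAULT_POCKET_RESIDUES)),
        moiety_definitions={k: list(v) for k, v in (raw.get("moieties") or {}).items()},
        region_definitions={k: list(v) for k, v in (raw.get("regions") or {}).items()},
        restraint_sets=restraints,
        ligand_resnames=list(raw.get("ligand_resnames", [])),
        solvent_resnames=list(raw.get("solvent_resnames", DEFAULT_SOLVENT_RESNAMES)),
    )
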