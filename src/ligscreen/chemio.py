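"""Molecular structures, trajectories and per-atom parameters.

Structure and trajectory files (PDB incl. multi-MODEL, single/multi-frame XYZ,
mol2 ATOM/BOND records) are read and written through MDAnalysis; this module
wraps them into the package's light containers and layers on the per-atom
parameterisation (partial charge, Lennard-Jones radius/epsilon, mass,
intrinsic Born radius) and the docking atom-type assignment that the scoring
stages need.

Unit system: Å / kcal·mol⁻¹ / amu / ps / elementary charge (see
:mod:`ligscreen.constants`).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyStructureError,
    FormatError,
    ParameterError,
    TrajectoryAlignmentError,
)


class DockType(str, Enum):
    """Closed enumeration of docking atom types.

    The empirical pair potential distinguishes hydrophobic carbons,
    hydrogen-bond donors/acceptors and everything else.
    """

    CARBON_HYDROPHOBIC = "carbon_hydrophobic"
    POLAR_DONOR = "polar_donor"
    POLAR_ACCEPTOR = "polar_acceptor"
    DONOR_ACCEPTOR = "donor_acceptor"
    OTHER = "other"


#: Default per-element parameters used when a structure file carries none:
#: (lj_radius [Å, Rmin/2 convention], lj_epsilon [kcal/mol], mass [amu],
#:  gb_radius [Å, intrinsic Born radius, Bondi-like minus 0.09 Å offset]).
ELEMENT_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "H": (1.20, 0.030, 1.008, 1.11),
    "C": (1.90, 0.086, 12.011, 1.61),
    "N": (1.80, 0.170, 14.007, 1.46),
    "O": (1.70, 0.210, 15.999, 1.43),
    "S": (2.00, 0.250, 32.060, 1.69),
    "P": (2.10, 0.200, 30.974, 1.79),
    "F": (1.60, 0.080, 18.998, 1.38),
    "CL": (1.90, 0.240, 35.450, 1.66),
    "BR": (2.00, 0.300, 79.904, 1.76),
    "I": (2.15, 0.350, 126.904, 1.89),
    "NA": (1.40, 0.047, 22.990, 1.76),
    "NE": (1.55, 0.069, 20.180, 1.45),
    "AR": (1.88, 0.238, 39.948, 1.79),
}
#: Fallback for elements not in the table.
UNKNOWN_ELEMENT_DEFAULTS = (1.80, 0.100, 1.000, 1.50)

#: Single-bond covalent radii (Å) for the bond-perception heuristic used only
#: when a format carries no bond records.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}


def element_defaults(element: str) -> tuple[float, float, float, float]:
    return ELEMENT_DEFAULTS.get(element.upper(), UNKNOWN_ELEMENT_DEFAULTS)


@dataclass
class Atom:
    """One atom with coordinates and force-field/docking parameters.

    ``coords`` records the construction-time position; once atoms are part of
    a :class:`MolecularSystem`, the system's ``coords`` array is the single
    source of truth for positions (frames replace that array wholesale).
    """

    element: str
    name: str
    coords: np.ndarray
    charge: float = 0.0
    lj_radius: float = 0.0
    lj_epsilon: float = 0.0
    mass: float = 1.0
    gb_radius: float = 1.5
    dock_type: DockType | None = None
    role: str = "ligand"  # "ligand" | "receptor"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.lj_radius < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: LJ parameters must be >= 0")
        if self.gb_radius <= 0:
            raise ValueError(f"atom {self.name}: gb_radius must be positive")

    @classmethod
    def from_element(cls, element: str, coords, **kw) -> "Atom":
        """Build an atom with table defaults for any parameter not given."""
        r, eps, m, gb = element_defaults(element)
        kw.setdefault("lj_radius", r)
        kw.setdefault("lj_epsilon", eps)
        kw.setdefault("mass", m)
        kw.setdefault("gb_radius", gb)
        kw.setdefault("name", element)
        return cls(element=element, coords=np.asarray(coords, float), **kw)


class MolecularSystem:
    """An ordered collection of atoms with an optional bond list.

    Per-atom attribute arrays (charges, radii, ...) are cached on first
    access; :meth:`with_coords` shares those caches so per-frame evaluation
    stays cheap.
    """

    def __init__(self, atoms: list[Atom], bonds: list[tuple[int, int]] | None = None,
                 name: str = "system"):
        if not atoms:
            raise EmptyStructureError(f"system '{name}' has no atoms")
        self.atoms = list(atoms)
        self.name = name
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm_bonds: list[tuple[int, int]] = []
        for i, j in (bonds or []):
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"bond ({i},{j}) joins an atom to itself")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append(key)
        self.bonds = norm_bonds
        self.coords = np.array([a.coords for a in self.atoms], dtype=float)
        self._cache: dict[str, np.ndarray] = {}

    # -- array views ------------------------------------------------------
    def _cached(self, key: str, getter):
        if key not in self._cache:
            self._cache[key] = np.array([getter(a) for a in self.atoms])
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> np.ndarray:
        return self._cached("elements", lambda a: a.element)

    @property
    def charges(self) -> np.ndarray:
        return self._cached("charges", lambda a: a.charge)

    @property
    def lj_radii(self) -> np.ndarray:
        return self._cached("lj_radii", lambda a: a.lj_radius)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._cached("lj_epsilons", lambda a: a.lj_epsilon)

    @property
    def masses(self) -> np.ndarray:
        return self._cached("masses", lambda a: a.mass)

    @property
    def gb_radii(self) -> np.ndarray:
        return self._cached("gb_radii", lambda a: a.gb_radius)

    @property
    def roles(self) -> np.ndarray:
        return self._cached("roles", lambda a: a.role)

    @property
    def dock_types(self) -> list[DockType | None]:
        return [a.dock_type for a in self.atoms]

    def ligand_indices(self) -> np.ndarray:
        return np.nonzero(self.roles == "ligand")[0]

    def receptor_indices(self) -> np.ndarray:
        return np.nonzero(self.roles == "receptor")[0]

    def heavy_indices(self) -> np.ndarray:
        return np.nonzero(self.elements != "H")[0]

    # -- derived topology --------------------------------------------------
    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs, excluded from nonbonded sums."""
        adj = self.adjacency()
        excl: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            excl.add((i, j))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
            for k in adj[i]:
                if k != j:
                    excl.add((min(j, k), max(j, k)))
        return excl

    # -- transforms --------------------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """Shallow copy carrying new coordinates (caches shared)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        new = copy.copy(self)
        new.coords = coords
        return new

    def subset(self, indices, name: str | None = None) -> "MolecularSystem":
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        atoms = []
        for old in indices:
            a = copy.copy(self.atoms[old])
            a.coords = self.coords[old].copy()
            atoms.append(a)
        bonds = [(remap[i], remap[j]) for i, j in self.bonds
                 if i in remap and j in remap]
        return MolecularSystem(atoms, bonds, name or f"{self.name}_subset")


def merge_systems(a: MolecularSystem, b: MolecularSystem,
                  name: str = "complex") -> MolecularSystem:
    """Concatenate two systems (atoms of ``a`` first); bond indices shifted."""
    atoms = []
    for sys_ in (a, b):
        for i, at in enumerate(sys_.atoms):
            at = copy.copy(at)
            at.coords = sys_.coords[i].copy()
            atoms.append(at)
    bonds = list(a.bonds) + [(i + a.n_atoms, j + a.n_atoms) for i, j in b.bonds]
    return MolecularSystem(atoms, bonds, name)


@dataclass
class Trajectory:
    """Ordered coordinate frames for one system at a fixed temperature."""

    system: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    temperature: float = 300.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (F, N, 3) array")
        if self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise TrajectoryAlignmentError(
                0, self.system.n_atoms, self.frames.shape[1])
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_system(self, i: int) -> MolecularSystem:
        return self.system.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_FORMAT_BY_EXT = {".pdb": "pdb", ".xyz": "xyz", ".mol2": "mol2"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower().replace("multi-model-pdb", "pdb").replace("multi-xyz", "xyz")
    ext = path.suffix.lower()
    if ext not in _FORMAT_BY_EXT:
        raise FormatError(f"cannot infer format from extension '{ext}'")
    return _FORMAT_BY_EXT[ext]


def _mda_universe(path: Path, fmt: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), format=fmt)


def _guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        return "X"
    if len(name) >= 2 and name[:2].upper() in ELEMENT_DEFAULTS and not name[0].isdigit():
        # two-letter element (Cl, Br, Na, ...)
        if name[:2].upper() in ("CL", "BR", "NA", "NE", "AR"):
            return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path, fmt: str | None = None, role: str = "ligand") -> MolecularSystem:
    """Read a molecular structure file into a :class:`MolecularSystem`.

    Supported dialects: PDB (first MODEL of a multi-model file, with a
    warning), XYZ (first frame) and mol2 (ATOM/BOND records).  Missing
    per-atom parameters default from the element table.  Bonds come from the
    file when the format has them (mol2, PDB CONECT); otherwise a
    covalent-radius heuristic perceives them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise EmptyStructureError(f"{path} is empty")
    fmt = _infer_format(path, fmt)
    try:
        u = _mda_universe(path, fmt)
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyStructureError(f"{path} contains no atoms")
    if hasattr(u, "trajectory") and len(u.trajectory) > 1:
        warnings.warn(
            f"{path.name}: {len(u.trajectory)} models/frames present; "
            "reading the first only", stacklevel=2)
        u.trajectory[0]

    try:
        elements = [str(e).capitalize() for e in u.atoms.elements]
        if any(not e or e == "X" for e in elements):
            raise AttributeError
    except Exception:
        elements = [_guess_element(n) for n in u.atoms.names]
    try:
        charges = np.asarray(u.atoms.charges, dtype=float)
    except Exception:
        charges = None

    atoms = []
    for i in range(len(u.atoms)):
        kw = {"name": str(u.atoms.names[i]), "role": role}
        if charges is not None:
            kw["charge"] = float(charges[i])
        atoms.append(Atom.from_element(elements[i], u.atoms.positions[i], **kw))

    bonds: list[tuple[int, int]] = []
    try:
        bonds = [(int(b[0].ix), int(b[1].ix)) for b in u.bonds]
    except Exception:
        bonds = []
    system = MolecularSystem(atoms, bonds, name=path.stem)
    if not bonds:
        system = perceive_bonds(system)
    return system


def perceive_bonds(system: MolecularSystem, tolerance: float = 0.45) -> MolecularSystem:
    """Assign bonds where interatomic distance < sum of covalent radii + tol.

    Used only for formats without bond records; atoms of unknown covalent
    radius never bond.
    """
    radii = np.array([_COVALENT_RADII.get(e.upper(), 0.0) for e in system.elements])
    d = np.linalg.norm(system.coords[:, None] - system.coords[None, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    np.fill_diagonal(d, np.inf)
    ii, jj = np.nonzero((d < cut) & (radii[:, None] > 0) & (radii[None, :] > 0))
    bonds = [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    return MolecularSystem(system.atoms, bonds, system.name)


def _system_to_universe(system: MolecularSystem, frames: np.ndarray):
    import MDAnalysis as mda

    n = system.n_atoms
    u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name[:4] or a.element for a in system.atoms])
    u.add_TopologyAttr("elements", [a.element for a in system.atoms])
    u.add_TopologyAttr("resnames", ["MOL"])
    u.add_TopologyAttr("resids", [1])
    u.load_new(np.asarray(frames, dtype=np.float32), order="fac")
    return u


def write_structure(system: MolecularSystem, path, fmt: str | None = None) -> None:
    """Write a single-frame structure file (PDB or XYZ)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, fmt)
    u = _system_to_universe(system, system.coords[None, :, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            w.write(u.atoms)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a multi-model PDB or multi-frame XYZ trajectory."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, fmt)
    u = _system_to_universe(traj.system, traj.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.system.n_atoms,
                        multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _scan_frame_atom_counts(path: Path, fmt: str) -> list[int]:
    """Cheap text pass counting atoms per frame, for frame-indexed errors."""
    counts: list[int] = []
    if fmt == "pdb":
        current = 0
        in_model = False
        with open(path) as fh:
            for line in fh:
                rec = line[:6].strip()
                if rec == "MODEL":
                    in_model = True
                    current = 0
                elif rec in ("ATOM", "HETATM"):
                    current += 1
                elif rec == "ENDMDL":
                    counts.append(current)
                    in_model = False
        if not counts and current:
            counts = [current]
        elif in_model and current:
            counts.append(current)
    elif fmt == "xyz":
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].split()[0])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad XYZ atom count at line {i + 1}") from exc
            counts.append(n)
            i += n + 2
    return counts


def read_trajectory(path, system: MolecularSystem, fmt: str | None = None,
                    temperature: float = 300.0) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a trajectory.

    Every frame must match the system's atom count; a mismatch raises a
    :class:`TrajectoryAlignmentError` naming the offending frame (0-based).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    for idx, count in enumerate(_scan_frame_atom_counts(path, fmt)):
        if count != system.n_atoms:
            raise TrajectoryAlignmentError(idx, system.n_atoms, count)
    try:
        u = _mda_universe(path, fmt)
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    frames = np.array([u.atoms.positions.astype(float).copy()
                       for _ in u.trajectory])
    if frames.shape[1] != system.n_atoms:
        raise TrajectoryAlignmentError(0, system.n_atoms, frames.shape[1])
    return Trajectory(system=system, frames=frames, temperature=temperature)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ["name", "element", "charge", "lj_radius", "lj_epsilon",
                 "mass", "gb_radius"]


def read_param_table(path) -> pd.DataFrame:
    """Read a per-atom parameter CSV (columns: name, element, charge,
    lj_radius, lj_epsilon, mass, gb_radius)."""
    table = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"parameter table missing columns: {missing}")
    return table


def apply_param_table(system: MolecularSystem, table: pd.DataFrame) -> MolecularSystem:
    """Overwrite per-atom parameters by atom name (falling back to element).

    Atoms matched by neither name nor element keep their current values.
    """
    by_name = {str(r["name"]): r for _, r in table.iterrows()}
    by_element = {}
    for _, r in table.iterrows():
        by_element.setdefault(str(r["element"]).upper(), r)
    atoms = []
    for i, a in enumerate(system.atoms):
        a = copy.copy(a)
        a.coords = system.coords[i].copy()
        row = by_name.get(a.name, by_element.get(a.element.upper()))
        if row is not None:
            a.charge = float(row["charge"])
            a.lj_radius = float(row["lj_radius"])
            a.lj_epsilon = float(row["lj_epsilon"])
            a.mass = float(row["mass"])
            a.gb_radius = float(row["gb_radius"])
        atoms.append(a)
    return MolecularSystem(atoms, system.bonds, system.name)


# ---------------------------------------------------------------------------
# Docking atom types
# ---------------------------------------------------------------------------

def assign_dock_types(system: MolecularSystem) -> MolecularSystem:
    """Assign a :class:`DockType` to every atom (total, deterministic).

    Rules: a carbon bonded only to carbon/hydrogen is hydrophobic; a nitrogen
    with an attached hydrogen is a donor; an oxygen is an acceptor, or a
    donor-acceptor when it carries a hydrogen (hydroxyl); everything else —
    including unknown elements — is ``other``.
    """
    adj = system.adjacency()
    for i, atom in enumerate(system.atoms):
        el = atom.element.upper()
        neighbors = {system.atoms[j].element.upper() for j in adj[i]}
        if el == "C":
            atom.dock_type = (DockType.CARBON_HYDROPHOBIC
                              if neighbors <= {"C", "H"}
                              else DockType.OTHER)
        elif el == "N":
            atom.dock_type = (DockType.POLAR_DONOR if "H" in neighbors
                              else DockType.OTHER)
        elif el == "O":
            atom.dock_type = (DockType.DONOR_ACCEPTOR if "H" in neighbors
                              else DockType.POLAR_ACCEPTOR)
        else:
            atom.dock_type = DockType.OTHER
    system._cache.pop("dock_types", None)
    return system
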