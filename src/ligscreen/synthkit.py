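"""Deterministic generators for every toy fixture the engine consumes.

Rather than sampling chemical libraries, the generators realise requested
physical parameters directly — binding-well depths, fluctuation variances,
ΔU distributions — so that every downstream quantity has an analytic or
constructive oracle.  All generators are pure functions of their seed and
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alchemy import AlchemicalSystem, Restraint
from .chemio import Atom, MolecularSystem, Trajectory
from .constants import K_B
from .dockscore import SearchBox
from .energetics import lj_energy_pairwise


@dataclass(frozen=True)
class ToyScreenSpec:
    """Composition of a synthetic screening set.

    Well depths are the target minimum of the ligand–pocket interaction
    energy in kcal·mol⁻¹ (active strictly deeper, i.e. more negative).
    Defaults emulate a strong binder (≈ −8, a good drug-like affinity on
    this scale) against weak non-binders (≈ −2).
    """

    n_active: int = 3
    n_decoy: int = 17
    active_well_depth: float = -8.0
    decoy_well_depth: float = -2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_active < 0 or self.n_decoy < 0:
            raise ValueError("counts must be >= 0")
        if self.active_well_depth >= self.decoy_well_depth:
            raise ValueError("active well must be deeper (more negative) "
                             "than decoy well")


@dataclass
class LabeledLigand:
    id: str
    system: MolecularSystem
    label: str  # "active" | "decoy"


def make_pocket_receptor(seed: int = 0, n_atoms: int = 20,
                         cage_radius: float = 4.8
                         ) -> tuple[MolecularSystem, SearchBox]:
    """A rigid concave cage of carbon atoms with an opening along +z.

    Atoms sit on a sphere of ``cage_radius`` with the polar cap removed
    (the pocket mouth) plus a small seeded jitter; the search box covers the
    cage interior.
    """
    rng = np.random.default_rng(seed)
    # oversample a golden spiral, drop the +z cap to open the pocket
    n_grid = int(n_atoms * 1.6) + 4
    k = np.arange(n_grid, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n_grid)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    pts = np.column_stack([np.sin(phi) * np.cos(theta),
                           np.sin(phi) * np.sin(theta),
                           np.cos(phi)])
    pts = pts[pts[:, 2] < 0.55][:n_atoms]
    coords = pts * cage_radius + rng.normal(0.0, 0.05, pts.shape)
    atoms = [Atom.from_element("C", c, name=f"C{i+1}", role="receptor")
             for i, c in enumerate(coords)]
    system = MolecularSystem(atoms, bonds=[], name=f"pocket_{seed}")
    box = SearchBox(center=(0.0, 0.0, 0.0), half_lengths=(2.5, 2.5, 2.5))
    return system, box


def _star_ligand(rng, n_arms: int, bond_length: float, element: str,
                 lj_radius: float, lj_epsilon: float, name: str,
                 jitter: float = 0.05) -> MolecularSystem:
    """A central atom with ``n_arms`` satellites — a small rigid blob."""
    dirs = {
        2: np.array([[1, 0, 0], [-1, 0, 0]], dtype=float),
        3: np.array([[1, 0, 0], [-0.5, 0.866, 0], [-0.5, -0.866, 0]]),
        4: np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
             / np.sqrt(3.0),
    }[n_arms]
    coords = np.vstack([np.zeros(3), dirs * bond_length])
    coords = coords + rng.normal(0.0, jitter, coords.shape)
    atoms = [Atom.from_element(element, c, name=f"{element}{i+1}",
                               lj_radius=lj_radius, lj_epsilon=lj_epsilon)
             for i, c in enumerate(coords)]
    bonds = [(0, i) for i in range(1, len(atoms))]
    return MolecularSystem(atoms, bonds, name=name)


def pocket_energy_scan(ligand: MolecularSystem, receptor: MolecularSystem,
                       axis=(0.0, 0.0, 1.0), t_min: float = -1.0,
                       t_max: float = 8.0, n_points: int = 400
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Ligand–receptor LJ energy along a 1-D displacement of the ligand
    centroid from the cage centre along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ts = np.linspace(t_min, t_max, n_points)
    centroid = ligand.coords.mean(axis=0)
    energies = np.empty_like(ts)
    for i, t in enumerate(ts):
        coords = ligand.coords - centroid + axis * t
        r = np.linalg.norm(coords[:, None, :] - receptor.coords[None, :, :],
                           axis=-1)
        rmin = ligand.lj_radii[:, None] + receptor.lj_radii[None, :]
        eps = np.sqrt(ligand.lj_epsilons[:, None]
                      * receptor.lj_epsilons[None, :])
        energies[i] = float(np.sum(lj_energy_pairwise(r, rmin, eps)))
    return ts, energies


def _calibrate_depth(ligand: MolecularSystem, receptor: MolecularSystem,
                     target_depth: float) -> MolecularSystem:
    """Scale the ligand's LJ epsilons so the pocket scan minimum hits the
    requested well depth (pair ε ∝ √ε_ligand, so scale by the square)."""
    _, energies = pocket_energy_scan(ligand, receptor)
    depth = float(np.min(energies))
    if depth >= 0:
        raise ValueError("ligand shows no attractive well to calibrate")
    factor = (target_depth / depth) ** 2
    for a in ligand.atoms:
        a.lj_epsilon *= factor
    ligand._cache.pop("lj_epsilons", None)
    return ligand


def make_ligand_set(spec: ToyScreenSpec,
                    receptor: MolecularSystem | None = None
                    ) -> list[LabeledLigand]:
    """Actives and decoys with calibrated pocket well depths.

    Actives are 5-atom hydrophobic carbon stars whose LJ epsilons are scaled
    to realise ``active_well_depth`` against the pocket; decoys are smaller
    neon stars (docking type ``other``, poorer steric fit) calibrated to the
    shallower ``decoy_well_depth``.
    """
    if receptor is None:
        receptor, _ = make_pocket_receptor(seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    ligands: list[LabeledLigand] = []
    for i in range(spec.n_active):
        lig = _star_ligand(rng, n_arms=4, bond_length=1.54, element="C",
                           lj_radius=1.9, lj_epsilon=0.1,
                           name=f"ACT{i+1:03d}")
        lig = _calibrate_depth(lig, receptor, spec.active_well_depth)
        ligands.append(LabeledLigand(id=lig.name, system=lig, label="active"))
    for i in range(spec.n_decoy):
        lig = _star_ligand(rng, n_arms=2, bond_length=1.8, element="Ne",
                           lj_radius=1.4, lj_epsilon=0.05,
                           name=f"DEC{i+1:03d}")
        lig = _calibrate_depth(lig, receptor, spec.decoy_well_depth)
        ligands.append(LabeledLigand(id=lig.name, system=lig, label="decoy"))
    return ligands


def harmonic_trajectory(system: MolecularSystem, force_constants,
                        temperature: float, n_frames: int,
                        seed: int = 0) -> Trajectory:
    """Frames from the exact Boltzmann distribution of independent harmonic
    modes centred on the current coordinates.

    ``force_constants`` (kcal·mol⁻¹·Å⁻², scalar or per-dof array of shape
    (N, 3) or (3N,)) set the per-mode variance k_B·T/k.
    """
    k = np.asarray(force_constants, dtype=float)
    if np.any(k <= 0):
        raise ValueError("force constants must be positive")
    n = system.n_atoms
    if k.ndim == 0:
        k = np.full((n, 3), float(k))
    k = k.reshape(n, 3)
    sigma = np.sqrt(K_B * temperature / k)
    rng = np.random.default_rng(seed)
    frames = system.coords[None, :, :] + rng.normal(0.0, 1.0,
                                                    (n_frames, n, 3)) * sigma
    return Trajectory(system=system, frames=frames, temperature=temperature)


def gaussian_du(mu: float, sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Seeded Normal(μ, σ²) ΔU samples (kcal·mol⁻¹)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return mu + sigma * rng.standard_normal(n)


@dataclass
class ToyDimer:
    """A one-dimensional two-atom binding system with an exact oracle.

    One fixed receptor atom at the origin; one ligand atom moving on the
    x-axis inside [x_min, x_max].  The physical interaction is a single LJ
    pair (depth ``epsilon`` at separation ``rmin``), so the bound-state
    configuration integral is a 1-D quadrature.
    """

    complex_system: MolecularSystem
    ligand_system: MolecularSystem
    bound: AlchemicalSystem
    unbound: AlchemicalSystem
    rmin: float
    epsilon: float
    x_min: float
    x_max: float
    restraint_k: float
    restraint_target: float

    def pair_energy(self, x):
        """Physical interaction energy at ligand position x (oracle input)."""
        return lj_energy_pairwise(np.asarray(x, dtype=float), self.rmin,
                                  self.epsilon)


def make_toy_dimer(well_depth: float = -4.0, rmin: float = 3.4,
                   x_min: float = 2.2, x_max: float = 10.2,
                   restraint_k: float = 10.0) -> ToyDimer:
    """Build the 1-D dimer with a distance restraint at the LJ minimum."""
    eps = abs(well_depth)
    rec = Atom.from_element("C", (0.0, 0.0, 0.0), name="REC",
                            lj_radius=rmin / 2.0, lj_epsilon=eps,
                            role="receptor")
    lig = Atom.from_element("C", (rmin, 0.0, 0.0), name="LIG",
                            lj_radius=rmin / 2.0, lj_epsilon=eps,
                            role="ligand")
    complex_system = MolecularSystem([rec, lig], bonds=[], name="dimer")
    ligand_system = complex_system.subset([1], name="dimer_ligand")
    ligand_system.atoms[0].role = "ligand"
    half_x = (x_max - x_min) / 2.0
    box = SearchBox(center=((x_min + x_max) / 2.0, 0.0, 0.0),
                    half_lengths=(half_x, 0.5, 0.5))
    bound_restraint = Restraint(kind="distance", force_constant=restraint_k,
                                target=rmin, anchor_atoms=(0,))
    unbound_restraint = Restraint(kind="distance", force_constant=restraint_k,
                                  target=rmin,
                                  anchor_point=np.zeros(3))
    bound = AlchemicalSystem(complex_system, [bound_restraint], box=box)
    unbound = AlchemicalSystem(ligand_system, [unbound_restraint], box=box)
    return ToyDimer(complex_system=complex_system, ligand_system=ligand_system,
                    bound=bound, unbound=unbound, rmin=rmin, epsilon=eps,
                    x_min=x_min, x_max=x_max, restraint_k=restraint_k,
                    restraint_target=rmin)


def make_ranked_labels(n_active: int, n_total: int, quality: float,
                       seed: int = 0) -> list[str]:
    """A ranked active/decoy label list with tunable ranking quality.

    quality 1 → perfect ranking (all actives first); 0 → random order.
    Intermediate values mix the two by seeded noise on the ideal positions.
    """
    if not 0 < n_active <= n_total:
        raise ValueError("need 0 < n_active <= n_total")
    rng = np.random.default_rng(seed)
    ideal = np.concatenate([np.zeros(n_active), np.ones(n_total - n_active)])
    keys = quality * ideal + rng.random(n_total)
    order = np.argsort(keys, kind="stable")
    return ["active" if ideal[i] == 0 else "decoy" for i in order]
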