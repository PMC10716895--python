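"""Molecular-mechanics energy and implicit-solvent free energy terms.

A configuration's energy decomposes into harmonic bonds/angles, cosine
dihedrals, Lennard-Jones 12-6 and Coulomb nonbonded terms (E_MM), a
generalized-Born polar solvation term with Debye ionic screening (G_polar),
and a surface-area nonpolar term γ·A_SA (G_nonpolar).

The GB model is the screened Still pairwise energy

    G_polar = −(k_e/2) Σ_i Σ_j D_ij q_i q_j / g_ij ,
    g_ij    = sqrt(r_ij² + α_i α_j exp(−r_ij²/(4 α_i α_j))) ,
    D_ij    = 1 − exp(−κ g_ij)/ε_s ,

with the double sum including i = j (g_ii = α_i), so a lone Born ion
recovers −(k_e/2)(1 − 1/ε_s)/α.  Effective radii α_i come from pairwise
descreening integrals with the Onufriev–Bashford–Case tanh rescaling
(coefficients 1.0, 0.8, 4.85); the stored per-atom ``gb_radius`` is the
intrinsic (already offset) descreening radius, so an isolated atom has
α equal to its gb_radius exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, K_E, MOLAR_TO_PER_A3
from .chemio import MolecularSystem
from .errors import ParameterError


@dataclass(frozen=True)
class SolventModel:
    """Continuum-solvent settings.

    gamma is the surface-tension coefficient of the nonpolar term in
    kcal·mol⁻¹·Å⁻²; ion_concentration is the monovalent salt concentration
    in mol·L⁻¹ entering the Debye screening length.
    """

    epsilon_s: float = 78.5
    ion_concentration: float = 0.0
    gamma: float = 0.005
    probe_radius: float = 1.4
    temperature: float = 300.0

    def __post_init__(self):
        if self.epsilon_s <= 1:
            raise ValueError("epsilon_s must exceed 1")
        if self.ion_concentration < 0 or self.gamma < 0:
            raise ValueError("ion_concentration and gamma must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class EnergyTerms:
    """Per-term energy decomposition for one configuration (kcal·mol⁻¹)."""

    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_lj: float = 0.0
    e_coulomb: float = 0.0
    g_polar: float = 0.0
    g_nonpolar: float = 0.0

    @property
    def total_mm(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral
                + self.e_lj + self.e_coulomb)

    @property
    def total(self) -> float:
        return self.total_mm + self.g_polar + self.g_nonpolar


@dataclass
class BondedParams:
    """Explicit bonded-term lists.

    bonds:     (i, j, k, r0)          with U = k (r − r0)²
    angles:    (i, j, k, k_th, th0)   with U = k_th (θ − θ0)²   [θ in rad]
    dihedrals: (i, j, k, l, k_phi, n, delta)  with U = k_phi (1 + cos(nφ − δ))
    """

    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)
    dihedrals: list[tuple] = field(default_factory=list)


def equilibrium_bond_params(system: MolecularSystem,
                            k_bond: float = 300.0) -> BondedParams:
    """Harmonic bond parameters with r0 taken from the current geometry.

    Useful when a structure arrives without a force field: every listed bond
    becomes a stiff spring at its observed length (k in kcal·mol⁻¹·Å⁻²).
    """
    coords = system.coords
    bonds = [(i, j, k_bond, float(np.linalg.norm(coords[i] - coords[j])))
             for i, j in system.bonds]
    return BondedParams(bonds=bonds)


def _angle(coords, i, j, k):
    a = coords[i] - coords[j]
    b = coords[k] - coords[j]
    cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _dihedral(coords, i, j, k, l):
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.arctan2(np.dot(m1, n2), np.dot(n1, n2))


def nonbonded_pair_indices(system: MolecularSystem):
    """Index arrays (i, j) of nonbonded pairs (i < j, 1-2/1-3 excluded)."""
    n = system.n_atoms
    ii, jj = np.triu_indices(n, k=1)
    excl = system.excluded_pairs()
    if excl:
        mask = np.array([(int(a), int(b)) not in excl for a, b in zip(ii, jj)])
        ii, jj = ii[mask], jj[mask]
    return ii, jj


def lj_energy_pairwise(r, rmin, eps):
    """12-6 LJ with Rmin convention: U = ε[(rmin/r)¹² − 2(rmin/r)⁶]."""
    x6 = (rmin / r) ** 6
    return eps * (x6 * x6 - 2.0 * x6)


def mm_energy(system: MolecularSystem,
              params: BondedParams | None = None) -> EnergyTerms:
    """Molecular-mechanics energy of one configuration.

    Every bond listed on the system must have a bond parameter; angle and
    dihedral terms are evaluated for exactly the tuples listed in ``params``.
    Nonbonded pairs use Lorentz–Berthelot combining (Rmin_ij = R_i + R_j with
    lj_radius = Rmin/2, ε_ij = √(ε_i ε_j)) and Coulomb with interior
    dielectric 1; 1-2 and 1-3 pairs are excluded.
    """
    params = params or BondedParams()
    terms = EnergyTerms()
    coords = system.coords

    bond_params = {(min(b[0], b[1]), max(b[0], b[1])): (b[2], b[3])
                   for b in params.bonds}
    for (i, j) in system.bonds:
        if (i, j) not in bond_params:
            raise ParameterError(f"no bond parameter for bond ({i},{j})")
        k, r0 = bond_params[(i, j)]
        r = float(np.linalg.norm(coords[i] - coords[j]))
        terms.e_bond += k * (r - r0) ** 2

    for (i, j, k_idx, k_th, th0) in params.angles:
        th = _angle(coords, i, j, k_idx)
        terms.e_angle += k_th * (th - th0) ** 2

    for (i, j, k_idx, l, k_phi, n_per, delta) in params.dihedrals:
        phi = _dihedral(coords, i, j, k_idx, l)
        terms.e_dihedral += k_phi * (1.0 + np.cos(n_per * phi - delta))

    ii, jj = nonbonded_pair_indices(system)
    if len(ii):
        r = np.linalg.norm(coords[ii] - coords[jj], axis=-1)
        rmin = system.lj_radii[ii] + system.lj_radii[jj]
        eps = np.sqrt(system.lj_epsilons[ii] * system.lj_epsilons[jj])
        terms.e_lj = float(np.sum(lj_energy_pairwise(r, rmin, eps)))
        terms.e_coulomb = float(np.sum(
            K_E * system.charges[ii] * system.charges[jj] / r))
    return terms


# ---------------------------------------------------------------------------
# Generalized Born
# ---------------------------------------------------------------------------

_OBC_A, _OBC_B, _OBC_C = 1.0, 0.8, 4.85


def born_radii(system: MolecularSystem) -> np.ndarray:
    """Effective Born radii α_i (Å) via pairwise descreening + OBC rescaling.

    An isolated atom's α equals its intrinsic gb_radius; burial only ever
    increases α.
    """
    rho = system.gb_radii.astype(float)
    if np.any(rho <= 0):
        raise ParameterError("all gb_radius values must be positive")
    n = system.n_atoms
    coords = system.coords
    r = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)

    rho_i = rho[:, None]
    rho_j = rho[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        U = r + rho_j
        L = np.maximum(np.abs(r - rho_j), rho_i)
        term = 0.5 * (1.0 / L - 1.0 / U
                      + 0.25 * (1.0 / U ** 2 - 1.0 / L ** 2) * (r - rho_j ** 2 / r)
                      + (0.5 / r) * np.log(L / U))
        # atom i swallowed inside j: extra closure term
        inside = rho_i < rho_j - r
        term = np.where(inside, term + (1.0 / rho_i - 1.0 / L), term)
        # atom j engulfed by i (no descreening) and the diagonal contribute 0
        term = np.where(rho_i >= U, 0.0, term)
    np.fill_diagonal(term, 0.0)
    I = np.sum(np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0), axis=1)
    I = np.maximum(I, 0.0)

    psi = I * rho
    tanh_term = np.tanh(_OBC_A * psi - _OBC_B * psi ** 2 + _OBC_C * psi ** 3)
    return rho / (1.0 - tanh_term)


def still_g(r, alpha_i, alpha_j):
    """Still's pairwise GB distance g_ij (Å); g(0, α, α) = α, g → r at large r."""
    r = np.asarray(r, dtype=float)
    aa = np.asarray(alpha_i, dtype=float) * np.asarray(alpha_j, dtype=float)
    return np.sqrt(r ** 2 + aa * np.exp(-(r ** 2) / (4.0 * aa)))


def debye_kappa(model: SolventModel) -> float:
    """Inverse Debye screening length κ (Å⁻¹); zero at zero ionic strength.

    κ² = 8π k_e n / (ε_s k_B T) with n the ion number density in Å⁻³, the
    monovalent-salt form (ionic strength equal to the concentration).
    """
    if model.ion_concentration == 0:
        return 0.0
    n_density = model.ion_concentration * MOLAR_TO_PER_A3
    kappa_sq = (8.0 * np.pi * K_E * n_density
                / (model.epsilon_s * K_B * model.temperature))
    return float(np.sqrt(kappa_sq))


def gb_polar_energy(system: MolecularSystem, alphas: np.ndarray,
                    model: SolventModel) -> float:
    """Screened Still GB polar solvation energy (kcal·mol⁻¹).

    Full double sum over atom pairs including the self terms i = j.
    """
    q = system.charges
    if not np.any(q):
        return 0.0
    alphas = np.asarray(alphas, dtype=float)
    coords = system.coords
    r = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    g = still_g(r, alphas[:, None], alphas[None, :])
    kappa = debye_kappa(model)
    D = 1.0 - np.exp(-kappa * g) / model.epsilon_s
    qq = q[:, None] * q[None, :]
    return float(-(K_E / 2.0) * np.sum(D * qq / g))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(system: MolecularSystem, probe_radius: float = 1.4,
         n_points: int = 960) -> float:
    """Shrake–Rupley solvent-accessible surface area (Å²).

    Atom radii are the LJ radii; each atom's accessible fraction is the
    share of its quadrature points not buried inside any neighbour's
    expanded sphere.
    """
    radii = system.lj_radii + probe_radius
    coords = system.coords
    pts = sphere_points(n_points)
    total = 0.0
    n = system.n_atoms
    d2 = np.sum((coords[:, None] - coords[None, :]) ** 2, axis=-1)
    for i in range(n):
        neighbors = np.nonzero(
            (d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i))[0]
        surface = coords[i] + radii[i] * pts
        if len(neighbors):
            dist2 = np.sum(
                (surface[:, None, :] - coords[neighbors][None, :, :]) ** 2,
                axis=-1)
            exposed = np.all(dist2 >= (radii[neighbors] ** 2)[None, :], axis=1)
            frac = float(np.mean(exposed))
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * radii[i] ** 2
    return total


def nonpolar_energy(area: float, model: SolventModel) -> float:
    """Nonpolar solvation term γ·A_SA (kcal·mol⁻¹)."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return model.gamma * area


def configuration_energy(system: MolecularSystem,
                         params: BondedParams | None = None,
                         model: SolventModel | None = None) -> EnergyTerms:
    """Full per-configuration decomposition: E_MM + G_polar + G_nonpolar."""
    model = model or SolventModel()
    terms = mm_energy(system, params)
    alphas = born_radii(system)
    terms.g_polar = gb_polar_energy(system, alphas, model)
    terms.g_nonpolar = nonpolar_energy(
        sasa(system, probe_radius=model.probe_radius), model)
    return terms
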