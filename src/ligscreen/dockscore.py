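"""Empirical docking score and rigid-body pose optimisation.

The score is the weighted sum of two Gaussians of the surface distance, a
quadratic repulsion on negative surface distance, a hydrophobic ramp between
hydrophobic carbons and a hydrogen-bond ramp between donor/acceptor pairs —
the classic empirical intermolecular scoring function of Trott & Olson's
optimiser family.  Ligands are treated as rigid bodies: only intermolecular
pairs contribute, and poses have exactly six degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .chemio import DockType, MolecularSystem
from .errors import LigscreenError


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned box constraining the ligand centroid during search."""

    center: tuple[float, float, float]
    half_lengths: tuple[float, float, float]

    def __post_init__(self):
        if any(h <= 0 for h in self.half_lengths):
            raise ValueError("half_lengths must be positive")

    def contains(self, point: np.ndarray) -> bool:
        d = np.abs(np.asarray(point) - np.asarray(self.center))
        return bool(np.all(d <= np.asarray(self.half_lengths) + 1e-12))

    def clip(self, point: np.ndarray) -> np.ndarray:
        c, h = np.asarray(self.center), np.asarray(self.half_lengths)
        return np.clip(point, c - h, c + h)


@dataclass(frozen=True)
class ScoringWeights:
    """Term weights and interaction cutoff of the empirical score."""

    w_gauss1: float = -0.0356
    w_gauss2: float = -0.00516
    w_repulsion: float = 0.840
    w_hydrophobic: float = -0.0351
    w_hbond: float = -0.587
    cutoff: float = 8.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


@dataclass
class Pose:
    """Rigid-body placement of a ligand: centroid translation + rotation.

    Applying a pose puts the ligand centroid at ``translation`` and rotates
    the body about its centroid by ``rotation`` (a unit quaternion in
    (x, y, z, w) scalar-last order).
    """

    translation: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    score: float | None = None
    term_breakdown: dict[str, float] | None = None

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.norm(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation quaternion must have unit norm")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform ligand coordinates (rotation about the centroid)."""
        centroid = coords.mean(axis=0)
        rot = Rotation.from_quat(self.rotation)
        return rot.apply(coords - centroid) + self.translation


def surface_distance(r: float, t1_radius: float, t2_radius: float) -> float:
    """Surface separation d = r − R₁ − R₂ (negative when atoms overlap)."""
    if np.any(np.asarray(r) < 0):
        raise LigscreenError("interatomic distance r must be >= 0")
    return r - t1_radius - t2_radius


def _is_hydrophobic(t: DockType) -> bool:
    return t == DockType.CARBON_HYDROPHOBIC


def _is_donor(t: DockType) -> bool:
    return t in (DockType.POLAR_DONOR, DockType.DONOR_ACCEPTOR)


def _is_acceptor(t: DockType) -> bool:
    return t in (DockType.POLAR_ACCEPTOR, DockType.DONOR_ACCEPTOR)


def hbond_pair(t1: DockType, t2: DockType) -> bool:
    """True when one atom can donate and the other accept."""
    return (_is_donor(t1) and _is_acceptor(t2)) or (_is_donor(t2) and _is_acceptor(t1))


def _terms(d: np.ndarray, hydrophobic: np.ndarray, hbond: np.ndarray,
           cutoff: float) -> dict[str, np.ndarray]:
    """Unweighted per-pair term values (vectorised over surface distances)."""
    d = np.asarray(d, dtype=float)
    inside = d < cutoff
    gauss1 = np.where(inside, np.exp(-((d / 0.5) ** 2)), 0.0)
    gauss2 = np.where(inside, np.exp(-(((d - 3.0) / 2.0) ** 2)), 0.0)
    repulsion = np.where(inside & (d < 0), d ** 2, 0.0)
    h = np.clip((1.5 - d) / 1.0, 0.0, 1.0)          # 1 for d<=0.5, 0 for d>=1.5
    b = np.clip(-d / 0.7, 0.0, 1.0)                 # 1 for d<=-0.7, 0 for d>=0
    hydro = np.where(inside & hydrophobic, h, 0.0)
    hb = np.where(inside & hbond, b, 0.0)
    return {"gauss1": gauss1, "gauss2": gauss2, "repulsion": repulsion,
            "hydrophobic": hydro, "hbond": hb}


def pair_term(d: float, types: tuple[DockType, DockType],
              weights: ScoringWeights = ScoringWeights()) -> float:
    """Score contribution of one atom pair at surface distance ``d`` (Å)."""
    t1, t2 = types
    terms = _terms(np.array([d]),
                   np.array([_is_hydrophobic(t1) and _is_hydrophobic(t2)]),
                   np.array([hbond_pair(t1, t2)]),
                   weights.cutoff)
    return float(weights.w_gauss1 * terms["gauss1"][0]
                 + weights.w_gauss2 * terms["gauss2"][0]
                 + weights.w_repulsion * terms["repulsion"][0]
                 + weights.w_hydrophobic * terms["hydrophobic"][0]
                 + weights.w_hbond * terms["hbond"][0])


def _pair_masks(ligand: MolecularSystem, receptor: MolecularSystem):
    lt, rt = ligand.dock_types, receptor.dock_types
    if any(t is None for t in lt) or any(t is None for t in rt):
        raise LigscreenError("dock types must be assigned before scoring")
    l_hydro = np.array([_is_hydrophobic(t) for t in lt])
    r_hydro = np.array([_is_hydrophobic(t) for t in rt])
    l_don = np.array([_is_donor(t) for t in lt])
    l_acc = np.array([_is_acceptor(t) for t in lt])
    r_don = np.array([_is_donor(t) for t in rt])
    r_acc = np.array([_is_acceptor(t) for t in rt])
    hydrophobic = l_hydro[:, None] & r_hydro[None, :]
    hbond = (l_don[:, None] & r_acc[None, :]) | (l_acc[:, None] & r_don[None, :])
    return hydrophobic, hbond


def _score_coords(lig_coords: np.ndarray, receptor: MolecularSystem,
                  lig_radii: np.ndarray, hydrophobic, hbond,
                  weights: ScoringWeights) -> tuple[float, dict[str, float]]:
    r = np.linalg.norm(lig_coords[:, None, :] - receptor.coords[None, :, :], axis=-1)
    d = r - lig_radii[:, None] - receptor.lj_radii[None, :]
    terms = _terms(d, hydrophobic, hbond, weights.cutoff)
    breakdown = {k: float(v.sum()) for k, v in terms.items()}
    score = (weights.w_gauss1 * breakdown["gauss1"]
             + weights.w_gauss2 * breakdown["gauss2"]
             + weights.w_repulsion * breakdown["repulsion"]
             + weights.w_hydrophobic * breakdown["hydrophobic"]
             + weights.w_hbond * breakdown["hbond"])
    return float(score), breakdown


def score_pose(ligand: MolecularSystem, receptor: MolecularSystem, pose: Pose,
               weights: ScoringWeights = ScoringWeights()) -> Pose:
    """Score a pose over all intermolecular pairs within the cutoff."""
    hydrophobic, hbond = _pair_masks(ligand, receptor)
    coords = pose.apply(ligand.coords)
    score, breakdown = _score_coords(coords, receptor, ligand.lj_radii,
                                     hydrophobic, hbond, weights)
    return Pose(translation=pose.translation, rotation=pose.rotation,
                score=score, term_breakdown=breakdown)


def optimize_pose(ligand: MolecularSystem, receptor: MolecularSystem,
                  box: SearchBox, weights: ScoringWeights = ScoringWeights(),
                  n_restarts: int = 8, seed: int = 0,
                  initial_pose: Pose | None = None) -> Pose:
    """Iterated local search over the six rigid-body degrees of freedom.

    Each restart perturbs the incumbent (random translation within the box,
    random rotation), runs a derivative-free simplex minimisation, and keeps
    the result only if it improves the score.  Deterministic for a fixed
    seed; ties keep the first pose found.
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    hydrophobic, hbond = _pair_masks(ligand, receptor)
    lig_radii = ligand.lj_radii
    lig_extent = float(np.max(np.linalg.norm(
        ligand.coords - ligand.coords.mean(axis=0), axis=-1)))
    if lig_extent > 0 and min(box.half_lengths) < 0.5:
        _warnings.warn("search box is very small relative to the ligand; "
                       "centroid moves are tightly constrained", stacklevel=2)

    def params_to_pose(p: np.ndarray) -> Pose:
        t = box.clip(p[:3])
        rotvec = p[3:]
        quat = Rotation.from_rotvec(rotvec).as_quat()
        quat = quat / np.linalg.norm(quat)
        return Pose(translation=t, rotation=quat)

    def objective(p: np.ndarray) -> float:
        t = p[:3]
        if not box.contains(t):
            # quadratic penalty keeps the simplex inside the box
            excess = np.linalg.norm(t - box.clip(t))
            t = box.clip(t)
            penalty = 10.0 * excess ** 2
        else:
            penalty = 0.0
        rot = Rotation.from_rotvec(p[3:])
        centroid = ligand.coords.mean(axis=0)
        coords = rot.apply(ligand.coords - centroid) + t
        s, _ = _score_coords(coords, receptor, lig_radii, hydrophobic, hbond,
                             weights)
        return s + penalty

    if initial_pose is None:
        initial_pose = Pose(translation=np.asarray(box.center, dtype=float))
    best = score_pose(ligand, receptor, initial_pose, weights)
    if n_restarts <= 0:
        return best

    best_params = np.concatenate([
        best.translation,
        Rotation.from_quat(best.rotation).as_rotvec(),
    ])
    half = np.asarray(box.half_lengths)
    center = np.asarray(box.center)
    for _ in range(int(n_restarts)):
        start = best_params.copy()
        start[:3] = center + rng.uniform(-1.0, 1.0, 3) * half
        start[3:] = Rotation.random(random_state=rng).as_rotvec()
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6,
                                "maxiter": 2000, "adaptive": True})
        candidate = score_pose(ligand, receptor, params_to_pose(res.x), weights)
        if candidate.score < best.score:
            best = candidate
            best_params = np.concatenate([
                best.translation,
                Rotation.from_quat(best.rotation).as_rotvec(),
            ])
    return best
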