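"""Alchemical free energy perturbation over a restrained thermodynamic cycle.

A coupling parameter λ ∈ [0, 1] scales the ligand–environment interactions
from fully physical (λ = 0) to annihilated (λ = 1); a second parameter
couples harmonic restraints that keep the fading ligand in the binding site.
Ensembles at each λ window come from a Metropolis sampler (standing in for an
MD engine), per-window free energy increments from the Zwanzig exponential
average

    ΔG_i = −k_B T ln ⟨exp(−ΔU_i / k_B T)⟩_{λ_i} ,

and the binding free energy closes a four-leg cycle — restraint coupling and
decoupling in the bound state, the same in the unbound state — with the
transfer of the non-interacting ligand between environments contributing
exactly zero.  Each leg is run forward and backward; the two estimates are
averaged and their mismatch reported as a hysteresis diagnostic.

Sign convention: ΔG_binding = −[ΔG(bound_restrain) + ΔG(bound_decouple)
− ΔG(unbound_decouple) − ΔG(unbound_restrain)], so stronger binding gives a
more negative ΔG_binding.  No standard-state volume correction is applied:
the unbound leg samples the same confinement volume as the bound leg, which
makes toy-cycle results directly comparable to configuration-integral
quadrature over that volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp

from .chemio import MolecularSystem
from .constants import K_B, K_E
from .dockscore import SearchBox
from .errors import LigscreenError

LEG_NAMES = ("bound_restrain", "bound_decouple",
             "unbound_decouple", "unbound_restrain")

#: Soft-core stiffness: t = 1 / (α_sc·λ + (r/rmin)⁶) keeps U finite at overlap.
ALPHA_SOFTCORE = 0.5


@dataclass(frozen=True)
class LambdaSchedule:
    """Strictly increasing coupling values from exactly 0 to exactly 1."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = tuple(float(x) for x in self.values)
        object.__setattr__(self, "values", v)
        if len(v) < 2:
            raise ValueError("schedule needs at least 2 values")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule endpoints must be exactly 0 and 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing")

    @classmethod
    def uniform(cls, K: int) -> "LambdaSchedule":
        if K < 2:
            raise ValueError("K must be >= 2")
        return cls(tuple(np.linspace(0.0, 1.0, K)))

    @classmethod
    def geometric(cls, K: int, first: float = 1e-3) -> "LambdaSchedule":
        """0, first, …, 1 with geometric spacing — dense near zero coupling.

        Suited to restraint-coupling legs, where the sampled distribution
        narrows like λ^(−1/2) and uniform windows overlap badly near λ = 0.
        """
        if K < 3:
            return cls.uniform(K)
        ratio = (1.0 / first) ** (1.0 / (K - 2))
        vals = [0.0] + [first * ratio ** i for i in range(K - 1)]
        vals[-1] = 1.0
        return cls(tuple(vals))

    @property
    def K(self) -> int:
        return len(self.values)


@dataclass
class Restraint:
    """Harmonic restraint on the ligand.

    kind "distance": k·(d − target)² with d the distance between the ligand
    centroid and the anchor (centroid of non-hydrogen receptor anchor atoms,
    or an explicit ``anchor_point`` for unbound systems).
    kind "rmsd": k·RMSD² of the ligand against ``reference`` coordinates
    after optimal rigid superposition (shape-only restraint).
    """

    kind: str
    force_constant: float
    target: float = 0.0
    anchor_atoms: tuple[int, ...] = ()
    anchor_point: np.ndarray | None = None
    reference: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("distance", "rmsd"):
            raise ValueError(f"unknown restraint kind '{self.kind}'")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.anchor_point is not None:
            self.anchor_point = np.asarray(self.anchor_point, dtype=float)
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)

    def resolve_anchor(self, receptor_coords: np.ndarray,
                       receptor_elements=None) -> np.ndarray:
        if self.anchor_point is not None:
            return self.anchor_point
        if not self.anchor_atoms:
            raise LigscreenError("distance restraint needs anchor atoms or "
                                 "an explicit anchor point")
        idx = np.asarray(self.anchor_atoms, dtype=int)
        if receptor_elements is not None:
            if any(str(receptor_elements[i]).upper() == "H" for i in idx):
                raise LigscreenError("restraint anchors must be non-hydrogen")
        return receptor_coords[idx].mean(axis=0)

    def energy(self, lig_coords: np.ndarray,
               receptor_coords: np.ndarray | None = None,
               receptor_elements=None) -> float:
        if self.force_constant == 0.0:
            return 0.0
        if self.kind == "distance":
            anchor = self.resolve_anchor(
                receptor_coords if receptor_coords is not None
                else np.zeros((0, 3)), receptor_elements)
            d = float(np.linalg.norm(lig_coords.mean(axis=0) - anchor))
            return self.force_constant * (d - self.target) ** 2
        ref = self.reference
        if ref is None:
            raise LigscreenError("rmsd restraint needs reference coordinates")
        a = lig_coords - lig_coords.mean(axis=0)
        b = ref - ref.mean(axis=0)
        if a.shape[0] >= 3:
            rot, _ = Rotation.align_vectors(b, a)
            a = rot.apply(a)
        rmsd2 = float(np.mean(np.sum((a - b) ** 2, axis=-1)))
        return self.force_constant * rmsd2


@dataclass
class FEPLeg:
    """Per-window increments of one leg in one direction."""

    name: str
    direction: str  # "forward" | "backward"
    per_window_dg: np.ndarray
    per_window_se: np.ndarray

    def __post_init__(self):
        self.per_window_dg = np.asarray(self.per_window_dg, dtype=float)
        self.per_window_se = np.asarray(self.per_window_se, dtype=float)

    @property
    def total(self) -> float:
        return float(np.sum(self.per_window_dg))

    @property
    def total_se(self) -> float:
        return float(np.sqrt(np.sum(self.per_window_se ** 2)))


@dataclass
class FEPResult:
    """Closed-cycle binding free energy with per-leg diagnostics."""

    legs: dict[str, tuple[FEPLeg, FEPLeg]]
    delta_g_binding: float
    delta_g_se: float
    hysteresis: dict[str, float]
    leg_estimates: dict[str, float]


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def zwanzig_increment(du_samples, temperature: float) -> float:
    """Zwanzig free energy increment −k_BT ln⟨e^{−βΔU}⟩ (log-sum-exp stable)."""
    du = np.asarray(du_samples, dtype=float)
    if du.size == 0:
        raise LigscreenError("Zwanzig estimator needs at least one sample")
    beta = 1.0 / (K_B * temperature)
    return float(-(logsumexp(-beta * du) - np.log(du.size)) / beta)


def zwanzig_increment_with_se(du_samples, temperature: float) -> tuple[float, float]:
    """Increment plus a delta-method standard error (samples treated iid)."""
    du = np.asarray(du_samples, dtype=float)
    dg = zwanzig_increment(du, temperature)
    beta = 1.0 / (K_B * temperature)
    x = np.exp(-beta * (du - du.min()))
    mean, n = x.mean(), x.size
    se = (x.std(ddof=1) / (mean * np.sqrt(n))) / beta if n > 1 else np.inf
    return dg, float(se)


def sum_windows(per_window) -> float:
    """Total ΔG as the arithmetic sum of per-window increments."""
    return float(np.sum(np.asarray(per_window, dtype=float))) if len(per_window) else 0.0


# ---------------------------------------------------------------------------
# λ-coupled potential
# ---------------------------------------------------------------------------

class AlchemicalSystem:
    """A system with a λ-coupled ligand–environment potential.

    Ligand/receptor membership comes from atom roles.  The potential is

        U(λ, λ_r) = U_intra(ligand) + (1−λ)·U_elec,inter
                    + (1−λ)·U_LJ,softcore(λ) + λ_r·U_restraints ,

    with the receptor held rigid (its internal energy is a constant and is
    omitted).  An optional box confines the ligand centroid (infinite energy
    outside), defining the configuration volume shared by the bound and
    unbound legs.
    """

    def __init__(self, system: MolecularSystem, restraints=(),
                 box: SearchBox | None = None, alpha_sc: float = ALPHA_SOFTCORE,
                 move_mask: np.ndarray | None = None):
        self.system = system
        self.restraints = list(restraints)
        self.box = box
        self.alpha_sc = alpha_sc
        self.lig = system.ligand_indices()
        self.rec = system.receptor_indices()
        if self.lig.size == 0:
            raise LigscreenError("alchemical system needs ligand-role atoms")
        self.rec_coords = system.coords[self.rec]
        self.rec_elements = system.elements[self.rec]
        q = system.charges
        rl = system.lj_radii
        el = system.lj_epsilons
        self.qq = q[self.lig][:, None] * q[self.rec][None, :]
        self.rmin = rl[self.lig][:, None] + rl[self.rec][None, :]
        self.eps = np.sqrt(el[self.lig][:, None] * el[self.rec][None, :])
        # ligand intra nonbonded pairs (beyond 1-2/1-3)
        excl = system.excluded_pairs()
        li, lj = [], []
        for a_pos, a in enumerate(self.lig):
            for b_pos in range(a_pos + 1, self.lig.size):
                b = self.lig[b_pos]
                if (min(a, b), max(a, b)) not in excl:
                    li.append(a_pos)
                    lj.append(b_pos)
        self._intra_i = np.asarray(li, dtype=int)
        self._intra_j = np.asarray(lj, dtype=int)
        self._intra_qq = (q[self.lig][self._intra_i] * q[self.lig][self._intra_j]
                          if len(li) else np.zeros(0))
        self._intra_rmin = (rl[self.lig][self._intra_i] + rl[self.lig][self._intra_j]
                            if len(li) else np.zeros(0))
        self._intra_eps = (np.sqrt(el[self.lig][self._intra_i]
                                   * el[self.lig][self._intra_j])
                           if len(li) else np.zeros(0))

    @property
    def ligand_coords(self) -> np.ndarray:
        return self.system.coords[self.lig]

    def potential(self, lig_coords: np.ndarray, lam: float,
                  restraint_lam: float) -> float:
        lig_coords = np.asarray(lig_coords, dtype=float).reshape(-1, 3)
        if self.box is not None and not self.box.contains(lig_coords.mean(axis=0)):
            return float("inf")
        u = 0.0
        # ligand intramolecular nonbonded
        if self._intra_i.size:
            r = np.linalg.norm(lig_coords[self._intra_i]
                               - lig_coords[self._intra_j], axis=-1)
            x6 = (self._intra_rmin / r) ** 6
            u += float(np.sum(self._intra_eps * (x6 * x6 - 2.0 * x6)))
            u += float(np.sum(K_E * self._intra_qq / r))
        # ligand–environment, λ-coupled
        if self.rec.size and lam < 1.0:
            r = np.linalg.norm(lig_coords[:, None, :]
                               - self.rec_coords[None, :, :], axis=-1)
            u += (1.0 - lam) * float(np.sum(K_E * self.qq / np.maximum(r, 1e-12)))
            t = 1.0 / (self.alpha_sc * lam + (r / self.rmin) ** 6)
            u += (1.0 - lam) * float(np.sum(self.eps * (t * t - 2.0 * t)))
        # restraints
        if restraint_lam > 0.0 and self.restraints:
            u += restraint_lam * sum(
                res.energy(lig_coords, self.rec_coords, self.rec_elements)
                for res in self.restraints)
        return u


def coupled_potential(system: MolecularSystem, lig_coords, lam: float,
                      restraints=(), restraint_lam: float = 0.0,
                      box: SearchBox | None = None,
                      alpha_sc: float = ALPHA_SOFTCORE) -> float:
    """One-shot λ-coupled potential evaluation (see :class:`AlchemicalSystem`)."""
    if not (0.0 <= lam <= 1.0) or not (0.0 <= restraint_lam <= 1.0):
        raise LigscreenError("lambda parameters must lie in [0, 1]")
    asys = AlchemicalSystem(system, restraints, box, alpha_sc)
    return asys.potential(lig_coords, lam, restraint_lam)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def metropolis_sample(potential, state0, n_steps: int, step_size,
                      temperature: float, seed: int,
                      proposal=None) -> tuple[list, float]:
    """Metropolis chain at k_BT; returns (states incl. initial, accept rate).

    The default proposal adds isotropic Gaussian noise of scale ``step_size``
    (scalar or broadcastable per-dof array; zero entries freeze dofs).
    """
    if np.any(np.asarray(step_size, dtype=float) < 0):
        raise ValueError("step sizes must be >= 0")
    rng = np.random.default_rng(seed)
    state = np.asarray(state0, dtype=float).copy()
    if proposal is None:
        def proposal(rng, s):
            return s + rng.normal(0.0, 1.0, s.shape) * step_size
    beta = 1.0 / (K_B * temperature)
    u = potential(state)
    states = [state.copy()]
    n_accept = 0
    for _ in range(int(n_steps)):
        cand = proposal(rng, state)
        u_cand = potential(cand)
        if u_cand <= u or rng.random() < np.exp(-beta * (u_cand - u)):
            state, u = cand, u_cand
            n_accept += 1
        states.append(state.copy())
    rate = n_accept / n_steps if n_steps else 0.0
    return states, rate


def rigid_ligand_proposal(step_size: float, rot_step: float = 0.15):
    """Rigid-body proposal: random translation + small random rotation of the
    whole ligand about its centroid (preserves internal geometry)."""
    def proposal(rng, coords):
        coords = coords.reshape(-1, 3)
        shift = rng.normal(0.0, step_size, 3)
        centroid = coords.mean(axis=0)
        if coords.shape[0] > 1 and rot_step > 0:
            rot = Rotation.from_rotvec(rng.normal(0.0, rot_step, 3))
            moved = rot.apply(coords - centroid) + centroid + shift
        else:
            moved = coords + shift
        return moved
    return proposal


@dataclass(frozen=True)
class SamplerSettings:
    """Metropolis settings for one λ window.

    ``jump_probability`` mixes occasional uniform in-box teleports of the
    ligand centroid into the local proposal — a symmetric kernel that keeps
    near-flat (weakly coupled) windows well mixed.
    """

    n_steps: int = 2000
    equilibration_fraction: float = 0.2
    step_size: float | tuple = 0.3
    stride: int = 5
    rigid_ligand: bool = False
    rotation_step: float = 0.15
    jump_probability: float = 0.1


def make_window_proposal(settings: SamplerSettings, box):
    """Proposal kernel for λ-window sampling (symmetric mixture).

    Local move: per-dof Gaussian of scale step_size, or a rigid-body
    translation+rotation when ``rigid_ligand`` is set.  With probability
    ``jump_probability`` (and a box present) the ligand centroid teleports
    uniformly inside the box instead; axes whose step size is zero stay
    frozen.
    """
    step = np.asarray(settings.step_size, dtype=float)
    rigid = (rigid_ligand_proposal(float(np.max(step)),
                                   settings.rotation_step)
             if settings.rigid_ligand else None)

    def proposal(rng, coords):
        coords = coords.reshape(-1, 3)
        if (box is not None and settings.jump_probability > 0
                and rng.random() < settings.jump_probability):
            c = np.asarray(box.center)
            h = np.asarray(box.half_lengths)
            shift = c + rng.uniform(-1.0, 1.0, 3) * h - coords.mean(axis=0)
            s3 = np.broadcast_to(step, coords.shape)
            axis_free = (s3 != 0).any(axis=0) if s3.ndim else np.ones(3, bool)
            return coords + np.where(axis_free, shift, 0.0)
        if rigid is not None:
            return rigid(rng, coords)
        return coords + rng.normal(0.0, 1.0, coords.shape) * step

    return proposal


def _leg_coupling(leg_name: str, s: float) -> tuple[float, float]:
    """Map a schedule value s to (interaction λ, restraint λ) for a leg."""
    if leg_name == "bound_decouple":
        return s, 1.0
    if leg_name == "unbound_decouple":
        return s, 0.0
    if leg_name == "bound_restrain":
        return 0.0, s
    if leg_name == "unbound_restrain":
        return 1.0, s
    raise LigscreenError(f"unknown leg '{leg_name}'")


def _run_direction(asys: AlchemicalSystem, leg_name: str, order,
                   schedule: LambdaSchedule, settings: SamplerSettings,
                   temperature: float, seed: int, direction: str) -> FEPLeg:
    values = schedule.values
    state = asys.ligand_coords.copy()
    proposal = make_window_proposal(settings, asys.box)
    dgs, ses = [], []
    for w, (i_here, i_next) in enumerate(order):
        lam, rlam = _leg_coupling(leg_name, values[i_here])
        lam_n, rlam_n = _leg_coupling(leg_name, values[i_next])
        states, _ = metropolis_sample(
            lambda x: asys.potential(x, lam, rlam), state,
            settings.n_steps, settings.step_size, temperature,
            seed=seed + 7919 * w, proposal=proposal)
        state = states[-1]
        n_equil = int(settings.equilibration_fraction * len(states))
        frames = states[n_equil::settings.stride]
        du = np.array([asys.potential(x, lam_n, rlam_n)
                       - asys.potential(x, lam, rlam) for x in frames])
        dg, se = zwanzig_increment_with_se(du, temperature)
        dgs.append(dg)
        ses.append(se)
    return FEPLeg(name=leg_name, direction=direction,
                  per_window_dg=np.array(dgs), per_window_se=np.array(ses))


def run_leg(asys: AlchemicalSystem, leg_name: str, schedule: LambdaSchedule,
            settings: SamplerSettings, temperature: float,
            seed: int) -> tuple[FEPLeg, FEPLeg]:
    """Run one leg in both directions.

    Forward samples each window at λ_i and perturbs to λ_{i+1}; backward
    samples at λ_i (walking down from λ_K) and perturbs to λ_{i−1}.  The
    backward total estimates the negative of the forward total.
    """
    if schedule.K < 2:
        raise LigscreenError("schedule must have K >= 2 windows")
    K = schedule.K
    fwd_order = [(i, i + 1) for i in range(K - 1)]
    bwd_order = [(i, i - 1) for i in range(K - 1, 0, -1)]
    fwd = _run_direction(asys, leg_name, fwd_order, schedule, settings,
                         temperature, seed, "forward")
    bwd = _run_direction(asys, leg_name, bwd_order, schedule, settings,
                         temperature, seed + 104729, "backward")
    return fwd, bwd


def binding_dg_from_cycle(legs: dict[str, tuple[FEPLeg, FEPLeg]]) -> FEPResult:
    """Close the four-leg cycle (non-interacting transfer leg ≡ 0).

    Each leg's estimate is the mean of the forward total and the negated
    backward total; |forward + backward| is the hysteresis diagnostic.
    """
    missing = [n for n in LEG_NAMES if n not in legs]
    if missing:
        raise LigscreenError(f"missing legs: {missing}")
    estimates, hysteresis, variances = {}, {}, {}
    for name in LEG_NAMES:
        fwd, bwd = legs[name]
        estimates[name] = 0.5 * (fwd.total - bwd.total)
        hysteresis[name] = abs(fwd.total + bwd.total)
        variances[name] = 0.25 * (fwd.total_se ** 2 + bwd.total_se ** 2)
    dg = -(estimates["bound_restrain"] + estimates["bound_decouple"]
           - estimates["unbound_decouple"] - estimates["unbound_restrain"])
    se = float(np.sqrt(sum(variances.values())))
    return FEPResult(legs=dict(legs), delta_g_binding=float(dg),
                     delta_g_se=se, hysteresis=hysteresis,
                     leg_estimates=estimates)


def run_cycle(bound: AlchemicalSystem, unbound: AlchemicalSystem,
              schedule: LambdaSchedule, settings: SamplerSettings,
              temperature: float, seed: int,
              restraint_schedule: LambdaSchedule | None = None) -> FEPResult:
    """Convenience driver: run all four legs and close the cycle.

    ``bound`` is the restrained complex; ``unbound`` is the ligand alone in
    the same confinement box with the restraint anchored at a fixed point.
    Restraint-coupling legs default to a geometric schedule of the same
    window count (good overlap near zero coupling).
    """
    if restraint_schedule is None:
        restraint_schedule = LambdaSchedule.geometric(schedule.K)
    legs = {}
    for k, (asys, name, sched) in enumerate([
            (bound, "bound_restrain", restraint_schedule),
            (bound, "bound_decouple", schedule),
            (unbound, "unbound_decouple", schedule),
            (unbound, "unbound_restrain", restraint_schedule)]):
        legs[name] = run_leg(asys, name, sched, settings, temperature,
                             seed + 15485863 * k)
    return binding_dg_from_cycle(legs)
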