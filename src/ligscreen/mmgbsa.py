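"""Trajectory-averaged MM/GBSA binding free energies.

Each subsystem's free energy is G = ⟨E_MM⟩ + ⟨G_polar⟩ + ⟨G_nonpolar⟩ − T·S
with the averages taken over its own trajectory and the entropy from the
quasiharmonic pipeline on the same (aligned) trajectory.  Binding follows the
three-trajectory protocol: separate complex (C), receptor (R) and ligand (L)
simulations, ΔG⁰ = G_C − G_R − G_L.  For a batch of N ligands that is
2N + 1 simulations: one receptor, one per ligand, one per complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import Trajectory
from .energetics import BondedParams, SolventModel, configuration_energy
from .errors import LigscreenError
from .quasiharm import trajectory_entropy

#: Fraction of initial frames discarded as equilibration before averaging.
DEFAULT_EQUILIBRATION_FRACTION = 0.1


@dataclass
class FreeEnergyReport:
    """Trajectory-averaged free energy of one subsystem."""

    mean_e_mm: float
    mean_g_polar: float
    mean_g_nonpolar: float
    entropy: float  # kcal·mol⁻¹·K⁻¹
    temperature: float
    n_frames: int

    @property
    def g_total(self) -> float:
        return (self.mean_e_mm + self.mean_g_polar + self.mean_g_nonpolar
                - self.temperature * self.entropy)


@dataclass
class BindingReport:
    """ΔG⁰ of binding with its per-term decomposition."""

    report_C: FreeEnergyReport
    report_R: FreeEnergyReport
    report_L: FreeEnergyReport

    @property
    def delta_g0(self) -> float:
        return (self.report_C.g_total - self.report_R.g_total
                - self.report_L.g_total)

    @property
    def term_deltas(self) -> dict[str, float]:
        c, r, l = self.report_C, self.report_R, self.report_L
        t = c.temperature
        return {
            "delta_e_mm": c.mean_e_mm - r.mean_e_mm - l.mean_e_mm,
            "delta_g_polar": c.mean_g_polar - r.mean_g_polar - l.mean_g_polar,
            "delta_g_nonpolar": (c.mean_g_nonpolar - r.mean_g_nonpolar
                                 - l.mean_g_nonpolar),
            "minus_t_delta_s": -t * (c.entropy - r.entropy - l.entropy),
        }


def trajectory_free_energy(traj: Trajectory,
                           params: BondedParams | None = None,
                           solvent_model: SolventModel | None = None,
                           equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
                           align_selection=None) -> FreeEnergyReport:
    """Average per-frame energetics and add the quasiharmonic entropy term.

    The first ``equilibration_fraction`` of frames is discarded before both
    the energy averages and the covariance used for the entropy.
    """
    solvent_model = solvent_model or SolventModel()
    if traj.n_frames < 2:
        raise LigscreenError("free energy averaging requires >= 2 frames "
                             "(entropy undefined on a single frame)")
    n_skip = int(equilibration_fraction * traj.n_frames)
    n_skip = min(n_skip, traj.n_frames - 2)
    production = Trajectory(system=traj.system, frames=traj.frames[n_skip:],
                            temperature=traj.temperature)

    e_mm, g_pol, g_np = [], [], []
    for f in range(production.n_frames):
        try:
            terms = configuration_energy(production.frame_system(f), params,
                                         solvent_model)
        except Exception as exc:
            raise LigscreenError(
                f"energy evaluation failed at frame {n_skip + f}: {exc}"
            ) from exc
        e_mm.append(terms.total_mm)
        g_pol.append(terms.g_polar)
        g_np.append(terms.g_nonpolar)

    entropy = trajectory_entropy(production, align_selection=align_selection)
    return FreeEnergyReport(
        mean_e_mm=float(np.mean(e_mm)),
        mean_g_polar=float(np.mean(g_pol)),
        mean_g_nonpolar=float(np.mean(g_np)),
        entropy=entropy,
        temperature=traj.temperature,
        n_frames=production.n_frames,
    )


def binding_free_energy(traj_C: Trajectory, traj_R: Trajectory,
                        traj_L: Trajectory,
                        params: dict[str, BondedParams | None] | None = None,
                        solvent_model: SolventModel | None = None,
                        receptor_alpha_carbons=None,
                        equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
                        ) -> BindingReport:
    """Three-trajectory MM/GBSA binding free energy ΔG⁰ = G_C − G_R − G_L.

    ``params`` optionally maps "C"/"R"/"L" to bonded parameter sets.
    Receptor-containing trajectories are aligned on the receptor α-carbon
    selection (defaulting to all receptor atoms); the ligand trajectory on
    its heavy atoms.
    """
    temps = {traj_C.temperature, traj_R.temperature, traj_L.temperature}
    if max(temps) - min(temps) > 1e-9:
        raise LigscreenError("temperature mismatch across trajectories")
    params = params or {}
    if receptor_alpha_carbons is None:
        receptor_alpha_carbons = np.arange(traj_R.system.n_atoms)
    receptor_alpha_carbons = np.asarray(list(receptor_alpha_carbons), dtype=int)
    rec_in_complex = traj_C.system.receptor_indices()
    complex_sel = (rec_in_complex[receptor_alpha_carbons]
                   if rec_in_complex.size else None)

    rep_c = trajectory_free_energy(traj_C, params.get("C"), solvent_model,
                                   equilibration_fraction, complex_sel)
    rep_r = trajectory_free_energy(traj_R, params.get("R"), solvent_model,
                                   equilibration_fraction,
                                   receptor_alpha_carbons)
    lig_sel = traj_L.system.heavy_indices()
    rep_l = trajectory_free_energy(traj_L, params.get("L"), solvent_model,
                                   equilibration_fraction,
                                   lig_sel if lig_sel.size else None)
    return BindingReport(report_C=rep_c, report_R=rep_r, report_L=rep_l)


@dataclass(frozen=True)
class MDJob:
    """Descriptor of one simulation in the 2N+1 batch."""

    kind: str  # "receptor" | "ligand" | "complex"
    ligand_id: str | None = None


def plan_md_batch(ligand_ids) -> list[MDJob]:
    """The 2N+1 bookkeeping: one receptor job, plus a ligand and a complex
    job for each of the N ligands."""
    if isinstance(ligand_ids, int):
        ligand_ids = [f"ligand_{i}" for i in range(ligand_ids)]
    jobs = [MDJob(kind="receptor")]
    for lid in ligand_ids:
        jobs.append(MDJob(kind="ligand", ligand_id=str(lid)))
        jobs.append(MDJob(kind="complex", ligand_id=str(lid)))
    return jobs
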