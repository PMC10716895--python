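"""Three-stage filter-and-rank screening pipeline.

Every ligand is docked and ranked by its empirical docking score; the best
n_to_md proceed to an MM/GBSA stage (2N+1 simulations: one receptor, one per
ligand, one per complex) and are re-ranked by ΔG⁰; the best n_to_fep of those
get an alchemical FEP cycle and a final ranking.  A ligand that fails at any
stage is never promoted and is ranked after every scored ligand — failures
are caught, annotated and reported, never raised out of the run.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alchemy import (AlchemicalSystem, LambdaSchedule, Restraint,
                      SamplerSettings, run_cycle)
from .chemio import MolecularSystem, Trajectory, assign_dock_types, merge_systems
from .dockscore import Pose, ScoringWeights, SearchBox, optimize_pose
from .energetics import SolventModel, equilibrium_bond_params
from .errors import LigscreenError
from .mmgbsa import binding_free_energy, plan_md_batch
from .synthkit import harmonic_trajectory

STAGES = ("dock", "md", "fep")
FAIL_STATUS = {"dock": "failed_dock", "md": "failed_sim", "fep": "failed_sim"}


@dataclass
class LigandRecord:
    """Per-ligand scorecard across the stages."""

    id: str
    system: MolecularSystem | None = None
    label: str | None = None  # optional active/decoy tag for benchmarking
    stage_scores: dict = field(default_factory=dict)
    status: str = "ok"
    rank_per_stage: dict = field(default_factory=dict)
    failure_reason: str | None = None
    pose: Pose | None = None

    def score(self, stage: str):
        return self.stage_scores.get(stage)


@dataclass
class StagePlan:
    """All knobs of one screening run."""

    n_to_md: int = 100
    n_to_fep: int = 15
    seed: int = 0
    temperature: float = 300.0
    solvent: SolventModel = field(default_factory=SolventModel)
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    n_restarts: int = 8
    md_n_frames: int = 120
    md_force_constant: float = 200.0  # kcal·mol⁻¹·Å⁻² jitter stiffness
    equilibration_fraction: float = 0.1
    fep_schedule: LambdaSchedule = field(
        default_factory=lambda: LambdaSchedule.uniform(6))
    fep_settings: SamplerSettings = field(
        default_factory=lambda: SamplerSettings(n_steps=600, step_size=0.25,
                                                stride=3, rigid_ligand=True))
    restraint_force_constant: float = 10.0

    def __post_init__(self):
        if self.n_to_fep > self.n_to_md:
            raise ValueError("n_to_fep must not exceed n_to_md")


@dataclass
class ScreenReport:
    """Ranked tables per stage plus a combined final table."""

    records: list[LigandRecord]
    stage_tables: dict[str, pd.DataFrame]
    final: pd.DataFrame
    md_jobs: list

    def write_csvs(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, stage in enumerate(STAGES, start=1):
            p = out_dir / f"stage{i}.csv"
            self.stage_tables[stage].to_csv(p, index=False,
                                            float_format="%.6f")
            paths.append(p)
        p = out_dir / "final.csv"
        self.final.to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
        return paths


def _derived_seed(base: int, salt: int) -> int:
    return int((base * 1000003 + salt * 7919 + 12345) % (2 ** 31))


def _stable_hash(text: str, mod: int) -> int:
    """Process-independent string hash (CRC32) for seed derivation."""
    return zlib.crc32(text.encode()) % mod


def rank_stage(records: list[LigandRecord], stage: str) -> list[LigandRecord]:
    """Ascending by stage score (more negative = better); failures last.

    Ties break lexicographically on ligand id; failed records order by id.
    """
    scored = [r for r in records if r.score(stage) is not None]
    failed = [r for r in records if r.score(stage) is None]
    scored.sort(key=lambda r: (r.score(stage), r.id))
    failed.sort(key=lambda r: r.id)
    ordered = scored + failed
    for rank, r in enumerate(ordered, start=1):
        r.rank_per_stage[stage] = rank
    return ordered


def promote(ordered: list[LigandRecord], n: int) -> list[LigandRecord]:
    """First min(n, #scored) records; failed ligands are never promoted."""
    if n < 0:
        raise ValueError("n must be >= 0")
    eligible = [r for r in ordered if r.status == "ok"]
    if len(eligible) < n:
        warnings.warn(f"only {len(eligible)} non-failed ligands available "
                      f"for {n} promotion slots", stacklevel=2)
    return eligible[:n]


def _stage_table(ordered: list[LigandRecord], stage: str) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [r.id for r in ordered],
        "score": [r.score(stage) if r.score(stage) is not None else np.nan
                  for r in ordered],
        "status": [r.status for r in ordered],
        "rank": [r.rank_per_stage[stage] for r in ordered],
    })


def build_complex(receptor: MolecularSystem, ligand: MolecularSystem,
                  pose: Pose | None = None) -> MolecularSystem:
    """Merge receptor (role receptor) and posed ligand (role ligand)."""
    for a in receptor.atoms:
        a.role = "receptor"
    receptor._cache.pop("roles", None)
    lig = ligand
    if pose is not None:
        lig = ligand.with_coords(pose.apply(ligand.coords))
    for a in lig.atoms:
        a.role = "ligand"
    lig._cache.pop("roles", None)
    return merge_systems(receptor, lig,
                         name=f"{receptor.name}+{ligand.name}")


def _md_score(receptor: MolecularSystem, record: LigandRecord,
              plan: StagePlan, receptor_traj: Trajectory) -> float:
    ligand = record.system.with_coords(record.pose.apply(record.system.coords))
    complex_system = build_complex(receptor, record.system, record.pose)
    seed = _derived_seed(plan.seed, _stable_hash(record.id, 100000))
    traj_l = harmonic_trajectory(ligand, plan.md_force_constant,
                                 plan.temperature, plan.md_n_frames,
                                 seed=seed)
    traj_c = harmonic_trajectory(complex_system, plan.md_force_constant,
                                 plan.temperature, plan.md_n_frames,
                                 seed=seed + 1)
    params = {
        "C": equilibrium_bond_params(complex_system),
        "R": equilibrium_bond_params(receptor_traj.system),
        "L": equilibrium_bond_params(ligand),
    }
    report = binding_free_energy(
        traj_c, receptor_traj, traj_l, params=params,
        solvent_model=plan.solvent,
        equilibration_fraction=plan.equilibration_fraction)
    return report.delta_g0


def _fep_score(receptor: MolecularSystem, record: LigandRecord,
               plan: StagePlan, box: SearchBox) -> float:
    complex_system = build_complex(receptor, record.system, record.pose)
    lig_idx = complex_system.ligand_indices()
    rec_idx = complex_system.receptor_indices()
    anchor_atoms = tuple(
        int(i - rec_idx[0]) for i in rec_idx
        if complex_system.atoms[i].element.upper() != "H")
    lig_centroid = complex_system.coords[lig_idx].mean(axis=0)
    anchor = complex_system.coords[rec_idx].mean(axis=0)
    restraint = Restraint(kind="distance",
                          force_constant=plan.restraint_force_constant,
                          target=float(np.linalg.norm(lig_centroid - anchor)),
                          anchor_atoms=anchor_atoms)
    bound = AlchemicalSystem(complex_system, [restraint], box=box)
    ligand_only = complex_system.subset(lig_idx, name=f"{record.id}_unbound")
    unbound_restraint = Restraint(kind="distance",
                                  force_constant=plan.restraint_force_constant,
                                  target=restraint.target,
                                  anchor_point=anchor)
    unbound = AlchemicalSystem(ligand_only, [unbound_restraint], box=box)
    result = run_cycle(bound, unbound, plan.fep_schedule, plan.fep_settings,
                       plan.temperature,
                       seed=_derived_seed(plan.seed, _stable_hash(record.id, 99991)))
    return result.delta_g_binding


def run_screen(receptor: MolecularSystem, ligands, plan: StagePlan,
               box: SearchBox, out_dir=None) -> ScreenReport:
    """Run dock → MM/GBSA → FEP with promotion between stages.

    ``ligands`` is an iterable of (id, MolecularSystem) pairs or of
    synthkit LabeledLigand records.  Per-ligand exceptions become failure
    statuses; only an unusable receptor aborts the run.
    """
    try:
        receptor = assign_dock_types(receptor)
        for a in receptor.atoms:
            a.role = "receptor"
        receptor._cache.pop("roles", None)
    except Exception as exc:
        raise LigscreenError(f"receptor unusable: {exc}") from exc

    records: list[LigandRecord] = []
    for entry in ligands:
        if hasattr(entry, "id") and hasattr(entry, "system"):
            rec = LigandRecord(id=str(entry.id), system=entry.system,
                               label=getattr(entry, "label", None))
        else:
            lid, system = entry
            rec = LigandRecord(id=str(lid), system=system)
        records.append(rec)

    # Stage 1: docking
    for r in records:
        try:
            assign_dock_types(r.system)
            pose = optimize_pose(r.system, receptor, box, plan.weights,
                                 n_restarts=plan.n_restarts,
                                 seed=_derived_seed(plan.seed,
                                                    _stable_hash(r.id, 65521)))
            r.pose = pose
            r.stage_scores["dock"] = float(pose.score)
        except Exception as exc:
            r.status = "failed_dock"
            r.failure_reason = str(exc)
    dock_order = rank_stage(records, "dock")
    to_md = promote(dock_order, plan.n_to_md)

    # Stage 2: MM/GBSA over the 2N+1 batch
    md_jobs = plan_md_batch([r.id for r in to_md])
    receptor_traj = harmonic_trajectory(receptor, plan.md_force_constant,
                                        plan.temperature, plan.md_n_frames,
                                        seed=_derived_seed(plan.seed, 1))
    for r in to_md:
        try:
            r.stage_scores["md"] = float(_md_score(receptor, r, plan,
                                                   receptor_traj))
        except Exception as exc:
            r.status = "failed_sim"
            r.failure_reason = str(exc)
    md_order = rank_stage(to_md, "md")
    to_fep = promote(md_order, plan.n_to_fep)

    # Stage 3: FEP
    for r in to_fep:
        try:
            r.stage_scores["fep"] = float(_fep_score(receptor, r, plan, box))
        except Exception as exc:
            r.status = "failed_sim"
            r.failure_reason = str(exc)
    fep_order = rank_stage(to_fep, "fep")

    stage_tables = {
        "dock": _stage_table(dock_order, "dock"),
        "md": _stage_table(md_order, "md"),
        "fep": _stage_table(fep_order, "fep"),
    }

    # Final combined table: FEP ranking first, then MD-only, dock-only, failed.
    placed = []
    seen = set()
    for group in (fep_order,
                  [r for r in md_order if r not in to_fep],
                  [r for r in dock_order
                   if r.score("dock") is not None and r not in to_md],
                  [r for r in dock_order if r.score("dock") is None]):
        for r in group:
            if r.id not in seen:
                placed.append(r)
                seen.add(r.id)
    final = pd.DataFrame({
        "id": [r.id for r in placed],
        "final_stage": [("fep" if "fep" in r.stage_scores else
                         "md" if "md" in r.stage_scores else
                         "dock" if "dock" in r.stage_scores else "none")
                        for r in placed],
        "score": [next((r.stage_scores[s] for s in ("fep", "md", "dock")
                        if s in r.stage_scores), np.nan) for r in placed],
        "status": [r.status for r in placed],
        "rank": list(range(1, len(placed) + 1)),
        "label": [r.label if r.label is not None else "" for r in placed],
    })

    report = ScreenReport(records=records, stage_tables=stage_tables,
                          final=final, md_jobs=md_jobs)
    if out_dir is not None:
        report.write_csvs(out_dir)
    return report
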