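"""Quasiharmonic entropy from trajectory covariance.

The Cartesian coordinate fluctuations of an aligned trajectory are treated as
a multivariate Gaussian; eigenvalues λ_k of the mass-weighted covariance
M^(1/2) σ M^(1/2) define mode frequencies ω_k = sqrt(k_B T / λ_k) (in the
amu/Å/ps unit system), and each mode contributes the quantum harmonic
oscillator entropy

    S_k / k_B = u_k/(e^{u_k} − 1) − ln(1 − e^{−u_k}),   u_k = ħω_k/(k_B T).

Rigid-body motion is removed beforehand by Kabsch superposition onto the
first frame — for receptor-containing systems over the receptor α-carbons,
for ligand-only systems over all heavy atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.transform import Rotation

from .chemio import Trajectory
from .constants import HBAR, K_B, KCAL_TO_AMU_A2_PS2
from .errors import LigscreenError

#: Mass-weighted covariance eigenvalues below this (amu·Å²) are treated as
#: numerically null modes (alignment leaves up to six) and discarded.
EIGENVALUE_FLOOR = 1e-8


@dataclass
class QuasiharmonicSpectrum:
    """Retained mode frequencies (rad·ps⁻¹, ascending) with bookkeeping."""

    frequencies: np.ndarray
    n_discarded: int
    temperature: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)


def kabsch_align(traj: Trajectory, selection) -> Trajectory:
    """Rigid-body superpose every frame onto frame 1 over ``selection``.

    With fewer than three selected atoms the rotation is under-determined; a
    translation-only alignment is applied with a warning.
    """
    selection = np.asarray(list(selection), dtype=int)
    if selection.size == 0:
        raise LigscreenError("alignment selection is empty")
    frames = traj.frames.copy()
    ref = frames[0][selection]
    ref_center = ref.mean(axis=0)
    rotate = selection.size >= 3
    if not rotate:
        warnings.warn("alignment selection has < 3 atoms; applying "
                      "translation-only alignment", stacklevel=2)
    for f in range(frames.shape[0]):
        mob = frames[f][selection]
        mob_center = mob.mean(axis=0)
        if rotate:
            rot, _ = Rotation.align_vectors(ref - ref_center, mob - mob_center)
            frames[f] = rot.apply(frames[f] - mob_center) + ref_center
        else:
            frames[f] = frames[f] - mob_center + ref_center
    return Trajectory(system=traj.system, frames=frames,
                      temperature=traj.temperature)


def covariance_matrix(traj: Trajectory) -> np.ndarray:
    """3N×3N coordinate covariance ⟨δx δxᵀ⟩ over frames (population mean)."""
    if traj.n_frames < 2:
        raise LigscreenError("covariance requires at least 2 frames")
    X = traj.frames.reshape(traj.n_frames, -1)
    dX = X - X.mean(axis=0)
    sigma = dX.T @ dX / traj.n_frames
    return 0.5 * (sigma + sigma.T)


def quasiharmonic_frequencies(sigma: np.ndarray, masses: np.ndarray,
                              temperature: float) -> QuasiharmonicSpectrum:
    """Mode frequencies from the mass-weighted covariance eigenproblem.

    ``masses`` is per-atom (amu) and is expanded to the three Cartesian
    components.  Eigenvalues below the floor are discarded and counted.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[0] != sigma.shape[1]:
        raise LigscreenError("covariance matrix must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise LigscreenError("covariance matrix is not symmetric")
    masses = np.asarray(masses, dtype=float)
    if masses.size * 3 != sigma.shape[0]:
        raise LigscreenError("mass vector does not match covariance size")
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    mw = sigma * sqrt_m[:, None] * sqrt_m[None, :]
    eigenvalues = eigh(mw, eigvals_only=True)  # ascending, amu·Å²
    retained = eigenvalues[eigenvalues > EIGENVALUE_FLOOR]
    n_discarded = int(eigenvalues.size - retained.size)
    if n_discarded > 6:
        warnings.warn(f"{n_discarded} null modes discarded (more than the "
                      "6 rigid-body modes); trajectory may be rank-deficient",
                      stacklevel=2)
    kT = K_B * temperature * KCAL_TO_AMU_A2_PS2  # amu·Å²·ps⁻²
    freqs = np.sqrt(kT / retained)[::-1]  # ascending ω
    return QuasiharmonicSpectrum(frequencies=freqs, n_discarded=n_discarded,
                                 temperature=temperature)


def quasiharmonic_entropy(spectrum: QuasiharmonicSpectrum) -> float:
    """Total quantum-harmonic-oscillator entropy, kcal·mol⁻¹·K⁻¹."""
    if spectrum.frequencies.size == 0:
        return 0.0
    u = HBAR * spectrum.frequencies / (K_B * spectrum.temperature)
    with np.errstate(over="ignore"):
        term = np.where(u < 700,
                        u / np.expm1(np.minimum(u, 700.0))
                        - np.log1p(-np.exp(-u)),
                        0.0)
    return float(K_B * np.sum(term))


def trajectory_entropy(traj: Trajectory, align_selection=None) -> float:
    """Aligned-covariance entropy pipeline for one trajectory.

    The default alignment selection is the receptor α-carbon convention
    where the system distinguishes roles, otherwise all heavy atoms.
    """
    if align_selection is None:
        rec = traj.system.receptor_indices()
        align_selection = rec if rec.size else traj.system.heavy_indices()
        if np.asarray(align_selection).size == 0:
            align_selection = np.arange(traj.system.n_atoms)
    aligned = kabsch_align(traj, align_selection)
    sigma = covariance_matrix(aligned)
    spectrum = quasiharmonic_frequencies(sigma, traj.system.masses,
                                         traj.temperature)
    return quasiharmonic_entropy(spectrum)


def binding_entropy(traj_C: Trajectory, traj_R: Trajectory, traj_L: Trajectory,
                    receptor_alpha_carbons=None) -> float:
    """Entropy change on binding: ΔS = S_C − S_R − S_L (kcal·mol⁻¹·K⁻¹).

    ``receptor_alpha_carbons`` indexes into the receptor system; the complex
    is assumed to tag its receptor atoms with role "receptor" so the same
    selection maps onto it.  Defaults to all receptor atoms.
    """
    temps = {traj_C.temperature, traj_R.temperature, traj_L.temperature}
    if max(temps) - min(temps) > 1e-9:
        raise LigscreenError("temperature mismatch across trajectories")
    if receptor_alpha_carbons is None:
        receptor_alpha_carbons = np.arange(traj_R.system.n_atoms)
    receptor_alpha_carbons = np.asarray(list(receptor_alpha_carbons), dtype=int)
    rec_in_complex = traj_C.system.receptor_indices()
    if rec_in_complex.size == 0:
        raise LigscreenError("complex system has no receptor-tagged atoms")
    complex_sel = rec_in_complex[receptor_alpha_carbons]
    s_c = trajectory_entropy(traj_C, align_selection=complex_sel)
    s_r = trajectory_entropy(traj_R, align_selection=receptor_alpha_carbons)
    lig_sel = traj_L.system.heavy_indices()
    if lig_sel.size == 0:
        lig_sel = np.arange(traj_L.system.n_atoms)
    s_l = trajectory_entropy(traj_L, align_selection=lig_sel)
    return s_c - s_r - s_l
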