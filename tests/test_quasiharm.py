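"""Alignment, covariance and quasiharmonic entropy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ligscreen import constants as C, quasiharm as qh, synthkit
from ligscreen.chemio import Atom, MolecularSystem, Trajectory
from ligscreen.errors import LigscreenError


def _system(n=5, seed=0, role="ligand", mass=12.0):
    rng = np.random.default_rng(seed)
    atoms = [Atom.from_element("C", c, mass=mass, role=role)
             for c in rng.normal(0, 2.0, (n, 3))]
    return MolecularSystem(atoms)


class TestKabschAlign:
    def test_identical_frames_unchanged(self):
        s = _system()
        traj = Trajectory(s, np.repeat(s.coords[None], 4, axis=0))
        out = qh.kabsch_align(traj, range(s.n_atoms))
        assert np.allclose(out.frames, traj.frames, atol=1e-12)

    def test_pure_rotations_removed_exactly(self):
        s = _system(6, seed=1)
        rng = np.random.default_rng(2)
        frames = np.array([Rotation.random(random_state=rng).apply(s.coords)
                           + rng.normal(0, 5.0, 3) for _ in range(8)])
        traj = Trajectory(s, frames)
        aligned = qh.kabsch_align(traj, range(s.n_atoms))
        sigma = qh.covariance_matrix(aligned)
        assert np.abs(sigma).max() < 1e-10

    def test_small_selection_warns_translation_only(self):
        s = _system(4, seed=3)
        frames = np.array([s.coords, s.coords + np.array([1.0, 2.0, 3.0])])
        traj = Trajectory(s, frames)
        with pytest.warns(UserWarning, match="translation-only"):
            out = qh.kabsch_align(traj, [0, 1])
        assert np.allclose(out.frames[0], out.frames[1], atol=1e-12)

    def test_empty_selection_rejected(self):
        s = _system()
        traj = Trajectory(s, np.repeat(s.coords[None], 2, axis=0))
        with pytest.raises(LigscreenError):
            qh.kabsch_align(traj, [])


class TestCovariance:
    def test_mirror_frames_hand_value(self):
        """Two frames of one atom at ±a on x: σ_xx = a², all else 0."""
        a = 0.7
        s = _system(1)
        frames = np.array([[[a, 0, 0]], [[-a, 0, 0]]])
        sigma = qh.covariance_matrix(Trajectory(s, frames))
        expected = np.zeros((3, 3))
        expected[0, 0] = a ** 2
        assert np.allclose(sigma, expected, atol=1e-12)

    def test_identical_frames_zero(self):
        s = _system(3)
        sigma = qh.covariance_matrix(
            Trajectory(s, np.repeat(s.coords[None], 5, axis=0)))
        assert np.abs(sigma).max() == 0.0

    def test_single_frame_rejected(self):
        s = _system(2)
        with pytest.raises(LigscreenError):
            qh.covariance_matrix(Trajectory(s, s.coords[None]))

    def test_gaussian_covariance_recovery(self):
        """Sampler with known Σ: recovered σ within 5% at n = 10⁴."""
        rng = np.random.default_rng(5)
        target = np.diag([0.5, 0.2, 0.1])
        X = rng.multivariate_normal(np.zeros(3), target, size=10000)
        s = _system(1)
        sigma = qh.covariance_matrix(Trajectory(s, X[:, None, :]))
        assert np.allclose(sigma, target, rtol=0.05, atol=0.01)


class TestFrequencies:
    def test_oscillator_frequency_recovery(self):
        """Analytic oscillator: variance k_BT/k maps to ω = √(k·conv/m)."""
        k, m, T = 2.0, 12.0, 300.0
        s = _system(1, mass=m)
        traj = synthkit.harmonic_trajectory(s, k, T, 10000, seed=11)
        spec = qh.quasiharmonic_frequencies(qh.covariance_matrix(traj),
                                            s.masses, T)
        w_exact = np.sqrt(k * C.KCAL_TO_AMU_A2_PS2 / m)
        assert spec.frequencies == pytest.approx([w_exact] * 3, rel=0.05)

    def test_zero_matrix_discards_everything(self):
        s = _system(2)
        spec = qh.quasiharmonic_frequencies(np.zeros((6, 6)), s.masses, 300.0)
        assert spec.frequencies.size == 0
        assert spec.n_discarded == 6

    def test_sorted_ascending(self):
        s = _system(1)
        sigma = np.diag([0.5, 0.2, 0.05])
        spec = qh.quasiharmonic_frequencies(sigma, s.masses, 300.0)
        assert np.all(np.diff(spec.frequencies) >= 0)

    def test_asymmetric_matrix_rejected(self):
        s = _system(1)
        bad = np.array([[1.0, 0.5, 0], [0, 1.0, 0], [0, 0, 1.0]])
        with pytest.raises(LigscreenError, match="symmetric"):
            qh.quasiharmonic_frequencies(bad, s.masses, 300.0)


class TestEntropy:
    def test_single_mode_u_equals_one(self):
        """u = 1 gives S/k_B = 1/(e−1) − ln(1−e⁻¹) ≈ 1.04065."""
        T = 300.0
        omega = C.K_B * T / C.HBAR  # makes u exactly 1
        spec = qh.QuasiharmonicSpectrum(np.array([omega]), 0, T)
        expected = C.K_B * (1 / (np.e - 1) - np.log(1 - np.exp(-1)))
        assert qh.quasiharmonic_entropy(spec) == pytest.approx(expected,
                                                               rel=1e-9)
        assert expected / C.K_B == pytest.approx(1.04065, abs=5e-5)

    def test_stiff_mode_contributes_nothing(self):
        spec = qh.QuasiharmonicSpectrum(np.array([1e9]), 0, 300.0)
        assert qh.quasiharmonic_entropy(spec) == pytest.approx(0.0, abs=1e-15)

    def test_classical_limit(self):
        """u ≪ 1: per-mode S/k_B → 1 − ln u."""
        T = 300.0
        u = 1e-4
        omega = u * C.K_B * T / C.HBAR
        spec = qh.QuasiharmonicSpectrum(np.array([omega]), 0, T)
        s_over_kb = qh.quasiharmonic_entropy(spec) / C.K_B
        assert s_over_kb == pytest.approx(1 - np.log(u), abs=1e-3)

    def test_monotone_decreasing_in_frequency(self):
        T = 300.0
        entropies = [qh.quasiharmonic_entropy(
            qh.QuasiharmonicSpectrum(np.array([w]), 0, T))
            for w in (1.0, 5.0, 25.0, 125.0)]
        assert all(b < a for a, b in zip(entropies, entropies[1:]))

    def test_empty_spectrum_zero(self):
        spec = qh.QuasiharmonicSpectrum(np.array([]), 6, 300.0)
        assert qh.quasiharmonic_entropy(spec) == 0.0

    def test_invariant_under_rigid_rotation_of_trajectory(self):
        s = _system(5, seed=9)
        traj = synthkit.harmonic_trajectory(s, 20.0, 300.0, 400, seed=10)
        s_base = qh.trajectory_entropy(traj)
        rot = Rotation.from_euler("xyz", [1.0, -0.5, 0.3])
        rotated = Trajectory(s, np.array([rot.apply(f) for f in traj.frames]))
        assert qh.trajectory_entropy(rotated) == pytest.approx(s_base,
                                                               rel=1e-6)


class TestBindingEntropy:
    def _receptor_traj(self, n_frames=400, k=2000.0, seed=20):
        rec = _system(8, seed=21, role="receptor")
        return rec, synthkit.harmonic_trajectory(rec, k, 300.0, n_frames,
                                                 seed=seed)

    def test_frozen_ligand_construction_near_zero(self):
        """Complex = moving receptor ⊕ frozen ligand, ligand alone frozen:
        every ligand mode is null, so ΔS ≈ 0 up to alignment bookkeeping."""
        rec, traj_r = self._receptor_traj()
        lig = _system(3, seed=22, role="ligand")
        lig_coords = lig.coords + np.array([6.0, 0.0, 0.0])
        lig_frozen = lig.with_coords(lig_coords)
        comp_atoms = ([a for a in rec.atoms] + [a for a in lig_frozen.atoms])
        comp = MolecularSystem(
            [Atom.from_element(a.element, (0, 0, 0), mass=a.mass, role=a.role)
             for a in comp_atoms])
        comp_frames = np.concatenate(
            [traj_r.frames,
             np.repeat(lig_coords[None], traj_r.n_frames, axis=0)], axis=1)
        traj_c = Trajectory(comp, comp_frames)
        traj_l = Trajectory(lig, np.repeat(lig_coords[None], 5, axis=0))
        ds = qh.binding_entropy(traj_c, traj_r, traj_l)
        assert abs(ds) < 2e-4

    def test_immobilised_ligand_loses_entropy(self):
        """Ligand mobile when free but frozen in the complex: ΔS < 0."""
        rec, traj_r = self._receptor_traj()
        lig = _system(3, seed=23, role="ligand")
        lig_coords = lig.coords + np.array([6.0, 0.0, 0.0])
        comp = MolecularSystem(
            [Atom.from_element(a.element, (0, 0, 0), mass=a.mass, role=a.role)
             for a in list(rec.atoms) + list(lig.atoms)])
        comp_frames = np.concatenate(
            [traj_r.frames,
             np.repeat(lig_coords[None], traj_r.n_frames, axis=0)], axis=1)
        traj_c = Trajectory(comp, comp_frames)
        traj_l = synthkit.harmonic_trajectory(
            lig.with_coords(lig_coords), 20.0, 300.0, 400, seed=24)
        assert qh.binding_entropy(traj_c, traj_r, traj_l) < 0

    def test_frame_permutation_invariance(self):
        rec, traj_r = self._receptor_traj(n_frames=100)
        lig = _system(3, seed=25, role="ligand")
        traj_l = synthkit.harmonic_trajectory(lig, 20.0, 300.0, 100, seed=26)
        comp = MolecularSystem(
            [Atom.from_element(a.element, (0, 0, 0), mass=a.mass, role=a.role)
             for a in list(rec.atoms) + list(lig.atoms)])
        comp_frames = np.concatenate([traj_r.frames, traj_l.frames], axis=1)
        traj_c = Trajectory(comp, comp_frames)
        ds1 = qh.binding_entropy(traj_c, traj_r, traj_l)
        perm = np.random.default_rng(0).permutation(100)
        ds2 = qh.binding_entropy(Trajectory(comp, comp_frames[perm]),
                                 Trajectory(rec.with_coords(traj_r.frames[0]),
                                            traj_r.frames[perm]),
                                 Trajectory(lig, traj_l.frames[perm]))
        # covariance is order-invariant; only the alignment reference
        # frame shifts, so agreement is near- but not bit-exact
        assert ds2 == pytest.approx(ds1, rel=1e-2, abs=1e-6)

    def test_temperature_mismatch_rejected(self):
        rec, traj_r = self._receptor_traj(n_frames=10)
        lig = _system(2, seed=27)
        traj_l = synthkit.harmonic_trajectory(lig, 20.0, 310.0, 10, seed=28)
        comp = MolecularSystem(
            [Atom.from_element(a.element, (0, 0, 0), mass=a.mass, role=a.role)
             for a in list(rec.atoms) + list(lig.atoms)])
        frames = np.concatenate([traj_r.frames,
                                 np.repeat(lig.coords[None], 10, 0)], axis=1)
        traj_c = Trajectory(comp, frames)
        with pytest.raises(LigscreenError, match="emperature"):
            qh.binding_entropy(traj_c, traj_r, traj_l)
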