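"""Zwanzig estimator, λ-coupled potential, sampler and the FEP cycle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligscreen import alchemy as al, constants as C, synthkit
from ligscreen.chemio import Atom, MolecularSystem
from ligscreen.errors import LigscreenError

T = 300.0
KT = C.K_B * T


class TestZwanzig:
    def test_constant_samples_return_constant(self):
        assert al.zwanzig_increment([1.3] * 50, T) == pytest.approx(1.3)

    def test_gaussian_closed_form(self):
        """ΔU ~ N(μ, σ²) gives ΔG = μ − σ²/(2 k_B T)."""
        du = synthkit.gaussian_du(1.0, np.sqrt(0.5), 100000, seed=3)
        dg = al.zwanzig_increment(du, T)
        assert dg == pytest.approx(1.0 - 0.5 / (2 * KT), abs=0.02)

    def test_convergence_rate(self):
        """Error vs the closed form shrinks roughly as n^(-1/2)."""
        exact = 1.0 - 0.5 / (2 * KT)
        errs = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            reps = [abs(al.zwanzig_increment(
                synthkit.gaussian_du(1.0, np.sqrt(0.5), n, seed=s), T) - exact)
                for s in range(5)]
            errs.append(np.mean(reps))
        assert errs[2] < errs[0]
        # two decades of n: expect about one decade of error reduction
        assert errs[2] < errs[0] / 3

    def test_empty_rejected(self):
        with pytest.raises(LigscreenError):
            al.zwanzig_increment([], T)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_jensen_bound(self, du):
        assert al.zwanzig_increment(du, T) <= np.mean(du) + 1e-9


class TestSumWindows:
    def test_simple_sum(self):
        assert al.sum_windows([1.0, -0.5, 0.25]) == pytest.approx(0.75)

    def test_empty_is_zero(self):
        assert al.sum_windows([]) == 0.0


def _dimer():
    return synthkit.make_toy_dimer(well_depth=-4.0)


class TestCoupledPotential:
    def test_identity_at_zero_coupling(self):
        d = _dimer()
        x = np.array([[3.4, 0.0, 0.0]])
        u = d.bound.potential(x, 0.0, 0.0)
        assert u == pytest.approx(float(d.pair_energy(3.4)), abs=1e-9)

    def test_annihilated_at_lambda_one(self):
        d = _dimer()
        x = np.array([[3.0, 0.0, 0.0]])
        assert d.bound.potential(x, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_softcore_finite_at_overlap(self):
        d = _dimer()
        x = np.array([[1e-6, 0.0, 0.0]])  # receptor position: full overlap
        # physically essentially-singular at full coupling (no box here)...
        u_phys = al.coupled_potential(d.complex_system, x, 0.0)
        assert u_phys > 1e6
        # ...but finite once even slightly decoupled
        u_soft = al.coupled_potential(d.complex_system, x, 0.999)
        assert np.isfinite(u_soft) and u_soft < 100.0

    def test_restraint_scales_linearly(self):
        d = _dimer()
        x = np.array([[5.0, 0.0, 0.0]])
        u0 = d.bound.potential(x, 1.0, 0.0)
        u1 = d.bound.potential(x, 1.0, 1.0)
        uh = d.bound.potential(x, 1.0, 0.5)
        assert uh - u0 == pytest.approx(0.5 * (u1 - u0), abs=1e-9)

    def test_box_confinement(self):
        d = _dimer()
        x = np.array([[50.0, 0.0, 0.0]])
        assert d.bound.potential(x, 0.0, 0.0) == np.inf

    def test_lambda_domain_checked(self):
        d = _dimer()
        with pytest.raises(LigscreenError):
            al.coupled_potential(d.complex_system, d.bound.ligand_coords, 1.5)


class TestRestraint:
    def test_rmsd_restraint_ignores_rigid_motion(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1.5, (4, 3))
        from scipy.spatial.transform import Rotation
        moved = Rotation.from_euler("z", 1.1).apply(ref) + np.array([5, 0, 0])
        r = al.Restraint(kind="rmsd", force_constant=10.0, reference=ref)
        assert r.energy(moved) == pytest.approx(0.0, abs=1e-9)
        deformed = ref.copy()
        deformed[0] += 1.0
        assert r.energy(deformed) > 0.1

    def test_hydrogen_anchor_rejected(self):
        rec = MolecularSystem([Atom.from_element("H", (0, 0, 0),
                                                 role="receptor"),
                               Atom.from_element("C", (2, 0, 0),
                                                 role="ligand")])
        r = al.Restraint(kind="distance", force_constant=5.0, target=1.0,
                         anchor_atoms=(0,))
        with pytest.raises(LigscreenError, match="non-hydrogen"):
            r.energy(np.array([[2.0, 0, 0]]), rec.coords[:1], ["H"])

    def test_validation(self):
        with pytest.raises(ValueError):
            al.Restraint(kind="spring", force_constant=1.0)
        with pytest.raises(ValueError):
            al.Restraint(kind="distance", force_constant=-1.0)


class TestMetropolis:
    def test_harmonic_variance(self):
        """Boltzmann closed form: var = k_B·T/k for U = ½kx²."""
        k = 1.0
        pot = lambda x: 0.5 * k * float(x[0] ** 2)
        states, rate = al.metropolis_sample(pot, np.array([0.0]), 30000, 0.8,
                                            T, seed=2)
        xs = np.array([s[0] for s in states[3000:]])
        assert xs.var() == pytest.approx(KT / k, rel=0.05)
        assert 0.2 < rate < 0.95

    def test_zero_steps_returns_initial(self):
        states, rate = al.metropolis_sample(lambda x: 0.0, np.array([1.0]),
                                            0, 0.5, T, seed=1)
        assert len(states) == 1 and states[0][0] == 1.0
        assert rate == 0.0

    def test_seed_determinism(self):
        pot = lambda x: float(np.sum(x ** 2))
        s1, _ = al.metropolis_sample(pot, np.zeros(3), 500, 0.4, T, seed=9)
        s2, _ = al.metropolis_sample(pot, np.zeros(3), 500, 0.4, T, seed=9)
        assert np.array_equal(np.array(s1), np.array(s2))


class TestSchedule:
    def test_uniform_endpoints(self):
        s = al.LambdaSchedule.uniform(5)
        assert s.values[0] == 0.0 and s.values[-1] == 1.0 and s.K == 5

    def test_geometric_dense_near_zero(self):
        s = al.LambdaSchedule.geometric(10)
        steps = np.diff(s.values)
        assert steps[1] < steps[-1]
        assert s.values[0] == 0.0 and s.values[-1] == 1.0

    @pytest.mark.parametrize("vals", [
        (0.0,), (0.1, 1.0), (0.0, 0.9), (0.0, 0.5, 0.5, 1.0),
        (0.0, 0.7, 0.3, 1.0)])
    def test_invalid_schedules_rejected(self, vals):
        with pytest.raises(ValueError):
            al.LambdaSchedule(vals)


SETTINGS_1D = al.SamplerSettings(n_steps=800, step_size=(0.35, 0.0, 0.0),
                                 stride=4)


class TestRunLeg:
    def test_noninteracting_ligand_gives_zero(self):
        d = _dimer()
        fwd, bwd = al.run_leg(d.unbound, "unbound_decouple",
                              al.LambdaSchedule.uniform(4), SETTINGS_1D, T,
                              seed=1)
        assert fwd.total == pytest.approx(0.0, abs=1e-9)
        assert bwd.total == pytest.approx(0.0, abs=1e-9)

    def test_zero_force_restraint_leg_is_zero(self):
        d = synthkit.make_toy_dimer(well_depth=-4.0, restraint_k=0.0)
        fwd, bwd = al.run_leg(d.unbound, "unbound_restrain",
                              al.LambdaSchedule.uniform(4), SETTINGS_1D, T,
                              seed=2)
        assert fwd.total == pytest.approx(0.0, abs=1e-9)

    def test_single_window_schedule_unconstructible(self):
        with pytest.raises(ValueError):
            al.LambdaSchedule((0.0,))

    def test_unknown_leg_rejected(self):
        d = _dimer()
        with pytest.raises(LigscreenError, match="unknown leg"):
            al.run_leg(d.bound, "sideways", al.LambdaSchedule.uniform(3),
                       SETTINGS_1D, T, seed=1)

    def test_leg_total_is_window_sum(self):
        d = _dimer()
        fwd, _ = al.run_leg(d.bound, "bound_restrain",
                            al.LambdaSchedule.geometric(6), SETTINGS_1D, T,
                            seed=3)
        assert fwd.total == pytest.approx(al.sum_windows(fwd.per_window_dg),
                                          abs=1e-9)

    def test_forward_backward_consistency(self):
        """Forward and negated-backward totals agree within 3× combined SE."""
        d = _dimer()
        settings = al.SamplerSettings(n_steps=2500,
                                      step_size=(0.35, 0.0, 0.0), stride=4)
        fwd, bwd = al.run_leg(d.bound, "bound_decouple",
                              al.LambdaSchedule.uniform(10), settings, T,
                              seed=4)
        combined_se = np.sqrt(fwd.total_se ** 2 + bwd.total_se ** 2)
        assert abs(fwd.total + bwd.total) < max(3 * combined_se, 0.15)


class TestCycle:
    def test_all_zero_legs_give_zero(self):
        leg = lambda n, d: al.FEPLeg(n, d, np.zeros(3), np.zeros(3))
        legs = {n: (leg(n, "forward"), leg(n, "backward"))
                for n in al.LEG_NAMES}
        res = al.binding_dg_from_cycle(legs)
        assert res.delta_g_binding == 0.0

    def test_missing_leg_rejected(self):
        leg = al.FEPLeg("bound_decouple", "forward", np.zeros(2), np.zeros(2))
        with pytest.raises(LigscreenError, match="missing"):
            al.binding_dg_from_cycle({"bound_decouple": (leg, leg)})

    def test_sign_convention_favours_binding(self):
        """A deep bound leg (costly decoupling) must give negative ΔG."""
        def leg(name, total):
            return (al.FEPLeg(name, "forward", np.array([total]),
                              np.array([0.0])),
                    al.FEPLeg(name, "backward", np.array([-total]),
                              np.array([0.0])))
        legs = {"bound_restrain": leg("bound_restrain", 0.2),
                "bound_decouple": leg("bound_decouple", 6.0),
                "unbound_decouple": leg("unbound_decouple", 0.0),
                "unbound_restrain": leg("unbound_restrain", 1.5)}
        res = al.binding_dg_from_cycle(legs)
        assert res.delta_g_binding == pytest.approx(-(0.2 + 6.0 - 0.0 - 1.5))
        assert res.delta_g_binding < 0

    def test_schedule_refinement_stability(self):
        """Doubling the window count moves the leg total by less than the
        hysteresis diagnostic of the coarse run."""
        d = _dimer()
        settings = al.SamplerSettings(n_steps=2000,
                                      step_size=(0.35, 0.0, 0.0), stride=4)
        f1, b1 = al.run_leg(d.bound, "bound_decouple",
                            al.LambdaSchedule.uniform(6), settings, T, seed=5)
        f2, _ = al.run_leg(d.bound, "bound_decouple",
                           al.LambdaSchedule.uniform(12), settings, T, seed=5)
        est1 = 0.5 * (f1.total - b1.total)
        tol = max(abs(f1.total + b1.total), 6 * f1.total_se, 0.1)
        assert abs(f2.total - est1) < tol
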