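"""Toy simulator: potentials, integrator physics, fixture generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratchetpath.toysim import (
    ContactPlanEntry, DoubleWell1D, FlatBottomPair, FunnelRadial,
    HarmonicWell, HarmonicWellBlock, LangevinParams, LangevinState,
    RadialDoubleWell, RelativeTether, RelativeTetherBlock, ToyLandscapeSpec,
    ToyPotential, flat_bottom_energy, flat_bottom_force, langevin_step,
    make_toy_complex, run_langevin, synth_contact_trajectory, synth_series,
)
from ratchetpath.units import KB


class TestFlatBottom:
    def test_zero_inside_window(self):
        assert flat_bottom_energy(3.0, 2.5, 3.5, 17.0) == 0.0

    def test_direct_evaluation_above(self):
        assert flat_bottom_energy(4.5, 2.5, 3.5, 2.0) == pytest.approx(1.0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            flat_bottom_energy(3.0, 2.5, 3.5, -1.0)

    def test_energy_equals_integral_of_force(self):
        # numerical-quadrature oracle: E(d) - E(d0) = integral of dE/dd
        from scipy.integrate import quad
        r_min, r_max, k = 2.0, 3.0, 4.0
        for d in (1.2, 2.5, 3.7, 5.0):
            integral, _ = quad(lambda s: flat_bottom_force(s, r_min, r_max, k),
                               2.5, d)
            assert integral == pytest.approx(
                flat_bottom_energy(d, r_min, r_max, k), abs=1e-6)


def _random_state(rng, n):
    return rng.uniform(-3, 3, size=(n, 3)) + np.array([1.0, -0.5, 2.0])


TERMS = [
    HarmonicWell(0, np.array([0.5, 0.0, 1.0]), 3.0),
    DoubleWell1D(1, 2, q0=1.0, half_separation=1.5, barrier=4.0),
    FunnelRadial((0, 2), np.zeros(3), np.array([0.0, 0.0, 1.0]), 2.0),
    FlatBottomPair(0, 1, 1.0, 2.0, 5.0),
    RelativeTether(0, 2, np.array([1.0, 0.5, -0.5]), 4.0),
    HarmonicWellBlock(np.array([0, 1]), np.array([[0.0, 0, 0], [1.0, 1, 1]]),
                      np.array([2.0, 3.0])),
    RelativeTetherBlock(0, np.array([1, 2]),
                        np.array([[1.0, 0, 0], [0, 1.0, 0]]),
                        np.array([2.0, 5.0])),
    RadialDoubleWell(0, 1, bound_rho=2.0, bound_depth=5.0,
                     intermediate_rho=5.0, intermediate_depth=2.0,
                     width=0.6, wall_rho=1.0),
]


@pytest.mark.parametrize("term", TERMS, ids=lambda t: type(t).__name__)
def test_force_is_minus_analytic_gradient(term):
    """Central-difference check of every potential term on random states."""
    rng = np.random.default_rng(42)
    pot = ToyPotential([term])
    h = 1e-5
    for _ in range(5):
        x = _random_state(rng, 3)
        grad = pot.gradient(x)
        scale = max(1.0, np.abs(grad).max())
        for i in range(3):
            for d in range(3):
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                num = (pot.energy(xp) - pot.energy(xm)) / (2 * h)
                assert grad[i, d] == pytest.approx(num, abs=2e-5 * scale)


class TestLangevin:
    def test_fixed_point_at_zero_temperature(self):
        pot = ToyPotential([HarmonicWell(0, np.zeros(3), 2.0)])
        params = LangevinParams(temperature=0.0, friction=60.0, dt=0.002)
        masses = np.array([12.0])
        state = LangevinState(coords=np.zeros((1, 3)),
                              velocities=np.zeros((1, 3)),
                              rng=np.random.default_rng(0))
        for _ in range(100):
            langevin_step(state, pot, params, masses)
        np.testing.assert_allclose(state.coords, 0.0, atol=1e-12)

    def test_same_seed_bit_identical(self):
        pot = ToyPotential([HarmonicWell(0, np.zeros(3), 2.0)])
        params = LangevinParams(temperature=300.0, friction=60.0, dt=0.002)
        masses = np.array([12.0])
        x0 = np.array([[0.5, 0.0, 0.0]])
        runs = [run_langevin(pot, masses, params, x0, 500,
                             rng=np.random.default_rng(99)) for _ in range(2)]
        assert np.array_equal(runs[0].positions, runs[1].positions)

    def test_single_step_matches_run_loop(self):
        """The fast inlined loop and langevin_step agree bit for bit."""
        pot = ToyPotential([HarmonicWell(0, np.zeros(3), 2.0)])
        params = LangevinParams(temperature=300.0, friction=60.0, dt=0.002)
        masses = np.array([12.0])
        x0 = np.array([[0.5, 0.2, -0.1]])
        res = run_langevin(pot, masses, params, x0, 50,
                           velocities0=np.zeros((1, 3)),
                           rng=np.random.default_rng(3))
        state = LangevinState(coords=x0.copy(), velocities=np.zeros((1, 3)),
                              rng=np.random.default_rng(3))
        for _ in range(50):
            langevin_step(state, pot, params, masses)
        np.testing.assert_array_equal(res.state.coords, state.coords)

    def test_equipartition_variance_short(self):
        # 1D harmonic well, light bead: variance ~ kT/k (tighter check in
        # the acceptance suite at full length)
        k = 1.0
        pot = ToyPotential([HarmonicWell(0, np.zeros(3), k)])
        params = LangevinParams(temperature=300.0, friction=60.0, dt=0.002)
        masses = np.array([1.0])
        res = run_langevin(pot, masses, params, np.zeros((1, 3)), 100_000,
                           record_every=10, rng=np.random.default_rng(11))
        x = res.positions[200:, 0, 0]
        assert np.var(x) == pytest.approx(KB * 300.0 / k, rel=0.10)


def test_boltzmann_sampling_of_double_well():
    """Long Langevin run reproduces the analytic Boltzmann marginal of a
    1D double well (histogram KL divergence < 0.05 at 1e6 steps)."""
    dw = DoubleWell1D(0, 0, q0=0.0, half_separation=1.0, barrier=2.0)
    pot = ToyPotential([
        dw,
        # confine y,z so the marginal of interest is the x double well
        FunnelRadial((0,), np.zeros(3), np.array([1.0, 0.0, 0.0]), 5.0),
    ])
    params = LangevinParams(temperature=300.0, friction=60.0, dt=0.002)
    res = run_langevin(pot, np.array([1.0]), params, np.array([[1.0, 0, 0]]),
                       1_000_000, record_every=10,
                       rng=np.random.default_rng(2024))
    q = res.positions[1000:, 0, 0]  # discard equilibration
    edges = np.linspace(-2.2, 2.2, 45)
    hist, _ = np.histogram(q, bins=edges)
    p_emp = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = dw.density(centers, 300.0)
    p_ref = dens * np.diff(edges)
    p_ref = p_ref / p_ref.sum()
    mask = p_emp > 0
    kl = float(np.sum(p_emp[mask] * np.log(p_emp[mask] / p_ref[mask])))
    assert kl < 0.05


class TestToyComplex:
    def test_minima_at_spec_positions(self):
        sys_ = make_toy_complex(ToyLandscapeSpec(bound_rho=5.0,
                                                 intermediate_rho=9.0))
        from scipy.optimize import minimize_scalar
        prof = sys_.landscape.profile
        lo = minimize_scalar(prof, bounds=(4.0, 6.0), method="bounded")
        li = minimize_scalar(prof, bounds=(8.0, 10.0), method="bounded")
        assert abs(lo.x - 5.0) < 1e-3
        assert abs(li.x - 9.0) < 1e-3

    def test_zero_intermediate_depth_single_minimum(self):
        sys_ = make_toy_complex(ToyLandscapeSpec(intermediate_depth=0.0))
        rho = np.linspace(3.6, 14.0, 2000)
        v = sys_.landscape.profile(rho)
        interior = (np.diff(np.sign(np.diff(v))) > 0).sum()
        assert interior == 1  # only the bound minimum

    def test_barrier_tops_exceed_well_energies(self):
        sys_ = make_toy_complex()
        prof = sys_.landscape.profile
        barrier = max(prof(r) for r in np.linspace(5.0, 9.0, 500))
        assert barrier > prof(5.0) and barrier > prof(9.0)

    def test_overlapping_wells_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ToyLandscapeSpec(bound_rho=5.0, intermediate_rho=6.0,
                             well_width=0.7)

    def test_moieties_partition_ligand(self):
        topo = make_toy_complex().topology
        moieties = [set(topo.group(m)) for m in ("core", "iBu", "Tol", "Ethe")]
        assert set().union(*moieties) == set(topo.group("ligand"))


class TestSynthSeries:
    def test_single_plateau_no_noise_is_constant(self):
        _, y = synth_series([(0.0, 100.0, 7.0, 0.0)], 100.0, 1.0)
        np.testing.assert_array_equal(y[:, 0], 7.0)

    def test_two_levels_zero_noise_is_exact_step(self):
        _, y = synth_series([(0.0, 50.0, 5.0, 0.0), (50.5, 100.0, 9.0, 0.0)],
                            100.0, 0.5)
        assert set(np.round(np.unique(y), 6)) == {5.0, 9.0}

    def test_planted_mean_within_standard_error(self):
        times, y = synth_series([(100.0, 400.0, 7.0, 0.2)], 500.0, 0.5,
                                seed=5)
        mask = (times >= 100.0) & (times <= 400.0)
        n = mask.sum()
        se = 0.2 / np.sqrt(n)
        assert y[mask, 0].mean() == pytest.approx(7.0, abs=4 * se)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth_series([(0, 60, 5, 0), (50, 100, 6, 0)], 100.0, 1.0)

    def test_interval_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            synth_series([(0, 200, 5, 0)], 100.0, 1.0)

    def test_multichannel_levels(self):
        _, y = synth_series([(0.0, 50.0, [5.0, 7.0], 0.0)], 50.0, 1.0)
        assert y.shape[1] == 2
        np.testing.assert_array_equal(y[:, 1], 7.0)


class TestSynthContacts:
    def test_frequency_one_pair_always_in_contact(self):
        traj = synth_contact_trajectory([(1.0, 3.2, 0.15)], 1000, seed=1)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        assert np.all(d < 4.0)
        assert np.std(d) == pytest.approx(0.15, rel=0.15)

    def test_frequency_zero_pair_never_in_contact(self):
        traj = synth_contact_trajectory([(0.0, 8.0, 0.3)], 500, seed=2)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        assert np.all(d >= 4.0)

    def test_realized_frequency_within_binomial_noise(self):
        n = 2000
        traj = synth_contact_trajectory([(0.55, 3.4, 0.2)], n, seed=3)
        d = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        freq = (d < 4.0).mean()
        sd = np.sqrt(0.55 * 0.45 / n)
        assert abs(freq - 0.55) <= 3 * sd

    def test_two_seeds_differ_but_statistics_agree(self):
        t1 = synth_contact_trajectory([(1.0, 3.2, 0.15)], 2000, seed=10)
        t2 = synth_contact_trajectory([(1.0, 3.2, 0.15)], 2000, seed=11)
        assert not np.array_equal(t1.frames, t2.frames)
        d1 = np.linalg.norm(t1.frames[:, 1] - t1.frames[:, 0], axis=1)
        d2 = np.linalg.norm(t2.frames[:, 1] - t2.frames[:, 0], axis=1)
        assert d1.mean() == pytest.approx(d2.mean(), abs=0.05)

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synth_contact_trajectory([(1.0, 8.0, 0.3)], 100, seed=0)

    def test_seed_deterministic(self):
        t1 = synth_contact_trajectory([(0.5, 3.0, 0.2)], 200, seed=4)
        t2 = synth_contact_trajectory([(0.5, 3.0, 0.2)], 200, seed=4)
        np.testing.assert_array_equal(t1.frames, t2.frames)


@settings(deadline=None, max_examples=20)
@given(d=st.floats(0.1, 10.0), r_min=st.floats(0.5, 3.0),
       width=st.floats(0.0, 2.0), k=st.floats(0.0, 50.0))
def test_flat_bottom_nonnegative_and_zero_inside(d, r_min, width, k):
    r_max = r_min + width
    e = flat_bottom_energy(d, r_min, r_max, k)
    assert e >= 0.0
    if r_min <= d <= r_max:
        assert e == 0.0
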