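"""Initial split, hindrance rates, bleach protocol and forward simulation."""

import numpy as np
import pytest

from flipdg.dg_core import DGSpace, StateFields, backward_euler_stepper
from flipdg.flip_model import (
    BleachProtocol,
    ModelParameters,
    OperatorCache,
    bleach_schedule,
    compute_rate_fields,
    equilibrium_constant,
    forward_simulate,
    split_initial_intensity,
    theta_at,
)
from flipdg.mesh_geometry import CYTOPLASM, NUCLEUS, aggregate_tag, is_aggregate


class TestInitialSplit:
    def test_uniform_field_is_all_free(self):
        u0, ub0 = split_initial_intensity(np.full(12, 3.7))
        assert u0 == 3.7
        assert np.all(ub0 == 0.0)

    def test_hindered_is_excess_over_minimum(self):
        c0 = np.array([0.2, 1.0, 0.5])
        u0, ub0 = split_initial_intensity(c0)
        assert u0 == pytest.approx(0.2)
        assert ub0[1] == pytest.approx(0.8)

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(5)
        c0 = rng.random(300) + 0.1
        u0, ub0 = split_initial_intensity(c0)
        assert np.array_equal(u0 + ub0, c0)
        assert np.all(ub0 >= 0)

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            split_initial_intensity(np.array([]))


class TestRateFields:
    def test_k_off_is_gamma_times_free_pool(self):
        rates = compute_rate_fields(0.2, 1.0, np.zeros(5))
        assert rates.k_off == pytest.approx(0.2)

    def test_no_hindrance_without_hindered_pool(self):
        rates = compute_rate_fields(0.5, 2.0, np.zeros(8))
        assert np.all(rates.k_on == 0.0)

    def test_initial_detailed_balance_identity(self):
        rng = np.random.default_rng(2)
        u0, ub0 = 1.3, rng.random(50)
        rates = compute_rate_fields(0.37, u0, ub0)
        assert np.allclose(rates.k_on * u0, rates.k_off * ub0)


class TestEquilibriumConstant:
    def test_constructed_aggregate_ratio(self, cell_mesh):
        dof_tags = np.repeat(cell_mesh.compartment, 3)
        c0 = np.ones(3 * cell_mesh.n_triangles)
        c0[is_aggregate(dof_tags)] = 1.16
        assert equilibrium_constant(c0, cell_mesh, "aggregate") == pytest.approx(1.16)

    def test_constructed_nucleus_ratio(self, cell_mesh):
        dof_tags = np.repeat(cell_mesh.compartment, 3)
        c0 = np.ones(3 * cell_mesh.n_triangles)
        c0[dof_tags == NUCLEUS] = 1.26
        assert equilibrium_constant(c0, cell_mesh, "nucleus") == pytest.approx(1.26)

    def test_equal_means_give_unity(self, cell_mesh):
        c0 = 2.5 * np.ones(3 * cell_mesh.n_triangles)
        assert equilibrium_constant(c0, cell_mesh, "aggregate") == pytest.approx(1.0)


class TestBleachProtocol:
    def test_default_cycle_matches_flip_experiment(self):
        # 2.8 s frame = 2 s full-power bleach + 0.8 s imaging
        p = BleachProtocol()
        segs = bleach_schedule(p)
        assert segs[0] == (0.0, 2.8, 0)  # pre-bleach frame
        assert segs[1] == (2.8, 4.8, 1)
        assert segs[2] == (4.8, 5.6, 0)
        on = [s for s in segs if s[2] == 1]
        assert all(s[1] - s[0] == pytest.approx(2.0) for s in on)
        assert len(on) == p.n_frames - 1

    def test_first_comparison_time(self):
        p = BleachProtocol(t_compare=2.6)
        assert p.frame_times()[0] == pytest.approx(2.6)
        assert p.frame_times()[10] == pytest.approx(2.8 * 10 + 2.6)

    def test_no_bleach_before_experiment_or_first_frame(self):
        p = BleachProtocol()
        assert theta_at(p, -1.0) == 0
        assert theta_at(p, 1.0) == 0
        assert theta_at(p, 3.0) == 1
        assert theta_at(p, 5.0) == 0

    def test_inconsistent_timing_rejected(self):
        with pytest.raises(ValueError):
            BleachProtocol(dt_frame=2.8, t_bleach=2.0, t_image=0.9)
        with pytest.raises(ValueError):
            BleachProtocol(t_compare=3.0)


@pytest.fixture(scope="module")
def small_protocol():
    return BleachProtocol(dt_frame=2.8, t_bleach=2.0, t_image=0.8, n_frames=5, t_compare=2.6)


class TestForwardSimulation:
    def test_stationary_without_bleach(self, cell_mesh, small_protocol):
        # beta = 0 and equal exchange rates: the initial split is an exact
        # steady state (reaction in detailed balance, free pool uniform)
        rng = np.random.default_rng(11)
        c0 = 1.0 + np.repeat(rng.random(cell_mesh.n_triangles), 3)
        params = ModelParameters(alpha=17.0, beta=0.0, gamma=0.2, k1=0.05, k2=0.05,
                                 membrane_mode="permeable", p=0.3)
        series = forward_simulate(cell_mesh, params, small_protocol, c0)
        for frame in series.values[1:]:
            assert np.allclose(frame, series.values[0], rtol=1e-8)

    def test_mass_monotone_under_bleach_conserved_without(self, cell_mesh, small_protocol):
        c0 = np.full(3 * cell_mesh.n_triangles, 2.0)
        cache = OperatorCache(cell_mesh, c0)
        ones = np.ones(cache.space.n_dofs)

        params = ModelParameters(alpha=10.0, beta=36.0, gamma=0.1, k1=0.07, k2=0.06,
                                 membrane_mode="permeable", p=0.3)
        series = forward_simulate(cell_mesh, params, small_protocol, c0, cache=cache)
        masses = [ones @ (cache.mass @ v) for v in series.values]
        assert all(m2 < m1 for m1, m2 in zip(masses[1:], masses[2:]))

        quiet = ModelParameters(alpha=10.0, beta=0.0, gamma=0.1, k1=0.07, k2=0.06,
                                membrane_mode="permeable", p=0.3)
        series0 = forward_simulate(cell_mesh, quiet, small_protocol, c0, cache=cache)
        masses0 = [ones @ (cache.mass @ v) for v in series0.values]
        assert np.allclose(masses0, masses0[0], rtol=1e-10)

    def test_simulated_intensity_stays_nonnegative_in_practice(self, cell_mesh, small_protocol):
        rng = np.random.default_rng(4)
        c0 = 1.0 + 0.5 * rng.random(3 * cell_mesh.n_triangles)
        params = ModelParameters(alpha=17.0, beta=36.0, gamma=0.2, k1=0.0718, k2=0.0619,
                                 membrane_mode="permeable", p=0.3)
        series = forward_simulate(cell_mesh, params, small_protocol, c0)
        assert series.values.min() >= -1e-6 * c0.max()

    def test_two_triangle_aggregate_exchange_against_dense_ode(self, make_interface_mesh):
        # method-of-lines oracle: integrate the same semi-discrete system with
        # a high-order stiff solver and compare the frame samples
        from scipy.integrate import solve_ivp
        import scipy.sparse as sp

        mesh = make_interface_mesh(CYTOPLASM, aggregate_tag(1))
        mesh.bleach_flag[:] = False
        protocol = BleachProtocol(dt_frame=1.0, t_bleach=0.5, t_image=0.5,
                                  n_frames=3, t_compare=0.75)
        c0 = np.array([1.0, 1.2, 1.1, 2.0, 1.9, 2.1])
        params = ModelParameters(alpha=0.5, beta=0.0, gamma=0.3, k1=0.4, k2=0.2,
                                 membrane_mode="permeable", p=0.0)
        cache = OperatorCache(mesh, c0)
        ops = cache.operators(params)
        M2 = sp.block_diag([cache.mass, cache.mass]).tocsc()
        S = ops.spatial(False).toarray()
        A = np.linalg.solve(M2.toarray(), S)
        x0 = cache.initial_state().stacked()
        sol = solve_ivp(lambda t, x: A @ x, (0, protocol.frame_times()[-1]), x0,
                        t_eval=protocol.frame_times(), rtol=1e-10, atol=1e-12)
        oracle_c = sol.y[:6].T + sol.y[6:].T

        def max_err(min_substeps):
            sim = forward_simulate(mesh, params, protocol, c0, cache=cache,
                                   min_substeps=min_substeps)
            return np.abs(sim.values - oracle_c).max()

        # first order in dt: quadrupling the step count quarters the error
        e8, e32, e128 = max_err(8), max_err(32), max_err(128)
        assert 3.0 < e8 / e32 < 5.0
        assert 3.0 < e32 / e128 < 5.0

    def test_lowering_export_rate_accumulates_nuclear_protein(self, cell_mesh, small_protocol):
        c0 = np.full(3 * cell_mesh.n_triangles, 2.0)
        cache = OperatorCache(cell_mesh, c0)
        areas = cell_mesh.areas()
        nuc = cell_mesh.compartment == NUCLEUS
        cyt = cell_mesh.compartment == CYTOPLASM

        def final_ratio(k_nc):
            params = ModelParameters(alpha=18.2, beta=32.0, gamma=0.06, k1=0.01, k2=0.01,
                                     membrane_mode="active", k_cn=0.377, k_nc=k_nc)
            series = forward_simulate(cell_mesh, params, small_protocol, c0, cache=cache)
            tri = series.values[-1].reshape(-1, 3).mean(axis=1)
            mn = np.sum(areas[nuc] * tri[nuc]) / areas[nuc].sum()
            mc = np.sum(areas[cyt] * tri[cyt]) / areas[cyt].sum()
            return mn / mc

        ratios = [final_ratio(k) for k in (0.342, 0.2, 0.05)]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_far_aggregate_decays_slower_than_cytoplasm(self, cell_mesh, small_protocol):
        # dim-aggregate visibility: slow release keeps aggregates bright while
        # the surrounding cytoplasm bleaches away
        c0 = np.full(3 * cell_mesh.n_triangles, 2.0)
        params = ModelParameters(alpha=17.0, beta=36.0, gamma=0.05, k1=0.0718, k2=0.0619,
                                 membrane_mode="permeable", p=0.3)
        series = forward_simulate(cell_mesh, params, small_protocol, c0)
        areas = cell_mesh.areas()
        agg = is_aggregate(cell_mesh.compartment)
        cyt = cell_mesh.compartment == CYTOPLASM

        def mean(v, sel):
            tri = v.reshape(-1, 3).mean(axis=1)
            return np.sum(areas[sel] * tri[sel]) / areas[sel].sum()

        agg_decay = mean(series.values[-1], agg) / mean(series.values[0], agg)
        cyt_decay = mean(series.values[-1], cyt) / mean(series.values[0], cyt)
        assert agg_decay > cyt_decay
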