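"""Operator assembly: exact local blocks, kernels, conservation, oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.linalg import expm

from flipdg.dg_core import (
    DGSpace,
    PenaltyConfig,
    ReactionBlocks,
    StateFields,
    SystemOperators,
    assemble_bleach,
    assemble_diffusion_sipg,
    assemble_directional_exchange,
    assemble_local_reaction,
    assemble_mass,
    assemble_permeable_membrane,
    backward_euler_stepper,
)
from flipdg.mesh_geometry import (
    AGGREGATE,
    CYTOPLASM,
    MEMBRANE,
    NUCLEUS,
    TriangleMesh,
    aggregate_tag,
    unit_square_mesh,
)


def _zero_ops(space):
    z = sp.csr_matrix((space.n_dofs, space.n_dofs))
    return SystemOperators(assemble_mass(space), z, ReactionBlocks(z, z, z, z), z, z, z)


def _single_triangle_space():
    mesh = TriangleMesh(
        np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 3.0]]),
        np.array([[0, 1, 2]]), np.array([CYTOPLASM]), np.array([False]),
    )
    return DGSpace(mesh)


class TestMass:
    def test_partition_of_unity_gives_total_area(self, cell_space):
        M = assemble_mass(cell_space)
        ones = np.ones(cell_space.n_dofs)
        assert ones @ (M @ ones) == pytest.approx(cell_space.mesh.total_area(), rel=1e-12)

    def test_single_triangle_local_block(self):
        space = _single_triangle_space()
        M = assemble_mass(space).toarray()
        T = 3.0  # area of the (2, 3) right triangle
        expected = (T / 12.0) * np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        assert np.allclose(M, expected)

    def test_symmetry(self, cell_space):
        M = assemble_mass(cell_space)
        assert abs(M - M.T).max() < 1e-14


class TestDiffusion:
    def test_constants_in_kernel(self, cell_space):
        D = assemble_diffusion_sipg(cell_space, cell_space.edges, 17.0)
        assert np.abs(D @ np.ones(cell_space.n_dofs)).max() < 1e-9

    def test_linear_field_dirichlet_energy(self, square_space):
        # u = x is continuous: jump and penalty terms vanish, energy = alpha*area
        alpha = 2.5
        D = assemble_diffusion_sipg(square_space, square_space.edges, alpha)
        u = square_space.interpolate(lambda x, y: x)
        assert u @ (D @ u) == pytest.approx(alpha * 1.0, rel=1e-12)

    def test_symmetric_positive_semidefinite(self, square_space):
        D = assemble_diffusion_sipg(square_space, square_space.edges, 1.0)
        assert abs(D - D.T).max() < 1e-12
        w = np.linalg.eigvalsh(D.toarray())
        assert w.min() > -1e-10

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(sigma=0.0)


class TestReaction:
    def test_zero_rates_zero_blocks(self, cell_space):
        R = assemble_local_reaction(cell_space, np.zeros(cell_space.n_dofs), 0.0)
        for blk in R:
            assert blk.nnz == 0 or abs(blk).max() < 1e-15

    def test_detailed_balance_is_stationary(self, cell_space):
        rng = np.random.default_rng(7)
        k_on = rng.random(cell_space.n_dofs)
        k_off = 0.7
        R = assemble_local_reaction(cell_space, k_on, k_off)
        u = 1.5 * np.ones(cell_space.n_dofs)
        ub = k_on * u / k_off  # pointwise equilibrium
        resid_u = R.uu @ u + R.uub @ ub
        resid_b = R.bu @ u + R.bub @ ub
        scale = abs(R.uub).max()
        assert np.abs(resid_u).max() < 1e-12 * scale
        assert np.abs(resid_b).max() < 1e-12 * scale

    def test_single_triangle_residual_integral(self):
        # k_on=2, k_off=1, u=1, ub=3: u-row against test function 1 gives (3-2)*T
        space = _single_triangle_space()
        R = assemble_local_reaction(space, 2.0 * np.ones(3), 1.0)
        u, ub = np.ones(3), 3.0 * np.ones(3)
        total = np.sum(R.uu @ u + R.uub @ ub)
        assert total == pytest.approx(3.0, rel=1e-12)  # T = 3

    def test_mass_conserving_pair(self, cell_space):
        rng = np.random.default_rng(3)
        R = assemble_local_reaction(cell_space, rng.random(cell_space.n_dofs), 0.4)
        u, ub = rng.random(cell_space.n_dofs), rng.random(cell_space.n_dofs)
        assert np.sum(R.uu @ u + R.uub @ ub) + np.sum(R.bu @ u + R.bub @ ub) == pytest.approx(0.0, abs=1e-12)

    def test_negative_rates_rejected(self, cell_space):
        with pytest.raises(ValueError):
            assemble_local_reaction(cell_space, -np.ones(cell_space.n_dofs), 0.1)


class TestBleach:
    def test_zero_beta_off_switch(self, cell_space):
        B = assemble_bleach(cell_space, cell_space.mesh, 0.0)
        assert B.nnz == 0 or abs(B).max() == 0.0

    def test_constant_quadratic_form_equals_beta_times_bleach_area(self, cell_space):
        beta = 36.0
        B = assemble_bleach(cell_space, cell_space.mesh, beta)
        ones = np.ones(cell_space.n_dofs)
        assert ones @ (B @ ones) == pytest.approx(beta * cell_space.mesh.bleach_area(), rel=1e-12)

    def test_rows_outside_bleach_region_are_zero(self, cell_space):
        B = assemble_bleach(cell_space, cell_space.mesh, 5.0).tocsr()
        outside = np.repeat(~cell_space.mesh.bleach_flag, 3)
        assert abs(B[outside]).max() == 0.0


class TestDirectionalExchange:
    def test_single_edge_blocks_and_totals(self, make_interface_mesh):
        # cytoplasm | aggregate split along the unit-square diagonal, |e| = sqrt(2)
        mesh = make_interface_mesh(CYTOPLASM, aggregate_tag(1))
        space = DGSpace(mesh)
        L = np.sqrt(2.0)
        A = assemble_directional_exchange(space, space.edges, AGGREGATE, 1.0, 0.0)
        u = np.zeros(space.n_dofs)
        u[0:3] = 1.0  # cytoplasm side constant 1
        flux = A @ u
        agg_gain = np.sum(flux[3:6])
        cyt_loss = np.sum(flux[0:3])
        assert agg_gain == pytest.approx(L, rel=1e-12)
        assert cyt_loss == pytest.approx(-L, rel=1e-12)
        # coupling block between the paired edge dofs is the P1 edge mass matrix
        k = int(space.edges.of_class(AGGREGATE)[0])
        dc, dx = space.edge_dofs(k, 0), space.edge_dofs(k, 1)
        block = A.toarray()[np.ix_(dx, dc)]
        assert np.allclose(block, (L / 6.0) * np.array([[2, 1], [1, 2]]))

    def test_equilibrium_ratio_in_kernel(self, make_interface_mesh):
        mesh = make_interface_mesh(CYTOPLASM, aggregate_tag(1))
        space = DGSpace(mesh)
        k1, k2 = 0.0718, 0.0619
        A = assemble_directional_exchange(space, space.edges, AGGREGATE, k1, k2)
        u = np.zeros(space.n_dofs)
        u[0:3] = 1.0
        u[3:6] = k1 / k2
        assert np.abs(A @ u).max() < 1e-14

    def test_column_sums_vanish(self, cell_space):
        A = assemble_directional_exchange(cell_space, cell_space.edges, AGGREGATE, 0.3, 0.7)
        assert np.abs(np.ones(cell_space.n_dofs) @ A).max() < 1e-12


class TestPermeableMembrane:
    def test_zero_permeability(self, cell_space):
        M = assemble_permeable_membrane(cell_space, cell_space.edges, 0.0)
        assert M.nnz == 0 or abs(M).max() == 0.0

    def test_continuous_field_in_kernel(self, cell_space):
        M = assemble_permeable_membrane(cell_space, cell_space.edges, 0.5)
        u = cell_space.interpolate(lambda x, y: 1.0 + 0.2 * x - 0.1 * y)
        assert np.abs(M @ u).max() < 1e-12

    def test_constant_jump_quadratic_form(self, make_interface_mesh):
        mesh = make_interface_mesh(CYTOPLASM, NUCLEUS)
        space = DGSpace(mesh)
        p, d, L = 0.3, 0.7, np.sqrt(2.0)
        M = assemble_permeable_membrane(space, space.edges, p)
        u = np.zeros(space.n_dofs)
        u[3:6] = d  # jump of size d across the membrane edge
        assert u @ (M @ u) == pytest.approx(-p * d**2 * L, rel=1e-12)

    def test_negative_semidefinite(self, cell_space):
        M = assemble_permeable_membrane(cell_space, cell_space.edges, 1.0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.standard_normal(cell_space.n_dofs)
            assert v @ (M @ v) <= 1e-12


class TestBackwardEuler:
    def test_zero_operators_identity(self, cell_space):
        ops = _zero_ops(cell_space)
        rng = np.random.default_rng(0)
        st = StateFields(u=rng.random(cell_space.n_dofs), ub=rng.random(cell_space.n_dofs))
        out = backward_euler_stepper(ops, st, 0.5, True)
        assert np.allclose(out.u, st.u, atol=1e-11)
        assert np.allclose(out.ub, st.ub, atol=1e-11)

    def test_pure_bleach_scalar_recursion(self):
        # whole domain bleached: implicit Euler gives u_n = u0 / (1 + beta dt)^n
        mesh = unit_square_mesh(2, tag=NUCLEUS)
        mesh.bleach_flag[:] = True
        space = DGSpace(mesh)
        beta, dt, n = 36.0, 0.2, 10
        z = sp.csr_matrix((space.n_dofs, space.n_dofs))
        ops = SystemOperators(assemble_mass(space), z, ReactionBlocks(z, z, z, z),
                              assemble_bleach(space, mesh, beta), z, z)
        st = StateFields(u=np.ones(space.n_dofs), ub=np.ones(space.n_dofs))
        for _ in range(n):
            st = backward_euler_stepper(ops, st, dt, bleach_on=True)
        expected = 1.0 / (1.0 + beta * dt) ** n
        assert np.allclose(st.u, expected, rtol=1e-10)
        assert np.allclose(st.ub, expected, rtol=1e-10)

    def test_two_triangle_exchange_first_order_in_dt(self, make_interface_mesh):
        # backward Euler error against the dense matrix-exponential solution is O(dt)
        mesh = make_interface_mesh(CYTOPLASM, aggregate_tag(1))
        space = DGSpace(mesh)
        z = sp.csr_matrix((space.n_dofs, space.n_dofs))
        A = assemble_directional_exchange(space, space.edges, AGGREGATE, 0.9, 0.4)
        M = assemble_mass(space)
        ops = SystemOperators(M, z, ReactionBlocks(z, z, z, z), z, A, z)
        x0 = np.concatenate([np.linspace(1, 2, space.n_dofs), np.zeros(space.n_dofs)])
        T = 1.0
        S = ops.spatial(False).toarray()
        M2 = sp.block_diag([M, M]).toarray()
        exact = expm(np.linalg.solve(M2, S) * T) @ x0

        def be_error(dt):
            st = StateFields(u=x0[: space.n_dofs].copy(), ub=x0[space.n_dofs:].copy())
            for _ in range(int(round(T / dt))):
                st = backward_euler_stepper(ops, st, dt, False)
            return np.linalg.norm(st.stacked() - exact)

        # first-order: halving dt halves the error (ratio -> 2, well below the
        # ratio 4 a second-order scheme would give)
        e1, e2, e3 = be_error(0.05), be_error(0.025), be_error(0.0125)
        assert 1.8 < e1 / e2 < 3.0
        assert 1.8 < e2 / e3 < 3.0

    def test_factorizations_cached_per_dt_and_flag(self, cell_space):
        ops = _zero_ops(cell_space)
        s1 = ops.solver(0.2, True)
        s2 = ops.solver(0.2, True)
        s3 = ops.solver(0.2, False)
        assert s1 is s2 and s1 is not s3
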