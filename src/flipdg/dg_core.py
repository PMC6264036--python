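"""Piecewise-linear discontinuous Galerkin operators and time stepping.

The spatial discretization lives on a broken P1 space: three nodal degrees of
freedom per triangle, discontinuous across every edge.  Diffusion of the free
pool is discretized with the symmetric interior-penalty (SIPG) form on
same-compartment interior edges only; nuclear-membrane and aggregate-boundary
edges instead carry dedicated interface operators (a jump-penalizing
permeable-membrane form, or a mass-conserving directional first-order
exchange form).  Binding/release between the free pool ``u`` and the hindered
pool ``u_b`` and the photobleaching sink are local volume terms.

The coupled two-species system is advanced monolithically by backward Euler,

    (Mass - dt * S) x_{n+1} = Mass x_n,     x = (u; u_b),

with ``S = -D + R + A + M - theta * B`` and one cached sparse LU factorization
per (dt, bleach on/off) pair, so that a whole FLIP protocol reuses exactly two
pre-assembled, pre-factored system matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh_geometry import (
    AGGREGATE,
    INTERIOR,
    MEMBRANE,
    EdgeSet,
    TriangleMesh,
)

__all__ = [
    "DGSpace",
    "PenaltyConfig",
    "ReactionBlocks",
    "SystemOperators",
    "StateFields",
    "assemble_mass",
    "assemble_diffusion_sipg",
    "assemble_local_reaction",
    "assemble_bleach",
    "assemble_directional_exchange",
    "assemble_permeable_membrane",
    "backward_euler_stepper",
    "triangle_quadrature",
    "edge_quadrature",
]


# ---------------------------------------------------------------------------
# quadrature (reference rules; assembly itself uses exact closed forms)
# ---------------------------------------------------------------------------


def triangle_quadrature(order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric points and weights (summing to 1) exact to ``order``."""
    if order <= 2:
        pts = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
        w = np.full(3, 1 / 3)
    else:  # Dunavant degree-4 six-point rule
        a1, a2 = 0.445948490915965, 0.091576213509771
        w1, w2 = 0.223381589678011, 0.109951743655322
        pts = np.array(
            [
                [1 - 2 * a1, a1, a1], [a1, 1 - 2 * a1, a1], [a1, a1, 1 - 2 * a1],
                [1 - 2 * a2, a2, a2], [a2, 1 - 2 * a2, a2], [a2, a2, 1 - 2 * a2],
            ]
        )
        w = np.array([w1, w1, w1, w2, w2, w2])
    return pts, w


def edge_quadrature(order: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Gauss points on [0, 1] and weights summing to 1."""
    n = max(1, (order + 2) // 2)
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


# ---------------------------------------------------------------------------
# the broken P1 space
# ---------------------------------------------------------------------------

_LOCAL_MASS = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
_EDGE_MASS = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0


class DGSpace:
    """Broken P1 space on a tagged triangle mesh: 3 dofs per triangle.

    Dof ``3*t + i`` is the nodal value of triangle ``t`` at its local vertex
    ``i``; basis functions are supported on exactly one triangle.
    """

    def __init__(self, mesh: TriangleMesh, edges: EdgeSet | None = None):
        from .mesh_geometry import classify_edges

        self.mesh = mesh
        self.edges = edges if edges is not None else classify_edges(mesh)
        self.n_dofs = 3 * mesh.n_triangles
        self.areas = mesh.areas()
        if np.any(self.areas <= 0):
            raise ValueError("mesh contains a degenerate triangle")
        p = mesh.vertices[mesh.triangles]  # (nt, 3, 2)
        # constant gradients of the three nodal basis functions
        a2 = 2.0 * mesh.signed_areas()[:, None]
        g0 = np.stack([p[:, 1, 1] - p[:, 2, 1], p[:, 2, 0] - p[:, 1, 0]], axis=1) / a2
        g1 = np.stack([p[:, 2, 1] - p[:, 0, 1], p[:, 0, 0] - p[:, 2, 0]], axis=1) / a2
        g2 = np.stack([p[:, 0, 1] - p[:, 1, 1], p[:, 1, 0] - p[:, 0, 0]], axis=1) / a2
        self.grads = np.stack([g0, g1, g2], axis=1)  # (nt, 3, 2)
        self.dof_coords = p.reshape(-1, 2)
        # local indices (0..2) of each edge's endpoints within each adjacent triangle
        self._edge_local = self._build_edge_local()

    def _build_edge_local(self) -> np.ndarray:
        tri = self.mesh.triangles
        e = self.edges
        loc = np.full((e.n_edges, 2, 2), -1, dtype=np.int64)  # (edge, side, endpoint)
        for k in range(e.n_edges):
            for side, t in enumerate((e.tri_minus[k], e.tri_plus[k])):
                if t < 0:
                    continue
                row = tri[t]
                loc[k, side, 0] = int(np.flatnonzero(row == e.vert_a[k])[0])
                loc[k, side, 1] = int(np.flatnonzero(row == e.vert_b[k])[0])
        return loc

    def dofs_of(self, t: int) -> np.ndarray:
        return np.arange(3 * t, 3 * t + 3)

    def edge_dofs(self, k: int, side: int) -> np.ndarray:
        """Global dofs of edge k's endpoints (a, b) on the given side (0=minus)."""
        t = self.edges.tri_minus[k] if side == 0 else self.edges.tri_plus[k]
        return 3 * t + self._edge_local[k, side]

    def interpolate(self, f) -> np.ndarray:
        """Nodal interpolation of a callable f(x, y) onto the broken space."""
        return np.asarray(f(self.dof_coords[:, 0], self.dof_coords[:, 1]), dtype=float)

    def l2_norm(self, vec: np.ndarray, mass: sp.spmatrix | None = None) -> float:
        m = mass if mass is not None else assemble_mass(self)
        return float(np.sqrt(vec @ (m @ vec)))


@dataclass(frozen=True)
class PenaltyConfig:
    """SIPG penalty: the jump term sigma/h_e uses the physical edge length h_e."""

    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("penalty coefficient sigma must be positive")


# ---------------------------------------------------------------------------
# volume operators
# ---------------------------------------------------------------------------


def assemble_mass(space: DGSpace) -> sp.csr_matrix:
    """Block-diagonal P1 mass matrix, (T/12)*[[2,1,1],[1,2,1],[1,1,2]] per triangle."""
    nt = space.mesh.n_triangles
    blocks = space.areas[:, None, None] * _LOCAL_MASS[None]
    rows = np.repeat(np.arange(space.n_dofs).reshape(nt, 3), 3, axis=1).ravel()
    cols = np.tile(np.arange(space.n_dofs).reshape(nt, 3), (1, 3)).ravel()
    return sp.csr_matrix((blocks.ravel(), (rows, cols)), shape=(space.n_dofs, space.n_dofs))


def _field_mass(space: DGSpace, coeff: np.ndarray) -> sp.csr_matrix:
    """Mass matrix weighted by a broken-P1 coefficient field: int coeff u v dx.

    Exact: uses int_T l_i l_j l_k dx = 2A * i!j!k!/(i+j+k+2)! closed forms.
    """
    nt = space.mesh.n_triangles
    c = coeff.reshape(nt, 3)
    # C[k] = 60/T * int phi_i phi_j phi_k: 6 if i=j=k, 2 if two equal, 1 otherwise
    C = np.empty((3, 3, 3))
    for i in range(3):
        for j in range(3):
            for k in range(3):
                m = len({i, j, k})
                C[i, j, k] = 6.0 if m == 1 else (2.0 if m == 2 else 1.0)
    blocks = np.einsum("tk,ijk->tij", c, C) * (space.areas[:, None, None] / 60.0)
    rows = np.repeat(np.arange(space.n_dofs).reshape(nt, 3), 3, axis=1).ravel()
    cols = np.tile(np.arange(space.n_dofs).reshape(nt, 3), (1, 3)).ravel()
    return sp.csr_matrix((blocks.ravel(), (rows, cols)), shape=(space.n_dofs, space.n_dofs))


class ReactionBlocks(NamedTuple):
    """Blocks of the binding/release coupling, rows ordered (u, u_b)."""

    uu: sp.csr_matrix   # -int k_on u v
    uub: sp.csr_matrix  # +int k_off u_b v
    bu: sp.csr_matrix   # +int k_on u w
    bub: sp.csr_matrix  # -int k_off u_b w


def assemble_local_reaction(space: DGSpace, k_on_field: np.ndarray, k_off: float,
                            mass: sp.spmatrix | None = None) -> ReactionBlocks:
    """First-order binding/release coupling between free and hindered pools.

    The u-equation receives ``k_off*u_b - k_on(x)*u`` and the u_b-equation the
    exact negative, so the pair conserves the summed mass identically.
    """
    k_on_field = np.asarray(k_on_field, dtype=float)
    if np.any(k_on_field < -1e-14) or k_off < 0:
        raise ValueError("reaction rates must be nonnegative")
    kon = _field_mass(space, np.maximum(k_on_field, 0.0))
    m = (mass if mass is not None else assemble_mass(space)).tocsr()
    return ReactionBlocks(uu=-kon, uub=k_off * m, bu=kon, bub=-k_off * m)


def assemble_bleach(space: DGSpace, mesh: TriangleMesh, beta: float) -> sp.csr_matrix:
    """Bleach sink: beta * int_{Omega_B} u v dx, zero outside the bleach region."""
    if beta < 0:
        raise ValueError("bleach rate beta must be nonnegative")
    nt = mesh.n_triangles
    w = np.where(mesh.bleach_flag, beta * space.areas, 0.0)
    blocks = w[:, None, None] * _LOCAL_MASS[None]
    rows = np.repeat(np.arange(space.n_dofs).reshape(nt, 3), 3, axis=1).ravel()
    cols = np.tile(np.arange(space.n_dofs).reshape(nt, 3), (1, 3)).ravel()
    return sp.csr_matrix((blocks.ravel(), (rows, cols)), shape=(space.n_dofs, space.n_dofs))


# ---------------------------------------------------------------------------
# SIPG diffusion
# ---------------------------------------------------------------------------


def assemble_diffusion_sipg(space: DGSpace, edges: EdgeSet, alpha: float,
                            penalty: PenaltyConfig = PenaltyConfig()) -> sp.csr_matrix:
    """Symmetric interior-penalty form of -div(alpha grad u) on interior edges.

    Volume Dirichlet energy plus, per same-compartment interior edge, the two
    consistency/symmetry flux terms and the sigma/h_e jump penalty.  Membrane
    and aggregate edges carry no diffusive coupling (they are handled by the
    interface operators) and the outer boundary is natural (zero flux).
    Returns the positive-semidefinite stiffness-side matrix D with D*const = 0.
    """
    if alpha < 0:
        raise ValueError("diffusion constant must be nonnegative")
    n = space.n_dofs
    rows, cols, vals = [], [], []

    # volume term: A * (G G^T)
    nt = space.mesh.n_triangles
    gg = np.einsum("tid,tjd->tij", space.grads, space.grads) * space.areas[:, None, None]
    r = np.repeat(np.arange(n).reshape(nt, 3), 3, axis=1).ravel()
    c = np.tile(np.arange(n).reshape(nt, 3), (1, 3)).ravel()
    rows.append(r), cols.append(c), vals.append(gg.ravel())

    sigma = penalty.sigma
    for k in np.flatnonzero(edges.edge_class == INTERIOR):
        L = edges.length[k]
        nrm = edges.normal[k]
        tm, tp = edges.tri_minus[k], edges.tri_plus[k]
        dofs_m = np.arange(3 * tm, 3 * tm + 3)
        dofs_p = np.arange(3 * tp, 3 * tp + 3)
        all_dofs = np.concatenate([dofs_m, dofs_p])

        # {grad u}.n per unit coefficient: row vector over the 6 local dofs
        gu = 0.5 * np.concatenate([space.grads[tm] @ nrm, space.grads[tp] @ nrm])
        # integral of the jump of each basis function over the edge
        jmp = np.zeros(6)
        em = space.edge_dofs(k, 0) - 3 * tm        # local (0..2) indices on minus side
        ep = space.edge_dofs(k, 1) - 3 * tp
        jmp[em] = L / 2.0
        jmp[3 + ep] = -L / 2.0

        block = -np.outer(jmp, gu) - np.outer(gu, jmp)

        # penalty: pair edge dofs across sides by shared endpoint
        P = np.zeros((6, 6))
        E = (sigma / L) * (L * _EDGE_MASS)  # = sigma * _EDGE_MASS
        idx = np.concatenate([em, 3 + ep])
        sgn = np.array([1.0, 1.0, -1.0, -1.0])
        for a in range(4):
            for b in range(4):
                P[idx[a], idx[b]] += sgn[a] * sgn[b] * E[a % 2, b % 2]
        block += P

        rr, cc = np.meshgrid(all_dofs, all_dofs, indexing="ij")
        rows.append(rr.ravel()), cols.append(cc.ravel()), vals.append(block.ravel())

    D = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return alpha * D


# ---------------------------------------------------------------------------
# interface operators
# ---------------------------------------------------------------------------


def assemble_directional_exchange(space: DGSpace, edges: EdgeSet, edge_class: int,
                                  k_fwd: float, k_bwd: float) -> sp.csr_matrix:
    """Directional first-order exchange across an interface class.

    The minus side of every MEMBRANE/AGGREGATE edge is the cytoplasm triangle;
    ``k_fwd`` carries intensity cytoplasm -> far side, ``k_bwd`` the reverse.
    Per edge the receiving side gains the P1 edge mass matrix (L/6)[[2,1],[1,2]]
    times the rate applied to the source-side trace, and the source side loses
    exactly the same, so the operator annihilates total mass (zero column sums
    against the all-ones test function).
    """
    if k_fwd < 0 or k_bwd < 0:
        raise ValueError("exchange rates must be nonnegative")
    if edge_class not in (MEMBRANE, AGGREGATE):
        raise ValueError("directional exchange applies to MEMBRANE or AGGREGATE edges")
    n = space.n_dofs
    rows, cols, vals = [], [], []
    for k in np.flatnonzero(edges.edge_class == edge_class):
        if edges.tri_plus[k] < 0:
            raise ValueError(f"interface edge {k} has no far side (ambiguous orientation)")
        L = edges.length[k]
        E = L * _EDGE_MASS
        dc = space.edge_dofs(k, 0)  # cytoplasm side, paired by endpoint
        dx = space.edge_dofs(k, 1)  # far side
        for (recv, src, rate) in ((dx, dc, k_fwd), (dc, dx, k_bwd)):
            if rate == 0.0:
                continue
            blk = rate * E
            rr, cc = np.meshgrid(recv, src, indexing="ij")
            rows += [rr.ravel(), np.meshgrid(src, src, indexing="ij")[0].ravel()]
            cols += [cc.ravel(), np.meshgrid(src, src, indexing="ij")[1].ravel()]
            vals += [blk.ravel(), -blk.ravel()]
    if not rows:
        return sp.csr_matrix((n, n))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def assemble_permeable_membrane(space: DGSpace, edges: EdgeSet, p: float) -> sp.csr_matrix:
    """Semipermeable nuclear membrane: M(u,v) = -p int_{Gamma_M} [u][v] ds.

    Negative semidefinite; vanishes on fields continuous across the membrane.
    """
    if p < 0:
        raise ValueError("membrane permeability must be nonnegative")
    n = space.n_dofs
    rows, cols, vals = [], [], []
    for k in np.flatnonzero(edges.edge_class == MEMBRANE):
        L = edges.length[k]
        E = L * _EDGE_MASS
        dm = space.edge_dofs(k, 0)
        dp = space.edge_dofs(k, 1)
        idx = np.concatenate([dm, dp])
        sgn = np.array([1.0, 1.0, -1.0, -1.0])
        blk = -p * (sgn[:, None] * sgn[None, :]) * np.tile(E, (2, 2))
        rr, cc = np.meshgrid(idx, idx, indexing="ij")
        rows.append(rr.ravel()), cols.append(cc.ravel()), vals.append(blk.ravel())
    if not rows:
        return sp.csr_matrix((n, n))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


# ---------------------------------------------------------------------------
# the coupled system and backward Euler
# ---------------------------------------------------------------------------


@dataclass
class StateFields:
    """Free (u) and hindered (u_b) DG coefficient vectors at time t (seconds)."""

    u: np.ndarray
    ub: np.ndarray
    t: float = 0.0

    @property
    def c(self) -> np.ndarray:
        """Observable intensity, the sum of free and hindered pools."""
        return self.u + self.ub

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.u, self.ub])


@dataclass
class SystemOperators:
    """Assembled operators of the coupled (u, u_b) system with LU caching.

    ``spatial(False)``/``spatial(True)`` are the stacked 2N x 2N operators
    without / with the bleach sink; backward-Euler left-hand sides are
    factored lazily and cached per (dt, bleach flag), so a whole FLIP
    protocol runs on exactly two pre-assembled system matrices.
    """

    mass: sp.csr_matrix
    diffusion: sp.csr_matrix
    reaction: ReactionBlocks
    bleach: sp.csr_matrix
    exchange: sp.csr_matrix
    membrane: sp.csr_matrix
    _mass2: sp.csr_matrix = field(init=False, repr=False)
    _spatial: dict = field(init=False, default_factory=dict, repr=False)
    _lu: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._mass2 = sp.block_diag([self.mass, self.mass], format="csr")

    @property
    def n(self) -> int:
        return self.mass.shape[0]

    def spatial(self, bleach_on: bool) -> sp.csr_matrix:
        key = bool(bleach_on)
        if key not in self._spatial:
            uu = -self.diffusion + self.exchange + self.membrane + self.reaction.uu
            s = sp.bmat(
                [[uu, self.reaction.uub], [self.reaction.bu, self.reaction.bub]], format="csr"
            )
            if key:
                s = s - sp.block_diag([self.bleach, self.bleach], format="csr")
            self._spatial[key] = s
        return self._spatial[key]

    def solver(self, dt: float, bleach_on: bool):
        key = (round(float(dt), 12), bool(bleach_on))
        if key not in self._lu:
            lhs = (self._mass2 - dt * self.spatial(bleach_on)).tocsc()
            try:
                self._lu[key] = splu(lhs)
            except RuntimeError as exc:
                raise RuntimeError(
                    f"backward-Euler system is singular (dt={dt}, bleach={bleach_on}); "
                    "check the SIPG penalty sigma"
                ) from exc
        return self._lu[key]

    def total_mass(self, state: StateFields) -> float:
        ones = np.ones(self.n)
        return float(ones @ (self.mass @ state.c))


def backward_euler_stepper(ops: SystemOperators, state: StateFields, dt: float,
                           bleach_on: bool) -> StateFields:
    """One implicit Euler step of the stacked (u; u_b) system."""
    if dt <= 0:
        raise ValueError("time step must be positive")
    rhs = ops._mass2 @ state.stacked()
    x = ops.solver(dt, bleach_on).solve(rhs)
    n = ops.n
    return StateFields(u=x[:n], ub=x[n:], t=state.t + dt)
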