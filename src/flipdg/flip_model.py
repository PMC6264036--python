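"""The FLIP reaction-diffusion model: parameters, rates, protocol, simulation.

Model summary.  The observable intensity is ``c = u + u_b``: a free pool
``u`` that diffuses (constant ``alpha``, um^2/s) and a hindered pool ``u_b``
that is immobile.  The two pools interconvert by a space-dependent first-order
reaction whose binding rate is proportional to the hindered intensity in the
pre-bleach frame, ``k_on(x) = gamma * u_b0(x)``, with constant release rate
``k_off = gamma * u0``.  Repeated laser bleaching applies a lumped sink rate
``beta`` (1/s) to both pools inside the bleach disc while the bleach indicator
is on.  The nuclear membrane either lets the free pool leak proportionally to
the concentration jump (permeability ``p``, um/s) or carries directional
import/export rates ``k_cn``/``k_nc``; aggregate boundaries carry directional
binding/release rates ``k1``/``k2``.

The pre-bleach frame fixes the initial split: the free pool is taken uniform
at the minimum observed intensity, and everything above it is hindered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .dg_core import (
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
from .mesh_geometry import AGGREGATE, MEMBRANE, NUCLEUS, CYTOPLASM, TriangleMesh, is_aggregate

__all__ = [
    "ModelParameters",
    "RateFields",
    "BleachProtocol",
    "FrameSeries",
    "OperatorCache",
    "split_initial_intensity",
    "compute_rate_fields",
    "equilibrium_constant",
    "bleach_schedule",
    "theta_at",
    "forward_simulate",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParameters:
    """Transport/kinetic parameters of the FLIP model (all nonnegative).

    ``membrane_mode`` selects the nuclear-membrane description: ``permeable``
    uses the permeability ``p`` (um/s); ``active`` uses directional rates
    ``k_cn`` (cytoplasm->nucleus) and ``k_nc`` (nucleus->cytoplasm).
    """

    alpha: float          # diffusion constant of the free pool, um^2/s
    beta: float           # lumped bleach rate inside the bleach disc, 1/s
    gamma: float          # hindrance proportionality constant, 1/(s * intensity)
    k1: float = 0.0       # cytoplasm -> aggregate binding rate
    k2: float = 0.0       # aggregate -> cytoplasm release rate
    membrane_mode: Literal["permeable", "active"] = "permeable"
    p: float = 0.0        # membrane permeability (permeable mode), um/s
    k_cn: float = 0.0     # import rate (active mode)
    k_nc: float = 0.0     # export rate (active mode)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "k1", "k2", "p", "k_cn", "k_nc"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")
        if self.membrane_mode not in ("permeable", "active"):
            raise ValueError(f"unknown membrane mode {self.membrane_mode!r}")


@dataclass(frozen=True)
class RateFields:
    """Space-dependent binding rate field and constant release rate."""

    k_on: np.ndarray  # broken-P1 field, 1/s, zero at the dimmest locations
    k_off: float      # 1/s


# ---------------------------------------------------------------------------
# initial split and hindrance rates
# ---------------------------------------------------------------------------


def split_initial_intensity(c0: np.ndarray) -> tuple[float, np.ndarray]:
    """Split the pre-bleach frame into a uniform free pool and the hindered rest.

    The free pool is uniform at the minimum of ``c0`` over all dofs (the model
    assumes free molecules are homogeneously distributed and that the dimmest
    locations hold no hindered protein), so ``u0 + ub0(x) = c0(x)`` exactly.
    """
    c0 = np.asarray(c0, dtype=float)
    if c0.size == 0:
        raise ValueError("empty intensity field")
    if np.any(c0 < 0):
        raise ValueError("intensities must be nonnegative")
    u0 = float(c0.min())
    return u0, c0 - u0


def compute_rate_fields(gamma: float, u0: float, ub0: np.ndarray) -> RateFields:
    """Hindrance rates from the pre-bleach split: k_on = gamma*ub0, k_off = gamma*u0."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return RateFields(k_on=gamma * np.asarray(ub0, dtype=float), k_off=gamma * u0)


def equilibrium_constant(c0: np.ndarray, mesh: TriangleMesh,
                         numerator: Literal["aggregate", "nucleus"] = "aggregate") -> float:
    """Pre-bleach intensity ratio between compartments.

    ``K = <c0>_aggregates / <c0>_cytoplasm`` (area-weighted means), used to
    eliminate the release rate ``k2 = k1/K``; with ``numerator='nucleus'`` the
    membrane equilibrium constant ``K_M`` eliminates ``k_nc = k_cn/K_M``.
    """
    c0 = np.asarray(c0, dtype=float).reshape(mesh.n_triangles, 3)
    tri_mean = c0.mean(axis=1)  # exact area-weighted P1 triangle averages
    areas = mesh.areas()
    if numerator == "aggregate":
        num_sel = is_aggregate(mesh.compartment)
    elif numerator == "nucleus":
        num_sel = mesh.compartment == NUCLEUS
    else:
        raise ValueError("numerator must be 'aggregate' or 'nucleus'")
    den_sel = mesh.compartment == CYTOPLASM
    if not num_sel.any() or not den_sel.any():
        raise ValueError("both regions of the equilibrium ratio must be nonempty")
    num = float(np.sum(areas[num_sel] * tri_mean[num_sel]) / areas[num_sel].sum())
    den = float(np.sum(areas[den_sel] * tri_mean[den_sel]) / areas[den_sel].sum())
    if den <= 0:
        raise ValueError("cytoplasm average intensity is zero")
    return num / den


# ---------------------------------------------------------------------------
# bleach protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BleachProtocol:
    """Timing of the repeated bleach/image cycle.

    Each frame interval of length ``dt_frame`` consists of ``t_bleach`` seconds
    of full-power bleaching followed by ``t_image`` seconds of low-power
    imaging; the first frame is acquired before any bleaching.  Frames are
    compared to the data at ``t_i = dt_frame*(i-1) + t_compare``.
    """

    dt_frame: float = 2.8
    t_bleach: float = 2.0
    t_image: float = 0.8
    n_frames: int = 40
    t_compare: float = 2.6

    def __post_init__(self) -> None:
        if abs(self.t_bleach + self.t_image - self.dt_frame) > 1e-9:
            raise ValueError("t_bleach + t_image must equal dt_frame")
        if not (0.0 < self.t_compare <= self.dt_frame):
            raise ValueError("t_compare must lie in (0, dt_frame]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    def frame_times(self) -> np.ndarray:
        i = np.arange(1, self.n_frames + 1)
        return self.dt_frame * (i - 1) + self.t_compare


def theta_at(protocol: BleachProtocol, t: float) -> int:
    """Bleach indicator at time t: on during the bleach segment of frames >= 2."""
    if t < protocol.dt_frame:  # pre-bleach frame, and anything before the experiment
        return 0
    phase = math.fmod(t, protocol.dt_frame)
    return 1 if phase < protocol.t_bleach else 0


def bleach_schedule(protocol: BleachProtocol) -> list[tuple[float, float, int]]:
    """Ordered (t_start, t_end, theta) intervals covering the whole protocol.

    The first frame interval is bleach-off (the pre-bleach acquisition); every
    later frame interval is bleach-on for ``t_bleach`` then off for ``t_image``.
    """
    segs: list[tuple[float, float, int]] = [(0.0, protocol.dt_frame, 0)]
    for i in range(2, protocol.n_frames + 1):
        t0 = protocol.dt_frame * (i - 1)
        segs.append((t0, t0 + protocol.t_bleach, 1))
        segs.append((t0 + protocol.t_bleach, t0 + protocol.dt_frame, 0))
    return segs


def _protocol_dt(protocol: BleachProtocol, min_substeps: int = 10) -> float:
    """Largest dt that lands every segment boundary and sample time on a step.

    Computed as the rational gcd of the bleach, bleach-to-sample and
    sample-to-frame-end durations, subdivided until a frame contains at least
    ``min_substeps`` steps.
    """
    durations = [protocol.t_bleach, protocol.t_compare,
                 protocol.t_compare - protocol.t_bleach, protocol.dt_frame - protocol.t_compare]
    fracs = [Fraction(d).limit_denominator(10**6) for d in durations if d > 1e-12]
    g = fracs[0]
    for f in fracs[1:]:
        g = Fraction(math.gcd(g.numerator * f.denominator, f.numerator * g.denominator),
                     g.denominator * f.denominator)
    base = float(g)
    per_frame = protocol.dt_frame / base
    if per_frame < min_substeps:
        base /= math.ceil(min_substeps / per_frame)
    return base


# ---------------------------------------------------------------------------
# frame series
# ---------------------------------------------------------------------------


@dataclass
class FrameSeries:
    """Observable intensity fields c(t_i) sampled at the frame comparison times."""

    times: np.ndarray           # (n,) seconds, strictly increasing
    values: np.ndarray          # (n, n_dofs) broken-P1 coefficients

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values lengths disagree")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# operator cache: everything is linear in the parameters
# ---------------------------------------------------------------------------


class OperatorCache:
    """Pre-assembled unit operators for fast re-parametrization.

    Every parameter enters its operator linearly (alpha the SIPG form, beta
    the bleach mass, gamma the hindrance blocks through ``k_on = gamma*ub0``
    and ``k_off = gamma*u0``, the interface rates their edge forms), so a
    calibration objective only combines cached sparse matrices and refactors
    the two backward-Euler systems per evaluation; nothing is re-integrated.
    """

    def __init__(self, mesh: TriangleMesh, c0: np.ndarray,
                 space: DGSpace | None = None,
                 penalty: PenaltyConfig = PenaltyConfig()):
        self.mesh = mesh
        self.space = space if space is not None else DGSpace(mesh)
        self.c0 = np.asarray(c0, dtype=float)
        self.u0, self.ub0 = split_initial_intensity(self.c0)
        s, e = self.space, self.space.edges
        self.mass = assemble_mass(s)
        self.diffusion_unit = assemble_diffusion_sipg(s, e, 1.0, penalty)
        self.bleach_unit = assemble_bleach(s, mesh, 1.0)
        self.kon_unit = assemble_local_reaction(s, self.ub0, 0.0, self.mass).bu  # int ub0 u v
        self.exch_fwd = assemble_directional_exchange(s, e, AGGREGATE, 1.0, 0.0)
        self.exch_bwd = assemble_directional_exchange(s, e, AGGREGATE, 0.0, 1.0)
        has_membrane = bool(np.any(e.edge_class == MEMBRANE))
        self.membrane_perm_unit = assemble_permeable_membrane(s, e, 1.0)
        if has_membrane:
            self.membrane_cn = assemble_directional_exchange(s, e, MEMBRANE, 1.0, 0.0)
            self.membrane_nc = assemble_directional_exchange(s, e, MEMBRANE, 0.0, 1.0)
        else:
            z = sp.csr_matrix((s.n_dofs, s.n_dofs))
            self.membrane_cn = self.membrane_nc = z

    def operators(self, params: ModelParameters) -> SystemOperators:
        g = params.gamma
        reaction = ReactionBlocks(
            uu=-g * self.kon_unit,
            uub=(g * self.u0) * self.mass,
            bu=g * self.kon_unit,
            bub=(-g * self.u0) * self.mass,
        )
        if params.membrane_mode == "permeable":
            membrane = params.p * self.membrane_perm_unit
        else:
            membrane = params.k_cn * self.membrane_cn + params.k_nc * self.membrane_nc
        return SystemOperators(
            mass=self.mass,
            diffusion=params.alpha * self.diffusion_unit,
            reaction=reaction,
            bleach=params.beta * self.bleach_unit,
            exchange=params.k1 * self.exch_fwd + params.k2 * self.exch_bwd,
            membrane=membrane,
        )

    def initial_state(self) -> StateFields:
        return StateFields(u=np.full(self.space.n_dofs, self.u0), ub=self.ub0.copy(), t=0.0)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def forward_simulate(mesh: TriangleMesh, params: ModelParameters,
                     protocol: BleachProtocol, c0: np.ndarray,
                     cache: OperatorCache | None = None,
                     min_substeps: int = 10) -> FrameSeries:
    """Run a full FLIP protocol and record c = u + u_b at every comparison time.

    The initial state splits ``c0`` into a uniform free pool plus hindered
    rest; the bleach indicator switches between the two pre-factored system
    operators according to the protocol schedule.
    """
    if cache is None:
        cache = OperatorCache(mesh, c0)
    ops = cache.operators(params)
    dt = _protocol_dt(protocol, min_substeps=min_substeps)
    state = cache.initial_state()

    sample_times = protocol.frame_times()
    frames = np.empty((protocol.n_frames, cache.space.n_dofs))
    next_sample = 0
    eps = 1e-9
    for (t0, t1, theta) in bleach_schedule(protocol):
        n_steps = int(round((t1 - t0) / dt))
        for _ in range(n_steps):
            state = backward_euler_stepper(ops, state, dt, bool(theta))
            while next_sample < len(sample_times) and state.t >= sample_times[next_sample] - eps:
                frames[next_sample] = state.c
                next_sample += 1
        if next_sample >= len(sample_times):
            break
    if next_sample < len(sample_times):
        raise RuntimeError("protocol schedule ended before all frames were sampled")
    return FrameSeries(times=sample_times, values=frames)
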