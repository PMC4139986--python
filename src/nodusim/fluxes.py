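"""Carrier-mediated auxin flux dynamics on a tissue graph.

Model
-----
Auxin concentration ``a_i`` (amount per unit area) in each cell obeys a
linear compartmental ODE.  Transport across each cell-cell wall is the
steady-state reduction of an explicit-apoplast carrier model: each membrane
releases auxin into the shared wall with efflux permeability

    E(side) = d_wall + p_pin * pin_density(side)

(passive leak plus PIN1-like carrier), and the wall pool is recaptured by
the two flanking cells in proportion to their influx permeabilities

    I(side) = i_base + p_aux * aux_density(side)

(passive protonated uptake plus AUX1-like carrier).  Eliminating the fast
wall pool gives the net flux per unit wall length, positive from i to j:

    J(i->j) = [ E_i * I_j * a_i  -  E_j * I_i * a_j ] / (I_i + I_j)

so an efflux carrier pushes auxin out of its own cell, while an influx
carrier biases the *capture* of wall auxin toward its cell (bounded by what
the neighbor releases) rather than pumping against the gradient.  The cell
balance is

    da_i/dt = (1/area_i) * sum_j wall_ij * J(j->i)
              + sigma + s_frankia * [has_frankia_i] - delta * a_i

The transport part conserves total area-weighted auxin exactly; with
``delta > 0`` the system has a unique, componentwise nonnegative steady
state, solved directly as the independent oracle for time integration.

All quantities are nondimensional; permeabilities are expressed in units of
the passive wall leak (``d_wall`` defaults to 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .carriers import CarrierLayout
from .tissue import Tissue

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass
class ModelParams:
    """Flux-model parameters (nondimensional).

    d_wall      passive wall (efflux) permeability per unit wall length
    p_pin       efflux-carrier coefficient, multiplies pin_density
    p_aux       influx-carrier coefficient, multiplies aux_density
    i_base      passive influx permeability (> 0; sets the capture baseline)
    sigma       basal auxin production rate per unit area, every cell
    delta       first-order decay rate (>= 0; > 0 for a bounded steady state)
    s_frankia   extra source rate in cells with a Frankia compartment
    a0          initial uniform auxin level
    dt          explicit integration step (None = auto from stability bound)
    t_max       integration horizon
    steady_tol  relative rate-of-change threshold for convergence
    """

    d_wall: float = 1.0
    p_pin: float = 10.0
    p_aux: float = 10.0
    i_base: float = 1.0
    sigma: float = 0.1
    delta: float = 1.0
    s_frankia: float = 1.0
    a0: float = 1.0
    dt: float | None = None
    t_max: float = 400.0
    steady_tol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("d_wall", "p_pin", "p_aux", "sigma", "delta", "s_frankia", "a0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.i_base > 0:
            raise ValueError("i_base must be positive")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_max > 0 or not self.steady_tol > 0:
            raise ValueError("t_max and steady_tol must be positive")

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class AuxinState:
    """Per-cell auxin concentrations (ordered as tissue.cells) at a time."""

    concentrations: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)


@dataclass
class SimulationResult:
    final_state: AuxinState
    converged: bool
    n_steps: int
    trajectory: list[AuxinState] | None = None
    pattern_state: AuxinState | None = None
    params: ModelParams | None = None
    layout_name: str = ""
    scenario: str = ""
    tissue_metadata: dict = field(default_factory=dict)

    def state_for_classification(self) -> AuxinState:
        """The state whose spatial pattern the run is about.

        Equal to the final state except for transient scenarios (decaying
        initial pool) where it is the time-integrated exposure profile.
        """
        return self.pattern_state if self.pattern_state is not None else self.final_state


# ---------------------------------------------------------------------------
# rate evaluation


def _edge_coefficients(tissue: Tissue, layout: CarrierLayout, params: ModelParams):
    """Per-interface outflow coefficients (k_a, k_b) of the flux law.

    J(a->b) = k_a * a_a - k_b * a_b with
    k_a = E_a * I_b / (I_a + I_b),  k_b = E_b * I_a / (I_a + I_b).
    """
    layout.validate_for(tissue)
    e = params.d_wall + params.p_pin * layout.pin
    i = params.i_base + params.p_aux * layout.aux
    denom = i[:, 0] + i[:, 1]
    k_a = e[:, 0] * i[:, 1] / denom
    k_b = e[:, 1] * i[:, 0] / denom
    return k_a, k_b


def cell_dynamics_rate(
    state: AuxinState,
    tissue: Tissue,
    layout: CarrierLayout,
    params: ModelParams,
) -> np.ndarray:
    """Evaluate da/dt per cell by looping over interfaces.

    Reference implementation of the flux law; the vectorized operator from
    :func:`build_rate_operator` must agree with it for all states.
    """
    a = np.asarray(state.concentrations, dtype=float)
    if a.shape != (len(tissue.cells),):
        raise SimulationError(
            f"state has {a.shape} concentrations for {len(tissue.cells)} cells"
        )
    order = {c.cell_id: k for k, c in enumerate(tissue.cells)}
    k_a, k_b = _edge_coefficients(tissue, layout, params)
    rate = np.zeros_like(a)
    for m, itf in enumerate(tissue.interfaces):
        ia, ib = order[itf.cell_a], order[itf.cell_b]
        flux_ab = itf.wall_length * (k_a[m] * a[ia] - k_b[m] * a[ib])
        rate[ia] -= flux_ab / tissue.cells[ia].area
        rate[ib] += flux_ab / tissue.cells[ib].area
    for k, c in enumerate(tissue.cells):
        rate[k] += params.sigma - params.delta * a[k]
        if c.has_frankia:
            rate[k] += params.s_frankia
    return rate


def build_rate_operator(
    tissue: Tissue,
    layout: CarrierLayout,
    params: ModelParams,
):
    """Assemble (M, c) with da/dt = M a + c as a sparse matrix and vector."""
    n = len(tissue.cells)
    order = {c.cell_id: k for k, c in enumerate(tissue.cells)}
    areas = tissue.areas()
    k_a, k_b = _edge_coefficients(tissue, layout, params)
    rows, cols, vals = [], [], []
    for m, itf in enumerate(tissue.interfaces):
        ia, ib = order[itf.cell_a], order[itf.cell_b]
        w = itf.wall_length
        rows += [ia, ib, ib, ia]
        cols += [ia, ia, ib, ib]
        vals += [
            -w * k_a[m] / areas[ia],
            w * k_a[m] / areas[ib],
            -w * k_b[m] / areas[ib],
            w * k_b[m] / areas[ia],
        ]
    for k in range(n):
        rows.append(k)
        cols.append(k)
        vals.append(-params.delta)
    M = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    c = np.full(n, params.sigma, dtype=float)
    c += params.s_frankia * np.array(
        [1.0 if cell.has_frankia else 0.0 for cell in tissue.cells]
    )
    return M, c


def steady_state_direct(
    tissue: Tissue,
    layout: CarrierLayout,
    params: ModelParams,
) -> AuxinState:
    """Solve M a + c = 0 directly (unique steady state; requires delta > 0)."""
    if not params.delta > 0:
        raise SimulationError("steady_state_direct requires delta > 0")
    M, c = build_rate_operator(tissue, layout, params)
    a = spsolve(M.tocsc(), -c)
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if not np.all(np.isfinite(a)):
        raise SimulationError("direct solve produced non-finite concentrations")
    # the steady state of this positive system is nonnegative; clip only
    # sub-epsilon negative roundoff
    if a.min() < -1e-9 * max(1.0, abs(a).max()):
        raise SimulationError("direct solve produced a negative steady state")
    return AuxinState(np.maximum(a, 0.0), time=math.inf)


def stable_dt(tissue: Tissue, layout: CarrierLayout, params: ModelParams) -> float:
    """Largest explicit-Euler step kept by the stability guard.

    Bounded by 1 over the maximum total per-cell outflow rate (transport
    plus decay), with a safety factor of 1/2; preserves nonnegativity.
    """
    M, _ = build_rate_operator(tissue, layout, params)
    max_rate = float(np.abs(M.diagonal()).max())
    if max_rate == 0.0:
        return params.t_max / 100.0
    return 0.5 / max_rate


def simulate(
    tissue: Tissue,
    layout: CarrierLayout,
    params: ModelParams,
    record_trajectory: bool = False,
    trajectory_stride: int = 50,
    accumulate_exposure: bool = False,
) -> SimulationResult:
    """Integrate the flux ODE from a uniform initial level to steady state.

    Explicit Heun (trapezoidal predictor-corrector; second order) with an
    automatic stability bound on ``dt`` (a user-supplied ``dt`` above the
    bound is halved until admissible, logged).  Each stage's transport term
    is exactly mass-free, so the scheme conserves area-weighted total auxin
    on closed tissues to rounding.
    Convergence when ``max|da/dt| / max(max a, 1e-12)`` drops
    below ``steady_tol``; divergence (non-finite values) raises naming the
    offending step.  With ``accumulate_exposure`` the trapezoidal cumulative
    exposure ``integral of a dt`` is tracked (used by the decaying-pool
    scenario, whose spatial pattern lives in the transient).
    """
    M, c = build_rate_operator(tissue, layout, params)
    n = len(tissue.cells)
    a = np.full(n, float(params.a0))
    dt_bound = stable_dt(tissue, layout, params)
    dt = params.dt if params.dt is not None else dt_bound
    while dt > dt_bound:
        dt /= 2.0
    if params.dt is not None and dt != params.dt:
        logger.info("dt %g exceeds stability bound; reduced to %g", params.dt, dt)

    exposure = np.zeros(n) if accumulate_exposure else None
    trajectory = [AuxinState(a.copy(), 0.0)] if record_trajectory else None
    t = 0.0
    step = 0
    converged = False
    max_steps = int(math.ceil(params.t_max / dt)) + 1
    while t < params.t_max and step < max_steps:
        rate = M @ a + c
        scale = max(float(a.max(initial=0.0)), 1e-12)
        if float(np.abs(rate).max()) / scale < params.steady_tol:
            converged = True
            break
        predictor = a + dt * rate
        rate2 = M @ predictor + c
        a_new = a + 0.5 * dt * (rate + rate2)
        if not np.all(np.isfinite(a_new)):
            raise SimulationError(f"divergence: non-finite value at step {step + 1}")
        if exposure is not None:
            exposure += 0.5 * dt * (a + a_new)
        a = a_new
        t += dt
        step += 1
        if record_trajectory and step % trajectory_stride == 0:
            trajectory.append(AuxinState(a.copy(), t))
    if record_trajectory and (not trajectory or trajectory[-1].time != t):
        trajectory.append(AuxinState(a.copy(), t))

    result = SimulationResult(
        final_state=AuxinState(a, t),
        converged=converged,
        n_steps=step,
        trajectory=trajectory,
        params=params,
        layout_name=layout.name,
        tissue_metadata=dict(tissue.metadata),
    )
    if exposure is not None:
        result.pattern_state = AuxinState(exposure, t)
    return result


def pool_exposure(
    tissue: Tissue,
    layout: CarrierLayout,
    params: ModelParams,
) -> AuxinState:
    """Time-integrated exposure profile of a decaying uniform auxin pool.

    For the linear system da/dt = M a starting at the uniform level ``a0``
    the integral of a(t) over all time is ``-M^{-1} a0``; it is dominated by
    the transient while the pool still exists and carries its spatial
    pattern (the absolute level decays to zero).  Requires ``delta > 0``.
    """
    if not params.delta > 0:
        raise SimulationError("pool_exposure requires delta > 0")
    M, _ = build_rate_operator(
        tissue, layout, params.with_overrides(sigma=0.0, s_frankia=0.0)
    )
    n = len(tissue.cells)
    x = spsolve(M.tocsc(), -np.full(n, float(params.a0)))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return AuxinState(np.maximum(x, 0.0), time=math.inf)


def total_auxin(state: AuxinState, tissue: Tissue) -> float:
    """Area-weighted total auxin amount (the conserved quantity)."""
    return float(tissue.areas() @ state.concentrations)
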