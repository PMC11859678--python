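"""Pennes bioheat conduction with perfusion sink and arterial feedback.

The tissue temperature obeys

    rho_t c_t dT/dt = k_t d²T/dx² − rho_b w_b c_b (T − T_a),

on a 1-D slab (property-level verification of the thermal model; the
organ-resolved cavity simulation is out of scope and its steady surface
plateaus are the canonical temperature inputs downstream). The lumped
arterial temperature T_a is updated from the whole-body heat balance

    ΔT_a = (q_m + q_therm − q_skin − q_tail) · Δt / (rho_b c_b V_b),

with metabolic gain q_m, perfusion exchange q_therm, and skin/tail
losses modelled as configurable linear sinks h·A·(T_a − T_env).

Time stepping is implicit (backward Euler), unconditionally stable for
the stiff perfusion sink over the 1800 s treatment horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import TissueThermalProperties

__all__ = [
    "BLOOD_RHO",
    "BLOOD_C",
    "ThermalField",
    "ArterialState",
    "step_bioheat",
    "steady_bioheat",
    "update_arterial",
    "linear_loss",
    "thermal_field_to_frame",
]

BLOOD_RHO = 1050.0  # kg/m³
BLOOD_C = 3800.0  # J/kg/K

#: boundary condition: ("fixed", T_surface_C) | ("flux", q_loss_W_m2)
#: | ("robin", h_W_m2K, T_env_C) | ("insulated",)
BoundaryCondition = tuple


@dataclass(frozen=True)
class ThermalField:
    """Cell-centered temperature field on a uniform 1-D slab.

    ``x`` holds cell centers [m]; initial condition is normothermic
    37 °C everywhere.
    """

    x: np.ndarray = field(repr=False)
    temperature: np.ndarray = field(repr=False)
    properties: TissueThermalProperties = None
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.temperature)):
            raise ValueError("temperatures must be finite")
        if self.x.shape != self.temperature.shape:
            raise ValueError("grid/temperature mismatch")

    @classmethod
    def uniform(
        cls, properties: TissueThermalProperties, length_m: float, n_cells: int, T0: float = 37.0
    ) -> "ThermalField":
        h = length_m / n_cells
        x = (np.arange(n_cells) + 0.5) * h
        return cls(x=x, temperature=np.full(n_cells, float(T0)), properties=properties)

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else float(2 * self.x[0])


def _assemble(
    field_: ThermalField,
    T_a: float,
    boundary: tuple[BoundaryCondition, BoundaryCondition],
    rho_b: float,
    c_b: float,
):
    """Steady operator A and source b with A·T = b at equilibrium.

    A has units W/m³/K; the perfusion sink rho_b w_b c_b (T − T_a) and
    the boundary closures are folded in.
    """
    p = field_.properties
    n = field_.x.size
    h = field_.spacing
    k = p.k_t
    sink = rho_b * p.w_b * c_b
    main = np.full(n, sink)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    b = np.full(n, sink * T_a)
    # interior conduction
    g = k / h**2
    main[1:] += g
    main[:-1] += g
    lower[:] = -g
    upper[:] = -g
    # boundary closures (cell-centered: fixed faces at distance h/2)
    for side, bc in ((0, boundary[0]), (n - 1, boundary[1])):
        kind = bc[0]
        if kind == "fixed":
            gb = 2 * k / h**2
            main[side] += gb
            b[side] += gb * bc[1]
        elif kind == "flux":  # prescribed loss q0 [W/m²] out of the domain
            b[side] -= bc[1] / h
        elif kind == "robin":
            hc, T_env = bc[1], bc[2]
            # series of half-cell conduction and film coefficient
            geff = 1.0 / (h / (2 * k) + 1.0 / hc) / h
            main[side] += geff
            b[side] += geff * T_env
        elif kind == "insulated":
            pass
        else:
            raise ValueError(f"unknown boundary condition {bc!r}")
    A = sp.diags_array([lower, main, upper], offsets=[-1, 0, 1], format="csc")
    return A, b


def step_bioheat(
    field_: ThermalField,
    T_a: float,
    boundary: tuple[BoundaryCondition, BoundaryCondition],
    dt: float,
    rho_b: float = BLOOD_RHO,
    c_b: float = BLOOD_C,
) -> ThermalField:
    """Advance the slab one backward-Euler step of size ``dt`` [s]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = field_.properties
    A, b = _assemble(field_, T_a, boundary, rho_b, c_b)
    cap = p.rho_t * p.c_t / dt
    n = field_.x.size
    M = A + sp.eye_array(n, format="csc") * cap
    T_new = spla.spsolve(M, b + cap * field_.temperature)
    return replace(field_, temperature=T_new, time_s=field_.time_s + dt)


def steady_bioheat(
    field_: ThermalField,
    T_a: float,
    boundary: tuple[BoundaryCondition, BoundaryCondition],
    rho_b: float = BLOOD_RHO,
    c_b: float = BLOOD_C,
) -> ThermalField:
    """Steady-state temperature profile (direct linear solve)."""
    A, b = _assemble(field_, T_a, boundary, rho_b, c_b)
    return replace(field_, temperature=spla.spsolve(A, b))


@dataclass(frozen=True)
class ArterialState:
    """Lumped arterial compartment for the whole-body heat balance.

    Heat rates are in W; ``q_therm`` is the net perfusion exchange
    integrated over tissue, ``q_skin``/``q_tail`` environmental losses.
    """

    T_a: float = 37.0
    q_m: float = 0.0  # metabolic gain; magnitude not tabulated, default 0
    q_therm: float = 0.0
    q_skin: float = 0.0
    q_tail: float = 0.0
    V_b: float = 1.6e-5  # m³
    rho_b: float = BLOOD_RHO
    c_b: float = BLOOD_C

    def __post_init__(self) -> None:
        if not self.V_b > 0:
            raise ValueError("blood volume must be positive")


def linear_loss(T_a: float, hA_W_K: float, T_env: float = 25.0) -> float:
    """Environmental loss h·A·(T_a − T_env) [W] for the skin/tail terms."""
    if hA_W_K < 0:
        raise ValueError("loss coefficient must be non-negative")
    return hA_W_K * (T_a - T_env)


def update_arterial(state: ArterialState, dt: float) -> ArterialState:
    """One explicit update of the arterial temperature (energy balance)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dT = (state.q_m + state.q_therm - state.q_skin - state.q_tail) * dt / (
        state.rho_b * state.c_b * state.V_b
    )
    return replace(state, T_a=state.T_a + dT)


def thermal_field_to_frame(fields: list[ThermalField]) -> pd.DataFrame:
    """Tidy frame (position_m, time_s, temp_c) across snapshots."""
    return pd.concat(
        [
            pd.DataFrame({"position_m": f.x, "time_s": f.time_s, "temp_c": f.temperature})
            for f in fields
        ],
        ignore_index=True,
    )
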