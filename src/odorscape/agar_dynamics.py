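"""Reaction-convection-diffusion dynamics of odor-agar interaction.

Water-soluble odorants such as butanone partition strongly into an agar
substrate, depressing the downstream airborne concentration until the gel is
loaded.  The phenomenology is captured by coupling the airborne field ``C``
to a depth-integrated agar reservoir ``A`` through saturable first-order
kinetics:

    dC/dt = L C - w dA/dt          (L = -v d/dx + D Laplacian)
    dA/dt = ka C (1 - A/M) - kd A

with association/dissociation rates ``ka``/``kd``, capacity ``M``, and a
coupling weight ``w`` (w = 0 means no agar).  At steady state dA/dt = 0, so
the C equation reduces to the agar-free one: the quasi-equilibrium airborne
landscape with agar equals the landscape without agar.  Because direct
loading of the gel at the target concentration is slow when ka >> kd, a
pre-equilibration protocol transiently raises the inflow concentration above
``M``, monitors the downstream boundary until it reaches the agar-free
steady value, and then switches back to the target source.

A point (non-spatial) version of the model, with a single chamber timescale
``tau`` replacing the transport operator, is provided for protocol design
and for checking the analytic fixed point

    C* = Co,   A* = ka Co M / (ka Co + kd M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ScalarField
from .plume_model import ChamberGeometry, PlumeParams, source_profile

__all__ = [
    "AgarModelParams",
    "AgarState",
    "SourceSchedule",
    "StepSizeError",
    "ConfigurationError",
    "ProtocolFailureError",
    "simulate_point_model",
    "point_model_fixed_point",
    "simulate_field",
    "steady_no_agar_field",
    "design_preequilibration",
    "fractional_difference",
    "boundary_profiles",
    "rectangle_mask",
]


class StepSizeError(ValueError):
    """Time step violates the stability bound."""


class ConfigurationError(ValueError):
    """Inconsistent geometry/mask configuration."""


class ProtocolFailureError(RuntimeError):
    """Pre-equilibration failed to reach the target within the duration."""


@dataclass
class AgarModelParams:
    """Parameters of the odor-agar model.

    ka, kd, M and w are not measurable directly in the instrument; the
    defaults put the system in the strongly absorbing regime (ka >> kd,
    target Co < M) that reproduces the observed downstream depression and
    slow approach to equilibrium.
    """

    chamber_timescale_tau: float = 60.0  # s, point model only
    absorption_weight_w: float = 1.0
    assoc_rate_ka: float = 0.05  # 1/s
    dissoc_rate_kd: float = 0.001  # 1/s
    capacity_M: float = 100.0  # ppm-equivalent
    flow_speed_v: float = 0.5  # cm/s
    diffusivity_D: float = 0.08  # cm^2/s

    def __post_init__(self) -> None:
        if self.chamber_timescale_tau <= 0 or self.capacity_M <= 0:
            raise ValueError("tau and M must be positive")
        if min(self.assoc_rate_ka, self.dissoc_rate_kd, self.absorption_weight_w) < 0:
            raise ValueError("ka, kd, w must be non-negative")


@dataclass
class AgarState:
    """Airborne field C and agar reservoir A at one instant."""

    air_field_C: ScalarField
    agar_field_A: ScalarField
    time: float

    def __post_init__(self) -> None:
        if self.air_field_C.values.shape != self.agar_field_A.values.shape:
            raise ValueError("C and A must share a grid")


@dataclass
class SourceSchedule:
    """Piecewise-constant inflow concentration Co(t) (ppm)."""

    breakpoints: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 100.0)]
    )

    def __post_init__(self) -> None:
        times = [t for t, _ in self.breakpoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be increasing")
        if any(co < 0 for _, co in self.breakpoints):
            raise ValueError("inflow concentrations must be non-negative")

    def co_at(self, t: float) -> float:
        co = self.breakpoints[0][1]
        for bt, bco in self.breakpoints:
            if t >= bt:
                co = bco
            else:
                break
        return co

    @classmethod
    def constant(cls, co: float) -> "SourceSchedule":
        return cls([(0.0, co)])


# ---------------------------------------------------------------------------
# point model
# ---------------------------------------------------------------------------

def point_model_fixed_point(params: AgarModelParams, co: float) -> tuple[float, float]:
    """Analytic steady state (C*, A*) of the point model for constant Co."""
    a_star = (
        params.assoc_rate_ka * co * params.capacity_M
        / (params.assoc_rate_ka * co + params.dissoc_rate_kd * params.capacity_M)
        if co > 0
        else 0.0
    )
    return co, a_star


def simulate_point_model(
    params: AgarModelParams,
    schedule: SourceSchedule,
    duration: float,
    dt: float,
    c0: float = 0.0,
    a0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the coupled (C, A) ODEs; returns (times, C, A).

    Explicit Euler with the documented stability bounds
    dt < tau/10 and dt < 1/(10 (ka + kd)).
    """
    tau = params.chamber_timescale_tau
    rate = params.assoc_rate_ka + params.dissoc_rate_kd
    if dt >= tau / 10.0 or (rate > 0 and dt >= 1.0 / (10.0 * rate)):
        raise StepSizeError(
            f"dt={dt} violates dt < min(tau/10, 1/(10(ka+kd)))"
        )
    n = int(np.ceil(duration / dt)) + 1
    times = np.arange(n) * dt
    c_arr = np.empty(n)
    a_arr = np.empty(n)
    c, a = float(c0), float(a0)
    w, ka, kd, m_cap = (
        params.absorption_weight_w,
        params.assoc_rate_ka,
        params.dissoc_rate_kd,
        params.capacity_M,
    )
    for i, t in enumerate(times):
        c_arr[i], a_arr[i] = c, a
        da = ka * c * (1.0 - a / m_cap) - kd * a
        dc = -(c - schedule.co_at(t)) / tau - w * da
        c = max(c + dt * dc, 0.0)
        a = min(max(a + dt * da, 0.0), m_cap)
    return times, c_arr, a_arr


# ---------------------------------------------------------------------------
# spatial model
# ---------------------------------------------------------------------------

def rectangle_mask(
    x: np.ndarray, y: np.ndarray, x_range: tuple[float, float], y_range: tuple[float, float]
) -> np.ndarray:
    """Boolean agar mask for a rectangle given in chamber coordinates (cm)."""
    return (
        (x[:, None] >= x_range[0])
        & (x[:, None] <= x_range[1])
        & (y[None, :] >= y_range[0])
        & (y[None, :] <= y_range[1])
    )


def _stable_dt(params: AgarModelParams, dx: float, dy: float) -> float:
    # combined explicit bound: upwind convection and centered diffusion
    # share the step, so their Courant fractions must sum below one
    transport = params.flow_speed_v / dx + 2.0 * params.diffusivity_D * (
        1.0 / dx**2 + 1.0 / dy**2
    )
    bounds = [1.0 / transport]
    rate = params.assoc_rate_ka + params.dissoc_rate_kd
    if rate > 0:
        bounds.append(1.0 / (10.0 * rate))
    return 0.8 * min(bounds)


def simulate_field(
    params: AgarModelParams,
    agar_mask: np.ndarray | None,
    schedule: SourceSchedule,
    geom: ChamberGeometry | None = None,
    dx: float = 0.2,
    dy: float = 0.2,
    duration: float = 600.0,
    dt: float | None = None,
    source_y: float = 0.0,
    source_width: float = 1.0,
    c_init: np.ndarray | None = None,
    a_init: np.ndarray | None = None,
    save_every_s: float | None = None,
) -> list[AgarState]:
    """Integrate the 2-D reaction-convection-diffusion system.

    Operator-split explicit update per step: first-order upwind convection in
    x, centered diffusion, then the local reaction exchange with the agar
    reservoir (restricted to the mask).  Boundary conditions: Dirichlet inlet
    profile from the schedule at x=0, zero-gradient (convective) outflow at
    x=L, no-flux side walls.  Returns saved states (always including the
    final one).
    """
    geom = geom or ChamberGeometry()
    nx = int(round(geom.length / dx)) + 1
    ny = int(round(geom.width / dy)) + 1
    x = np.linspace(0.0, geom.length, nx)
    y = np.linspace(-geom.width / 2.0, geom.width / 2.0, ny)

    if agar_mask is None:
        agar_mask = np.zeros((nx, ny), dtype=bool)
    agar_mask = np.asarray(agar_mask, dtype=bool)
    if agar_mask.shape != (nx, ny):
        raise ConfigurationError("agar_mask shape must match the grid")
    if agar_mask[0].any():
        raise ConfigurationError("agar mask must not touch the inlet boundary")

    if dt is None:
        dt = _stable_dt(params, dx, dy)
    else:
        if dt > _stable_dt(params, dx, dy) / 0.8:
            raise StepSizeError("dt violates the CFL/reaction stability bound")

    src_params = PlumeParams(
        source_concentration_Co=1.0,
        flow_speed_v=params.flow_speed_v,
        diffusivity_D=params.diffusivity_D,
        source_y=source_y,
    )
    inlet_shape = source_profile(src_params, y, source_width)

    c = np.zeros((nx, ny)) if c_init is None else np.array(c_init, dtype=float)
    a = np.zeros((nx, ny)) if a_init is None else np.array(a_init, dtype=float)
    v, d_coef = params.flow_speed_v, params.diffusivity_D
    w, ka, kd, m_cap = (
        params.absorption_weight_w,
        params.assoc_rate_ka,
        params.dissoc_rate_kd,
        params.capacity_M,
    )

    n_steps = int(np.ceil(duration / dt))
    save_stride = (
        max(1, int(round(save_every_s / dt))) if save_every_s else n_steps
    )
    states: list[AgarState] = []

    def snapshot(t):
        states.append(
            AgarState(
                ScalarField(x, y, np.maximum(c, 0.0)),
                ScalarField(x, y, np.where(agar_mask, a, 0.0)),
                time=t,
            )
        )

    for step in range(1, n_steps + 1):
        t = step * dt
        c[0] = schedule.co_at(t - dt) * inlet_shape

        # upwind convection in x (v > 0)
        conv = np.zeros_like(c)
        conv[1:] = -v * (c[1:] - c[:-1]) / dx

        # centered diffusion, no-flux side walls, zero-gradient outflow
        lap = np.zeros_like(c)
        lap[1:-1, :] += (c[2:, :] - 2 * c[1:-1, :] + c[:-2, :]) / dx**2
        lap[-1, :] += (c[-2, :] - c[-1, :]) / dx**2  # zero-gradient at x=L
        lap[:, 1:-1] += (c[:, 2:] - 2 * c[:, 1:-1] + c[:, :-2]) / dy**2
        lap[:, 0] += 2 * (c[:, 1] - c[:, 0]) / dy**2
        lap[:, -1] += 2 * (c[:, -2] - c[:, -1]) / dy**2

        # reaction exchange with the agar reservoir
        da = np.where(agar_mask, ka * c * (1.0 - a / m_cap) - kd * a, 0.0)

        c[1:] += dt * (conv[1:] + d_coef * lap[1:] - w * da[1:])
        a += dt * da
        np.clip(c, 0.0, None, out=c)
        np.clip(a, 0.0, m_cap, out=a)

        if step % save_stride == 0 or step == n_steps:
            snapshot(t)
    if not states:
        snapshot(n_steps * dt)
    return states


def steady_no_agar_field(
    params: AgarModelParams,
    co: float,
    geom: ChamberGeometry | None = None,
    dx: float = 0.2,
    dy: float = 0.2,
    source_y: float = 0.0,
    source_width: float = 1.0,
    duration: float | None = None,
) -> ScalarField:
    """Agar-free steady state of the PDE (reference for quasi-equilibrium)."""
    geom = geom or ChamberGeometry()
    if duration is None:
        duration = 4.0 * geom.length / params.flow_speed_v
    no_agar = AgarModelParams(
        chamber_timescale_tau=params.chamber_timescale_tau,
        absorption_weight_w=0.0,
        assoc_rate_ka=0.0,
        dissoc_rate_kd=0.0,
        capacity_M=params.capacity_M,
        flow_speed_v=params.flow_speed_v,
        diffusivity_D=params.diffusivity_D,
    )
    states = simulate_field(
        no_agar,
        None,
        SourceSchedule.constant(co),
        geom,
        dx=dx,
        dy=dy,
        duration=duration,
        source_y=source_y,
        source_width=source_width,
    )
    return states[-1].air_field_C


def design_preequilibration(
    params: AgarModelParams,
    agar_mask: np.ndarray,
    target_Co: float,
    boost_Co: float,
    monitor_points: list[tuple[float, float]],
    tolerance: float = 0.05,
    geom: ChamberGeometry | None = None,
    dx: float = 0.2,
    dy: float = 0.2,
    max_duration: float = 36000.0,
    hold_duration: float = 600.0,
    monitor_interval_s: float = 10.0,
    source_y: float = 0.0,
    source_width: float = 1.0,
) -> tuple[SourceSchedule, dict]:
    """Design and simulate the pre-equilibration source schedule.

    Runs the model with the boosted source until the mean concentration at
    the downstream monitor points first reaches the agar-free steady value
    for the target source, then switches to the target concentration and
    holds.  Returns the schedule and a diagnostics dict (switch time,
    monitored trace, final state).
    """
    if boost_Co < target_Co:
        raise ValueError("boost_Co must be >= target_Co")
    geom = geom or ChamberGeometry()

    reference = steady_no_agar_field(
        params, target_Co, geom, dx, dy, source_y, source_width
    )
    pts = np.asarray(monitor_points, dtype=float)
    target_level = float(np.mean(reference.at(pts[:, 0], pts[:, 1])))

    if boost_Co == target_Co:
        schedule = SourceSchedule.constant(target_Co)
        states = simulate_field(
            params, agar_mask, schedule, geom, dx=dx, dy=dy,
            duration=hold_duration, source_y=source_y, source_width=source_width,
        )
        return schedule, {
            "switch_time_s": 0.0,
            "target_level_ppm": target_level,
            "final_state": states[-1],
            "monitored": [],
        }

    dt = _stable_dt(params, dx, dy)
    chunk = max(monitor_interval_s, 2.0 * dt)
    schedule_boost = SourceSchedule.constant(boost_Co)
    c_cur: np.ndarray | None = None
    a_cur: np.ndarray | None = None
    t_elapsed = 0.0
    monitored: list[tuple[float, float]] = []
    switch_time = None
    while t_elapsed < max_duration:
        states = simulate_field(
            params, agar_mask, schedule_boost, geom, dx=dx, dy=dy,
            duration=chunk, source_y=source_y, source_width=source_width,
            c_init=c_cur, a_init=a_cur,
        )
        final = states[-1]
        c_cur = final.air_field_C.values
        a_cur = final.agar_field_A.values
        t_elapsed += chunk
        level = float(np.mean(final.air_field_C.at(pts[:, 0], pts[:, 1])))
        monitored.append((t_elapsed, level))
        if level >= target_level:
            switch_time = t_elapsed
            break
    if switch_time is None:
        raise ProtocolFailureError(
            f"monitored concentration reached {monitored[-1][1]:.3g} ppm "
            f"(target {target_level:.3g} ppm) within {max_duration:.0f} s"
        )

    schedule = SourceSchedule([(0.0, boost_Co), (switch_time, target_Co)])
    hold_states = simulate_field(
        params, agar_mask, SourceSchedule.constant(target_Co), geom,
        dx=dx, dy=dy, duration=hold_duration, source_y=source_y,
        source_width=source_width, c_init=c_cur, a_init=a_cur,
        save_every_s=chunk,
    )
    post_levels = [
        float(np.mean(s.air_field_C.at(pts[:, 0], pts[:, 1]))) for s in hold_states
    ]
    overshoot_ok = all(
        lv <= target_level * (1.0 + 2.0 * tolerance) for lv in post_levels[-3:]
    )
    return schedule, {
        "switch_time_s": switch_time,
        "target_level_ppm": target_level,
        "monitored": monitored,
        "post_switch_levels": post_levels,
        "overshoot_decays": overshoot_ok,
        "final_state": hold_states[-1],
    }


# ---------------------------------------------------------------------------
# comparison utilities
# ---------------------------------------------------------------------------

def fractional_difference(
    a: ScalarField, b: ScalarField, region_mask: np.ndarray, floor: float = 1e-9
) -> float:
    """Mean of |a - b| / b over the masked region (b above floor)."""
    if a.values.shape != b.values.shape or not np.allclose(a.x, b.x) or not np.allclose(a.y, b.y):
        raise ValueError("fields must share a grid")
    mask = np.asarray(region_mask, bool) & (b.values > floor)
    if not mask.any():
        raise ValueError("region mask is empty after flooring b")
    return float(np.mean(np.abs(a.values[mask] - b.values[mask]) / b.values[mask]))


def boundary_profiles(
    state: AgarState, agar_mask: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Spanwise C profiles at the first free rows up- and downstream of agar.

    Returns ``((y, C_upstream), (y, C_downstream))``, emulating sensor bars
    mounted along the boundary of the agar plate.
    """
    agar_mask = np.asarray(agar_mask, bool)
    rows = np.where(agar_mask.any(axis=1))[0]
    if rows.size == 0:
        raise ValueError("mask is empty")
    first, last = rows[0], rows[-1]
    if first == 0 or last == agar_mask.shape[0] - 1:
        raise ValueError("mask spans the full chamber length; no free rows")
    f = state.air_field_C
    return (f.y.copy(), f.values[first - 1].copy()), (f.y.copy(), f.values[last + 1].copy())
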