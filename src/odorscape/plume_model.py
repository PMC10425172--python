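"""Steady plume model, model fitting, droplet diffusion, flow diagnostics.

In the flow chamber, a laminar carrier stream (speed ``v``, cm/s) advects
odorized air down the x axis while molecular diffusion (``D``, cm^2/s)
spreads it spanwise.  At steady state the concentration obeys

    v dC/dx = D d^2C/dy^2,

a heat-equation analogue in which downstream distance plays the role of
time: a narrow source at the inlet relaxes into Gaussian cross-sections of
variance sigma^2 = 2 D x / v.  The module provides the marching numerical
solution of this equation, the closed-form Gaussian cross-section, a
least-squares fit of the effective diffusivity to sensor snapshots, the
transient solution for a sealed-chamber odor droplet, and the Reynolds and
Peclet diagnostics used to confirm laminar, convection-dominated transport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .fields import ScalarField

__all__ = [
    "ChamberGeometry",
    "PlumeParams",
    "ResolutionError",
    "plume_cross_section",
    "cross_section_sigma",
    "steady_plume_field",
    "fit_plume",
    "PlumeFit",
    "bulk_velocity",
    "reynolds_number",
    "peclet_number",
    "molar_volume_ml",
    "droplet_equilibrium_concentration",
    "droplet_transient_field",
]

GAS_CONSTANT_ML_ATM = 82.057  # mL atm / (mol K)


class ResolutionError(ValueError):
    """Grid too coarse to resolve the plume near the source."""


@dataclass
class ChamberGeometry:
    """Flow-chamber geometry (cm) and the working-fluid viscosity.

    Defaults match a 15 cm wide, 1 cm deep chamber with a 17 cm streamwise
    extent and the kinematic viscosity of air (~0.15 cm^2/s).
    """

    width: float = 15.0
    depth: float = 1.0
    length: float = 17.0
    kinematic_viscosity: float = 0.15

    def __post_init__(self) -> None:
        if min(self.width, self.depth, self.length, self.kinematic_viscosity) <= 0:
            raise ValueError("all geometry parameters must be positive")

    @property
    def cross_section_area(self) -> float:
        """Spanwise cross-section, cm^2 (= width * depth)."""
        return self.width * self.depth

    @property
    def volume_ml(self) -> float:
        return self.width * self.depth * self.length


@dataclass
class PlumeParams:
    """Source and transport parameters of the steady plume."""

    source_concentration_Co: float = 100.0  # ppm at the inlet port
    flow_speed_v: float = 0.5  # cm/s
    diffusivity_D: float = 0.08  # cm^2/s (butanone in air)
    source_y: float = 0.0  # cm, spanwise source position

    def __post_init__(self) -> None:
        if self.source_concentration_Co < 0:
            raise ValueError("Co must be non-negative")
        if self.flow_speed_v <= 0 or self.diffusivity_D <= 0:
            raise ValueError("v and D must be positive")


# ---------------------------------------------------------------------------
# closed form
# ---------------------------------------------------------------------------

def plume_cross_section(params: PlumeParams, x_c: float, y, peak_ppm: float):
    """Gaussian spanwise cross-section at downstream distance ``x_c``.

    Returns ``peak_ppm * exp(-(y - source_y)^2 / (4 D x_c / v))``: variance
    grows linearly downstream, sigma^2 = 2 D x_c / v, because x_c / v is the
    travel time available for spanwise diffusion.
    """
    if x_c <= 0:
        raise ValueError("x_c must be positive")
    y = np.asarray(y, dtype=float)
    s2 = 4.0 * params.diffusivity_D * x_c / params.flow_speed_v
    return peak_ppm * np.exp(-((y - params.source_y) ** 2) / s2)


def cross_section_sigma(params: PlumeParams, x_c: float) -> float:
    """Gaussian sigma (cm) of the plume cross-section at ``x_c``."""
    return float(np.sqrt(2.0 * params.diffusivity_D * x_c / params.flow_speed_v))


# ---------------------------------------------------------------------------
# marching solver
# ---------------------------------------------------------------------------

def source_profile(
    params: PlumeParams, y: np.ndarray, source_width: float = 1.0
) -> np.ndarray:
    """Inlet boundary condition: top-hat of one inlet-port spacing (cm)."""
    prof = np.where(
        np.abs(y - params.source_y) <= source_width / 2.0,
        params.source_concentration_Co,
        0.0,
    )
    return prof.astype(float)


def steady_plume_field(
    params: PlumeParams,
    geom: ChamberGeometry,
    dx: float = 0.2,
    dy: float = 0.2,
    source_width: float = 1.0,
) -> ScalarField:
    """March ``v dC/dx = D d^2C/dy^2`` downstream of the inlet source.

    The inlet carries a top-hat of width ``source_width`` (default one inlet
    port spacing, chamber width / 15 inlets ~ 1 cm) at ``source_y``; side
    walls are no-flux, so the spanwise integral of C is conserved along x.
    Internally the x-step is subdivided to keep the explicit diffusion update
    stable.
    """
    ny = int(round(geom.width / dy)) + 1
    y = np.linspace(-geom.width / 2.0, geom.width / 2.0, ny)
    nx = int(round(geom.length / dx)) + 1
    x = np.linspace(0.0, geom.length, nx)

    sigma1 = cross_section_sigma(params, x[1] if nx > 1 else dx)
    sigma_eff = max(sigma1, source_width)
    if dy > sigma_eff / 4.0 * (1 + 1e-9):
        raise ResolutionError(
            f"dy={dy:.3g} cm coarser than a quarter of the plume width "
            f"({sigma_eff:.3g} cm) at the first x-node"
        )

    alpha = params.diffusivity_D / params.flow_speed_v  # effective "time" rate
    values = np.empty((nx, ny))
    c = source_profile(params, y, source_width)
    values[0] = c
    # explicit FTCS in x with sub-stepping: alpha * dxs / dy^2 <= 0.45
    nsub = max(1, int(np.ceil(alpha * dx / (0.45 * dy * dy))))
    dxs = dx / nsub
    r = alpha * dxs / (dy * dy)
    for i in range(1, nx):
        for _ in range(nsub):
            lap = np.empty_like(c)
            lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
            lap[0] = 2 * (c[1] - c[0])  # reflecting (no-flux) walls
            lap[-1] = 2 * (c[-2] - c[-1])
            c = c + r * lap
        values[i] = c
    return ScalarField(x, y, np.maximum(values, 0.0))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class PlumeFit:
    diffusivity_D_hat: float
    amplitude: float
    source_y_hat: float
    mse: float
    field: ScalarField


def _closed_form_model(x, y, amp, d_coef, y0, v, source_width):
    """Sustained top-hat source in an unbounded span: the heat-kernel
    convolution of a width-w top-hat, evaluated at diffusion "time" x/v.
    Reduces to the Gaussian cross-section once 2 D x / v >> w^2/12."""
    s = np.sqrt(4.0 * d_coef * np.asarray(x, float) / v)
    yy = np.asarray(y, float) - y0
    return 0.5 * amp * (
        special.erf((yy + source_width / 2.0) / s)
        - special.erf((yy - source_width / 2.0) / s)
    )


def fit_plume(
    observed: pd.DataFrame,
    flow_speed_v: float,
    geom: ChamberGeometry | None = None,
    d_bounds: tuple[float, float] = (1e-3, 2.0),
    source_width: float = 1.0,
) -> PlumeFit:
    """Fit the effective diffusivity to a per-sensor (x, y, ppm) snapshot.

    The flow speed is fixed from the flow rate and geometry; ``D`` is the
    free parameter minimizing the mean-squared error between the closed-form
    plume and the measurements, with the source amplitude and spanwise
    position as nuisance parameters.
    """
    geom = geom or ChamberGeometry()
    x = observed["x_cm"].to_numpy(float)
    y = observed["y_cm"].to_numpy(float)
    c = observed["ppm"].to_numpy(float)
    if x.size < 20 or np.unique(np.round(x, 6)).size < 3:
        raise ValueError("need >= 20 sensors spanning >= 3 distinct x positions")
    if np.any(x <= 0):
        raise ValueError("snapshot x positions must be downstream of the inlet")

    def residuals(theta):
        log_amp, log_d, y0 = theta
        return _closed_form_model(
            x, y, np.exp(log_amp), np.exp(log_d), y0, flow_speed_v, source_width
        ) - c

    # amp is the source amplitude; the measured peak is attenuated by the
    # spread factor erf(w / (2 s)) at the typical downstream distance
    s_med = np.sqrt(4.0 * 0.05 * np.median(x) / flow_speed_v)
    amp0 = max(c.max(), 1e-6) / max(special.erf(source_width / (2.0 * s_med)), 1e-3)
    theta0 = np.array([np.log(amp0), np.log(0.05), float(np.sum(y * c) / max(np.sum(c), 1e-12))])
    lb = [-20.0, np.log(d_bounds[0]), y.min()]
    ub = [30.0, np.log(d_bounds[1]), y.max()]
    sol = optimize.least_squares(residuals, theta0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    amp, d_hat, y0 = np.exp(sol.x[0]), np.exp(sol.x[1]), sol.x[2]
    mse = float(np.mean(sol.fun**2))

    # identifiability: MSE must actually vary with D
    probe = [np.mean(residuals([sol.x[0], np.log(d_hat * f), y0]) ** 2) for f in (0.5, 2.0)]
    scale = np.mean(c**2)
    if scale > 0 and max(probe) - mse < 1e-6 * scale:
        warnings.warn("MSE nearly flat in D; diffusivity unidentifiable", UserWarning)

    xg = np.linspace(max(x.min(), 1e-2), x.max(), 64)
    yg = np.linspace(y.min(), y.max(), 64)
    vals = _closed_form_model(
        xg[:, None], yg[None, :], amp, d_hat, y0, flow_speed_v, source_width
    )
    field = ScalarField(xg, yg, np.maximum(vals, 0.0))
    return PlumeFit(float(d_hat), float(amp), float(y0), mse, field)


# ---------------------------------------------------------------------------
# flow diagnostics
# ---------------------------------------------------------------------------

def bulk_velocity(geom: ChamberGeometry, flow_rate_ml_min: float) -> float:
    """Mean streamwise air speed (cm/s) for a volumetric flow in mL/min."""
    if flow_rate_ml_min <= 0:
        raise ValueError("flow rate must be positive")
    return flow_rate_ml_min / 60.0 / geom.cross_section_area


def reynolds_number(geom: ChamberGeometry, flow_rate_ml_min: float) -> float:
    """Re = v * depth / nu with v the bulk velocity of the given flow rate.

    For the default 15 x 1 cm chamber in air this evaluates to about 7.4 per
    L/min of flow, far below the ~2000 turbulence onset.
    """
    v = bulk_velocity(geom, flow_rate_ml_min)
    return v * geom.depth / geom.kinematic_viscosity


def peclet_number(flow_speed_v: float, length_L: float, diffusivity_D: float) -> float:
    """Pe = v L / D, the convection-to-diffusion transport ratio."""
    if min(flow_speed_v, length_L, diffusivity_D) <= 0:
        raise ValueError("all arguments must be positive")
    return flow_speed_v * length_L / diffusivity_D


# ---------------------------------------------------------------------------
# sealed-chamber droplet release
# ---------------------------------------------------------------------------

def molar_volume_ml(temperature_k: float = 298.0, pressure_atm: float = 1.0) -> float:
    """Ideal-gas molar volume in mL at the given temperature and pressure."""
    if temperature_k <= 0 or pressure_atm <= 0:
        raise ValueError("temperature and pressure must be positive")
    return GAS_CONSTANT_ML_ATM * temperature_k / pressure_atm


def droplet_equilibrium_concentration(
    n_mol: float, chamber_volume_ml: float, temperature_k: float = 298.0
) -> float:
    """Uniform ppm after a fully evaporated droplet mixes into the chamber.

    ppm = 1e6 * (gas volume of n_mol at T) / chamber volume.
    """
    if n_mol < 0 or chamber_volume_ml <= 0:
        raise ValueError("need n_mol >= 0 and a positive chamber volume")
    return 1e6 * n_mol * molar_volume_ml(temperature_k) / chamber_volume_ml


def droplet_transient_field(
    n_mol: float,
    diffusivity_D: float,
    geom: ChamberGeometry,
    t: float,
    dx: float = 0.25,
    dy: float = 0.25,
    temperature_k: float = 298.0,
    n_modes: int = 200,
) -> ScalarField:
    """Depth-averaged diffusion from a central point release, sealed chamber.

    Spectral (cosine-series) solution of the 2-D diffusion equation with
    reflecting walls; mass is conserved exactly and the long-time limit is
    the uniform equilibrium concentration.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    c_eq = droplet_equilibrium_concentration(n_mol, geom.volume_ml, temperature_k)
    lx, ly = geom.length, geom.width
    x = np.arange(0.0, lx + 0.5 * dx, dx)
    y = np.arange(0.0, ly + 0.5 * dy, dy)
    x0, y0 = lx / 2.0, ly / 2.0

    def kernel(coords, l_dim, c0):
        k = np.arange(1, n_modes + 1)
        decay = np.exp(-diffusivity_D * (k * np.pi / l_dim) ** 2 * t)
        modes = np.cos(np.outer(coords, k * np.pi / l_dim)) * np.cos(k * np.pi * c0 / l_dim)
        return 1.0 + 2.0 * modes @ decay  # L * Green's function (dimensionless)

    gx = kernel(x, lx, x0)
    gy = kernel(y, ly, y0)
    values = c_eq * np.maximum(np.outer(gx, gy), 0.0)
    return ScalarField(x - x0, y - y0, values, time=t)
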