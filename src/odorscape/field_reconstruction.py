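"""Continuous concentration fields from sparse sensor-array snapshots.

The odor sensor array (OSA) consists of up to seven odor sensor bars (OSBs)
mounted orthogonal to the flow.  Each bar carries 16 odor sensors in two
staggered columns 1 cm apart with 1.5 cm within-column spacing, giving
0.75 cm effective spanwise resolution; columns of adjacent bars are 1 cm
apart, so seven bars tile the chamber with 112 sensors at ~1 cm resolution.

A snapshot of per-sensor concentrations is turned into a continuous field by
thin-plate-spline smoothing with the length scale tied to the median
inter-sensor spacing, and gradients are obtained by centered finite
differences after a light Gaussian pre-smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, distance

from .fields import ScalarField, VectorField

__all__ = [
    "SensorLayout",
    "Snapshot",
    "build_layout",
    "interpolate_field",
    "gradient_field",
    "gaussian_fit_profile",
    "GaussianProfileFit",
]

logger = logging.getLogger(__name__)

BAR_PITCH_CM = 2.0  # adjacent-bar column spacing 1 cm => 2 cm bar pitch
COLUMN_SPACING_CM = 1.0
WITHIN_COLUMN_SPACING_CM = 1.5
STAGGER_CM = 0.75
SENSORS_PER_COLUMN = 8


@dataclass
class SensorLayout:
    """Positions and kinds of the sensors on an array.

    ``table`` columns: ``sensor_id, x_cm, y_cm, bar, kind`` with kind in
    {"odor", "humidity"}.  Humidity sensors are carried for completeness but
    excluded from concentration interpolation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sensor_id", "x_cm", "y_cm", "bar", "kind"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"layout table must have columns {sorted(required)}")
        pos = self.table[["x_cm", "y_cm"]].to_numpy()
        if len(np.unique(pos.round(9), axis=0)) != len(pos):
            raise ValueError("sensor positions must be unique")

    @property
    def odor(self) -> pd.DataFrame:
        return self.table[self.table["kind"] == "odor"].reset_index(drop=True)

    @property
    def positions(self) -> np.ndarray:
        """Odor-sensor positions, shape (n, 2), cm."""
        return self.odor[["x_cm", "y_cm"]].to_numpy(float)

    def median_spacing(self) -> float:
        """Median nearest-neighbour distance between odor sensors, cm."""
        pos = self.positions
        d = distance.squareform(distance.pdist(pos))
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorLayout":
        return cls(pd.read_csv(path))


def build_layout(n_bars: int, origin: tuple[float, float] = (1.0, -5.625)) -> SensorLayout:
    """Deterministic triangular-grid layout of ``n_bars`` sensor bars.

    Bars run spanwise (along y) and are stacked downstream (along x); the
    two columns of a bar are staggered by half the within-column spacing so
    no sensor directly blocks the flow from its downstream neighbour.
    ``origin`` is the (x, y) of the first sensor of bar 0 in cm.
    """
    if not 1 <= n_bars <= 7:
        raise ValueError("n_bars must be between 1 and 7")
    x0, y0 = origin
    rows = []
    for bar in range(n_bars):
        for col in range(2):
            x = x0 + bar * BAR_PITCH_CM + col * COLUMN_SPACING_CM
            for k in range(SENSORS_PER_COLUMN):
                y = y0 + col * STAGGER_CM + k * WITHIN_COLUMN_SPACING_CM
                rows.append(
                    {
                        "sensor_id": f"os_b{bar}c{col}s{k}",
                        "x_cm": x,
                        "y_cm": y,
                        "bar": bar,
                        "kind": "odor",
                    }
                )
        # humidity sensors sit between the columns in a rectangular grid
        for k in range(SENSORS_PER_COLUMN):
            rows.append(
                {
                    "sensor_id": f"th_b{bar}s{k}",
                    "x_cm": x0 + bar * BAR_PITCH_CM + COLUMN_SPACING_CM / 2.0,
                    "y_cm": y0 + 0.375 + k * WITHIN_COLUMN_SPACING_CM,
                    "bar": bar,
                    "kind": "humidity",
                }
            )
    return SensorLayout(pd.DataFrame(rows))


@dataclass
class Snapshot:
    """One concentration value per odor sensor at a given instant.

    ``values`` is indexed by sensor_id; missing sensors are NaN and flagged.
    """

    layout: SensorLayout
    values: pd.Series
    time: float | None = None

    def __post_init__(self) -> None:
        odor_ids = set(self.layout.odor["sensor_id"])
        self.values = self.values.reindex(sorted(odor_ids))
        finite = self.values.dropna()
        if (finite < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(self.values.notna().sum())

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        odor = self.layout.odor.set_index("sensor_id")
        finite = self.values.dropna()
        pos = odor.loc[finite.index, ["x_cm", "y_cm"]].to_numpy(float)
        return pos, finite.to_numpy(float)


def interpolate_field(
    snapshot: Snapshot,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    smoothing: float = 1e-3,
) -> ScalarField:
    """Thin-plate smoothing-spline surface through a sensor snapshot.

    Coordinates are scaled by the median inter-sensor spacing (~1 cm), which
    sets the smoothing length scale; ``smoothing`` is the spline penalty in
    those units (0 = exact interpolation).  Negative interpolant values are
    clipped to zero with a logged count, and grid nodes outside the sensor
    convex hull are flagged as extrapolated.
    """
    if snapshot.n_valid < 4:
        raise ValueError("need at least 4 non-missing sensors")
    pos, vals = snapshot.valid_points()
    scale = snapshot.layout.median_spacing()

    rbf = RBFInterpolator(
        pos / scale, vals, kernel="thin_plate_spline", smoothing=smoothing
    )
    gx = np.asarray(grid_x, float)
    gy = np.asarray(grid_y, float)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    est = rbf(pts / scale).reshape(xx.shape)

    n_neg = int((est < 0).sum())
    if n_neg:
        logger.info("clipped %d negative interpolant values to 0", n_neg)
    est = np.maximum(est, 0.0)

    hull = Delaunay(pos)
    outside = hull.find_simplex(pts) < 0
    return ScalarField(
        gx, gy, est, time=snapshot.time, extrapolated=outside.reshape(xx.shape)
    )


def gradient_field(field: ScalarField, presmooth_sigma_cm: float = 0.5) -> VectorField:
    """Concentration gradient (ppm/cm) by centered finite differences.

    The field is Gaussian pre-smoothed (sigma 0.5 cm) to suppress
    interpolation ripple; differences are centered in the interior and
    one-sided at the edges, so the gradient of a linear ramp is exact.
    """
    if field.dx > 0.5 or field.dy > 0.5:
        raise ValueError("grid spacing must be <= 0.5 cm for gradients")
    vals = field.values
    if presmooth_sigma_cm > 0:
        vals = ndimage.gaussian_filter(
            vals,
            sigma=(presmooth_sigma_cm / field.dx, presmooth_sigma_cm / field.dy),
            mode="nearest",
        )
    gx, gy = np.gradient(vals, field.x, field.y)
    return VectorField(field.x, field.y, gx, gy)


@dataclass
class GaussianProfileFit:
    peak: float
    center: float
    width_sigma: float
    baseline: float
    mse: float
    degenerate: bool = False


def gaussian_fit_profile(
    positions: np.ndarray,
    values: np.ndarray,
    with_baseline: bool = True,
) -> GaussianProfileFit:
    """Least-squares Gaussian fit to a 1-D concentration profile.

    Returns peak amplitude, center, Gaussian sigma (reported as the width),
    optional baseline, and the residual MSE.  A profile with no positive
    dynamic range is flagged degenerate with peak equal to the mean.
    """
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if positions.size < 5:
        raise ValueError("need at least 5 points for a Gaussian fit")
    rng_dyn = values.max() - values.min()
    if rng_dyn <= 1e-12 * max(1.0, abs(values.mean())):
        return GaussianProfileFit(
            float(values.mean()), float(positions.mean()), np.nan,
            0.0, 0.0, degenerate=True,
        )

    def model(xp, amp, mu, sigma, base=0.0):
        return base + amp * np.exp(-((xp - mu) ** 2) / (2.0 * sigma**2))

    mu0 = positions[np.argmax(values)]
    sigma0 = max((positions.max() - positions.min()) / 6.0, 1e-3)
    if with_baseline:
        p0 = [rng_dyn, mu0, sigma0, values.min()]
    else:
        p0 = [rng_dyn, mu0, sigma0]
    popt, _ = optimize.curve_fit(model, positions, values, p0=p0, maxfev=20000)
    pred = model(positions, *popt)
    mse = float(np.mean((pred - values) ** 2))
    base = float(popt[3]) if with_baseline else 0.0
    return GaussianProfileFit(
        float(popt[0]), float(popt[1]), float(abs(popt[2])), base, mse
    )
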