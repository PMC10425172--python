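"""Scalar concentration fields on rectangular grids.

The :class:`ScalarField` is the central exchange type of the package: a 2-D
odor-concentration grid in ppm with chamber coordinates in cm.  The coordinate
convention used throughout is

* ``x`` — streamwise, cm, 0 at the inlet manifold, increasing downstream;
* ``y`` — spanwise, cm, 0 at the chamber centerline.

``values[i, j]`` is the concentration at ``(x[i], y[j])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator


@dataclass
class ScalarField:
    """A 2-D concentration grid (ppm) with coordinate metadata.

    Parameters
    ----------
    x, y:
        Strictly increasing grid coordinates in cm (x streamwise, y spanwise).
    values:
        Concentration in ppm, shape ``(len(x), len(y))``, non-negative.
    time:
        Optional timestamp in seconds (``None`` for stationary fields).
    extrapolated:
        Optional boolean mask marking nodes outside the supporting data
        (e.g. outside the sensor convex hull after interpolation).
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    time: float | None = None
    extrapolated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be 1-D coordinate vectors")
        if np.any(np.diff(self.x) <= 0) or np.any(np.diff(self.y) <= 0):
            raise ValueError("coordinates must be strictly increasing")
        if self.values.shape != (self.x.size, self.y.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.x.size}, {self.y.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if np.any(self.values < -1e-12):
            raise ValueError("concentrations must be non-negative")

    # -- geometry -----------------------------------------------------------
    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 0.0

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0]) if self.y.size > 1 else 0.0

    @property
    def max_ppm(self) -> float:
        return float(self.values.max())

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")

    # -- sampling -----------------------------------------------------------
    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.x, self.y), self.values, bounds_error=False, fill_value=None
        )

    def at(self, x_cm, y_cm) -> np.ndarray:
        """Bilinear sample of the field at points (cm)."""
        pts = np.column_stack([np.atleast_1d(x_cm), np.atleast_1d(y_cm)])
        return self.interpolator()(pts)

    # -- I/O ----------------------------------------------------------------
    def to_hdf5(self, path, name: str = "field") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("x", data=self.x)
            g.create_dataset("y", data=self.y)
            g.create_dataset("values", data=self.values)
            g.attrs["units"] = "ppm"
            g.attrs["coord_units"] = "cm"
            if self.time is not None:
                g.attrs["time_s"] = float(self.time)

    @classmethod
    def from_hdf5(cls, path, name: str = "field") -> "ScalarField":
        with h5py.File(path, "r") as f:
            g = f[name]
            time = float(g.attrs["time_s"]) if "time_s" in g.attrs else None
            return cls(g["x"][...], g["y"][...], g["values"][...], time=time)

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = self.meshgrid()
        return pd.DataFrame(
            {"x_cm": xx.ravel(), "y_cm": yy.ravel(), "ppm": self.values.ravel()}
        )


@dataclass
class VectorField:
    """A 2-D vector field (e.g. concentration gradient, ppm/cm)."""

    x: np.ndarray
    y: np.ndarray
    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        shape = (self.x.size, self.y.size)
        if self.gx.shape != shape or self.gy.shape != shape:
            raise ValueError("component shapes must match the grid")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    def at(self, x_cm, y_cm) -> tuple[np.ndarray, np.ndarray]:
        pts = np.column_stack([np.atleast_1d(x_cm), np.atleast_1d(y_cm)])
        fx = RegularGridInterpolator(
            (self.x, self.y), self.gx, bounds_error=False, fill_value=None
        )
        fy = RegularGridInterpolator(
            (self.x, self.y), self.gy, bounds_error=False, fill_value=None
        )
        return fx(pts), fy(pts)
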