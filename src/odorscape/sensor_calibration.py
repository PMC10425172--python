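"""Metal-oxide gas-sensor calibration against a reference detector.

Inexpensive metal-oxide (MOx) gas sensors report a raw, dimensionless signal
that maps nonlinearly to odor concentration.  Calibration pairs each sensor
with a photo-ionization detector (PID) reading in ppm, recorded downstream of
the sensor, and fits the exponential response law

    ppm(t) = A * exp(B * raw(t - tau))

where ``A`` is a ppm-scale factor, ``B`` the per-raw-unit sensitivity, and
``tau`` the transport delay between the sensor location and the reference
detector.  The delay is estimated by cross-correlation, the (A, B) pair by
log-linear least squares on delay-aligned samples.

The reference detector's voltage-to-ppm gain is a per-instrument constant
(two dynamic ranges exist, 0-200 and 0-1000 ppm) supplied by the user, never
inferred from data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SensorSeries",
    "CalibrationCurve",
    "NoSignalError",
    "InsufficientDataError",
    "UnreliableDelayWarning",
    "PoorFitWarning",
    "ExtrapolationWarning",
    "align_delay",
    "fit_calibration",
    "apply_calibration",
    "invert_calibration",
    "validate_calibration",
    "read_series_csv",
    "write_series_csv",
    "write_calibration_table",
]

REFERENCE_FLOOR_PPM = 1e-3  # positive clip of the reference before taking logs


class NoSignalError(ValueError):
    """Raised when a series has no variance to correlate or fit."""


class InsufficientDataError(ValueError):
    """Raised when too few aligned samples are available for a fit."""


class UnreliableDelayWarning(UserWarning):
    """Correlation peak at the edge of the search window."""


class PoorFitWarning(UserWarning):
    """Raw-vs-reference relation is non-monotone beyond noise."""


class ExtrapolationWarning(UserWarning):
    """Calibration applied outside the fitted raw range."""


@dataclass
class SensorSeries:
    """A single sensor (or reference-detector) time series.

    ``values`` are raw dimensionless readings for MOx sensors, volts or ppm
    for the reference detector.  ``times`` are seconds, strictly increasing.
    """

    sensor_id: str
    times: np.ndarray
    values: np.ndarray
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not (0.5 <= self.rate_hz <= 20):
            raise ValueError("rate_hz must lie in [0.5, 20] Hz")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def resample(self, rate_hz: float) -> "SensorSeries":
        """Linear resample onto a uniform grid at `rate_hz`."""
        dt = 1.0 / rate_hz
        t = np.arange(self.times[0], self.times[-1] + 0.5 * dt, dt)
        v = np.interp(t, self.times, self.values)
        return SensorSeries(self.sensor_id, t, v, rate_hz=rate_hz)


@dataclass
class CalibrationCurve:
    """Fitted parameters mapping raw readings to ppm.

    The mapping ``ppm = scale_A * exp(sensitivity_B * raw)`` is strictly
    monotone on the fitted range (sign of B fixed by the fit); ``delay_tau``
    is the sensor-to-reference transport delay in seconds.
    """

    sensor_id: str
    scale_A: float
    sensitivity_B: float
    delay_tau: float
    fit_mse: float
    raw_range: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.scale_A <= 0:
            raise ValueError("scale_A must be positive")
        if self.delay_tau < 0:
            raise ValueError("delay_tau must be non-negative")

    def predict(self, raw) -> np.ndarray:
        return self.scale_A * np.exp(self.sensitivity_B * np.asarray(raw, float))

    def invert(self, ppm) -> np.ndarray:
        if self.sensitivity_B == 0:
            raise ValueError("degenerate curve (B=0) is not invertible")
        return np.log(np.asarray(ppm, float) / self.scale_A) / self.sensitivity_B


# ---------------------------------------------------------------------------
# delay alignment
# ---------------------------------------------------------------------------

def align_delay(
    sensor: SensorSeries,
    reference: SensorSeries,
    max_lag_s: float | None = None,
) -> float:
    """Transport delay (s) between a sensor and the reference detector.

    Both series are linearly resampled to the coarser of the two nominal
    rates, mean-subtracted, and cross-correlated.  The correlation is
    normalized by the overlap length at each lag (otherwise slowly varying
    calibration waveforms bias the peak toward zero lag) and the search is
    limited to ``max_lag_s`` (default a quarter of the common record, an
    order of magnitude above plausible transport delays).  The returned lag
    maximizes the normalized correlation, refined to sub-sample precision by
    parabolic interpolation of the peak.  Positive when the reference lags
    the sensor (reference downstream).  Antisymmetric under argument swap.
    """
    if np.var(sensor.values) == 0 or np.var(reference.values) == 0:
        raise NoSignalError("flat (zero-variance) input; cannot estimate delay")

    rate = min(sensor.rate_hz, reference.rate_hz)
    t0 = max(sensor.times[0], reference.times[0])
    t1 = min(sensor.times[-1], reference.times[-1])
    if t1 <= t0:
        raise ValueError("series do not overlap in time")
    dt = 1.0 / rate
    t = np.arange(t0, t1 + 0.5 * dt, dt)
    a = np.interp(t, sensor.times, sensor.values)
    b = np.interp(t, reference.times, reference.values)
    if max_lag_s is None:
        max_lag_s = (t1 - t0) / 4.0
    max_lag = max(1, int(round(max_lag_s * rate)))
    max_lag = min(max_lag, a.size - 2)

    # Pearson correlation per lag over the overlapping segment: using the
    # local (overlap) means avoids the zero-lag bias that global-mean
    # cross-correlation shows for slowly varying calibration waveforms
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # positive lag: reference(t + lag) tracks sensor(t)
        if lag >= 0:
            seg_a, seg_b = a[: a.size - lag], b[lag:]
        else:
            seg_a, seg_b = a[-lag:], b[: b.size + lag]
        sa, sb = seg_a.std(), seg_b.std()
        corr[i] = (
            np.mean((seg_a - seg_a.mean()) * (seg_b - seg_b.mean())) / (sa * sb)
            if sa > 0 and sb > 0
            else -np.inf
        )
    k = int(np.argmax(corr))
    if k == 0 or k == corr.size - 1:
        warnings.warn(
            "correlation peak at window edge; delay estimate unreliable",
            UnreliableDelayWarning,
        )
        return float(lags[k] * dt)

    # parabolic sub-sample refinement around the discrete peak; skipped if a
    # neighbouring lag had a degenerate (zero-variance) overlap segment
    y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0
    if np.isfinite(denom) and denom != 0:
        frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float((lags[k] + frac) * dt)


# ---------------------------------------------------------------------------
# calibration fit
# ---------------------------------------------------------------------------

def fit_calibration(
    sensor: SensorSeries,
    reference_ppm: SensorSeries,
    delay: float,
    min_pairs: int = 50,
) -> CalibrationCurve:
    """Least-squares fit of ``reference = A * exp(B * raw)`` on aligned pairs.

    The fit is performed in log space (linear regression of log reference on
    raw) with the reference clipped at a small positive floor; ``fit_mse`` is
    reported in linear (ppm^2) space.  A constant reference is flagged
    degenerate with ``scale_A`` equal to the mean reference and ``B = 0``.
    """
    # pair raw(t) with reference(t + delay)
    t0 = max(sensor.times[0], reference_ppm.times[0] - delay)
    t1 = min(sensor.times[-1], reference_ppm.times[-1] - delay)
    if t1 <= t0:
        raise InsufficientDataError("no overlapping support after delay shift")
    dt = 1.0 / sensor.rate_hz
    t = np.arange(t0, t1 + 0.5 * dt, dt)
    raw = np.interp(t, sensor.times, sensor.values)
    ref = np.interp(t + delay, reference_ppm.times, reference_ppm.values)
    if t.size < min_pairs:
        raise InsufficientDataError(
            f"only {t.size} aligned pairs; need at least {min_pairs}"
        )

    raw_range = (float(raw.min()), float(raw.max()))
    ref_clip = np.clip(ref, REFERENCE_FLOOR_PPM, None)

    # degenerate: no dynamic range in the reference
    if np.std(ref) < 1e-12 * max(1.0, abs(np.mean(ref))) or np.std(raw) == 0:
        a = float(max(np.mean(ref), REFERENCE_FLOOR_PPM))
        mse = float(np.mean((ref - a) ** 2))
        return CalibrationCurve(
            sensor.sensor_id, a, 0.0, max(delay, 0.0), mse, raw_range, degenerate=True
        )

    b_coef, log_a = np.polyfit(raw, np.log(ref_clip), 1)
    curve = CalibrationCurve(
        sensor.sensor_id,
        float(np.exp(log_a)),
        float(b_coef),
        max(delay, 0.0),
        0.0,
        raw_range,
    )
    pred = curve.predict(raw)
    curve.fit_mse = float(np.mean((pred - ref) ** 2))

    # monotonicity check beyond noise: raw and reference should co-vary
    # consistently with the fitted sign of B
    r = np.corrcoef(raw, ref)[0, 1]
    if abs(r) < 0.5 or np.sign(r) != np.sign(b_coef):
        warnings.warn(
            f"raw-vs-reference relation non-monotone beyond noise "
            f"(corr={r:.2f}); fit_mse={curve.fit_mse:.3g}",
            PoorFitWarning,
        )
    return curve


def apply_calibration(raw: SensorSeries, curve: CalibrationCurve) -> SensorSeries:
    """Map a raw series to ppm; the time axis is shifted by ``-delay_tau``.

    Readings outside the fitted raw range by more than 20% of that range
    trigger an extrapolation warning (never silent).
    """
    lo, hi = curve.raw_range
    span = max(hi - lo, 1e-12)
    if np.any(raw.values < lo - 0.2 * span) or np.any(raw.values > hi + 0.2 * span):
        warnings.warn(
            f"raw readings for {raw.sensor_id} outside fitted range "
            f"[{lo:.3g}, {hi:.3g}] by >20% of range",
            ExtrapolationWarning,
        )
    ppm = np.maximum(curve.predict(raw.values), 0.0)
    return SensorSeries(
        raw.sensor_id, raw.times - curve.delay_tau, ppm, rate_hz=raw.rate_hz
    )


def invert_calibration(ppm: SensorSeries, curve: CalibrationCurve) -> SensorSeries:
    """Inverse mapping ppm -> raw (used to synthesize recordings)."""
    return SensorSeries(
        ppm.sensor_id, ppm.times, curve.invert(ppm.values), rate_hz=ppm.rate_hz
    )


def validate_calibration(
    curve: CalibrationCurve,
    replicate: tuple[SensorSeries, SensorSeries],
    min_duration_s: float = 100.0,
) -> tuple[float, bool]:
    """Fractional scale deviation between a curve and an independent refit.

    Refits the calibration on a replicate recording of the same sensor and
    returns the maximum fractional change of predicted concentration over the
    common raw range, plus a boolean pass at the 10% stability criterion.
    """
    sensor, reference = replicate
    if sensor.duration < min_duration_s:
        raise InsufficientDataError(
            f"replicate spans {sensor.duration:.0f} s; need {min_duration_s:.0f} s"
        )
    delay = align_delay(sensor, reference)
    refit = fit_calibration(sensor, reference, delay)
    lo = max(curve.raw_range[0], refit.raw_range[0])
    hi = min(curve.raw_range[1], refit.raw_range[1])
    if hi <= lo:
        raise ValueError("replicate raw range does not overlap original fit")
    grid = np.linspace(lo, hi, 256)
    p0 = curve.predict(grid)
    p1 = refit.predict(grid)
    dev = float(np.max(np.abs(p1 - p0) / np.clip(p0, REFERENCE_FLOOR_PPM, None)))
    return dev, dev < 0.10


# ---------------------------------------------------------------------------
# tidy-CSV and table I/O
# ---------------------------------------------------------------------------

def read_series_csv(path) -> dict[str, SensorSeries]:
    """Read tidy CSV (`sensor_id,time_s,value`) into per-sensor series."""
    df = pd.read_csv(path)
    out: dict[str, SensorSeries] = {}
    for sid, grp in df.groupby("sensor_id"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
        rate = min(max(rate, 0.5), 20.0)
        out[str(sid)] = SensorSeries(str(sid), t, grp["value"].to_numpy(), rate)
    return out


def write_series_csv(series: dict[str, SensorSeries] | list[SensorSeries], path) -> None:
    if isinstance(series, dict):
        series = list(series.values())
    frames = [
        pd.DataFrame({"sensor_id": s.sensor_id, "time_s": s.times, "value": s.values})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_calibration_table(curves: list[CalibrationCurve], path) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sensor_id": [c.sensor_id for c in curves],
            "scale_A": [c.scale_A for c in curves],
            "sensitivity_B": [c.sensitivity_B for c in curves],
            "delay_tau_s": [c.delay_tau for c in curves],
            "fit_mse": [c.fit_mse for c in curves],
        }
    )
    df.to_csv(path, index=False)
    return df
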