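"""Chemotaxis strategy quantification from trajectories on a known field.

Given animal (or agent) trajectories and the odor landscape they navigated,
this module quantifies the two classical gradient-climbing strategies of
crawling animals plus the overall performance:

* **biased random walk** — the rate of sharp turns (pirouettes, >60 degree
  heading change over 1 s) as a function of the bearing to the local
  gradient; chemotaxis shows up as a lower rate when headed up-gradient;
* **weathervaning** — gradual curving of runs toward the gradient, read out
  from the distribution of trajectory curvature (deg/mm at 1 mm arc-length
  steps) conditioned on bearing;
* **drift velocity** — V cos(theta), the velocity component along the
  gradient, binned by gradient magnitude.

Conventions: angles are degrees in (-180, 180], counter-clockwise positive
viewed from above; bearing 0 means moving straight up-gradient.  Bearings
are undefined (and excluded) where the gradient magnitude is below 1% of its
field maximum.  Trajectories are in mm in the arena frame; fields are in cm,
the conversion is handled by :class:`GradientContext`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .field_reconstruction import gradient_field
from .fields import ScalarField, VectorField

__all__ = [
    "Trajectory",
    "GradientContext",
    "TurnEvent",
    "wrap_deg",
    "circular_mean_deg",
    "smooth_track",
    "filter_tracks",
    "detect_turns",
    "bearing_series",
    "turn_rate_by_bearing",
    "curvature_series",
    "curvature_by_bearing",
    "mean_curvature_vs_bearing",
    "drift_velocity_curve",
    "larva_turn_statistics",
    "read_tracks_csv",
    "write_tracks_csv",
]

MM_PER_CM = 10.0
SPEED_FLOOR_MM_S = 0.01  # below this, displacement angles are noise
GRADIENT_FLOOR_FRACTION = 0.01  # of the field-maximum |grad| for defined bearing


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def wrap_deg(angle):
    """Wrap angles (deg) into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def circular_mean_deg(angles) -> float:
    """Circular mean in degrees; mean of {+179, -179} is +-180, not 0."""
    a = np.deg2rad(np.asarray(angles, dtype=float))
    return float(wrap_deg(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped 2-D positions (mm) of one animal or agent."""

    track_id: str
    times: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.x_mm = np.asarray(self.x_mm, float)
        self.y_mm = np.asarray(self.y_mm, float)
        if not (self.times.shape == self.x_mm.shape == self.y_mm.shape):
            raise ValueError("times, x, y must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def net_displacement(self) -> float:
        return float(np.hypot(self.x_mm[-1] - self.x_mm[0], self.y_mm[-1] - self.y_mm[0]))

    def velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample velocity components (mm/s) by central differences."""
        vx = np.gradient(self.x_mm, self.times)
        vy = np.gradient(self.y_mm, self.times)
        return vx, vy

    @property
    def speed(self) -> np.ndarray:
        vx, vy = self.velocities()
        return np.hypot(vx, vy)

    @property
    def heading_deg(self) -> np.ndarray:
        """Direction of travel (deg CCW from +x); noisy where speed ~ 0."""
        vx, vy = self.velocities()
        return np.rad2deg(np.arctan2(vy, vx))


@dataclass
class GradientContext:
    """Odor field plus its gradient, queryable in trajectory (mm) units."""

    field: ScalarField
    grad: VectorField
    max_ppm: float

    @classmethod
    def from_field(cls, fld: ScalarField, presmooth_sigma_cm: float = 0.5) -> "GradientContext":
        grad = gradient_field(fld, presmooth_sigma_cm=presmooth_sigma_cm)
        return cls(fld, grad, fld.max_ppm)

    @property
    def gradient_floor(self) -> float:
        """ppm/cm below which bearings are undefined."""
        return GRADIENT_FLOOR_FRACTION * float(self.grad.magnitude.max())

    def concentration(self, x_mm, y_mm) -> np.ndarray:
        return self.field.at(np.asarray(x_mm) / MM_PER_CM, np.asarray(y_mm) / MM_PER_CM)

    def gradient_mm(self, x_mm, y_mm) -> tuple[np.ndarray, np.ndarray]:
        """Gradient components in ppm/mm at trajectory positions."""
        gx, gy = self.grad.at(np.asarray(x_mm) / MM_PER_CM, np.asarray(y_mm) / MM_PER_CM)
        return gx / MM_PER_CM, gy / MM_PER_CM

    def gradient_defined(self, x_mm, y_mm) -> np.ndarray:
        gx, gy = self.grad.at(np.asarray(x_mm) / MM_PER_CM, np.asarray(y_mm) / MM_PER_CM)
        return np.hypot(gx, gy) > self.gradient_floor


@dataclass
class TurnEvent:
    """A sharp reorientation: >threshold heading change across 1 s windows."""

    track_id: str
    time: float
    angle_change: float
    bearing_before: float
    bearing_after: float
    x_mm: float = np.nan
    y_mm: float = np.nan


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def smooth_track(track: Trajectory, window_s: float = 0.5, polyorder: int = 3) -> Trajectory:
    """Local cubic polynomial smoothing of positions (0.5 s window).

    Savitzky-Golay per coordinate; endpoints are filled by evaluating the
    edge-window polynomial fits.  Tracks shorter than one window are
    returned unsmoothed (flagged via ``smoothed=False``).
    """
    rate = track.rate_hz
    window = int(round(window_s * rate))
    window = max(window + 1 if window % 2 == 0 else window, polyorder + 2)
    if window % 2 == 0:
        window += 1
    if len(track) < window:
        return Trajectory(track.track_id, track.times, track.x_mm, track.y_mm, smoothed=False)
    xs = signal.savgol_filter(track.x_mm, window, polyorder, mode="interp")
    ys = signal.savgol_filter(track.y_mm, window, polyorder, mode="interp")
    return Trajectory(track.track_id, track.times.copy(), xs, ys, smoothed=True)


def filter_tracks(
    tracks: list[Trajectory],
    context: GradientContext,
    min_duration_s: float = 60.0,
    min_displacement_mm: float = 3.0,
    max_start_fraction: float = 0.7,
) -> list[Trajectory]:
    """Keep analyzable tracks, dropping likely finished chemotaxers.

    A track survives iff its duration exceeds 1 min, its net displacement
    exceeds 3 mm, and its starting concentration is not higher than 70% of
    the field maximum (animals starting near the peak have already done
    their chemotaxis).  All thresholds are strict in the stated direction.
    """
    kept = []
    for tr in tracks:
        if tr.duration <= min_duration_s:
            continue
        if tr.net_displacement <= min_displacement_mm:
            continue
        c0 = float(context.concentration(tr.x_mm[0], tr.y_mm[0])[0])
        if c0 > max_start_fraction * context.max_ppm:
            continue
        kept.append(tr)
    return kept


# ---------------------------------------------------------------------------
# turn detection
# ---------------------------------------------------------------------------

def _window_angles(track: Trajectory, window_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Angle change between displacement vectors spanning consecutive windows.

    Returns (indices, angle_change_deg, heading_before_deg, heading_after_deg)
    for every sample index with a full window on both sides; entries where
    either window's mean speed is below the floor are NaN.
    """
    w = max(1, int(round(window_s * track.rate_hz)))
    n = len(track)
    if n < 2 * w + 1:
        return (np.array([], int), np.array([]), np.array([]), np.array([]))
    idx = np.arange(w, n - w)
    px, py = track.x_mm, track.y_mm
    v1x, v1y = px[idx] - px[idx - w], py[idx] - py[idx - w]
    v2x, v2y = px[idx + w] - px[idx], py[idx + w] - py[idx]
    h1 = np.rad2deg(np.arctan2(v1y, v1x))
    h2 = np.rad2deg(np.arctan2(v2y, v2x))
    ang = wrap_deg(h2 - h1)
    slow = (np.hypot(v1x, v1y) / window_s < SPEED_FLOOR_MM_S) | (
        np.hypot(v2x, v2y) / window_s < SPEED_FLOOR_MM_S
    )
    ang = np.where(slow, np.nan, ang)
    return idx, ang, h1, h2


def detect_turns(
    track: Trajectory,
    threshold_deg: float = 60.0,
    window_s: float = 1.0,
    refractory_s: float = 1.0,
    context: GradientContext | None = None,
) -> list[TurnEvent]:
    """Sharp-turn events: heading changes larger than the threshold.

    The heading change is measured between displacement vectors spanning
    consecutive windows of ``window_s``.  Candidate instants above threshold
    within one refractory period of each other are merged into a single
    event at the instant of maximum angle change, so a slow continuous turn
    is not double-counted.  With a gradient context, ``bearing_before``/
    ``bearing_after`` are relative to the local gradient; otherwise they are
    arena-frame headings.
    """
    idx, ang, h1, h2 = _window_angles(track, window_s)
    if idx.size == 0:
        return []
    cand = np.where(np.abs(ang) > threshold_deg)[0]
    if cand.size == 0:
        return []
    refr = max(1, int(round(refractory_s * track.rate_hz)))
    groups: list[list[int]] = [[cand[0]]]
    for k in cand[1:]:
        if idx[k] - idx[groups[-1][-1]] <= refr:
            groups[-1].append(k)
        else:
            groups.append([k])

    events = []
    for grp in groups:
        k = grp[int(np.argmax(np.abs(ang[grp])))]
        i = idx[k]
        xb, yb = track.x_mm[i], track.y_mm[i]
        if context is not None:
            gx, gy = context.gradient_mm(xb, yb)
            if np.hypot(gx[0], gy[0]) * MM_PER_CM <= context.gradient_floor:
                b_before = b_after = np.nan
            else:
                gdir = np.rad2deg(np.arctan2(gy[0], gx[0]))
                b_before = wrap_deg(h1[k] - gdir)
                b_after = wrap_deg(h2[k] - gdir)
        else:
            b_before, b_after = h1[k], h2[k]
        events.append(
            TurnEvent(
                track.track_id,
                float(track.times[i]),
                float(ang[k]),
                float(b_before),
                float(b_after),
                float(xb),
                float(yb),
            )
        )
    return events


# ---------------------------------------------------------------------------
# bearings
# ---------------------------------------------------------------------------

def bearing_series(track: Trajectory, context: GradientContext) -> np.ndarray:
    """Signed bearing (deg) of travel relative to the local gradient.

    0 = straight up-gradient, +-180 = down-gradient, CCW positive.  NaN
    where the gradient is below the floor or the animal is not moving.
    """
    vx, vy = track.velocities()
    gx, gy = context.gradient_mm(track.x_mm, track.y_mm)
    theta = wrap_deg(np.rad2deg(np.arctan2(vy, vx)) - np.rad2deg(np.arctan2(gy, gx)))
    undefined = (np.hypot(gx, gy) * MM_PER_CM <= context.gradient_floor) | (
        np.hypot(vx, vy) < SPEED_FLOOR_MM_S
    )
    return np.where(undefined, np.nan, theta)


# ---------------------------------------------------------------------------
# biased random walk: turn rate vs bearing
# ---------------------------------------------------------------------------

def turn_rate_by_bearing(
    tracks: list[Trajectory],
    context: GradientContext,
    bin_edges_deg: np.ndarray | None = None,
    threshold_deg: float = 60.0,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Turn rate (events/s) binned by |bearing| to the local gradient.

    Rate = (# turns whose pre-turn |bearing| falls in the bin) / (total time
    all tracks spent traveling at |bearing| in the bin); the quoted error is
    the counting-statistics estimate sqrt(N)/T.  Empty bins carry NaN rates.
    """
    if bin_edges_deg is None:
        bin_edges_deg = np.arange(0.0, 181.0, 30.0)
    edges = np.asarray(bin_edges_deg, float)
    occupancy = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1)
    for tr in tracks:
        theta = np.abs(bearing_series(tr, context))
        dt = np.gradient(tr.times)
        ok = np.isfinite(theta)
        if ok.any():
            occupancy += np.histogram(theta[ok], bins=edges, weights=dt[ok])[0]
        for ev in detect_turns(tr, threshold_deg, window_s, context=context):
            if np.isfinite(ev.bearing_before):
                b = abs(ev.bearing_before)
                k = np.searchsorted(edges, b, side="right") - 1
                if 0 <= k < counts.size:
                    counts[k] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
        err = np.where(occupancy > 0, np.sqrt(counts) / occupancy, np.nan)
    return pd.DataFrame(
        {
            "bearing_lo": edges[:-1],
            "bearing_hi": edges[1:],
            "bearing_mid": 0.5 * (edges[:-1] + edges[1:]),
            "n_turns": counts.astype(int),
            "occupancy_s": occupancy,
            "rate_per_s": rate,
            "rate_err": err,
        }
    )


# ---------------------------------------------------------------------------
# weathervaning: curvature statistics
# ---------------------------------------------------------------------------

def curvature_series(track: Trajectory, step_mm: float = 1.0) -> pd.DataFrame:
    """Signed path curvature (deg/mm) at fixed 1 mm arc-length steps.

    The path is resampled at ``step_mm`` arc length (stationary segments are
    skipped); curvature is the signed (CCW positive) angle between
    successive displacement vectors divided by the step.  Each sample
    carries the vertex position, time, and incoming segment direction.
    """
    dx = np.diff(track.x_mm)
    dy = np.diff(track.y_mm)
    seg = np.hypot(dx, dy)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 2 * step_mm:
        return pd.DataFrame(
            columns=["s_mm", "time_s", "x_mm", "y_mm", "heading_deg", "curvature_deg_mm"]
        )
    # drop zero-length segments so s is strictly increasing for interp
    keep = np.concatenate([[True], seg > 1e-12])
    s_u, x_u, y_u, t_u = s[keep], track.x_mm[keep], track.y_mm[keep], track.times[keep]
    s_grid = np.arange(0.0, s_u[-1] + 1e-9, step_mm)
    xs = np.interp(s_grid, s_u, x_u)
    ys = np.interp(s_grid, s_u, y_u)
    ts = np.interp(s_grid, s_u, t_u)
    hx, hy = np.diff(xs), np.diff(ys)
    head = np.rad2deg(np.arctan2(hy, hx))
    curv = wrap_deg(np.diff(head)) / step_mm  # at interior vertices
    return pd.DataFrame(
        {
            "s_mm": s_grid[1:-1],
            "time_s": ts[1:-1],
            "x_mm": xs[1:-1],
            "y_mm": ys[1:-1],
            "heading_deg": head[:-1],  # incoming segment direction
            "curvature_deg_mm": curv,
        }
    )


def _curvature_with_bearing(
    tracks: list[Trajectory],
    context: GradientContext,
    step_mm: float,
    exclude_sharp_deg: float | None = 60.0,
) -> pd.DataFrame:
    """Pool curvature samples with bearings over tracks.

    Weathervaning is a property of forward runs, so per-step angle changes
    at or above ``exclude_sharp_deg`` (the sharp-turn threshold) are dropped
    by default; pass ``None`` to keep them.
    """
    frames = []
    for tr in tracks:
        cs = curvature_series(tr, step_mm)
        if cs.empty:
            continue
        if exclude_sharp_deg is not None:
            cs = cs[np.abs(cs["curvature_deg_mm"] * step_mm) < exclude_sharp_deg]
            if cs.empty:
                continue
        gx, gy = context.gradient_mm(cs["x_mm"].to_numpy(), cs["y_mm"].to_numpy())
        gmag = np.hypot(gx, gy) * MM_PER_CM
        gdir = np.rad2deg(np.arctan2(gy, gx))
        cs = cs.assign(
            bearing_deg=wrap_deg(cs["heading_deg"].to_numpy() - gdir),
            defined=gmag > context.gradient_floor,
        )
        frames.append(cs[cs["defined"]])
    if not frames:
        return pd.DataFrame(columns=["curvature_deg_mm", "bearing_deg"])
    return pd.concat(frames, ignore_index=True)


QUADRANTS = ("up", "perpendicular", "down")


def _quadrant_of(theta_abs: np.ndarray) -> np.ndarray:
    out = np.full(theta_abs.shape, "down", dtype=object)
    out[theta_abs < 45.0] = "up"
    out[(theta_abs >= 45.0) & (theta_abs < 135.0)] = "perpendicular"
    return out


def curvature_by_bearing(
    tracks: list[Trajectory],
    context: GradientContext,
    step_mm: float = 1.0,
    min_samples: int = 50,
) -> dict:
    """Curvature distributions per bearing quadrant, with pairwise KS tests.

    Curvature is re-oriented so that positive means turning toward the
    gradient (for bearing theta, toward-gradient curvature is
    ``-sign(theta) * curvature``; the two perpendicular half-classes fold
    onto one signed axis).  Weathervaning shows as a positive mean in the
    perpendicular class; the aligned (up/down) classes stay centered at 0 by
    symmetry.
    """
    samples = _curvature_with_bearing(tracks, context, step_mm)
    theta = samples["bearing_deg"].to_numpy()
    kappa = samples["curvature_deg_mm"].to_numpy()
    toward = -np.sign(theta) * kappa
    quad = _quadrant_of(np.abs(theta))

    result: dict = {"classes": {}, "pairwise_ks": {}}
    for q in QUADRANTS:
        vals = toward[quad == q]
        n = vals.size
        result["classes"][q] = {
            "samples": vals,
            "n": int(n),
            "mean": float(np.mean(vals)) if n else np.nan,
            "se": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "low_power": n < min_samples,
        }
    for i, qa in enumerate(QUADRANTS):
        for qb in QUADRANTS[i + 1:]:
            a = result["classes"][qa]["samples"]
            b = result["classes"][qb]["samples"]
            if a.size and b.size:
                ks = stats.ks_2samp(a, b)
                result["pairwise_ks"][(qa, qb)] = {
                    "statistic": float(ks.statistic),
                    "pvalue": float(ks.pvalue),
                }
    return result


def mean_curvature_vs_bearing(
    tracks: list[Trajectory],
    context: GradientContext,
    bin_width_deg: float = 30.0,
    step_mm: float = 1.0,
) -> pd.DataFrame:
    """Mean signed curvature (CCW +, deg/mm) per signed-bearing bin with SE.

    With our sign conventions the weathervaning signature is a curve
    proportional to ``-sin(bearing)``: at bearing +90 (gradient to the
    right) the animal curves clockwise, i.e. negatively.
    """
    samples = _curvature_with_bearing(tracks, context, step_mm)
    edges = np.arange(-180.0, 180.0 + 1e-9, bin_width_deg)
    rows = []
    theta = samples["bearing_deg"].to_numpy()
    kappa = samples["curvature_deg_mm"].to_numpy()
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (theta >= lo) & (theta < hi)
        vals = kappa[sel]
        rows.append(
            {
                "bearing_mid": 0.5 * (lo + hi),
                "n": int(vals.size),
                "mean_curvature": float(np.mean(vals)) if vals.size else np.nan,
                "se": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drift velocity
# ---------------------------------------------------------------------------

def drift_velocity_curve(
    tracks: list[Trajectory],
    context: GradientContext,
    n_bins: int = 5,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Binned drift velocity V cos(theta) versus gradient magnitude.

    Samples are pooled over tracks; bins are gradient-magnitude quantiles
    (ppm/mm).  Each bin reports the mean, lower/upper quartiles, a
    one-sample t-test against zero drift, and two-sample t and KS tests
    against the lowest-gradient bin.
    """
    v_all, theta_all, g_all = [], [], []
    for tr in tracks:
        theta = bearing_series(tr, context)
        vx, vy = tr.velocities()
        gx, gy = context.gradient_mm(tr.x_mm, tr.y_mm)
        gmag = np.hypot(gx, gy)
        ok = np.isfinite(theta)
        v_all.append(np.hypot(vx, vy)[ok])
        theta_all.append(theta[ok])
        g_all.append(gmag[ok])
    v = np.concatenate(v_all) if v_all else np.array([])
    theta = np.concatenate(theta_all) if theta_all else np.array([])
    g = np.concatenate(g_all) if g_all else np.array([])
    if v.size == 0:
        raise ValueError("no samples with defined bearing")
    drift = v * np.cos(np.deg2rad(theta))

    edges = np.quantile(g, np.linspace(0.0, 1.0, n_bins + 1))
    edges[-1] += 1e-12
    which = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, n_bins - 1)
    base = drift[which == 0]
    rows = []
    for k in range(n_bins):
        vals = drift[which == k]
        row = {
            "grad_lo": edges[k],
            "grad_hi": edges[k + 1],
            "grad_mid": float(np.median(g[which == k])) if (which == k).any() else np.nan,
            "n": int(vals.size),
            "mean_drift": float(np.mean(vals)) if vals.size else np.nan,
            "q25": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "q75": float(np.percentile(vals, 75)) if vals.size else np.nan,
            "p_vs_zero": np.nan,
            "p_t_vs_lowest": np.nan,
            "p_ks_vs_lowest": np.nan,
        }
        if vals.size > 1:
            row["p_vs_zero"] = float(stats.ttest_1samp(vals, 0.0).pvalue)
            if k > 0 and base.size > 1:
                row["p_t_vs_lowest"] = float(stats.ttest_ind(vals, base, equal_var=False).pvalue)
                row["p_ks_vs_lowest"] = float(stats.ks_2samp(vals, base).pvalue)
        row["significant"] = bool(row["p_vs_zero"] < alpha) if np.isfinite(row["p_vs_zero"]) else False
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# larva statistics
# ---------------------------------------------------------------------------

LARVA_QUADRANTS = ("up", "plus90", "minus90", "down")


def _signed_quadrant(theta: np.ndarray) -> np.ndarray:
    out = np.full(theta.shape, "down", dtype=object)
    out[np.abs(theta) < 45.0] = "up"
    out[(theta >= 45.0) & (theta < 135.0)] = "plus90"
    out[(theta <= -45.0) & (theta > -135.0)] = "minus90"
    return out


def larva_turn_statistics(
    tracks: list[Trajectory],
    context: GradientContext,
    threshold_deg: float = 60.0,
    window_s: float = 1.0,
    min_turns: int = 20,
) -> dict:
    """Turn rate and mean post-turn heading change per bearing quadrant.

    Larva turns are detected from centroid heading changes with the same
    windowed operator as for worms (posture-based head-cast detection needs
    body-shape data and is out of scope).  The chemotaxis signatures are a
    higher turn rate when headed down-gradient than up-gradient, and
    corrective reorientation: mean heading change negative from the +90
    bearing quadrant and positive from the -90 quadrant.
    """
    occupancy = dict.fromkeys(LARVA_QUADRANTS, 0.0)
    counts = dict.fromkeys(LARVA_QUADRANTS, 0)
    changes: dict[str, list[float]] = {q: [] for q in LARVA_QUADRANTS}
    total_turns = 0
    for tr in tracks:
        theta = bearing_series(tr, context)
        dt = np.gradient(tr.times)
        ok = np.isfinite(theta)
        quad = _signed_quadrant(theta[ok])
        for q in LARVA_QUADRANTS:
            occupancy[q] += float(dt[ok][quad == q].sum())
        for ev in detect_turns(tr, threshold_deg, window_s, context=context):
            if not np.isfinite(ev.bearing_before):
                continue
            total_turns += 1
            q = _signed_quadrant(np.asarray([ev.bearing_before]))[0]
            counts[q] += 1
            changes[q].append(wrap_deg(ev.bearing_after - ev.bearing_before))

    rate_rows, change_rows = [], []
    for q in LARVA_QUADRANTS:
        occ, n = occupancy[q], counts[q]
        rate_rows.append(
            {
                "quadrant": q,
                "n_turns": n,
                "occupancy_s": occ,
                "rate_per_s": n / occ if occ > 0 else np.nan,
                "rate_err": np.sqrt(n) / occ if occ > 0 else np.nan,
            }
        )
        ch = np.asarray(changes[q], float)
        change_rows.append(
            {
                "quadrant": q,
                "n_turns": int(ch.size),
                "mean_change_deg": circular_mean_deg(ch) if ch.size else np.nan,
                "se": float(np.std(ch, ddof=1) / np.sqrt(ch.size)) if ch.size > 1 else np.nan,
            }
        )
    return {
        "turn_rate": pd.DataFrame(rate_rows),
        "heading_change": pd.DataFrame(change_rows),
        "n_turns_total": total_turns,
        "low_power": total_turns < min_turns,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks_csv(path, max_gap_s: float = 1.0) -> list[Trajectory]:
    """Read `track_id,time_s,x_mm,y_mm` CSV; gaps > 1 s split tracks."""
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(float)
        x = grp["x_mm"].to_numpy(float)
        y = grp["y_mm"].to_numpy(float)
        splits = np.where(np.diff(t) > max_gap_s)[0] + 1
        for part, (ts, xs, ys) in enumerate(
            zip(np.split(t, splits), np.split(x, splits), np.split(y, splits))
        ):
            if ts.size < 2:
                continue
            name = str(tid) if len(splits) == 0 else f"{tid}_{part}"
            tracks.append(Trajectory(name, ts, xs, ys))
    return tracks


def write_tracks_csv(tracks: list[Trajectory], path) -> None:
    frames = [
        pd.DataFrame(
            {"track_id": tr.track_id, "time_s": tr.times, "x_mm": tr.x_mm, "y_mm": tr.y_mm}
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
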