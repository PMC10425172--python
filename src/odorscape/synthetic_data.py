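"""Ground-truth generators: navigating agents and raw sensor recordings.

Every analysis stage in this package can be exercised without hardware by
generating data whose true parameters are known:

* **agents** — run-and-turn walkers with a tunable biased-random-walk term
  (turn rate ``lambda(theta) = lambda0 * (1 - b cos theta)``) and a
  weathervaning term (toward-gradient curvature ``g * sin |theta|``),
  at worm (~0.1 mm/s) or larva (~3 mm/s) speeds;
* **recordings** — per-sensor raw time series produced by pushing the true
  ppm at each sensor position through the inverse of the exponential
  calibration law, with transport delay and multiplicative noise, plus the
  delayed reference-detector (ppm) series.

The agent model is a deliberately simple construction: real animals are
described by the statistics these agents reproduce, not by this generative
law.  Every scenario carries a manifest of its true parameters so recovery
tests are self-documenting.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .agar_dynamics import StepSizeError
from .field_reconstruction import SensorLayout, Snapshot, build_layout
from .fields import ScalarField
from .navigation_analysis import GradientContext, Trajectory, wrap_deg
from .plume_model import ChamberGeometry, PlumeParams, steady_plume_field
from .sensor_calibration import CalibrationCurve, SensorSeries

__all__ = [
    "AgentParams",
    "RecordingSpec",
    "WORM_DEFAULTS",
    "LARVA_DEFAULTS",
    "simulate_agents",
    "synthesize_recording",
    "make_scenarios",
    "Scenario",
    "SCENARIO_NAMES",
]

OUTPUT_RATE_HZ = 14.0  # camera frame rate the trajectories emulate


@dataclass
class AgentParams:
    """Parameters of the run-and-turn agent model.

    ``turn_bias_b`` modulates the Poisson turn rate with bearing,
    ``lambda(theta) = lambda0 (1 - b cos theta)`` (b in [0, 1] keeps the
    rate non-negative); ``weathervane_gain_g`` curves runs toward the
    gradient at ``g sin|theta|`` deg/mm.  ``post_turn_kernel`` is the
    (mode, sd) in degrees of the wrapped-normal turn-magnitude distribution,
    ~120 deg for worm pirouettes, ~60 deg for larva turns; its sign is
    random unless ``turn_correction`` > 0, which biases the sign toward the
    gradient (corrective reorientation, the larva signature).
    """

    speed: float = 0.1  # mm/s
    base_turn_rate_lambda0: float = 0.03  # 1/s
    turn_bias_b: float = 0.0
    weathervane_gain_g: float = 0.0  # deg/mm
    heading_noise: float = 2.0  # deg / sqrt(s)
    post_turn_kernel: tuple[float, float] = (120.0, 30.0)
    turn_correction: float = 0.0  # probability bias of corrective turn sign

    def __post_init__(self) -> None:
        if self.speed < 0 or self.heading_noise < 0:
            raise ValueError("speed and heading_noise must be non-negative")
        if not 0.0 <= self.turn_bias_b <= 1.0:
            raise ValueError("turn_bias_b must lie in [0, 1] so the rate stays >= 0")
        if not 0.0 <= self.turn_correction <= 1.0:
            raise ValueError("turn_correction must lie in [0, 1]")

    def turn_rate(self, bearing_deg) -> np.ndarray:
        return self.base_turn_rate_lambda0 * (
            1.0 - self.turn_bias_b * np.cos(np.deg2rad(bearing_deg))
        )


WORM_DEFAULTS = AgentParams(
    speed=0.1, base_turn_rate_lambda0=0.03, heading_noise=2.0,
    post_turn_kernel=(120.0, 30.0),
)
LARVA_DEFAULTS = AgentParams(
    speed=3.0, base_turn_rate_lambda0=0.05, heading_noise=8.0,
    post_turn_kernel=(60.0, 20.0),
)


def simulate_agents(
    context: GradientContext,
    params: AgentParams,
    n_agents: int,
    duration_s: float,
    dt_s: float = 1.0 / OUTPUT_RATE_HZ,
    seed: int = 0,
    start_region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    arena_mm: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> list[Trajectory]:
    """Simulate a population of run-and-turn agents on an odor field.

    Per step the heading picks up the weathervaning drift plus Gaussian
    noise; with probability ``lambda(theta) dt`` a turn fires, adding a
    heading change drawn from the post-turn kernel; the position advances
    ``speed * dt`` along the heading with reflecting arena walls.  Bearings
    use the field gradient at the current position; where the gradient is
    undefined both biases vanish.  Reproducible given the seed; output at
    the camera rate (14 Hz by default).
    """
    max_rate = params.base_turn_rate_lambda0 * (1.0 + params.turn_bias_b)
    if max_rate * dt_s > 0.2:
        raise StepSizeError("lambda(theta) * dt exceeds 0.2; reduce dt_s")
    rng = np.random.default_rng(seed)

    if arena_mm is None:
        arena_mm = (
            (float(context.field.x[0]) * 10.0, float(context.field.x[-1]) * 10.0),
            (float(context.field.y[0]) * 10.0, float(context.field.y[-1]) * 10.0),
        )
    (x_lo, x_hi), (y_lo, y_hi) = arena_mm
    if start_region is None:
        start_region = arena_mm
    (sx_lo, sx_hi), (sy_lo, sy_hi) = start_region

    n_steps = int(round(duration_s / dt_s))
    x = rng.uniform(sx_lo, sx_hi, n_agents)
    y = rng.uniform(sy_lo, sy_hi, n_agents)
    heading = rng.uniform(-180.0, 180.0, n_agents)

    xs = np.empty((n_steps + 1, n_agents))
    ys = np.empty((n_steps + 1, n_agents))
    xs[0], ys[0] = x, y
    noise_sd = params.heading_noise * np.sqrt(dt_s)
    step_mm = params.speed * dt_s
    mode, sd = params.post_turn_kernel

    for k in range(1, n_steps + 1):
        gx, gy = context.gradient_mm(x, y)
        gmag = np.hypot(gx, gy)
        defined = gmag * 10.0 > context.gradient_floor
        gdir = np.rad2deg(np.arctan2(gy, gx))
        theta = wrap_deg(heading - gdir)
        sin_t = np.where(defined, np.sin(np.deg2rad(theta)), 0.0)
        cos_t = np.where(defined, np.cos(np.deg2rad(theta)), 0.0)

        # weathervane: curve toward the gradient at g*sin|theta| deg/mm
        heading = heading - params.weathervane_gain_g * sin_t * step_mm
        heading = heading + rng.normal(0.0, noise_sd, n_agents)

        # biased-random-walk turns
        lam = params.base_turn_rate_lambda0 * (1.0 - params.turn_bias_b * cos_t)
        fire = rng.random(n_agents) < lam * dt_s
        if fire.any():
            nf = int(fire.sum())
            magnitude = rng.normal(mode, sd, nf)
            # corrective reorientation: bias the turn sign toward the
            # gradient (sign -sign(theta) reduces |bearing|); unbiased
            # when turn_correction = 0 or the bearing is undefined
            toward = -np.sign(theta[fire])
            toward[toward == 0] = 1.0
            toward[~defined[fire]] *= rng.choice([-1.0, 1.0], int((~defined[fire]).sum()))
            p_toward = 0.5 + 0.5 * params.turn_correction
            sign = np.where(rng.random(nf) < p_toward, toward, -toward)
            heading[fire] += sign * magnitude
        heading = wrap_deg(heading)

        x = x + step_mm * np.cos(np.deg2rad(heading))
        y = y + step_mm * np.sin(np.deg2rad(heading))

        # reflecting walls
        over = x > x_hi
        x[over] = 2 * x_hi - x[over]
        under = x < x_lo
        x[under] = 2 * x_lo - x[under]
        flip_x = over | under
        over = y > y_hi
        y[over] = 2 * y_hi - y[over]
        under = y < y_lo
        y[under] = 2 * y_lo - y[under]
        flip_y = over | under
        heading[flip_x] = wrap_deg(180.0 - heading[flip_x])
        heading[flip_y] = wrap_deg(-heading[flip_y])
        xs[k], ys[k] = x, y

    times = np.arange(n_steps + 1) * dt_s
    return [
        Trajectory(f"agent_{i:04d}", times, xs[:, i], ys[:, i])
        for i in range(n_agents)
    ]


# ---------------------------------------------------------------------------
# sensor recordings
# ---------------------------------------------------------------------------

@dataclass
class RecordingSpec:
    """Acquisition parameters for a synthetic calibration recording."""

    layout: SensorLayout
    curves: dict[str, CalibrationCurve]
    odor_rate_hz: float = 1.0
    pid_rate_hz: float = 13.0
    noise_sd: float = 0.0  # fractional, multiplicative on ppm
    delay_s: float = 5.0
    ppm_floor: float = 1e-2

    def __post_init__(self) -> None:
        if self.odor_rate_hz <= 0 or not 0 < self.pid_rate_hz <= 13.0:
            raise ValueError("rates must be positive (PID at most 13 Hz)")
        if self.noise_sd < 0 or self.delay_s < 0:
            raise ValueError("noise_sd and delay_s must be non-negative")


def synthesize_recording(
    fld: ScalarField,
    spec: RecordingSpec,
    duration_s: float,
    seed: int = 0,
    modulation=None,
) -> tuple[dict[str, SensorSeries], SensorSeries]:
    """Synthesize raw sensor series plus the delayed reference ppm series.

    The true ppm at each odor-sensor position follows the field scaled by a
    temporal ``modulation`` m(t) (default: a 500 s-period triangle wave
    between 0.1 and 1, the waveform used in calibration runs).  Raw readings
    are the inverse of the calibration law applied to the noisy true ppm;
    the reference detector sees the spatial-mean ppm delayed by the
    transport time ``delay_s``.  ppm below the floor is clamped.
    """
    rng = np.random.default_rng(seed)
    if modulation is None:
        def modulation(t):
            return 0.1 + 0.9 * (1.0 - np.abs(2.0 * ((t / 500.0) % 1.0) - 1.0))

    odor = spec.layout.odor
    base = fld.at(odor["x_cm"].to_numpy(), odor["y_cm"].to_numpy())
    t_os = np.arange(0.0, duration_s, 1.0 / spec.odor_rate_hz)
    m_os = np.asarray(modulation(t_os), dtype=float)

    raw_series: dict[str, SensorSeries] = {}
    for j, sid in enumerate(odor["sensor_id"]):
        curve = spec.curves[sid]
        ppm = base[j] * m_os
        if spec.noise_sd > 0:
            ppm = ppm * (1.0 + spec.noise_sd * rng.standard_normal(ppm.size))
        ppm = np.clip(ppm, spec.ppm_floor, None)
        raw = curve.invert(ppm)
        raw_series[sid] = SensorSeries(sid, t_os, raw, rate_hz=spec.odor_rate_hz)

    t_pid = np.arange(0.0, duration_s, 1.0 / spec.pid_rate_hz)
    m_pid = np.asarray(modulation(t_pid - spec.delay_s), dtype=float)
    ref_ppm = float(np.mean(base)) * m_pid
    reference = SensorSeries("pid", t_pid, np.clip(ref_ppm, 0.0, None), rate_hz=spec.pid_rate_hz)
    return raw_series, reference


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("cone", "narrow_cone", "inverse_cone", "biased_cone", "uniform", "droplet")


@dataclass
class Scenario:
    """A bundled deterministic fixture with its ground-truth manifest."""

    name: str
    field: ScalarField
    layout: SensorLayout
    snapshot: Snapshot
    worm_params: AgentParams
    larva_params: AgentParams
    manifest: dict = field(default_factory=dict)


def _cone_field(geom: ChamberGeometry, source_y: float, d_coef: float, co: float) -> ScalarField:
    params = PlumeParams(
        source_concentration_Co=co, flow_speed_v=0.5, diffusivity_D=d_coef, source_y=source_y
    )
    return steady_plume_field(params, geom)


def make_scenarios(names=SCENARIO_NAMES, geom: ChamberGeometry | None = None) -> dict[str, Scenario]:
    """Deterministic fixture bundles for the named landscape shapes.

    cone: single peak on the centerline; narrow_cone: tighter plume (faster
    carrier flow regime, emulated by a smaller effective diffusivity);
    inverse_cone: odor at both distal inlets so concentration is lowest on
    the centerline; biased_cone: peak offset 4 cm from the centerline;
    uniform: flat field; droplet: radially symmetric peak at the arena
    center.
    """
    geom = geom or ChamberGeometry()
    if isinstance(names, str):
        names = (names,)
    out: dict[str, Scenario] = {}
    for name in names:
        if name == "cone":
            fld = _cone_field(geom, 0.0, 0.08, 100.0)
            manifest = {"shape": "cone", "source_y_cm": 0.0, "D": 0.08, "Co": 100.0}
        elif name == "narrow_cone":
            fld = _cone_field(geom, 0.0, 0.03, 100.0)
            manifest = {"shape": "narrow_cone", "source_y_cm": 0.0, "D": 0.03, "Co": 100.0}
        elif name == "biased_cone":
            fld = _cone_field(geom, 4.0, 0.08, 100.0)
            manifest = {"shape": "biased_cone", "source_y_cm": 4.0, "D": 0.08, "Co": 100.0}
        elif name == "inverse_cone":
            side = geom.width / 2.0 - 1.0
            f1 = _cone_field(geom, side, 0.08, 100.0)
            f2 = _cone_field(geom, -side, 0.08, 100.0)
            fld = ScalarField(f1.x, f1.y, f1.values + f2.values)
            manifest = {"shape": "inverse_cone", "source_y_cm": [side, -side], "D": 0.08, "Co": 100.0}
        elif name == "uniform":
            x = np.linspace(0.0, geom.length, 86)
            y = np.linspace(-geom.width / 2.0, geom.width / 2.0, 76)
            fld = ScalarField(x, y, np.full((x.size, y.size), 50.0))
            manifest = {"shape": "uniform", "Co": 50.0}
        elif name == "droplet":
            x = np.linspace(0.0, geom.length, 86)
            y = np.linspace(-geom.width / 2.0, geom.width / 2.0, 76)
            xx, yy = np.meshgrid(x, y, indexing="ij")
            r2 = (xx - geom.length / 2.0) ** 2 + yy**2
            fld = ScalarField(x, y, 150.0 * np.exp(-r2 / (2.0 * 3.0**2)))
            manifest = {"shape": "droplet", "peak_ppm": 150.0, "sigma_cm": 3.0}
        else:
            raise ValueError(f"unknown scenario {name!r}")

        layout = build_layout(7, origin=(1.0, -5.625))
        odor = layout.odor
        values = pd.Series(
            fld.at(odor["x_cm"].to_numpy(), odor["y_cm"].to_numpy()),
            index=odor["sensor_id"].to_numpy(),
        ).clip(lower=0.0)
        snap = Snapshot(layout, values, time=0.0)
        worm = AgentParams(
            **{**asdict(WORM_DEFAULTS), "turn_bias_b": 0.5, "weathervane_gain_g": 2.0}
        )
        larva = AgentParams(
            **{**asdict(LARVA_DEFAULTS), "turn_bias_b": 0.5, "weathervane_gain_g": 2.0}
        )
        manifest.update(
            {
                "worm_params": asdict(worm),
                "larva_params": asdict(larva),
                "n_odor_sensors": int(len(odor)),
            }
        )
        out[name] = Scenario(name, fld, layout, snap, worm, larva, manifest)
    return out
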