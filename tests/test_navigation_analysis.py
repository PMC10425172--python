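"""Trajectory statistics: smoothing, filtering, turns, bearings, curvature."""

import numpy as np
import pandas as pd
import pytest

from odorscape.fields import ScalarField
from odorscape.navigation_analysis import (
    GradientContext,
    Trajectory,
    bearing_series,
    circular_mean_deg,
    curvature_by_bearing,
    curvature_series,
    detect_turns,
    drift_velocity_curve,
    filter_tracks,
    larva_turn_statistics,
    mean_curvature_vs_bearing,
    read_tracks_csv,
    smooth_track,
    turn_rate_by_bearing,
    wrap_deg,
)

RATE = 14.0
DT = 1.0 / RATE


def make_track(points_mm, track_id="t0", rate=RATE):
    pts = np.asarray(points_mm, float)
    return Trajectory(track_id, np.arange(pts.shape[0]) / rate, pts[:, 0], pts[:, 1])


def path_from_headings(headings_deg, speed=1.0, start=(0.0, 0.0), rate=RATE):
    """Integrate per-step headings (deg) into a path at constant speed."""
    h = np.deg2rad(np.asarray(headings_deg, float))
    step = speed / rate
    x = np.concatenate([[start[0]], start[0] + np.cumsum(step * np.cos(h))])
    y = np.concatenate([[start[1]], start[1] + np.cumsum(step * np.sin(h))])
    return make_track(np.column_stack([x, y]))


def ramp_context(slope_ppm_per_cm=2.0, size_cm=40.0):
    """Uniform gradient pointing along +x."""
    x = np.arange(0.0, size_cm + 0.01, 0.25)
    y = np.arange(-size_cm / 2, size_cm / 2 + 0.01, 0.25)
    vals = slope_ppm_per_cm * x[:, None] + 1.0 + 0.0 * y[None, :]
    return GradientContext.from_field(ScalarField(x, y, vals))


class TestAngles:
    def test_wrap_into_half_open_interval(self):
        assert wrap_deg(180.0) == 180.0
        assert wrap_deg(-180.0) == 180.0
        assert wrap_deg(190.0) == -170.0
        assert wrap_deg(-190.0) == 170.0
        assert wrap_deg(720.0) == 0.0

    def test_circular_mean_of_wrapped_angles(self):
        assert abs(circular_mean_deg([179.0, -179.0])) == pytest.approx(180.0)
        assert circular_mean_deg([10.0, 20.0]) == pytest.approx(15.0)


class TestSmoothTrack:
    def test_straight_line_unchanged(self):
        t = np.arange(0.0, 10.0, DT)
        tr = Trajectory("s", t, 0.3 * t, -0.1 * t)
        sm = smooth_track(tr)
        assert np.allclose(sm.x_mm, tr.x_mm, atol=1e-9)
        assert np.allclose(sm.y_mm, tr.y_mm, atol=1e-9)

    def test_constant_position_unchanged(self):
        t = np.arange(0.0, 5.0, DT)
        tr = Trajectory("c", t, np.full(t.size, 2.0), np.full(t.size, 3.0))
        sm = smooth_track(tr)
        assert np.allclose(sm.x_mm, 2.0) and np.allclose(sm.y_mm, 3.0)

    def test_noise_reduced_on_sine_path(self):
        """One-pixel (32 um) white tracking noise on a gentle sine path:
        smoothing shrinks the RMS deviation from the clean path by at least
        a third (the 7-sample cubic window removes ~2/3 of noise power)."""
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0, DT)
        x = 0.1 * t + 0.5 * np.sin(2 * np.pi * t / 10.0)
        y = 0.1 * t
        tr = Trajectory("n", t, x + rng.normal(0, 0.032, t.size), y + rng.normal(0, 0.032, t.size))
        sm = smooth_track(tr)
        rms_raw = np.sqrt(np.mean((tr.x_mm - x) ** 2 + (tr.y_mm - y) ** 2))
        rms_sm = np.sqrt(np.mean((sm.x_mm - x) ** 2 + (sm.y_mm - y) ** 2))
        assert rms_sm < (2.0 / 3.0) * rms_raw

    def test_short_track_returned_unsmoothed_with_flag(self):
        tr = make_track([[0, 0], [1, 0], [2, 0]])
        sm = smooth_track(tr)
        assert not sm.smoothed
        assert np.array_equal(sm.x_mm, tr.x_mm)


class TestFilterTracks:
    def test_rule_application_on_constructed_fixtures(self):
        """Five constructed tracks exercise every clause; two survive."""
        ctx = ramp_context()  # max at x = 40 cm (400 mm)
        max_ppm = ctx.max_ppm

        def track(duration, disp_mm, start_x_mm, tid):
            t = np.arange(0.0, duration + DT, DT)
            x = start_x_mm + disp_mm * t / t[-1]
            return Trajectory(tid, t, x, np.zeros_like(t))

        # start-point concentrations: the ramp is C = 2x_cm + 1
        x_low = 10.0  # mm -> far below 70% of max
        c70 = 0.7 * max_ppm
        x_at_80 = (0.8 * max_ppm - 1.0) / 2.0 * 10.0
        x_at_69 = (0.69 * max_ppm - 1.0) / 2.0 * 10.0
        tracks = [
            track(90.0, 5.0, x_low, "keep_a"),
            track(30.0, 5.0, x_low, "drop_short"),
            track(90.0, 1.0, x_low, "drop_small_disp"),
            track(90.0, 5.0, x_at_80, "drop_high_start"),
            track(61.0, 3.1, x_at_69, "keep_b"),
        ]
        kept = filter_tracks(tracks, ctx)
        assert sorted(tr.track_id for tr in kept) == ["keep_a", "keep_b"]

    def test_all_passing_is_identity(self):
        ctx = ramp_context()
        t = np.arange(0.0, 100.0, DT)
        tracks = [Trajectory(f"t{i}", t, 10.0 + 0.1 * t, np.zeros_like(t)) for i in range(3)]
        assert filter_tracks(tracks, ctx) == tracks

    def test_boundary_cases_use_strict_inequalities(self):
        ctx = ramp_context()

        def track(duration, disp):
            t = np.linspace(0.0, duration, int(duration * RATE) + 1)
            return Trajectory("b", t, 10.0 + disp * t / duration, np.zeros_like(t))

        assert filter_tracks([track(60.0, 5.0)], ctx) == []  # exactly 1 min: dropped
        assert filter_tracks([track(90.0, 3.0)], ctx) == []  # exactly 3 mm: dropped
        # exactly 70% of max concentration: kept (only "higher than" removed);
        # built so the 70% point sits on a grid node and interpolates exactly
        x = np.arange(0.0, 40.01, 0.25)
        y = np.arange(-20.0, 20.01, 0.25)
        exact_ctx = GradientContext.from_field(
            ScalarField(x, y, 2.5 * x[:, None] + 0.0 * y[None, :])
        )
        t = np.arange(0.0, 90.0, DT)
        tr = Trajectory("edge", t, 280.0 - 0.1 * t, np.zeros_like(t))
        assert float(exact_ctx.concentration(280.0, 0.0)[0]) == 0.7 * exact_ctx.max_ppm
        assert filter_tracks([tr], exact_ctx) == [tr]


def brute_force_turns(track, threshold=60.0, window_s=1.0, refractory_s=1.0):
    """Independent sliding-window oracle for turn instants."""
    w = int(round(window_s * RATE))
    px, py = track.x_mm, track.y_mm
    n = len(track)
    cands = []
    for i in range(w, n - w):
        v1 = np.array([px[i] - px[i - w], py[i] - py[i - w]])
        v2 = np.array([px[i + w] - px[i], py[i + w] - py[i]])
        if np.linalg.norm(v1) / window_s < 0.01 or np.linalg.norm(v2) / window_s < 0.01:
            continue
        ang = wrap_deg(
            np.degrees(np.arctan2(v2[1], v2[0]) - np.arctan2(v1[1], v1[0]))
        )
        if abs(ang) > threshold:
            cands.append((i, ang))
    merged = []
    refr = int(round(refractory_s * RATE))
    group = []
    for i, ang in cands:
        if group and i - group[-1][0] > refr:
            merged.append(max(group, key=lambda t: abs(t[1])))
            group = []
        group.append((i, ang))
    if group:
        merged.append(max(group, key=lambda t: abs(t[1])))
    return merged


class TestDetectTurns:
    def test_straight_track_no_events(self):
        tr = path_from_headings(np.zeros(200))
        assert detect_turns(tr) == []

    def test_single_instantaneous_bend(self):
        headings = np.concatenate([np.zeros(100), np.full(100, 90.0)])
        tr = path_from_headings(headings)
        events = detect_turns(tr)
        assert len(events) == 1
        assert events[0].angle_change == pytest.approx(90.0, abs=2.0)

    def test_slow_arc_below_rate_threshold_silent(self):
        # 30 deg/s arc: windowed change stays ~30 deg < 60
        headings = 30.0 * np.arange(300) * DT
        assert detect_turns(path_from_headings(headings)) == []

    def test_fast_arc_deduplicated_to_single_bout(self):
        # 90 deg/s for 3 s between straight runs: many candidate instants,
        # one merged event
        headings = np.concatenate(
            [np.zeros(100), 90.0 * np.arange(int(3 * RATE)) * DT, np.full(100, 270.0)]
        )
        events = detect_turns(path_from_headings(headings))
        assert len(events) == 1

    def test_agrees_with_brute_force_oracle_on_random_paths(self):
        """Same events as the exhaustive oracle within one sample on 100
        random heading-walk paths."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = 300
            headings = np.cumsum(rng.normal(0, 8.0, n))
            turn_at = rng.choice(np.arange(40, n - 40), size=rng.integers(0, 4), replace=False)
            for i in np.sort(turn_at):
                headings[i:] += rng.choice([-1, 1]) * rng.uniform(70, 150)
            tr = path_from_headings(headings, speed=0.5)
            got = detect_turns(tr)
            want = brute_force_turns(tr)
            assert len(got) == len(want)
            for ev, (i, ang) in zip(got, want):
                assert abs(ev.time - i * DT) <= DT + 1e-9
                assert ev.angle_change == pytest.approx(ang, abs=1e-6)


class TestBearings:
    def test_up_and_down_gradient(self):
        ctx = ramp_context()
        t = np.arange(0.0, 10.0, DT)
        up = Trajectory("u", t, 100.0 + 1.0 * t, np.full(t.size, 0.0))
        down = Trajectory("d", t, 300.0 - 1.0 * t, np.full(t.size, 0.0))
        assert np.allclose(bearing_series(up, ctx)[2:-2], 0.0, atol=1e-6)
        assert np.allclose(np.abs(bearing_series(down, ctx)[2:-2]), 180.0, atol=1e-6)

    def test_uniform_field_all_undefined(self):
        x = np.arange(0.0, 30.01, 0.25)
        ctx = GradientContext.from_field(
            ScalarField(x, x, np.full((x.size, x.size), 5.0))
        )
        t = np.arange(0.0, 5.0, DT)
        tr = Trajectory("u", t, 100.0 + t, 100.0 + t)
        assert np.all(np.isnan(bearing_series(tr, ctx)))

    def test_rotation_invariance_of_binned_rates(self):
        """Rotating field and tracks together leaves the turn-rate curve
        unchanged."""
        ctx = ramp_context()
        rng = np.random.default_rng(5)
        headings = np.cumsum(rng.normal(0, 5.0, 800))
        headings[200:] += 120.0
        headings[500:] -= 140.0
        tr = path_from_headings(headings, speed=0.5, start=(150.0, 0.0))
        base = turn_rate_by_bearing([tr], ctx)

        phi = 35.0
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        # rotate the scene: gradient now points along (c, s)
        x = np.arange(0.0, 40.01, 0.25)
        y = np.arange(-20.0, 20.01, 0.25)
        vals = 2.0 * (c * x[:, None] + s * y[None, :]) + 100.0
        ctx_rot = GradientContext.from_field(ScalarField(x, y, vals))
        xr = c * tr.x_mm - s * tr.y_mm + 150.0
        yr = s * tr.x_mm + c * tr.y_mm + 50.0
        tr_rot = Trajectory("r", tr.times, xr, yr)
        rot = turn_rate_by_bearing([tr_rot], ctx_rot)
        assert np.allclose(
            base["occupancy_s"], rot["occupancy_s"], rtol=0.05, atol=0.5
        )
        assert np.array_equal(base["n_turns"], rot["n_turns"])


class TestCurvature:
    def test_straight_path_zero(self):
        tr = path_from_headings(np.zeros(400), speed=1.0)
        cs = curvature_series(tr)
        assert np.allclose(cs["curvature_deg_mm"], 0.0, atol=1e-9)

    @pytest.mark.parametrize("radius", [3.0, 5.0, 10.0])
    def test_circle_constant_curvature(self, radius):
        phi = np.linspace(0.0, 2 * np.pi, 2000)
        pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi)])
        cs = curvature_series(make_track(pts))
        expected = np.degrees(1.0 / radius)
        assert np.abs(cs["curvature_deg_mm"]).mean() == pytest.approx(expected, rel=0.02)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(8)
        headings = np.cumsum(rng.normal(0, 10.0, 500))
        tr = path_from_headings(headings, speed=1.0)
        mirrored = Trajectory("m", tr.times, tr.x_mm, -tr.y_mm)
        k1 = curvature_series(tr)["curvature_deg_mm"].to_numpy()
        k2 = curvature_series(mirrored)["curvature_deg_mm"].to_numpy()
        assert np.allclose(k1, -k2, atol=1e-9)


class TestBinnedStatistics:
    def test_single_turn_single_bin_rate_definition(self):
        ctx = ramp_context()
        headings = np.concatenate([np.zeros(150), np.full(150, 170.0)])
        tr = path_from_headings(headings, speed=0.5, start=(150.0, 0.0))
        df = turn_rate_by_bearing([tr], ctx, bin_edges_deg=np.array([0.0, 90.0, 180.0]))
        low = df.iloc[0]
        assert low["n_turns"] == 1
        assert low["rate_per_s"] == pytest.approx(1.0 / low["occupancy_s"])

    def test_empty_bins_reported_as_nan(self):
        ctx = ramp_context()
        t = np.arange(0.0, 20.0, DT)
        tr = Trajectory("u", t, 100.0 + 0.5 * t, np.zeros_like(t))  # always bearing 0
        df = turn_rate_by_bearing([tr], ctx)
        assert np.isnan(df["rate_per_s"].iloc[-1])
        assert df["occupancy_s"].iloc[0] > 0

    def test_drift_velocity_bounded_by_speed(self):
        ctx = ramp_context()
        rng = np.random.default_rng(9)
        headings = np.cumsum(rng.normal(0, 15.0, 2000))
        tr = path_from_headings(headings, speed=1.0, start=(200.0, 0.0))
        df = drift_velocity_curve([tr], ctx, n_bins=3)
        speed_max = tr.speed.max()
        assert np.all(np.abs(df["mean_drift"].dropna()) <= speed_max + 1e-9)

    def test_mean_curvature_antisymmetric_under_gradient_reversal(self):
        rng = np.random.default_rng(21)
        headings = np.cumsum(rng.normal(0, 12.0, 4000))
        tr = path_from_headings(headings, speed=1.0, start=(200.0, 0.0))
        up = ramp_context(2.0)
        x = up.field.x
        down = GradientContext.from_field(
            ScalarField(x, up.field.y, up.field.values[::-1, :])
        )
        c_up = mean_curvature_vs_bearing([tr], up)
        c_dn = mean_curvature_vs_bearing([tr], down)
        # reversing the gradient maps bearing theta -> wrap(theta + 180)
        k_up = c_up["mean_curvature"].to_numpy()
        k_dn = c_dn["mean_curvature"].to_numpy()
        n_half = k_up.size // 2
        flipped = np.concatenate([k_dn[n_half:], k_dn[:n_half]])
        ok = np.isfinite(k_up) & np.isfinite(flipped)
        assert np.allclose(k_up[ok], flipped[ok], atol=1e-9)

    def test_single_larva_turn_definition(self):
        """One turn from bearing +90 to 0 produces mean change -90 in the
        +90 class."""
        ctx = ramp_context()
        headings = np.concatenate([np.full(150, 90.0), np.zeros(150)])
        tr = path_from_headings(headings, speed=1.0, start=(150.0, -20.0))
        stats = larva_turn_statistics([tr], ctx)
        changes = stats["heading_change"].set_index("quadrant")
        assert changes.loc["plus90", "n_turns"] == 1
        assert changes.loc["plus90", "mean_change_deg"] == pytest.approx(-90.0, abs=3.0)


class TestTrackIO:
    def test_roundtrip_and_gap_splitting(self, tmp_path):
        t1 = np.arange(0.0, 2.0, DT)
        t2 = t1 + 5.0  # 3 s gap
        df = pd.DataFrame(
            {
                "track_id": "w1",
                "time_s": np.concatenate([t1, t2]),
                "x_mm": np.arange(t1.size * 2, dtype=float),
                "y_mm": 0.0,
            }
        )
        path = tmp_path / "tracks.csv"
        df.to_csv(path, index=False)
        tracks = read_tracks_csv(path)
        assert len(tracks) == 2
        assert all(np.all(np.diff(tr.times) < 1.0) for tr in tracks)
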