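import numpy as np
import pytest
from conftest import earth_field_ned, rotation_body_from_ned

from divetrack import deadreckon as dr
from divetrack.config import MagneticModel
from divetrack.geo import destination_point, haversine_m
from divetrack.sensor_io import AccelSeries, FixSeries


def _accel(values, hz=25):
    n = values.shape[0]
    t = np.arange(n) / hz
    return AccelSeries(t, values[:, 0], values[:, 1], values[:, 2])


# ------------------------------------------------- static/dynamic split

def test_split_constant_input_gives_zero_dynamic():
    a = _accel(np.tile([0.1, -0.2, 0.97], (200, 1)))
    static, dynamic = dr.split_static_dynamic(a, 3.0)
    assert np.allclose(dynamic.xyz(), 0.0, atol=1e-14)
    assert np.allclose(static.xyz(), a.xyz())


def test_split_is_exact_decomposition():
    rng = np.random.default_rng(0)
    a = _accel(rng.normal(0, 1, (500, 3)))
    static, dynamic = dr.split_static_dynamic(a, 3.0)
    assert np.allclose(static.xyz() + dynamic.xyz(), a.xyz(), atol=1e-12)


def test_split_running_mean_attenuates_fast_sinusoid():
    # 5 Hz stroking on a 1 G gravity baseline: a 3 s mean almost removes it
    t = np.arange(0, 20, 1 / 25)
    z = 1.0 + 0.3 * np.sin(2 * np.pi * 5 * t)
    a = AccelSeries(t, np.zeros_like(t), np.zeros_like(t), z)
    static, _ = dr.split_static_dynamic(a, 3.0)
    inner = slice(75, len(t) - 75)
    assert np.max(np.abs(static.heave[inner] - 1.0)) < 0.02


def test_split_too_short_raises():
    a = _accel(np.zeros((10, 3)))
    with pytest.raises(ValueError, match="shorter than window"):
        dr.split_static_dynamic(a, 3.0)


# ------------------------------------------------- attitude

def test_attitude_level_and_nose_up():
    s = _accel(np.array([[0, 0, 1.0], [-1.0, 0, 0]]), hz=1)
    att = dr.attitude_from_static(s)
    assert att.pitch[0] == pytest.approx(0.0)
    assert att.roll[0] == pytest.approx(0.0)
    assert att.pitch[1] == pytest.approx(np.pi / 2)


def test_attitude_recovers_random_rotations():
    """Forward oracle: rotate gravity by random (heading, pitch, roll), invert."""
    rng = np.random.default_rng(7)
    n = 300
    heading = rng.uniform(0, 2 * np.pi, n)
    pitch = rng.uniform(-1.4, 1.4, n)
    roll = rng.uniform(-0.6, 0.6, n)
    g = np.array([rotation_body_from_ned(h, p, r) @ [0, 0, 1]
                  for h, p, r in zip(heading, pitch, roll)])
    att = dr.attitude_from_static(_accel(g, hz=1))
    assert np.max(np.abs(att.pitch - pitch)) < 1e-9
    assert np.max(np.abs(att.roll - roll)) < 1e-9


def test_attitude_low_norm_interpolated():
    g = np.array([[0, 0, 1.0], [1e-3, 0, 1e-3], [0, 0, 1.0]])
    att = dr.attitude_from_static(_accel(g, hz=1))
    assert att.flagged[1] and not att.flagged[0]
    assert att.pitch[1] == pytest.approx(0.0, abs=1e-9)


# ------------------------------------------------- heading

def test_heading_level_aligned_field():
    model = MagneticModel(declination_deg=0.0, inclination_deg=-60.0)
    h, fl = dr.tilt_compensated_heading([30.0], [0.0], [-52.0], np.array([0.0]),
                                        np.array([0.0]), model)
    assert h[0] == pytest.approx(0.0, abs=1e-12)
    assert not fl[0]


def test_heading_recovers_random_attitudes_with_study_field():
    """Forward-simulate the local field (decl 7.698, incl -68.012) and invert."""
    model = MagneticModel()  # study-area values
    F = earth_field_ned(model.declination_deg, model.inclination_deg)
    rng = np.random.default_rng(11)
    n = 500
    heading = rng.uniform(0, 2 * np.pi, n)
    pitch = rng.uniform(np.radians(-80), np.radians(80), n)
    roll = rng.uniform(-0.8, 0.8, n)
    m = np.array([rotation_body_from_ned(h, p, r) @ F
                  for h, p, r in zip(heading, pitch, roll)])
    got, fl = dr.tilt_compensated_heading(m[:, 0], m[:, 1], m[:, 2], pitch, roll, model)
    err = np.abs((got - heading + np.pi) % (2 * np.pi) - np.pi)
    assert np.max(err) < 1e-6
    assert not fl.any()


def test_heading_degenerate_horizontal_field_interpolated():
    model = MagneticModel(declination_deg=0.0, inclination_deg=-90.0)
    # straight-down field has no horizontal component when level
    m = np.array([[30, 0, -52.0], [0, 0, -60.0], [30, 0, -52.0]])
    pitch = np.zeros(3)
    h, fl = dr.tilt_compensated_heading(m[:, 0], m[:, 1], m[:, 2], pitch, pitch,
                                        MagneticModel(0.0, -60.0) , t=np.arange(3.0),
                                        min_horizontal=1.0)
    assert fl[1] and not fl[0]
    assert h[1] == pytest.approx(h[0], abs=1e-9)


# ------------------------------------------------- speed

@pytest.mark.parametrize("depth_rate,pitch_deg,expected", [
    (1.0, -45.0, np.sqrt(2)),
    (0.0, 30.0, 0.0),
    (0.5, 90.0, 0.5),
])
def test_estimate_speed_closed_form(depth_rate, pitch_deg, expected):
    s = dr.estimate_speed(np.array([depth_rate]), np.array([np.radians(pitch_deg)]),
                          fallback=1.0)
    assert s[0] == pytest.approx(expected, rel=1e-12)


def test_estimate_speed_fallback_and_clip():
    s = dr.estimate_speed(np.array([1.0, 10.0]), np.array([0.0, np.radians(6)]),
                          fallback=1.3, clip=12.0)
    assert s[0] == 1.3       # level: no vertical information
    assert s[1] == 12.0      # implausible ratio clipped


def test_estimate_speed_interpolated_bridges_level_gaps():
    t = np.arange(20.0)
    pitch = np.radians(np.where((t < 5) | (t >= 15), 45.0, 0.0))
    depth_rate = np.where((t < 5) | (t >= 15), np.sin(np.radians(45)) * 2.0, 0.0)
    s = dr.estimate_speed_interpolated(depth_rate, pitch, t, fallback=1.0)
    assert np.allclose(s[:5], 2.0)
    assert np.allclose(s[5:15], 2.0)  # interpolated across the level gap


# ------------------------------------------------- integration

def test_integrate_due_east():
    n = 60
    tr = dr.integrate_pseudo_track(np.full(n, np.pi / 2), np.ones(n), np.zeros(n),
                                   np.arange(n, dtype=float))
    assert tr.x_east[-1] == pytest.approx(60.0)
    assert tr.y_north[-1] == pytest.approx(0.0, abs=1e-9)


def test_integrate_zero_speed_stays_at_origin():
    n = 30
    tr = dr.integrate_pseudo_track(np.zeros(n), np.zeros(n), np.zeros(n),
                                   np.arange(n, dtype=float), origin=(5.0, -3.0))
    assert np.allclose(tr.x_east, 5.0) and np.allclose(tr.y_north, -3.0)


def test_integrate_out_and_back_returns_to_origin():
    h = np.concatenate([np.zeros(30), np.full(30, np.pi)])
    tr = dr.integrate_pseudo_track(h, np.ones(60), np.zeros(60), np.arange(60.0))
    assert abs(tr.x_east[-1]) < 1e-9 and abs(tr.y_north[-1]) < 1e-9


def test_integrate_pitch_shortens_horizontal_step():
    n = 10
    tr = dr.integrate_pseudo_track(np.zeros(n), np.ones(n), np.full(n, np.pi / 3),
                                   np.arange(n, dtype=float))
    assert tr.y_north[-1] == pytest.approx(n * 0.5, rel=1e-12)  # cos 60 deg


# ------------------------------------------------- georeferencing

def _pseudo_line(n=601, speed=1.0):
    t = np.arange(n, dtype=float)
    return dr.PseudoTrack(t, speed * t, np.zeros(n), np.zeros(n))


def test_georeference_exact_when_pseudo_matches_fixes():
    pseudo = _pseudo_line()
    lat0, lon0 = -35.994, 137.317
    fts = np.array([0.0, 300.0, 600.0])
    lats, lons = [], []
    for ft in fts:
        la, lo = destination_point(lat0, lon0, np.pi / 2, ft * 1.0)
        lats.append(la)
        lons.append(lo)
    fixes = FixSeries(fts, np.array(lats), np.array(lons), np.full(3, 8))
    geo_tr = dr.georeference(pseudo, fixes)
    for ft, la, lo in zip(fts, lats, lons):
        i = int(ft)
        assert haversine_m(geo_tr.lat[i], geo_tr.lon[i], la, lo) < 1e-3


def test_georeference_distributes_drift_linearly():
    # pseudo underestimates east progress by a factor 2; at the segment
    # midpoint the applied correction must be half the endpoint drift
    pseudo = _pseudo_line(speed=0.5)
    lat0, lon0 = 0.0, 0.0
    end_lat, end_lon = destination_point(lat0, lon0, np.pi / 2, 600.0)
    fixes = FixSeries(np.array([0.0, 600.0]), np.array([lat0, end_lat]),
                      np.array([lon0, end_lon]), np.full(2, 8))
    geo_tr = dr.georeference(pseudo, fixes)
    mid_true_half = haversine_m(geo_tr.lat[300], geo_tr.lon[300], lat0, lon0)
    # pseudo mid = 150 m; drift at end = 300 m; correction at mid = 150 m
    assert mid_true_half == pytest.approx(300.0, rel=1e-3)


def test_georeference_requires_two_fixes_and_trims_outside():
    pseudo = _pseudo_line()
    one = FixSeries(np.array([10.0]), np.array([0.0]), np.array([0.0]), np.array([8]))
    with pytest.raises(ValueError, match="at least 2 fixes"):
        dr.georeference(pseudo, one)
    stray = FixSeries(np.array([-50.0, 10.0, 500.0, 1e5]),
                      np.zeros(4), np.array([0.0, 0.0, 0.005, 0.1]), np.full(4, 8))
    geo_tr = dr.georeference(pseudo, stray)  # outside fixes trimmed with warning
    assert geo_tr.t.size == pseudo.t.size


def test_georeference_track_at_least_straight_line_over_fixes(default_result):
    r = default_result
    track_total = r.track.total_distance_m()
    fx = r.fixes
    straight = float(np.sum(haversine_m(fx.lat[:-1], fx.lon[:-1], fx.lat[1:], fx.lon[1:])))
    assert track_total >= straight
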