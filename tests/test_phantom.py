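"""Phantom geometry, keyframe motion, and valve implantation."""

import numpy as np
import pytest

from ibvalve.motion import extract_landing_zone
from ibvalve.phantom import (
    Placement,
    PhantomConfig,
    implant_valve,
    make_phantom,
    make_valve,
    shoelace_area,
    standard_placements,
)


def test_config_invariants():
    with pytest.raises(ValueError):
        PhantomConfig(ejection_fraction=0.0)
    with pytest.raises(ValueError):
        PhantomConfig(ejection_fraction=1.0)
    with pytest.raises(ValueError):
        PhantomConfig(n_phases=1)
    with pytest.raises(ValueError):
        PhantomConfig(channel_width=0.015, annulus_diameter=0.020)
    with pytest.raises(ValueError):
        PhantomConfig(period=-1.0)


def test_keyframe_times_and_zero_phase(scene):
    kf = scene.keyframes
    assert len(kf.phase_times) == 20
    assert np.allclose(kf.phase_times, np.arange(20) / 20.0)
    assert np.all(kf.displacements[:, 0, :] == 0.0)  # phase 0 exactly zero
    # periodic wrap: phase N maps back to phase 0
    assert np.allclose(kf.displacement(1.0), kf.displacement(0.0), atol=1e-12)


def test_ejection_fraction_reproduced_by_shoelace_oracle(scene):
    assert scene.measured_ejection_fraction() == pytest.approx(0.5, abs=0.01)
    areas = [
        shoelace_area(scene.chamber_polygon(scene.keyframes.displacements[:, k, :]))
        for k in range(20)
    ]
    A0 = shoelace_area(scene.chamber_polygon())
    g = scene.systolic_profile(scene.keyframes.phase_times)
    assert np.allclose(areas, A0 * (1 - 0.5 * g), rtol=1e-9)


def test_unreachable_ejection_fraction_names_the_phase():
    with pytest.raises(ValueError, match="phase"):
        make_phantom(PhantomConfig(ejection_fraction=0.93))


def test_sample_clouds_have_twenty_points(scene):
    assert scene.clouds.lv.shape == (20, 2)
    assert scene.clouds.aorta.shape == (20, 2)


def test_valve_construction_correspondence_and_geometry():
    cfg = PhantomConfig()
    valve = make_valve(cfg)
    assert len(valve.leaflets) == 2
    for cl, op in zip(valve.leaflets_closed, valve.leaflets_open):
        assert np.asarray(cl).shape == np.asarray(op).shape
    # closed leaflet tips meet at the centerline within one grid spacing
    tips = [np.asarray(cl)[39] for cl in valve.leaflets_closed]  # first-row tips
    gap = abs(tips[0][1] - tips[1][1])
    assert gap <= cfg.h
    # open leaflets stay within the housing bounding region
    hx = valve.housing.X
    lo = hx.min(axis=0) - cfg.h
    hi = hx.max(axis=0) + cfg.h
    for op in valve.leaflets_open:
        assert np.all(op >= lo - 1e-12) and np.all(op <= hi + 1e-12)


def test_annulus_diameter_exceeding_channel_rejected():
    with pytest.raises(ValueError):
        make_valve(PhantomConfig(channel_width=0.023, annulus_diameter=0.024))


def test_identity_placement_is_exact(scene):
    X0 = scene.wall.X.copy()
    v0 = scene.valve.housing.X.copy()
    v = implant_valve(scene.valve, scene, Placement("identity"))
    assert np.allclose(scene.wall.X, X0, atol=1e-15)
    assert np.allclose(v.housing.X, v0, atol=1e-15)


def test_ventricular_translation_shifts_housing_exactly(scene):
    c0 = scene.valve.housing.X.mean(axis=0)
    axis0 = scene.valve.annulus_axis.copy()
    v = implant_valve(scene.valve, scene, Placement("t6", translation=(-0.006, 0.0)))
    assert np.allclose(v.housing.X.mean(axis=0) - c0, [-0.006, 0.0], atol=1e-12)
    assert np.allclose(v.annulus_axis, axis0, atol=1e-15)


def test_rotation_angle_recovered_from_housing_axis(scene):
    v = implant_valve(scene.valve, scene, Placement("r27", rotation_deg=27.0))
    cosang = float(np.dot(v.annulus_axis, [1.0, 0.0]))
    assert np.degrees(np.arccos(cosang)) == pytest.approx(27.0, abs=1e-9)


def test_rigid_placement_preserves_pairwise_distances(scene):
    pts0 = np.vstack([scene.valve.housing.X] + list(scene.valve.leaflets_closed))
    v = implant_valve(scene.valve, scene, Placement("r14", rotation_deg=14.0))
    pts1 = np.vstack([v.housing.X] + list(v.leaflets_closed))
    i = np.arange(0, len(pts0), 7)
    d0 = np.linalg.norm(pts0[i][:, None] - pts0[i][None], axis=2)
    d1 = np.linalg.norm(pts1[i][:, None] - pts1[i][None], axis=2)
    assert np.max(np.abs(d0 - d1)) <= 1e-12


def test_apposition_leaves_no_gap_and_keyframes_rebuilt(scene):
    ef0 = scene.measured_ejection_fraction()
    v = implant_valve(scene.valve, scene, Placement("r27", rotation_deg=27.0))
    # contact: a non-empty landing zone exists at the reference configuration
    lz = extract_landing_zone(scene.wall, v.housing, threshold=0.6 * scene.grid.h)
    assert len(lz.indices) > 20
    # wall point spacing stays below the kernel width (no through-gap)
    for seg in scene.wall.segments:
        d = np.linalg.norm(np.diff(scene.wall.X[seg], axis=0), axis=1)
        assert d.max() < 2.0 * scene.grid.h
    # ejection fraction still exact after the keyframe rebuild
    assert scene.measured_ejection_fraction() == pytest.approx(ef0, abs=1e-6)


def test_bad_placements_rejected(scene):
    with pytest.raises(ValueError, match="axially"):
        implant_valve(scene.valve, scene, Placement("far", translation=(0.06, 0.0)))
    with pytest.raises(ValueError, match="exits the channel"):
        implant_valve(scene.valve, scene, Placement("out", translation=(0.0, 0.02)))
    with pytest.raises(ValueError, match="far wall"):
        implant_valve(scene.valve, scene, Placement("r80", rotation_deg=80.0))


def test_standard_placement_set():
    pls = standard_placements()
    assert [p.label for p in pls] == [
        "baseline",
        "translated_6mm",
        "rotated_14deg",
        "rotated_27deg",
    ]
    assert pls[1].translation == (-0.006, 0.0)
    assert pls[3].rotation_deg == 27.0


def test_channel_walls_are_stationary_at_outlet(scene):
    """Wall keyframe displacement vanishes near the outlet (static mount)."""
    near_outlet = scene.wall.X[:, 0] > scene.x_end - 0.005
    D = scene.keyframes.displacements[near_outlet]
    assert np.max(np.abs(D)) <= 1e-12


def test_landing_zone_motion_is_axial_translation(scene):
    """Wall points on the housing move as a near-rigid axial translation
    (the annular-excursion plateau), so the Horn fit recovers it."""
    from ibvalve.motion import valve_rigid_motion

    lz = extract_landing_zone(scene.wall, scene.valve.housing, 0.6 * scene.grid.h)
    t = 0.45  # mid systole (cycle phase origin is in diastasis)
    tr = valve_rigid_motion(scene.keyframes, lz, t)
    assert abs(tr.angle) < 0.02
    assert abs(tr.translation[0]) > 1e-5  # annular excursion present
    assert abs(tr.translation[1]) < 0.2 * abs(tr.translation[0])
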