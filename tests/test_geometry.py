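import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import podomech as pm
from podomech.geometry import (TrackTooShortError, chord_tangents,
                               filament_strain, joint_energy, local_curvature,
                               orientation_to_membrane, resample, tangents)

from conftest import circle_resampled, straight_track

KAPPA = 4e-26
KBT = 4.11e-21


# --------------------------------------------------------------- resampling

def test_resample_straight_segment():
    t = straight_track(9.0, n=2)
    rs = resample(t, 3.0)
    np.testing.assert_allclose(rs.points[:, 0], [0, 3, 6, 9], atol=1e-9)


def test_resample_preserves_arc_contour():
    arc = pm.make_arc_filament(100.0, 30.0, 3.0)
    rs = resample(arc, 3.0)
    assert abs(rs.contour_length - 30.0) / 30.0 < 1e-3
    assert rs.points[0] == pytest.approx(arc.points[0])
    assert rs.points[-1] == pytest.approx(arc.points[-1])


def test_resample_idempotent_on_uniform_track():
    t = straight_track(30.0, n=11)
    rs1 = resample(t, 3.0)
    rs2 = resample(rs1, 3.0)
    np.testing.assert_allclose(rs1.points, rs2.points, atol=1e-6)


def test_resample_uniform_spacing():
    # a smoothly bending chain (curvature radius >> spacing), as traced
    # filaments are: resampled chords all within 5% of the nominal spacing
    rng = np.random.default_rng(5)
    fil = pm.sample_wlc_filament(200.0, 0.5, np.zeros(3),
                                 np.array([0.0, 0.0, 1.0]), 8.0, rng)
    rs = resample(fil, 3.0)
    seps = np.linalg.norm(np.diff(rs.points, axis=0), axis=1)
    assert np.all(np.abs(seps - rs.spacing_a) / rs.spacing_a < 0.05)


def test_resample_too_short_raises():
    with pytest.raises(TrackTooShortError):
        resample(straight_track(5.0, n=2), 3.0)


# ----------------------------------------------------------------- tangents

def test_tangents_collinear_and_reversal():
    t = straight_track(30.0, n=11, direction=(1, 2, 2))
    rs = resample(t, 3.0)
    tg = tangents(rs)
    np.testing.assert_allclose(tg, np.tile(tg[0], (len(tg), 1)), atol=1e-12)
    np.testing.assert_allclose(tangents(rs.reversed()), -tg, atol=1e-12)


def test_circle_tangent_turning_angle_is_a_over_r():
    """Central-angle identity: chords of points at arc spacing a on a circle
    of radius R turn by exactly a/R between neighbours."""
    R, a = 100.0, 3.0
    rs = circle_resampled(R, 30.0, a)
    tg = chord_tangents(rs)
    angles = np.arccos(np.clip(np.einsum("ij,ij->i", tg[:-1], tg[1:]), -1, 1))
    np.testing.assert_allclose(angles, a / R, rtol=1e-12)


# ---------------------------------------------------------------- curvature

def test_curvature_straight_is_zero():
    rs = resample(straight_track(30.0, n=4), 3.0)
    np.testing.assert_allclose(local_curvature(rs), 0.0, atol=1e-12)


@pytest.mark.parametrize("radius, expected", [(100.0, 1e-2), (1000.0, 1e-3)])
def test_curvature_circle_closed_form(radius, expected):
    rs = circle_resampled(radius, 30.0 * radius / 100.0, 3.0)
    np.testing.assert_allclose(local_curvature(rs), expected, rtol=1e-6)


# -------------------------------------------------------------- orientation

def test_orientation_limits(membrane):
    flat = resample(straight_track(30.0, n=11, direction=(1, 0, 0)), 3.0)
    steep = resample(straight_track(30.0, n=11, direction=(0, 0, 1)), 3.0)
    diag = resample(straight_track(30.0, n=11, direction=(1, 0, 1)), 3.0)
    assert orientation_to_membrane(flat, membrane) == pytest.approx(0.0)
    assert orientation_to_membrane(steep, membrane) == pytest.approx(90.0)
    np.testing.assert_allclose(orientation_to_membrane(diag, membrane), 45.0,
                               atol=1e-9)


# ------------------------------------------------------------------- strain

def test_strain_straight_is_zero():
    assert filament_strain(straight_track(50.0)) == pytest.approx(0.0, abs=1e-12)


def test_strain_semicircle():
    arc = pm.make_arc_filament(100.0, math.pi * 100.0, 1.0)
    assert filament_strain(arc) == pytest.approx(1 - 2 / math.pi, rel=1e-3)


@pytest.mark.parametrize("phi", [0.1, 0.5, 1.0, 2.0])
def test_strain_arc_closed_form(phi):
    """Arc of central angle phi: strain = 1 - sin(phi/2)/(phi/2)."""
    R = 200.0
    arc = pm.make_arc_filament(R, phi * R, 0.5)
    expected = 1 - math.sin(phi / 2) / (phi / 2)
    assert filament_strain(arc) == pytest.approx(expected, rel=1e-3, abs=1e-6)


# ----------------------------------------------------------- bending energy

def test_joint_energy_straight_zero_and_positive():
    rs = resample(straight_track(30.0, n=4), 3.0)
    u = joint_energy(rs, KAPPA)
    # ~1e-12 kBT: zero up to the arccos round-off floor
    np.testing.assert_allclose(u, 0.0, atol=1e-30)


def test_arc_energy_closed_form_40_kbt():
    """An arc bent at R = 116 nm over L = 111 nm stores kappa*L/(2R^2),
    about 40 kBT - the scale of a visibly bent core filament."""
    R, L = 116.0, 111.0
    rs = circle_resampled(R, L, 3.0)
    u_tot = joint_energy(rs, KAPPA).sum()
    expected = KAPPA * (L * 1e-9) / (2 * (R * 1e-9) ** 2)
    assert u_tot == pytest.approx(expected, rel=1e-3)
    assert u_tot / KBT == pytest.approx(40.2, rel=0.02)


def test_joint_energy_linear_in_kappa():
    rs = circle_resampled(100.0, 60.0, 3.0)
    np.testing.assert_allclose(joint_energy(rs, 2 * KAPPA),
                               2 * joint_energy(rs, KAPPA), rtol=1e-12)


@pytest.mark.parametrize("a", [1.0, 3.0, 6.0])
def test_arc_energy_discretization_error(a):
    """Discrete arc energy matches kappa*L/(2R^2) with O((a/R)^2) error."""
    R, L = 150.0, 120.0
    rs = circle_resampled(R, L, a)
    u_tot = joint_energy(rs, KAPPA).sum()
    expected = KAPPA * (L * 1e-9) / (2 * (R * 1e-9) ** 2)
    assert abs(u_tot / expected - 1) < (a / R) ** 2 + 1e-9


# ------------------------------------------------- invariance property tests

@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """Curvature, strain and bending energy are invariant under rotation +
    translation; orientation follows the membrane when it is co-rotated."""
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(scale=6.0, size=(25, 3)), axis=0)
    rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
    shift = rng.normal(scale=100.0, size=3)
    t1 = pm.FilamentTrack("t", pts)
    t2 = pm.FilamentTrack("t", pts @ rot.T + shift)
    rs1, rs2 = resample(t1, 3.0), resample(t2, 3.0)
    # atol ~2e-8 nm^-1: the arccos round-off floor at near-zero curvature
    np.testing.assert_allclose(local_curvature(rs1), local_curvature(rs2),
                               atol=2e-8)
    assert filament_strain(t1) == pytest.approx(filament_strain(t2), abs=1e-12)
    np.testing.assert_allclose(joint_energy(rs1, KAPPA).sum(),
                               joint_energy(rs2, KAPPA).sum(), rtol=1e-9)
    m1 = pm.MembranePlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    m2 = pm.MembranePlane(shift, rot @ np.array([0.0, 0.0, 1.0]))
    np.testing.assert_allclose(orientation_to_membrane(rs1, m1),
                               orientation_to_membrane(rs2, m2), atol=1e-6)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_reversal_invariance(seed):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(scale=6.0, size=(20, 3)), axis=0)
    t = pm.FilamentTrack("t", pts)
    rs = resample(t, 3.0)
    assert filament_strain(t) == pytest.approx(filament_strain(t.reversed()))
    np.testing.assert_allclose(local_curvature(rs),
                               local_curvature(rs.reversed())[::-1], atol=1e-9)
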