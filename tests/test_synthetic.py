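import math

import numpy as np
import pytest

import podomech as pm
from podomech.geometry import resample_network
from podomech.profiles import density_profile, radial_distance
from podomech.synthetic import (PROTRUSIVE_LAYER_NM, generate_podosome,
                                make_arc_filament, sample_wlc_filament,
                                truncated_normal_mean)


def _wlc(lc_um, length=300.0, seed=0, n=1):
    rng = np.random.default_rng(seed)
    return [sample_wlc_filament(length, lc_um, np.zeros(3),
                                np.array([0.0, 0.0, 1.0]), 3.0, rng)
            for _ in range(n)]


# ------------------------------------------------------------- WLC sampler

def test_wlc_rigid_limit_is_straight():
    fil = _wlc(1e6, seed=3)[0]
    assert fil.end_to_end / fil.contour_length > 0.9999


def test_wlc_requires_unit_tangent():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="unit"):
        sample_wlc_filament(100, 1.0, np.zeros(3), np.array([0, 0, 2.0]),
                            3.0, rng)


def test_wlc_uniform_step_spacing():
    fil = _wlc(1.68, seed=1)[0]
    seps = np.linalg.norm(np.diff(fil.points, axis=0), axis=1)
    np.testing.assert_allclose(seps, 3.0, rtol=1e-9)


def test_wlc_correlation_length_recovered():
    """Generator/fitter loop closure: the sampled ensemble's fitted tangent
    correlation length matches the configured one."""
    lc = 1.68
    tracks, _ = resample_network(_wlc(lc, seed=7, n=300), 3.0)
    res = pm.fit_correlation_length(pm.tangent_correlation(tracks))
    assert abs(res.lc_um - lc) / lc < 0.15


def test_wlc_strain_scale_matches_compressed_filaments():
    """At lc = 1.68 um a 111 nm chain has mean strain ~L/(6 lc) ~ 1e-2."""
    fils = _wlc(1.68, length=111.0, seed=11, n=400)
    strains = [pm.filament_strain(f) for f in fils]
    assert 0.003 < np.mean(strains) < 0.05


# ------------------------------------------------------------ arc fixtures

def test_arc_point_count_and_radius():
    arc = make_arc_filament(100.0, 30.0, 3.0)
    assert arc.n_points == 11
    np.testing.assert_allclose(np.linalg.norm(arc.points, axis=1), 100.0,
                               atol=1e-6)
    seps = np.linalg.norm(np.diff(arc.points, axis=0), axis=1)
    np.testing.assert_allclose(seps, seps[0], rtol=1e-9)


def test_arc_rejects_bad_geometry():
    with pytest.raises(ValueError):
        make_arc_filament(100.0, 40.0, 50.0)  # step > arc
    with pytest.raises(ValueError):
        make_arc_filament(100.0, 700.0, 3.0)  # > full circle
    with pytest.raises(ValueError):
        make_arc_filament(-1.0, 30.0, 3.0)


def test_arc_straight_line_limit():
    rs = pm.resample(make_arc_filament(1e9, 90.0, 3.0), 3.0)
    assert np.max(pm.local_curvature(rs)) < 1e-7  # float floor, vs 1/R = 1e-9


def test_arc_semicircle_strain():
    arc = make_arc_filament(100.0, math.pi * 100.0, 1.0)
    assert pm.filament_strain(arc) == pytest.approx(1 - 2 / math.pi, rel=1e-3)


# -------------------------------------------------------- podosome networks

def test_generator_deterministic():
    cfg = pm.SyntheticPodosomeConfig(seed=42, core_filament_count=30,
                                     radial_filament_count=40,
                                     protrusive_count=5)
    n1, f1, g1 = generate_podosome(cfg)
    n2, f2, g2 = generate_podosome(cfg)
    assert len(n1) == len(n2)
    for a, b in zip(n1.tracks, n2.tracks):
        np.testing.assert_array_equal(a.points, b.points)
    assert g1["filaments"] == g2["filaments"]


def test_config_validation():
    with pytest.raises(ValueError):
        pm.SyntheticPodosomeConfig(core_filament_count=-1)
    with pytest.raises(ValueError):
        pm.SyntheticPodosomeConfig(core_orientation_mean_deg=95.0)
    with pytest.raises(ValueError):
        pm.SyntheticPodosomeConfig(core_correlation_length_um=0.0)


def test_no_radial_filaments_stay_near_core():
    cfg = pm.SyntheticPodosomeConfig(seed=5, radial_filament_count=0,
                                     core_filament_count=50,
                                     protrusive_count=5)
    net, frame, gt = generate_podosome(cfg)
    max_len = max(f["length_nm"] for f in gt["filaments"])
    for t in net.tracks:
        r = radial_distance(t.points, frame)
        assert np.max(r) <= cfg.core_radius_true_nm + max_len + 1e-6


def test_points_never_below_membrane():
    cfg = pm.SyntheticPodosomeConfig(seed=9, core_filament_count=80,
                                     radial_filament_count=120,
                                     protrusive_count=20)
    net, frame, _ = generate_podosome(cfg)
    for t in net.tracks:
        assert np.min(t.points[:, 2]) >= cfg.membrane_z_nm - 1e-9


def test_planted_protrusive_reach_membrane_layer():
    cfg = pm.SyntheticPodosomeConfig(seed=13, core_filament_count=40,
                                     radial_filament_count=0,
                                     protrusive_count=30)
    net, frame, gt = generate_podosome(cfg)
    prot = {f["filament_id"] for f in gt["filaments"]
            if f["class"] == "protrusive"}
    for t in net.tracks:
        in_layer = np.sum(t.points[:, 2] <= PROTRUSIVE_LAYER_NM)
        if t.filament_id in prot:
            assert in_layer >= 2
        else:
            assert in_layer == 0  # layer reserved to the protrusive class


def test_sample_statistics_match_configured_distributions():
    """Drawn lengths and orientations match the analytic means of their
    truncated normals within 3 standard errors."""
    cfg = pm.SyntheticPodosomeConfig(seed=21, core_filament_count=400,
                                     radial_filament_count=400,
                                     protrusive_count=0)
    _, _, gt = generate_podosome(cfg)
    fil = gt["filaments"]
    for cls, mean, sd, lo, hi, field in [
        ("core", cfg.core_orientation_mean_deg, cfg.core_orientation_sd_deg,
         0.0, 90.0, "orientation_deg"),
        ("radial", cfg.radial_orientation_mean_deg,
         cfg.radial_orientation_sd_deg, 0.0, 90.0, "orientation_deg"),
        ("core", cfg.core_length_mean_nm, cfg.core_length_sd_nm,
         6.0, np.inf, "length_nm"),
        ("radial", cfg.radial_length_mean_nm, cfg.radial_length_sd_nm,
         6.0, np.inf, "length_nm"),
    ]:
        vals = np.array([f[field] for f in fil if f["class"] == cls])
        target = truncated_normal_mean(mean, sd, lo, hi)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se, (cls, field)


def test_density_contrast_configuration():
    """A generation config calibrated for a 2.5x core/surround density
    contrast realizes it within 20%."""
    cfg = pm.SyntheticPodosomeConfig(seed=2, radial_filament_count=1020)
    net, frame, _ = generate_podosome(cfg)
    net = pm.filter_min_length(net, 60.0)
    rs, _ = resample_network(net.tracks, 3.0)
    r = np.concatenate([radial_distance(t.points, frame) for t in rs])
    prof = density_profile(r, 25.0, cfg.slab_height_nm)
    rb, vb = prof.bin_centers_nm, prof.values
    inside = np.nanmean(vb[rb < cfg.core_radius_true_nm])
    outside = np.nanmean(vb[(rb > cfg.core_radius_true_nm)
                            & (rb < cfg.outer_radius_nm)])
    assert inside / outside == pytest.approx(2.5, rel=0.20)
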