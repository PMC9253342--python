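import math

import numpy as np
import pytest

import podomech as pm
from podomech.geometry import joint_energy, resample, resample_network
from podomech.mechanics import (MechanicsConstants, ProtrusivePortion,
                                core_energy, core_pressure,
                                core_strain_and_height, elastic_force,
                                polymerization_energy, polymerization_force,
                                pressure_uncertainty, select_protrusive,
                                stall_force, surface_tension,
                                volume_fraction_modulus, young_modulus)

from conftest import circle_resampled, straight_track

C_PAPER = MechanicsConstants(kbt_j=4.00e-21)  # the value the printed stall
# forces imply (the Methods' 4.11e-21 J overshoots them by ~3%)


# -------------------------------------------------------------- stall force

def test_stall_force_values():
    assert stall_force(C_PAPER) == pytest.approx(11.4, abs=0.05)
    assert stall_force(MechanicsConstants(kbt_j=4.00e-21, c_um=50.0)) == \
        pytest.approx(9.8, abs=0.05)
    # canonical fixed-factor convention: 10.46 pN, reported as 10
    assert stall_force(MechanicsConstants(), use_fixed_factor=True) == \
        pytest.approx(10.46, abs=0.01)


def test_stall_force_degenerate_concentrations():
    near = MechanicsConstants(c_um=0.06 + 1e-9, cc_um=0.06)
    assert stall_force(near) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        MechanicsConstants(c_um=0.05, cc_um=0.06)


def test_persistence_length_is_thermal_lc():
    assert MechanicsConstants().persistence_length_um == pytest.approx(9.73, abs=0.02)


# ------------------------------------------------------ protrusive selection

def test_select_protrusive_far_filament_excluded(membrane):
    tracks, _ = resample_network(
        [straight_track(90, 31, (1, 0, 0), "high", start=(0, 0, 50.0))], 3.0)
    assert select_protrusive(tracks, membrane) == []


def test_select_protrusive_descending_polyline(membrane):
    """A filament descending through the 10 nm zone contributes exactly its
    sub-10 nm points."""
    z = np.array([20.0, 15.0, 11.0, 9.0, 6.0, 2.0, 0.5])
    pts = np.column_stack([np.arange(len(z)) * 3.0, np.zeros(len(z)), z])
    track = pm.ResampledTrack("desc", pts, 3.0)
    portions = select_protrusive([track], membrane)
    assert len(portions) == 1
    assert portions[0].start_index == 3 and portions[0].n_points == 4


def test_select_protrusive_single_point_run_dropped(membrane):
    z = np.array([30.0, 9.0, 30.0, 30.0])
    pts = np.column_stack([np.arange(4) * 3.0, np.zeros(4), z])
    assert select_protrusive([pm.ResampledTrack("t", pts, 3.0)], membrane) == []


def test_protrusive_count_recovered_from_generator(default_run):
    """The planted protrusive subpopulation (45) is recovered at
    Poisson-level accuracy."""
    n_p = default_run.polymerization.n_portions
    assert abs(n_p - 45) <= 3 * math.sqrt(45)


# ------------------------------------------------------ polymerization force

def test_polymerization_force_worked_examples():
    p90 = [ProtrusivePortion("a", 0, 2, 90.0)]
    assert polymerization_force(p90, 10.0) == pytest.approx(10.0)
    p30 = [ProtrusivePortion("a", 0, 2, 30.0),
           ProtrusivePortion("b", 0, 2, 30.0)]
    assert polymerization_force(p30, 10.0) == pytest.approx(40.0)
    p61 = [ProtrusivePortion(f"f{i}", 0, 2, 61.0) for i in range(45)]
    assert polymerization_force(p61, 10.0) == pytest.approx(514.6, abs=0.1)


def test_polymerization_force_excludes_flat_portions():
    flat = [ProtrusivePortion("a", 0, 2, 0.5),
            ProtrusivePortion("b", 0, 2, 45.0)]
    with pytest.warns(UserWarning, match="flatter"):
        f = polymerization_force(flat, 10.0)
    assert f == pytest.approx(10.0 / math.sin(math.radians(45.0)))


def test_polymerization_force_lower_bound():
    rng = np.random.default_rng(1)
    thetas = rng.uniform(5, 90, size=50)
    f = polymerization_force(thetas, 10.0)
    assert f >= 50 * 10.0


def test_polymerization_energy():
    assert polymerization_energy(0.0, C_PAPER) == 0.0
    # 50 um of core filament, log factor 7: (50000 / 2.75) * 7 kBT
    assert polymerization_energy(50_000.0, C_PAPER) == \
        pytest.approx(1.27e5, rel=0.005)
    assert polymerization_energy(100_000.0, C_PAPER) == \
        pytest.approx(2 * polymerization_energy(50_000.0, C_PAPER))


# ------------------------------------------------------------- core energy

def test_core_energy_empty_and_linear():
    u = np.array([1e-20, 2e-20])
    r = np.array([300.0, 400.0])
    assert core_energy(u, r, 200.0) == 0.0
    assert core_energy(2 * u, np.array([10.0, 20.0]), 200.0) == \
        pytest.approx(2 * core_energy(u, np.array([10.0, 20.0]), 200.0))


def test_core_energy_of_bent_arc_population():
    """300 arcs bent at R = 116 nm (L = 111 nm) inside the core store
    ~300 x 40 kBT ~ 1.2e4 kBT."""
    kappa, kbt = 4e-26, 4.11e-21
    rs = circle_resampled(116.0, 111.0, 3.0)
    u_one = joint_energy(rs, kappa)
    u = np.tile(u_one, 300)
    r = np.zeros_like(u)
    total_kbt = core_energy(u, r, 200.0) / kbt
    assert total_kbt == pytest.approx(300 * 40.2, rel=0.02)
    assert 1e4 < total_kbt < 5e4


# --------------------------------------------------------- strain and height

def test_core_strain_straight_and_semicircle():
    strains = {"s": 0.0, "c": 1 - 2 / math.pi}
    r_in = {"s": np.array([10.0, 20.0]), "c": np.array([15.0, 25.0])}
    z = {"s": np.array([0.0, 100.0]), "c": np.array([0.0, 100.0])}
    eps, _ = core_strain_and_height({"s": 0.0}, {"s": r_in["s"]},
                                    {"s": z["s"]}, 200.0)
    assert eps == 0.0
    eps, _ = core_strain_and_height(strains, r_in, z, 200.0)
    assert eps == pytest.approx((0.0 + 1 - 2 / math.pi) / 2)


def test_core_height_percentile_extent():
    rng = np.random.default_rng(0)
    z = {"f": rng.uniform(0, 400, size=20_000)}
    r = {"f": np.zeros(20_000)}
    _, h = core_strain_and_height({"f": 0.1}, r, z, 200.0)
    assert h == pytest.approx(380.0, abs=5.0)


def test_core_strain_requires_core_filament():
    with pytest.raises(ValueError, match="majority-inside"):
        core_strain_and_height({"f": 0.1}, {"f": np.array([500.0, 600.0])},
                               {"f": np.array([0.0, 1.0])}, 200.0)


# ------------------------------------------------------- force and pressure

def test_elastic_force_worked_example():
    # U = 4e4 kBT, eps = 0.016, h = 370 nm -> the reported-scale mean force
    assert elastic_force(1.64e-16, 0.016, 370.0) == pytest.approx(27.7, abs=0.05)
    assert elastic_force(0.0, 0.016, 370.0) == 0.0
    assert elastic_force(1.64e-16, 0.016, 185.0) == \
        pytest.approx(2 * 27.7, abs=0.1)
    with pytest.raises(ValueError, match="undeformed"):
        elastic_force(1e-16, 0.0, 370.0)


def test_pressure_from_pfm_force():
    assert core_pressure(10.4, 203.0) == pytest.approx(80.3, abs=0.1)
    assert core_pressure(0.0, 203.0) == 0.0
    assert core_pressure(10.4, 4 * 203.0) == \
        pytest.approx(core_pressure(10.4, 203.0) / 16)


def test_pressure_uncertainty_propagation():
    assert pressure_uncertainty(10.4, 3.8, 203.0, 38.0) == \
        pytest.approx(59.4, abs=0.1)
    assert pressure_uncertainty(10.4, 0.0, 203.0, 0.0) == 0.0
    assert pressure_uncertainty(10.4, 7.6, 203.0, 76.0) == \
        pytest.approx(2 * pressure_uncertainty(10.4, 3.8, 203.0, 38.0))


def test_young_modulus():
    assert young_modulus(202.4, 0.016) == pytest.approx(12.65, abs=0.01)
    assert young_modulus(5.0, 1.0) == pytest.approx(0.005)
    assert young_modulus(404.8, 0.016) == pytest.approx(2 * 12.65, abs=0.02)


def test_volume_fraction_modulus():
    c = MechanicsConstants()
    phi, y = volume_fraction_modulus(0.0, 200.0, 400.0, c)
    assert phi == 0.0 and y == 0.0
    # total length chosen so phi = 0.0722: Y = Y_a phi^2 ~ 12 MPa
    r, h = 200.0, 400.0
    total = 0.0722 * r**2 * h / c.filament_radius_nm**2
    phi, y = volume_fraction_modulus(total, r, h, c)
    assert phi == pytest.approx(0.0722, rel=1e-9)
    assert y == pytest.approx(12.0, abs=0.05)
    phi2, y2 = volume_fraction_modulus(2 * total, r, h, c)
    assert y2 == pytest.approx(4 * y)


def test_surface_tension_and_balance_identity():
    sigma = surface_tension(27.7, 203.0, 23.0)
    assert sigma == pytest.approx(55.6, abs=0.1)
    assert surface_tension(27.7, 203.0, 90.0) == \
        pytest.approx(27.7e-9 / (2 * math.pi * 203e-9) * 1e3)
    # algebraic inversion recovers the force to 1e-9 relative
    f_back = sigma * 1e-3 * 2 * math.pi * 203e-9 * math.sin(math.radians(23.0))
    assert f_back * 1e9 == pytest.approx(27.7, rel=1e-9)
    with pytest.raises(ValueError):
        surface_tension(27.7, 203.0, 0.0)
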