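"""The podosome force model.

Three force estimates are combined:

* **Polymerization** (Brownian ratchet): a single filament growing
  perpendicular to the membrane stalls at ``f_a = (kBT / delta) ln(C / Cc)``;
  a filament inclined at ``theta`` to the membrane pushes with ``f_a /
  sin(theta)``, so the total membrane-proximal polymerization force is
  ``F_polym = f_a * sum_i 1 / sin(theta_i)`` over the protrusive portions
  (points within 10 nm of the membrane).

* **Elastic**: the bending energy stored in the core network,
  ``U_core = sum of joint energies with r <= r_core``, relaxes over the
  compression ``delta_h = eps_core * h_core``, giving
  ``F_elastic = U_core / (eps_core * h_core)``, the pressure
  ``P = F / (pi r_core^2)`` with first-order uncertainty
  ``dP = (2F / (pi r^3)) dr + dF / (pi r^2)``, and the Young's modulus
  ``Y = P / eps_core`` cross-checked against the volume-fraction scaling
  ``Y = Y_a * phi^2``.

* **Balance**: the surface tension of the radial-filament meshwork that
  balances the elastic push, ``sigma = F / (2 pi r_core sin(theta_radial))``.

All numeric fields of the report types carry their unit in the field name.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import (FilamentSummary, ResampledTrack,
                       orientation_to_membrane)
from .io_tracks import MembranePlane
from . import units
from .units import (M_PER_NM, j_to_kbt, n_to_nn, n_to_pn, nm_to_m,
                    npm_to_mnpm, pa_to_kpa, pa_to_mpa)

__all__ = [
    "MechanicsConstants",
    "CoreMechanicsReport",
    "PolymerizationReport",
    "ProtrusivePortion",
    "stall_force",
    "select_protrusive",
    "polymerization_force",
    "polymerization_report",
    "core_energy",
    "core_strain_and_height",
    "elastic_force",
    "core_pressure",
    "pressure_uncertainty",
    "young_modulus",
    "volume_fraction_modulus",
    "surface_tension",
    "polymerization_energy",
]


@dataclass(frozen=True)
class MechanicsConstants:
    """Physical constants of the force model (defaults as used throughout).

    kappa: filament bending modulus, N m^2.
    kbt_j: thermal energy, J (4.11e-21 J at 37 degC).
    delta_nm: filament elongation per added monomer, nm.
    c_um / cc_um: monomer and critical concentrations, uM.
    stall_log_factor: canonical value of ln(C/Cc) used for the 10 pN
        reporting convention.
    membrane_proximity_nm: distance defining protrusive portions.
    actin_young_modulus_pa: Young's modulus of a single filament, Pa.
    filament_radius_nm: filament cross-section radius for volume fractions.
    """

    kappa: float = 4e-26
    kbt_j: float = units.KBT_DEFAULT_J
    delta_nm: float = 2.75
    c_um: float = 150.0
    cc_um: float = 0.06
    stall_log_factor: float = 7.0
    membrane_proximity_nm: float = 10.0
    actin_young_modulus_pa: float = 2.3e9
    filament_radius_nm: float = 4.0

    def __post_init__(self) -> None:
        for name in ("kappa", "kbt_j", "delta_nm", "c_um", "cc_um",
                     "stall_log_factor", "membrane_proximity_nm",
                     "actin_young_modulus_pa", "filament_radius_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_um <= self.cc_um:
            raise ValueError("monomer concentration C must exceed Cc")

    @property
    def persistence_length_um(self) -> float:
        """Thermal persistence length kappa / kBT, um."""
        return self.kappa / self.kbt_j * 1e6


# ---------------------------------------------------------------------------
# polymerization


def stall_force(constants: MechanicsConstants, use_fixed_factor: bool = False) -> float:
    """Single-filament stall force ``(kBT / delta) ln(C / Cc)``, pN.

    With ``use_fixed_factor`` the log term is replaced by the canonical
    ``stall_log_factor`` (7, which rounds to the conventional 10 pN).
    """
    if constants.c_um <= constants.cc_um:
        raise ValueError("C <= Cc: no pushing-force regime")
    log_term = (constants.stall_log_factor if use_fixed_factor
                else math.log(constants.c_um / constants.cc_um))
    f_n = constants.kbt_j / nm_to_m(constants.delta_nm) * log_term
    return n_to_pn(f_n)


@dataclass(frozen=True)
class ProtrusivePortion:
    """The maximal membrane-proximal run of one filament."""

    filament_id: str
    start_index: int
    n_points: int
    theta_deg: float  # mean point orientation over the portion


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True; length 0 if none."""
    best_start = best_len = 0
    start = None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


def select_protrusive(
    tracks: list[ResampledTrack],
    membrane: MembranePlane,
    proximity_nm: float = 10.0,
) -> list[ProtrusivePortion]:
    """Per filament, the maximal run of consecutive resampled points with
    signed membrane distance in [0, proximity]; runs of >= 2 points are kept
    and their mean point orientation becomes ``theta_i``."""
    portions = []
    for t in tracks:
        d = membrane.signed_distance(t.points)
        mask = (d >= 0.0) & (d <= proximity_nm)
        start, length = _longest_true_run(mask)
        if length < 2:
            continue
        theta = orientation_to_membrane(t, membrane)[start : start + length]
        portions.append(
            ProtrusivePortion(t.filament_id, start, length, float(np.mean(theta)))
        )
    return portions


def polymerization_force(
    portions: list[ProtrusivePortion] | np.ndarray,
    f_a_pn: float,
    theta_min_deg: float = 1.0,
) -> float:
    """``F_polym = f_a * sum_i 1 / sin(theta_i)``, pN.

    Portions flatter than ``theta_min_deg`` are excluded with a warning (the
    1/sin leverage diverges; observed protrusive angles are ~61 deg).
    """
    if len(portions) and isinstance(portions[0], ProtrusivePortion):
        thetas = np.asarray([p.theta_deg for p in portions], dtype=float)
    else:
        thetas = np.asarray(portions, dtype=float)
    flat = thetas <= theta_min_deg
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} portion(s) flatter than "
            f"{theta_min_deg} deg from the polymerization sum"
        )
        thetas = thetas[~flat]
    if len(thetas) == 0:
        return 0.0
    return float(f_a_pn * np.sum(1.0 / np.sin(np.radians(thetas))))


@dataclass(frozen=True)
class PolymerizationReport:
    n_portions: int
    theta_deg: list[float]
    f_a_pn: float
    f_polym_pn: float  # at f_a_pn
    f_polym_1pn_pn: float  # rescaled to a 1 pN stall force
    u_polym_kbt: float | None = None


def polymerization_report(
    portions: list[ProtrusivePortion],
    constants: MechanicsConstants,
    use_fixed_factor: bool = True,
    total_core_length_nm: float | None = None,
) -> PolymerizationReport:
    """Assemble the polymerization-force report at the canonical 10 pN stall
    force (fixed log factor, rounded) and its 1 pN lower-bound rescaling."""
    f_a = stall_force(constants, use_fixed_factor=use_fixed_factor)
    if use_fixed_factor:
        f_a = float(round(f_a))  # reporting convention: 10.46 -> 10 pN
    leverage = polymerization_force(portions, 1.0)
    u_polym = (None if total_core_length_nm is None
               else polymerization_energy(total_core_length_nm, constants))
    return PolymerizationReport(
        n_portions=len(portions),
        theta_deg=[p.theta_deg for p in portions],
        f_a_pn=f_a,
        f_polym_pn=f_a * leverage,
        f_polym_1pn_pn=1.0 * leverage,
        u_polym_kbt=u_polym,
    )


def polymerization_energy(
    total_core_length_nm: float,
    constants: MechanicsConstants,
    use_fixed_factor: bool = True,
) -> float:
    """Energy released by polymerizing the whole core length, kBT:
    one ``ln(C/Cc)`` per added monomer, ``length / delta`` monomers."""
    if total_core_length_nm < 0:
        raise ValueError("length must be >= 0")
    log_term = (constants.stall_log_factor if use_fixed_factor
                else math.log(constants.c_um / constants.cc_um))
    return total_core_length_nm / constants.delta_nm * log_term


# ---------------------------------------------------------------------------
# elastic force model


def core_energy(
    joint_energies_j: np.ndarray, positions_r_nm: np.ndarray, r_core_nm: float
) -> float:
    """Total bending energy of joints within the core radius, J."""
    if r_core_nm <= 0:
        raise ValueError("r_core must be positive")
    u = np.asarray(joint_energies_j, float)
    r = np.asarray(positions_r_nm, float)
    return float(u[r <= r_core_nm].sum())


def core_strain_and_height(
    strains: dict[str, float],
    per_filament_r_nm: dict[str, np.ndarray],
    per_filament_z_nm: dict[str, np.ndarray],
    r_core_nm: float,
) -> tuple[float, float]:
    """Core compressive strain and height.

    A filament belongs to the core when the majority of its resampled points
    lie within ``r_core``; ``eps_core`` is the mean strain of those
    filaments, ``h_core`` the 2.5-97.5 percentile extent of their point
    heights above the membrane (robust to stray segmentation outliers).
    """
    core_eps, core_z = [], []
    for fid, r in per_filament_r_nm.items():
        if np.mean(np.asarray(r) <= r_core_nm) > 0.5:
            core_eps.append(strains[fid])
            core_z.append(np.asarray(per_filament_z_nm[fid]))
    if not core_eps:
        raise ValueError("no filament lies majority-inside the core radius")
    z = np.concatenate(core_z)
    h = float(np.percentile(z, 97.5) - np.percentile(z, 2.5))
    return float(np.mean(core_eps)), h


def elastic_force(u_core_j: float, eps_core: float, h_core_nm: float) -> float:
    """``F = U_core / (eps_core * h_core)``, nN."""
    if eps_core <= 0:
        raise ValueError("undeformed network (eps_core = 0); force undefined "
                         "under this model")
    if h_core_nm <= 0:
        raise ValueError("h_core must be positive")
    return n_to_nn(u_core_j / (eps_core * nm_to_m(h_core_nm)))


def core_pressure(f_nn: float, r_core_nm: float) -> float:
    """``P = F / (pi r_core^2)``, kPa."""
    if r_core_nm <= 0:
        raise ValueError("r_core must be positive")
    p_pa = (f_nn * 1e-9) / (math.pi * nm_to_m(r_core_nm) ** 2)
    return pa_to_kpa(p_pa)


def pressure_uncertainty(
    f_nn: float, df_nn: float, r_core_nm: float, dr_nm: float
) -> float:
    """First-order propagated pressure uncertainty
    ``dP = (2F / (pi r^3)) dr + dF / (pi r^2)``, kPa."""
    if min(f_nn, df_nn, r_core_nm, dr_nm) < 0:
        raise ValueError("all inputs must be >= 0")
    r = nm_to_m(r_core_nm)
    term_r = 2.0 * (f_nn * 1e-9) / (math.pi * r**3) * nm_to_m(dr_nm)
    term_f = (df_nn * 1e-9) / (math.pi * r**2)
    return pa_to_kpa(term_r + term_f)


def young_modulus(p_kpa: float, eps_core: float) -> float:
    """``Y = P / eps_core``, MPa."""
    if eps_core <= 0:
        raise ValueError("eps_core must be positive")
    return pa_to_mpa(p_kpa * 1e3 / eps_core)


def volume_fraction_modulus(
    total_core_length_nm: float,
    r_core_nm: float,
    h_core_nm: float,
    constants: MechanicsConstants,
) -> tuple[float, float]:
    """Actin volume fraction ``phi`` of the core cylinder and the predicted
    network modulus ``Y = Y_a phi^2``, MPa."""
    if r_core_nm <= 0 or h_core_nm <= 0:
        raise ValueError("core volume must be positive")
    fil_volume = total_core_length_nm * math.pi * constants.filament_radius_nm**2
    core_volume = math.pi * r_core_nm**2 * h_core_nm
    phi = fil_volume / core_volume
    return phi, pa_to_mpa(constants.actin_young_modulus_pa * phi**2)


def surface_tension(f_nn: float, r_core_nm: float, theta_radial_deg: float) -> float:
    """Radial-meshwork tension balancing the elastic push:
    ``sigma = F / (2 pi r_core sin(theta_radial))``, mN/m."""
    if not (0.0 < theta_radial_deg <= 90.0):
        raise ValueError("theta_radial must be in (0, 90] degrees")
    s_npm = (f_nn * 1e-9) / (
        2.0 * math.pi * nm_to_m(r_core_nm) * math.sin(math.radians(theta_radial_deg))
    )
    return npm_to_mnpm(s_npm)


@dataclass(frozen=True)
class CoreMechanicsReport:
    """Headline mechanical quantities of one podosome core."""

    r_core_nm: float
    h_core_nm: float
    u_core_j: float
    u_core_kbt: float
    eps_core: float
    f_elastic_nn: float
    p_kpa: float
    dp_kpa: float | None
    y_mpa: float
    phi: float
    y_pred_mpa: float
    sigma_mn_per_m: float
    theta_radial_deg: float


def core_mechanics_report(
    joint_energies_j: np.ndarray,
    joint_r_nm: np.ndarray,
    summaries: list[FilamentSummary],
    per_filament_r_nm: dict[str, np.ndarray],
    per_filament_z_nm: dict[str, np.ndarray],
    r_core_nm: float,
    constants: MechanicsConstants,
    theta_radial_deg: float | None = None,
    df_nn: float | None = None,
    dr_nm: float | None = None,
) -> CoreMechanicsReport:
    """Assemble the full elastic-force report from per-joint energies and
    per-filament summaries.

    ``theta_radial`` defaults to the mean orientation of filaments lying
    majority-outside the core.  The pressure uncertainty is only reported
    when ``df_nn`` and ``dr_nm`` are both supplied.
    """
    strains = {s.filament_id: s.strain for s in summaries}
    u_core = core_energy(joint_energies_j, joint_r_nm, r_core_nm)
    eps_core, h_core = core_strain_and_height(
        strains, per_filament_r_nm, per_filament_z_nm, r_core_nm
    )
    f_el = elastic_force(u_core, eps_core, h_core)
    p = core_pressure(f_el, r_core_nm)
    dp = (pressure_uncertainty(f_el, df_nn, r_core_nm, dr_nm)
          if df_nn is not None and dr_nm is not None else None)
    if theta_radial_deg is None:
        outside = [
            s.mean_orientation_deg for s in summaries
            if np.mean(np.asarray(per_filament_r_nm[s.filament_id]) <= r_core_nm) <= 0.5
        ]
        theta_radial_deg = float(np.mean(outside)) if outside else 90.0
    core_len = sum(
        s.contour_length_nm for s in summaries
        if np.mean(np.asarray(per_filament_r_nm[s.filament_id]) <= r_core_nm) > 0.5
    )
    phi, y_pred = volume_fraction_modulus(core_len, r_core_nm, h_core, constants)
    return CoreMechanicsReport(
        r_core_nm=float(r_core_nm),
        h_core_nm=h_core,
        u_core_j=u_core,
        u_core_kbt=j_to_kbt(u_core, constants.kbt_j),
        eps_core=eps_core,
        f_elastic_nn=f_el,
        p_kpa=p,
        dp_kpa=dp,
        y_mpa=young_modulus(p, eps_core),
        phi=phi,
        y_pred_mpa=y_pred,
        sigma_mn_per_m=surface_tension(f_el, r_core_nm, theta_radial_deg),
        theta_radial_deg=float(theta_radial_deg),
    )
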