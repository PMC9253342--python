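"""Centralized unit conversions.

The force computation crosses ~12 orders of magnitude (J to kBT, N to pN,
Pa to MPa); every conversion in the package goes through these helpers so a
unit slip can only happen in one place.
"""

from __future__ import annotations

NM_PER_M = 1e9
M_PER_NM = 1e-9
UM_PER_NM = 1e-3
NM_PER_UM = 1e3

PN_PER_N = 1e12
NN_PER_N = 1e9
KPA_PER_PA = 1e-3
MPA_PER_PA = 1e-6
MN_PER_M_PER_N_PER_M = 1e3  # N/m -> mN/m

#: thermal energy at 37 degC as used in the force model Methods, J
KBT_DEFAULT_J = 4.11e-21


def j_to_kbt(energy_j: float, kbt_j: float = KBT_DEFAULT_J) -> float:
    return energy_j / kbt_j


def kbt_to_j(energy_kbt: float, kbt_j: float = KBT_DEFAULT_J) -> float:
    return energy_kbt * kbt_j


def nm_to_m(x_nm: float) -> float:
    return x_nm * M_PER_NM


def m_to_nm(x_m: float) -> float:
    return x_m * NM_PER_M


def nm_to_um(x_nm: float) -> float:
    return x_nm * UM_PER_NM


def um_to_nm(x_um: float) -> float:
    return x_um * NM_PER_UM


def n_to_pn(f_n: float) -> float:
    return f_n * PN_PER_N


def n_to_nn(f_n: float) -> float:
    return f_n * NN_PER_N


def pa_to_kpa(p_pa: float) -> float:
    return p_pa * KPA_PER_PA


def pa_to_mpa(p_pa: float) -> float:
    return p_pa * MPA_PER_PA


def npm_to_mnpm(s_npm: float) -> float:
    """Surface tension N/m -> mN/m."""
    return s_npm * MN_PER_M_PER_N_PER_M
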