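"""Unit conventions and conversions.

The package works in reduced units throughout: lengths in nm, energies in
k_BT (beta = 1).  Surface tensions and tilt moduli therefore carry units of
k_BT/nm^2; bending moduli are dimensionless (beta*kappa).  The only place
where absolute units enter is the conversion of a tension-like quantity to
mN/m, which requires a temperature.
"""

from __future__ import annotations

BOLTZMANN_J_PER_K = 1.380649e-23  # exact (SI definition)


def kbt_per_nm2_to_mn_per_m(value: float, temperature: float) -> float:
    """Convert a tension from k_BT/nm^2 to mN/m at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    # k_B T [J] / 1e-18 m^2 -> N/m, then x1e3 -> mN/m
    return value * BOLTZMANN_J_PER_K * temperature * 1e21


def mn_per_m_to_kbt_per_nm2(value: float, temperature: float) -> float:
    """Convert a tension from mN/m to k_BT/nm^2 at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return value / (BOLTZMANN_J_PER_K * temperature * 1e21)


_CONVERTERS = {
    ("kBT/nm2", "mN/m"): kbt_per_nm2_to_mn_per_m,
    ("mN/m", "kBT/nm2"): mn_per_m_to_kbt_per_nm2,
}


def unit_convert(value: float, unit_from: str, unit_to: str, temperature: float = 320.0) -> float:
    """Convert tension-like quantities between reduced and absolute units.

    Identity conversions are allowed for any unit string.
    """
    if unit_from == unit_to:
        return value
    try:
        return _CONVERTERS[(unit_from, unit_to)](value, temperature)
    except KeyError:
        raise ValueError(f"unsupported conversion {unit_from!r} -> {unit_to!r}") from None
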