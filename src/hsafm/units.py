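"""Unit conventions and conversions.

The package uses one internal convention throughout:

* heights and molecular lengths in nanometres (nm)
* time in seconds (s)
* diffusion coefficients in µm² s⁻¹
* surface densities in µm⁻² and box/trajectory coordinates in µm
* free energies as dimensionless multiples of the thermal energy k_BT

All conversions between these scales live here so that no factor of 10³
is ever written inline elsewhere.
"""

NM_PER_UM = 1.0e3
UM3_PER_LITER = 1.0e15
AVOGADRO = 6.02214076e23


def nm_to_um(x: float) -> float:
    return x / NM_PER_UM


def um_to_nm(x: float) -> float:
    return x * NM_PER_UM


def molar_to_per_um3(c_molar: float) -> float:
    """Convert a bulk molar concentration to molecules per µm³."""
    return c_molar * AVOGADRO / UM3_PER_LITER


def per_s_to_rpm(omega_deg_per_s: float) -> float:
    """Convert an angular velocity from degrees per second to revolutions per minute."""
    return omega_deg_per_s * 60.0 / 360.0
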