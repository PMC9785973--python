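"""Unit conventions and conversion constants.

Internal units throughout the package:

* length      : angstrom (A)
* time        : femtosecond (fs)
* mass        : atomic mass unit (amu)
* charge      : elementary charge (e)
* wavenumber  : reciprocal centimetre (cm^-1)
* density     : gram per cubic centimetre (g cm^-3)

Velocities are A/fs, so a dipole flux sum(e_j * v_j) is in e*A/fs.
"""

#: speed of light, cm per fs  (ties angular frequency rad/fs to cm^-1)
C_CM_PER_FS = 2.99792458e-5

#: one atomic mass unit in grams
AMU_G = 1.66053906660e-24

#: one cubic angstrom in cubic centimetres
A3_CM3 = 1.0e-24

#: amu / A^3  ->  g / cm^3
DENSITY_AMU_A3_TO_G_CM3 = AMU_G / A3_CM3  # = 1.66053906660

NM_TO_A = 10.0
A_TO_NM = 0.1
PS_TO_FS = 1000.0
FS_TO_PS = 1.0e-3

#: reference mass of one water molecule, amu
WATER_MOLECULE_MASS = 18.015

#: bulk liquid-water density at ambient conditions, g cm^-3
BULK_WATER_DENSITY = 0.997


def wavenumber_to_angular_frequency(nu_cm1):
    """cm^-1 -> rad/fs."""
    import numpy as np

    return 2.0 * np.pi * C_CM_PER_FS * np.asarray(nu_cm1, dtype=float)


def angular_frequency_to_wavenumber(omega_rad_fs):
    """rad/fs -> cm^-1."""
    import numpy as np

    return np.asarray(omega_rad_fs, dtype=float) / (2.0 * np.pi * C_CM_PER_FS)


def number_density_from_mass_density(rho_g_cm3, molecule_mass_amu=WATER_MOLECULE_MASS):
    """Molecules per A^3 corresponding to a mass density in g cm^-3."""
    return rho_g_cm3 / (molecule_mass_amu * DENSITY_AMU_A3_TO_G_CM3)
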