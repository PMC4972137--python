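"""Physical constants and electrolyte parameter tables.

All equations downstream work in mV, molar, ångström, kelvin unless a
docstring says otherwise.
"""

from __future__ import annotations

#: Universal gas constant, J mol^-1 K^-1 (CODATA exact).
R_GAS = 8.31446261815324

#: Faraday constant, C mol^-1 (CODATA exact).
FARADAY = 96485.33212331001

#: Default recording temperature, K.  Whole-cell recordings at ambient
#: room temperature; gives RT/F ~ 25.4 mV.
DEFAULT_TEMPERATURE_K = 295.0

#: Extended Debye-Hueckel coefficients for water at 25 C.
#: A in M^-1/2, B in A^-1 M^-1/2 (ångström^-1).
DH_A = 0.509
DH_B = 0.328

#: Kielland ion-size parameters (å, ångström) for the extended
#: Debye-Hueckel equation.  Overridable per species.
KIELLAND_SIZE_A = {
    "Na": 4.0,
    "K": 3.0,
    "Li": 6.0,
    "Rb": 2.5,
    "Cs": 2.5,
    "Mg": 8.0,
    "Ca": 6.0,
    "Sr": 5.0,
    "Ba": 5.0,
    "NMDG": 4.0,  # impermeant organic cation; size only matters via I
}

#: Born radii (ångström) used for continuum-electrostatics probe ions.
BORN_RADIUS_A = {
    "Na": 1.68,
    "K": 2.2,
    "Li": 1.39,
    "Ca": 1.73,
}

#: Default cation valences.
VALENCE = {
    "Na": 1,
    "K": 1,
    "Li": 1,
    "Rb": 1,
    "Cs": 1,
    "NMDG": 1,
    "Mg": 2,
    "Ca": 2,
    "Sr": 2,
    "Ba": 2,
}

#: Boltzmann constant, J K^-1.
K_BOLTZMANN = 1.380649e-23

#: Elementary charge, C.
E_CHARGE = 1.602176634e-19

#: Vacuum permittivity, C^2 J^-1 m^-1.
EPS0 = 8.8541878128e-12

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23


def rt_over_f_mv(temperature_k: float) -> float:
    """Thermal voltage RT/F in millivolts."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1000.0 * R_GAS * temperature_k / FARADAY
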