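"""Physical constants and the package-wide unit conventions.

All in-memory quantities use the molecular-simulation unit system:
length nm, time ns, temperature K, energy kJ/mol, force kJ mol^-1 nm^-1,
spring constant kJ mol^-1 nm^-2, conductance pS.  SI values (CODATA 2018)
are kept only for the electrostatics where they are unavoidable.
"""

import math

# --- SI constants (CODATA 2018, exact where defined) ---
KB_SI = 1.380649e-23           # Boltzmann constant, J/K
NA = 6.02214076e23             # Avogadro number, 1/mol
E_CHARGE = 1.602176634e-19     # elementary charge, C
EPS0 = 8.8541878128e-12        # vacuum permittivity, F/m

# --- molar energy units ---
KB_KJMOL = KB_SI * NA / 1000.0          # 8.3144626e-3 kJ mol^-1 K^-1
FARADAY = E_CHARGE * NA                 # 96485.332 C/mol

# --- unit conversions (one table; round-trip tested) ---
EMV_TO_KJMOL = FARADAY / 1e6            # 1 e*mV = 0.0964853 kJ/mol
M2_PER_S_TO_NM2_PER_NS = 1e9            # 1 m^2/s = 1e9 nm^2/ns
NS_TO_S = 1e-9
PER_NS_TO_PER_S = 1e9
S_TO_PS = 1e12                          # siemens -> picosiemens
A_TO_PA = 1e12                          # ampere -> picoampere
ANG_TO_NM = 0.1
NM_TO_ANG = 10.0


def kBT(T: float) -> float:
    """Thermal energy in kJ/mol at absolute temperature ``T`` (K)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return KB_KJMOL * T


def beta(T: float) -> float:
    """Inverse thermal energy 1/(kB*T) in mol/kJ."""
    return 1.0 / kBT(T)


def diffusion_si_to_sim(D_m2_s: float) -> float:
    """Convert a diffusion coefficient from m^2/s to nm^2/ns."""
    return D_m2_s * M2_PER_S_TO_NM2_PER_NS


def _self_check() -> None:
    assert math.isclose(KB_KJMOL, 8.31446261815324e-3, rel_tol=1e-12)
    assert math.isclose(diffusion_si_to_sim(1.957e-9), 1.957, rel_tol=1e-12)


_self_check()
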