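"""Physical constants and unit conversions.

Internal conventions: lengths in Å, energies in eV (per cell) or kJ/mol
(per molecule), masses in amu, frequencies in cm⁻¹ (wavenumbers),
pressures in GPa, time in fs, dipoles in e·Å.  Everything here is derived
from CODATA values via :mod:`scipy.constants`.
"""

from __future__ import annotations

import scipy.constants as _c

#: Boltzmann constant, eV/K
KB_EV = _c.value("Boltzmann constant in eV/K")
#: Boltzmann constant, kJ/mol/K
KB_KJMOL = _c.R / 1000.0
#: Avogadro constant, 1/mol
N_A = _c.Avogadro
#: eV → kJ/mol
EV_TO_KJMOL = _c.electron_volt * _c.Avogadro / 1000.0
#: energy (eV) of a 1 cm⁻¹ photon: h·c·(100 m⁻¹)/e
CM1_TO_EV = _c.h * _c.c * 100.0 / _c.electron_volt
#: angular frequency (rad/s) of a 1 cm⁻¹ wavenumber
CM1_TO_RADS = 2.0 * _c.pi * _c.c * 100.0
#: rad/fs per cm⁻¹
CM1_TO_RAD_PER_FS = CM1_TO_RADS * 1e-15

#: sqrt(eV Å⁻² amu⁻¹) → cm⁻¹ (the standard phonon-frequency conversion)
SQRT_EV_A2_AMU_TO_CM1 = (
    (_c.electron_volt / (_c.atomic_mass * 1e-20)) ** 0.5 / CM1_TO_RADS
)

#: GPa·Å³ → eV (PV work term)
GPA_A3_TO_EV = 1e9 * 1e-30 / _c.electron_volt

#: Lorentz oscillator-strength prefactor: e²/(ε0·amu·Å³) expressed in cm⁻²,
#: i.e. the dielectric contribution of |Σ Z*·e/√m|² (units e²/amu) in a cell
#: of volume V Å³ is  OSC_STRENGTH_CM2 · |…|² / V / ω₀²  with ω₀ in cm⁻¹.
OSC_STRENGTH_CM2 = (
    _c.elementary_charge**2 / (_c.epsilon_0 * _c.atomic_mass * 1e-30)
) / CM1_TO_RADS**2

#: (e·Å)²/(ε0·Å³·eV) → dimensionless; prefactor for the classical
#: fluctuation–dissipation permittivity  β⟨M²⟩/(3Vε0).
DIPOLE_FLUCT_EPS = (_c.elementary_charge * 1e-10) ** 2 / (
    _c.epsilon_0 * 1e-30 * _c.electron_volt
)

#: ħ in eV·fs
HBAR_EV_FS = _c.hbar / _c.electron_volt * 1e15
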