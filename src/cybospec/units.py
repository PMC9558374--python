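"""Unit conventions and conversion factors.

Internal conventions used throughout the package:

* lengths in angstrom (Å),
* times in picoseconds,
* energies in hartree,
* charges in units of the elementary charge.

Coulomb sums are evaluated in atomic units; the Å → bohr conversion
happens in exactly one place (:data:`BOHR_PER_ANGSTROM`) so that no
other module carries its own copy of the factor.
"""

from __future__ import annotations

import numpy as np

#: Å → bohr. Multiply an angstrom length by this to obtain bohr.
BOHR_PER_ANGSTROM: float = 1.8897259886

#: hartree → cm⁻¹ (CODATA).
WAVENUMBER_PER_HARTREE: float = 219474.6313632

#: hartree → eV.
EV_PER_HARTREE: float = 27.211386245988

#: Conversion between oscillator strength and integrated molar
#: absorptivity: ∫ ε(ν̃) dν̃ = f / OSCILLATOR_TO_ABSORPTIVITY
#: with ε in M⁻¹ cm⁻¹ and ν̃ in cm⁻¹.
OSCILLATOR_TO_ABSORPTIVITY: float = 4.319e-9


def angstrom_to_bohr(x):
    """Convert length(s) from Å to bohr."""
    return np.asarray(x, dtype=float) * BOHR_PER_ANGSTROM


def nm_to_wavenumber(lam):
    """Wavelength in nm → wavenumber in cm⁻¹ (ν̃ = 10⁷ / λ)."""
    return 1.0e7 / np.asarray(lam, dtype=float)


def wavenumber_to_nm(nu):
    """Wavenumber in cm⁻¹ → wavelength in nm."""
    return 1.0e7 / np.asarray(nu, dtype=float)


def hartree_to_nm(e_hartree):
    """Excitation energy in hartree → transition wavelength in nm."""
    return wavenumber_to_nm(np.asarray(e_hartree, dtype=float) * WAVENUMBER_PER_HARTREE)


def hartree_to_wavenumber(e_hartree):
    """Energy in hartree → wavenumber in cm⁻¹."""
    return np.asarray(e_hartree, dtype=float) * WAVENUMBER_PER_HARTREE
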