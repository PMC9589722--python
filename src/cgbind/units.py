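"""Internal unit system and physical constants.

Energies are kcal/mol, lengths are Angstrom, temperatures Kelvin.  Time is
measured in the reduced unit tau with a uniform bead mass of ``BEAD_MASS``
(in kcal/mol * tau^2 / A^2).  The value 100 approximates the residue-mass
scale of C-alpha models in these units, so the stiffest bonded mode
(100 kcal/mol/A^2 bonds and rigid-ligand restraints) satisfies
omega*dt ~ 0.1 at the default time step of 0.1 tau, mirroring the stability
margin of standard coarse-grained MD engines.
"""

KB = 0.0019872041  # kcal/mol/K
DEFAULT_TEMPERATURE = 300.0  # K
BEAD_MASS = 100.0  # reduced units, uniform for every bead

NM_TO_ANGSTROM = 10.0
ANGSTROM_TO_NM = 0.1


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
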