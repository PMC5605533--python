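"""Physical constants and unit conventions used throughout the package.

Internal unit system (chosen so that D*Q**2*tau0 is dimensionless with no
hidden factors):

* energy transfer E and line widths Gamma in micro-electronvolts (ueV)
* momentum transfer Q in inverse Angstrom (1/A)
* time in picoseconds (ps)
* diffusion coefficient D in A**2/ps
* lengths in Angstrom (A); jump lengths reported in nm

The customary reporting unit for water diffusion coefficients is
1e-10 m**2/s; 1 A**2/ps = 1e-20 m**2 / 1e-12 s = 100 x 1e-10 m**2/s.
"""

#: Reduced Planck constant, ueV * ps.
HBAR_UEV_PS = 658.212

#: Boltzmann constant, ueV / K.
KB_UEV_PER_K = 86.173

#: Multiply a D in A**2/ps by this to express it in 1e-10 m**2/s.
D_A2PS_TO_1E10_M2S = 100.0

#: Angstrom per nanometre.
A_PER_NM = 10.0


def d_to_report_units(d_a2_ps: float) -> float:
    """Convert a diffusion coefficient from A**2/ps to 1e-10 m**2/s."""
    return d_a2_ps * D_A2PS_TO_1E10_M2S


def d_from_report_units(d_1e10_m2s: float) -> float:
    """Convert a diffusion coefficient from 1e-10 m**2/s to A**2/ps."""
    return d_1e10_m2s / D_A2PS_TO_1E10_M2S
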