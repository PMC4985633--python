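"""Physical constants and neutron scattering lengths.

Bound coherent scattering lengths are from the standard Sears (1992)
compilation (Neutron News 3, 26); values in femtometres.  Only the
elements that occur in water, ectoine and protein are carried — this
package is not a general-purpose SLD calculator.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K

FM_TO_CM = 1e-13

#: bound coherent scattering lengths, fm.  H is negative, D positive —
#: the sign difference is what makes H/D contrast variation work.
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
}

# isotopic waters at 25 degC
H2O_MOLAR_MASS = 18.0153  # g/mol
D2O_MOLAR_MASS = 20.0276  # g/mol
H2O_DENSITY = 0.99707  # g/cm3
D2O_DENSITY = 1.1044  # g/cm3

#: resilience conversion: <k'> [N/m] = 2 kB / (d<u2>/dT in m2/K);
#: with the slope in A2/K this is 2*kB/1e-20 = 2.761e-3 / slope.
TWO_KB_OVER_A2 = 2.0 * BOLTZMANN / 1e-20  # N/m per (A2/K)
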