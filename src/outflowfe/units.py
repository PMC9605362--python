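"""Unit system helpers.

Internally everything runs in a consistent explicit-dynamics unit set:
mm - MPa - N - tonne/mm^3 - s.  Geometric inputs arrive in micrometres and
pressures in mmHg; they are converted once, at the boundary of the package.
"""

#: 1 mmHg expressed in MPa.
MMHG_TO_MPA = 1.33322e-4

#: 1 mmHg expressed in Pa.
MMHG_TO_PA = 133.322

#: 1 micrometre expressed in mm.
UM_TO_MM = 1.0e-3

#: 1 mm expressed in micrometres.
MM_TO_UM = 1.0e3

#: Water-like soft-tissue density in tonne/mm^3 (1000 kg/m^3).
TISSUE_DENSITY = 1.0e-9


def mmhg_to_mpa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_MPA


def um_to_mm(x_um):
    return x_um * UM_TO_MM


def mm_to_um(x_mm):
    return x_mm * MM_TO_UM
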