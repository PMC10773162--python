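"""Unit conversion constants.

External interfaces use clinical units (mmHg, L/min, mm); all internal
dynamics are solved in SI (Pa, m3/s, m).
"""

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA

LMIN_TO_M3S = 1e-3 / 60.0
M3S_TO_LMIN = 60.0 / 1e-3

MM_TO_M = 1e-3
M_TO_MM = 1e3

ML_PER_M3 = 1e6
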