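"""Canonical internal units and the conversion constants between them.

Geometry is kept in micrometres, pressures in mmHg, viscosities in mPa*s and
flows in um^3/s throughout the package; oxygen quantities use cm-based units
(cm^3 O2, cm, s) as is conventional for Krogh-type diffusion constants.
Interfaces convert at the boundary, never inside numerical kernels.
"""

# 1 mmHg expressed in mPa: Q [um^3/s] = (pi r^4 / (8 mu L)) [um^3/(mPa s)]
# * MMHG_TO_MPA * dp [mmHg]
MMHG_TO_MPA = 133_322.387_415

UM_TO_CM = 1.0e-4
UM3_TO_CM3 = 1.0e-12
UM3_TO_MM3 = 1.0e-9
MM3_TO_ML = 1.0e-3

#: perfusion conversion: (Q [um^3/s] / V [um^3]) * PERFUSION_FACTOR
#: gives mL blood / 100 mL tissue / min
PERFUSION_FACTOR = 100.0 * 60.0
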