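"""Absolute-scale scattering of pure surfactant micelles.

Builds the fitted SDS micelle geometry (prolate core of alkyl chains plus a
head-group shell), evaluates the core-shell ellipsoid model on absolute
scale and prints the derived quantities a SAXS analysis reports.
"""

import numpy as np

from saxsflow import (
    ContrastSet,
    aggregation_number,
    effective_radius,
    micelle_intensity_absolute,
)
from saxsflow.presets import MICELLE_PRESETS

cs = ContrastSet.from_config()
geo = MICELLE_PRESETS["sds"]

q = np.geomspace(0.005, 0.4, 200)
I = micelle_intensity_absolute(
    q, Rcore=geo["Rcore"], eps=geo["eps"], Dhead=geo["Dhead"],
    C_total=10.0, C_free=2.0, cs=cs, head="sds",
)

short_axis = effective_radius(geo["Rcore"], geo["eps"], theta=0.0)
n_agg = aggregation_number(geo["Rcore"], geo["eps"], cs.v_chain)

print(f"SDS micelle: core long-axis radius {geo['Rcore']:.1f} A, "
      f"axis ratio {geo['eps']:.2f}")
print(f"  core short semi-axis : {short_axis:.2f} A "
      "(long-axis radius x axis ratio; ~length of a C12 chain)")
print(f"  aggregation number   : {n_agg:.1f} "
      "(core volume / 350 A^3 per chain)")
print(f"  I(q=0.005)           : {I[0]:.4f} 1/cm at 8 mM micellised SDS")
print("The forward intensity scales with micelle mass; the oscillation near "
      "q~0.2 1/A reflects the core-shell contrast structure.")
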