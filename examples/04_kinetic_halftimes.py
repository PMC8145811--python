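"""Multi-exponential fitting of a stopped-flow fluorescence trace.

Builds a triple-exponential tryptophan-fluorescence trace of the kind
recorded during SDS unfolding (an overshoot followed by a decay and a slow
rise), adds 1% noise, refits it, and tabulates the half-times.
"""

import numpy as np

from saxsflow import fit_exponentials, halftime_table
from saxsflow.synthetic import simulate_kinetic_trace, trace_truth_from_halftimes

truth = trace_truth_from_halftimes(
    halftimes=(0.23, 0.75, 3.84), amplitudes=(1.0, -0.4, 0.6), offset=1.0
)
t = np.geomspace(0.005, 60, 500)
trace, _ = simulate_kinetic_trace(truth, t, noise_rel=0.01, seed=7)

fit = fit_exponentials(trace, n=3)
auto = fit_exponentials(trace, n="auto")

print("generating half-times: 0.23 / 0.75 / 3.84 s")
print("recovered            : "
      + " / ".join(f"{h:.3f}" for h in sorted(fit.halftimes)) + " s")
print(f"F-test model order   : {auto.n} (three phases are significant at 1%)")
print()
print(halftime_table({"Trp fluorescence": fit}).to_string(index=False))
print("\nHalf-times are ln2/k per component, fastest first; empty cells "
      "mark absent components.")
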