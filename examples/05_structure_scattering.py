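"""Debye-equation scattering of bead models and monomer/dimer fitting.

The native-protein basis of the refolding analysis comes from atomic
structures via the Debye equation. Here synthetic globular bead models
(one bead per residue; use `saxsflow.from_pdb` on real structures) stand
in for the monomeric and dimeric crystal structures: a 77:23 dimer:monomer
mixture is generated with noise and the fractions are recovered.
"""

import numpy as np

from saxsflow import ScatteringCurve, fit_monomer_dimer, guinier_fit
from saxsflow.structures import debye_intensity, synthetic_dimer, synthetic_globule

mono = synthetic_globule(seed=1)   # ~162 residues, 18 A radius
dim = synthetic_dimer(seed=1)

q = np.geomspace(0.008, 0.3, 120)
I_mono = debye_intensity(mono, q, c_mg_ml=2.0)
I_dim = debye_intensity(dim, q, c_mg_ml=2.0)

rng = np.random.default_rng(5)
I_mix = 0.23 * I_mono + 0.77 * I_dim
sigma = 0.01 * I_mix
curve = ScatteringCurve(q=q, I=I_mix + rng.standard_normal(q.shape) * sigma,
                        sigma=sigma)

fit = fit_monomer_dimer(curve, I_mono, I_dim)
g = guinier_fit(ScatteringCurve(q=q, I=I_mono, sigma=0.01 * I_mono))

print(f"monomer bead model : {len(mono.b)} beads, "
      f"coordinate Rg = {mono.rg:.1f} A, Guinier Rg = {g.Rg:.1f} A")
print(f"generated mixture  : 77% dimer / 23% monomer + 1% noise")
print(f"recovered fractions: {fit.f_dim:.1%} dimer / {fit.f_mono:.1%} monomer "
      f"(chi2_red = {fit.chi2_red:.2f})")
print("Dimers double the forward scattering per mass, so the low-q level "
      "pins the dimer fraction.")
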