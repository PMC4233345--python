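"""Removing the concentration effect from a simulated dilution series.

Interparticle interference suppresses the low-angle intensity in proportion
to the solute concentration.  Three noisy curves at 1, 2 and 4 mg/ml are
scaled together, extrapolated pointwise to zero concentration and merged;
the Rg of the result should match the infinite-dilution truth, while the
apparent Rg of the most concentrated curve is biased low.
"""

import numpy as np

from saskit import curves, dilution, synthio

s = np.linspace(1e-3, 0.4, 400)
base = synthio.sphere_curve(30.0, s, i0=1000.0)     # the c→0 truth
noise = synthio.NoiseModel(relative=0.01, floor=1e-3)
series = synthio.noisy_series(base, [1.0, 2.0, 4.0], k=0.05,
                              noise=noise, seed=1)

print("apparent Rg per concentration:")
for c in series:
    print(f"  c = {c.concentration:g} mg/ml: Rg = {curves.autorg(c).rg:.2f} Å")

merged, report = dilution.automerge(series)
print(f"fit range: s ∈ [{report.fit_range[0]:.3f}, {report.fit_range[1]:.3f}] Å⁻¹, "
      f"merge point s = {report.merge_point:.3f} Å⁻¹")
print(f"extrapolated Rg = {report.rg_extrapolated:.2f} Å "
      f"(linear Rg²-vs-c prediction {report.rg_linear_pred:.2f} Å, "
      f"consistent: {report.rg_consistent})")
print(f"true infinite-dilution Rg = {curves.autorg(base).rg:.2f} Å")
print(f"{int(np.sum(report.info_gain))} low-angle points carry genuine "
      "information beyond any single input curve")
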