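"""Saturation (uptake) and Hill (displacement) binding-curve fits.

Uptake versus concentration follows a Michaelis-Menten-like saturation
I = I_max [S] / (K50 + [S]); competitive displacement of membrane
binding follows a modified Hill curve.  Both are refit from noisy
synthetic data.
"""

import numpy as np

from clusterflim.kinetics import fit_displacement_hill, fit_saturation

rng = np.random.default_rng(2)

conc = np.array([0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0])  # uM
uptake = 100.0 * conc / (2.0 + conc) * (1 + rng.normal(0, 0.02, conc.size))
sat = fit_saturation(conc, uptake)
print(f"saturation fit: I_max = {sat.I_max:.1f} (true 100), "
      f"K50 = {sat.K50:.2f} uM (true 2.0)")

nc = np.geomspace(10, 10000, 10)  # nM competitor
area = 1.0 + (0.1 - 1.0) * nc**1.5 / (200.0**1.5 + nc**1.5)
area *= 1 + rng.normal(0, 0.02, nc.size)
hill = fit_displacement_hill(nc, area)
print(f"displacement fit: K50 = {hill.K50:.0f} nM (true 200), "
      f"n_hill = {hill.n_hill:.2f} (true 1.5)")
print("\nK50 is the half-maximum concentration; n_hill > 1 indicates")
print("cooperative displacement")
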