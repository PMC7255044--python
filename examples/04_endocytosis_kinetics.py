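"""Fit the four-pool transport model to cluster-fraction time courses.

The model chains receptor binding at the membrane (cyan cluster),
capture into caveolae, internalization, and lysosomal accumulation (red
cluster); imaging observes cyan / yellow (both caveolar pools) / red
fractions.  Here a noisy synthetic time course at the experimental
incubation times is refit and the recovered time constants printed.
"""

import numpy as np

from clusterflim.kinetics import fit_kinetics, observed_fractions

true_taus = (8.0, 28.0, 88.0, 107.0)  # minutes
times = np.array([15.0, 45.0, 90.0, 180.0, 270.0])

obs = observed_fractions(true_taus, [1, 0, 0, 0], times)
rng = np.random.default_rng(1)
noisy = np.clip(obs + rng.normal(0.0, 0.05 * np.abs(obs)), 0.0, 1.0)

fit = fit_kinetics(times, noisy, seed=0)
names = ("tau1 (capture)", "tau-1 (back reaction)",
         "tau2 (internalization)", "tau3 (lysosomal transport)")
print("time constant            true    fitted   SE")
for name, want, got in zip(names, true_taus, fit.taus()):
    se = fit.stderr[["tau1", "tau_m1", "tau2", "tau3"][names.index(name)]]
    print(f"{name:24s} {want:6.1f}  {got:7.1f}  {se:6.1f}")
print("\n(the back-reaction constant is weakly identified from five time")
print(" points, which its larger standard error reflects)")
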