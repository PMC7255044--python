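"""Cluster a simulated FLIM image and inspect the lifetime signatures.

Simulates a three-species image (fast / intermediate / slow decays drawn
from the 0.20-1.53 ns validation panel), runs the cluster analysis, and
prints per-cluster photon fractions and moment lifetime estimates.
"""

import numpy as np

from clusterflim import cluster_flim, render_false_color
from clusterflim.synthetic import (
    block_layout,
    fig2_species_panel,
    gaussian_irf,
    simulate_image,
)

species = fig2_species_panel(5)[::2]  # 0.20, 0.865, 1.53 ns mean lifetimes
layout = block_layout(3, shape=(64, 64), mean_counts=300.0)
irf = gaussian_irf(512, 19.97, t0=300.0, fwhm=100.0)
cube, truth = simulate_image(species, layout, irf=irf, n_channels=512, seed=1)

result = cluster_flim(cube, k=3, b=64, min_counts=10, seed=1)

print("cluster  fraction  pixels  ~mean lifetime (ns)")
for c in range(result.k):
    print(
        f"{c:7d}  {result.fractions[c]:8.3f}  {result.member_counts[c]:6d}"
        f"  {result.mean_lifetimes_ns[c]:8.3f}"
    )
agreement = (result.labels == truth)[result.labels >= 0].mean()
print(f"\npixel-label agreement with ground truth: {agreement:.3f}")
print("(clusters are ordered by ascending lifetime, so labels align with")
print(" the simulated species; each fraction is that cluster's share of")
print(" the image's photons)")

rgb = render_false_color(result)
print(f"false-color image shape: {rgb.shape} (cyan/yellow/red + white mask)")
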