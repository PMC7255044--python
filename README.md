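# clusterflim

Fitting-free analysis of time-correlated single-photon-counting (TCSPC)
FLIM images by clustering per-pixel fluorescence decay histograms.

## The problem

In fluorescence lifetime imaging, every pixel holds a photon-arrival
histogram — typically 1024 time channels of ~20 ps — with only tens to a
few hundred photons.  Classical per-pixel multi-exponential fitting needs
~10⁴ photons per pixel to be reliable, which costs acquisition time and
light dose that live cells cannot afford.  `clusterflim` instead groups
pixels whose decay *shapes* match: the image's N decay histograms
x′₁,…,x′_N (rebinned to b time bins and normalized to unit area) are
partitioned by k-means under the Euclidean distance
D = √Σⱼ(xᵢⱼ − x_cⱼ)², and all photons of each cluster are accumulated
into one high signal-to-noise **fluorescence lifetime signature (FLS)**
per cluster — obtained without fitting anything.  Pixel labels are then
sharpened by reassigning each pixel to the cluster whose FLS gives its
photon counts the highest Poisson likelihood.  The false-color cluster
image maps distinct molecular microenvironments (e.g. receptor-bound at
the membrane, caveolar, lysosomal) at single-pixel resolution from tens
of photons per pixel.

Around that core the package provides the quantitative machinery an
uptake/interaction study needs:

- **decayfit** — Poisson maximum-likelihood fitting of an FLS with
  I(t) = Σᵢ αᵢ e^(−t/τᵢ) convolved with the instrument response, plus
  the derived mean lifetimes τ_m,a = Σ αᵢτᵢ and τ_m = Σ βᵢτᵢ with
  βᵢ = αᵢτᵢ / Σ αⱼτⱼ.
- **synthetic** — a generative FLIM simulator (multi-exponential
  species, Gaussian IRF, Poisson noise) with a validation panel of
  biexponential species spanning 0.20–1.53 ns mean lifetime.
- **validation** — per-class sensitivity TP/(TP+FN) and specificity
  TN/(TN+FP) versus ground truth after optimal (Hungarian) label
  matching, as a function of photon budget.
- **kinetics** — a four-pool first-order model of nanocarrier
  endocytosis (membrane receptor ⇌ membrane caveolae → cytoplasmic
  vesicles → lysosomes) fit to cluster-fraction time courses; plus
  Michaelis-Menten-like saturation and modified-Hill displacement fits.
- **coloc** — Manders' M1/M2 colocalization with Costes automatic
  thresholding.
- **workflow** — a config-driven assessment pipeline (cluster → match
  clusters across a series → quantify fractions → threshold rule →
  verdict) with deterministic JSON/CSV/PNG outputs.

## Worked example

```python
from clusterflim import cluster_flim
from clusterflim.synthetic import (
    block_layout, fig2_species_panel, gaussian_irf, simulate_image)

species = fig2_species_panel(5)[::2]      # 0.20, 0.865, 1.53 ns
layout = block_layout(3, shape=(64, 64), mean_counts=300.0)
irf = gaussian_irf(512, 19.97, t0=300.0, fwhm=100.0)
cube, truth = simulate_image(species, layout, irf=irf, n_channels=512, seed=1)

result = cluster_flim(cube, k=3, b=64, min_counts=10, seed=1)
for c in range(result.k):
    print(c, round(result.fractions[c], 3), round(result.mean_lifetimes_ns[c], 3))
```

prints (cluster id, photon fraction, moment lifetime estimate in ns):

```
0 0.328 0.132
1 0.328 0.577
2 0.344 1.027
```

Three clusters of equal photon share, ordered fastest (cyan) to slowest
(red); at 300 counts/pixel the pixel-label agreement with the simulated
ground truth is 1.000.  The moment estimates order the clusters; exact
lifetimes come from `fit_multiexp` on each accumulated FLS.  The
`examples/` directory has one short script per capability
(`python examples/01_cluster_image.py`, …), and the `clusterflim` CLI
wraps the same functions for shell use
(`clusterflim cluster --input cube.h5 --k 3 --out prefix`).

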