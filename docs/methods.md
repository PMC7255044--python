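# Methods

## Data model

A FLIM acquisition is a cube of non-negative integer photon counts
indexed `(row, col, time_channel)`.  Time channel `k` covers the
half-open interval `[k·Δt, (k+1)·Δt)` ps; the default calibration is
1024 channels × 19.97 ps (a TCSPC module at a ~19.5 MHz excitation
rate).  HDF5 (`/counts` + attributes) is the canonical container;
multi-page TIFF with a JSON sidecar is supported for interoperability,
and Becker & Hickl `.sdt` files are read through an optional adapter
when the `sdtfile` package is installed.  Rebinning the time axis
aggregates contiguous channels and sends any remainder channels to the
last bin, so integer photon totals are conserved exactly — a property
the test suite asserts without tolerance.

## Cluster analysis

Pixels below a minimum photon total (default 10 counts) are masked and
take no part in the analysis.  Remaining decays are rebinned to `b`
time bins (default 64) and normalized to unit area, which removes
brightness and leaves decay shape.  The partition is obtained in three
stages:

1. **k-means** (k-means++ initialization, best of 10 restarts, center
   tolerance 1e-6) on the square root of the unit-area histograms.
   The sqrt maps the Poisson channel noise to near-constant variance,
   so the algorithm's Euclidean metric acts as a Hellinger distance
   between decay distributions instead of being dominated by the bright
   early channels.  Optionally the initial features are averaged over a
   small spatial window (3×3 by default): at tens of photons per pixel
   the aggregated decays seed far more accurate signatures, while the
   final labels (stage 3) remain strictly per-pixel.
2. **FLS accumulation** — all photons of each cluster's pixels are
   summed channel-wise at full time resolution.  Cluster photon totals
   partition the unmasked photon total exactly.
3. **Poisson refinement** — each pixel is reassigned to the cluster
   under whose normalized FLS its photon counts are most probable
   (multinomial log-likelihood, half-count floor on empty channels),
   and the FLSs are re-accumulated; iterated to a fixed point (≤ 50
   rounds).  This uses the method's own high-SNR object — the FLS — as
   the per-cluster template and the exact counting-noise model, while
   staying free of per-pixel curve fitting.  On the synthetic
   validation panels the refined partition operates within ~1
   percentage point of the Bayes-optimal classifier that knows the true
   decay curves; plain Euclidean assignment on normalized counts loses
   6–8 points at 90–170 counts/pixel.

Clusters are ordered by ascending amplitude-weighted mean lifetime,
estimated by a fast moment method (background-subtracted first moment
of arrival time past the peak), and colored cyan → yellow → red →
further colors; masked pixels render white.  `normalize=False`,
`hellinger=False`, `init_smooth=1` and `refine=False` restore the
plain k-means-on-raw/normalized-histograms behavior.  Across an image
series, cluster identities are kept consistent by optimal assignment
between unit-area FLSs against a reference image.

k is user-supplied; `scan_k` reports silhouette and seed-stability
(adjusted Rand index) over a k range as selection diagnostics.

## Decay fitting

An FLS is fit with I(t) = Σᵢ αᵢ e^(−t/τᵢ) (n = 1…4) convolved linearly
(no wrap-around) with the instrument response, plus a flat background,
by maximizing the Poisson likelihood — FLS channels span several
decades and Gaussian-weighted least squares biases the low-count tail.
Component scales, lifetimes and background are optimized on the log
scale (L-BFGS-B) with lifetime bounds [0.01, 20] ns and multi-start
over decade-spaced lifetime grids plus a moment-based start.  Standard
errors come from the finite-difference observed information; a
Poisson-weighted reduced χ² is reported for comparability.  Derived
quantities: τ_m,a = Σ αᵢτᵢ, βᵢ = αᵢτᵢ/Σ αⱼτⱼ, τ_m = Σ βᵢτᵢ, with the
invariant τ_m,a ≤ τ_m.  A BIC helper compares component counts.  The
IRF is an analytic Gaussian (FWHM 100 ps default, bin-integrated) or a
measured per-channel vector.

## Synthetic data

The generator draws each pixel's channel counts as independent Poisson
variables around the IRF-convolved multi-exponential decay, scaled so
the decay part sums to the requested mean counts per pixel, plus a flat
background rate.  Per-pixel totals therefore fluctuate around the mean,
as in a counting experiment; repetition-period wrap-around of slow
tails is omitted (at ≤ ~2 ns lifetimes and ~51 ns excitation period the
carried-over tail is negligible) so closed-form oracles hold exactly.
The validation panel (`fig2_species_panel`) provides 4 or 5
biexponential species whose amplitude-weighted mean lifetimes are
evenly spaced over 0.20–1.53 ns — the span of the dye environments in
the original titration design.  Each species uses amplitudes (0.5, 0.5)
and components at 0.5× and 1.5× its target mean lifetime: a one-line,
documented rule that makes every species genuinely biexponential while
pinning the mean lifetime exactly.  Because all panel members come from
this single two-parameter family, they are, if anything, harder to
distinguish than chemically distinct microenvironments whose decay
shapes differ more freely — passing the discrimination targets on this
panel is a conservative in-silico statement and not a claim about any
specific real sample.  What the simulator does not model: detector
afterpulsing, dead time, pile-up, spatially varying IRF, or correlated
background.

## Validation scoring

Unsupervised cluster ids are matched one-to-one to species by
maximizing the confusion-matrix diagonal (Hungarian assignment), then
sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are computed
one-vs-rest per class and macro-averaged.  Layouts are balanced
equal-area blocks, so class prevalence does not distort specificity and
per-class and macro rates coincide in expectation.  The titration runs
5 replicate 128×128 images per photon-budget level with
seed-derived sub-seeds; the discrimination targets use the same
machinery end to end.

## Kinetics

The transport model is the closed first-order chain

    c ⇌ y_pm → y_cp → r        (rates 1/τ₁, 1/τ₋₁, 1/τ₂, 1/τ₃)

whose linear ODE system is solved exactly by the matrix exponential
(`expm`); an LSODA integration is kept as an independent cross-check
(agreement asserted to 1e-8).  Because imaging cannot generally
separate the two caveolar pools, fitting targets the observable triple
(cyan, yellow_total, red) by default, with a four-channel option when
membrane/cytoplasm segmentation is available.  Fractions (not absolute
intensities) are fit, removing photobleaching and intensity scale.
Time constants are optimized in log space by Levenberg-Marquardt least
squares with multi-start (one literature-informed start plus random
log-uniform starts over 1–300 min); the initial state defaults to all
material receptor-bound, (1, 0, 0, 0).  Standard errors come from the
Jacobian at the optimum.  With five observation times the back-reaction
constant τ₋₁ is weakly identified; its large standard error and wide
replicate spread reflect that honestly (medians over replicates remain
unbiased).

Saturation uptake is fit as I = I_max·[S]/(K₅₀+[S]) and displacement as
A = A_max + (A_min−A_max)·[S]ⁿ/(K₅₀ⁿ+[S]ⁿ) with the Hill coefficient
free (or pinned via `fix_n`), both by bounded nonlinear least squares.

## Colocalization

Thresholds follow the Costes procedure: an orthogonal (total least
squares) regression B ≈ a·A + b is walked down A's intensity quantiles
until the Pearson correlation of pixels below both thresholds is ≤ 0 or
undefined.  Manders' coefficients then use
M1 = Σ A[A>T_A ∧ B>T_B] / Σ A[A>T_A] (and symmetrically M2): the
numerator is the channel's own above-threshold signal gated by the
partner's threshold, which guarantees 0 ≤ M ≤ 1, exact channel-swap
symmetry, and invariance to scaling either channel.  Costes
randomization significance testing is not implemented.

## Workflow

`run_workflow` consumes a YAML/dict config (inputs, k, bins,
min_counts, seed, assessment rule), clusters every cube, matches
clusters across the series to the first image, quantifies
photon-weighted fractions (pixel-weighted behind a flag), applies the
threshold rule (e.g. "red ≥ 0.90"), and writes report.json,
fractions.csv, per-image FLS CSVs and false-color PNGs.  Outputs embed
a config digest, the seed and the package version, and identical
config+seed reruns are byte-identical (asserted in the tests).

## Problem sizes and defaults

Validation images are 128×128 pixels × 1024 channels with 5 replicates
per condition (the full titration of the original design); unit tests
use 48×48 × 256-channel images and the acceptance run completes in
about a minute on one core.  Key defaults: b = 64 feature bins,
min_counts = 10, k-means restarts = 10, IRF FWHM 100 ps at t₀ 500 ps,
lifetime bounds [0.01, 20] ns, kinetic noise model 5% multiplicative
Gaussian with 50 replicates.

## Known limitations

- The refinement step assumes cluster-homogeneous decay shapes; a
  continuum of environments violates that and will be quantized.
- Cluster count k is an input, not an inference.
- At ≤ 40 counts/pixel the 4-species macro sensitivity is photon-limited
  (~85–88% even for the Bayes classifier); only specificity reaches the
  95% operating point there.
- The SDT reader depends on the optional `sdtfile` package and is not
  exercised by the test suite.
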