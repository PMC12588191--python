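# Methods

`preictal` implements an unsupervised, CPU-only workflow for discovering
quasi-stable microstates in pediatric pre-seizure scalp EEG, together with a
synthetic cohort generator that makes every stage testable without clinical
recordings. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic experiments do and do
not demonstrate about real data.

## The analysis model

The unit of analysis is a 5-s, 18-channel segment cut from a 30-s window that
ends at a clinically annotated seizure onset. Windows abut the onset by
default (`gap_s = 0`, configurable); segmentation is 0-based and half-open,
so segment *i* covers samples `[i·5·fs, (i+1)·5·fs)` and a 30-s window yields
exactly six segments. The default montage is the 18-derivation longitudinal
bipolar ("double banana") layout; nothing in the code depends on that choice
beyond the channel count, and the frontal derivations (FP1-*, FP2-*) are the
ones searched for ocular artifacts.

Each segment is mapped to an 80-feature-per-channel vector
(18 × 80 = 1,440):

| block | count | content |
|---|---|---|
| time statistics | 8 | mean, population variance, Fisher skewness, excess kurtosis, RMS, peak-to-peak, zero-crossing rate, line length (mean first difference) |
| Hjorth | 3 | activity, mobility √(var Δx / var x), complexity |
| spectral | 18 | absolute and relative power in δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz; total power; normalized spectral entropy; 95 % spectral edge; peak and median frequency; θ/α, δ/β, (δ+θ)/(α+β) ratios |
| entropies | 3 | sample entropy (m = 2, r = 0.2 σ), permutation entropy (order 3, delay 1, normalized), histogram Shannon entropy (10 equal-width bins, normalized) |
| wavelet | 48 | db4, 5-level periodized DWT; per subband (cA5, cD5 … cD1): mean, SD, mean |c|, energy, relative energy, max |c|, skewness, kurtosis |

The literature this workflow follows never enumerates its feature vector
beyond the family names and the total dimensionality; the composition above
is this package's declared canonical layout and is fully driven by
`FeatureConfig`, so alternative inventories remain expressible. Spectral
quantities use Welch's method with 2-s Hamming windows at 50 % overlap
(0.5 Hz resolution). The contiguous bands tile the 0.5–45 Hz analysis range
with half-open intervals, the topmost band closing at 45 Hz so relative
powers sum exactly to 1.

Degenerate inputs never produce non-finite features: constant signals map
skewness/kurtosis/entropies to 0, all-zero signals map relative powers and
ratios to 0, and sample entropy returns 0 when no template matches exist at
either length.

Sample entropy is the computational hot spot (it is quadratic in the 1,280
samples of a segment). The packaged kernel is an exact O(n²) count
reorganized as a sorted sweep over the first template coordinate and
JIT-compiled with numba; tests pin it against a naive pairwise oracle.

## Preprocessing and artifact accounting

The cleaning path is: high-pass at 0.5 Hz (zero-phase 4th-order Butterworth,
applied forward–backward), FastICA decomposition of the window, removal of
flagged artifact components, then per-channel z-scoring (population SD) and
the 0.5–45 Hz band-pass. ICA runs *before* the low-pass edge on purpose:
mains interference sits above 45 Hz, and cleaning it with ICA — rather than
letting the band-pass absorb it — is what makes the before/after artifact
report meaningful in microvolts.

Component flags are declared, configurable rules (there is no standard):

* **blink**: mixing-column loading fraction on frontal channels > 0.6, source
  excess kurtosis > 5, and > 50 % of source power below 5 Hz;
* **line**: > 30 % of source power within ±1 Hz of the mains frequency
  (default 50 Hz, configurable to 60 Hz).

FastICA on EEG-like data contains a large near-Gaussian subspace in which the
symmetric rotation criterion cannot settle, so the iteration limit is
routinely reached even though the spiky blink and sinusoidal line components
separate within a few iterations. The fitter therefore *warns* on
non-convergence by default; `on_nonconvergence="raise"` restores a hard
error.

Artifact burden is quantified two ways:

* **line-noise amplitude** — median over channels of the mean single-sided
  DFT amplitude (rectangular window, 2/N normalization) across the
  mains ± 1 Hz band. Note this is a *band-mean*: a pure tone of peak
  amplitude A concentrated in one bin of a 30-s window reads ≈ A/61.
* **blink rate** — positive excursions of the 0.5–5 Hz-filtered frontal-mean
  signal beyond 4 MAD-based robust SDs, at least 0.5 s apart, normalized to
  a per-30-s rate. The robust SD is estimated per 2.5-s block (floored by
  the whole-window MAD) because slow state-dependent drift in background
  delta power otherwise masquerades as blinks; a 0.5-s edge guard excludes
  the zero-phase filter's boundary transients, and only positive peaks are
  counted because blinks deflect frontal derivations positively while the
  high-pass filter's undershoot is negative.

Percent changes are reported signed, `−100·(pre−post)/pre`, so a reduction
prints as a negative Δ, matching how such tables are usually typeset.

## Reduction and clustering

Features are column-standardized (zero-variance columns dropped with a
warning — mixed-unit features make this mandatory), then projected onto the
smallest number of principal components whose cumulative explained variance
reaches 95 %. The retained scores are embedded in 2-D with UMAP
(`n_neighbors = 15`, `min_dist = 0.1`, Euclidean, fixed seed recorded in all
outputs). PCA pools all subjects; the embedding is for the cohort.

K-Means (k-means++ starts, best of 10 by inertia) is scanned over k = 2..10.
Two diagnostics are computed: the elbow of the inertia curve, defined as the
interior k maximizing the second difference (the curve is computed from
k = 1 so k = 2 is eligible), and the mean silhouette, smallest k winning
ties. When they disagree the silhouette choice wins and a warning is logged.
On smooth convex inertia curves the second-difference elbow systematically
lands at small k (2–3), so disagreement is the norm on the synthetic preset;
the silhouette maximum is the operative criterion.

Internal validity is reported as Silhouette, Davies–Bouldin, and
Calinski–Harabasz, computed in the 2-D embedding space (configurable).
Davies–Bouldin raises on coincident centroids; Calinski–Harabasz returns
`inf` when the within-cluster scatter is exactly zero. Clusters with fewer
than 20 members (strict: exactly 20 survives) are relabeled −1 and *kept* in
every output with a removal mask; metrics are recomputed on the retained
points. DBSCAN (eps from the knee — maximum smoothed second difference — of
the sorted k-distance curve with k = 2·dim, `min_samples = 5`) and
Ward-linkage agglomerative clustering provide baselines on the same
embedding.

## Transition dynamics

Within each window the six segment labels form a sequence; consecutive pairs
are transitions. Transitions never span window boundaries, and filtered
(−1) segments break adjacency rather than bridge it. A "moving average" of
categorical labels is undefined, so smoothing is declared as: one-hot encode,
average over a trailing window of 2 segments, re-discretize by argmax,
ties resolved in favor of the previous smoothed label, first element
unchanged. Two consequences worth knowing: single-segment flickers are
removed, and a genuine state change is delayed by exactly one segment
(the window ties at the change point). Smoothing provably never increases
the label-change count, and the report asserts it. Transition counts are
row-normalized into a stochastic matrix; rows without outgoing transitions
stay all-zero.

## The synthetic cohort generator

The generator emulates the study conditions so that recovery of planted
structure is a meaningful end-to-end check:

* **cohort shape** — 12 subjects × 8 windows (96 windows → 576 segments) by
  default; the k-recovery preset uses 25 × 8 = 200 windows.
* **latent states** — a 4-state Markov chain advancing only at 5-s segment
  boundaries (each segment has one ground-truth state). Default profiles
  (δ, θ, α, β, γ relative power): α-dominant (.05 .08 .65 .17 .05),
  θ-dominant (.10 .70 .10 .07 .03), δ-dominant slow-wave
  (.70 .15 .07 .05 .03), β/γ-dominant (.05 .08 .12 .45 .30). The chain has
  self-transition 0.5, elevated flow into the slow-wave state
  (P(0→2) = P(1→2) = 0.3), and a suppressed P(3→0) = 0.02.
* **signal model** — per segment, one unit-variance band-limited Gaussian
  source per band, shared across channels through per-channel gains
  (inducing realistic inter-channel correlation), scaled by the square root
  of the state's band weight and a 30 μV rhythm RMS; plus per-channel 1/f
  background (12 μV RMS, exponent 1) band-limited to 45 Hz so the mains
  region stays clean unless line noise is planted.
* **artifacts** — blinks as 300-ms raised-cosine bumps (200 μV, a mid-range
  clinical blink amplitude) on the four frontal derivations at a Poisson
  rate of 3.4 per 30 s; mains line noise as a 50 Hz sinusoid whose peak
  amplitude is calibrated by the DFT bin count of the band so that the
  *measured* band-mean amplitude equals the nominal 2.6 μV parameter. Both
  defaults equal the pre-cleaning artifact burden of the clinical setting
  this emulates.
* **inter-subject variability** — per-subject channel gains jittered by 10 %
  (plus 5 % per band).

What the generator deliberately does **not** model: within-segment state
changes, epileptiform spikes, muscle/movement artifact, electrode pops,
developmental drift of rhythms, or volume-conduction topography. Passing the
end-to-end tests therefore demonstrates that the pipeline recovers *cleanly
planted* spectral states at realistic SNR — not that four microstates exist
in any particular clinical recording.

## Numerical choices and problem sizes

* All randomness flows through explicit seeds; UMAP is run with a fixed
  `random_state`, making full-pipeline outputs byte-identical across reruns.
* Filters are SOS Butterworth run through `sosfiltfilt` (zero phase, squared
  magnitude response); linearity and band edges are property-tested.
* The EDF writer quantizes to 16 bits against per-channel physical ranges
  printed into the header, so a round-trip is exact to one digital step.
* Validity metrics, K-Means, DBSCAN, Ward, PCA, and UMAP are delegated to
  scikit-learn/umap-learn; the test suite pins each against independent
  brute-force oracles (hand-computed instances and O(n²) reimplementations).
* The k-recovery experiment runs 20 replicates of the 200-window preset
  (1,200 segments each) with z-score + band-pass preprocessing; per-window
  ICA cleaning is exercised in its own experiments. These sizes keep one
  replicate at roughly half a minute on one CPU while leaving the selection
  statistics stable.

## Known limitations

* The blink detector is amplitude-threshold-based; it under-counts blinks
  closer than 0.5 s (they merge) and is blind to blinks that are atypically
  small relative to frontal background.
* The trailing-window smoother delays genuine transitions by one segment;
  with 6-segment windows this is visible in transition counts.
* The elbow diagnostic's max-second-difference definition prefers small k on
  smooth inertia curves; it is reported for transparency but the silhouette
  criterion decides.
* Validity metrics computed in the 2-D embedding inherit UMAP's distortions;
  the metric space is configurable but the defaults mirror the published
  workflow.
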