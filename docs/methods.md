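# Methods

## The pipeline

`dbfn` implements an EEG affective-analysis pipeline built on *dynamic brain
functional networks*: graphs whose nodes are electrodes and whose edges encode
statistical dependence between channel signals, recomputed on successive short
time windows so that the second-scale reconfiguration of cortical coupling is
retained rather than averaged away.

Given one trial (channels × samples at sampling rate `fs`):

1. **Band decomposition.** Each channel is convolved with one complex Morlet
   wavelet per rhythm — theta 4–8 Hz, alpha 8–12 Hz, beta 12–32 Hz, gamma
   32–42 Hz. The amplitude envelope `A_b(t)` is the modulus of the analytic
   signal, the instantaneous phase `φ_b(t)` its argument.
2. **Inter-band difference signals.** For each of the 6 unordered band pairs
   (named higher band first: `alpha_theta`, …, `gamma_beta`) the per-channel
   amplitude difference `A_hi − A_lo` and wrapped phase difference
   `wrap(φ_hi − φ_lo)` are formed: 12 difference signals per trial.
3. **Windowing.** Each difference signal is cut into contiguous,
   non-overlapping windows of `t ∈ {1, 3, 6, 10}` s (dynamic) or a single
   60 s window (static); a 60 s trial yields `60/t` windows per signal.
4. **Connectivity.** Per window, the mutual information
   `MI_xy = H_x + H_y − H_xy` (nats) is estimated between every channel pair
   from equal-width histograms; the matrix diagonal carries the marginal
   entropies `H_x`.
5. **Positional thresholding.** All `n²` matrix entries (diagonal included)
   are sorted ascending and the element at 1-based rank `⌊q·n²⌋` is the
   threshold (`q = 0.3` on 32 channels → rank 307 of 1024). Entries strictly
   above it become edges; ties are discarded; the diagonal is zeroed. The
   threshold is per matrix, not global, because absolute MI levels vary
   strongly across individuals.
6. **Graph attributes.** Each binary network contributes the feature block
   `[E_g, E_loc(1..n), C(1..n)]` of length `1 + 2n` (65 on 32 channels):
   global efficiency (mean inverse shortest path over ordered pairs, with
   `1/∞ = 0`), Latora–Marchiori local efficiency (global efficiency of each
   node's neighbour-induced subgraph), and the clustering coefficient. The
   characteristic path length `L_p` is computed for diagnostics only: it is
   undefined on disconnected graphs, which thresholding routinely produces,
   so it never enters feature vectors. A trial analysed at window length `t`
   yields `12 · (60/t) · (1 + 2n)` features, ordered signal-major then
   window-minor.
7. **Selection and classification.** Greedy mRMR (MID variant: relevance
   minus mean redundancy, on 3-level quantile-discretized features,
   lowest-index tie-break) selects `k` columns using training rows only.
   Classification is a repeated protocol: per repetition, z-scoring on
   training statistics, a grid search over SVM kernel ∈ {linear, rbf} and
   `C ∈ {2⁻⁵, 2⁻³, …, 2⁵}` scored by stratified 5-fold CV accuracy on the
   training set with a repeat-specific fold seed, a refit on the full
   training set, and test-class probabilities; final probabilities are the
   mean over repetitions and hard labels their arg-max.

Three evaluation designs probe increasingly hard generalization:
subject-dependent (per-subject stratified 3:1 trial split), subject-
independent (leave-one-subject-out), and subject-and-trial-independent (per
held-out subject, a seeded random half of the trial indices is tested; the
other subjects train only on the complementary indices, so no trial index
appears on both sides). Paired per-subject accuracies are compared with a
two-sided Wilcoxon signed-rank test (zero differences discarded; an all-tie
comparison is flagged degenerate).

## Parameters that matter

| Parameter | Default | Meaning / rationale |
|---|---|---|
| bands | 4–8, 8–12, 12–32, 32–42 Hz | the four rhythms analysed |
| Morlet spectral SD | (high − low)/4 | ≈95% of wavelet energy inside the band; one kernel per band |
| window length `t` | 1 s (plus 3/6/10/60) | temporal resolution of the dynamic networks |
| histogram bins | 8 | 128-sample windows at t = 1 s make finer binning unstable |
| threshold position `q` | 0.3 (0.5, 0.7 available) | fraction of sorted entries below the cutoff |
| mRMR `k` | 256 | selected feature count; features ≫ trials, so selection strength is an honest tuning knob |
| mRMR bins | 3 | quantile levels for selection MI |
| SVM grid | {linear, rbf} × C ∈ 2^{−5..5} | `gamma="scale"` for rbf (variance-scaled heuristic) |
| repetitions | 100 (5 in the test-bench) | probability-averaging repeats |

## Numerical choices

- **Histogram binning** is equal-width over each channel's own `[min, max]`
  per window, which makes MI invariant to per-channel affine gain; constant
  channels have zero entropy by the `0·ln 0 = 0` convention.
- **Threshold ties** go to the discard side (strictly-greater retention), so
  an all-equal matrix yields an empty graph and edge counts are never
  inflated; the 1-based `⌊q·n²⌋` rank convention uniquely reproduces rank 307
  at `q = 0.3`, `n = 32`.
- **Local efficiency** follows the standard neighbours-only subgraph; the
  variant including the node itself is available via `include_node=True`.
- **Phase differences** are wrapped to (−π, π] (disable with
  `wrap_phases=False`); wrapping keeps phase semantics under subtraction.
- **Edge handling** in the wavelet convolution is reflect-padding of one
  wavelet half-length, so outputs are length-preserving and deterministic.
- **Entropy summations** are performed over sorted probability vectors, so
  MI is bit-exact symmetric and MI with a constant is exactly zero.
- The batched graph-metric path (boolean matrix-product BFS, batched
  neighbour-subgraph efficiency, triangle counting via `diag(A³)`) is
  algebraically identical to the per-graph definitions; the test-bench pins
  it to a literal Floyd–Warshall + triple-loop oracle at 1e-12 and to
  networkx.
- Reported `mean ± std` uses the population SD (`ddof = 0`) over subjects and
  is always recomputable from the stored per-subject list.
- Degenerate inputs: disconnected pairs contribute zero efficiency; nodes of
  degree < 2 have zero local efficiency and clustering; a disconnected graph
  reports `L_p = ∞` with a `connected=False` flag.

## The synthetic study

Real affective EEG corpora are access-restricted, so the package ships a
generator whose output exercises every pipeline stage with known ground
truth. Each channel carries unit-variance *broadband* Gaussian background
(FFT-masked white noise spanning 4–42 Hz, mirroring the broadband character
of scalp EEG); every planted edge adds a shared source band-limited to the
coupled rhythm at mixing weight `w` to both endpoints; white measurement
noise is added throughout. Mutual information provably detects
shared-source mixing, which is why this coupling model was chosen over
phase coupling. Because only a small fraction of background power falls
inside any one rhythm, wavelet filtering isolates the coupled band at high
SNR — a narrowband background concentrated in the coupled band would cap
the in-band correlation and starve the band-difference features of signal.
A `community_sources` option replaces per-edge sources with one latent
source per connected component (a synchronizing assembly), which keeps
pairwise correlations from diluting as node degrees grow.

Coupling can be made *non-stationary*: each source is switched by an
independent Bernoulli gate resampled every `gate_s` seconds with duty cycle
`gate_duty`, modelling transient synchronization episodes — the regime
dynamic network analysis exists for: a 60 s static window blurs the
episodes into their time average, while second-scale windows resolve them
at full strength.

The standard recovery fixture (`two_class_fixture`) has 6 subjects × 20
trials × 16 channels × 60 s at 128 Hz. A 16-channel montage is enough to
embed two clearly distinct coupling graphs while keeping the full-pipeline
test-bench desk-scale. The two classes share band (alpha), strength (0.8),
noise (0.3) and gating (1 s segments, 50% duty) and differ **only** in
planted-edge density: 2 edges versus a 28-edge clique on half the channels.
Ratings are drawn on the correct side of the 5-point midpoint so label
binarization recovers the class. Inter-subject variability is emulated by
log-normal per-subject gain and noise-floor multipliers (the gain is
invisible to the affine-invariant MI estimator by design; the noise floor is
not), which opens the usual gap between within-subject and cross-subject
protocols.

What passing recovery tests show: the full pipeline — decomposition,
windowed MI, positional thresholding, graph features, mRMR, SVM — transmits
planted connectivity-density differences across held-out subjects, and the
windowed networks at both tested lengths outperform the single static
network. What they do not show: performance on real EEG, whose coupling is
neither band-pure nor shared-source, whose artifacts and non-stationarities
are far richer, and whose class structure is vastly weaker. One estimator
property is worth knowing: at the shortest window (128 samples) the
histogram-MI estimate pays a variance penalty, so on this synthetic data
the 10 s windows classify at least as well as the 1 s windows; the gain the
1 s resolution buys on real recordings rests on temporal structure this
generator does not attempt to reproduce.

## Problem sizes in the test-bench

The shipped suite runs the full pipeline at window lengths 1/10/60 s on the
6 × 20 × 16 fixture with 5-repetition probability averaging and `k = 256`
(protocol mechanics are additionally exercised on a 3 × 8 × 8 study at
t = 10 s). These sizes keep a complete from-scratch run of every stage —
synthesis, feature extraction, three protocols, ablations — in the minutes
range while leaving all estimator settings at their defaults.

## Known limitations

- The histogram MI estimator is biased upward at short windows; the bias is
  common to all pairs and largely removed by per-matrix positional
  thresholding, but MI values themselves are not bias-corrected.
- Positional thresholding fixes the edge *count* per network, so class
  information must reside in edge placement and its temporal variability,
  not in overall density — as with the per-matrix thresholds it mirrors.
- The Morlet bandwidth rule, histogram bin counts, mRMR variant and `k`, and
  the SVM grid are documented conventions; none is fitted to data.
- `L_p` is reported only with its connectivity flag; downstream users should
  not average it across thresholded (often fragmented) networks.
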