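# Methods

This note records the models, the defaults and the design choices behind
`freqec`, and what the synthetic benchmarks do and do not establish.

## Signal model and band decomposition

Component time courses are treated as superpositions of narrowband
oscillations plus noise. EMD extracts intrinsic mode functions by iterated
sifting: cubic-spline envelopes through the local maxima and minima (two
extrema mirrored beyond each boundary), subtraction of the envelope mean,
repeated until a Cauchy-type criterion Σ(h_prev − h)²/Σh_prev² < 0.2 **and**
the IMF condition |#extrema − #zero-crossings| ≤ 1 hold, capped at 50 sifts
per mode. Mode extraction stops when the residue has fewer than two interior
extrema (monotonic remainder) — a signal with no oscillatory structure yields
zero modes and itself as residue.

CEEMDAN follows the stage-wise adaptive-noise scheme: an ensemble
(default 100) of unit-variance noise realizations is fully EMD-decomposed
once; at stage k the k-th noise mode, scaled by `noise_sd` (default 0.2)
times the current residue's standard deviation, perturbs the residue before
the stage mode is averaged across the ensemble. The final residue is defined
as the remainder, so reconstruction is exact by construction. `noise_sd = 0`
collapses to plain EMD (logged). Defaults cap the decomposition at 5 modes
plus residue — at TR = 2 s five orders already reach the sub-0.01 Hz range.

**Hilbert weighted frequency.** Each mode's analytic signal gives amplitude
a(t) and unwrapped phase; the instantaneous frequency is the discrete phase
derivative over 2π. HWF is the amplitude-weighted time average with squared
amplitude (power) weights by default (`weighting="amplitude"` switches to
linear weights), excluding the first and last 5% of samples to suppress
Hilbert end effects, clipped to [0, Nyquist]. On white noise the per-order
HWF medians form a near-dyadic ladder (ratios ≈ 2 between successive orders),
the filter-bank behaviour the band derivation relies on.

**Frequencies of interest.** Per mode order, the band is the central
`ci_level` (default 95%) interval of the pooled HWF distribution across
subjects and components, trimming extreme values; bands are reported in
descending frequency order (FOI-1 highest). Because no voxel-level data is in
scope, pooling is over component time courses rather than gray-matter voxels.
The conventional 0.01–0.08 Hz band (FOI-N) is defined by fixed cutoffs, so it
is realized by a zero-phase 4th-order Butterworth band-pass rather than mode
membership. Band-limited signals for the data-driven FOIs are, by default,
the sum of the modes whose HWF falls inside the band (`mode="imf"`); a
band-pass alternative at the FOI cutoffs (`mode="filter"`) is provided and is
what the cohort-scale benchmarks use, since it is orders of magnitude cheaper
and band ground truth in the generator is exact under it.

## Time-course cleaning

The chain is fixed: polynomial detrend (Legendre basis, up to cubic) →
nuisance regression (demeaned regressors plus intercept; rank-deficient
columns dropped with a warning) → despiking (median/MAD z > 4 replaced by
cubic interpolation from clean neighbours) → 0.15 Hz low-pass. The low-pass
is an ideal zero-phase frequency-domain filter on the mirror-extended series,
the construction used by standard resting-state filtering tools. Two reasons:
an ideal mask is exactly idempotent (a finite-order IIR re-attenuates its
transition band on every reapplication), and its stopband rejection is
complete. Because discarding stopband noise perturbs the polynomial
projection, the chain ends by re-projecting onto the detrended subspace; with
that step the full chain is idempotent to well below 1% of the signal's
standard deviation. Reordering the steps changes the result and is not
supported. In the pipeline the 0.15 Hz filter is applied only on the FOI-N
path; data-driven bands impose their own limits.

## Connectivity model

A VAR(p) with intercept is fit per subject and band by per-target OLS on the
lagged design; collinear designs fall back to a lightly ridge-regularised
solve with a warning. Order selection minimises
AIC(p) = ln det Σ̂(p) + 2pn²/T_eff over p ∈ [1, p_max] (default p_max = 5,
i.e. 10 s of memory at TR = 2 s), ties toward the smaller order, with
T_eff = T − p and the MLE residual covariance.

The directed strength is pairwise-conditional Geweke causality: for each
source j and target k, the reduced model omits all lags of j while keeping
every other component, and GC(j→k) = ln(σ²_reduced/σ²_full), clamped at zero.
Components are standardised internally — the statistic is invariant to
per-component affine rescaling — and reduced models reuse the full Gram
matrix, so a 21-component subject costs n² small linear solves rather than n²
refits. Per-subject edge significance uses the asymptotic null
T_eff·GC ~ χ²(p) with Benjamini–Hochberg correction across the n(n−1) edges;
this is the "random-effect per-subject significance map" interpretation.
Network-block summaries average the directed entries between (or within,
excluding the diagonal) the DMN/SN/CEN partitions. Group averages use raw
(unmasked) values by default.

A caveat the benchmarks make visible: band-limiting with zero-phase filters
is acausal, so a genuine lagged interaction inside a band leaks a smaller
reverse-direction causality. The injected-effect benchmarks therefore assert
detection of the true block and direction-specific effect sizes, not the
absence of the mirrored one.

## Group inference

Group differences use two-sided label-permutation tests on the mean
difference (patients − controls) with the add-one estimator
p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1) (10,000 permutations by default);
when the number of distinct relabelings is below n_perm the exact tail is
enumerated instead. FDR families follow the per-band reporting structure:
edges are corrected within band, network blocks within band, and symptom
correlations across the tested correlations. Symptom association is a partial
Spearman correlation: ranks of both variables, covariates (age, gender coded
0/1, mean framewise displacement) regressed out of each rank vector, Pearson
correlation of the residuals with a t-approximation on n − 2 − k degrees of
freedom. (Unlike some implementations the covariates are not themselves
ranked; the unit test against an independent implementation pre-ranks them to
align the two definitions.)

## Classification

Features are the vectorised off-diagonal causality entries per band,
optionally concatenated across bands. The classifier is a linear soft-margin
SVM inside repeated stratified k-fold CV (defaults 10 × 10). Inside each
training fold: z-scoring (parameters from the training fold only), MRMR
retaining the top 30% of features (floor 20) — greedy mutual-information
ranking on 3 equal-frequency bins, relevance minus mean redundancy, ties to
the lower index — then an SVM-RFE elimination path (smallest |weight| removed,
10% chunks above 50 features, tied weights drop the higher index), with the
final subset size ({10, 20, 40, all} ∩ available) and C
({0.01, 0.1, 1, 10, 100}) chosen by inner 5-fold accuracy. Patients are the
positive class for sensitivity. Reported metrics are means over folds ×
repeats (pooled-prediction accuracy reported alongside); AUC uses a
trapezoidal ROC equal to the tie-corrected Mann–Whitney statistic. The
leakage test poisons held-out rows and asserts that no training-time decision
(selection, C, scaler parameters) changes.

## Synthetic cohorts

Each component signal is Σ_bands (band-limited unit-variance noise source +
lagged coupling terms from the *pre-coupling* sources, with group-dependent
strength) + white measurement noise (sd 0.5 by default, keeping ≥ 70% of a
single-band component's power inside its band). Defaults mirror the emulated
design: 49 + 54 subjects, 21 components (DMN 9 / SN 4 / CEN 8), TR = 2 s, the
five bands 0.12–0.18 / 0.04–0.08 / 0.02–0.04 / 0.01–0.02 / 0–0.01 Hz, and
230 time points — the scan length is not reported in the source design, so a
typical 8-minute acquisition minus ten discarded volumes is assumed.
Covariates are drawn to match the reported demographics (age ≈ 34 ± 12 y,
mean FD ≈ 0.14 ± 0.08 mm, ~46% female) and play no causal role. Optional
hemodynamic smoothing convolves every component with the same canonical
double-gamma kernel, which cannot create directional asymmetries. Symptom
scores at a requested Spearman correlation with a per-patient quantity use a
Gaussian copula (Pearson parameter 2·sin(πρ/6)) followed by a strictly
monotone squash into a plausible positive range, so the population rank
correlation is exact.

What the generator does **not** emulate: ICA mixing and component estimation,
spatial structure, motion and physiological artifacts, hemodynamic
variability across regions, or scanner drift beyond simple trends. Passing
benchmarks therefore demonstrate that the machinery is correct and calibrated
under the stated signal model, not that the original study's effect sizes are
reproduced on real data.

## Benchmark designs and problem sizes

The cohort-scale benchmarks (`freqec.validation`) run at the study's group
sizes. The block-recovery design injects six CEN→SN couplings
(0.6 vs 0.1) in the 0.04–0.08 Hz band over 20 replicate cohorts with 2,000
permutations; the null design re-runs the same analysis without coupling. The
band-combination design uses 10-component cohorts with six coupled edges in
each of three disjoint bands; per-band strengths (0.26 / 0.38 / 1.2) are
equated so each band alone discriminates comparably — higher bands complete
more oscillation cycles per scan and need weaker coupling for equal
detectability, mirroring the comparable single-band performance of multi-band
designs — and CV uses 10 folds × 3 repeats with a reduced selection grid.
Chance-level AUC uses 100 runs of a 60-subject, 40-feature null table with a
small CV configuration.

## Known limitations

- EMD/CEEMDAN quality is interpolation-dependent near boundaries; long
  signals (≥ 64 samples, preferably hundreds) are assumed.
- Conditional GC assumes linear stationary dynamics; band-limited inputs are
  strongly autocorrelated, so absolute GC values across bands are not
  comparable (group contrasts within band are).
- The asymptotic χ² edge test is slightly anticonservative at small T;
  group-level inference relies on permutations instead.
- `mode="imf"` band extraction can return an empty (zero) series when no
  mode's HWF falls inside a band; downstream code treats such components as
  degenerate and flags them.
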