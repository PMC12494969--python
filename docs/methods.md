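# Methods

This note records the models, conventions and numerical choices behind
`mecmap`, in the order the pipeline applies them.

## Behaviour preprocessing

Raw VR frames are resampled to a uniform 50 Hz grid by linear
interpolation of *unwrapped* position (cumulative distance), so no
interpolation ever crosses a teleport; positions below 0 or above the
track length thereby land on the neighbouring lap. Trial boundaries are
frames where position drops by more than 100 cm. Running speed is the
frame-to-frame position difference times the frame rate; samples ≤ 5 cm/s
or > 150 cm/s are treated as sensor artifacts, removed and linearly
interpolated, and the trace is smoothed with a Gaussian of SD 0.2 samples
(a nearly-delta kernel that removes single-sample jitter only). Analyses
then exclude stationary bins (speed < 2 cm/s). The artifact low-cut (5
cm/s) and the stationary threshold (2 cm/s) interact awkwardly — samples
interpolated away at 5 cm/s can no longer fall below 2 — so both are
exposed as parameters (`low_cut`, `threshold`); prolonged true pauses
survive the artifact interpolation in practice because interpolation
across a long all-slow stretch keeps values near the flanking slow
speeds.

Binning is half-open `[left, right)` with 0-based indices and the final
bin closed, package-wide.

The contrast-sensitivity psychometric is a least-squares sigmoid
`y = 1/(1+exp(−(x−center)/scale))` fit to fraction-requested vs
reward-zone opacity (bin 0.1), initialised at center 0.1, scale 0.002.
That initial scale puts the optimiser on a nearly flat gradient for some
inputs, so a second start from a data-driven guess (the half-maximum
opacity, scale = 10 % of the opacity range) is tried and the better fit
kept; constant responses return a flagged, non-converged fit.

## Spatial tuning metrics

Firing rates are spikes over occupancy per trial in 2 cm bins; bins a
trial never visited are missing and are linearly interpolated within the
trial before smoothing (Gaussian, reflect padding; SD 4 cm for tuning
curves and dark autocorrelations, 5 cm for population tensors — smoothing
preserves the trial-mean rate to machine precision). Coherence correlates
each bin's rate with the mean of its 8 nearest bins; the neighbourhood
wraps because the track is circular. Sparsity `Σ P_i R_i²/R²` is 1 for
uniform firing and `1/P_i` for a single active bin; information
`Σ P_i R_i log₂(R_i/R)` uses `0·log 0 = 0`. Both are undefined (NaN) for
silent cells; coherence is undefined for constant vectors.

The dark-running autocorrelation concatenates the smoothed per-trial
vectors of dark trials and uses a Pearson-type (mean-removed,
variance-normalised, biased) estimator, so the lag-0 value is exactly 1
and the peak-height/prominence thresholds are scale-free. Peaks come
from standard peak finding with width measured at half prominence.
Distance tuning requires a peak with width > 10 cm, height > 0.1,
prominence > 0.15; grid scale uses the *first* peak under relaxed
criteria (8 cm / 0.05 / 0.05) so the fundamental period, not the largest
harmonic, is read out.

**Shuffle null.** All significance tests circularly shift spike times by
offsets drawn uniformly from [20 s, duration − 20 s] (n = 100 shuffles;
the upper margin exists because a shift by nearly the whole session wraps
to a near-identity transform — an effect negligible in hour-long
recordings but dominant in minutes-long synthetic sessions). Percentiles
interpolate linearly between order statistics; with n = 100 the 99th
percentile sits between the two largest values. For distance tuning the
null statistic is selection-matched: the real cell's maximal qualifying
peak prominence is compared with the 99th percentile of each shuffle's
own maximal peak prominence. Comparing a max-over-lags statistic with
shuffle values at one fixed lag understates the null and fires on ~15 %
of untuned cells at these data sizes; the selection-matched null is
calibrated by construction. Ties at the 99th percentile count as
detection for distance tuning but not for speed/spatial typing, which
require strict exceedance.

## Speed tuning

Instantaneous rate is the per-frame spike count smoothed by a Gaussian
kernel whose SD is specified in track distance (default 40 cm) and
converted to time as 40 cm ÷ session mean running speed; the parameter
`speed_kernel_sd_cm` exposes this interpretation, which is the package's
resolution of a unit mismatch inherited from prior use of the kernel.
The speed score is the Pearson correlation of this rate with speed
(stationary bins excluded), with least-squares slope and intercept.
Stability scores are spike-count-weighted means of speed scores per 80 cm
section or per trial; strata with zero spikes drop out.

## Cell typing

QC removes units with signal:noise < 1, rate < 0.10 Hz, negative
repolarization slope, depth > 3200 µm along the probe, halfwidth
> 0.30 ms, or ≤ 350 spikes; sessions with fewer than 10 surviving cells
are flagged excluded. Interneurons are units with waveform duration
< 0.35 ms or mean rate > 40 Hz; the rest are putative excitatory cells.
Speed cells need |speed score| and |speed stability| both above their
shuffle 99th percentiles; spatial cells need coherence and sparsity both
above theirs (computed on Block A trials in the split-maze task to keep
context remapping out of the statistic). Grid cells are excitatory,
distance-tuned cells with dark rate > 0.05 Hz, overall rate ≥ 0.3 Hz and
trial-averaged-rate noise (SEM/mean) ≤ 0.45 in *both* context blocks
(exclusion on either, resolving an ambiguity in the rule's phrasing
toward the stricter reading); NGS cells are spatial non-grid excitatory
cells. Subtypes are set algebra on these flags.

## Similarity and remapping measures

Population tensors min-max scale each cell to [0, 1] (silent cells stay
zero) after 5 cm smoothing; dark and gain trials are omitted. Split-maze
tensors use the back half of the track (bins [200, 400) cm) and sort
alternation trials by context with a stable sort, so "5 nearest trials"
neighbourhoods in the alternation phase are context-sorted (chronological
order is available via `sort_alternation=False`). The cross-trial matrix
is the Pearson correlation of mean-centred spatial vectors for every
trial pair — mathematically the lag-0 normalised cross-correlation.
Zero-variance trials yield missing entries, which are excluded from every
group mean rather than imputed.

The block similarity ratio is `mean(A×A, B×B)/mean(A×B)` where each
`G×H` is the mean pairwise similarity between trial groups (the group
means are averaged, matching the printed notation, rather than pooling
all matched pairs); the alternation-phase ratio is
`mean(A×A′, B×B′)/mean(A×B′, B×A′)`. Both equal 1 under exchangeable
context labels and exceed 1 for context-specific firing; a
non-positive mismatched mean leaves the ratio undefined. Rate remapping
is the percent change of the peak of the trial-averaged normalised
vector from Block A to B; global remapping (spatial dissimilarity) is
1 − cosine similarity of the two block means. Gain responses compare
mean pairwise similarity within the last `n_post` pre-gain trials against
pre×post similarity, with pre and post matched in size. Remapping
coordination correlates a unit's cross-trial matrix with the network
matrix built from the *other* units, over the upper triangle.

## Factorized k-means and model selection

The clustering model is `X̂_ijk = Σ_r U_i⁽ʳ⁾ V_jk⁽ʳ⁾` with one-hot rows
`U_i` — k-means on flattened trial vectors, where each centroid slice is
a spatial map. Optimisation is Lloyd iteration with k-means++-style
seeding, 100 restarts by default, and the restart with the lowest
reconstruction error wins (the restart-acceptance rule left open
upstream). Under a speckled-holdout mask, centroid updates are means
over observed entries, assignments use mean squared distance over
observed entries, and seeding uses a column-mean-imputed copy — stated
because these choices move the cross-validation scores slightly. Empty
clusters are re-seeded at the worst-fit trial.

k ∈ {2..4} is selected by the repetition-mean silhouette score
(Euclidean metric on the flattened normalised trial vectors, the metric
being unstated upstream; silhouette repetitions differ only in their
random restarts) over 10 repetitions of 100 restarts. k = 1 ("one-map")
sessions are detected separately: ten replicates of 10 %
speckled-holdout cross-validation (uncentered test R²) on the real
tensor are compared with the same masks applied to a rotation-shuffled
tensor (left-multiplication of the trial-mode unfolding by a random
orthogonal matrix — norm- and bin×cell-Gram-preserving, one-hot
structure destroying) by a one-sided Wilcoxon signed-rank test at
α = 0.05; failing to reject flags one map. Note the test needs ≥ 5
replicates to be able to reject at all (the one-sided n = 3 minimum p is
0.125). A rank-matched EM-imputed truncated SVD on the same masks
quantifies how discrete the maps are (tSVD relaxes the one-hot
constraint, so its noise-free test R² bounds the k-means score).

Maps are relabelled deterministically (split-maze: map 1 = most Block A
trials, then most Block B, then — for k = 4 — more trials before the
context-sorted alternation midpoint; ties to the lowest raw id.
Random-foraging: ascending mean running speed). Map 1 and 2 inherit
context identities A and B; maps 3–4 take the context whose block trials
they are more similar to on average (ties to A, with a warning). Remaps
are label changes between consecutive trials; remap frequency divides by
the phase's trial count; a trial is context-aligned when its map's
identity matches the displayed context.

## Position decoding

Positions map to angles `y = 2π·position/L`. The decoder's prediction is
`ŷ_t = atan2(Σ β⁽¹⁾s, Σ β⁽²⁾s)`; coefficients are initialised by ridge
least squares of (sin y, cos y) on the counts (ridge 1e-6) and refined by
L-BFGS maximisation of the mean-cosine objective
`mean cos(y − ŷ)` with the same ridge penalty (tolerance 1e-6, ≤ 500
iterations); `method="lsq"` stops at the initialisation and is
cross-checked against the refined fit on synthetic data (the upstream EM
formulation lives in an external reference; maximising the same
predictive objective directly is this package's equivalent). Spike
counts are binned at 200 ms (a compromise between per-bin spike yield
and angular resolution; the bin width is a parameter), bins with mean
speed < 2 cm/s are dropped, and all-zero count rows give undefined
predictions that are excluded from scoring. Evaluation repeats a random
90/10 split ten times; the chance control re-runs the protocol on
per-unit circularly time-shifted spike trains. Training-set matching
(for map-conditioned comparisons) greedily equalises counts over
position-octant × speed-quartile strata.

## LFP

One channel per session: the highest theta power among the 200 channels
closest to the probe tip that carry at least one good unit. Band power
uses a DPSS multitaper spectrogram with 0.5 s non-overlapping windows
(time-bandwidth 3, 5 tapers — unstated upstream, exposed in the API),
integrated over theta 6–12 Hz, slow gamma 20–50 Hz or fast gamma
50–110 Hz, giving a 2 Hz power trace; session spectra use Welch's method
(segment length 4 s by default). The power trace is up-sampled to 50 Hz
with a second-order spline and averaged over frames with
20 ≤ speed ≤ 40 cm/s, both boundaries included. The 0.5 s window's
±6 Hz analysis bandwidth smears narrowband theta beyond the band edges;
Parseval holds over the full spectrum to ~1 %, and disjoint bands add to
the covered-range power within taper leakage (~5 %).

## The synthetic generator

`synthio` emulates the task structure: `n_dark` leading dark trials, two
sequential context blocks, pseudorandom alternation (an independent
uniform A/B draw per trial, mirroring the task engine's per-teleport
random number), and trailing gain trials whose position increment is
scaled by 0.7. Defaults are the full task (20 dark + 60 + 60 + 80 + 20
trials, 400 cm track, 50 Hz); tests run reduced counts. Speed is a
smoothed positive AR(1) stream (mean 40, clipped to 2–150 cm/s)
modulated by anticipatory slowing around the reward zone and occasional
pauses (~30 % of trials), giving lap-duration variability and genuine
sub-2 cm/s frames — without the pauses, circular time shifts on
metronomic laps are near-identities and every shuffle null inflates.

Spikes are inhomogeneous Poisson, discretised per 20 ms frame. Grid
cells are von-Mises bumps periodic in position (period = grid scale,
drawn from {40, 60, 80, 100} cm) and in cumulative distance during dark
running; NGS cells are single Gaussian fields silent (baseline only) in
the dark; ± speed cells are linear in speed; fast-spiking interneurons
are high-rate (> 42 Hz) with narrow waveforms; untuned cells are
homogeneous at 3 Hz. Global remapping is one network-wide map label per
trial: at each context switch the label follows the new context with
probability `remap_probability_per_context_switch` (default 1), and each
tuned cell expresses a circularly shifted copy of its tuning under map
B. Per-trial lognormal rate jitter (`rate_noise`, default 0.1) and
per-trial Gaussian phase drift (`drift_sd`, default 0 cm) model slow
instability. Waveform/QC metadata are drawn consistent with each
archetype so the typing thresholds are exercised.

What the generator does **not** emulate: 2-D open-field structure,
theta-phase dynamics, head-direction/border/object-vector tuning,
behaviourally-correlated licking artifacts, spike-sorting errors,
electrode drift, or the spike-count correlations of real simultaneously
recorded populations. Passing tests therefore show that the analysis
chain recovers the statistical structure it targets when that structure
is present and stays calibrated when it is absent — not that real MEC
data will look like the synthetic sessions. LFP synthesis is a
sum-of-sinusoids helper for testing the spectral code only.

## Problem sizes

The test suite and examples run at desk scale, chosen so the full suite
completes in minutes: sessions of ~20–60 trials with 10–90 cells,
100-shuffle nulls, 100-seed sweeps for map-count recovery on constructed
tensors (36 trials × 40 bins × 10 cells), 500 untuned cells for null
calibration on one ~20-trial session, and 10 repeated fits elsewhere.
Shorter sessions inflate shuffle nulls (stereotyped laps) and lower
decoder scores relative to hour-long recordings; the directional and
calibration properties are unaffected.

## Known limitations

Eq-2-style sparsity is bounded below by 1 and barely moves under circular
time shifts of tightly stereotyped running, making it the weaker half of
the spatial-typing conjunction on short sessions (NGS sensitivity is
accordingly modest at desk scale, while grid and speed typing and untuned
specificity are strong). The speed-kernel distance-to-time conversion
uses the session mean speed, not instantaneous speed. The decoder's
shuffle control stays above zero on short stereotyped sessions.
`_phase_of_trials` cannot distinguish alternation trials that open with
context B from a block tail when no session config is available.
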