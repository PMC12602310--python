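# Methods

`pfcdyn` analyses drug-vs-vehicle block-design electrophysiology from rat
medial prefrontal cortex (mPFC): multi-channel LFP sampled at 2.5 kHz across
the infralimbic (IL), prelimbic (PL) and cingulate (CG) subregions, together
with sorted single-unit spike times.  A session consists of 15-min rest and
task blocks before and after an intraperitoneal injection (vehicle or one of
two psilocybin doses), with drug-free follow-up sessions on later days.  This
note records the models, parameter choices and numerical conventions; every
empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Time and depth conventions

All times are seconds (float64) on the recording clock; the injection time is
stored absolutely and converted to injection-relative time only for display.
Bins and block intervals are half-open `[t, t + dt)`; a spike exactly on a bin
edge belongs to the later bin.  Channel and unit depths are micrometres
measured upward from the ventral boundary of the channel's region; for
topographic plots the three regions are concatenated on a normalised axis
(IL = [0,1), PL = [1,2), CG = [2,3)), each scaled by its own dorsoventral
extent.

## LFP spectral analysis

Power spectral densities use Welch's method with 4-s Hann windows, no
overlap, constant detrend and one-sided density scaling; at 2.5 kHz this
gives 10000-sample segments and an exact 0.25-Hz frequency grid.

**HFO unmasking.** Narrowband high-frequency oscillations (HFO, 80–110 Hz)
ride on a steep 1/f background.  The baseline under the band is a straight
line in log10(power) versus log10(frequency), least-squares fitted to the
flank bands 60–80 and 110–130 Hz and evaluated on the band's bins; it is
exact on any pure power law and excludes any bump confined to the band.  The
HFO magnitude is the band mean of `10*log10(raw/baseline)` (dB), which makes
it invariant to overall recording gain; a linear-difference variant is
available behind a flag.  Flank bands and the measure's dB convention are
package conventions — the interpolation domain is not standardised in the
field.

**Peak frequency.** The difference curve from an attainable amount of Welch
averaging fluctuates bin to bin, so a raw argmax jitters by several bins even
for a clear spectral bump.  The peak estimate therefore smooths the curve
with a 1-Hz Gaussian kernel, takes the argmax, refines it with a
least-squares parabola over ±2 Hz, and snaps the vertex back to the 0.25-Hz
grid (clipped inside the band).  The reported band-mean magnitude is
unsmoothed.

**Channel selection.** One analysis channel per region: IL is the channel
with the largest HFO 1/f power difference (the region's HFO hotspot); PL is
the channel nearest the region's mid-depth; CG the channel nearest a
configurable 284 µm above the region's ventral boundary.  A region without
channels raises an error naming the region, so sessions whose probe missed a
region are flagged rather than silently skipped.

**Coherence.** Magnitude-squared coherence between region channels uses the
same Welch windowing.  With K windows the estimator's null bias is roughly
1/K; the independent-noise test checks this decay.

**Longitudinal contrasts.** Follow-up days are compared against the shared
day-0 pre-injection baseline as log10 power ratios and coherence differences
per (day, block kind, frequency), mirroring the "post divided by baseline"
arithmetic used throughout.

## Unit quality control and cell types

QC follows the standard sorted-unit triple (thresholds: ISI violations
< 0.5, amplitude cutoff < 0.1, presence ratio > 0.9; strict inequalities):

* *ISI violations*: Hill-style ratio of the observed rate of inter-spike
  intervals below 1.5 ms to the rate expected for a Poisson process at the
  unit's mean rate (each spike exposes a `2 × 1.5 ms` window).
* *Presence ratio*: fraction of 100 equal subdivisions of the recording
  containing at least one spike.
* *Amplitude cutoff*: the amplitude histogram (500 bins, smoothed with a
  3-bin Gaussian) is assumed symmetric when fully captured; the mass above
  the point on the high side whose density matches the low-edge density,
  renormalised as `tail/(1 + tail)`, estimates the missed-spike fraction of
  the full distribution (capped at 0.5).  For a Gaussian truncated at
  µ − 1σ this converges to Φ(−1) ≈ 0.159, which the tests verify.

**Classification.** Trough-to-peak width is measured on the mean waveform
after 10× cubic-spline upsampling (scale-invariant; stable under
resampling).  Width < 425 µs → narrow-spiking (NS, putative interneuron).
Broader units with ≥ 100 spikes get an autocorrelogram (0.5-ms bins, ±50 ms)
fitted with `a·(1 − exp(−(t − t0)/τ_rise))·exp(−t/τ_decay) + c`; τ_rise
> 6 ms → wide-slow (WS), otherwise regular-spiking (RS, putative pyramidal).
The five-parameter form is degenerate on a noisy short-lag ACG, so the fit
normalises by the ACG plateau, smooths with a 2-bin Gaussian, bounds
τ_decay ≥ 200 ms and t0 ≤ 2 ms, and multi-starts τ_rise at 1/4/15 ms, keeping
the best SSE.  With ~9000-spike trains this discriminates 2-ms from 12-ms
rise times essentially without error (the acceptance suite demands ≥ 99/100).

## Firing-rate analyses

Windowed rates (60-s windows) are reported as differences from each unit's
mean rate over the pooled pre-injection baseline (rest + task; the pooling is
a package convention).  Per-cell change classification compares 10-s bin
counts pre versus post (rest blocks) with a two-sided Wilcoxon rank-sum test
at α = 0.05 per cell, gated by magnitude: *increase* requires significance
and fold change ≥ 2, *decrease* significance and fold ≤ 0.5, else
*no change*.  The per-cell test and bin size are not standardised anywhere;
both are config-exposed.  Under the null the twofold gate pushes the
mislabel rate far below α.  Change-class proportions per region × cell class
feed Pearson chi-squared tests with Bonferroni-corrected pairwise post-hocs.

## Network-state MSD and Lempel-Ziv complexity

Spike trains are binarized at 20 ms (MSD) or 10 ms (LZC): a bin is 1 iff it
contains ≥ 1 spike.  The network state `S_t` is the N-bit vector across
units; `MSD_{n,t} = ⟨|S_{t+nΔt} − S_t|²⟩_N` equals the Hamming distance
divided by N (bounded in [0, 1]) and is averaged over lags n = 1..50 — one
second ahead at 20-ms bins.  Only start bins with all 50 lags available are
kept, avoiding edge bias.  The implementation is exact (integer XOR
arithmetic) and is tested for equality against a per-definition loop oracle.

For the pre/post contrast, pre-drug MSD values are z-scored and post-drug
values have the pre mean subtracted; the package also divides the post values
by the pre SD so both phases share units (the literal mean-subtraction-only
behaviour is available via `scale_post=False`).  The two post blocks of each
kind are pairwise averaged pointwise, then subjects pooled by concatenation.

LZC uses the LZ76 exhaustive-history phrase count (shortest-next-phrase
production rule; the final, possibly reproducible, phrase counts as one).
Two backends implement the same parse — a numba-compiled linear scan and a
pure-Python `bytes.find` bisection (reproducibility of a prefix is monotone
in its length, so bisection is valid) — cross-checked against each other and
against a brute-force oracle on all short strings.  Both the raw count and
the normalised `c·log2(L)/L` are reported; contrasts use the normalised
value so blocks of unequal length compare fairly.  Per-unit post-minus-pre
differences (block-pair averaged, matched by unit id) are tested with the
sign-flip permutation test and summarised with Cohen's d.  LZC is computed
per block and then averaged, not on concatenated blocks.

## Statistical layer

* **Scheirer–Ray–Hare**: all values rank-transformed jointly (average ranks
  for ties); two-way sums of squares on the ranks; `H = SS_effect/MS_total`
  with `MS_total = SS_total/(n − 1)`, referred to χ² with the factorial
  degrees of freedom; the interaction is `SS_cells − SS_A − SS_B`.  No
  additional tie correction of MS_total (the classical construction).  When
  one factor is constant the statistic reduces exactly to tie-corrected
  Kruskal–Wallis, which the tests assert at 1e-9.
* **Permutation test**: sign-flip of per-unit paired differences, statistic
  = mean difference (the simplest location statistic for paired designs),
  `p = (1 + #extreme)/(B + 1)` with B = 10,000 by default; for n ≤ 12 all 2^n
  sign patterns are enumerated exactly.
* **Partial Bonferroni**: for frequency-resolved families (e.g. 0–200 Hz at
  0.25 Hz), α is divided by the number of leading principal components
  explaining > 95% of the family's variance (covariance PCA on centred data;
  correlation form behind a flag), applied once per variable family.
* **Effect size**: Cohen's d with n−1-weighted pooled SD.
* **Baseline contrasts**: `change = mean(post)/mean(baseline)` per condition
  and `percent_diff = 100·(change_drug/change_saline − 1)`, rest and task
  always separate.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions every end-to-end test runs under.

* **Schedule**: day-0 rest/task baseline, injection, then rest/task/rest/
  task/rest; follow-up days have 2 rest + 2 task blocks.  Blocks default to
  60 s (standing in for the study's 15 min) with all analysis parameters
  unchanged, so a full experiment simulates and analyses in seconds.
* **LFP**: 1/f² coloured noise synthesised in the frequency domain (random
  phases, amplitude ∝ f^(−β/2)) for exact spectral control, half of its
  power shared across channels as a volume-conduction stand-in (baseline
  inter-channel coherence ≈ 0.25).  Drug sessions add a narrowband Gaussian
  bump (σ = 1.5 Hz) at 100 Hz (low dose) or 93 Hz (high dose), +6 dB over
  the background at its centre on IL channels, decaying to 0.45× (PL) and
  0.15× (CG), gated in time from the injection with a 10-s onset ramp.  The
  narrow bandwidth reflects the sharpness of the rhythm being emulated and
  makes one-bin peak-recovery tests well-posed.
* **Spikes**: per unit, an inhomogeneous Poisson train (5-ms rate grid,
  2-ms absolute refractory period) with log-normal baseline rates
  (median 2.5 Hz, σ_log = 0.7) and a task-block rate factor of 0.8.  Cell
  classes are drawn 75/15/10% RS/NS/WS with matching waveform templates, and
  class-specific recovery thinning (τ = 2 ms for RS/NS, 12 ms for WS) shapes
  the autocorrelogram rise the classifier fits.  Post-injection, each unit
  draws a persistent response from the dose's mixture — low dose: 40%
  decrease to 0.35×, 8% increase to 2.5×; high dose: 55% to 0.30×, 5% to
  2.5× — chosen so the minority increases clear the twofold gate, the net
  change is dose-ordered with clear margins, and the response heterogeneity
  (majority suppression, detectable minority enhancement) is respected.
  Drug effects are attenuated in task blocks (log-factor and modulation
  depth × 0.5), making effects rest-dominant.
* **Entropy drop**: post-drug rates are multiplied by `1 + d·x(t)` where
  `x(t)` is a ±1 telegraph process with 0.5-s switching timescale shared
  across units (d = 0.45/0.65 by dose).  Mean-preserving slow common
  modulation makes binarized states stickier, lowering both MSD and unit
  LZC — the phenomenology the contrasts must recover.  It is a generative
  stand-in, not a biophysical mechanism.

**What the generator does not emulate**: biophysical spike waveform
variability, electrode drift, behavioural covariates, non-Poisson burst
structure beyond the recovery/telegraph mechanisms, non-stationary 1/f
slopes, and the injection-stress response seen after vehicle injections.
Passing end-to-end tests therefore demonstrates correct recovery of the
modelled effects, not robustness to every property of real recordings.

## Problem sizes used in tests

Unit counts default to 25/60/25 (IL/PL/CG) with a 12-channel probe map;
recovery tests use a 6-channel map and 20 seeds; the end-to-end check runs
50 replicates of the three-condition experiment; SRH calibration uses 2000
null replicates of a 3×2, n = 60 design; LZ76 is verified against the brute
parse on all 65,534 binary strings of length ≤ 15 plus random length-1000
strings.  These sizes are the package's chosen test conditions; all analysis
parameters are the study's.

## Known limitations

* The ACG τ_rise fit needs several thousand spikes for reliable WS/RS
  separation; sparse units fall back to RS more often than they should.
* The amplitude-cutoff estimator assumes a unimodal, roughly symmetric
  amplitude distribution; drifting or multi-modal units violate it.
* `scheirer_ray_hare` is asymptotic (χ² reference); small, heavily tied
  designs inherit the usual rank-test approximation error.
* The 1/f baseline assumes the flanks are bump-free; oscillations inside
  60–80 or 110–130 Hz would bias the interpolation.
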