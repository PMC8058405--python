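# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package. All symbols follow the field's conventions:
firing rates in Hz, times in seconds, depths in micrometers, channel 0 the
most superficial probe site.

## The analysis pipeline

The package analyzes extracellular recordings from auditory cortex of
head-fixed mice that run freely on a ball while 600 ms white-noise (WN)
bursts and matched silent blanks are presented at 1 s inter-stimulus
interval, each with or without an 800 ms optogenetic laser pulse that spans
the sound (onset 50 ms before the sound, offset 150 ms after), with at
least 30 repeats of each (stim, laser) combination. The question it serves
is whether the effects of locomotion on sound encoding are mediated by the
VIP-interneuron disinhibitory circuit: if the two modulations act through
independent mechanisms, their combined effect should equal the arithmetic
sum of the effects measured separately (the epistasis logic of genetics).

Stage order: trial classification → laminar assignment via evoked CSD →
waveform-based cell classification → per-condition response metrics →
modulation indices, effect decomposition, additivity test → population
distance-correlation timescale sweep → laminar group statistics.

### Behavioral state

The running trace is smoothed with a 200 ms centered moving median
(robust to single-sample optical-mouse artifacts; edge samples use
shrinking windows). A trial is *running* when its mean smoothed speed over
the 600 ms stimulus window is strictly above 5% of the session's maximum
smoothed speed, else *sitting*; sessions with fewer than 7 running trials
are excluded from running analyses. Both the maximum and the trial means
are taken on the same smoothed trace — using the raw maximum would couple
the threshold to artifact amplitude, which the smoothing exists to remove.
"Moving median average" is implemented as a moving median (not a
median-then-mean cascade); the artifact-suppression purpose admits only
that reading. The high-arousal mask marks samples where pupil size is
strictly above 60% of the session maximum; a session without a pupil trace
raises rather than silently passing.

### Laminar assignment

The LFP (25 um site spacing) is zero-phase band-pass filtered to 1–300 Hz
(4th-order Butterworth, forward–backward, so the sink latency is not
displaced) and the CSD is the discrete second spatial difference
`(trace[j-1] + trace[j+1] - 2 trace[j]) / spacing^2`. The trial-averaged
evoked CSD over WN laser-off trials shows a short-latency sink at the
layer-3/4 boundary; the most negative value within 0–50 ms post-onset is
the sink if its magnitude exceeds `k = 3` standard deviations of the
pre-stimulus trial-averaged CSD (the depth-of-modulation criterion; the
source text gives no quantitative rule, so `k` is configurable and logged
per session). The sink channel is anchored at 400 um; each unit's depth is
`400 + (peak_channel - sink_channel) * 25` um using the channel with the
maximum peak-to-trough waveform amplitude. Layers follow the fixed table
L1 0–128, L2/3 129–380, L4 381–525, L5 526–805, L6 806–1200 um; depths
outside 0–1200 um, and all units of a session with an undetected sink, are
left unassigned and excluded from laminar analyses only. L1 units are
reported but excluded from layer-group statistics by default (the
in-vivo dataset contained a single L1 unit).

### Cell classes

Waveform width is the trough-to-subsequent-peak time on the peak channel
(the extracellular convention; the source's "distance from the peak to the
trough" states no order, so the convention is configurable). End-slope is
the least-squares slope over the final 0.2 ms of the waveform (the epoch is
unstated in the source; 0.2 ms is this package's default). Narrow-spiking
(NS) requires width < 0.5 ms AND negative end-slope; width ≥ 0.5 ms is
regular-spiking (RS); a narrow width with non-negative end-slope satisfies
neither rule and is left unclassified rather than forced — unclassified
units are excluded from NS/RS contrasts but kept in all-cell analyses.

### Response metrics

Per-trial rates are spike counts in half-open windows divided by window
length: onset = 0–100 ms and offset = 600–700 ms re stimulus onset (the
offset window tracks the stimulus duration). Spontaneous rate is measured
on interleaved blanks, which match the sound trials' duration and
presentation intervals. A unit is *sound-responsive* when a two-sided
Wilcoxon rank-sum test between per-trial onset rates on WN trials and the
onset-matched window on blanks (sitting laser-off) gives p < 0.01 with a
rate increase; the exact null distribution is used when both samples have
≤ 25 trials, the normal approximation otherwise. The significance test
uses the onset-matched blank window (like-for-like comparison); reported
spontaneous rates and the MI denominator use the full 600 ms blank window
(the stable estimate) — both choices are explicit in the API.

Latency is read from the trial-averaged PSTH (5 ms bins, 15 ms centered
moving average): the first post-onset time at which the smoothed rate
reaches half of its peak, measured from a 0 Hz baseline, linearly
interpolated between bins, undefined (NaN) at zero peak. On synthetic
units whose evoked rate is a step rather than a sharp transient, the noisy
PSTH peak biases individual latencies late; group *differences* are
recovered accurately because the bias is common to the groups compared.

### Modulation indices and the additivity test

`MI = (E − S)/(E + S)` with E the mean onset-window rate on WN trials of a
(state, laser) condition and S the mean blank rate of the same condition;
MI is undefined (NaN, excluded pairwise, never imputed) when E = S = 0 or
when either trial selection has fewer than 7 trials (the same floor as the
session-inclusion rule, applied per condition as a symmetric evidence
requirement; configurable). Only sound-responsive units enter MI analyses,
so MI(sitting, laser-off) ∈ [0, 1]. Effects:

    running effect     = MI(run, off) − MI(sit, off)
    VIP effect         = MI(sit, on)  − MI(sit, off)
    predicted combined = running effect + VIP effect
    observed combined  = MI(run, on)  − MI(sit, off)

The additivity test reports the Spearman rank correlation between
predicted and observed across units (the analysis family is nonparametric
throughout, and the source does not state which correlation its ρ is; rank
correlation is this package's choice) together with the OLS slope,
intercept, and r² of observed ~ predicted, plus the two single-predictor
fits (observed ~ running effect alone, observed ~ VIP effect alone) for
the model-comparison argument.

A companion check (`rate_additivity_test`) repeats the observed-vs-
predicted comparison on raw evoked and spontaneous firing-rate changes
instead of MI differences, confirming the conclusion does not hinge on the
bounded MI normalization; on calibrated synthetic data the spontaneous
changes are the better predicted of the two (their 600 ms measurement
window is six times the onset window).

Because running trials are scarce, the sitting-vs-running MI contrast is
repeated 100 times on random sitting-trial subsets matched in count to the
running trials (WN and blank counts matched separately, drawn without
replacement), reporting the distribution of population means and paired
signed-rank p-values. The subsampling RNG is independent of the
generator's RNG streams.

The normalized laser effect is `(rate_on − rate_off) / peak_off` on
sitting trials, computed separately for evoked (onset window, WN) and
spontaneous (blank window) activity; the normalizer is the peak of the
smoothed laser-off WN PSTH, making the quantity scale-invariant.

### Population timescale

The sample distance correlation (double-centered pairwise-distance
definition, biased/classical dCov estimator) is computed between the
n_units × n_bins rate matrix and the bin-averaged speed vector. It is
swept over a doubling bin-size ladder from 50 ms (default ceiling 40 s;
the source states 40 s in its methods but reports results to 12.8 s, so
the ceiling is configuration). Each raw value is corrected by subtracting
the mean over 50 random permutations of the *binned* speed vector, and
`p = #{shuffled ≥ raw}/n_shuffles`. Permuting binned values conjugates the
centered distance matrix by the permutation, so shuffles reuse the two
centered matrices (one gather + one mean product each). A circular-shift
null is available as an option because full permutation overstates
significance under autocorrelation; the permutation null is the default
for fidelity to the original procedure. Ladder steps with fewer than 4
bins are undefined.

### Group statistics

Within-group contrasts use the two-sided Wilcoxon signed-rank test,
between-group contrasts the two-sided rank-sum test, multi-group laminar
comparisons the Kruskal–Wallis test with pairwise rank-sum post-hocs at a
Bonferroni-corrected threshold (familywise alpha divided by the exact
number of pairs). Effect size is `r = z/√N` with z the normal-scale
Wilcoxon statistic (normal approximation with continuity correction,
midranks for ties) and N the total cases — twice the sample size for
paired tests. A grouping utility applies the same Kruskal–Wallis machinery
across recordings or animals as a robustness check.

## The synthetic-session generator

The generator emulates the recorded experiment so every stage has a
recoverable ground truth. One seed governs all draws through named
`SeedSequence` child streams (schedule, behavior, units, waveforms,
spikes, lfp, pupil); identical parameters yield byte-identical sessions.

**Schedule.** The four (stim, laser) combinations, each repeated
`n_trials_per_combo` (≥ 30) times, are randomly interleaved on a 1.6 s
cycle (600 ms stimulus + 1 s ISI).

**Running.** A two-state Markov chain at the 100 Hz trace rate
(bout start 0.04 /s, stop 1/3 /s — mean 3 s bouts every ~25 s) smoothed by
200 ms raised-cosine ramps, with ~7 cm/s bout speed (AR(1) jitter, ~1 s
correlation time) and ~0.02 cm/s rectified sensor noise when sitting.
These rates were chosen so that ~13% of trials are running trials, the
fraction reported for the in-vivo sessions. Pupil size co-varies with the
bout envelope (0.5 + 0.4 × envelope + noise), placing running inside the
high-arousal state.

**Trial-state truth.** The per-trial ground-truth state is computed by the
*same* deterministic labeling rule the analysis uses (median smoothing, 5%
of max), applied to the generated speed trace, and spiking is driven by
that trial-level state. Driving spikes from the instantaneous Markov state
instead would make ramp-straddling trials carry a state label that only
partially matches their spiking condition and would bias recovery tests
for reasons unrelated to the estimators under test.

**Spiking.** Per unit, an inhomogeneous Poisson process with
piecewise-constant rate on each trial cycle: baseline + additive condition
deltas. Evoked onset/offset increments occupy latency-shifted 100 ms
windows on WN trials; running deltas apply on running trials; laser deltas
inside the laser window (−50 to +750 ms re onset). Rates are clipped at 0
and any clipping is recorded per unit so recovery tests can exclude
saturated units. An optional multiplicative running × laser interaction
term scales all deltas by (1 + γ) on running laser-on trials; γ < 0 yields
the sub-additive signature that the interaction-detection tests must find.
No refractory period is modeled: every downstream statistic is rate-based.

**Calibration.** Population means across units target the in-vivo values:
spontaneous 4.87 Hz sitting / 6.50 Hz running, onset-window 15.81 Hz
sitting / 13.97 Hz running. Baselines are gamma-distributed (spontaneous
shape 2.5, evoked-gain shape 3.0); condition deltas are normal with sd
4 Hz (spontaneous) and 10 Hz (evoked), spreads chosen to reproduce the
broad single-cell diversity of the effect decomposition (MI effects
spanning roughly ±1). Two corrections make the *measured* means hit the
targets exactly rather than approximately:

1. *Window dilution.* The analysis windows are fixed at 0–100 and
   600–700 ms while the injected increments start at the unit's latency
   (uniform 10–30 ms), so only a fraction (1 − latency/100 ms) of the
   window carries the increment; mean gains are scaled up by the expected
   factor (×1/0.8).
2. *Rectification.* Clipping rates at 0 raises the mean of a normal delta;
   delta means are therefore moment-matched numerically (2 × 10⁶ Monte
   Carlo draws of the unit-parameter distributions + Brent root finding)
   so the clipped population means equal the targets. Laser-delta means
   are anchored the same way to a +1 Hz spontaneous increase with the
   evoked increase that leaves the population-mean MI unchanged, matching
   the observed no-net-effect of VIP activation on sound encoding.

**Waveforms.** The peak-channel template is a negative trough Gaussian
(σ 0.06 ms) plus a 0.4-amplitude positive peak Gaussian (σ 0.25 ms) at the
drawn trough-to-peak width — NS uniform 0.25–0.45 ms, RS 0.55–0.85 ms, so
every drawn width is at least 0.05 ms from the 0.5 ms threshold — with a
decaying tail that keeps the end-slope strictly negative. Amplitude decays
exponentially across channels (space constant 50 um) and peaks at the
channel nearest the unit's true depth. True depths are drawn per layer
(weights L2/3 0.15, L4 0.20, L5 0.50, L6 0.15, echoing the reported
laminar sampling with its L5 peak and undersampled L6) within the probe's
span (sink channel 10 of 32 ⇒ 150–925 um).

**LFP.** Each WN onset adds a 30 ms half-sine, 60 uV deflection with a
compactly supported raised-cosine spatial profile (half-width 4 channels)
centered on the channel anchored at 400 um; its second spatial difference
is a sink at that channel flanked by sources, and compact support makes
the noiseless CSD sum to zero across channels at every sample (current
conservation). Pink (1/f) noise at 15 uV rms is added per channel. This is
a descriptive dipole, not a biophysical model: it reproduces the features
the laminar stage consumes (sink depth, short latency, superficial source)
and nothing else.

**Timescale coupling.** A separate generator produces a population whose
rates follow a latent Ornstein–Uhlenbeck process z with correlation time
τ = 0.4 s (`rate = base (1 + 0.8 z)`, clipped), while speed is the
rectified sum of z, a slow drift (τ 8 s) and fast per-sample noise. Only z
is shared, so the shuffle-corrected distance correlation peaks near τ:
finer bins are diluted by spike noise and the fast speed component,
coarser bins average z away while retaining the uncoupled drift.

## What the generator does and does not emulate

Passing recovery tests shows the estimators invert the generator's model
at realistic sample sizes; it does not certify performance on real
recordings, which additionally contain non-Poisson spiking (bursting,
refractoriness), drift and unit instability, spike-sorting contamination,
movement artifacts in the LFP, correlated noise across units, and
arousal effects not locked to locomotion. Trial-state truth is defined at
the trial level, so within-trial state transitions are absent. Waveform
realism is limited to the width/end-slope/amplitude-decay features the
classifier consumes.

## Numerical choices and degenerate inputs

* Delimited text is written with `%.17g` and read with round-trip float
  parsing: serialization is lossless for float64 and byte-deterministic;
  HDF5 datasets disable timestamp tracking for the same reason.
* MI at E = S = 0, latency at zero peak, and dcor on constant input are
  undefined/zero by convention, flagged, and excluded pairwise.
* The distance correlation clamps a (numerically) negative dCov² to 0
  before the square root; 0/0 is defined as 0 (no measurable dependence).
* First-crossing tie-breaks (latency) use linear interpolation between
  bins for deterministic sub-bin precision.
* Kruskal–Wallis group tests drop empty groups and require at least two
  nonempty ones; post-hoc tests run only on an omnibus rejection.

## Problem sizes used in tests and the acceptance script

Recovery suites use 100-unit populations with 100 trials per combination
(additivity), 30 trials per combination with 100 noise seeds (laminar),
30-unit populations over 160 s with 20 seeds (timescale), and 1000 null
replicates at 4 × 15 samples (type-I calibration) — sizes at which the
targeted effects are identifiable while the full suite stays fast. The
acceptance script regenerates every quantity from scratch at the same
scales with seeds derived from its `--seed` argument; sessions that fail
the 7-running-trial inclusion floor are regenerated at the next seed, the
same exclusion applied to the in-vivo recordings.

## Known limitations

* The additivity analysis is performed on MI differences, but MI is a
  bounded nonlinear function of rates; effects that sum exactly in Hz are
  therefore only approximately additive in MI. On calibrated synthetic
  populations this intrinsic curvature caps the observed-vs-predicted
  rank correlation near ~0.85–0.9 and compresses the regression slope to
  ~0.6 even with purely additive generation — closely matching the
  slope the original analysis reported. The sub-additivity *contrast*
  (interaction vs no interaction) remains cleanly detectable.
* The permutation null for the distance correlation is anti-conservative
  under strong autocorrelation; use the circular-shift option when that
  matters.
* Latency estimates on step-like responses are biased late at realistic
  trial counts (see above); compare groups, not absolute values.
* The phy/Kilosort reader covers the minimal spike_times / spike_clusters
  / templates layout only.
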