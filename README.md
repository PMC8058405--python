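# lamstate

Laminar analysis of locomotion and optogenetic state modulation in
auditory cortex recordings.

## What this package is for

Movement changes what sensory cortex does with stimuli: in auditory
cortex, running raises spontaneous firing but suppresses sound-evoked
responses, shrinking the neural contrast between sound and silence. A
candidate circuit for such state modulation is the VIP-interneuron
disinhibitory motif, which can be probed directly by optogenetically
activating VIP cells while sounds play. Whether locomotion acts *through*
that circuit is an interaction question: if running and VIP activation
work through independent mechanisms, their combined effect on each
neuron's sound encoding should equal the arithmetic sum of the two
effects measured separately; if VIP circuitry mediates the running
effect, the combination should be sub-additive.

`lamstate` implements the full analysis chain needed to ask that question
of a laminar silicon-probe recording, for systems neuroscientists working
with spike-sorted extracellular data:

* **Trial classification** — 200 ms moving-median smoothing of the
  running trace; a trial is *running* when its mean smoothed speed over
  the 600 ms stimulus window exceeds 5% of the session maximum; sessions
  need ≥ 7 running trials to enter running analyses. A pupil-based
  high-arousal gate (> 60% of max) is included.
* **Laminar assignment** — evoked current-source density
  (`CSD_j = (trace_{j-1} + trace_{j+1} - 2 trace_j)/Δz²` on 1–300 Hz
  zero-phase-filtered LFP); the short-latency sink is anchored at the
  layer-3/4 boundary (400 μm) and unit depths follow from their
  max-amplitude waveform channel (25 μm/channel), with the layer table
  L1 0–128, L2/3 129–380, L4 381–525, L5 526–805, L6 806–1200 μm.
* **Cell classes** — narrow-spiking (width < 0.5 ms and negative
  end-slope) vs regular-spiking (width ≥ 0.5 ms).
* **Sound modulation** — per unit and condition (sitting/running ×
  laser off/on), `MI = (E − S)/(E + S)` with E the mean onset rate
  (0–100 ms) on white-noise trials and S the matched blank rate, then

      running effect     = MI(run, off) − MI(sit, off)
      VIP effect         = MI(sit, on)  − MI(sit, off)
      predicted combined = running effect + VIP effect
      observed combined  = MI(run, on)  − MI(sit, off)

  with the additivity test (rank correlation + regression of observed on
  predicted) and 100-repeat matched-trial-count subsampling of sitting
  trials.
* **Population timescale** — shuffle-corrected distance correlation
  between the binned population rate matrix and running speed, swept over
  a doubling bin ladder from 50 ms, with permutation p-values.
* **Group statistics** — signed-rank/rank-sum tests with effect size
  `r = z/√N`, and Kruskal–Wallis across layers with Bonferroni-corrected
  post-hocs.
* **A calibrated synthetic-session generator** — Poisson spiking with
  additive condition deltas (population means matched to in-vivo values:
  spontaneous 4.87/6.50 Hz sitting/running, onset 15.81/13.97 Hz),
  bout-structured running (~13% running trials), an evoked laminar LFP
  dipole, and class-consistent waveforms — so every stage can be tested
  against recoverable ground truth, including an injectable
  running × laser interaction.

See `docs/methods.md` for estimator details, calibration derivations,
numerical conventions, and known limitations.

## Worked example

```python
import lamstate as ls

params = ls.GeneratorParams(n_units=60, n_trials_per_combo=100, seed=3)
session, truth = ls.generate_session(params)
cfg = ls.PipelineConfig(dcor_bin_start_s=0.1, dcor_bin_ceiling_s=1.6,
                        dcor_shuffles=20, seed=0)
report = ls.run_pipeline(session, cfg)
```

Formatting the report's stage outputs prints:

```
running trials      : 52/400 (included=True)
CSD sink            : channel 11 at 31 ms (generator truth: 10)
cell classes        : 10 NS / 50 RS
sound-responsive    : 54/60 units
sound MI            : sitting 0.55 (matched-trial range 0.51-0.57), running 0.37, mean p = 4.5e-02
additivity          : rho = 0.76 (p = 3.3e-10), slope = 0.67, r2 = 0.61, n = 49
dcor (100 ms bins)  : raw = 0.31, corrected = 0.26, p = 0.00
```

Reading the numbers: 13% of trials were running trials, clearing the
7-trial inclusion floor. The evoked CSD sink was localized one channel
(25 μm) off the generator's true layer-3/4 anchor, and waveform widths
split the population into 10 narrow- and 50 regular-spiking units. Among
sound-responsive units the modulation index drops from 0.55 sitting to
0.37 running — running weakens sound encoding — and the drop survives
matching the sitting trial count to the scarcer running trials (the
100-subsample range stays well above 0.37). Observed combined
running + laser effects correlate strongly with the additive prediction
(ρ = 0.76, slope < 1 reflecting the bounded, nonlinear MI scale — see
`docs/methods.md`), the signature of independent mechanisms. The
distance correlation confirms that population firing tracks running
speed (shuffle-corrected 0.26, p = 0 over 20 permutations).

The same stages are available as a CLI for session directories in the
native on-disk format (`trials.tsv`, `spikes.tsv`, `units.tsv`,
`running.tsv`, `lfp.h5`, `meta.json`):

```sh
lamstate simulate --out session/ --seed 3
lamstate classify-trials session/
lamstate csd session/
lamstate report session/ --out session/report/
```

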