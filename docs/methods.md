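# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `oddwave`. Notation: µV for amplitudes, ms for times;
epochs are channels × samples matrices sampled at 1000 Hz on the half-open
window [−150, 750) ms (900 samples; stimulus onset at sample 150).

## Oddball sequence model

A block is `16 habituation standards → (run of standards, deviant) × 40 →
1 final standard`, with run lengths in [4, 9] summing to 271, so every
deviant is preceded by an unbroken run of 4–9 standards and a block has
328 trials. A session holds six deviant conditions — tense (`past`,
`present`), voicing (`+voi`, `−voi`) and VOT (`+asp`, `−asp`) — three
blocks each (18 blocks, 5,904 trials), ordered uniformly at random over all
orderings with no adjacent repeat (rejection sampling over permutations;
the attempt count is available from the sampler). Habituation trials do
not count toward the first deviant's run: the opening habituation series is
treated as a separate segment from the pseudorandom sequence.

**Run-length sampling.** "Pseudorandom" is realized as *exactly uniform*
over the set of bounded compositions of 271 into 40 parts in [4, 9].
Uniformity is the least-informative choice and is testable: the sampler
draws each run length with probability proportional to the exact count of
completions (bottom-up dynamic-programming table over arbitrary-precision
integers; the uniform index below a count is drawn by bit-rejection so no
floating-point bias enters). Tests compare sampled frequencies against
exhaustive enumeration on small instances.

**Tokens and ITIs.** Each trial's token is drawn i.i.d. uniformly from its
role's inventory (three deviants and 12 standards in tense blocks, five and
five in voicing blocks, one and one in VOT blocks); deviant tokens of one
condition are the critical standards of the sibling condition. Balanced
without-replacement sampling is deliberately *not* used: run-time uniform
choice matches how such experiments present tokens and yields "similar"
rather than identical token counts. The inter-trial interval is an
offset-to-onset gap drawn uniformly from the integers [900, 1100] ms.

**Reproducibility.** All randomness flows from one master seed through
named substreams (`SeedSequence` spawn keys derived from CRC32 of path
labels), so regenerating a session is byte-identical and adding draws to
one stage cannot perturb another.

## Synthetic EEG model

The generator produces epoched data directly (every downstream rule
operates on epochs; continuous recording adds nothing testable here):

```
epoch(trial) = c_participant,contrast · K · [deviant]  +  ε  +  artifact
```

- `c ~ Normal(μ_subj, σ_subj)`, one draw per participant per contrast.
  Defaults µ_subj = −0.84 µV and σ_subj = 2.28 µV — the mean and
  between-participant SD of a reference MMN measured at Cz over 200–400 ms
  (24 participants), which give the assumed effect size d = −0.84/2.28 =
  −0.37.
- `K` is a separable unit-peak kernel: raised-cosine time course over
  200–400 ms and Gaussian spatial falloff from Cz (FWHM defaulting to the
  median inter-electrode distance; mastoids weighted 0). The kernel's peak
  matches the electrode and window the reference effect was measured at.
- `ε` is i.i.d. Gaussian with SD `σ_trial` at every channel and sample —
  white in time and space. This is the minimal structure consistent with
  the two-level variance decomposition the power analysis uses; spatial or
  temporal correlation is out of scope (see Limitations).
- Artifacts: with probability `artifact_rate` per trial, a ±`artifact_amplitude`
  (default 120 µV) square pulse of 100 ms lands on one random scalp channel
  inside −150..600 ms. Metadata records the flag and the drawn `c`, so
  rejection and recovery can be validated against ground truth.

**σ_trial has no reference value.** The single-trial noise SD is a
required parameter with *no default*: no published value exists for this
component, and every power figure depends on it, so the user must own the
choice. Two magnitudes are used in the documentation:

- *30 µV* as a plausible single-trial scale in the power-analysis model,
  where noise enters only through condition means (no amplitude screen).
- *10 µV* in full-EEG pipeline studies. White noise interacts with the
  75 µV screen much more aggressively than real (autocorrelated) EEG: at
  σ_trial = 20 µV the probability that at least one of the ~9,000 screened
  white-noise samples exceeds 75 µV is ≈ 0.4 per trial, which would reject
  nearly everything at 30 µV. At 10 µV clean-trial rejection is ~10⁻¹⁰
  while 120 µV pulses are still caught essentially always. This is a
  white-noise artifact of the generator, not a property of real data, and
  is the reason pipeline-level simulations run at 10 µV.

**Layout.** The 64-channel scalp montage uses extended 10/20 labels with
positions from the idealized-head montage shipped with MNE-Python,
projected to 2-D; neighbors come from a Delaunay triangulation with edges
longer than 1.8× the median pruned (hull-spanning shortcuts), re-attaching
any channel the pruning isolates. Micro-layouts (`chain-N`, `complete-N`,
`mesh-RxC`) give hand-checkable neighbor structures for tests.

## Preprocessing

Stage order is fixed and provenance-logged: interpolation → mastoid
re-referencing → whole-epoch demeaning → (ICA placeholder, logged as
skipped — the synthetic data carry no ocular components) → 100 ms
pre-stimulus baseline → 75 µV rejection → 30 Hz low-pass. Reordering
requires an explicit override that is recorded and warned about. All
operations are pure: inputs are never mutated.

- *Rejection* removes a trial iff any **scalp** channel exceeds 75 µV in
  absolute amplitude at any sample in −150..600 ms; mastoid/reference
  channels are not screened (the original rule's treatment of non-scalp
  channels is unstated; screening signal channels only is the conservative
  reading). "Exceeds" is strict: a 75.0 µV peak is kept.
- *Filtering* uses a Hamming-windowed sinc FIR with transition bandwidth
  25% of the cutoff (7.5 Hz at 30 Hz), order 3.3/(normalized transition
  width) rounded to even — 441 taps at 1000 Hz — applied by centered
  convolution with reflect padding, which is exactly zero-phase for the
  symmetric kernel. The designed response (passband ripple < 0.1 dB,
  stopband attenuation > 50 dB; 72 dB at 60 Hz) is written into the
  provenance log. Epochs are filtered after segmentation, hence the
  explicit reflect-padding policy.
- *Interpolation* replaces up to three bad channels by the
  inverse-distance-weighted mean of their good neighbors. Spherical-spline
  interpolation would be more faithful to common practice but is not
  exactly testable by hand; the difference is irrelevant for the synthetic
  data, which have no realistic topographies.

## Identity-MMN construction

Excluded from analysis: all habituation trials, the first deviant of each
block, and the standard immediately after every deviant — leaving
(40−1) × 3 = 117 analyzable deviants per condition. "First series of
standards" is read as exactly the habituation segment, not additionally the
4–9 run before the first deviant (the habituation series is the only
segment the design singles out; the alternative reading would remove 4–9
more standards but no deviants). The iMMN for a deviant condition is the
mean ERP of its deviant tokens *as deviants* minus the mean ERP of the same
tokens *as standards* in the sibling block type, both restricted to
analyzable, artifact-free trials. Participants enter group analysis only
with ≥ 30 trials in every condition (inclusive bound); the stricter
original profile (≥ 50) is available as a config switch, but its
signal-to-noise criterion is not implemented (the method lives outside this
package's scope).

**Amplitude readout.** `kernel_aligned_amplitude` divides the difference
wave's mean over the kernel support at the peak channel by the kernel's own
support mean, so on noiseless data the estimate equals the generating
effect exactly for any unit-peak time-course shape.

## Cluster-based permutation test

Pointwise statistic: one-sample t of the per-participant difference waves,
df = n−1. Zero-variance cells are degenerate synthetic inputs: 0/0 is
defined as t = 0 and c/0 as ±∞, both warned; infinite cells never enter
clusters. Cluster forming: one-tailed p < 0.1 in the tested tail (negative
by default — the MMN direction), then a single pruning pass per time slice
removing cells with fewer than `minnbchan` = 2 suprathreshold spatial
neighbors at the same sample, then connected components over spatial
neighbors at the same sample plus lag-1 temporal adjacency on the same
channel (no wraparound). Cluster score: mass (summed t); the permutation
reference is the most extreme mass per iteration, 0 when an iteration has
no cluster.

The null is realized by independent whole-wave sign flips per participant —
the standard exchangeability argument for paired designs (the design's
exact permutation scheme is not pinned down anywhere; sign flipping is the
within-participant realization). p = (r+1)/(n_perm+1), so p is never 0 and
the observed data count as one permutation; this convention guarantees
validity at any n_perm. The permutation loop exploits that sign flips leave
each cell's sum of squares invariant, so only means are recomputed per
iteration; clustering runs on sparse connected components.

**Correctness and calibration.** Cluster extraction is verified cell-for-cell
against an exhaustive prune + flood-fill oracle over *every* mask of small
grids (≤ 4,096 masks × 3 pruning levels per graph). Familywise error,
measured over 400 null datasets (15 participants, 12 channels × 50 samples,
200 permutations), sits inside the 95% binomial band around 0.05.

**Detection ceiling.** With per-participant effects Normal(−0.84, 2.28)
and small residual noise, the difference waves are nearly rank-one
(effect × kernel), and the cluster max-mass sign-flip test is then
equivalent to a one-sided sign-flip test on the drawn effects. Its
detection probability is therefore capped by the one-tailed paired-t power
at d = 0.37, n = 60 — 0.880 — and measured detection rates hover at
0.87–0.90. Aggregating over the cluster cannot beat this bound in the
rank-one limit; only trial-level noise averaging (more trials) or more
participants move it.

## Power analysis

Each simulated dataset draws `c_p ~ Normal(μ_subj, σ_subj)`; participant
condition means are `c_p + Normal(0, σ_trial/√n_dev)` for deviants and
`Normal(0, σ_trial/√n_std)` for standards with `n_std = n_dev·85/15`
(ratio configurable; 50:50 reproduces the classic equal-n paired design).
The one-tailed paired t at α = 0.05 tests whether deviants are more
negative. The headline mode mirrors a single-electrode window mean, not
the cluster test (cluster-test power is available only through the full
pipeline path, which is far more expensive).

Benchmark: as σ_trial → 0 the power equals
`1 − F_nct(t₁₋α,df; df = n−1, ncp = |d|√n)`; the implementation was checked
against an independent quadrature oracle of the noncentral-t tail
(integrating `Φ(ncp − t_crit·√(u/df))` against the χ²_df density; agreement
to 10⁻⁹). Published power percentages for this paradigm are **not**
reproduction targets: they depend on trial-level variance components that
were never printed, which is exactly why σ_trial is a mandatory input here.

Grid simulations use common random numbers along the participant axis
(draw once at the largest n, slice), making power exactly monotone in n up
to test discreteness; the deviant-count axis shows the expected plateau
once `σ_trial²/n_dev` falls below `σ_subj²`.

## Problem sizes used in validation

Validation studies are sized to run on one CPU in about a minute total:
design counts use the full 18-block session; cluster calibration uses 400
null datasets of 15 participants on a 12-channel mesh × 50 samples with 200
permutations; detection uses 100 datasets of 60 participants on the same
grid; power comparisons use 4,000 simulations; effect-mean recovery runs 60
participants through the complete pipeline on a 4-channel chain layout with
one block pair each. These scales keep Monte-Carlo error well below the
tolerances being checked.

## Known limitations

- Noise is white in time and space; no 1/f background, drift, line noise,
  ocular/EMG morphology, or realistic forward-model topographies. Passing
  tests demonstrate correctness of the *analysis chain*, not robustness to
  real-EEG noise structure.
- ICA is a logged no-op; the signal-to-noise participant criterion of the
  stricter inclusion profile is not implemented.
- The amplitude screen's behavior on white noise differs sharply from real
  EEG (see σ_trial above).
- Continuous-data filtering and vendor EEG formats are out of scope; the
  epochs container is a plain HDF5 layout, not BIDS.
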