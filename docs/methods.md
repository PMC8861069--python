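# Methods

## The translation model

The translator is a one-dimensional adaptation of the pix2pix conditional
GAN. The generator input is one channel's subject-average ERP over the
0–1000 ms post-stimulus window sampled at 256 Hz — exactly 256 samples
under the package's half-open window convention (`[start, stop)`, sample
index `floor(t·fs/1000)`), which makes the signal divisible by 2⁸ and the
architecture's arithmetic exact: eight stride-2 kernel-2 convolutions reach
a length-1 bottleneck, eight stride-2 transposed convolutions return to 256
samples, and the PatchGAN discriminator's four stride-2 blocks plus a 1×1
map emit 256/2⁴ = 16 patch scores.

Objective and training regime: discriminator ascends
`E[log D(x,y)] + E[log(1 − D(x,G(x)))]`; the generator descends the
non-saturating heuristic `−E[log D(x,G(x))]` plus `λ·E[|y − G(x)|]` with
λ = 100; batch size 1, 15 epochs, Adam with learning rate 2·10⁻⁴ and
β₁ = 0.5 (the conventions of the 2-D source architecture), weight
initialization N(0, 0.02²), seeded. One independent model is trained per
EEG channel; subject-level K-fold cross-validation (default K = 10)
guarantees that every reported generated signal comes from a fold where
that subject was held out. Expectations in the objective are realized as
means over patches and samples; discriminator scores are clamped at 10⁻⁷
inside logarithms.

Decisions where the design was genuinely open:

- **Normalization.** Per-channel min–max to [−1, 1] (the tanh range),
  fitted jointly over *both* conditions of the training split. Fitting per
  condition would remove part of the between-condition amplitude difference
  — the very effect of interest — during normalization. Test-split values
  may fall outside [−1, 1] and are never clipped. The inverse map restores
  µV-space for all reported signals.
- **Batch norm with batch size 1** degenerates to per-feature-map
  (instance) normalization over the temporal axis; the same batch
  statistics are used at inference so generation is deterministic per
  input. At the length-1 bottleneck the normalized activation is exactly
  zero and information flows through the skip connections — a well-known
  property of this architecture, kept as printed (a `batchnorm=False`
  switch exists).
- **Dropout** (50% on the first four decoder blocks) is active only during
  training; inference is deterministic. The 2-D source architecture samples
  dropout at test time; determinism was preferred here so that fold outputs
  are exactly reproducible.
- **Encoder/decoder naming.** The printed architecture lists the
  *downsampling* stack as C'64…C512 and the *upsampling* stack as
  CD512×4–C256–C128–C64–final; the implementation follows that data flow
  (downsampling = encoder).
- **Numerics.** The network core is numpy with hand-written
  backpropagation; convolutions with kernel 2 / stride 2 are exact
  reshape-plus-matmul operations, so the whole training loop runs inside
  BLAS. The per-channel models are evaluated as one batched "model bank"
  (identical arithmetic to training them separately) in float32. Gradient
  correctness is verified against finite differences in the test suite
  (float64, away from rectifier kinks).

## Synthetic cohorts

The cohort generator produces the statistical structure the analysis
assumes, not biophysically detailed EEG. A subject's average for one
condition is

```
x_s(c, t) = Σ_k (a_k(cond) + α_sk) · w_k(c) · exp(−(t − μ_k(cond) − τ_sk)² / 2σ_k²)
            + ε  ,   ε ~ N(0, ν_cond²) i.i.d.
```

Gaussian components k (P1, N1, N2, fronto-central P3, parietal P3) with
fixed topographies `w_k` over a schematic spherical montage (8 named 10-05
electrodes by default; a 60-electrode cap is available). Per-subject
amplitude offsets `α_sk ~ N(0, 2.0²) µV` and latency offsets
`τ_sk ~ N(0, 20²) ms` are drawn once per subject and shared across
conditions, so the cohort is paired and every subject has its own component
amplitudes *and latencies* — without the latency variability, "moving a
component in time" would degenerate to memorizing a constant target
latency. Default condition effects are the component quantifications
reported for real Go/Nogo cohorts (N2 at Cz −3.9 vs −7.09; FC1 P3 1.86 vs
8.25; parietal P3 9.26 vs 8.32, all µV/m²). Residual noise on the averages
is ν = 1 µV per condition.

Presets: `paper_like` (amplitude-only condition effects), `latency_shift`
(equal amplitudes, both P3 components 150 ms later in Nogo), `asymmetric_noise`
(`paper_like` with ν_Go = ν_Nogo/√3, standing in for the 3:1 Go/Nogo trial
ratio), `identity` (conditions identical, zero noise).

The single-trial mode emits a continuous multichannel session (default
500 Hz) from the task design (450 trials, 70/30 Go/Nogo, 200 ms stimuli,
1000–1300 ms jittered ITI, lognormal RTs with 98.75% Go accuracy and 11.86%
false alarms), with white (4 µV) plus 1/f (6 µV) background noise — about
3.5 µV SD inside the 0.5–18 Hz analysis band, a clean laboratory recording;
this level is what makes 40 trials/condition recover the band-limited
template at r > 0.95 through the full chain. Optional artifacts (voltage
steps, ±100 µV excursions, flat stretches, fast drifts) are injected at
chosen trials to exercise each rejection rule. What the simulator does
*not* model: ocular/muscle/cardiac artifact morphology, alpha rhythms and
other structured background, volume-conduction-consistent topographies,
latency–amplitude correlations, RT-locked component jitter. Passing tests
on these cohorts therefore demonstrate the pipeline's correctness and the
model's behavior under controlled conditions, not performance on real EEG.

## Preprocessing

Session order: polyphase resampling to 256 Hz → zero-phase band-limiting
(0.5 Hz high-pass and 18 Hz low-pass, each an 8th-order Butterworth — a
48 dB/oct asymptotic slope at 6 dB/oct per order — applied
forward–backward) → optional spherical-spline interpolation of a named
electrode → segmentation into 4-s epochs around correct-trial markers (Go
responses must precede the 1200 ms deadline; Nogo trials must have no
response) → the four rejection rules → −200–0 ms baseline → per-condition
averages cropped to 0–1000 ms → optionally the CSD transform. All stages
except rejection are linear, so their order only affects edge behavior.

Rejection rules, evaluated on every channel with 1-sample-step sliding
windows: adjacent-sample step > 50 µV; max−min within any 200 ms window
> 100 µV; any |amplitude| > 100 µV; max−min within any 100 ms window
< 0.5 µV. An epoch is dropped if any rule fires anywhere. "Difference of
values within an interval" is read as max−min per window. On the synthetic
sessions the flat-signal rule removes a few percent of clean epochs: smooth
band-limited synthetic noise reaches quiet 100 ms stretches more often than
real EEG with its structured background. Manual inspection and ocular ICA
have no synthetic counterpart and are logged as skipped stages.

The CSD transform is a Perrin-style spherical-spline surface Laplacian:
spline order m = 4, Legendre series truncated at degree 10, regularization
e⁻⁷ added to the g-matrix diagonal (the printed "precision 2.72⁻⁷" read as
e⁻⁷; both the degree and the regularization are config fields), solved with
a zero-sum constraint and scaled by an 8.5 cm head radius to µV/m². The
implementation agrees with an independent spherical-spline CSD
implementation to machine precision in the test suite; interpolation uses
the same spline machinery.

## Statistics

- Window means over half-open ms windows at named electrodes, per subject
  and condition.
- 2×2 within-subject ANOVA via difference contrasts: for two-level factors
  each effect's F is the squared paired t of its contrast;
  partial η² = SS_effect/(SS_effect + SS_effect×subject). Verified against
  a brute-force sums-of-squares decomposition and a reference
  implementation.
- Paired Cohen's d = mean(Δ)/sd(Δ) (n−1 denominator); degenerate zero-SD
  input is an error, not a zero.
- JZS Bayes factor for the paired t-test: Cauchy prior (default scale
  0.707) on the standardized effect via the usual scale-mixture integral,
  `scipy.integrate.quad`; two-sided. Verified against a noncentral-t
  marginal-likelihood quadrature. Display convention: BF₁₀ capped at 30
  for plots, raw value preserved.
- Cluster-based permutation test: per-sample dependent t; entry threshold
  the two-sided t quantile at α = 0.05 with df = n−1; a sample enters only
  with ≥ 2 simultaneously supra-threshold spatial neighbors (channel
  adjacency from a 2-D distance threshold tuned to mean degree ≈ 4);
  clusters are connected components under channel adjacency × temporal
  contiguity, same sign; mass = Σt; the null is the maximum |mass| over
  1000 per-subject sign flips; p = (1 + #{null ≥ observed})/(draws + 1), so
  the attainable floor is 1/1001. Type-I error is simulation-checked in the
  acceptance suite. Significance grids are aggregated into 50 ms epochs
  (20 per second; 50 ms is 12.8 samples at 256 Hz, boundaries snap to the
  earlier sample and the aggregation notes it).

## Scaled-down experiment sizes

The cross-validated GAN experiments in the test suite and acceptance script
run at desk scale, chosen once: 40-subject cohorts, 8 channels, 5 folds, 15
epochs; network width (`base_filters`) 16 for the noisy fixtures, 32 for
the noise-free identity benchmark (whose accuracy is capacity- rather than
noise-limited), 8 for the repeated direction-comparison runs and the
examples; the published width 64 remains the library default. At these
sizes the paper-style fixture reaches mean held-out r ≈ 0.83 against a
noise ceiling of ≈ 0.87 (the correlation between each subject's noise-free
template and its noisy average), and the identity fixture r ≈ 0.992.

## Comparative experiments and known limitations

Two qualitative claims are probed on synthetic cohorts:

- **Latency shifts are harder than amplitude changes.** Reconstruction
  error grows with the size of the between-condition latency shift: at a
  sub-width shift (50 ms against 35–45 ms component widths) the latency
  task is *not* harder than amplitude recoloring — the network shifts a
  bump locally as easily as it rescales one — and the cost crosses the
  amplitude-task error between roughly two and three bump widths. The
  `latency_shift` preset therefore encodes a significant shift (150 ms),
  where translation is measurably worse than on `paper_like` both against
  the real targets and against the noise-free templates.
- **Direction asymmetry under asymmetric noise.** The expectation that
  translating the cleaner condition into the noisier one (Go→Nogo) works
  better does **not** reproduce at desk scale: across three metrics
  (per-subject L1, cohort-average L1, and L1 against the noise-free
  synthetic templates), cohort sizes 20 and 40, and training budgets from
  240 to ~3400 steps per model, Nogo→Go is consistently more accurate.
  Two desk-scale mechanisms dominate: with tens of training subjects the
  noisier Nogo *training targets* corrupt the learned Go→Nogo map more than
  noisy inputs corrupt the reverse map (with hundreds of subjects,
  unbiased target noise averages out), and Go→Nogo must amplify the
  fronto-central P3 roughly 4.4-fold, amplifying input-side error, whereas
  the reverse direction attenuates it. The corresponding acceptance test
  asserts the original expectation and fails; this is a documented
  limitation of the desk-scale reproduction, not of the implementation.

Other limitations: the montage is schematic (real electrode geometry can be
loaded but is not bundled); the translator consumes averaged ERPs, not
single trials; channels are translated independently, so cross-channel
covariance of the generated cohort is inherited from the inputs rather than
modeled; BrainVision/EDF ingestion assumes 10-05 channel names and carries
no behavioral log (a placeholder RT marks all trials correct).
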