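# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limits of `dynconn`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Preprocessing

Continuous EEG (microvolts, 500 Hz, 10-20 labels) is re-referenced to the
mean of the mastoid channels TP9/TP10, band-passed 0.1–30 Hz with a
zero-phase Hamming windowed-sinc FIR (transition widths 0.1 Hz at the low
edge, 7.5 Hz at the high edge; ~53 dB stopband), cut into trials on the
half-open grid [−200, 1000) ms (600 samples at 500 Hz, onset at index
100), baseline-corrected to the −200–0 ms mean, and screened for
amplitude artifacts. A 50 Hz notch exists but is off by default, treating
mains suppression as an acquisition property.

The rejection statistic is the per-trial maximum absolute voltage across
channels (peak-to-peak available as an option); trials above
`mean + k·SD` of that statistic over trials (k = 3) are dropped, with a
strict inequality so that identical trials (SD = 0) are all kept. The
rule is applied per trial on filtered data; whether it should run per
channel or on raw data is a genuinely open choice and the per-trial form
was picked as the simplest deterministic one.

The 27-electrode network montage (Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6
T7 C3 Cz C4 T8 CP5 CP1 CP2 CP6 P7 P3 Pz P4 P8 O1 O2) is a symmetric
frontal/central/temporal/parietal/occipital cover of the 10-20 system,
configurable.

## Time-varying MVAR (Kalman MVAAR)

State: the vectorized lag matrices `[A_1(t) … A_p(t)]` (n²p entries),
evolving as a random walk with process covariance `uc·I`. Observation:
`y(t) = [A_1 … A_p] φ(t) + e(t)` with `φ(t)` the stacked p lagged sample
vectors. Because all output channels share the regressor φ(t), the state
covariance factorises as `I_n ⊗ P` with P of size (np × np) whenever the
observation noise is isotropic; the implementation tracks that factor,
which is what makes a 600-step, 27-channel filter pass affordable. The
observation-noise level is adapted by exponential smoothing of the mean
squared innovation (factor 0.02); the full innovation covariance is
smoothed alongside for reporting.

Parameters: order p = 5 (the epoch-level default; an information-criterion
helper `select_order` exists but is not auto-applied), uc = 1e-3, initial
state zero with unit initial covariance. Coefficients before the first
estimable sample (t ≤ p) are back-filled with the first estimate so time
grids stay aligned; a `store_every` argument keeps coefficients on a
decimated grid (the pipeline uses every 25th sample = 50 ms) to bound
memory.

Behavioural trade-off (measured in the tests): larger uc tracks a planted
coefficient step faster but wobbles more in steady state — at uc = 1e-3 a
0 → 0.5 step is crossed at half-height within a few tens of samples,
while the stationary wobble has sd ≈ (uc·r)^¼. For stationarity checks
the near-RLS limit (uc ≤ 1e-5) is therefore the appropriate setting, and
the white-noise and pointwise-recovery tests use it; the default uc is
kept for everything event-related.

## ADTF

`Ā(f,t) = I − Σ_k A_k(t)·exp(−i2πfk/fs)`, `H = Ā⁻¹` (batched LAPACK
inversion; singular points get 1e-8 jitter and are counted). The ADTF is
sink-row-normalized |H|²; band integration is the ratio of band sums,
which preserves row normalization exactly (the per-frequency-mean variant
is available). The frequency grid is 1–30 Hz at 1 Hz: a 1.2 s epoch
cannot resolve 0.1 Hz, so the grid starts at 1 Hz even though the
band-pass opens at 0.1 Hz. Diagonal (self-inflow) entries are kept in the
matrices but zeroed before graph metrics. Per-trial networks are averaged
entrywise; averaging N noisy trials shrinks entrywise RMSE like 1/√N.

## Graph properties

On the symmetrized weight matrix (w + wᵀ)/2 with zero diagonal
(directed variants — Fagiolo clustering, directed Dijkstra — behind a
flag):

* C — mean over nodes of the geometric-mean triangle intensity
  Σ (w_ij w_ih w_jh)^⅓ / (k_i(k_i−1)). Weights are used as given (ADTF
  weights are already in [0,1]); no per-graph max rescaling is applied,
  because rescaling would make C invariant to exactly the global strength
  differences the cohort analysis needs to see.
* Shortest paths via Dijkstra on lengths 1/w. L averages distances over
  connected ordered pairs (+∞ sentinel for an empty graph); Ge averages
  1/d over all ordered pairs with disconnected pairs contributing 0; Le
  is the mean over nodes of the global efficiency of the neighborhood
  subgraph (< 2 neighbors ⇒ 0).

Edge-wise group tests are Welch t-tests per directed edge at the snapshot
latency (nearest grid sample), retaining p < α = 0.05 *uncorrected* —
deliberately, as the retention rule of the analysis being implemented; a
BH-corrected mode exists behind a flag. Under a group null the expected
retained fraction equals α (verified to ±0.01). Subject-level properties
are computed on the time-averaged weight matrix over 0–1000 ms
(metrics-then-average available). Pearson r with CRS-R totals uses the
t transform with n−2 degrees of freedom.

## Synthetic data

The generator defines the study conditions end to end:

* **Paradigm** — blocks of 86 standards + 12 happy + 12 sad deviants;
  deviants occupy distinct gaps between standards, the weakest constraint
  guaranteeing no two rare sounds in a row.
* **Epochs** — a stable VAR background: diagonal AR(2) (0.5, −0.2) plus a
  weak always-on directed ring (0.15 at lag 1) shared by all groups. The
  ring matters: with a purely diagonal background a single planted edge
  makes clustering respond non-monotonically to coupling strength;
  a weak shared background restores the expected ordering (C, Ge, Le rise
  and L falls as strength grows — asserted in the tests). The planted
  contrast is one Fz → Pz edge switched on at 300–1000 ms during deviant
  trials only, strength 0.4 (MCS-like) vs 0.1 (UWS-like), scaled by the
  subject's latent strength multiplier. Innovations are Gaussian, sd 4 µV
  (epoch sd ≈ 5 µV — a realistic single-trial noise floor against µV-scale
  components).
* **ERP templates** — Gaussian bumps with fixed scalp weights: N1
  (150 ms, σ 25 ms, Fz-maximal; −3 µV standard / −6 µV deviant in both
  groups), P3a (300 ms, σ 45 ms, frontal; +5 µV deviant, MCS-like only),
  LPP defined but zero-amplitude in both patient groups. Gaussian bumps
  were chosen over windowed half-sines because they are analytically
  integrable, which the component-measurement oracles exploit.
* **Cohort** — per aetiology group, (latent strength, CRS-R total) pairs
  are bivariate Gaussian with the configured correlation (0.5 traumatic,
  0.0 nontraumatic); totals are 7 ± 3, clipped to [0, 23] and decomposed
  greedily into sub-scores respecting the CRS-R maxima (4,5,6,3,2,3).
  Diagnosis is assigned by ranking totals within the group (upper half
  MCS): the diagnosis is itself a reading of the behavioural scale, and
  assigning it any other way would either break the MCS > UWS score
  ordering or leak a diagnosis-driven correlation into the nontraumatic
  group, which must stay null.
* **Association model** — for cohort-level association studies each
  subject's network is the band-integrated transfer function of the
  coupling-on VAR at a nominal (MCS-level) strength scaled by the
  subject's multiplier, plus additive edge noise of sd 0.005. That noise
  level corresponds to the 10–50 % relative error a 60-trial average
  leaves on edge weights of 0.01–0.05; re-estimating EEG per subject for
  every association replicate would add nothing statistically and is far
  more expensive.

What the generator does **not** emulate: volume conduction and field
spread (channels mix only through the planted VAR couplings), ocular/
muscle artifacts, non-Gaussian noise, between-subject montage or latency
variability, and real voice acoustics. Passing tests therefore establish
that the estimators recover what they are pointed at under a faithful
generative model of the *analysis* assumptions — not that the pipeline is
robust to everything real EEG does.

## Desk-scale replication study

The end-to-end study (`run_replicate`) uses 8 subjects per group with 60
artefact-free deviant trials each, 20 seeded replicates — and a reduced
10-electrode montage (Fz F3 F4 Cz C3 C4 Pz P3 P4 O1). The montage
reduction is purely a problem-size choice: per-trial Kalman+ADTF cost
scales ~n³ in channels, and ten channels preserve the frontal→parietal
contrast being recovered. Outcomes per replicate: (a) the planted edge
retained with direction MCS > UWS at 300/600/1000 ms and not retained at
100 ms; (b) FDR significance at Fz inside the P3a window in the MCS-like
group only, where a component counts as present only with ≥ 5 significant
samples (isolated single-sample discoveries, which FDR control permits,
are not a component); (c) the traumatic-group bootstrap CI of r(Ge,
CRS-R) covering the planted 0.5, and |r| < 0.4 in the nontraumatic group.

One calibration fact worth stating: with n = 16 and a true null, the
probability of |r| < 0.4 is P(|t₁₄| < 1.63) ≈ 0.875, so the nontraumatic
null criterion hovers near its own threshold by construction; the
acceptance script reports the realized rate rather than hiding it.

## Numerical choices and degenerate inputs

* Zero-variance t-test points → t = 0, p = 1 with a logged warning, never
  NaN. BH-FDR pools channels × time into one family.
* Singular Ā(f,t) → jittered inverse (1e-8·I), with a logged count; zero
  ADTF rows → uniform row.
* Amplitude rejection with SD = 0 keeps ties; rejecting every trial is a
  pipeline error.
* Empty graphs: C = Ge = Le = 0, L = +∞. Scaling all weights by c scales
  Ge by c and leaves edge-test retention patterns unchanged (t-tests are
  scale-invariant) — both asserted.
* The pipeline writes TSV with a fixed float format and hashes its
  effective config; identical config + seed reproduce outputs
  byte-identically, and completed stages are skipped on resume via
  `<stage>.done.json` markers.

## Limitations

Sensor-space directed connectivity cannot distinguish genuine cortical
interaction from shared sources; the ADTF's sink normalization makes
inflow fractions relative, so absolute flow magnitudes are not
interpretable across montages of different size. The Kalman filter runs
forward only (no smoothing), so coefficient estimates lag abrupt changes
by the tracking latency measured in the tests. Edge retention is
uncorrected by design and should be read as descriptive, not
confirmatory. Model order, uc and the integration band are assumptions —
the analysis they come from does not publish them — and all are exposed
in the configuration.
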