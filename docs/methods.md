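# Methods

This note documents the models, numerical conventions and design choices
behind `dyadscan`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Synthetic cohort generator

### Signal model

Every subject × modality series follows the additive inter-subject
correlation decomposition

    x_A(t) = α·c(t) + β·id_A(t) + ε_A(t)

* `c(t)` — stimulus-locked component, identical for all subjects: white
  noise low-passed to ~0.5 Hz (4th-order zero-phase Butterworth),
  standardized, then modulated by a per-segment amplitude envelope
  (each localizer clip gets its own random amplitude in [0.8, 1.6],
  silences sit at 0.15, the drama at 1.0; the envelope is smoothed over
  ~1 s so segment transitions are not step discontinuities).
* `id_A(t)` — idiosyncratic component: an equally smooth process, plus —
  for the action-unit modalities — a sparse train of Gaussian bursts
  (0.3–1.2 s wide, gamma-distributed amplitudes, `burst_rate` = 6/min)
  emulating discrete facial events.
* `ε_A(t)` — white Gaussian noise with `noise_sd` = 0.5.

Defaults `α = β = 1.0` give a between-singles window ISC around
r ≈ 0.3–0.5, a plausible regime for stimulus-locked facial signals.

### Modality shaping

Action-unit intensities from automatic face tracking are bursty with long
stretches of exactly zero; gaze angle is smooth and rarely silent. The
generator therefore soft-thresholds the AU mixtures at the
`burst_floor`-quantile (default 0.35), zeroing that fraction of samples,
and low-passes the gaze mixture at `gaze_smoothness` = 0.5 Hz instead.
Every signal is finally min–max rescaled into [0, 1] per signal —
Pearson-based analyses are affine-invariant and the RQA radius adapts per
window, so per-signal scaling changes nothing downstream while keeping
each subject's generation independent of the rest of the cohort.
`burst_floor` = 0.35 keeps zero-segments clearly visible while making a
fully-zero (constant) 20 s drama window — which would produce a missing
feature row — vanishingly unlikely, so default cohorts yield the complete
36 × 81 = 2,916-row feature table.

### Within-dyad coupling

`couple_dyad` models dialogue-like turn taking: time is cut into 5 s
epochs; in even epochs partner A "attends" B and vice versa in odd epochs,
so the influence is never simultaneous. While attending, the subject's
signal becomes a blend `x' = (1−γ)·x + γ·g(x_partner(t − lag))` with
`γ = coupling_weight` (default 0.6) and `lag` = 1 s. Two response mappings
are provided:

* `mirror` (default): `g(u) = u` — the attending partner tracks the other,
  raising lagged cross-correlation within the pair;
* `complement`: `g(u) = 1 − u` — a compensatory reply (one partner's
  activity met by the other's withdrawal), driving the zero-lag
  correlation of true pairs strongly negative. Social coupling is a
  functional relation between *different* states of two systems, not
  imitation; the complement mode realizes that regime.

`γ = 0` is the exact identity. Outputs are re-clipped to [0, 1]. Coupling
can be confined to a time window (`coupling_window`), which is how
localized effects are planted for scan experiments.

### Planted weak-coupling group effect

The weak coupling model hypothesizes that dyadic interaction induces a
component shared by *all* paired-group subjects regardless of partnership.
`sp_shared_weight` implements exactly that: one extra smooth process per
modality, common to every SP subject, blended into their signals inside
`coupling_window`. Pairwise coupling alone cannot produce a strong
weak-model contrast — it moves only the 9 true-pair cells of the 630-cell
RDM, and any attenuation-style group effect drags the 324 mixed SS–SP
cells halfway along with the 153 SP–SP cells, capping the achievable rank
correlation — so this is the mechanism used to validate the scan's
localization power.

### What the generator does not emulate

Real AU/gaze traces have heavier-tailed amplitude distributions, tracker
dropouts and artifacts, non-stationary baselines, and richer spectral
content than the ~0.5 Hz processes used here; dyadic behavior is far more
structured than alternating 5 s epochs. Passing tests therefore establish
that the *pipeline* recovers effects of the assumed form at study scale —
not that real recordings contain such effects, nor calibrated effect sizes
for them.

## Similarity analysis

* Correlation distance `d_P = 1 + r`; RDM diagonal fixed at 2; subject
  ordering is always the SS block (sorted) followed by SP subjects with
  true pairs adjacent, carried as metadata with every RDM.
* Zero-variance windows (all-zero AU stretches) have undefined Pearson r;
  those cells are recorded as NaN and dropped pairwise in RDM comparisons
  rather than silently coerced to 0.
* Localizer RDMs use a 20 s window from clip onset — the 12 s clip plus
  8 s of the following silence, capturing lingering responses.
* RDM-to-RDM and RDM-to-model comparisons use Kendall tau-b (tie-corrected,
  two-sided analytic p). In the per-clip comparison matrices, cells are
  masked at p < 0.05 without multiplicity correction; FDR control is
  applied only in the sliding-window scan, where the multiplicity is three
  orders of magnitude larger.

### Sliding-window scan inference

RDM cells are not independent observations — each subject contributes to
n−1 cells — so the analytic tau p-value is drastically anticonservative
for model comparisons (measured: ~40–66 spurious intervals per null scan
of 1601 windows). The scan therefore keeps tau-b as the reported statistic
but draws its p-value from a **subject-relabeling permutation null**: group
labels are permuted over subjects (equivalently, RDM rows/columns), the
statistic is recomputed for each of 1000 shared permutations, and the
two-sided p is `(1 + #{|τ*| ≥ |τ|}) / (1 + P)`. Because the model vector
is binary, tau-b reduces to a tie-corrected rank-sum over the model-2
cells, so each permutation costs one gather of precomputed mid-ranks; a
full 1601-window scan runs in seconds. BH-FDR is applied across windows
(rejection at q < α, α = 0.05) and only runs of ≥ `min_run` = 2
consecutive significant windows are reported, as half-open intervals in
0-based drama seconds (window [s, s+20)).

## Recurrence quantification

* No embedding (`D = τ = 1`); requesting `D > 1` is rejected. Only
  between-subject comparisons matter here, and unembedded plots compare
  as well as embedded ones while avoiding two unidentifiable parameters.
* The line of identity is excluded from `N_p`, `N_rec` and all line counts
  by default (`exclude_loi`). Minimal line lengths `l_min = v_min = 2`.
  Lines truncated by the matrix border count at their observed length.
* Radius selection is an exact empirical quantile of the n(n−1)/2 pairwise
  distances: `E` is placed midway between the k-th and (k+1)-th order
  statistics, `k = round(target·m/100)`, so the strict `< E` condition
  recurs exactly k pairs — deterministic, and exact up to pair-count
  quantization (for 600-sample windows, 3.0% to four decimals). When a tie
  atom straddles the quantile — exact-zero plateaus of thresholded AU
  signals — no radius can realize the target; `E` advances past the atom
  and the achieved rate (recorded on every plot) exceeds the target. A
  constant window has no valid radius: its features are set missing and
  the row is later dropped.
* The diagonal line-length histogram is counted on the upper triangle (one
  entry per mirrored pair); DET doubles the point count back to the full
  matrix so that `DET = 100·N_diag/N_rec` uses consistent totals. ENTR is
  the base-2 Shannon entropy of the histogram (invariant to the
  mirror-counting convention); ENTR = 0 whenever at most one distinct line
  length exists. LAM counts vertical runs over all columns.
* Signals are used exactly as generated/recorded — no per-window
  re-normalization — since the per-window radius search already adapts the
  scale.
* `rr_linearity_diagnostic` reports the quantifiers at 2/3/4% target rates
  with a local linearity residual. The fixed-rate convention is trusted
  where that scaling is near-linear; the diagnostic is informational and
  never enforced.

## Classification

* Features: DET, ENTR, LAM × three modalities = 9 columns; RR is excluded
  because the radius search pins it at the target. Rows missing any
  feature are dropped (counted), never imputed.
* Engine: gradient-boosted decision trees (LightGBM), 100 trees, learning
  rate 0.1, single-threaded and deterministic. Hyperparameters — tree
  depth uniform on {3..8}, L2 regularization log-uniform on [0.1, 30] —
  are drawn by a seeded randomized search (default budget 20; the
  full-scale evaluation in the acceptance tests uses 10) and scored on an
  internal 75/25 validation split of the training rows only; the winner is
  refit on the full training side.
* Baseline: constant predictor of the training majority class, ties broken
  in the documented order (SP, SS).
* Splits: random = row-level, train `floor(0.8·N)`, unstratified;
  subject-wise = whole subjects per side with the test-subject count chosen
  to bring expected test rows closest to 20% (36 subjects × 81 segments →
  29/7 subjects, 2,349/567 rows), resampled if a class is absent from
  either side.
* Importances: LightGBM gain importances normalized to sum to 100 per fit
  (uniform fallback when a degenerate fit yields zero total gain).
* `repeated_eval` re-splits and refits `n_iter` times (default 200 — means
  are stable at this scale; the protocol generalizes to arbitrarily many
  iterations) with per-iteration seeds cascaded from one seed, recording
  both accuracy distributions and per-fit importances.
* Under a row-level label permutation, test labels are independent of
  anything learnable, so model accuracy matches the dummy — this null is
  verified in the tests. Note that a *subject-level* permutation is not a
  valid null for the random split: subject identity leaks across the
  split and a classifier can legitimately score above baseline there.

## Pipeline

One YAML config with sections timeline / generator / similarity / rqa /
classify and a mandatory global seed. Stage seeds are derived from the
global seed via `numpy.random.SeedSequence(seed).generate_state(...)` with
fixed stage indices (generator 0, annotations 1, classify 2), so stages
re-run in isolation reproduce the full run. All artifacts are plain text
(CSV/TSV/JSON) under a run directory with a manifest; identical configs
produce byte-identical summaries. The full-scale experiments in the test
suite use the study-size cohort (36 subjects, 1620 s drama at 30 Hz);
unit tests run on reduced timelines (2–3 clips, 1–5 min drama) chosen to
exercise identical code paths at a fraction of the cost.

## Known limitations

* The scan's permutation null conditions on the observed cohort; with only
  9 dyads the strong-coupling model has little power in the scan (9 of 630
  cells), and weak-model effects below |τ| ≈ 0.2 are not detectable after
  FDR over 1601 windows at n = 36 — a property of the design, not the
  implementation.
* Fixed-rate radius selection loses exactness on heavily tied windows (see
  above); the achieved rate is always recorded so such windows can be
  audited.
* The classifier's random-split accuracy partially reflects subject
  re-identification rather than group structure; the subject-wise split is
  the generalization estimate and is reported alongside it everywhere.
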