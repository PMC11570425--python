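# Methods

This note documents the models, estimators and numerical choices behind the
`fingertap` package: a pipeline for scoring finger-tapping motor-sequence
learning and testing offline consolidation ("boost") effects in a mixed
(split-plot) design, together with the synthetic cohort generator used to
validate the whole chain.

## The task and the scoring model

Participants repeatedly type the cyclic five-key sequence 4-1-3-2-4 for
30-s blocks: twelve learning blocks (session S1) and, after a break of
30 min or 4 h spent actively or passively, two test blocks (S2). Per block:

- **Speed** = block duration / number of keypresses, in seconds per
  keypress (no rescaling before exponentiation).
- **Accuracy** (an *error fraction*) = (keypresses − correct chunks) /
  keypresses, where a *chunk* is a run of three consecutive keypresses
  matching the cyclic order of the target.
- **GPI** (Global Performance Index) = e^(−Speed) × e^(−Accuracy) ∈ (0, 1],
  higher is better. We read "e-Speed" as e^(−Speed): with seconds-per-key
  speed and an error-fraction accuracy, both exponents must be negated for
  better performance to raise the score.

**Chunk rule.** Chunks are counted over *overlapping* stride-1 windows
matched against the cyclic extension of the target, so the 4→4 seam between
repetitions counts and a perfect n-keypress block contains n − 2 chunks
(hence accuracy is bounded below by 2/n). Whether the original index used
overlapping or disjoint triplets is not decidable from public materials;
a greedy disjoint-triplet variant is available via `overlap=False`, the
overlapping rule is the default.

**Degenerate blocks.** A zero-keypress block cannot be scored; it returns the
sentinel (speed = ∞, accuracy = 1, GPI = 0) and is flagged for exclusion
review instead of failing the run, mirroring performance-based screening.

## Preprocessing

- **Exclusion screens**: corrupted recordings; insufficient motor
  performance (configurable minimum median keypress count — no default
  threshold is imposed); sleep quality, SDSC total > 67 for children and
  PSQI total > 7 for adults, both strict inequalities. Archival participants
  (imported from an earlier active-break dataset) carry no questionnaire and
  bypass the sleep screens. A missing sleep score retains the participant
  with a warning.
- **Z-scoring**: each participant's 14 GPI values are standardized against
  their own mean and SD across all 14 blocks, removing baseline
  speed/accuracy differences between age groups. The SD uses the sample
  (n − 1) denominator; the choice is immaterial to all downstream F, p and d
  statistics (the affine-invariance test covers both conventions).
- **Design tables**: the online table is one row per participant × learning
  block (1–12); the offline table has two rows per participant, S1 = mean
  z-GPI of blocks 11–12 and S2 = mean z-GPI of blocks 13–14.

## Mixed ANOVA

`fit_mixed_anova` is a from-scratch split-plot implementation: one within
factor crossed with up to three between factors. It works stratum-wise,
which is exact for this design:

- between effects are tested on per-subject means against the
  subjects-within-cells mean square (df = N − c for c cells);
- within-involving effects are tested on within-subject deviations against
  the within residual (df = (w − 1)(N − c)).

Sums of squares are Type III partial SS under sum-to-zero coding (JASP's
default); on balanced designs these coincide with Type II, and the real
design's reference totals (58 per age group over 4 cells) are close to but not
exactly balanced, so the choice matters in principle. Identities asserted in
tests: df arithmetic for all reference layouts, F = t² for two-level within
factors, η²p = df₁F/(df₁F + df₂) = SS_eff/(SS_eff + SS_err), and agreement
to 1e-6 with independent reference implementations (pingouin's mixed ANOVA,
statsmodels' pure-within RM-ANOVA) on random balanced designs.

**Sphericity.** Greenhouse–Geisser ε̂ is computed from the pooled
within-cell covariance matrix (ε̂ = tr(PSP)²/((w−1)tr((PSP)²)), bounded in
[1/(w−1), 1]); Mauchly's test uses the orthonormal-contrast covariance with
error df N − c. Policy "when-violated" (default): the corrected p is primary
when Mauchly p < 0.05 and the within factor has more than two levels; raw
and corrected p are always both reported. Two-level factors have ε = 1 by
construction.

**Post hocs.** Paired t contrasts of the within factor inside each cell of
interest; each call is one multiple-comparison family. Bonferroni (default;
its capping at p = 1 matches common reporting practice) or a
studentized-range ("Tukey") adjustment applied to √2·|t| with the pair's own
df — a Games–Howell-style variant chosen because a pooled repeated-measures
error term is not defined for unbalanced cells. Paired Cohen's d = mean
difference / SD of differences, signed first-minus-second level (S1 − S2),
so improvement at S2 is a *negative* d.

**Inclusion Bayes factors.** BF_incl is approximated by BIC weights
(unit-information prior, uniform model priors) with matched-models
averaging: models that contain the effect but no higher-order interaction
involving it, against the same models with the effect removed. The model
space is enumerated stratum-wise — between effects compete on subject means,
within-involving effects on within-subject deviations — because fixed
subject terms would be collinear with between effects. This is deliberately
an *approximation* to JZS-prior Bayesian ANOVA: values are interpreted only
through the conventional >3 / <1/3 evidence thresholds, and the package's
tests assert threshold behaviour (strong simulated effects exceed 3, null
effects fall below 1 in the median), never specific values.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated; real keypress data can be substituted via the CSV interfaces.

- **Design**: 2 age groups × 2 break durations × 2 break types, default 14
  participants per cell (the balanced split implied by the reference totals of
  58 + 58 over four conditions per age group), 12 + 2 blocks of 30 s.
- **Keypress streams**: renewal processes with gamma inter-press intervals,
  shape 4 (CV = 0.5, right-skewed like human inter-tap intervals), mean
  1/rate. Errors are independent per keypress with probability p_err; a
  wrong key is uniform over the other three. By default an error does not
  reset the cyclic position ("continue"); a "restart-sequence-after-error"
  mode is available.
- **Learning dynamics**: latent rate R(b) = r_∞ − (r_∞ − r₀)e^(−(b−1)/τ)
  with defaults r₀ = 2.2 keys/s, r_∞ = 3.3 keys/s, τ = 2.5 blocks — typical
  non-dominant-hand tapping rates reaching ~3.3 keys/s by end of learning.
  Error probability follows its own curve, 0.08 → 0.02 with τ = 3.
  Participant heterogeneity: between-participant SD 0.35 keys/s;
  block-to-block SD 0.15 keys/s.
- **Offline boost**: the S2 latent rate is the mean of the latent curve over
  the last two S1 blocks — the same blocks the offline contrast averages, so
  a zero boost is an exact null for the Session effect — plus δ·σ_diff,
  where σ_diff is the analytic SD of the paired session-difference score on
  the log-GPI scale. σ_diff combines (i) latent block noise and (ii) renewal
  count noise var(r̂) ≈ r/(shape·T), both mapped through speed = 1/r, with
  (iii) binomial accuracy noise var(acc) ≈ 9p(1−p)/n (each wrong key removes
  up to three overlapping windows); the total is mapped back to rate units
  with slope r². By construction the latent paired Cohen's d of the S1-vs-S2
  contrast equals δ, which the recovery study confirms empirically
  (mean d ≈ −1.33 at δ = 1.3). The accuracy term assumes the default
  "continue" error mode.
- **Default δ map** encodes the qualitative result pattern under study:
  adults +1.3 after 30 min (either break type), 0 after 4 h; children +1.2
  after an active break (either duration), 0 after a passive one.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: within-block fatigue and micro-offline gains,
reaction-time microstructure, learning-strategy differences between ages
(both age groups share one latent curve; baseline differences are removed by
z-scoring anyway), correlated error bursts, and any reminiscence effect.
Validation demonstrates that the *pipeline* is calibrated and sensitive
under these conditions, not that the substantive findings replicate.

## Validation studies and problem sizes

- **Type-I calibration**: 1000 replicate null cohorts at 4 participants per
  cell (32 × 14 blocks each) — the offline Session effect rejects at
  0.05 within the 95% binomial interval. The reduced cell size keeps the
  study a few minutes long while leaving 24 error df.
- **Boost recovery**: 200 replicate default-condition cohorts (112
  participants each); adults-only and children-only Session post hocs
  (Bonferroni within family). Recovery of the adult-30-min and child-active
  improvements, absence of systematic adult-4h / child-passive improvement,
  and mean recovered d are reported by `scripts/acceptance.py`.
- **Scorer oracle**: 10⁴ random streams of length 0–200 against an
  independent brute-force window counter.

## Numerical details and edge cases

- All randomness flows through `numpy.random.default_rng`; identical
  config + seed produces byte-identical cohorts and reports.
- Least-squares fits use `numpy.linalg.lstsq`; partial SS are clamped at 0
  against round-off; BF ratios are formed in log space (overwhelming
  evidence may legitimately return `inf`).
- Singular designs fail loudly: empty or singleton between cells raise
  errors naming the cell; incomplete within designs name the subjects.
- Zero-variance or incomplete participants are flagged, never silently
  dropped; design-table builders either raise or, with
  `on_incomplete="drop"`, warn and drop.
- The latent rate is floored at 0.2 keys/s so extreme noise draws cannot
  produce a non-positive tapping rate.

## Known limitations

- BF_incl values are BIC approximations and not comparable digit-for-digit
  with JZS-prior software output.
- The Tukey variant uses per-pair df rather than a pooled error term.
- The split-plot decomposition assumes one within factor; factorial within
  designs (e.g. Block × Session jointly) are out of scope.
- With very small cells (< 4 subjects) Mauchly's χ² approximation is crude;
  the Greenhouse–Geisser correction itself remains available via
  `sphericity="always"`.
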