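# Methods

## Assay and data model

The pipeline targets transient-transfection reporter screens in 96-well
plates.  A *screen* is a set of plates; each plate carries 12 treatment
groups of 4 replicate wells, two of which are controls transfected with the
empty expression vector: a sham-dosed baseline group and a group stimulated
with 3 µM forskolin (a direct adenylate-cyclase activator).  The stimulated
empty-vector group doubles as the assay positive control and as the
between-plate normalizer.  Receptor identity enters only as a label; well
positions are carried for provenance and never used in computation
(physical guard rows against optical cross-talk are an instrument matter,
not an analysis one).

Datasets are tidy CSV (`plate_id,well,construct,condition,rlu`), UTF-8,
comma-delimited.  A grid (plate-map) importer is deliberately out of scope:
every computation keys on (plate, construct, condition).

## Statistical model

### Normalization and effect estimate

Stage 1 divides each group mean by its plate's positive-control mean;
stage 2 divides the receptor group by the same-plate, same-condition
empty-vector group and subtracts 1.  The per-plate fractional changes are
averaged arithmetically across plates (the within-block-comparison
philosophy of a blocked design), not computed as a pooled ratio of grand
means.

Because the matched control shares the plate's stage-1 divisor, that
divisor cancels algebraically in the fractional change.  The implementation
computes per-plate fractional changes directly from the raw group means, so
the cancellation identity holds bit-for-bit rather than merely to rounding;
stage-1 values are still produced — they are the reported
`normalized_value`s and the ANOVA response.  Plate-scale invariance is
likewise exact by construction; when verified by literally rescaling a
plate's raw values, it is bit-exact for scale factors representable without
binary rounding (powers of two) and holds to ~1e-12 relative otherwise.

### Significance

Significance comes from a replicated randomized complete block ANOVA,
written from scratch (it is the analytic core of the package): treatments
× blocks with `r` replicates per cell, classical balanced decomposition
into treatment, block, interaction and within-cell residual, F against the
residual mean square, p from the upper F tail.  Choices the design left
open, and how they were resolved:

* **Per-comparison models.** Each receptor is tested against the
  empty-vector control in a two-level model per condition, rather than one
  omnibus 12-level model per plate set.  Screens of this kind report an
  overall treatment p per comparison, and treating conditions separately is
  forced by the calling rule (below) requiring per-condition significance.
* **Error term.** The fixed-effects reading (test against pooled
  within-cell residual, interaction reported as a diagnostic) is the
  default; `error_term="interaction"` gives the random-blocks alternative.
* **Response variable.** The plate-normalized *per-well* signal (stage 1
  only).  Using per-plate fractional changes would collapse the n = 4
  within-cell replication that the design provides; using raw RLU would
  put plate scale into the residual.  Note the block factor is additive
  while plate effects are multiplicative; stage-1 division removes the
  plate scale so the additive block term absorbs only what remains.
* **Degenerate inputs.** If the error mean square vanishes (noise-free
  data), p is reported as 0 for any source with positive SS and 1
  otherwise, with a `degenerate` flag.  "Zero" means below 1e-12 of the
  data's scale (max of total SS and N·ȳ²), so algebraically-zero sums of
  squares that accumulate rounding still count as zero.
* **No multiplicity correction by default.** The screen protocol applies
  none across receptors; a Benjamini–Hochberg option (`fdr_adjust=True`)
  exists but must stay off when comparing against the published tallies.

### Calling and grouping

A receptor is constitutively active if, with the same-condition treatment
p below alpha = 0.05, its mean fractional change meets one of: ≥ +2.0
(baseline), ≤ −0.40 (baseline), ≤ −0.40 (forskolin condition).  Threshold
comparisons are inclusive.  Two readings of "200 % elevation" exist
(fractional change ≥ 2.0, i.e. 3× control, vs. a plain 2× ratio); the
default follows the percent-change-over-control axis on which such screens
are graphed, and the alternative is a one-line config change
(`stimulation_threshold: 1.0`).

Significance is gated *per condition per criterion*: a large forskolin-
condition inhibition with p ≥ alpha does not satisfy criterion 3 (this is
how a receptor with +250 % baseline stimulation and a noisy, formally
−50 % forskolin effect at p = 0.072 ends up in group D, not B).  The 0.01
level is a display convention only (double star in reports).

The criteria pattern maps to groups by a total decision table: (2∧3)→A,
(1∧3)→B, (3 alone)→C, (1 without 3)→D, none→E.  The remaining pattern —
baseline inhibition without forskolin-condition inhibition (2 without 3) —
has not been observed in real screens; it gets an explicit OTHER label
rather than silent coercion into A, so simulation-based evaluation counts
it as an error rather than hiding it.  Receptors with fewer than two
usable plates in either condition are labelled UNEVALUABLE and excluded
from tallies, with a reason.

## Simulator

The generator exists to exercise the pipeline under the statistical
structure the analysis assumes, with known truth.  Expected well signal is
a product: baseline scale (default 20 000 RLU) × forskolin ratio (default
5.0, matching the roughly 5:1 positive-control to baseline-control ratio
such assays maintain) × the construct's condition-matched effect
multiplier × a per-plate log-normal block effect × per-well log-normal
noise.  Both random factors use log-mean −σ²/2 so each has expectation
exactly 1, making group means unbiased for the design constants times the
effect multiplier.

Noise is multiplicative rather than additive-Gaussian because luminescence
readouts are positive with roughly constant coefficient of variation, and
because a shared multiplicative plate factor is precisely what both the
positive-control normalization and blocking presuppose — the simulator and
the analysis agree on the invariance being exploited.  Defaults:
`plate_effect_sd = 0.3` (log scale — plates varying by tens of percent)
and `well_noise_cv = 0.15`, a typical replicate CV for transient
transfection; `n_plates = 4`, the lower end of the 4–8 replicate plates
the analysis expects.  An optional per-plate effect jitter
(`effect_jitter_sd`, default 0) can mimic the treatment-by-block
variability some receptors show; no magnitude for it is established, so it
is off by default and excluded from calibration claims.

Archetype profiles (baseline ×, forskolin ×): A (0.4, 0.4), B (4.0, 0.5),
C (1.0, 0.5), D (4.0, 1.0), E (1.0, 1.0) — one per response group, each
sitting well past the calling thresholds so that default-noise recovery is
nearly certain.  Receptors beyond one plate's capacity (5, beside the two
controls) are split into batches, each batch on its own plates; every
plate always carries both controls.

**What the simulator does not emulate:** transfection-efficiency variation
as a distinct mechanism (subsumed into plate/well noise), forskolin
dose–response, receptor over-expression artefacts, heavy-tailed instrument
glitches, or condition-specific noise.  Passing calibration tests
therefore shows the pipeline is correct *under its own assumptions*; it
does not certify behavior on real plates whose noise violates them.

## Verification

* The ANOVA is checked against an independent sequential least-squares
  projection oracle (and statsmodels' type-I `anova_lm`) to 1e-8 relative
  on all SS, F and p over random balanced layouts spanning t ∈ {2,3,12},
  b ∈ 2–8, r ∈ {2,4}.
* Null calibration: on 2000 simulated all-null screens at default noise,
  treatment p-values are uniform (Kolmogorov–Smirnov at level 0.01) and
  the pipeline's false-positive rate stays at or below the nominal 0.05 —
  empirically near zero, because calling requires magnitude *and*
  significance jointly.
* Ground truth recovery: ≥ 95 % correct group assignment over 200
  default-noise screens with four receptors per archetype; exact recovery
  in the zero-noise limit.
* Unbiasedness: the pooled fractional change of a 0.4× archetype matches a
  direct 10⁵-replicate Monte-Carlo of the generative model within combined
  Monte-Carlo error (the small ratio-of-means bias, ≈ 0.2 % at default
  noise, is shared by both routes).

Problem sizes used by the shipped acceptance computation (100 recovery
seeds, 500 null screens) are chosen to estimate percentages to a few
tenths of a point; the test suite runs the larger 200/2000-seed versions.

## Known limitations

* Balanced designs only: unequal replication within a cell is rejected and
  routed to the dataset validator rather than analyzed with type-II/III
  sums of squares.
* The block model is multiplicative-scale only; additive plate offsets
  (e.g. luminescence background) are not modelled and would bias
  fractional changes — consistent with an assay that performs no
  background subtraction.
* Direction tallies for the published screen derive from group membership
  (A/B/C imply inhibition, B/D imply stimulation), not from re-measured
  magnitudes; per-receptor numeric values for that screen exist only as
  figure bars and are not encoded.
* One roster discrepancy in the published screen is recorded rather than
  resolved: GPR55 appears in the detailed group-A roster (17 receptors)
  but not in the abstract's summary list; the fixture follows the detailed
  roster and notes the difference.
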