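# Methods

## Case/non-case disproportionality

The pharmacovigilance arm treats each spontaneous report as one
observation.  Within the target-drug stratum (default: reports listing
`paclitaxel`, exact match after normalization; an optional synonym map can
fold `paclitaxel protein-bound` into the stratum, off by default), reports
are cross-classified as case × exposed:

* **case** — the report lists any term of the case definition.  The
  default PIPN definition is the three preferred terms *peripheral
  neuropathy*, *peripheral sensory neuropathy*, *peripheral sensorimotor
  neuropathy*, matched exactly on normalized strings (no MedDRA hierarchy
  traversal).
* **exposed** — the report lists any member of the drug group.
  "Concomitant" means co-occurrence on the same report; no therapy-date
  logic.  The built-in pooled α1-antagonist class is {tamsulosin,
  doxazosin, alfuzosin, silodosin, terazosin, prazosin, urapidil,
  naftopidil} and is fully configurable, since published analyses rarely
  enumerate class membership.

The ROR is the sample odds ratio of the 2×2 table and its CI is the Woolf
(log-normal) interval with the natural logarithm and z = 1.96.  Numerical
choices:

* **Zero cells.** The ROR and CI are undefined at any zero cell; the
  default is an explicit `UndefinedResultError`.  The Haldane–Anscombe
  correction (+0.5 to all four cells) is opt-in and flagged in the result,
  never silent.  In the batched `signal_table` a zero-cell group is
  reported as NaN so other groups still compute.
* **Yates trigger.** The continuity correction is applied when any
  *observed* cell is < 5 (a literal reading of the small-cell rule);
  the textbook expected-cell rule, plus `always`/`never`, are available
  through `yates_policy` because the intent of such rules is ambiguous.
  The corrected statistic is floored at zero when |ad−bc| ≤ N/2.  A zero
  row or column margin yields χ² = 0, p = 1 (degenerate table).
* **Rounding.** Percentages and printed RORs round half-up (4.575% prints
  as 4.58%); all internal comparisons use full precision.

`invert_counts` is a verification oracle for published tables whose cells
were never printed: given a rounded ROR, a rounded CI and the two margins
(total reports, total cases), it scans n11, inverts the ROR relation to
bound n12 over the rounding interval (±2 integer padding beyond the exact
inverse image), and returns every integer table whose recomputed ROR and
CI round half-up to the printed values.  A printed CI lower bound of 0.00
is treated as "rounds below 0.005", not as infeasible.  Ambiguity
(multiple matching tables) is expected and returned in full.

## Synthetic report universe

`generate_reports` draws, per report: target-drug membership
(`p_target_drug`, default 0.5), then — only for target reports —
concomitant exposure (`p_exposed_given_target`, default 0.10) and case
status.  Case status is generated on the **odds scale**: unexposed
probability `baseline_event_prob` (default 0.0458, a realistic background
PIPN reporting rate among paclitaxel reports), exposed odds = baseline
odds × `exposure_odds_multiplier`.  The multiplier is therefore exactly
the estimand of the ROR, which makes parameter recovery a meaningful
check rather than an approximation.  Decoy drugs and events are attached
independently of case status (no confounding) from a random stream
spawned separately from the core draws, so `realized_contingency` — a
light path that never materializes report objects — produces the identical
2×2 table for the same seed; a unit test pins this equality against the
full `generate_reports` → `build_contingency` route.  Case terms appear
only in the target stratum, and decoy events never collide with the case
definition; the generator makes no attempt to emulate reporting biases
(duplicates, stimulated reporting, missing drugs), so calibration results
speak to the estimator, not to FAERS data quality.

Degenerate parameter combinations (baseline probability 1 with a
multiplier ≠ 1) are rejected at construction.

## Von Frey up–down estimation

Sessions are staircases over a filament series; the default series is the
standard rat set 0.41–15.1 g (8 filaments, mean log10 spacing
δ ≈ 0.224).  This series, the mid-series start filament and the stopping
rule are conventions of the standard protocol, configurable and not
study-reported facts.  The simulator draws responses from a logistic
psychometric function in log10 force centred at the true threshold
(slope default 8; slope 30 is used for "steep/near-deterministic"
consistency checks), steps down after a withdrawal and up after none,
clamping at the series boundaries, and stops four trials after the first
reversal or at nine trials.

The threshold estimator is `10^(X_f + k·δ)`.  The offset k is read from a
pattern-keyed table shipped with the package; the table's values are the
maximum-likelihood estimates of the 50% point under Dixon's model (normal
psychometric function with spread σ = δ), computed by the in-package
routine `dixon_k` (bounded scalar minimization of the probit negative
log-likelihood, tolerance 1e-10) and frozen into
`data/k_table.json` for all 158 terminal patterns the stopping rule can
produce.  When a session's pattern is missing from the table, or its
observed forces deviate from the unclipped staircase the pattern implies
(boundary clamping), k is computed directly from the observed trials by
the same MLE — so table and fallback are mutually consistent by
construction, and users can override the table per session.

Censoring: a session with no reversal (all responses positive or all
negative) is assigned the boundary filament force with an explicit
`floor`/`ceiling` flag, keeping group means computable.  Trials recorded
after the stopping rule fired are ignored with a warning.

Group summaries report mean ± SEM (sd/√n; NaN with a warning for n = 1).
Pairwise comparisons use the Tukey–Kramer studentized-range test with the
unequal-n standard error `√(MSW/2·(1/ni+1/nj))` and p-values from
`scipy.stats.studentized_range`; the one-way ANOVA F is computed alongside
but does not gate the pairwise tests (gating is a lab convention, not a
statistical requirement).  The implementation is independent of
statsmodels' `pairwise_tukeyhsd`, which serves as a cross-check oracle in
the tests.

## Fiber morphometry

Fibers are nested simple polygons in µm.  Circularity is `4πA/P²` with
shoelace area and exact vertex-path perimeter; it is computed on the
**axon** contour by default (the axonal-damage index), with a flag for
whole-fiber circularity since the choice of contour is a genuine
ambiguity.  The g-ratio uses equivalent-circle diameters from areas
(`2√(A/π)`), which is robust to boundary noise, rather than caliper
diameters; myelin thickness is half the diameter difference.  The
isoperimetric bound is enforced with tolerance 1e-6.

The polygon pathway is the reference measurement.  The label-mask pathway
(axon = 2k, myelin = 2k+1 for fiber k ≥ 1) extracts subpixel
marching-squares contours and smooths them with a circular moving average
(window 7 vertices, shrunk for very short contours): raw marching-squares
contours staircase along pixel diagonals, inflating perimeter by 5–10%
and deflating circularity accordingly; after smoothing a rasterized
r = 50 px circle measures within 0.5% of circularity 1, and mask-derived
indices agree with the polygon oracle within 3% relative for fiber
diameters ≥ 20 px.  Fibers violating the label convention are skipped
with a warning.

## Synthetic nerve cross-sections

Fiber diameters are lognormal (moment-matched to the requested mean 8 µm
and SD 2 µm — a realistic large-myelinated-fiber calibre range);
g-ratios are normal (mean 0.6, SD 0.05) truncated to (0, 1).  Fibers are
placed by rejection sampling of non-overlapping circumscribing circles
(bounded at 200 attempts per fiber; shortfall is logged, never an
infinite loop).  Boundaries are 64-gons; a regular 64-gon has circularity
(π/64)/tan(π/64) ≈ 0.9992, which bounds the discretization error.
`degeneration_level` L ∈ [0, 1] adds a smooth radial perturbation
(harmonics 2–5, amplitude 0.25·L of the radius, normalized so level is
comparable across fibers) to both boundaries and inflates the g-ratio by
g → g + 0.5·L·(1−g) (myelin thinning); the axon is clipped to 97% of the
local fiber radius so nesting always holds.  Level 0.6 versus 0 produces
the qualitative histological pattern of degeneration — lower circularity,
thinner myelin, higher g-ratio — which is what the end-to-end checks
assert; magnitudes are not calibrated to any real nerve.  Rasterization to
a label mask is a separate, lossy export.

## Pipeline and reproducibility

`pipn run` executes the configured arms from a single YAML file.
Validation is explicit Python-side checking (exactly one of
`generate`/`inputs` per arm; integer seed mandatory when generating) with
readable error messages.  Outputs contain no timestamps; per-arm seeds are
derived deterministically from the run seed (NumPy `SeedSequence`
spawning for the report generator's core/decoy streams; fixed offsets per
group for the behavioral and histology arms), so identical config + seed
gives byte-identical files.  A failing arm is recorded in
`manifest.json` and does not abort the other arms.

## Check problem sizes

The verification suite runs the calibration experiment at 1,000 replicates
of 20,000 reports, ROR recovery at 100 replicates of 100,000 reports per
multiplier, count inversion on 100 forward-generated instances at the
printed margins, the staircase consistency check over 500 sessions, and
the morphometry contrast at 100 fibers per group — sizes at which the
Monte-Carlo standard errors are small relative to the tolerances asserted.

## Known limitations

* Exact term matching only; real FAERS data would need MedDRA coding and
  case-version deduplication before these tools apply.
* The Woolf CI is asymptotic; with expected exposed-case counts below ~5
  its coverage degrades, which is why the generator defaults keep that
  count near 45.
* The published per-drug RORs for this research question rest on cell
  counts that were never printed; `invert_counts` can audit their
  consistency but cannot recover them uniquely (ambiguity grows as cells
  shrink).
* The staircase estimator inherits Dixon's σ = δ assumption; thresholds
  near the series boundary are censored, which biases group means toward
  the interior.
* Synthetic nerves have no staining noise, overlapping fibers, or
  non-circular base shapes; mask-pathway accuracy claims hold for the
  geometry this generator produces.
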