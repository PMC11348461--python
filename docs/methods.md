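# Methods

## Scope and data model

The package implements the model-building half of a small-molecule QSAR
study: given a compounds × descriptors numeric matrix and a log-scale
activity vector, it (i) prunes the descriptor pool, (ii) builds a linear
model by greedy forward selection with the standard QSAR statistics
panel, and (iii) searches for a nonlinear model by gene expression
programming over the surviving descriptor terminals.  Computing the
descriptors themselves (3-D structure optimization, semi-empirical
quantum chemistry, CODESSA-style descriptor generation) is out of scope:
descriptor tables are consumed as delimited text.

The bundled benchmark is a 39-compound series of RANKL/RANK-axis
osteoclastogenesis inhibitors in three scaffold blocks, with experimental
TRAP-inhibition percentages (mean ± s.d.), a 30/9 train/test split, and
the predictions of the two published models.  The modeled response is

    y = log10(inhibition %),

adopted because it reproduces every checkable log-scale Target cell of
the printed source table to 3 decimals (68.4 → 1.835, 33.6 → 1.526,
90.3 → 1.956).  The source table reports activity as TRAP inhibition
percentages rather than IC50 values; the package models the tabulated
quantity and attempts no IC50 conversion.

## Fixture curation and audit trail

The printed benchmark table carries typographic noise.  The fixture
therefore stores two views: curated modeling columns (`inhibition_pct`,
`target_log`, `hm_predicted`, `gep_model`, `is_test`) and verbatim
printed columns (`printed_target_hm`, `printed_difference`,
`printed_target_gep`, `printed_residual`, `inhibition_pct_printed`) used
only for auditing.  Documented defects (see
`gepqsar.dataset.TABLE1_AUDIT_NOTES`):

- **Compound 6**: the printed inhibition "41.7 ± 0.6" disagrees with all
  four of the row's printed log-scale cells, every one of which matches
  47.1 % (log10(47.1) = 1.673).  The curated value is 47.1 — a digit
  transposition is the only reading that makes the row self-consistent —
  and the printed 41.7 is retained in `inhibition_pct_printed`.
- **Compounds 20–25**: the GEP-side Target column is shifted down by one
  row; consequently the printed residuals of compounds 24 and 25 are
  consistent only with the shifted cells.
- **Compound 28**: the printed HM Difference has a flipped sign
  (1.811 − 1.926 = −0.115, printed +0.116).
- **Residual column**: 20 of the 39 printed GEP residual cells are
  10⁻ⁿ renderings of small residuals (e.g. "5.461" for 0.005); these are
  treated as ill-formed and never compared.  Residuals are always
  recomputed from the Model and Target columns.

All comparisons against printed 3-decimal cells use an absolute tolerance
of 0.0011 (one ulp of the last printed digit); the published 2-/4-decimal
summary statistics use ±0.01 / ±0.0005.  Recomputed quantities that
disagree with a printed value beyond those tolerances are not silently
skipped: tests assert the frozen recomputed value and the presence of the
audit note.  Concretely, the GEP *training* statistics recomputed from
the table (r² = 0.773, MSE = 0.0083 over the 30 unstarred rows) agree
with the published 0.78 / 0.0085, while the published GEP *test* figures
(0.71 / 0.0121; recomputed 0.784 / 0.0147) and the published HM figures
(0.5516 / 0.0195; recomputed squared-Pearson r² ≈ 0.496–0.502 and
s²(k = 2) ≈ 0.0201 under both the 39- and 30-row conventions) cannot be
derived from the printed columns under any divisor or row convention we
tried; the HM statistics presumably came from the original software's
internal fit rather than from the rounded printed predictions.  Both row
conventions are reported side by side because the source does not state
which sample set its HM statistics describe.

## Descriptor screening

Three rules, applied in order, each returning a report fragment whose
union with the survivors always partitions the original names:

1. **Degeneracy**: drop exactly-constant columns (max = min, an exact
   test rather than float variance, which can be a nonzero rounding
   artifact for a constant column).
2. **Inter-correlation** (default r_max = 0.95): offending pairs are
   processed in decreasing |r|; within a pair the member with the smaller
   |correlation to activity| is dropped, exact ties broken by name order.
   This greedy pass guarantees no surviving pair exceeds the threshold
   and is deterministic across platforms.
3. **Relevance** (default r_min = 0.05): drop descriptors with
   |r(x, y)| < r_min.

The thresholds are conventional QSAR screening values declared as
defaults, not inferred from data; every downstream property holds for any
valid threshold.  Descriptors are never scaled or centered — selection
order under the R² criterion is scale-invariant, and raw coefficients
stay comparable to descriptor-software output.

## Forward-selection MLR

OLS always includes an intercept.  `r2 = 1 − SSres/SStot`;
`s2 = SSres/(n − k − 1)`; leave-one-out R²cv is computed through the hat
matrix identity e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ) and is tested against literal n-refit
leave-one-out on every tested instance.  A constant response yields
r2 = 0 with a warning (degenerate input, not an error).  Rank-deficient
designs raise an error naming the collinear columns.

The greedy step adds the descriptor maximizing R² of the refitted model
(equivalently minimizing SSres), ties broken by name order; the step
criterion is a design choice, made to match the monotone R²-vs-k
narrative the trace is meant to reproduce.  The breaking-point rule picks
the smallest k whose next gain is below tol (default ΔR² = 0.02, a
declared default — the source only says gains became negligible near
k = 2), capped by n ≥ 3(k + 1); at n = 30 the cap is k ≤ 9.  The source
is internally inconsistent about whether its final linear model used 2 or
5 descriptors, so model size is exposed as a parameter and both are
obtainable.

## GEP engine

Karva encoding with head length h, tail length h(a − 1) + 1 = h + 1 for
the all-binary function set {+, −, *, /}; tails hold terminals only, so
every gene decodes to a valid tree by breadth-first filling and every
genetic operator preserves validity by construction.  Numeric random
constants are deliberately absent from the terminal set (the modeled
function set contains only the four operators and named descriptors);
this is a documented limitation — constant-valued sub-expressions can
only arise as combinations such as x/x or x − x.

- **Fitness**: f = 1000/(1 + RMSE) on the training rows — bounded,
  monotone in RMSE, with f = 0 reserved for invalid individuals.  The
  published study never states its fitness function; MSE-based
  evaluation downstream is independent of this choice.
- **Safe division**: a divisor with |b| < 1e-12, or any non-finite
  intermediate, invalidates the individual (fitness 0) rather than
  substituting a sentinel value, so selection cannot reward numerical
  artifacts.
- **Selection**: roulette with replacement; elitism ≥ 1 guarantees a
  monotonically non-decreasing best fitness.  If every fitness is zero
  the fallback is uniform selection with a warning.
- **Operators**: point mutation (per-symbol probability, head positions
  resample from functions ∪ terminals, tail from terminals), one- and
  two-point recombination over the concatenated chromosome, and
  head-segment inversion.  Transposition operators (IS/RIS/gene) are an
  extension point, not implemented.
- **Termination**: generation budget, or early stop at fitness
  ≥ 1000 − 1e-9 (numerically perfect training fit).
- **Defaults**: head 7, 3 genes linked by "+", population 100, 500
  generations, p_mut 0.044, p_inv 0.1, p_rec 0.3/0.3, elitism 1 —
  conventional GEP settings; the original study's control parameters
  were not published.

Runs are fully reproducible: a single integer seeds one `numpy`
Generator that drives initialization, selection, and every operator, and
mutation draws its replacement symbols unconditionally so the random
stream does not depend on which positions mutate.

## Synthetic data generator

The generator emulates the structure the analysis assumes in a
CODESSA-scale export (default 39 × 551; tests and validation studies use
smaller tables for speed, e.g. 40 × 22 for the selection study and 60
rows × 5 terminals for the expression study): i.i.d. standard-normal base
descriptors (log-normal marginals available for realism; real
quantum-chemical descriptors are heterogeneous in scale, but selection
under the R² criterion is scale-covariant), exactly-degenerate columns
(all-zero or constant 3.2), collinear pairs built as
x′ = r·x + √(1 − r²)·ε so the sample correlation concentrates near the
target r, and a planted response — linear with known coefficients, or a
{+, −, *, /} expression tree — plus N(0, σ²) noise.  What it does *not*
emulate: physical inter-descriptor constraints, heavy-tailed or discrete
descriptor distributions, and block structure across scaffolds.  Passing
recovery tests therefore demonstrate algorithmic correctness under the
stated statistical assumptions, not performance on real descriptor sets.

Measured validation results (all recomputed by the test suite and the
`analysis/` drivers):

- screening + forward selection recovers planted supports of size 1–3 in
  50/50 replicates at σ = 0 and at σ = 0.05 (40 compounds, 22 descriptors
  with degenerate and collinear decoys);
- the GEP engine recovers the noiseless planted expression
  y = d1 + d2·d3 (60 compounds, 5 terminals, head 7, population 100,
  ≤ 200 generations) to training RMSE < 1e-6 in 20/20 seeds; the
  regression test asserts ≥ 18/20, one seed of slack below the measured
  rate.

## Pipeline and degenerate outcomes

`run_pipeline` derives independent per-stage seeds from one global seed
via `numpy.random.SeedSequence` spawning, so stages can be re-run in
isolation.  With no input table it synthesizes a descriptor matrix at
benchmark scale and attaches the benchmark's real log-activities.  That
default run doubles as a cautionary demonstration: selecting 8 of 551
irrelevant descriptors at n = 30 produces an apparent R² ≈ 0.96 — the
selection-bias trap that motivates external test sets and the n ≥ 3(k+1)
cap — and the GEP stage, lacking numeric constants, converges to an
exact constant built from x/x terms, which the manifest reports as
"constant prediction: r2 undefined" (the MSE is still reported).
Per-compound report fields carry 3-decimal rounding wherever they are
compared against printed table values.

## Known limitations

- Squared-Pearson r² (used for cross-family model comparison) and the
  OLS-internal 1 − SSres/SStot coincide only for fitted linear models;
  both are exposed and labeled to avoid conflation, and MSE divisor n
  (comparison metrics) is kept distinct from s² = SSres/(n − k − 1)
  (linear-model statistic).
- Forward selection is greedy with no removal step; it does not reproduce
  any particular commercial implementation's internal ranking heuristics
  beyond the published criteria.
- The GEP terminal set excludes random numerical constants, and there are
  no multi-population islands or automatically defined functions.
- The original 551-descriptor matrix is unpublished, so the published
  models themselves cannot be refit; all end-to-end claims about the
  algorithms rest on the synthetic planted-truth studies plus the printed
  prediction columns of the benchmark.
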