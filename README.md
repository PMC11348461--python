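# gepqsar

Two-stage QSAR modeling for small structure–activity datasets: descriptor
screening plus greedy forward-selection multiple linear regression (the
"heuristic method", HM), followed by gene expression programming (GEP)
symbolic regression over the same descriptor terminals.

The package is built around a benchmark of 39 synthetic RANKL/RANK
inhibitors assayed for osteoclast TRAP-activity inhibition (30 training,
9 test compounds), shipped as a curated, audited fixture.  The modeled
response is `y = log10(inhibition %)`.  Because the original 551
quantum-chemical descriptors (a commercial CODESSA export) were never
published, model refitting from structures is not reproducible; instead
the package validates both algorithms by planted-truth recovery on
synthetic descriptor tables with the same statistical structure.

## The methods

**HM stage.**  Descriptors are pre-screened by three rules — (a) drop
zero-variance columns, (b) for every pair with |Pearson r| > r_max keep
the member better correlated with activity, (c) drop descriptors with
|r(x, y)| < r_min — then added greedily, each step keeping the candidate
that maximizes R² of the refitted OLS model

    y = b0 + b1 x1 + … + bk xk,
    R² = 1 − SSres/SStot,   s² = SSres/(n − k − 1),
    R²cv = 1 − PRESS/SStot,  F = (R²/k) / ((1 − R²)/(n − k − 1)).

Model size is chosen by the *breaking point* rule — stop once the R² gain
falls below a tolerance (default ΔR² < 0.02) — capped by the sample-size
constraint n ≥ 3(k + 1).

**GEP stage.**  Fixed-length chromosomes in Karva notation (gene = head of
h symbols over {+, −, *, /} ∪ terminals, tail of h + 1 terminals, decoded
breadth-first into an expression tree; multigene chromosomes joined by a
linking operator).  Fitness is `1000/(1 + RMSE)` with fitness 0 for any
individual that divides by a near-zero quantity.  Roulette selection with
elitism; point mutation, head-segment inversion, one- and two-point
recombination — all validity-preserving by construction.

## Worked example

```python
>>> from gepqsar import load_table1_fixture, log_activity, compare_models
>>> records = load_table1_fixture()
>>> len(records), sum(r.is_test for r in records)
(39, 9)
>>> round(log_activity(68.4), 3)        # compound 1: 68.4 % inhibition
1.835
>>> comparison = compare_models(records)
>>> print(comparison.summary_frame().round(4).to_string(index=False))
model split  n     r2    mse   rmse
   HM train 30 0.4953 0.0181 0.1345
   HM  test  9 0.5070 0.0199 0.1411
  GEP train 30 0.7737 0.0083 0.0910
  GEP  test  9 0.7841 0.0147 0.1211
>>> comparison.verdicts
{'train': 'GEP', 'test': 'GEP'}
```

The transform reproduces the benchmark's log-scale Target column
(compound 1: 68.4 % → 1.835); the summary shows the GEP model beating the
linear HM model on both r² (squared Pearson correlation) and MSE on the
training and test splits — the central comparative claim of the study the
benchmark comes from.  On the training set the GEP figures (0.773 /
0.0083) agree with the published 0.78 / 0.0085 to the table's printing
precision; the published test-set and HM figures are not recoverable from
the printed table (see `docs/methods.md` and the audit columns of the
fixture).

The synthetic validation path:

```python
>>> from gepqsar import SyntheticSpec, generate, forward_select, screen_descriptors
>>> spec = SyntheticSpec(n_compounds=40, n_descriptors=22, n_degenerate=2,
...                      n_collinear_pairs=2, true_support=("d003", "d007"),
...                      true_coefficients=(1.0, 2.0), noise_sd=0.05, seed=1)
>>> table, truth = generate(spec)
>>> screened, _ = screen_descriptors(table)
>>> forward_select(screened, k_max=2).models[-1].descriptors
['d007', 'd003']
```

## Command line

`gepqsar` exposes the stages as subcommands: `screen`, `hm-fit`,
`gep-fit`, `evaluate`, `simulate` and `run` (full pipeline with one global
seed deriving all stage seeds).  `gepqsar run --seed 7 --out results/run`
writes a screening report, the selection trace (R²/R²cv/s² vs k), the GEP
model and fitness trajectory, the benchmark comparison table and a
machine-readable manifest.

## Analysis scripts

Numbered drivers under `analysis/` reproduce the package's result tables
into `results/`:

1. `01_table1_audit.py` — recomputes every derived cell of the benchmark
   table and flags the printed cells that disagree (with documented
   explanations).
2. `02_headline_statistics.py` — the train/test r²/MSE/s² panel above.
3. `03_hm_validation.py` — planted-support recovery of the screening +
   forward-selection stage (50 replicates per condition).
4. `04_gep_validation.py` — 20-seed expression-recovery sweep for the GEP
   engine on the planted response y = d1 + d2·d3.
5. `05_full_pipeline.py` — the end-to-end pipeline run.

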