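# snspmf

Weighted semi-nonnegative sparse matrix factorization for multi-tissue eQTL
effect sizes, with stability-based model selection, per-eQTL factor
assignment, heuristic baselines, a simulation harness, and downstream
genomic enrichment statistics.

## The problem

Expression quantitative trait loci (eQTLs) measured across many tissues show
complex sharing patterns: some variants shift a gene's expression everywhere,
others only in the brain, the liver, or a handful of related tissues. Given a
matrix **X** (D eQTLs × T tissues) of effect sizes (regression slopes from
per-tissue association tests) and their standard errors, this package learns
a small set of interpretable *tissue factors* and decomposes every eQTL's
effect profile over them:

```
min over F, L   (1/2D) ‖(X − L Fᵀ) ⊙ W‖²_F + α‖L‖₁ + λ‖F‖₁ ,   F ≥ 0
```

where **F** (T × K) holds nonnegative tissue factors, **L** (D × K) holds
real-valued loadings, and **W** is the elementwise reciprocal of the standard
errors (weight 0 marks an untested tissue, so missingness costs nothing).
Nonnegativity makes factors readable as tissue groups; the L1 penalties make
both factors and loadings sparse; weighting makes precisely measured effects
count more. The objective is biconvex and is optimized by alternating least
squares, each half-step a weighted (nonnegative) lasso solved exactly by
coordinate descent.

On top of the factorization the package provides:

- **Model selection** — consensus matrices over repeated random
  initializations, cophenetic correlation as a stability score, and a
  three-stage grid selector (stability first, factor independence last).
- **eQTL → factor assignment** — a second-pass weighted regression
  `x ≈ F l` per eQTL with t-tests, Benjamini–Hochberg correction,
  perfect-LD pruning with q-value propagation, and sign-consistency filters;
  eQTLs loading on the full-support factor are *u-eQTLs* (ubiquitous), those
  loading on any other factor are *ts-eQTLs* (tissue-specific).
- **Heuristic baselines** — the classical per-tissue p-value thresholding
  rules (single tissues, or manually grouped tissue subsets).
- **Simulation** — a generator with one dense and K−1 sparse nonnegative
  factors, standard-normal sparse loadings, and Gaussian noise, plus
  permutation-aligned recovery scoring (factor/loading correlations, RRMSE,
  u/ts precision–recall).
- **Enrichment statistics** — matched background sampling (MAF, signed TSS
  distance, variants per gene), 5-bp-window interval overlap, one-sided
  Fisher tests with BH correction, DerSimonian–Laird random-effects odds
  ratio combination, TF expression filters, and the exact two-tailed
  binomial test for allele-specific binding.

## Worked example

`examples/fit_factors.py` simulates 100 eQTLs over 10 tissues from 5 known
factors (noise variance 0.001), fits the factorization (K = 5,
α = λ = 1.0, best of 10 random initializations), and scores recovery:

```
learned factors: 5 (requested 5)
converged: False after 100 iterations
final objective: 114.410
mean factor correlation vs truth:  0.901
mean loading correlation vs truth: 0.923
reconstruction RRMSE: 0.0289

factor support (tissues with nonzero weight per factor):
  factor 1: tissues [5, 8, 9]
  factor 2: tissues [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
  factor 3: tissues [0, 3, 5, 7, 9]
  factor 4: tissues [2, 4, 5]
  factor 5: tissues [1, 3, 5, 6]
```

Factor 2 is the recovered ubiquitous factor (support on all 10 tissues); the
others match the simulated tissue groups. Correlations near 1 mean the
sharing structure was recovered; the RRMSE of 0.03 means X is reconstructed
essentially down to the noise floor. The other scripts in `examples/` walk
through assignment and u/ts classification, hyper-parameter selection,
the heuristic baselines, and the enrichment statistics, each printing and
explaining its numbers.

A command-line layer mirrors the library:

```bash
snspmf simulate --n 100 --t 10 --k 5 --sigma2 0.001 --seed 1 --out sim/
snspmf fit --x sim/X.tsv --se sim/SE.tsv -K 5 --alpha 1 --lambda 1 --seed 1 --out model/
snspmf assign --x sim/X.tsv --se sim/SE.tsv --factors model/F.tsv --out assignments.tsv
snspmf run --config run.yaml          # full pipeline with manifest
```

All commands are seed-driven and bit-reproducible.

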