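# Methods

This note records the model, the conventions that the learned parameters
depend on, the synthetic-data generator, the numerical choices, and the known
limitations of `pfalign`.

## The scoring model

A site of a protein profile is a PSSV: 20 values in [0, 1], one per amino
acid, taken from the weighted-observed-percentage block of a PSI-BLAST-style
ASCII PSSM divided by 100. (The PSSM's log-odds block is parsed for
validation but unused; which block feeds the scorer is a documented modeling
choice — percentages are likelihood-like and already bounded.)

The neural similarity of two PSSVs is

    y = w2 · relu(x_a W1 + x_b W1 + b1) + b2,

with `W1` (20×H), `b1`, `w2` (H), `b2` scalar. Sharing `W1` between the two
arguments makes the score exactly symmetric — a requirement for an alignment
scorer — and reduces the parameter count to `20H + 2H + 1`. With the two gap
penalties appended, the CMA-ES search space has dimension `22H + 3` (3171 at
H = 144, 179 at the desk-scale H = 8).

Baselines operate on the same PSSVs: cosine similarity, Pearson correlation,
and sequence-level BLOSUM62/MIQS lookups. The bundled MIQS table is a
clearly-labeled synthetic stand-in (mean of BLOSUM45 and BLOSUM62, one
decimal; `data/miqs_synthetic.tsv`, SHA-256 frozen in the test suite): it
reproduces MIQS's remote-homolog orientation but not its exact published
values, which are not redistributable here.

## Alignment conventions

Semi-global alignment (global with free end gaps) by the three-state Gotoh
recursion. Two conventions are pinned because learned gap penalties are
meaningless without them:

* **Gap cost.** An internal gap run of length k costs `open + (k−1)·extend`;
  a length-1 run costs `open` alone. Runs of opposite gap type break each
  other (an interleaved insertion/deletion region pays one `open` per
  maximal same-type run).
* **Free terminal runs.** A gap run is free exactly when it contains the
  first or the last alignment column. This is precisely the family of
  layouts that the zero-boundary semi-global recursion scores as free: when
  both sequences have gaps at one end, only the outermost run is free, the
  inner one is charged as internal.
* **Tie-break.** Traceback prefers aligned pair over gap-in-B over gap-in-A,
  deterministically; the end cell is chosen by a fixed documented scan order.

The brute-force oracle enumerates every monotone column layout (Delannoy
count; bound L_A·L_B ≤ 36) and scores each with the identical conventions
and the identical left-to-right addition order, so optimal scores agree
**bitwise** with the DP — the acceptance check asserts exact equality, not a
tolerance. DP inner loops are compiled with numba when available; the
pure-Python fallback computes the same IEEE-754 operations in the same
order.

Quality metrics: sensitivity = correctly aligned site pairs / reference
pairs; precision = correct / test pairs. Zero denominators yield an
undefined flag, excluded from dataset means (macro-average by default; a
micro-average pooling counts is available).

## CMA-ES

Standard (μ/μ_w, λ)-CMA-ES with log-decreasing recombination weights,
cumulative step-size adaptation, rank-1 + rank-μ covariance update, and the
canonical default learning rates as functions of the dimension. The method's
hyperparameters are σ0 = 0.032, λ = 70, μ = 35 (desk scale: λ = 12, μ = 6).
Numerical choices: stable sort for fitness ranking (ties keep candidate
order), covariance symmetrized every update, eigenvalue floor
`1e-14·trace(C)/n`, eigendecomposition cached per generation. Minimization
convention throughout; the incumbent best is monotone by construction.

## Training

One epoch = one CMA-ES generation: λ evaluations of the batch cost
`1 − mean alignment sensitivity` over the training split, each requiring one
score matrix and one DP per training pair. Gap penalties ride in the search
vector and are clamped (extend ≤ 0, open ≤ extend) inside the cost rather
than constraining the solver. Validation: from `validation_start_epoch`
(default 50; desk runs 10) every `validation_stride` (5) epochs, the
generation-best-by-training-cost candidate is scored on the validation
split; the checkpoint maximizing validation sensitivity is selected, earliest
epoch on ties. Storing the generation-best candidate (rather than the
distribution mean) in checkpoints is a documented choice.

**Pretraining** initializes the search at a network fitted by plain
mini-batch gradient descent (squared error, lr 0.1, batch 128, 80 epochs,
He-scaled init) to correlation-coefficient targets on independently drawn
Dirichlet PSSV pairs.

**A structural limit worth knowing.** Because `W1` is shared, the hidden
layer receives only the coordinatewise *sum* `x_a + x_b`. The correlation
coefficient of an independent pair is *not* a function of that sum: writing
`V_a, V_b, V_s` for the coordinate variances of `x_a`, `x_b` and the sum,
`cc = (V_s − V_a − V_b) / (2√(V_a V_b))`, and `(V_a, V_b)` remains random
given the sum. The test suite contains a constructed witness (two pairs with
identical sums and different correlations), and pretraining accordingly
converges to the best sum-measurable approximation — held-out RMSE ≈ 0.19–0.20
versus ≈ 0.23 for the best constant predictor at the shipped desk scale — not
to an arbitrarily faithful copy of the coefficient. That approximation is
all the training loop needs: it is an initialization, and CMA-ES immediately
optimizes alignment sensitivity, not correlation fidelity.

**Gap-penalty grid search** for the fixed baselines evaluates mean
sensitivity over open ∈ [−2.0, −0.6], extend ∈ [−0.4, −0.1] in steps of 0.1
(60 combinations), selecting the sensitivity maximum (first in ascending
scan order on ties).

## Synthetic data

The generator emulates remote-homolog profile pairs with a known homology
map: an ancestral profile of symmetric-Dirichlet PSSVs (concentration 0.3 —
peaked columns, top-residue mass ≈ 0.31, resembling real profile columns)
diverges along two independent lineages. Each inherited site is perturbed as
`(ancestor + τ·Dirichlet)/(1 + τ)` (default τ = 1.3); deletions start at
each site with probability `indel_rate/2` and remove a geometric-length
segment (union of overlapping runs), insertions add geometric-length novel
segments at each boundary with the same rate (defaults: rate 0.04, mean
length 3). Sequence letters are the argmax residue of each PSSV (ties broken
in canonical order ARNDCQEGHILKMFPSTWYV). Surviving ancestral sites define
the reference alignment; sites surviving in one lineage, and all insertions,
appear as gap columns.

Defaults were calibrated once so that default pairs land at ≈ 10–30%
sequence identity (mean ≈ 19%), the twilight-zone regime the method targets.

What the generator does **not** emulate: substitution-matrix-structured site
evolution, rate heterogeneity across sites, domain architecture, alignment
ambiguity in repetitive regions, or DELTA-BLAST's pseudocount and weighting
machinery. Tests passing on this generator demonstrate the correctness and
trainability of the machinery — DP optimality, metric identities, learning
dynamics — not biological alignment accuracy on real profiles.

## Problem sizes and what the shipped runs show

The shipped test and acceptance runs use desk-scale sizes chosen as a
package default: 500 brute-force-checked DP instances up to 5×5, pretraining
at H = 64 on 20k pairs, a 20-pair / length-40 / H = 8 / λ = 12 / 30-epoch
training run, and 10⁵-pair overlap counts. At these sizes the desk-trained
network improves sharply over its initialization (validation sensitivity
0 → ≈ 0.46–0.55) but does not yet overtake the correlation-coefficient
baseline, and its six-decimal score-overlap count remains *higher* than the
baseline's: the overlap statistic is dominated by the scorer's output spread
(the cc-mimicking initialization is narrower than the coefficient's [−1, 1]
range, and 30 desk epochs barely move it), so overlap comparisons are only
meaningful between scorers of comparable scale or after much longer
training. Full-scale runs (1536 pairs, H = 144, λ = 70, 150 epochs) are out
of desk scope.

## Known limitations

* Learned gap penalties are tied to this package's gap-cost convention
  (length-1 run costs `open`); penalties fitted under an
  `open + k·extend` convention are not directly comparable.
* The MIQS stand-in is synthetic (see above).
* No local (Smith–Waterman) mode, banded DP, or suboptimal-alignment
  sampling; no restarts or box constraints in CMA-ES.
* `X` and other nonstandard residues pass through sequence scoring via each
  matrix's X row (or its minimum entry); their PSSV rows are used as given.
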