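# Methods

## The optimization problem

`crossbic` selects a bicluster (I, J) of a signed log-expression matrix
maximizing Σ_{i∈I} δ_i(J) Σ_{s∈S} ω_is(J) subject to the negative-fraction
constraint #{(i,j) ∈ I×J : m_ij < 0} ≤ μ|I||J|.  The components:

* **ω_is(J)** — per-sample specificity: the sum of m_ij over the selected
  cells of sample s minus κ times the positive expression of the same gene
  in the sample's unselected cells.  Because both terms are plain sums over
  many entries, single outlying values (transcriptional bursts, per-sample
  level shifts) move the objective little; this is the source of the
  method's batch-effect robustness and the reason no prior data integration
  is required.
* **δ_i(J)** — the ratio of the geometric to the arithmetic mean of the
  per-sample ω values, each clipped below at ε.  It equals 1 exactly when
  all clipped values coincide (AM–GM) and decays toward 0 when the signal
  is concentrated in few samples; a gene strong in one sample and absent in
  the others is effectively cancelled, which is what forces solutions to be
  shared across samples.  The geometric mean is deliberately asymmetric: a
  gene weak in one of many samples is penalized mildly, a gene strong in
  only one severely — a variance-style penalty could not distinguish the
  two cases.
* **the μ constraint** — caps the fraction of non-expressed entries in the
  selected submatrix, preventing loose solutions that absorb cells which do
  not actually express the markers.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| κ (kappa) | penalty on out-of-cluster positive expression | 100/\|C\| | larger ⇒ fewer, more differentiated genes |
| μ (mu) | max fraction of negative entries in I×J | 0.1 | 0 forbids any non-expressed entry |
| ε (epsilon) | clipping floor inside δ | 0.1 | keeps the geometric mean real and positive |
| pseudocount | log10(x + pseudocount) | 0.1 | zero counts ↦ −1; sign boundary at x = 0.9 |
| max. expression fraction | gene filter | 0.25 | genes expressed in >25% of cells are generic markers, not rare-population signal |
| beam width | states kept per sample beam | 10 | |
| patience | non-improving rounds before stopping | 8 | see below |

Entries exactly 0 after the transform (x = 0.9) count as non-expressed for
the filter, contribute nothing to either term of ω (max{0, m} = 0), and
are not counted by the constraint (which counts m < 0 strictly).  CPM
normalization is available but off by default: input that is already
normalized should not be rescaled again.

## Gene selection for fixed J

For fixed J the objective is additive over genes, so the optimal gene set
contains exactly the genes with positive contribution — except that the
negative-fraction constraint couples them.  Writing w_i = neg_i − μ|J|
(neg_i = number of negative entries of gene i inside J), a gene set is
feasible iff Σ w_i ≤ 0.  Genes with positive contribution and w_i ≤ 0 are
always selected (they add value and slack); the remaining positive-weight
candidates form a 0/1 knapsack with budget equal to the accumulated slack,
solved exactly by dynamic programming on integer weights (μ is handled as
an exact rational, so feasibility decisions carry no floating-point error).
Above 24 such candidates a greedy by contribution is used instead; the
exact regime covers every desk-scale instance in the test suite, where the
DP is validated against brute-force subset enumeration.  Genes are never
selected with non-positive contribution, even when including one would
relax the constraint for others — selected genes must each argue for
themselves.

## Search over cell sets

The problem is NP-hard, so the solver is a beam search with one beam per
sample, kept deterministic throughout (ties break toward smaller cell
indices; a seed only matters for the optional randomized restarts).

A subtlety dominates the design: while a subpopulation is only partly
selected, its *own unselected members* sit in the out-of-cluster penalty
term.  With κ = 100/|C| and a 20-cell subpopulation, every ancestor of the
true cluster therefore scores exactly zero, and a greedy search on the
exact objective reliably drifts into shallow local optima (pairs of cells
sharing one private gene).  The solver therefore separates two roles:

* **Ranking** of partial states uses an optimistic guide: ω with the
  penalty charged only for cells that can never enter J (cells excluded by
  earlier runs or outside the candidate pool), and the positive δ-weighted
  contributions summed without the knapsack.  Under this guide a partially
  assembled subpopulation scores in proportion to what it can still become.
  The same machinery ranks the per-sample seed cells, which stratifies the
  initialization across samples; after seeding, beams may absorb cells from
  any sample, since a cross-sample solution must mix them.
* **Reporting** uses the exact objective: every kept state is evaluated
  with the full gene-selection step, and the returned bicluster is the best
  exact objective over all states visited.  The beam result consequently
  never exceeds the exhaustive optimum, which the tests verify on random
  ≤12-cell instances (the beam attains the optimum on all 50).

The search stops after `patience` (default 8) consecutive rounds in which
neither any beam's best guide score nor the global best exact objective
improves; a single non-improving round is not conclusive because the exact
objective can sit on a plateau for several steps while a cluster is being
assembled.  Work per round is (beam width × |S|) states × |C| candidate
evaluations at O(genes) each, i.e. linear in the number of cells at fixed
beam width; an instrumentation counter asserts this bound in the tests.

Further biclusters are found by re-running with the previously selected
cells removed from the candidate pool; their expression still counts in
the out-of-cluster penalty (in both the exact objective and the guide), so
later runs are actively steered away from already-explained patterns.
Returned cell sets are pairwise disjoint.  An alternative mode excludes the
previously selected *genes* instead, which lets cells recur and can expose
hierarchical structure.

## The synthetic benchmark

The generator emulates a controlled two-cell-type experiment: an abundant
background type plus a rare type carrying a dedicated marker program, in
the spirit of mixing two immortalized cell lines.

* Background counts are per-gene negative binomial (dispersion r = 2, i.e.
  var = m + m²/2) with means drawn from a log-normal (median 0.1, shape
  σ = 1.5).  This long-tailed law produces a realistic sparse universe:
  most genes are expressed in ~5–10% of cells, and the upper tail is
  removed by the 25% filter just as broadly expressed genes would be in
  real data (≈80% of genes survive the filter).
* The `n_marker_genes = 50` marker genes have their background mean lowered
  to 0.02 and gain additional negative-binomial counts with mean
  `marker_rate = 5` in the `n_rare` rare cells.  This makes the two types
  strongly transcriptionally distinct — the regime the mixture design
  emulates, where the rare type is a different cell line, not a subtle
  state — while leaving ~8% marker dropouts per rare cell, close to the
  μ = 0.1 budget.
* 1000 cells are split into two samples of 500 with the rare cells divided
  as evenly as possible (odd counts place the extra cell in sample 1).
* Batch effects multiply the CPM-normalized expression values of sample 2
  only (sample 1 is bit-identical before and after): `global` — one
  Gaussian N(0.5, 0.02) factor per gene (negatives clipped at 0, an
  astronomically rare event at σ = 0.02); `gene_specific` — one uniform
  [0.2, 1.8] factor per gene; `value_specific` — an independent uniform
  [0.5, 1.5] factor per entry.  Perturbing normalized values keeps all
  three scenarios meaningful: a near-uniform per-gene factor applied
  *before* library-size normalization would be silently removed by it.
* Recovery is scored as precision (fraction of returned cells that are
  truly rare), recall (fraction of rare cells returned) and their harmonic
  mean F1.

What the generator does **not** model: per-cell library-size variation
beyond the NB noise, gene–gene correlation within the background,
continuous differentiation gradients, doublets, or ambient RNA.  Passing
the benchmark therefore shows that the objective and solver recover a
transcriptionally distinct rare type under multiplicative batch
distortion — not that they resolve subtle cell states in real tissue.

`scripts/acceptance.py` runs the full protocol (1000 cells, 20 rare cells,
3 scenarios × 10 replicates) with the gene universe scaled to 400 genes
(50 of them markers) rather than a full transcriptome; the package's other
tests exercise 150–400-gene instances.  Replicate r of a run with seed s
uses generator seed s + r, and the batch-effect draw uses its own derived
seed, so the whole benchmark is bit-reproducible from the command line
arguments.

## Numerical and degenerate-case choices

* All tie-breaks are lexicographic toward smaller indices; no randomness
  anywhere in the default pipeline, so identical inputs give bit-identical
  results.
* δ of a single sample is defined as 1 (the GM/AM ratio of one value), so
  the single-sample reduction needs no special casing; `delta_one=True`
  forces the same behaviour with multiple samples.
* An empty gene selection (no gene with positive contribution) yields an
  empty bicluster with objective 0; an iterative run returning an empty
  bicluster stops the loop with a logged notice.
* A cell with zero total counts makes CPM undefined and raises, naming the
  cell; negative input counts and unknown/duplicated identifiers raise
  before any computation.
* μ is converted to an exact rational (`Fraction(mu).limit_denominator(1e6)`)
  so constraint feasibility is decided in integer arithmetic.

## Known limitations

* The beam search is a heuristic: the guide can in principle lead it past
  the global optimum (the oracle bound is one-sided).  On the tested
  instance families it attains the exhaustive optimum, but no approximation
  guarantee is claimed.
* Matrices are handled densely; tens of thousands of cells after gene
  filtering are fine, but atlas-scale inputs would need a sparse or
  out-of-core backend.
* The number of iterative runs is left to the user (each run reports its
  objective and gene program; runs that return tiny clusters with weak
  programs are the natural stopping signal).
* Choosing how many biclusters are real biology versus noise requires
  external validation (e.g. functional enrichment of the gene programs);
  the tool only quantifies pattern strength.
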