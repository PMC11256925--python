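"""Why the cross-sample consistency weight matters.

Builds a 6-gene x 12-cell toy with two planted expression blocks over three
samples: a high-value block confined to the third sample, and a smaller
block spread over all three samples.  Solving the problem exhaustively with
the consistency weight switched off (delta == 1, the single-sample
objective) picks the confined block; the full cross-sample objective picks
the spread block instead, because the geometric/arithmetic-mean weight
cancels genes whose specificity lives in a single sample.
"""

import numpy as np

from crossbic import ExpressionMatrix, Params, SampleMap, exhaustive_search

V = -np.ones((6, 12))
V[np.ix_([0, 1], [0, 1, 4, 5, 8, 9])] = 2.0  # spread: two cells per sample
V[np.ix_([2, 3], [8, 9, 10, 11])] = 3.5  # confined: third sample only
m = ExpressionMatrix(V, [f"g{i}" for i in range(6)], [f"c{j}" for j in range(12)])
samples = SampleMap(["donorA"] * 4 + ["donorB"] * 4 + ["donorC"] * 4)

single = exhaustive_search(m, samples, Params(kappa=1.0, mu=0.1, delta_one=True))
cross = exhaustive_search(m, samples, Params(kappa=1.0, mu=0.1))

print("single-sample objective (delta == 1):")
print(f"  cells {single.cell_ids}  genes {single.gene_ids}  objective {single.objective:.1f}")
print("cross-sample objective:")
print(f"  cells {cross.cell_ids}  genes {cross.gene_ids}  objective {cross.objective:.1f}")
print()
print(
    "The confined block sums higher (28 > 24), so the single-sample criterion"
    " selects it;\nthe consistency weight collapses its contribution"
    " (omega = (0, 0, 14) per sample -> delta ~ 0.11),\nso the full objective"
    " prefers the subpopulation present in every donor."
)
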