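"""Preprocessing: CPM normalization, signed log transform, sparse-gene filtering.

The downstream objective assumes a matrix whose entry signs encode
expressed / non-expressed, and a gene universe restricted to sparsely
expressed genes (generic high-expression markers carry no rare-population
signal and would dominate a global sum).
"""

from __future__ import annotations

import numpy as np

from .matrix import CountMatrix, ExpressionMatrix

__all__ = ["cpm_normalize", "log_transform", "filter_genes"]


def cpm_normalize(counts: CountMatrix) -> CountMatrix:
    """Counts-per-million library-size normalization (per cell column).

    Raises if a cell has an all-zero column, naming the offending cell.
    """
    sums = counts.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [counts.cell_ids[j] for j in zero[:5]]
        raise ValueError(f"cannot CPM-normalize cells with zero total counts: {names}")
    values = counts.values * (1e6 / sums)
    return CountMatrix(values, list(counts.gene_ids), list(counts.cell_ids))


def log_transform(counts: CountMatrix, pseudocount: float = 0.1) -> ExpressionMatrix:
    """Signed log transform ``log10(x + pseudocount)``.

    With the default pseudocount 0.1, zero counts map exactly to -1 and
    entries are positive iff the (normalized) count exceeds 0.9.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if np.any(counts.values < 0):
        raise ValueError("negative values in count matrix")
    values = np.log10(counts.values + pseudocount)
    return ExpressionMatrix(
        values,
        list(counts.gene_ids),
        list(counts.cell_ids),
        pseudocount=pseudocount,
        provenance={"transform": f"log10(x + {pseudocount})"},
    )


def filter_genes(m: ExpressionMatrix, max_expr_fraction: float = 0.25) -> ExpressionMatrix:
    """Keep genes expressed (entry > 0) in at most ``max_expr_fraction`` of cells.

    Genes expressed in strictly more than the threshold fraction are dropped.
    The kept gene indices (relative to the input) are recorded in provenance.
    Idempotent: filtering an already-filtered matrix changes nothing.
    """
    if not (0 < max_expr_fraction <= 1):
        raise ValueError("max_expr_fraction must be in (0, 1]")
    n_pos = (m.values > 0).sum(axis=1)
    keep = np.flatnonzero(n_pos <= max_expr_fraction * m.n_cells)
    if keep.size == 0:
        raise ValueError(
            "no gene is expressed in at most "
            f"{max_expr_fraction:.0%} of cells; raise max_expr_fraction"
        )
    provenance = dict(m.provenance)
    provenance.update(
        {
            "filter": f"expressed fraction <= {max_expr_fraction}",
            "kept_gene_indices": keep.tolist(),
            "n_genes_before": m.n_genes,
        }
    )
    return ExpressionMatrix(
        m.values[keep],
        [m.gene_ids[i] for i in keep],
        list(m.cell_ids),
        pseudocount=m.pseudocount,
        provenance=provenance,
    )
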