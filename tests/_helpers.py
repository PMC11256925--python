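"""Shared fixtures-in-code: instance builders and independent brute-force oracles."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from crossbic import ExpressionMatrix, Params, SampleMap
from crossbic.objective import gene_contribution


def make_expression(values, labels) -> tuple[ExpressionMatrix, SampleMap]:
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    m = ExpressionMatrix(values, [f"g{i}" for i in range(n_g)], [f"c{j}" for j in range(n_c)])
    return m, SampleMap(list(labels))


def planted_block_instance() -> tuple[ExpressionMatrix, SampleMap, dict]:
    """Two planted blocks over three samples of four cells.

    The 'confined' block (genes 2,3 on cells 8-11, all in the third sample)
    has the larger raw expression sum; the 'spread' block (genes 0,1 on two
    cells of every sample) is smaller but present in all samples.
    """
    V = -np.ones((6, 12))
    spread_cells = (0, 1, 4, 5, 8, 9)
    confined_cells = (8, 9, 10, 11)
    for g in (0, 1):
        V[g, list(spread_cells)] = 2.0
    for g in (2, 3):
        V[g, list(confined_cells)] = 3.5
    m, sm = make_expression(V, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    truth = {
        "spread_cells": spread_cells,
        "spread_genes": (0, 1),
        "confined_cells": confined_cells,
        "confined_genes": (2, 3),
    }
    return m, sm, truth


def random_instance(rng: np.random.Generator, max_cells: int = 10, max_genes: int = 10):
    """Small random two-sample instance, sometimes with a planted block."""
    n_c = int(rng.integers(6, max_cells + 1))
    n_g = int(rng.integers(4, max_genes + 1))
    V = rng.normal(-0.3, 1.2, size=(n_g, n_c))
    if rng.random() < 0.7:
        gs = rng.choice(n_g, size=min(3, n_g), replace=False)
        cs = rng.choice(n_c, size=min(4, n_c), replace=False)
        V[np.ix_(gs, cs)] += 2.0
    m, sm = make_expression(V, ["A" if j < n_c // 2 else "B" for j in range(n_c)])
    params = Params(
        kappa=float(rng.choice([0.3, 0.5, 1.0])),
        mu=float(rng.choice([0.1, 0.2])),
    )
    return m, sm, params


def brute_force_gene_selection(m, J, samples, params) -> tuple[float, tuple[int, ...]]:
    """Independent oracle: enumerate all subsets of the candidate genes.

    Candidates are the genes with strictly positive contribution (a gene is
    never selected when its contribution is negative); feasibility of the
    negative-fraction constraint is checked in exact rational arithmetic.
    Returns (best objective, best gene subset); the empty set scores 0.
    """
    J = sorted(J)
    stats = [gene_contribution(m, i, J, samples, params) for i in range(m.n_genes)]
    cand = [i for i, gs in enumerate(stats) if gs.contribution > 0]
    mu = Fraction(params.mu).limit_denominator(10**6)
    best_obj, best_I = 0.0, ()
    for r in range(1, len(cand) + 1):
        for I in combinations(cand, r):
            neg_total = sum(stats[i].neg_count for i in I)
            if Fraction(neg_total, len(I) * len(J)) > mu:
                continue
            obj = sum(stats[i].contribution for i in I)
            if obj > best_obj:
                best_obj, best_I = obj, I
    return best_obj, best_I
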