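"""End-to-end orchestration: preprocess counts, run the search, build reports."""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import CountMatrix, ExpressionMatrix, SampleMap
from .objective import Params
from .preprocess import cpm_normalize, filter_genes, log_transform
from .solver import RunResult, SearchConfig, iterative_runs

__all__ = ["preprocess_counts", "find_biclusters", "PipelineResult"]


def preprocess_counts(
    counts: CountMatrix,
    normalize: str = "none",
    pseudocount: float = 0.1,
    max_expr_fraction: float = 0.25,
) -> ExpressionMatrix:
    """Optional CPM, signed log transform, sparse-gene filter."""
    if normalize not in ("none", "cpm"):
        raise ValueError("normalize must be 'none' or 'cpm'")
    if normalize == "cpm":
        counts = cpm_normalize(counts)
    return filter_genes(log_transform(counts, pseudocount), max_expr_fraction)


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    runs: list[RunResult]
    params: Params
    config: SearchConfig


def find_biclusters(
    counts: CountMatrix,
    sample_map: SampleMap,
    normalize: str = "none",
    pseudocount: float = 0.1,
    max_expr_fraction: float = 0.25,
    params: Params | None = None,
    beam_width: int = 10,
    max_cluster_size: int | None = None,
    n_runs: int = 1,
    exclude: str = "cells",
    seed: int = 0,
) -> PipelineResult:
    """Preprocess and run the iterative multi-bicluster search."""
    params = params or Params()
    expression = preprocess_counts(counts, normalize, pseudocount, max_expr_fraction)
    config = SearchConfig(
        beam_width=beam_width,
        max_cluster_size=max_cluster_size,
        seed=seed,
        params=params,
    )
    runs = iterative_runs(
        expression, sample_map, params=params, n_runs=n_runs, config=config, exclude=exclude
    )
    return PipelineResult(expression=expression, runs=runs, params=params, config=config)
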