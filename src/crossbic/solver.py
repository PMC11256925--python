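"""Search over cell subsets: exhaustive oracle, per-sample beam search,
and the iterative multi-bicluster protocol.

The optimization problem is NP-hard; the beam search finds a good
approximation in time linear in the number of cells at fixed beam width.
Diversity is ensured by maintaining one beam per sample, seeded with the
sample's most promising single cells; after seeding, a beam may absorb
cells from any sample (a cross-sample solution must mix samples, so only
the initialization is stratified).  Partial states are ranked by an
optimistic guide score in which the out-of-cluster penalty is charged only
for cells that can never enter J (the exact objective of a partial cluster
is dominated by its own still-unselected members and sits at zero until
the cell set is nearly complete); the exact optimal-gene objective is
evaluated for every kept state, and the best exact objective over all
visited states is returned.  The search stops once ``patience`` consecutive
extension rounds improve neither any beam's best guide score nor the global
best exact objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable

import numpy as np

from .matrix import ExpressionMatrix, SampleMap
from .objective import Bicluster, BeamState, ObjectiveEngine, Params

__all__ = ["SearchConfig", "RunResult", "exhaustive_search", "beam_search", "iterative_runs"]

logger = logging.getLogger("crossbic")

_EXHAUSTIVE_LIMIT = 16


@dataclass(frozen=True)
class SearchConfig:
    """Beam-search configuration.

    ``candidate_pool`` restricts which cells may enter J (default: all);
    ``excluded_cells`` (cells selected in earlier runs) are removed from the
    pool but still contribute to the out-of-cluster penalty.  ``seed`` only
    matters when ``n_restarts`` > 0 (randomized re-seeding of the beams).
    """

    beam_width: int = 10
    max_cluster_size: int | None = None
    patience: int = 8
    candidate_pool: frozenset[int] | None = None
    excluded_cells: frozenset[int] = frozenset()
    excluded_genes: frozenset[int] = frozenset()
    seed: int = 0
    n_restarts: int = 0
    params: Params = field(default_factory=Params)

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.candidate_pool is not None and self.candidate_pool & self.excluded_cells:
            raise ValueError("candidate_pool and excluded_cells must be disjoint")


@dataclass
class RunResult:
    """One solver run: the bicluster, the per-step best-objective trace."""

    bicluster: Bicluster
    trace: list[float]
    run_index: int = 0


def _pool(
    n_cells: int,
    candidate_pool: Iterable[int] | None,
    excluded: Iterable[int],
) -> np.ndarray:
    pool = set(range(n_cells)) if candidate_pool is None else set(int(c) for c in candidate_pool)
    pool -= set(int(c) for c in excluded)
    return np.asarray(sorted(pool), dtype=np.int64)


def _empty_result(engine: ObjectiveEngine) -> Bicluster:
    return Bicluster(
        genes=np.empty(0, dtype=np.int64),
        cells=np.empty(0, dtype=np.int64),
        gene_stats=[],
        objective=0.0,
        neg_fraction=0.0,
    )


def exhaustive_search(
    m: ExpressionMatrix,
    samples: SampleMap,
    params: Params | None = None,
    max_cells: int = 14,
    candidate_pool: Iterable[int] | None = None,
) -> Bicluster:
    """Global optimum by enumerating every nonempty cell subset.

    Oracle for tiny instances only (2^n subsets); ties broken toward the
    lexicographically smallest cell set.
    """
    engine = ObjectiveEngine(m, samples, params)
    pool = _pool(m.n_cells, candidate_pool, ())
    if pool.size > min(max_cells, _EXHAUSTIVE_LIMIT):
        raise ValueError(
            f"{pool.size} candidate cells is too many for exhaustive enumeration; "
            "use beam_search"
        )
    best_obj, best_J = 0.0, None
    for r in range(1, pool.size + 1):
        for J in combinations(pool.tolist(), r):
            state = engine.make_state(J)
            obj = state.objective
            if obj > best_obj or (obj == best_obj and best_J is not None and J < best_J):
                best_obj, best_J = obj, J
    if best_J is None or best_obj <= 0.0:
        return _empty_result(engine)
    return engine.select_genes(best_J)


def _run_beam(
    engine: ObjectiveEngine,
    pool: np.ndarray,
    config: SearchConfig,
    seed_cells: dict[str, np.ndarray],
) -> tuple[BeamState | None, list[float]]:
    """One beam-search pass from given per-sample seed candidates.

    Partial states are *ranked* by the optimistic guide score (out-of-cluster
    penalty charged only for cells that can never enter J); the *returned*
    bicluster is the best exact objective over every state visited.  Greedy
    exact scoring would be blind here: while a subpopulation is only partly
    selected, its own unselected members dominate the penalty term, so every
    ancestor of the true cluster scores zero and the search drifts to
    shallow local optima.
    """
    width = config.beam_width
    empty = engine.empty_state()
    beams: dict[str, list[tuple[float, BeamState]]] = {}  # (guide, state)
    beam_best_guide: dict[str, float] = {}
    best_state: BeamState | None = None
    best_obj = 0.0

    seed_guide = dict(zip(pool.tolist(), engine.guide_extensions(empty, pool).tolist()))
    for s in engine.samples.samples:
        ranked = sorted(seed_cells[s].tolist(), key=lambda c: (-seed_guide[c], c))[:width]
        beams[s] = [(seed_guide[c], engine.extend_state(empty, c)) for c in ranked]
        beam_best_guide[s] = max((g for g, _ in beams[s]), default=-np.inf)
        for _, st in beams[s]:
            if st.objective > best_obj or (
                st.objective == best_obj
                and best_state is not None
                and st.cells < best_state.cells
            ):
                best_obj, best_state = st.objective, st
    trace = [best_obj]

    pool_set = set(pool.tolist())
    stale_rounds = 0
    while True:
        improved = False
        step_cache: dict[tuple[int, ...], list[tuple[float, int]]] = {}
        new_beams: dict[str, list[tuple[float, BeamState]]] = {}
        for s in engine.samples.samples:
            entries: dict[tuple[int, ...], tuple[float, BeamState, int]] = {}
            for _, st in beams[s]:
                if (
                    config.max_cluster_size is not None
                    and len(st.cells) >= config.max_cluster_size
                ):
                    continue
                key = st.cells
                if key in step_cache:
                    scored = step_cache[key]
                else:
                    cands = np.asarray(sorted(pool_set - set(st.cells)), dtype=np.int64)
                    guides = engine.guide_extensions(st, cands)
                    order = np.lexsort((cands, -guides))[:width]
                    scored = [(float(guides[k]), int(cands[k])) for k in order]
                    step_cache[key] = scored
                for guide, cell in scored:
                    new_cells = tuple(sorted(st.cells + (cell,)))
                    cur = entries.get(new_cells)
                    if cur is None or guide > cur[0]:
                        entries[new_cells] = (guide, st, cell)
            ranked = sorted(entries.items(), key=lambda kv: (-kv[1][0], kv[0]))[:width]
            new_states = [
                (guide, engine.extend_state(parent, cell))
                for _, (guide, parent, cell) in ranked
            ]
            new_beams[s] = new_states
            if new_states:
                step_guide = max(g for g, _ in new_states)
                if step_guide > beam_best_guide[s] + 1e-12:
                    improved = True
                beam_best_guide[s] = max(beam_best_guide[s], step_guide)
                for _, st in new_states:
                    if st.objective > best_obj + 1e-12:
                        improved = True
                    if st.objective > best_obj:
                        best_obj, best_state = st.objective, st
        beams = new_beams
        trace.append(best_obj)
        stale_rounds = 0 if improved else stale_rounds + 1
        if stale_rounds >= config.patience or all(len(b) == 0 for b in beams.values()):
            break
    return (best_state if best_obj > 0 else None), trace


def beam_search(
    m: ExpressionMatrix,
    samples: SampleMap,
    config: SearchConfig | None = None,
) -> RunResult:
    """Per-sample beam search for the best bicluster.

    Deterministic given the configuration and input; ties break toward
    higher objective, then the lexicographically smaller cell set.
    """
    config = config or SearchConfig()
    params = config.params
    selectable = None
    if config.excluded_genes:
        selectable = sorted(set(range(m.n_genes)) - set(config.excluded_genes))
    engine = ObjectiveEngine(m, samples, params, selectable_genes=selectable)
    pool = _pool(m.n_cells, config.candidate_pool, config.excluded_cells)
    if pool.size == 0:
        raise ValueError("empty candidate pool")
    # guide penalty: only cells that can never be selected (spec of the guide)
    engine.set_fixed_penalty(set(range(m.n_cells)) - set(pool.tolist()))

    seed_cells = {
        s: pool[samples.codes[pool] == s_i] for s_i, s in enumerate(samples.samples)
    }
    best_state, trace = _run_beam(engine, pool, config, seed_cells)

    if config.n_restarts > 0:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_restarts):
            rnd_seed = {
                s: rng.permutation(cells)[: config.beam_width]
                for s, cells in seed_cells.items()
            }
            cand_state, cand_trace = _run_beam(engine, pool, config, rnd_seed)
            if cand_state is not None and (
                best_state is None or cand_state.objective > best_state.objective
            ):
                best_state, trace = cand_state, cand_trace

    if best_state is None:
        return RunResult(bicluster=_empty_result(engine), trace=trace)
    return RunResult(bicluster=engine.select_genes(best_state.cells), trace=trace)


def iterative_runs(
    m: ExpressionMatrix,
    samples: SampleMap,
    params: Params | None = None,
    n_runs: int = 1,
    config: SearchConfig | None = None,
    exclude: str = "cells",
) -> list[RunResult]:
    """Repeat the search, excluding previous selections.

    ``exclude='cells'`` (default): cells from earlier runs can no longer be
    selected but still weigh on the out-of-cluster penalty; returned cell
    sets are pairwise disjoint.  ``exclude='genes'``: earlier marker genes
    are removed from the selectable gene universe instead (useful to expose
    hierarchical structure; cells may then recur).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if exclude not in ("cells", "genes"):
        raise ValueError("exclude must be 'cells' or 'genes'")
    config = config or SearchConfig()
    if params is not None:
        config = replace(config, params=params)
    excluded_cells = set(config.excluded_cells)
    excluded_genes = set(config.excluded_genes)
    results: list[RunResult] = []
    for r in range(n_runs):
        cfg = replace(
            config,
            excluded_cells=frozenset(excluded_cells),
            excluded_genes=frozenset(excluded_genes),
        )
        res = beam_search(m, samples, cfg)
        res.run_index = r
        if res.bicluster.is_empty:
            logger.info("run %d returned an empty bicluster; stopping early", r)
            break
        results.append(res)
        if exclude == "cells":
            excluded_cells |= set(res.bicluster.cells.tolist())
        else:
            excluded_genes |= set(res.bicluster.genes.tolist())
    return results
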