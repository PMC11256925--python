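"""The cross-sample biclustering objective.

A bicluster is a gene set I and a cell set J.  Per sample s, the specificity
of gene i for J is

    omega_is(J) = sum_{j in C_s ∩ J} m_ij  -  kappa * sum_{k in C_s \\ J} max(0, m_ik)

i.e. the in-cluster expression sum minus a penalty on out-of-cluster positive
expression within the same sample.  A cross-sample consistency weight

    delta_i(J) = GM_s( max(eps, omega_is) ) / AM_s( max(eps, omega_is) )

(geometric over arithmetic mean of the eps-clipped omegas, in (0, 1]) down-
weights genes whose specificity is confined to a few samples.  The global
objective is

    maximize  sum_{i in I} delta_i(J) * sum_s omega_is(J)
    s.t.      #{(i,j) : i in I, j in J, m_ij < 0}  <=  mu * |I| * |J|

For a fixed J the optimal gene set is a knapsack variant: writing the
per-gene weight w_i = neg_count_i - mu*|J|, a gene set is feasible iff
sum w_i <= 0.  Genes with positive contribution and w_i <= 0 are always
included (they add both value and slack); the remaining positive-weight
candidates are chosen by an exact dynamic program on integer-scaled rational
weights, with a greedy fallback above a candidate-count threshold.

With a single sample (or ``delta_one=True``) delta is identically 1 and the
objective reduces to the single-sample MicroCellClust criterion computed over
the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .matrix import ExpressionMatrix, SampleMap

__all__ = [
    "Params",
    "GeneStats",
    "Bicluster",
    "ObjectiveEngine",
    "omega",
    "delta",
    "gene_contribution",
    "negative_fraction",
    "select_genes",
    "evaluate",
]


@dataclass(frozen=True)
class Params:
    """Objective parameters.

    kappa : penalty weight on out-of-cluster positive expression; ``None``
        means the default 100 / n_cells.  Larger values keep only the most
        differentiated genes.
    mu : maximum fraction of negative entries allowed in the selected
        submatrix (default 0.1).
    epsilon : positive clipping floor applied to omegas inside the
        geometric/arithmetic means (default 0.1).
    delta_one : force delta == 1, i.e. the single-sample objective that
        ignores the partition into samples.
    exact_gene_limit : largest number of constrained (positive-weight)
        candidate genes solved by the exact DP; above it a greedy by
        contribution is used.
    """

    kappa: float | None = None
    mu: float = 0.1
    epsilon: float = 0.1
    delta_one: bool = False
    exact_gene_limit: int = 24

    def __post_init__(self) -> None:
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 <= self.mu <= 1):
            raise ValueError("mu must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def resolve_kappa(self, n_cells: int) -> float:
        return self.kappa if self.kappa is not None else 100.0 / n_cells


@dataclass
class GeneStats:
    """Per-gene quantities for a candidate cell set J."""

    gene: int
    gene_id: str
    omega_per_sample: dict[str, float]
    delta: float
    contribution: float
    neg_count: int


@dataclass
class Bicluster:
    """A gene set I, a cell set J, per-gene stats, and the objective value."""

    genes: np.ndarray
    cells: np.ndarray
    gene_stats: list[GeneStats]
    objective: float
    neg_fraction: float
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.genes.size == 0

    def __repr__(self) -> str:
        return (
            f"Bicluster(|I|={self.genes.size}, |J|={self.cells.size}, "
            f"objective={self.objective:.4f}, neg_fraction={self.neg_fraction:.4f})"
        )


def _delta_from_clipped(clipped: np.ndarray) -> np.ndarray:
    """GM/AM ratio along axis 1 of an already eps-clipped positive array."""
    gm = np.exp(np.log(clipped).mean(axis=1))
    am = clipped.mean(axis=1)
    return gm / am


class ObjectiveEngine:
    """Vectorized evaluation of the objective for one expression matrix.

    Precomputes per-sample out-of-cluster positive sums so that evaluating a
    cell set J, or scoring all single-cell extensions of J, costs O(genes)
    per candidate.
    """

    def __init__(
        self,
        m: ExpressionMatrix,
        samples: SampleMap,
        params: Params | None = None,
        selectable_genes: Iterable[int] | None = None,
    ):
        params = params or Params()
        if samples.n_cells != m.n_cells:
            raise ValueError(
                f"sample map covers {samples.n_cells} cells, matrix has {m.n_cells}"
            )
        self.m = m
        self.samples = samples
        self.params = params
        self.n_genes, self.n_cells = m.values.shape
        self.n_samples = samples.n_samples
        self.kappa = params.resolve_kappa(self.n_cells)
        V = np.ascontiguousarray(m.values, dtype=np.float64)
        self.V = V
        self.pos = np.maximum(V, 0.0)
        self.isneg = V < 0.0
        # out-of-cluster penalty base: total positive expression per (gene, sample)
        self.P = np.stack(
            [self.pos[:, samples.cells_of(s)].sum(axis=1) for s in samples.samples],
            axis=1,
        )
        # when cell c joins J, omega of its sample gains m_ic + kappa*max(0, m_ic)
        self.ext_gain = V + self.kappa * self.pos
        frac = Fraction(params.mu).limit_denominator(10**6)
        self._mu_p, self._mu_q = frac.numerator, frac.denominator
        self.gene_mask = np.zeros(self.n_genes, dtype=bool)
        if selectable_genes is None:
            self.gene_mask[:] = True
        else:
            self.gene_mask[np.asarray(list(selectable_genes), dtype=np.int64)] = True
        self.cells_scored = 0  # instrumentation: candidate evaluations performed
        self.P_fixed = np.zeros((self.n_genes, self.n_samples))  # see set_fixed_penalty

    # ------------------------------------------------------------------ states

    def empty_state(self) -> "BeamState":
        shape = (self.n_genes, self.n_samples)
        return BeamState(
            cells=(),
            in_sum=np.zeros(shape),
            in_pos=np.zeros(shape),
            neg=np.zeros(self.n_genes, dtype=np.int64),
            objective=0.0,
        )

    def make_state(self, cells: Iterable[int]) -> "BeamState":
        cells = tuple(sorted(int(c) for c in cells))
        cols = np.asarray(cells, dtype=np.int64)
        if cols.size and (cols.min() < 0 or cols.max() >= self.n_cells):
            raise IndexError("cell index out of range")
        shape = (self.n_genes, self.n_samples)
        in_sum = np.zeros(shape)
        in_pos = np.zeros(shape)
        for s_i, s in enumerate(self.samples.samples):
            js = cols[self.samples.codes[cols] == s_i] if cols.size else cols
            if js.size:
                in_sum[:, s_i] = self.V[:, js].sum(axis=1)
                in_pos[:, s_i] = self.pos[:, js].sum(axis=1)
        neg = (
            self.isneg[:, cols].sum(axis=1).astype(np.int64)
            if cols.size
            else np.zeros(self.n_genes, dtype=np.int64)
        )
        st = BeamState(cells=cells, in_sum=in_sum, in_pos=in_pos, neg=neg, objective=0.0)
        if cells:
            st.objective = self._objective_of_state(st)
        return st

    def extend_state(self, state: "BeamState", cell: int) -> "BeamState":
        """State for J ∪ {cell}; its exact objective is evaluated eagerly."""
        s_i = int(self.samples.codes[cell])
        in_sum = state.in_sum.copy()
        in_pos = state.in_pos.copy()
        in_sum[:, s_i] += self.V[:, cell]
        in_pos[:, s_i] += self.pos[:, cell]
        neg = state.neg + self.isneg[:, cell]
        cells = tuple(sorted(state.cells + (int(cell),)))
        st = BeamState(cells=cells, in_sum=in_sum, in_pos=in_pos, neg=neg, objective=0.0)
        st.objective = self._objective_of_state(st)
        return st

    # -------------------------------------------------------------- evaluation

    def omega_matrix(self, state: "BeamState") -> np.ndarray:
        return state.in_sum - self.kappa * (self.P - state.in_pos)

    def _contrib(self, omega_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(delta, contribution) per gene from an omega matrix (genes x samples)."""
        total = omega_mat.sum(axis=1)
        if self.params.delta_one or self.n_samples == 1:
            dlt = np.ones(omega_mat.shape[0])
        else:
            dlt = _delta_from_clipped(np.maximum(omega_mat, self.params.epsilon))
        return dlt, dlt * total

    def _choose_genes(
        self, contrib: np.ndarray, neg: np.ndarray, j_size: int
    ) -> np.ndarray:
        """Optimal gene set for fixed J: indices, sorted ascending."""
        cand = np.flatnonzero((contrib > 0) & self.gene_mask)
        if cand.size == 0:
            return cand
        q, p = self._mu_q, self._mu_p
        w = neg[cand] * q - p * j_size  # integer weights; feasible iff sum <= 0
        free = cand[w <= 0]
        heavy = cand[w > 0]
        if heavy.size == 0:
            return np.sort(free)
        budget = int(-w[w <= 0].sum())
        chosen = self._solve_heavy(
            heavy, (neg[heavy] * q - p * j_size).astype(np.int64), contrib[heavy], budget
        )
        return np.sort(np.concatenate([free, np.asarray(chosen, dtype=np.int64)]))

    def _solve_heavy(
        self,
        genes: np.ndarray,
        weights: np.ndarray,
        values: np.ndarray,
        budget: int,
    ) -> list[int]:
        """Pick positive-weight genes maximizing value with total weight <= budget."""
        if budget <= 0 or genes.size == 0:
            return []
        if genes.size > self.params.exact_gene_limit:
            order = np.lexsort((genes, -values))
            used, chosen = 0, []
            for k in order:
                if used + weights[k] <= budget:
                    chosen.append(int(genes[k]))
                    used += int(weights[k])
            return chosen
        # exact DP on reachable total weights; dominance-pruned
        states: dict[int, tuple[float, tuple[int, ...]]] = {0: (0.0, ())}
        order = np.argsort(genes)
        for k in order:
            w, v, g = int(weights[k]), float(values[k]), int(genes[k])
            updates = {}
            for wt, (val, sel) in states.items():
                nw = wt + w
                if nw > budget:
                    continue
                candv = (val + v, sel + (g,))
                cur = states.get(nw)
                best = updates.get(nw, cur)
                if best is None or candv[0] > best[0] or (
                    candv[0] == best[0] and candv[1] < best[1]
                ):
                    updates[nw] = candv
            states.update(updates)
            if len(states) > 20000:  # dominance pruning to bound DP size
                pruned: dict[int, tuple[float, tuple[int, ...]]] = {}
                best_val = -np.inf
                for wt in sorted(states):
                    val, sel = states[wt]
                    if val > best_val:
                        pruned[wt] = (val, sel)
                        best_val = val
                states = pruned
        best = max(states.values(), key=lambda t: (t[0], tuple(-g for g in t[1])))
        return list(best[1])

    def _objective_of_state(self, state: "BeamState") -> float:
        _, contrib = self._contrib(self.omega_matrix(state))
        I = self._choose_genes(contrib, state.neg, len(state.cells))
        return float(contrib[I].sum()) if I.size else 0.0

    def select_genes(self, J: Iterable[int]) -> Bicluster:
        """Optimal gene set and full stats for a fixed cell set J."""
        state = self.make_state(J)
        if not state.cells:
            raise ValueError("J must be nonempty")
        omega_mat = self.omega_matrix(state)
        dlt, contrib = self._contrib(omega_mat)
        I = self._choose_genes(contrib, state.neg, len(state.cells))
        return self._build_bicluster(state, omega_mat, dlt, contrib, I)

    def evaluate(self, I: Iterable[int], J: Iterable[int]) -> Bicluster:
        """Stats/objective for a user-supplied bicluster (reporting path).

        The negative-fraction constraint is reported, not enforced.
        """
        I = np.asarray(sorted(set(int(i) for i in I)), dtype=np.int64)
        if I.size == 0:
            raise ValueError("I must be nonempty")
        if I.min() < 0 or I.max() >= self.n_genes:
            raise IndexError("gene index out of range")
        state = self.make_state(J)
        if not state.cells:
            raise ValueError("J must be nonempty")
        omega_mat = self.omega_matrix(state)
        dlt, contrib = self._contrib(omega_mat)
        return self._build_bicluster(state, omega_mat, dlt, contrib, I)

    def _build_bicluster(
        self,
        state: "BeamState",
        omega_mat: np.ndarray,
        dlt: np.ndarray,
        contrib: np.ndarray,
        I: np.ndarray,
    ) -> Bicluster:
        cells = np.asarray(state.cells, dtype=np.int64)
        if I.size == 0:
            return Bicluster(
                genes=I,
                cells=cells,
                gene_stats=[],
                objective=0.0,
                neg_fraction=0.0,
                gene_ids=[],
                cell_ids=[self.m.cell_ids[j] for j in cells],
            )
        stats = [
            GeneStats(
                gene=int(i),
                gene_id=self.m.gene_ids[i],
                omega_per_sample={
                    s: float(omega_mat[i, s_i]) for s_i, s in enumerate(self.samples.samples)
                },
                delta=float(dlt[i]),
                contribution=float(contrib[i]),
                neg_count=int(state.neg[i]),
            )
            for i in I
        ]
        neg_frac = float(state.neg[I].sum() / (I.size * cells.size))
        return Bicluster(
            genes=I,
            cells=cells,
            gene_stats=stats,
            objective=float(contrib[I].sum()),
            neg_fraction=neg_frac,
            gene_ids=[self.m.gene_ids[i] for i in I],
            cell_ids=[self.m.cell_ids[j] for j in cells],
        )

    # ------------------------------------------------------ search guidance

    def set_fixed_penalty(self, cells: Iterable[int]) -> None:
        """Declare the cells that can never enter J (excluded / out of pool).

        Their positive expression is the only penalty charged by the
        optimistic guide score: cells still in the candidate pool may yet
        join J, so penalizing them while a cluster is under construction is
        pessimistic and hides any subpopulation larger than a couple of
        cells.  The exact objective is unaffected.
        """
        cells = np.asarray(sorted(set(int(c) for c in cells)), dtype=np.int64)
        if cells.size == 0:
            self.P_fixed = np.zeros((self.n_genes, self.n_samples))
            return
        self.P_fixed = np.stack(
            [
                self.pos[:, cells[self.samples.codes[cells] == s_i]].sum(axis=1)
                for s_i in range(self.n_samples)
            ],
            axis=1,
        )

    def guide_score(self, state: "BeamState") -> float:
        """Optimistic objective of a state (penalty from fixed cells only)."""
        base = state.in_sum - self.kappa * self.P_fixed
        _, contrib = self._contrib(base)
        sel = (contrib > 0) & self.gene_mask
        return float(contrib[sel].sum())

    def guide_extensions(self, state: "BeamState", candidates: np.ndarray) -> np.ndarray:
        """Optimistic guide scores of J ∪ {c}, aligned with ``candidates``.

        The guide replaces omega by its optimistic version
        ``in_sum - kappa * P_fixed`` (see :meth:`set_fixed_penalty`) and sums
        the positive delta-weighted gene contributions without the
        negative-fraction knapsack; it is used only to rank partial states
        during the search, never reported.
        """
        candidates = np.asarray(candidates, dtype=np.int64)
        if candidates.size == 0:
            return np.empty(0)
        self.cells_scored += int(candidates.size)
        eps = self.params.epsilon
        base = state.in_sum - self.kappa * self.P_fixed  # (G, S)
        g = np.empty(candidates.size)
        for s_i in range(self.n_samples):
            sel = self.samples.codes[candidates] == s_i
            grp = candidates[sel]
            if grp.size == 0:
                continue
            new_w = base[:, s_i : s_i + 1] + self.V[:, grp]  # (G, n_s)
            other = [t for t in range(self.n_samples) if t != s_i]
            if self.params.delta_one or self.n_samples == 1:
                contrib = new_w if self.n_samples == 1 else (
                    base[:, other].sum(axis=1)[:, None] + new_w
                )
            else:
                clip_base = np.maximum(base[:, other], eps)
                log_other = np.log(clip_base).sum(axis=1)
                sum_other_clip = clip_base.sum(axis=1)
                clip_new = np.maximum(new_w, eps)
                gm = np.exp((log_other[:, None] + np.log(clip_new)) / self.n_samples)
                am = (sum_other_clip[:, None] + clip_new) / self.n_samples
                total = base[:, other].sum(axis=1)[:, None] + new_w
                contrib = (gm / am) * total
            contrib = np.where((contrib > 0) & self.gene_mask[:, None], contrib, 0.0)
            g[sel] = contrib.sum(axis=0)
        return g


@dataclass
class BeamState:
    """Cached per-sample sums for a cell set J, used by the search."""

    cells: tuple[int, ...]
    in_sum: np.ndarray  # (genes, samples) sum of m over C_s ∩ J
    in_pos: np.ndarray  # (genes, samples) sum of max(0, m) over C_s ∩ J
    neg: np.ndarray  # (genes,) count of negative entries over J
    objective: float


# ------------------------------------------------------------------ functional


def omega(
    m: ExpressionMatrix,
    gene: int,
    sample_cells: Iterable[int],
    J: Iterable[int],
    kappa: float,
) -> float:
    """Specificity of one gene for J within one sample (direct evaluation)."""
    sample_cells = set(int(j) for j in sample_cells)
    J = set(int(j) for j in J)
    row = m.values[gene]
    in_term = sum(row[j] for j in sample_cells & J)
    out_term = sum(max(0.0, row[k]) for k in sample_cells - J)
    return float(in_term - kappa * out_term)


def delta(omegas: Sequence[float], epsilon: float = 0.1) -> float:
    """GM/AM ratio of the eps-clipped per-sample omegas; in (0, 1]."""
    if len(omegas) == 0:
        raise ValueError("need at least one omega value")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    clipped = np.maximum(np.asarray(omegas, dtype=float), epsilon)
    return float(np.exp(np.log(clipped).mean()) / clipped.mean())


def gene_contribution(
    m: ExpressionMatrix,
    gene: int,
    J: Iterable[int],
    samples: SampleMap,
    params: Params | None = None,
) -> GeneStats:
    """All per-gene quantities (omegas, delta, contribution, negative count)."""
    params = params or Params()
    J = sorted(set(int(j) for j in J))
    if not J:
        raise ValueError("J must be nonempty")
    kappa = params.resolve_kappa(m.n_cells)
    omegas = {s: omega(m, gene, samples.cells_of(s), J, kappa) for s in samples.samples}
    vals = list(omegas.values())
    dlt = 1.0 if (params.delta_one or samples.n_samples == 1) else delta(vals, params.epsilon)
    neg_count = int((m.values[gene, J] < 0).sum())
    return GeneStats(
        gene=int(gene),
        gene_id=m.gene_ids[gene],
        omega_per_sample=omegas,
        delta=dlt,
        contribution=float(dlt * sum(vals)),
        neg_count=neg_count,
    )


def negative_fraction(m: ExpressionMatrix, I: Iterable[int], J: Iterable[int]) -> float:
    """Fraction of strictly negative entries in the I x J submatrix."""
    I = np.asarray(sorted(set(int(i) for i in I)), dtype=np.int64)
    J = np.asarray(sorted(set(int(j) for j in J)), dtype=np.int64)
    if I.size == 0 or J.size == 0:
        raise ValueError("I and J must be nonempty")
    sub = m.values[np.ix_(I, J)]
    return float((sub < 0).sum() / sub.size)


def select_genes(
    m: ExpressionMatrix,
    J: Iterable[int],
    samples: SampleMap,
    params: Params | None = None,
) -> Bicluster:
    """Optimal gene set I for fixed J under the negative-fraction constraint."""
    return ObjectiveEngine(m, samples, params).select_genes(J)


def evaluate(
    m: ExpressionMatrix,
    I: Iterable[int],
    J: Iterable[int],
    samples: SampleMap,
    params: Params | None = None,
) -> Bicluster:
    """Assemble stats/objective for a user-supplied bicluster."""
    return ObjectiveEngine(m, samples, params).evaluate(I, J)
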