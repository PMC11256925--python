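"""Core in-memory containers: count matrices, log-expression matrices, sample maps.

All matrices are genes x cells, dense ``float64`` numpy arrays.  The method is
aimed at rare-population analysis at desk scale (hundreds to a few tens of
thousands of cells after gene filtering), where dense arithmetic is both
simpler and faster than sparse for the column-sum-heavy objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["CountMatrix", "ExpressionMatrix", "SampleMap"]


def _check_ids(ids: Sequence[str], kind: str, n: int) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise ValueError(f"{kind} ids length {len(ids)} does not match matrix dimension {n}")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {kind} ids: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Non-negative (raw or normalized) counts, genes x cells."""

    values: np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = _check_ids(self.gene_ids, "gene", self.values.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell", self.values.shape[1])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.gene_ids), list(self.cell_ids))


@dataclass
class ExpressionMatrix:
    """Signed log-expression, genes x cells: ``log10(x + pseudocount)``.

    The sign of an entry encodes expression: strictly positive means the cell
    expresses the gene, strictly negative means it does not.  With the default
    pseudocount of 0.1, zero counts map exactly to -1 and the sign boundary
    sits at a (normalized) count of 0.9.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]
    pseudocount: float = 0.1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression must be a 2-D genes x cells matrix")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        self.gene_ids = _check_ids(self.gene_ids, "gene", self.values.shape[0])
        self.cell_ids = _check_ids(self.cell_ids, "cell", self.values.shape[1])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


class SampleMap:
    """Partition of cell indices into named samples (the set S and the C_s).

    Samples are ordered by first appearance of their label; every sample is
    non-empty and the per-sample index sets partition ``range(n_cells)``.
    """

    def __init__(self, labels: Sequence[str], samples: Sequence[str] | None = None):
        labels = [str(x) for x in labels]
        if not labels:
            raise ValueError("empty sample label vector")
        if samples is None:
            samples = []
            for lab in labels:
                if lab not in samples:
                    samples.append(lab)
        else:
            samples = [str(s) for s in samples]
            if set(samples) != set(labels) or len(set(samples)) != len(samples):
                raise ValueError("explicit sample order must list each observed sample once")
        self.samples: list[str] = list(samples)
        self._index = {s: i for i, s in enumerate(samples)}
        self.codes = np.array([self._index[lab] for lab in labels], dtype=np.int64)
        self._cells_of = [np.flatnonzero(self.codes == i) for i in range(len(samples))]

    @classmethod
    def from_assignment(cls, assignment: Mapping[int, str], n_cells: int) -> "SampleMap":
        missing = [j for j in range(n_cells) if j not in assignment]
        if missing:
            raise ValueError(f"cells without a sample assignment: {missing[:5]}")
        return cls([assignment[j] for j in range(n_cells)])

    @property
    def n_cells(self) -> int:
        return self.codes.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cells_of(self, sample: str) -> np.ndarray:
        """Index set C_s for one sample."""
        return self._cells_of[self._index[sample]]

    def sample_of(self, cell: int) -> str:
        return self.samples[self.codes[cell]]

    def labels(self) -> list[str]:
        return [self.samples[c] for c in self.codes]

    def subset_labels(self, cells: Iterable[int]) -> list[str]:
        return [self.samples[self.codes[j]] for j in cells]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SampleMap)
            and self.samples == other.samples
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:
        sizes = {s: len(self.cells_of(s)) for s in self.samples}
        return f"SampleMap({sizes})"
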