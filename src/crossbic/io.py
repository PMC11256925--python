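"""Readers and writers: MatrixMarket/10x triplet and dense CSV/TSV matrices,
sample-label TSVs, and JSON + TSV run reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import CountMatrix, SampleMap
from .objective import Bicluster

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "RunReport",
    "write_report",
    "load_report",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_sidecar_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()  # 10x dialect: extra name/type columns tolerated


def _locate(directory: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {what} file among {list(names)} in {directory}")


def read_matrix(path: str | Path, layout: str = "mtx", transposed: bool = False) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``layout='mtx'``: ``path`` is a matrix.mtx file or a directory holding
    matrix.mtx plus features.tsv/genes.tsv and barcodes.tsv sidecars (10x
    triplet layout).  ``layout='dense_csv'``/``'dense_tsv'``: genes as rows,
    first column gene ids, header row cell ids.  ``transposed=True`` flips a
    cells x genes input.
    """
    path = Path(path)
    if layout == "mtx":
        if path.is_dir():
            mtx = _locate(path, ["matrix.mtx"], "matrix")
        else:
            mtx = path
        d = mtx.parent
        mat = spio.mmread(mtx)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        genes = _read_sidecar_ids(_locate(d, ["features.tsv", "genes.tsv"], "features"), "features")
        cells = _read_sidecar_ids(_locate(d, ["barcodes.tsv"], "barcodes"), "barcodes")
    elif layout in ("dense_csv", "dense_tsv"):
        sep = "," if layout == "dense_csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise ValueError(f"non-numeric entries in columns: {bad[:5]}")
        values = df.to_numpy(dtype=np.float64)
        genes = [str(x) for x in df.index]
        cells = [str(x) for x in df.columns]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if transposed:
        values = values.T
        genes, cells = cells, genes
    if values.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {values.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    return CountMatrix(values, genes, cells)


def write_matrix(counts: CountMatrix, directory: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + features.tsv + barcodes.tsv into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
    }
    spio.mmwrite(paths["matrix"], sparse.coo_matrix(counts.values))
    pd.DataFrame({"id": counts.gene_ids, "name": counts.gene_ids}).to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


def read_samples(path: str | Path, counts: CountMatrix) -> SampleMap:
    """Read a two-column TSV (cell_id, sample_id) covering every matrix cell.

    Samples are ordered by first appearance.  Unknown or missing cell ids
    raise errors naming the offenders.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, names=["cell_id", "sample_id"])
    if len(df) and df.iloc[0, 0].lower() == "cell_id":
        df = df.iloc[1:].reset_index(drop=True)
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids in sample file: {dups[:5]}")
    mapping = dict(zip(df["cell_id"], df["sample_id"]))
    known = set(counts.cell_ids)
    unknown = [c for c in mapping if c not in known]
    if unknown:
        raise ValueError(f"sample file names cells absent from the matrix: {unknown[:5]}")
    missing = [c for c in counts.cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"cells without a sample label: {missing[:5]}")
    return SampleMap([mapping[c] for c in counts.cell_ids])


def write_samples(sample_map: SampleMap, cell_ids: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"cell_id": list(cell_ids), "sample_id": sample_map.labels()}).to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


@dataclass
class RunReport:
    """Everything needed to reproduce and inspect a multi-run analysis."""

    inputs: dict = field(default_factory=dict)  # file paths + sha256 checksums
    params: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    seed: int = 0
    version: str = ""
    runs: list = field(default_factory=list)  # one dict per bicluster

    @staticmethod
    def bicluster_record(b: Bicluster, run_index: int, sample_ids: Sequence[str]) -> dict:
        return {
            "run_index": run_index,
            "objective": b.objective,
            "neg_fraction": b.neg_fraction,
            "n_genes": int(b.genes.size),
            "n_cells": int(b.cells.size),
            "cell_ids": list(b.cell_ids),
            "genes": [
                {
                    "gene_id": gs.gene_id,
                    "delta": gs.delta,
                    "contribution": gs.contribution,
                    "neg_count": gs.neg_count,
                    **{f"omega_{s}": gs.omega_per_sample[s] for s in sample_ids},
                }
                for gs in b.gene_stats
            ],
        }

    @staticmethod
    def file_record(path: str | Path) -> dict:
        p = Path(path)
        return {"path": str(p), "sha256": _sha256(p)}


def write_report(report: RunReport, directory: str | Path) -> dict[str, Path]:
    """Write report.json plus one TSV per bicluster (deterministic ordering)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    json_path = directory / "report.json"
    with open(json_path, "w") as fh:
        json.dump(asdict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report"] = json_path
    for run in report.runs:
        r = run["run_index"]
        tsv = directory / f"bicluster_{r}.tsv"
        genes = run["genes"]
        if genes:
            df = pd.DataFrame(genes)
            cols = ["gene_id", "delta"] + [
                c for c in df.columns if c.startswith("omega_")
            ] + ["contribution", "neg_count"]
            df = df[cols].sort_values("contribution", ascending=False)
        else:
            df = pd.DataFrame(columns=["gene_id", "delta", "contribution", "neg_count"])
        with open(tsv, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            fh.write("# cells\t" + ",".join(run["cell_ids"]) + "\n")
        paths[f"bicluster_{r}"] = tsv
    return paths


def load_report(path: str | Path) -> RunReport:
    with open(Path(path)) as fh:
        data = json.load(fh)
    return RunReport(**data)
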