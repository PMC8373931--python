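"""Readers and writers for the formats the pipeline exchanges.

FASTA goes through Biopython; counts through scipy's MatrixMarket support;
interval tracks are plain BED6/bedGraph; contact matrices are TSV triples
(bin1_start, bin2_start, count; upper triangle including the diagonal) with a
JSON sidecar naming the chromosome, bin size and coordinate system. All
writers emit deterministic bytes for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .contacts import ContactMatrix, SignedMatrix
from .zeroprop import CountMatrix

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_counts",
    "read_counts",
    "write_json",
]


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(path, df: pd.DataFrame) -> None:
    """Write BED (3-6 columns depending on what the frame carries)."""
    cols = [c for c in _BED6 if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED6[: df.shape[1]]
    return df


def write_bedgraph(path, chrom: str, bin_size: int, values: np.ndarray, offset: int = 0) -> None:
    """Per-bin track; NaN (masked) bins are skipped."""
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            if np.isnan(v):
                continue
            start = offset + i * bin_size
            fh.write(f"{chrom}\t{start}\t{start + bin_size}\t{v:.10g}\n")


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_matrix_tsv(path, m: ContactMatrix | SignedMatrix) -> None:
    """TSV triples (upper triangle incl. diagonal, zero entries skipped) plus a
    JSON sidecar at ``<path>.json``."""
    mat = m.matrix
    n = mat.shape[0]
    with open(path, "w") as fh:
        fh.write("bin1_start\tbin2_start\tcount\n")
        for i in range(n):
            for j in range(i, n):
                v = mat[i, j]
                if v == 0:
                    continue
                fh.write(
                    f"{m.offset + i * m.bin_size}\t{m.offset + j * m.bin_size}\t{v:.10g}\n"
                )
    sidecar = {
        "chromosome": m.chrom,
        "bin_size": m.bin_size,
        "coordinate_system": m.coordinate_system,
        "offset": m.offset,
        "n_bins": n,
        "signed": bool(isinstance(m, SignedMatrix)),
    }
    write_json(_sidecar_path(path), sidecar)


def read_matrix_tsv(path) -> ContactMatrix | SignedMatrix:
    meta = json.loads(_sidecar_path(path).read_text())
    n = meta["n_bins"]
    mat = np.zeros((n, n))
    df = pd.read_csv(path, sep="\t")
    i = ((df["bin1_start"] - meta["offset"]) // meta["bin_size"]).to_numpy().astype(int)
    j = ((df["bin2_start"] - meta["offset"]) // meta["bin_size"]).to_numpy().astype(int)
    mat[i, j] = df["count"].to_numpy()
    mat[j, i] = df["count"].to_numpy()
    cls = SignedMatrix if meta.get("signed") else ContactMatrix
    return cls(mat, meta["bin_size"], meta["chromosome"], meta["coordinate_system"], meta["offset"])


def write_counts(prefix, m: CountMatrix) -> None:
    """MatrixMarket MTX (cells x genes) + cell and gene TSV tables."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", csr_matrix(m.counts))
    m.cells[["cell_id", "genotype", "cluster", "depth"]].to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": m.genes}).to_csv(str(prefix) + ".genes.tsv", sep="\t", index=False)


def read_counts(prefix) -> CountMatrix:
    prefix = str(prefix)
    counts = np.asarray(mmread(prefix + ".mtx").todense()).astype(np.int64)
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene"].tolist()
    return CountMatrix(counts, cells[["cell_id", "genotype", "cluster"]], genes)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
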