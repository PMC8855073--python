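"""Reading and writing count matrices, metadata and result tables.

Counts are genes x samples. TSV carries gene ids in the first column and a
header of sample ids; MatrixMarket (.mtx) input expects ``<stem>.genes.txt``
and ``<stem>.samples.txt`` sidecars with one id per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse


def read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        mat = sio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        return pd.DataFrame(
            np.asarray(mat, dtype=np.int64),
            index=pd.Index(genes, name="gene_id"),
            columns=pd.Index(samples, name="sample_id"),
        )
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sio.mmwrite(str(path), sparse.csr_matrix(counts.to_numpy()))
    stem = path.with_suffix("")
    Path(f"{stem}.genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    Path(f"{stem}.samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    need = {"sample_id", "group"}
    if not need <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(need)}")
    return meta


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip parsing, so reloaded tables reproduce in-memory floats exactly
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    # repr writes the shortest digit string that round-trips a float64, so
    # tables reloaded from disk reproduce in-memory results exactly
    df.to_csv(
        path,
        sep="\t",
        index_label=index_label,
        lineterminator="\n",
        float_format=lambda x: repr(float(x)),
    )
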