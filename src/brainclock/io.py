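"""TSV reading/writing for expression/methylation matrices and sample tables.

Canonical dialect: tab-separated, UTF-8, header row of sample IDs, first
column the gene/probe ID, missing values spelled ``NA``. Gene IDs are opaque
strings; duplicates are an error. ``read_matrix(write_matrix(X)) == X``
bit-exact (Python float repr round-trips).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_samples", "write_samples", "write_results"]

NA_TOKEN = "NA"


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes/probes x samples matrix; strict validation.

    Errors (with the 1-based line number) on ragged rows and non-numeric
    cells other than ``NA``; errors on duplicated row IDs, naming the ID.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split(sep)[1:]
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(sep)
            if len(fields) != len(cols) + 1:
                raise ValueError(
                    f"{path} line {lineno}: expected {len(cols) + 1} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            vals = np.empty(len(cols))
            for j, tok in enumerate(fields[1:]):
                if tok == NA_TOKEN:
                    vals[j] = np.nan
                else:
                    try:
                        vals[j] = float(tok)
                    except ValueError:
                        raise ValueError(
                            f"{path} line {lineno}: non-numeric value {tok!r}"
                        ) from None
            rows.append(vals)
    index = pd.Index(ids, name="gene_id")
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated row IDs: {dup[:5]}")
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(cols))),
                        index=index, columns=cols)


def write_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join([matrix.index.name or "gene_id", *map(str, matrix.columns)]))
        fh.write("\n")
        arr = matrix.to_numpy()
        for gid, row in zip(matrix.index, arr):
            toks = [NA_TOKEN if isinstance(v, float) and np.isnan(v) else repr(float(v)) for v in row]
            fh.write(sep.join([str(gid), *toks]))
            fh.write("\n")


def read_samples(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample table (first column = sample ID)."""
    tab = pd.read_csv(path, sep=sep, index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if tab.index.has_duplicates:
        dup = tab.index[tab.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample IDs: {dup[:5]}")
    return tab


def write_samples(samples: pd.DataFrame, path, sep: str = "\t") -> None:
    samples.to_csv(path, sep=sep, na_rep=NA_TOKEN, index_label=samples.index.name or "sample_id")


def write_results(table: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    table.to_csv(path, sep=sep, na_rep=NA_TOKEN, index=index)
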