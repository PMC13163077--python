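"""Readers and writers for every external table the pipeline touches.

Formats: TSV count matrices (genes x samples, header = sample ids),
MatrixMarket ``.mtx`` with sidecar ``rows.txt``/``cols.txt``, design TSV,
GMT gene sets, and a two-column cell label TSV. All outputs are UTF-8 TSV
with a header and '.' decimal separator.
"""

from __future__ import annotations

import os

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .containers import (
    CountMatrix,
    GeneSetCollection,
    ReferenceMatrix,
    SampleDesign,
    ValidationError,
)


def read_counts(path: str, format: str | None = None, allow_rounding: bool = False) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket.

    For ``mtx``, row and column identifiers are read from ``<stem>.rows.txt``
    and ``<stem>.cols.txt`` next to the matrix file. Row and column order is
    preserved from the files.
    """
    if format is None:
        format = "mtx" if str(path).endswith(".mtx") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
    elif format == "mtx":
        stem = str(path)[: -len(".mtx")]
        rows = _read_id_file(stem + ".rows.txt")
        cols = _read_id_file(stem + ".cols.txt")
        mat = mmread(path)
        df = pd.DataFrame(
            mat.toarray() if hasattr(mat, "toarray") else mat, index=rows, columns=cols
        )
    else:
        raise ValueError(f"unknown counts format {format!r}")
    return CountMatrix(df, allow_rounding=allow_rounding)


def _read_id_file(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"identifier sidecar not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_counts(counts: CountMatrix, path: str, format: str | None = None) -> None:
    if format is None:
        format = "mtx" if str(path).endswith(".mtx") else "tsv"
    if format == "tsv":
        counts.counts.to_csv(path, sep="\t")
    elif format == "mtx":
        stem = str(path)[: -len(".mtx")]
        mmwrite(path, csr_matrix(counts.values()))
        for ids, suffix in ((counts.gene_ids, ".rows.txt"), (counts.sample_ids, ".cols.txt")):
            with open(stem + suffix, "w", encoding="utf-8") as fh:
                fh.write("\n".join(ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def read_design(path: str) -> SampleDesign:
    """Read a sample design TSV (sample_id, region, condition, side, subject)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file: term id, description, then tab-separated member genes.

    Duplicate members within one line are collapsed; lines with fewer than
    three fields raise a located error.
    """
    terms = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, term_name = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            terms.append((term_id, term_name, members))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, term_name, members in collection:
            fh.write("\t".join([term_id, term_name, *sorted(members)]) + "\n")


def read_reference(counts_path: str, labels_path: str) -> ReferenceMatrix:
    """Read a reference: counts file plus two-column cell_id -> label TSV."""
    counts = read_counts(counts_path)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if labels.shape[1] < 2:
        raise ValidationError("cell label file needs two columns: cell_id, cell_type")
    labels = labels.set_index(labels.columns[0])[labels.columns[1]]
    return ReferenceMatrix(counts.counts, labels)


def write_reference(reference: ReferenceMatrix, counts_path: str, labels_path: str) -> None:
    reference.counts.to_csv(counts_path, sep="\t")
    out = reference.cell_labels.rename("cell_type")
    out.index.name = "cell_id"
    out.to_csv(labels_path, sep="\t")
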