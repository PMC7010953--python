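"""Core data containers and readers for expression matrices and sample labels.

The canonical orientation is genes-as-rows, samples-as-columns (the L1000
convention). Values are arbitrary continuous expression units; no
normalisation is applied anywhere in the pipeline. Missing values are
rejected at load time rather than imputed, because imputation would silently
change downstream mutual-information estimates.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "ConfusionMatrix",
    "load_expression",
    "write_expression",
    "load_labels",
    "write_labels",
    "align_labels",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of continuous expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers, order preserved from the source.
    sample_ids : list of str
        Unique column identifiers, order preserved from the source.
    values : ndarray of shape (n_genes, n_samples)
        Finite floats; any NaN/inf is rejected on construction.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {vals.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.sample_ids)} samples"
            )
        if vals.size == 0:
            raise ValueError("empty expression matrix")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[rows])


@dataclass(frozen=True)
class LabelVector:
    """Binary class labels per sample; 1 = positive class (KRAS mutation +).

    The positive class is always explicit — never inferred from label order.
    """

    sample_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        lab = np.asarray(self.labels)
        if lab.ndim != 1 or len(lab) != len(self.sample_ids):
            raise ValueError("labels must be 1-D and match sample_ids length")
        if not np.isin(lab, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "labels", lab.astype(np.int64))
        _check_unique(self.sample_ids, "sample")
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("both classes must be present in a LabelVector")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts for a binary classification outcome."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    @property
    def n_positive(self) -> int:
        return self.TP + self.FN

    @property
    def n_negative(self) -> int:
        return self.TN + self.FP


# ---------------------------------------------------------------------------
# readers / writers


def _parse_delimited(text: str, sep: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValueError("empty expression matrix")
    return df


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        bad = out.isna().to_numpy()
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[g]!r}, sample {df.columns[s]!r}: "
            f"{df.iat[g, s]!r}"
        )
    return out


def _read_series_matrix(text: str) -> pd.DataFrame:
    """Extract the table between !series_matrix_table_begin/end markers."""
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip().lower().startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.strip().lower().startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError("no !series_matrix_table_begin/end block found") from None
    block = "\n".join(lines[start + 1 : end])
    df = _parse_delimited(block, "\t")
    # GEO quotes identifiers; strip surrounding quotes from ids only
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def load_expression(
    path: str | Path,
    format: str = "delimited",
    sep: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix from delimited text or a GEO series matrix.

    Parameters
    ----------
    path : path
        Input file. For ``format='delimited'`` the first column holds gene
        ids and the header row holds sample ids. For
        ``format='geo_series_matrix'`` only the table block between the
        ``!series_matrix_table_begin/end`` markers is read; metadata lines
        are ignored.
    sep : str, optional
        Field separator for the delimited format; inferred from the file
        extension (``.csv`` -> comma, otherwise tab) when omitted.
    transpose : bool
        Set when the file stores samples as rows; the canonical in-memory
        orientation is always genes x samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    text = path.read_text()
    if format == "delimited":
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = _parse_delimited(text, sep)
    elif format == "geo_series_matrix":
        df = _read_series_matrix(text)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if transpose:
        df = df.T
    df = _coerce_numeric(df)
    return ExpressionMatrix.from_dataframe(df)


def write_expression(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_dataframe().to_csv(path, sep=sep, index_label="gene_id")


def load_labels(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    sep: str = "\t",
) -> LabelVector:
    """Read labels from a two-column file (sample id, 0/1) or a list of
    positive sample ids (one per line; requires ``sample_ids`` for the
    universe of samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    rows = [l.split(sep) for l in path.read_text().splitlines() if l.strip()]
    if all(len(r) >= 2 for r in rows):
        ids = [r[0].strip() for r in rows]
        labels = []
        for r in rows:
            v = r[1].strip()
            if v not in {"0", "1"}:
                raise ValueError(f"label for sample {r[0]!r} must be 0 or 1, got {v!r}")
            labels.append(int(v))
        return LabelVector(tuple(ids), np.array(labels))
    if sample_ids is None:
        raise ValueError(
            "positive-id list format requires the full sample_ids universe"
        )
    positives = {r[0].strip() for r in rows}
    return LabelVector(
        tuple(sample_ids), np.array([1 if s in positives else 0 for s in sample_ids])
    )


def write_labels(l: LabelVector, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for s, y in zip(l.sample_ids, l.labels):
            fh.write(f"{s}{sep}{int(y)}\n")


def align_labels(m: ExpressionMatrix, l: LabelVector) -> LabelVector:
    """Reorder ``l`` to the matrix's sample order.

    Label entries for samples absent from the matrix are dropped with a
    warning; a matrix sample missing from ``l`` is a hard error.
    """
    lookup = {s: int(y) for s, y in zip(l.sample_ids, l.labels)}
    missing = [s for s in m.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples missing from label vector: {missing}")
    extra = [s for s in l.sample_ids if s not in set(m.sample_ids)]
    if extra:
        logger.warning("dropping %d labelled samples absent from matrix", len(extra))
    return LabelVector(m.sample_ids, np.array([lookup[s] for s in m.sample_ids]))
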