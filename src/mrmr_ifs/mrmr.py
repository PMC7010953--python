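"""First selection stage: discretization, mutual information, mRMR ranking.

Continuous expression is discretized per gene into three states (low /
medium / high) by mean +/- t * sd, the scheme of the classical C/C++ mRMR
software. All mutual information is the plug-in (maximum-likelihood)
estimate from empirical joint frequencies, in bits, with no small-sample
bias correction. The ranking objective is the difference (MID) form:
relevance I(g, t) minus the mean mutual information with already-selected
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, LabelVector

__all__ = [
    "DiscretizedMatrix",
    "RankedGeneList",
    "RankedGene",
    "discretize",
    "mutual_information",
    "relevance_all",
    "mrmr_rank",
]


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Per-gene three-state assignments (0=low, 1=medium, 2=high)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.states)
        if st.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match identifiers")
        if not np.isin(st, [0, 1, 2]).all():
            raise ValueError("states must be in {0, 1, 2}")
        object.__setattr__(self, "states", st.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class RankedGene:
    rank: int          # 1-based position in the ranking
    gene_id: str
    relevance: float   # I(g, t) in bits
    redundancy: float  # mean I(g, selected) in bits at selection time
    score: float       # relevance - redundancy at selection time


@dataclass(frozen=True)
class RankedGeneList:
    """The ordered mRMR ranking with per-gene relevance/redundancy scores."""

    entries: tuple[RankedGene, ...]

    def __post_init__(self) -> None:
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..N with no gaps")
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(e.gene_id for e in self.entries)

    def top(self, k: int) -> tuple[str, ...]:
        return self.gene_ids[:k]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "gene_id": e.gene_id,
                    "relevance_bits": e.relevance,
                    "redundancy_bits": e.redundancy,
                    "score": e.score,
                }
                for e in self.entries
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t")
        return cls(
            tuple(
                RankedGene(
                    int(r["rank"]),
                    str(r["gene_id"]),
                    float(r["relevance_bits"]),
                    float(r["redundancy_bits"]),
                    float(r["score"]),
                )
                for _, r in df.iterrows()
            )
        )


def discretize(m: ExpressionMatrix, threshold_sigma: float = 0.5) -> DiscretizedMatrix:
    """Map each gene's values to three states around its own mean.

    Values below mean - t*sd become state 0, above mean + t*sd state 2,
    else state 1. A zero-variance gene maps entirely to the medium state.
    The mapping is invariant to positive affine transforms of a gene row.
    """
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be positive")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd; scale-free either way
    nz = (sd > 0).ravel()
    lo = mean - threshold_sigma * sd
    hi = mean + threshold_sigma * sd
    states = np.where(vals < lo, 0, np.where(vals > hi, 2, 1))
    states[~nz, :] = 1  # zero-variance genes are all-medium
    return DiscretizedMatrix(m.gene_ids, m.sample_ids, states)


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Uses the empirical joint distribution with the 0*log(0) = 0 convention;
    symmetric and non-negative by construction.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint[None, :, :])[0]


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits from a stack of joint count tables, shape (G, nx, ny)."""
    n = joint.sum(axis=(1, 2), keepdims=True).astype(float)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    terms = np.where(joint > 0, terms, 0.0)
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def _mi_rows_vs_vector(states: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI of every row of a 3-state matrix with one discrete vector (bits)."""
    y = np.asarray(y)
    _, yi = np.unique(y, return_inverse=True)
    ny = yi.max() + 1
    codes = states * ny + yi[None, :]
    ncodes = 3 * ny
    G = states.shape[0]
    joint = np.empty((G, 3, ny), dtype=np.int64)
    flat = joint.reshape(G, ncodes)
    for c in range(ncodes):
        flat[:, c] = (codes == c).sum(axis=1)
    return _mi_from_joint(joint)


def relevance_all(d: DiscretizedMatrix, l: LabelVector) -> dict[str, float]:
    """Relevance D = I(gene states, class label) for every gene, in bits."""
    if d.sample_ids != l.sample_ids:
        raise ValueError("discretized matrix and labels are not sample-aligned")
    mi = _mi_rows_vs_vector(d.states, l.labels)
    return {g: float(v) for g, v in zip(d.gene_ids, mi)}


def mrmr_rank(
    d: DiscretizedMatrix,
    l: LabelVector,
    top_n: int = 200,
) -> RankedGeneList:
    """Greedy minimal-redundancy maximal-relevance forward ranking.

    Rank 1 is the gene with maximal relevance D (redundancy taken as 0 when
    nothing is selected). Each later step selects the candidate maximizing
    D(g) - mean_{selected} I(g, g_i). Ties break toward the lowest input
    gene index, so the ranking is deterministic and order-stable; scores
    within 1e-10 of the step maximum count as tied, so that mathematically
    equal candidates (e.g. exact duplicates) are not split by float
    round-off. Stops after min(top_n, n_genes) ranks.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if d.n_genes < 2:
        raise ValueError("need at least 2 genes to rank")
    if d.sample_ids != l.sample_ids:
        raise ValueError("discretized matrix and labels are not sample-aligned")

    G = d.n_genes
    n_ranks = min(top_n, G)
    relevance = _mi_rows_vs_vector(d.states, l.labels)

    selected: list[int] = []
    remaining = np.ones(G, dtype=bool)
    mi_sum = np.zeros(G)  # sum of MI with selected genes, per candidate
    entries: list[RankedGene] = []

    for step in range(n_ranks):
        if step == 0:
            score = np.where(remaining, relevance, -np.inf)
            red = np.zeros(G)
        else:
            red = mi_sum / len(selected)
            score = np.where(remaining, relevance - red, -np.inf)
        j = int(np.argmax(score >= score.max() - 1e-10))  # first near-max: lowest index wins ties
        entries.append(
            RankedGene(
                rank=step + 1,
                gene_id=d.gene_ids[j],
                relevance=float(relevance[j]),
                redundancy=float(red[j]),
                score=float(score[j]),
            )
        )
        selected.append(j)
        remaining[j] = False
        if step + 1 < n_ranks:
            mi_sum += _mi_rows_vs_vector(d.states, d.states[j])
    return RankedGeneList(tuple(entries))
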