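"""Second selection stage: incremental feature selection (IFS).

For each classifier family, LOOCV is run on the top-1, top-2, ..., top-k
prefixes of the mRMR ranking (continuous expression values — discretization
exists only inside the mRMR stage) and the per-prefix metrics form the IFS
curve. The curve's MCC peak defines the selected biomarker panel; ties
break toward the smaller prefix (parsimony).

kNN families use a vectorised LOOCV that reuses pairwise squared distances
across prefixes (the prefix-k distance matrix is the prefix-(k-1) matrix
plus the new feature's squared differences); this is numerically the same
euclidean kNN vote as naive per-fold retraining. Per-(family, k) records
can be checkpointed to a TSV so an interrupted build resumes identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec
from .data import ConfusionMatrix, ExpressionMatrix, LabelVector
from .evaluation import (
    MetricSet,
    confusion_from_predictions,
    knn_loocv_predictions,
    loocv,
    metrics,
)
from .mrmr import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = ["IFSRecord", "IFSCurve", "PeakSelection", "build_curve",
           "find_peak", "select_best", "plot_curve"]

_KNN_K = {"1NN": 1, "3NN": 3, "5NN": 5}


@dataclass(frozen=True)
class IFSRecord:
    family: str
    k: int
    metric_set: MetricSet


@dataclass(frozen=True)
class PeakSelection:
    """The best prefix for one family: its size, MCC and gene panel."""

    family: str
    k_star: int
    mcc_star: float
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.k_star:
            raise ValueError("gene panel length must equal k_star")


@dataclass(frozen=True)
class IFSCurve:
    """Per-(family, prefix-size) LOOCV metric records plus the ranking used."""

    records: tuple[IFSRecord, ...]
    gene_order: RankedGeneList

    def __post_init__(self) -> None:
        for fam in self.families:
            ks = sorted(r.k for r in self.records if r.family == fam)
            if ks != list(range(1, len(ks) + 1)):
                raise ValueError(f"prefix sizes for {fam} must run 1..max with no gaps")

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.records:
            if r.family not in seen:
                seen.append(r.family)
        return tuple(seen)

    def family_records(self, family: str) -> list[IFSRecord]:
        recs = [r for r in self.records if r.family == family]
        if not recs:
            raise KeyError(f"no records for family {family!r}")
        return sorted(recs, key=lambda r: r.k)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            c = r.metric_set.source
            rows.append(
                {
                    "family": r.family, "k": r.k,
                    "TP": c.TP, "FN": c.FN, "FP": c.FP, "TN": c.TN,
                    "Sn": r.metric_set.Sn, "Sp": r.metric_set.Sp,
                    "ACC": r.metric_set.ACC, "MCC": r.metric_set.MCC,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _record_from_counts(family: str, k: int, tp: int, fn: int, fp: int, tn: int
                        ) -> IFSRecord:
    return IFSRecord(family, k, metrics(ConfusionMatrix(tp, fn, fp, tn)))


def _load_checkpoint(path: Path) -> dict[tuple[str, int], IFSRecord]:
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        rec = _record_from_counts(str(r["family"]), int(r["k"]),
                                  int(r["TP"]), int(r["FN"]),
                                  int(r["FP"]), int(r["TN"]))
        out[(rec.family, rec.k)] = rec
    return out


def _append_checkpoint(path: Path, rec: IFSRecord) -> None:
    c = rec.metric_set.source
    header = not path.exists()
    with open(path, "a") as fh:
        if header:
            fh.write("family\tk\tTP\tFN\tFP\tTN\n")
        fh.write(f"{rec.family}\t{rec.k}\t{c.TP}\t{c.FN}\t{c.FP}\t{c.TN}\n")


def build_curve(
    ranked: RankedGeneList,
    X: ExpressionMatrix,
    y: LabelVector,
    families: Sequence[ClassifierSpec],
    max_k: int = 200,
    checkpoint: str | Path | None = None,
) -> IFSCurve:
    """LOOCV metrics for every (family, top-k prefix), k = 1..max_k.

    ``max_k`` is capped at the ranking length. All ranked genes must be
    present in the matrix. With ``checkpoint`` set, completed records are
    appended to a TSV and reused on resume; a resumed build is identical to
    a fresh one because every record is a deterministic function of its
    (family, prefix) inputs.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    max_k = min(max_k, len(ranked))
    genes = ranked.top(max_k)
    sub = X.subset_genes(genes)  # raises naming any missing gene
    if X.sample_ids != y.sample_ids:
        raise ValueError("matrix and labels are not sample-aligned")
    feat = sub.values.T  # samples x features, ranked order
    labels = y.labels
    n = feat.shape[0]

    ckpt = Path(checkpoint) if checkpoint is not None else None
    done = _load_checkpoint(ckpt) if ckpt else {}

    records: list[IFSRecord] = []
    for spec in families:
        fam = spec.family
        knn_k = _KNN_K.get(fam)
        d2 = np.zeros((n, n)) if knn_k is not None else None
        for k in range(1, max_k + 1):
            if d2 is not None:
                f = feat[:, k - 1]
                d2 += (f[:, None] - f[None, :]) ** 2
            if (fam, k) in done:
                records.append(done[(fam, k)])
                continue
            if knn_k is not None:
                preds = knn_loocv_predictions(None, labels, knn_k, d2=d2)
                cm = confusion_from_predictions(labels, preds)
            else:
                cm = loocv(spec, feat[:, :k], labels)
            rec = IFSRecord(fam, k, metrics(cm))
            records.append(rec)
            if ckpt:
                _append_checkpoint(ckpt, rec)
        logger.info("IFS: family %s done (%d prefixes)", fam, max_k)
    return IFSCurve(tuple(records), ranked)


def find_peak(curve: IFSCurve, family: str) -> PeakSelection:
    """The MCC-maximising prefix for one family; ties go to smaller k."""
    recs = curve.family_records(family)
    best = max(recs, key=lambda r: (r.metric_set.MCC, -r.k))
    return PeakSelection(
        family=family,
        k_star=best.k,
        mcc_star=best.metric_set.MCC,
        gene_ids=curve.gene_order.top(best.k),
    )


def select_best(curve: IFSCurve) -> PeakSelection:
    """The best peak across families.

    Ties break by smaller k_star, then by family declaration order in the
    curve.
    """
    fams = curve.families
    if not fams:
        raise ValueError("empty IFS curve")
    peaks = [find_peak(curve, f) for f in fams]
    order = {f: i for i, f in enumerate(fams)}
    return min(peaks, key=lambda p: (-p.mcc_star, p.k_star, order[p.family]))


def plot_curve(curve: IFSCurve, path: str | Path | None = None, ax=None):
    """Plot prefix size against LOOCV MCC, one line per family."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for fam in curve.families:
        recs = curve.family_records(fam)
        peak = find_peak(curve, fam)
        ax.plot([r.k for r in recs], [r.metric_set.MCC for r in recs],
                label=f"{fam} (peak {peak.mcc_star:.3f} @ {peak.k_star})")
    ax.set_xlabel("number of top-ranked genes")
    ax.set_ylabel("LOOCV MCC")
    ax.legend(fontsize=8)
    ax.set_title("IFS curves")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
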