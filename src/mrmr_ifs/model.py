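"""Model/results surface for the two-stage biomarker selection procedure.

:class:`MrmrIfs` is constructed from an expression matrix and a binary
label vector; :meth:`MrmrIfs.fit` runs discretization, mRMR ranking and the
IFS sweep, returning a :class:`MrmrIfsResults` with the ranked list, the
per-family IFS curves, each family's peak and the overall best panel, plus
a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .classifiers import FAMILIES, ClassifierSpec, default_specs
from .data import ExpressionMatrix, LabelVector, align_labels
from .ifs import IFSCurve, PeakSelection, build_curve, find_peak, plot_curve, select_best
from .mrmr import DiscretizedMatrix, RankedGeneList, discretize, mrmr_rank

__all__ = ["MrmrIfs", "MrmrIfsResults"]


class MrmrIfs:
    """Two-stage gene panel selection: mRMR ranking, then IFS under LOOCV.

    Parameters
    ----------
    exog : ExpressionMatrix
        Genes x samples continuous expression.
    endog : LabelVector
        Binary class per sample (1 = positive class); reordered to the
        matrix's sample order if needed.
    families : sequence of ClassifierSpec, optional
        Classifier families for the IFS stage; defaults to all six
        (SVM, 1NN, 3NN, 5NN, decision tree, neural net).
    top_n : int
        Genes kept from the mRMR stage (default 200).
    max_k : int, optional
        Largest IFS prefix; defaults to ``top_n``, capped at the ranking
        length.
    threshold_sigma : float
        Discretization threshold in per-gene sd units (default 0.5).
    seed : int
        Seed recorded into default classifier specs.
    """

    def __init__(
        self,
        exog: ExpressionMatrix,
        endog: LabelVector,
        families: Sequence[ClassifierSpec] | None = None,
        top_n: int = 200,
        max_k: int | None = None,
        threshold_sigma: float = 0.5,
        seed: int = 0,
    ) -> None:
        self.exog = exog
        self.endog = align_labels(exog, endog)
        self.families = list(families) if families is not None else default_specs(seed)
        self.top_n = top_n
        self.max_k = max_k if max_k is not None else top_n
        self.threshold_sigma = threshold_sigma
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        labels: Sequence[int] | pd.Series,
        genes_as_rows: bool = True,
        **kwargs,
    ) -> "MrmrIfs":
        """Build from a pandas DataFrame (index = gene ids, columns =
        sample ids when ``genes_as_rows``) and a label sequence aligned to
        the samples."""
        if not genes_as_rows:
            data = data.T
        exog = ExpressionMatrix.from_dataframe(data)
        if isinstance(labels, pd.Series):
            endog = LabelVector(tuple(map(str, labels.index)), labels.to_numpy())
        else:
            endog = LabelVector(exog.sample_ids, labels)
        return cls(exog, endog, **kwargs)

    def rank(self) -> RankedGeneList:
        """Stage one only: discretize and run the greedy mRMR ranking."""
        disc = discretize(self.exog, self.threshold_sigma)
        return mrmr_rank(disc, self.endog, top_n=self.top_n)

    def fit(self, checkpoint=None) -> "MrmrIfsResults":
        """Run both stages and return the results object."""
        ranking = self.rank()
        curve = build_curve(
            ranking, self.exog, self.endog, self.families,
            max_k=min(self.max_k, len(ranking)), checkpoint=checkpoint,
        )
        return MrmrIfsResults(self, ranking, curve)


class MrmrIfsResults:
    """Fitted two-stage selection: ranking, IFS curves, peaks, best panel."""

    def __init__(self, model: MrmrIfs, ranking: RankedGeneList, curve: IFSCurve):
        self.model = model
        self.ranking = ranking
        self.curve = curve
        self.peaks: dict[str, PeakSelection] = {
            f: find_peak(curve, f) for f in curve.families
        }
        self.best: PeakSelection = select_best(curve)

    @property
    def selected_genes(self) -> tuple[str, ...]:
        """The winning panel: the best family's peak prefix."""
        return self.best.gene_ids

    def peak_table(self) -> pd.DataFrame:
        rows = []
        for fam, p in self.peaks.items():
            rec = next(r for r in self.curve.family_records(fam) if r.k == p.k_star)
            rows.append(
                {"family": fam, "k_star": p.k_star,
                 **rec.metric_set.rounded()}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_pos = self.model.endog.n_positive
        n_neg = self.model.endog.n_negative
        lines = [
            "Two-stage biomarker selection (mRMR + IFS, LOOCV)",
            "=" * 58,
            f"Samples: {n_pos + n_neg}  (positive {n_pos}, negative {n_neg})",
            f"Genes: {self.model.exog.n_genes}; ranked (mRMR): {len(self.ranking)}; "
            f"IFS prefixes: 1..{max(r.k for r in self.curve.records)}",
            "",
            "Per-family IFS peaks",
            "-" * 58,
            self.peak_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "-" * 58,
            f"Best: {self.best.family} with {self.best.k_star} genes, "
            f"LOOCV MCC = {self.best.mcc_star:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, path=None, ax=None):
        """IFS curves: prefix size vs LOOCV MCC per family."""
        return plot_curve(self.curve, path=path, ax=ax)
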