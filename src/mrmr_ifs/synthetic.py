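"""Synthetic expression data with the structure the two-stage analysis assumes.

The generator emulates an L1000-style landmark matrix with a rare positive
class: by default 978 genes by 156 positive + 3582 negative samples (~4%
prevalence, the study scale), a handful of class-informative genes whose
means shift between classes, and blocks of redundant genes correlated with
an informative parent. Everything is Gaussian per gene — the minimal model
that exercises discretization, mutual information and the redundancy term;
it does not attempt bead-array technical artifacts or perturbation
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ExpressionMatrix, LabelVector

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "write_ground_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated study.

    effect_size is the between-class mean shift of informative genes in
    units of the per-gene noise sd. block_correlation is the target Pearson
    correlation of each redundant gene with its parent informative gene.
    """

    n_genes: int = 978
    n_pos: int = 156
    n_neg: int = 3582
    n_informative: int = 10
    effect_size: float = 2.0
    n_redundant_blocks: int = 0
    block_size: int = 1
    block_correlation: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_pos, self.n_neg) < 1:
            raise ValueError("gene and per-class sample counts must be >= 1")
        if self.n_informative < 0 or self.n_redundant_blocks < 0:
            raise ValueError("counts must be non-negative")
        if self.n_redundant_blocks > self.n_informative:
            raise ValueError("each redundant block needs its own informative parent")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_redundant = self.n_redundant_blocks * self.block_size
        if self.n_informative + n_redundant > self.n_genes:
            raise ValueError(
                f"gene budget infeasible: {self.n_informative} informative + "
                f"{n_redundant} redundant > {self.n_genes} genes"
            )

    @property
    def n_samples(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class GroundTruth:
    """Which generated genes carry signal, and redundancy parentage."""

    informative: tuple[str, ...]
    redundant: tuple[str, ...]
    parents: dict[str, str] = field(default_factory=dict)  # redundant -> parent


def generate(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, LabelVector, GroundTruth]:
    """Draw one synthetic dataset; bit-reproducible under cfg.seed.

    Informative genes are Normal(0, noise_sd) in negatives and
    Normal(effect_size * noise_sd, noise_sd) in positives. Noise genes are
    Normal(0, noise_sd) regardless of class. Each redundant gene is its
    parent's values plus Gaussian noise whose sd is calibrated from the
    parent's empirical variance so that the population correlation equals
    block_correlation.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i + 1:0{len(str(n))}d}" for i in range(n)]
    labels = np.concatenate([np.ones(cfg.n_pos, int), np.zeros(cfg.n_neg, int)])

    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    informative = gene_ids[: cfg.n_informative]
    values[: cfg.n_informative, labels == 1] += cfg.effect_size * cfg.noise_sd

    redundant: list[str] = []
    parents: dict[str, str] = {}
    r = cfg.block_correlation
    pos = cfg.n_informative
    for b in range(cfg.n_redundant_blocks):
        parent_idx = b
        base = values[parent_idx]
        v = base.var()
        extra_sd = np.sqrt(v * (1.0 / r**2 - 1.0)) if r > 0 else np.inf
        for _ in range(cfg.block_size):
            if r > 0:
                values[pos] = base + rng.normal(0.0, extra_sd, size=n)
            else:
                values[pos] = rng.normal(0.0, cfg.noise_sd, size=n)
            redundant.append(gene_ids[pos])
            parents[gene_ids[pos]] = gene_ids[parent_idx]
            pos += 1

    m = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    l = LabelVector(tuple(sample_ids), labels)
    truth = GroundTruth(tuple(informative), tuple(redundant), parents)
    return m, l, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar file mapping gene id to its generative role."""
    payload = {
        "informative": list(truth.informative),
        "redundant": list(truth.redundant),
        "parents": dict(truth.parents),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
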