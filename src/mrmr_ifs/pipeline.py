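"""End-to-end pipeline runs driven by a single YAML config, with a manifest.

A run loads (or simulates) an expression matrix and labels, ranks genes by
mRMR, sweeps IFS prefixes, and writes the full artifact set: ranked-list
TSV, IFS curve TSV, curve plot, final report, and a JSON run manifest with
config snapshot, seeds, input checksums, per-stage timings and output
checksums. Deterministic stages reproduce their checksums when rerun with
the manifest's config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .classifiers import FAMILIES, ClassifierSpec
from .data import align_labels, load_expression, load_labels, write_expression, write_labels
from .ifs import plot_curve
from .model import MrmrIfs
from .synthetic import SyntheticConfig, generate, write_ground_truth

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run", "load_config"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str = __version__
    seeds: dict[str, int] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    status: str = "incomplete"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "input" not in cfg and "synthetic" not in cfg:
        raise ValueError("config needs an 'input' or a 'synthetic' block")
    return cfg


def _families_from_config(cfg: dict[str, Any], seed: int) -> list[ClassifierSpec]:
    ifs_cfg = cfg.get("ifs", {})
    fams = ifs_cfg.get("families", list(FAMILIES))
    specs = []
    for f in fams:
        if isinstance(f, str):
            specs.append(ClassifierSpec(f, seed=seed))
        else:
            d = dict(f)
            d.setdefault("seed", seed)
            specs.append(ClassifierSpec.from_dict(d))
    return specs


def run(config_path: str | Path, output_dir: str | Path | None = None) -> RunManifest:
    """Execute a full rank -> IFS -> report run from a config file."""
    cfg = load_config(config_path)
    out = Path(output_dir or cfg.get("output_dir", "mrmr_ifs_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config=cfg, seeds={"master": seed})
    manifest_path = out / "manifest.json"

    def stage(name: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.timings_s[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    manifest.status = f"failed at stage {name}: {exc}"
                    manifest.write(manifest_path)
                    logger.error("stage %s: failed (%s)", name, exc)
                return False

        return _T()

    with stage("load"):
        if "synthetic" in cfg:
            scfg = SyntheticConfig(**{**cfg["synthetic"], "seed": seed})
            X, y, truth = generate(scfg)
            write_expression(X, out / "expression.tsv")
            write_labels(y, out / "labels.tsv")
            write_ground_truth(truth, out / "ground_truth.json")
        else:
            inp = cfg["input"]
            expr_path = Path(inp["expression"])
            label_path = Path(inp["labels"])
            X = load_expression(
                expr_path,
                format=inp.get("format", "delimited"),
                transpose=bool(inp.get("transpose", False)),
            )
            y = align_labels(X, load_labels(label_path, sample_ids=X.sample_ids))
            manifest.input_checksums[str(expr_path)] = _sha256(expr_path)
            manifest.input_checksums[str(label_path)] = _sha256(label_path)

    mrmr_cfg = cfg.get("mrmr", {})
    ifs_cfg = cfg.get("ifs", {})
    model = MrmrIfs(
        X, y,
        families=_families_from_config(cfg, seed),
        top_n=int(mrmr_cfg.get("top_n", 200)),
        max_k=int(ifs_cfg["max_k"]) if "max_k" in ifs_cfg else None,
        threshold_sigma=float(mrmr_cfg.get("threshold_sigma", 0.5)),
        seed=seed,
    )

    with stage("mrmr"):
        ranking = model.rank()
        ranking.write_tsv(out / "ranked_genes.tsv")

    with stage("ifs"):
        from .ifs import build_curve

        curve = build_curve(
            ranking, model.exog, model.endog, model.families,
            max_k=min(model.max_k, len(ranking)),
            checkpoint=out / "ifs_checkpoint.tsv" if ifs_cfg.get("checkpoint") else None,
        )
        curve.write_tsv(out / "ifs_curve.tsv")
        plot_curve(curve, path=out / "ifs_curve.png")

    with stage("report"):
        from .model import MrmrIfsResults

        results = MrmrIfsResults(model, ranking, curve)
        (out / "report.txt").write_text(results.summary() + "\n")
        panel = results.best
        (out / "selected_panel.tsv").write_text(
            "rank\tgene_id\n"
            + "".join(f"{i + 1}\t{g}\n" for i, g in enumerate(panel.gene_ids))
        )

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    manifest.status = "complete"
    manifest.write(manifest_path)
    return manifest
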