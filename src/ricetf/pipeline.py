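"""End-to-end pipeline runner.

Ties the analysis stages — tissue specificity, stress-response calling,
closest-paralog extraction, dominance summary, co-expression — into one
configured run with versioned, re-derivable outputs.  Configuration is a
plain mapping (the CLI loads it from TOML); every stage is optional and runs
only when its section is present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .coexpression import CoexpressionNetworkBuilder
from .io import aggregate_by_group, read_expression_table
from .phylo import assign_paralogs, read_trees
from .redundancy import (
    ParalogDominanceClassifier,
    summarize_characterized,
)
from .specificity import TissueSpecificityClassifier, calls_to_frame
from .stress import StressResponseCaller
from .synthetic import make_characterized_fixture

log = logging.getLogger("ricetf")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _require_path(stage: str, path: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"path does not exist: {p}")
    return p


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write per-stage outputs.

    Returns a machine-readable run report: package version, config hash,
    thresholds used, per-stage output counts.  Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir or config.get("output_dir", "ricetf_out"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "stages": {},
    }

    if "specificity" in config:
        cfg = dict(config["specificity"])
        matrix = read_expression_table(
            _require_path("specificity", cfg.pop("matrix")),
            _require_path("specificity", cfg.pop("meta")),
            scale=cfg.pop("scale", "log2_intensity"),
        )
        profiles = aggregate_by_group(matrix).values
        est = TissueSpecificityClassifier(
            **{k: v for k, v in cfg.items() if k != "out"}
        ).fit(profiles)
        frame = calls_to_frame(est.calls_)
        dest = out / "specificity_calls.tsv"
        frame.to_csv(dest, sep="\t", index=False)
        counts = frame["label"].str.split(":").str[0].value_counts().to_dict()
        log.info("specificity: cutoffs %.2f/%.2f, %d genes",
                 est.ubiquitous_cutoff, est.preferential_cutoff, len(frame))
        report["stages"]["specificity"] = {"out": str(dest), "label_counts": counts}

    if "stress" in config:
        cfg = dict(config["stress"])
        fc = pd.read_csv(_require_path("stress", cfg.pop("fc")), sep="\t", index_col=0)
        groups_df = pd.read_csv(_require_path("stress", cfg.pop("groups")), sep="\t")
        groups = dict(zip(groups_df["experiment"], groups_df["condition"]))
        est = StressResponseCaller(
            alpha=cfg.get("alpha", 0.05),
            log2fc_threshold=cfg.get("log2fc_threshold", 1.0),
            bh_correct=cfg.get("bh_correct", False),
        ).fit(fc, condition_groups=groups)
        dest = out / "response_calls.tsv"
        est.calls_.to_csv(dest, sep="\t", index=False)
        log.info("stress: alpha=%s log2fc=%s, %d responsive calls",
                 est.alpha, est.log2fc_threshold, len(est.responsive_))
        report["stages"]["stress"] = {
            "out": str(dest),
            "n_responsive": int(len(est.responsive_)),
        }

    if "paralogs" in config:
        cfg = dict(config["paralogs"])
        trees = read_trees(_require_path("paralogs", cfg.pop("trees")))
        assignments = assign_paralogs(trees, max_distance=cfg.get("max_distance"))
        frame = pd.DataFrame([dataclasses.asdict(a) for a in assignments])
        dest = out / "paralog_pairs.tsv"
        frame.to_csv(dest, sep="\t", index=False)
        report["stages"]["paralogs"] = {
            "out": str(dest),
            "n_singletons": int(frame["singleton"].sum()),
        }

    if "redundancy" in config:
        cfg = dict(config["redundancy"])
        threshold = cfg.get("threshold", 0.5)
        if cfg.get("use_fixture", True):
            cset, _trees, _matrix = make_characterized_fixture()
        else:
            raise PipelineError(
                "redundancy",
                "only the packaged characterized fixture is wired into `run`; "
                "use the `redundancy` subcommand for custom matrices",
            )
        summary = summarize_characterized(cset, threshold=threshold)
        dest = out / "dominance_summary.json"
        dest.write_text(json.dumps(dataclasses.asdict(summary), indent=2))
        log.info("redundancy: threshold %.2f, %.1f%% predominant",
                 threshold, summary.pct_predominant)
        report["stages"]["redundancy"] = dataclasses.asdict(summary)

    if "coexpression" in config:
        cfg = dict(config["coexpression"])
        matrix = read_expression_table(
            _require_path("coexpression", cfg.pop("matrix")),
            _require_path("coexpression", cfg.pop("meta")),
            scale=cfg.pop("scale", "log2_intensity"),
        )
        builder = CoexpressionNetworkBuilder(
            min_pcc=cfg.get("min_pcc", 0.75), top_k=cfg.get("top_k", 50)
        ).fit(matrix.values)
        net = builder.network(cfg["query"])
        dest = out / "coexpression_network.json"
        dest.write_text(
            json.dumps(
                {
                    "query": net.query,
                    "neighbors": net.neighbors,
                    "edges": net.edges,
                    "terms": net.terms,
                },
                indent=2,
            )
        )
        report["stages"]["coexpression"] = {
            "out": str(dest),
            "n_neighbors": len(net.neighbors),
        }

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
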