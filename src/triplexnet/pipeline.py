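"""End-to-end orchestration and count bookkeeping.

``run_pipeline`` chains preprocess -> per-target streamwise fits -> network
assembly -> typed clique mining -> survival/stage annotation -> count
summary, writing every artifact plus a JSON manifest.  ``summarize_counts``
reproduces the per-biotype bookkeeping of the analysis: how many transcripts
were measured, how many entered the network, how many sit in triplets, and
the derived percentages.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .containers import BIOTYPES, ClinicalTable, ExpressionMatrix
from .preprocess import preprocess
from .vif_net import VifParams, build_network, fit_all_targets
from .clique_mine import (enumerate_typed_fourcliques, enumerate_typed_triplets,
                          write_fourcliques_tsv, write_triplets_tsv)
from .assoc_stats import annotate_triplets

logger = logging.getLogger(__name__)


@dataclass
class CountSummary:
    """Per-biotype transcript bookkeeping with derived percentages.

    ``pct_network`` is 100 * network / expression (share of measured
    transcripts that entered the network); ``pct_triplet`` is
    100 * triplet / network (share of network transcripts that function
    through clique structures).  Percentages are stored at full precision;
    ``display`` rounds to one decimal, or two when the value is below 10.
    """

    expression: dict[str, int]
    network: dict[str, int]
    triplet: dict[str, int]
    pct_network: dict[str, float] = field(default_factory=dict)
    pct_triplet: dict[str, float] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        return {
            "expression": sum(self.expression.values()),
            "network": sum(self.network.values()),
            "triplet": sum(self.triplet.values()),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bt in BIOTYPES:
            rows.append({
                "biotype": bt,
                "n_expression": self.expression[bt],
                "n_network": self.network[bt],
                "n_triplet": self.triplet[bt],
                "pct_network": self.pct_network.get(bt, float("nan")),
                "pct_triplet": self.pct_triplet.get(bt, float("nan")),
            })
        t = self.totals
        rows.append({"biotype": "total", "n_expression": t["expression"],
                     "n_network": t["network"], "n_triplet": t["triplet"],
                     "pct_network": float("nan"), "pct_triplet": float("nan")})
        return pd.DataFrame(rows)

    @staticmethod
    def display(pct: float) -> str:
        if not np.isfinite(pct):
            return "NA"
        return f"{pct:.2f}" if pct < 10 else f"{pct:.1f}"


def summarize_counts(expression_counts: dict[str, int], network_counts: dict[str, int],
                     triplet_counts: dict[str, int]) -> CountSummary:
    """Derive the per-biotype percentage bookkeeping from raw counts.

    Requires triplet <= network <= expression per biotype; a zero
    denominator yields a missing (NaN) percentage.
    """
    for bt in BIOTYPES:
        e = int(expression_counts.get(bt, 0))
        n = int(network_counts.get(bt, 0))
        t = int(triplet_counts.get(bt, 0))
        if min(e, n, t) < 0:
            raise ValueError(f"{bt}: counts must be non-negative")
        if not t <= n <= e:
            raise ValueError(f"{bt}: need triplet <= network <= expression, got {t}/{n}/{e}")
    summary = CountSummary(
        expression={bt: int(expression_counts.get(bt, 0)) for bt in BIOTYPES},
        network={bt: int(network_counts.get(bt, 0)) for bt in BIOTYPES},
        triplet={bt: int(triplet_counts.get(bt, 0)) for bt in BIOTYPES},
    )
    for bt in BIOTYPES:
        e, n, t = summary.expression[bt], summary.network[bt], summary.triplet[bt]
        summary.pct_network[bt] = 100.0 * n / e if e else float("nan")
        summary.pct_triplet[bt] = 100.0 * t / n if n else float("nan")
    return summary


@dataclass
class RunConfig:
    """Inputs, parameters and outputs for one full pipeline run."""

    expression_path: str
    annotation_path: str
    output_dir: str
    clinical_path: Optional[str] = None
    vif: VifParams = field(default_factory=VifParams)
    clique_sizes: tuple[int, ...] = (3, 4)
    stage_rule: str = "all"
    cox_coding: str = "continuous"
    zero_policy: str = "per_transcript"
    seed: int = 0
    km_plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        vif = VifParams(**raw.pop("vif", {}))
        if "clique_sizes" in raw:
            raw["clique_sizes"] = tuple(raw["clique_sizes"])
        return cls(vif=vif, **raw)

    def validate(self) -> None:
        for name in ("expression_path", "annotation_path", "clinical_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if set(self.clique_sizes) - {3, 4}:
            raise ValueError("clique_sizes may only contain 3 and 4")
        self.vif.validate()


def _biotype_triplet_counts(triplets) -> dict[str, int]:
    per_bt = {"mRNA": set(), "lncRNA": set(), "miRNA": set()}
    for t in triplets:
        per_bt["mRNA"].add(t.mrna_id)
        per_bt["lncRNA"].add(t.lncrna_id)
        per_bt["miRNA"].add(t.mirna_id)
    return {bt: len(v) for bt, v in per_bt.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest.

    Stage failures abort with the stage name; artifacts of completed stages
    are left in place.  Deterministic given the config seed.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": asdict(config.vif),
        "stages": [],
        "counts": {},
    }

    stage = "load"
    try:
        expr = ExpressionMatrix.from_tsv(config.expression_path, config.annotation_path)
        clinical = None
        if config.clinical_path is not None:
            clinical = ClinicalTable.from_tsv(config.clinical_path)

        stage = "preprocess"
        logged = preprocess(expr, zero_policy=config.zero_policy)
        logged.to_tsv(outdir / "expression.log2.tsv", outdir / "annotation.filtered.tsv")
        manifest["counts"]["expression"] = logged.biotype_counts()
        manifest["stages"].append(stage)

        stage = "regression"
        models = fit_all_targets(logged, config.vif, config.seed)
        kept = sum(1 for m in models if m.adj_r2 > config.vif.r2_threshold)
        manifest["counts"]["models_fitted"] = len(models)
        manifest["counts"]["models_kept"] = kept
        manifest["stages"].append(stage)

        stage = "network"
        net = build_network(models, logged, config.vif)
        net.write_edge_tsv(outdir / "network.tsv")
        net.write_graphml(outdir / "network.graphml")
        manifest["counts"]["network"] = net.biotype_counts()
        manifest["counts"]["n_edges"] = net.n_edges
        manifest["stages"].append(stage)

        stage = "cliques"
        triplets = enumerate_typed_triplets(net) if 3 in config.clique_sizes else []
        if 3 in config.clique_sizes:
            write_triplets_tsv(triplets, outdir / "triplets.tsv")
            manifest["counts"]["n_triplets"] = len(triplets)
        if 4 in config.clique_sizes:
            fours = enumerate_typed_fourcliques(net)
            write_fourcliques_tsv(fours, outdir / "fourcliques.tsv")
            manifest["counts"]["n_fourcliques"] = len(fours)
        manifest["stages"].append(stage)

        if clinical is not None and triplets:
            stage = "annotate"
            flags = annotate_triplets(triplets, logged, clinical,
                                      stage_rule=config.stage_rule,
                                      coding=config.cox_coding)
            flags.to_csv(outdir / "triplets.annotated.tsv", sep="\t", index=False)
            manifest["counts"]["n_survival_triplets"] = int(flags["multivariate_flag"].sum())
            manifest["counts"]["n_both_significant"] = int(flags["both_significant"].sum())
            manifest["stages"].append(stage)
            if config.km_plots:
                from .assoc_stats import plot_km

                km_dir = outdir / "km"
                km_dir.mkdir(exist_ok=True)
                flagged = {x for _, row in flags[flags["multivariate_flag"] == 1].iterrows()
                           for x in (row["mrna_id"], row["lncrna_id"], row["mirna_id"])}
                for tid in sorted(flagged):
                    plot_km(logged.row(tid), clinical, str(km_dir / f"{tid}.svg"), title=tid)

        stage = "summarize"
        summary = summarize_counts(
            manifest["counts"]["expression"],
            manifest["counts"]["network"],
            _biotype_triplet_counts(triplets),
        )
        summary.to_frame().to_csv(outdir / "count_summary.tsv", sep="\t", index=False)
        manifest["counts"]["summary_totals"] = summary.totals
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest["wall_time_s"] = round(_time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete in %.1fs: %s", manifest["wall_time_s"],
                manifest["counts"])
    return manifest
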