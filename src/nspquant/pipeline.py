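"""End-to-end orchestration: read/simulate -> filter -> quantify ->
ratios -> metrics -> per-time-point DE -> temporal classes -> ORA.

Every stage writes its TSV into the output directory together with a
machine-readable run manifest (package version, config hash, seed, row
counts per stage), and rerunning with the same config reproduces
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffexpr, io, metrics, ora, quant, simulate, timecourse

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationError", "load_config", "run_pipeline"]


class ValidationError(ValueError):
    """The pipeline configuration is invalid; nothing was computed."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    outdir: str = "results/run"
    seed: int = 0
    # either a simulate block (SimDesign fields) or an input block
    simulate: dict | None = None
    input: dict | None = None  # {report, dialect, channel_map}
    quant_source: str = "MS2"
    quant_mode: str = "joint"
    min_shared_peptides: int = 1
    ratio_pair: tuple = ("H", "M")
    filters: dict = field(default_factory=dict)  # FilterConfig fields (+ contaminants file)
    de: dict = field(default_factory=lambda: {"fc_threshold": 0.585, "alpha": 0.05})
    classify: dict = field(
        default_factory=lambda: {
            "select_fc": 1.0, "class_fc": 0.585, "alpha": 0.05,
            "cv_threshold": 20.0, "cv_mode": "max", "class_map": None,
        }
    )
    gene_sets: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValidationError("config needs exactly one of 'simulate' or 'input'")
        if self.quant_source.upper() not in {"MS1", "MS2"}:
            raise ValidationError(f"quant_source must be MS1 or MS2, got {self.quant_source!r}")
        if self.quant_mode not in {"joint", "per_channel"}:
            raise ValidationError(f"quant_mode must be joint or per_channel, got {self.quant_mode!r}")
        pair = tuple(self.ratio_pair)
        if len(pair) != 2 or pair[0] == pair[1] or not set(pair) <= {"L", "M", "H"}:
            raise ValidationError(f"ratio_pair must be two distinct channels, got {self.ratio_pair!r}")
        for key in ("fc_threshold", "alpha"):
            if self.de.get(key) is not None and self.de[key] <= 0:
                raise ValidationError(f"de.{key} must be positive")
        if self.input is not None and "report" not in self.input:
            raise ValidationError("input block needs a 'report' path")
        if self.input is not None and not Path(self.input["report"]).exists():
            raise ValidationError(f"input report {self.input['report']!r} does not exist")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ValidationError(f"gene_sets file {self.gene_sets!r} does not exist")
        if self.simulate is not None:
            try:
                self.design()
            except simulate_mod_error as exc:
                raise ValidationError(str(exc)) from exc

    def design(self) -> simulate.SimDesign:
        block = dict(self.simulate or {})
        block.setdefault("seed", self.seed)
        return simulate.design_from_dict(block)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratio_pair"] = list(self.ratio_pair)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


simulate_mod_error = simulate.ConfigError


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc
    if "ratio_pair" in raw:
        cfg.ratio_pair = tuple(raw["ratio_pair"])
    return cfg


def _filter_config(block: dict) -> io.FilterConfig:
    block = dict(block)
    path = block.pop("contaminants_file", None)
    ids = frozenset(block.pop("contaminant_ids", ()))
    if path:
        ids |= io.load_contaminants(path)
    return io.FilterConfig(contaminant_ids=ids, **block)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # --- obtain the precursor table -------------------------------------
    if config.simulate is not None:
        design = config.design()
        truth = simulate.generate_ground_truth(design)
        report = simulate.simulate_precursor_report(truth, design)
        simulate.write_report(report, outdir / "report.tsv")
        simulate.write_ground_truth(truth, outdir / "ground_truth_proteins.tsv")
        simulate.write_design(design, outdir / "design.yaml")
        table = io.read_precursor_table(
            outdir / "report.tsv", quant_source=config.quant_source, dialect="diann_channels"
        )
        time_points = list(design.time_points)
    else:
        table = io.read_precursor_table(
            config.input["report"],
            quant_source=config.quant_source,
            dialect=config.input.get("dialect", "diann_channels"),
            channel_map=config.input.get("channel_map"),
        )
        time_points = list(config.input.get("time_points", []))
    counts["precursors_read"] = len(table)

    # --- filtering -------------------------------------------------------
    fcfg = _filter_config(config.filters)
    table = io.remove_contaminants(table, fcfg)
    counts["after_contaminant_removal"] = len(table)
    table = io.apply_qvalue_filters(table, fcfg)
    counts["after_qvalue_filters"] = len(table)
    io.write_precursor_table(table, outdir / "filtered_precursors.tsv", dialect="simple")

    # --- quantification and ratios ---------------------------------------
    quants = quant.quantify_all(
        table,
        quant_source=config.quant_source,
        mode=config.quant_mode,
        min_shared_peptides=config.min_shared_peptides,
    )
    quants.to_csv(outdir / "protein_lfq.tsv", sep="\t", index=False)
    counts["protein_channel_quants"] = len(quants)

    pair = tuple(config.ratio_pair)
    ratios = quant.compute_ratios(quants, pair=pair)
    ratios.to_csv(outdir / "ratios.tsv", sep="\t")
    counts["proteins_with_ratio"] = int(ratios.notna().any(axis=1).sum())

    # --- benchmark metrics ------------------------------------------------
    label_ratios = quant.precursor_label_ratio(table, quant_source=config.quant_source)
    summary = {
        "n_quantified_overall": metrics.count_quantified(ratios, "overall"),
        "n_quantified_per_sample": metrics.count_quantified(ratios, "per_sample").to_dict(),
        "missing_rate_percent": metrics.missing_rate(ratios, "overall"),
        "median_cv_percent": float(np.nanmedian(metrics.replicate_cv(ratios)["all"]))
        if ratios.shape[1] >= 2 else None,
        "median_log2_ratio": float(np.nanmedian(ratios.to_numpy())),
    }
    if len(label_ratios):
        med = label_ratios.groupby("channel")["log2_ratio"].median()
        summary["median_log2_label_over_light"] = {k: float(v) for k, v in med.items()}
    with open(outdir / "benchmark_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    genes = quants.drop_duplicates("protein_group").set_index("protein_group")["gene"]
    n_precursors = (
        quants.drop_duplicates("protein_group").set_index("protein_group")["n_precursors"]
    )

    # --- per-time-point DE, classes, ORA ---------------------------------
    de_by_tp: dict = {}
    ratios_by_tp: dict = {}
    if time_points:
        rep_of = {c: c.rsplit("_rep", 1)[0] for c in ratios.columns}
        for tp in time_points:
            cols = [c for c in ratios.columns if rep_of[c] == tp]
            if len(cols) < 2:
                log.warning("time point %s has < 2 replicate columns; skipped", tp)
                continue
            ratios_by_tp[tp] = ratios[cols]
            stats = diffexpr.fit_protein_stats(ratios[cols], n_precursors=n_precursors)
            prior = diffexpr.estimate_variance_prior(stats)
            res = diffexpr.moderate_and_test(stats, prior)
            res["p_adj"] = diffexpr.adjust_bh(res["p"].to_numpy())
            res = diffexpr.call_significance(
                res,
                fc_threshold=config.de.get("fc_threshold", 0.585),
                alpha=config.de.get("alpha", 0.05),
            )
            res.insert(0, "gene", genes.reindex(res.index))
            res.to_csv(outdir / f"de_{tp}.tsv", sep="\t", index_label="protein_group")
            de_by_tp[tp] = res
            counts[f"de_tested_{tp}"] = len(res)

        if len(de_by_tp) == len(time_points) and de_by_tp:
            ccfg = dict(config.classify)
            classes = timecourse.timecourse_report(
                de_by_tp, ratios_by_tp, time_points,
                class_map=ccfg.get("class_map"),
                select_fc=ccfg.get("select_fc", 1.0),
                class_fc=ccfg.get("class_fc", 0.585),
                alpha=ccfg.get("alpha", 0.05),
                cv_threshold=ccfg.get("cv_threshold", 20.0),
                cv_mode=ccfg.get("cv_mode", "max"),
                genes=genes,
            )
            classes.to_csv(outdir / "timecourse_classes.tsv", sep="\t", index=False)
            counts["selected_proteins"] = len(classes)

            if config.gene_sets:
                sets = ora.read_gmt(config.gene_sets)
                upregulated = sorted(
                    {
                        str(genes.get(p, p))
                        for tp, res in de_by_tp.items()
                        for p in res.index[res["significant_up"]]
                    }
                )
                background = [str(g) for g in genes.reindex(ratios.index).dropna()]
                ora_table = ora.run_ora(upregulated, sets, background)
                ora_table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
                counts["ora_sets_tested"] = len(ora_table)

    manifest = {
        "package": "nspquant",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
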