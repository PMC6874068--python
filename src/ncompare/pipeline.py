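"""Full-comparison orchestration: ingest -> normalize -> concordance -> ANOVA -> trends.

``run_pipeline`` executes every analysis of the platform comparison on one
input (raw RCC directory, normalized annotated matrix, or the synthetic
generator), writes all artifacts under an output directory, and returns a
summary report.  A MANIFEST records which stages completed, so a failed run
leaves an inspectable partial output tree.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import loess
from .anova import decompose_matrix, model_spec, MODEL_IDS
from .errors import ConfigurationError, NCompareError
from .io import (
    ExpressionMatrix,
    matrix_from_lanes,
    read_annotated_matrix,
    read_rcc_dir,
    write_annotated_matrix,
)
from .normalization import NormConfig, normalize
from .synthetic import ControlSpec, SyntheticConfig, generate_log2

logger = logging.getLogger(__name__)

INPUT_MODES = ("rcc_dir", "matrix", "synthetic")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    mode: str = "synthetic"
    input_path: str | None = None
    outdir: str = "ncompare_out"
    seed: int | None = None
    norm: NormConfig = field(default_factory=NormConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    loess_span: float = 0.75
    loess_degree: int = 2
    grid_points: int = 100
    trim_fraction: float = 0.98
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    high_expression_percentile: float = 50.0
    cross_scan_cartridges: tuple[str, ...] = ("A", "B")
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ConfigurationError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")
        if self.mode != "synthetic" and not self.input_path:
            raise ConfigurationError(f"mode {self.mode!r} requires input_path")
        if self.seed is not None:
            self.synthetic = self.synthetic.with_(seed=int(self.seed))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        kwargs = {}
        if "normalization" in raw:
            kwargs["norm"] = NormConfig(**raw.pop("normalization"))
        if "synthetic" in raw:
            synth = dict(raw.pop("synthetic"))
            if "control_spec" in synth:
                synth["control_spec"] = ControlSpec(**synth["control_spec"])
            kwargs["synthetic"] = SyntheticConfig(**synth)
        loess_cfg = raw.pop("loess", {})
        kwargs["loess_span"] = loess_cfg.get("span", 0.75)
        kwargs["loess_degree"] = loess_cfg.get("degree", 2)
        kwargs["grid_points"] = loess_cfg.get("grid_points", 100)
        kwargs["trim_fraction"] = loess_cfg.get("trim_fraction", 0.98)
        cluster_cfg = raw.pop("clustering", {})
        kwargs["cluster_metric"] = cluster_cfg.get("metric", "euclidean")
        kwargs["cluster_method"] = cluster_cfg.get("method", "average")
        if "cross_scan_cartridges" in raw:
            kwargs["cross_scan_cartridges"] = tuple(raw.pop("cross_scan_cartridges"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SummaryReport:
    """Machine-readable run summary.

    ``pcc`` maps comparison labels to min/max correlation; ``rms_ratios``
    maps each model to, per technical source, the median over
    high-expression features of RMS(source) / RMS(residual) — near 1 means
    the source contributes no more than duplicate noise.
    """

    pcc: dict
    rms_ratios: dict
    files: list[str]
    n_features: int
    high_expression_percentile: float

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "rms_ratios": self.rms_ratios,
            "files": sorted(self.files),
            "n_features": self.n_features,
            "high_expression_percentile": self.high_expression_percentile,
        }


def _stage(name: str, manifest: list[str]):
    """Context manager tagging stage failures and recording completions."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest.append(name)
                logger.info("stage %s: done", name)
                return False
            raise NCompareError(f"stage {name!r} failed: {exc}") from exc
    return _Ctx()


def _ingest(config: RunConfig, outdir: Path, files: list[str]):
    if config.mode == "synthetic":
        matrix, truth = generate_log2(config.synthetic)
        return matrix, None
    if config.mode == "matrix":
        return read_annotated_matrix(config.input_path), None
    lanes = read_rcc_dir(config.input_path)
    raw = matrix_from_lanes(lanes)
    matrix, report = normalize(raw, config.norm)
    report.to_frame().to_csv(outdir / "normalization_report.tsv", sep="\t")
    (outdir / "removed_features.txt").write_text("\n".join(report.removed_features) + "\n")
    files += ["normalization_report.tsv", "removed_features.txt"]
    return matrix, report


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Run the full comparison and write every artifact under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    files: list[str] = []
    try:
        report = _run(config, outdir, manifest, files)
        (outdir / "MANIFEST").write_text(
            "status: complete\nstages: " + ", ".join(manifest) + "\n"
        )
        return report
    except Exception:
        (outdir / "MANIFEST").write_text(
            "status: INCOMPLETE\nstages: " + ", ".join(manifest) + "\n"
        )
        raise


def _run(config: RunConfig, outdir: Path, manifest: list[str], files: list[str]) -> SummaryReport:
    with _stage("ingest", manifest):
        matrix, _ = _ingest(config, outdir, files)
        write_annotated_matrix(matrix, outdir / "log2_matrix.tsv")
        files.append("log2_matrix.tsv")

    with _stage("clustering", manifest):
        heat_out = outdir / "heatmap.png" if config.make_plots else None
        cluster = conc.cluster_heatmap(
            matrix, heat_out, metric=config.cluster_metric, method=config.cluster_method
        )
        if config.make_plots:
            files += ["heatmap.png", "heatmap.tsv"]

    pcc_summary: dict[str, dict] = {}
    with _stage("concordance", manifest):
        cartridges = sorted(set(matrix.lane_annotations["cartridge"]))
        for c1, c2 in itertools.combinations(cartridges, 2):
            table = conc.pairwise_pcc(matrix, (c1, c2), scan_index=1)
            name = f"pcc_scan1_{c1}-vs-{c2}.tsv"
            table.to_csv(outdir / name, sep="\t", index=False)
            files.append(name)
            lo, hi = conc.pcc_range(table)
            pcc_summary[f"scan1:{c1}-vs-{c2}"] = {"min": lo, "max": hi, "n": len(table)}
        scans = set(matrix.lane_annotations["scan_index"])
        if scans == {1, 2}:
            for cart in config.cross_scan_cartridges:
                if cart not in cartridges:
                    continue
                table = conc.scanpair_pcc(matrix, cart)
                name = f"pcc_cross_scan_{cart}.tsv"
                table.to_csv(outdir / name, sep="\t", index=False)
                files.append(name)
                lo, hi = conc.pcc_range(table)
                pcc_summary[f"cross_scan:{cart}"] = {"min": lo, "max": hi, "n": len(table)}

    rms_ratios: dict[str, dict] = {}
    with _stage("decomposition", manifest):
        tables = {}
        for model_id in MODEL_IDS:
            spec = model_spec(model_id)
            table = decompose_matrix(matrix, spec)
            tables[model_id] = (spec, table)
            name = f"anova_{model_id}.tsv"
            table.to_csv(outdir / name, sep="\t")
            files.append(name)
            sidecar = {
                "model_id": model_id,
                "terms": [{"name": t.name, "df": t.df} for t in spec.terms],
                "residual_df": spec.residual_df,
                "n_observations": spec.expected_n,
            }
            sname = f"anova_{model_id}.json"
            (outdir / sname).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
            files.append(sname)

    with _stage("trend_curves", manifest):
        for model_id, (spec, table) in tables.items():
            curves = loess.curves_for_model(
                table, span=config.loess_span, degree=config.loess_degree,
                grid_points=config.grid_points, trim_fraction=config.trim_fraction,
            )
            paths = loess.export_curves(curves, outdir / f"trend_{model_id}",
                                        plot=config.make_plots)
            files += [p.name for p in paths.values()]
            # per-source RMS ratio vs residual, medians over high-expression features
            cut = np.percentile(table["mean_expression"], config.high_expression_percentile)
            high = table[table["mean_expression"] >= cut]
            ratios = {}
            for source in [t.name for t in spec.terms]:
                ratios[source] = float(
                    (high[f"rms_{source}"] / high["rms_residual"]).median()
                )
            rms_ratios[model_id] = ratios

    with _stage("report", manifest):
        report = SummaryReport(
            pcc=pcc_summary,
            rms_ratios=rms_ratios,
            files=sorted(files),
            n_features=matrix.n_features,
            high_expression_percentile=config.high_expression_percentile,
        )
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return report
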