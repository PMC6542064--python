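"""End-to-end orchestration: preprocess, segment, infer, validate.

A single ``PipelineConfig`` carries every tunable with a documented
default; one master seed is split deterministically per stage.  Each stage
writes its artifacts plus a manifest (input hashes, resolved config, seeds,
versions) so a rerun with the same config and seed is hash-stable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cpd import CPDConfig, aggregate_change_points, detect_panel
from .network import (
    load_module_map,
    load_reference_edges,
    module_lag_matrix,
    run_phase_networks,
    validate,
)
from .preprocess import (
    ExpressionMatrix,
    compute_fold_change,
    filter_differentially_expressed,
)
from .simulate import mef_like_scenario
from .var import VARConfig

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs"]

_STAGE_SEED_STEP = 99991  # deterministic per-stage seed split


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run (all fields have defaults)."""

    expression: str | None = None
    module_map: str | None = None
    reference: str | None = None
    baseline_columns: list[int] = field(default_factory=lambda: [0])
    t0_column: int = 0
    fold_threshold: float = 2.0
    already_fold_change: bool = True
    # change-point detection
    cpd_N: int = 20
    cpd_M: int = 10
    cpd_q: int = 10
    cpd_l: int = 3
    cpd_surrogates: int = 24
    cpd_kappa: float = 0.75
    n_peaks: int = 3
    min_separation: int = 5
    # VAR inference
    d_max: int = 9
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    V: int = 10
    rss_source: str = "escv"
    lag_rule: str = "max_coefficient"
    validation_mode: str = "undirected"
    # global
    seed: int = 0
    outdir: str = "tvgranger_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cpd_config(self) -> CPDConfig:
        return CPDConfig(
            N=self.cpd_N,
            M=self.cpd_M,
            q=self.cpd_q,
            l=self.cpd_l,
            n_surrogates=self.cpd_surrogates,
            kappa=self.cpd_kappa,
            seed=self.seed + _STAGE_SEED_STEP,
        )

    def var_config(self) -> VARConfig:
        return VARConfig(
            d_max=self.d_max,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            V=self.V,
            rss_source=self.rss_source,
            seed=self.seed + 2 * _STAGE_SEED_STEP,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig, inputs: list[str]) -> None:
    manifest = {
        "tvgranger_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "inputs": {
            p: _sha256(Path(p)) for p in inputs if p and Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def simulate_inputs(outdir, k: int = 20, T: int = 96, seed: int = 0) -> dict:
    """Write the flagship synthetic scenario's input files and ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scen = mef_like_scenario(k=k, T=T, seed=seed)
    io.write_expression_tsv(scen["matrix"], out / "expression.tsv")
    scen["modules"].to_csv(out / "modules.tsv", sep="\t", index=False)
    scen["reference"].to_csv(out / "reference.tsv", sep="\t", index=False)
    truth = scen["truth"]
    genes = scen["matrix"].genes
    payload = {
        "change_points": truth.change_points,
        "edges": sorted([genes[j], genes[i], l] for (j, i, l) in truth.edges),
        "affected": {str(b): g for b, g in truth.affected.items()},
        "seed": seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return scen


_STAGES = ("preprocess", "detect-phases", "infer-network", "validate")


def run_pipeline(config: PipelineConfig, until: str = "validate") -> dict:
    """Run preprocess -> detect-phases -> infer-network -> validate.

    ``until`` stops the chain after the named stage.  Returns the in-memory
    results and writes every artifact to ``config.outdir``.
    """
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = _STAGES.index(until)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.expression is None:
        raise ValueError("config.expression is required")
    raw = io.read_expression_tsv(config.expression)
    if config.already_fold_change:
        times = raw.columns.to_numpy(dtype=float)
        matrix = ExpressionMatrix(
            list(raw.index.astype(str)),
            raw.to_numpy(dtype=float),
            t0=float(times[0]),
            dt=float(times[1] - times[0]),
            baseline_columns=config.baseline_columns,
        )
    else:
        matrix = compute_fold_change(raw, config.baseline_columns)
        matrix = filter_differentially_expressed(
            matrix, config.fold_threshold, config.t0_column
        )
    io.write_expression_tsv(matrix, outdir / "fold_change.tsv")
    if last < 1:
        _write_manifest(outdir, config, [config.expression])
        return {"matrix": matrix}
    # phase segmentation
    results = detect_panel(matrix, config.cpd_config())
    seg = aggregate_change_points(
        results,
        matrix.T,
        t0=matrix.t0,
        dt=matrix.dt,
        n_peaks=config.n_peaks,
        min_separation=config.min_separation,
    )
    io.write_change_points_tsv(results, outdir / "change_points.tsv", matrix.t0, matrix.dt)
    io.write_segmentation_json(seg, outdir / "segmentation.json")
    if last < 2:
        _write_manifest(outdir, config, [config.expression])
        return {"matrix": matrix, "cpd_results": results, "segmentation": seg}
    # per-window networks
    networks = run_phase_networks(matrix, seg, config.var_config(), config.lag_rule)
    modules = None
    if config.module_map:
        modules = load_module_map(config.module_map)
    reports = []
    reference = None
    if last >= 3 and config.reference:
        reference = load_reference_edges(config.reference)
    audit = []
    for i, net in enumerate(networks, start=1):
        tag = f"window{i}"
        io.write_edge_list_tsv(net, outdir / f"network_{tag}.tsv")
        io.write_graphml(net, outdir / f"network_{tag}.graphml")
        io.write_sif(net, outdir / f"network_{tag}.sif")
        mod_map = (
            dict(zip(modules.iloc[:, 0], modules.iloc[:, 1])) if modules is not None else None
        )
        io.write_node_table_tsv(net, outdir / f"nodes_{tag}.tsv", mod_map)
        if modules is not None:
            lm = module_lag_matrix(net, modules)
            io.write_lag_matrix_tsv(lm, outdir / f"lag_matrix_{tag}.tsv")
        if reference is not None:
            rep = validate(net, reference, mode=config.validation_mode)
            reports.append(rep)
            pd.DataFrame(
                [
                    {
                        "window": tag,
                        "TP": rep.tp,
                        "FP": rep.fp,
                        "precision": rep.precision,
                        "FDR": rep.fdr,
                        "mode": rep.mode,
                    }
                ]
            ).to_csv(outdir / f"validation_{tag}.tsv", sep="\t", index=False)
        for fit in net.fits:
            audit.append(
                {
                    "window": tag,
                    "gene": fit.gene_id,
                    "d_opt": fit.d_opt,
                    "lambda_cv": fit.lambda_cv,
                    "lambda_escv": fit.lambda_escv,
                    "nnz": fit.nnz,
                }
            )
    pd.DataFrame(audit).to_csv(outdir / "fit_audit.tsv", sep="\t", index=False)
    _write_manifest(
        outdir,
        config,
        [config.expression, config.module_map or "", config.reference or ""],
    )
    return {
        "matrix": matrix,
        "cpd_results": results,
        "segmentation": seg,
        "networks": networks,
        "validation": reports,
    }
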