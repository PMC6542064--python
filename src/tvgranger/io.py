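"""Readers and writers for the pipeline's tabular formats.

Expression tables are TSV with a gene_id first column and a header row of
time stamps in hours.  Networks export as TSV edge lists, GraphML and SIF;
segmentations as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cpd import CPDResult, PhaseSegmentation
from .network import CausalNetwork
from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_offsets_tsv",
    "write_change_points_tsv",
    "write_segmentation_json",
    "write_edge_list_tsv",
    "write_graphml",
    "write_sif",
    "write_node_table_tsv",
    "write_lag_matrix_tsv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x time table; columns parsed as hours where possible."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df.columns = df.columns.astype(float)
    except (TypeError, ValueError):
        pass
    return df


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_offsets_tsv(offsets: dict[str, tuple[int, float]], path) -> None:
    """Rows (gene_id, offset_samples, peak_correlation)."""
    rows = [(g, o, r) for g, (o, r) in sorted(offsets.items())]
    pd.DataFrame(
        rows, columns=["gene_id", "offset_samples", "peak_correlation"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_change_points_tsv(
    results: list[CPDResult], path, t0: float = 0.5, dt: float = 0.5
) -> None:
    rows = []
    for r in results:
        for tau in r.change_points:
            w = r.W[tau] if 0 <= tau < r.W.size else np.nan
            rows.append((r.gene_id, tau, t0 + dt * tau, w))
    pd.DataFrame(
        rows, columns=["gene_id", "tau_sample", "tau_hours", "W_value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_segmentation_json(seg: PhaseSegmentation, path) -> None:
    payload = {
        "counts": seg.counts.tolist(),
        "boundaries_samples": seg.boundaries_samples,
        "boundaries_hours": seg.boundaries_hours,
        "intervals_hours": [list(iv) for iv in seg.intervals],
        "t0": seg.t0,
        "dt": seg.dt,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_edge_list_tsv(network: CausalNetwork, path) -> None:
    network.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(network: CausalNetwork, path) -> None:
    g = network.graph.copy()
    for _u, _v, d in g.edges(data=True):
        d["lags"] = ",".join(map(str, d.get("lags", [])))
    nx.write_graphml(g, path)


def write_sif(network: CausalNetwork, path) -> None:
    """Simple interaction format: source <lag_l> target, one edge per line."""
    lines = [f"{u}\tlag_{lag}\t{v}" for u, v, lag, _w in network.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_node_table_tsv(
    network: CausalNetwork, path, modules: dict[str, str] | None = None
) -> None:
    rows = [
        (n, (modules or {}).get(n, ""), d.get("d_opt", ""))
        for n, d in sorted(network.graph.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_id", "module", "d_opt"]).to_csv(
        path, sep="\t", index=False
    )


def write_lag_matrix_tsv(lag_matrix: pd.DataFrame, path) -> None:
    lag_matrix.to_csv(path, sep="\t", float_format="%.3f", na_rep="")
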