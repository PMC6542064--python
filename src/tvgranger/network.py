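"""Directed lag-labeled network assembly, module lag analysis, validation.

One edge j -> i exists per (source j, target i) pair with at least one
nonzero lagged coefficient in target i's sparse VAR fit; the edge's lag
label is the lag of the largest-magnitude coefficient for the pair (one
lag = half an hour), and the target's selected VAR order is kept as a node
attribute.  Networks are built per cumulative phase window, averaged into
process-by-process temporal-dependence matrices, and validated against a
reference interaction set by precision and false discovery rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cpd import PhaseSegmentation
from .preprocess import ExpressionMatrix
from .var import SparseVARFit, VARConfig, fit_window

__all__ = [
    "CausalNetwork",
    "ValidationReport",
    "assemble_network",
    "module_lag_matrix",
    "validate",
    "run_phase_networks",
    "load_module_map",
    "load_reference_edges",
]


@dataclass
class CausalNetwork:
    """Lag-labeled directed gene network for one analysis window."""

    window: tuple[float, float]
    graph: nx.DiGraph
    fits: list[SparseVARFit] = field(default_factory=list)

    @property
    def edges(self) -> list[tuple[str, str, int, float]]:
        """(source, target, lag, weight) rows, deterministically ordered."""
        return sorted(
            (u, v, d["lag"], d["weight"])
            for u, v, d in self.graph.edges(data=True)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["source", "target", "lag", "weight"]
        )


@dataclass
class ValidationReport:
    """Precision / FDR of predicted edges against a reference set."""

    tp: int
    fp: int
    precision: float | None
    fdr: float | None
    matched: list[tuple[str, str]]
    unmatched: list[tuple[str, str]]
    mode: str = "undirected"


def assemble_network(
    fits: list[SparseVARFit],
    window: tuple[float, float] = (0.0, 0.0),
    lag_rule: str = "max_coefficient",
) -> CausalNetwork:
    """Collapse per-target sparse fits into a lag-labeled directed graph.

    ``lag_rule`` picks the reported lag when a pair has several nonzero
    coefficients: "max_coefficient" (largest |a|; default), "min_lag", or
    "all" (one parallel edge per lag is not representable in a DiGraph, so
    the smallest lag is kept and every lag recorded in the edge attribute
    ``lags``).  Self-loops (a gene's own history) are fitted but never
    reported.
    """
    if lag_rule not in ("max_coefficient", "min_lag", "all"):
        raise ValueError(f"unknown lag rule {lag_rule!r}")
    g = nx.DiGraph()
    for fit in fits:
        g.add_node(fit.gene_id, d_opt=fit.d_opt)
    for fit in fits:
        per_source: dict[str, list[tuple[int, float]]] = {}
        for (src, lag), coef in fit.coefficients.items():
            if src == fit.gene_id:
                continue
            per_source.setdefault(src, []).append((lag, coef))
        for src, entries in per_source.items():
            entries.sort()
            if lag_rule == "max_coefficient":
                lag, coef = max(entries, key=lambda e: (abs(e[1]), -e[0]))
            else:
                lag, coef = entries[0]
            g.add_edge(
                src,
                fit.gene_id,
                lag=lag,
                weight=coef,
                lags=[l for l, _ in entries],
            )
    return CausalNetwork(window=window, graph=g, fits=list(fits))


def module_lag_matrix(
    network: CausalNetwork, modules: pd.DataFrame | dict[str, str]
) -> pd.DataFrame:
    """Average edge lag between every ordered pair of processes.

    Entry (p, q) is the mean lag label over edges from genes in process p
    to genes in process q (units: lags; one lag = 0.5 h); pairs with no
    edges are NaN, never zero.  Genes missing from the module map are
    skipped with a warning.
    """
    if isinstance(modules, pd.DataFrame):
        mapping = dict(zip(modules.iloc[:, 0], modules.iloc[:, 1]))
        order = list(dict.fromkeys(modules.iloc[:, 1]))
    else:
        mapping = dict(modules)
        order = list(dict.fromkeys(mapping.values()))
    unmapped = sorted(set(network.graph.nodes) - set(mapping))
    if unmapped:
        warnings.warn(f"genes missing from module map skipped: {unmapped}")
    sums = pd.DataFrame(0.0, index=order, columns=order)
    counts = pd.DataFrame(0, index=order, columns=order)
    for u, v, lag, _w in network.edges:
        if u in mapping and v in mapping:
            p, q = mapping[u], mapping[v]
            sums.loc[p, q] += lag
            counts.loc[p, q] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts.replace(0, np.nan)
    return out


def load_module_map(path) -> pd.DataFrame:
    """Two-column TSV gene_id -> process; duplicate genes are rejected."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("module map needs gene_id and process columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "process"]
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"genes mapped to several processes: {sorted(set(dup))}")
    return df


def load_reference_edges(path) -> pd.DataFrame:
    """Reference edge TSV (two gene columns, optional direction flag).

    Duplicate rows are dropped at load so validation counts each reference
    pair once.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("reference needs two gene columns")
    return df.drop_duplicates().reset_index(drop=True)


def validate(
    network: CausalNetwork | list[tuple[str, str]],
    reference: pd.DataFrame | list[tuple[str, str]],
    mode: str = "undirected",
) -> ValidationReport:
    """Precision = TP / (TP + FP) and FDR = FP / (TP + FP) of predicted edges.

    In undirected mode (default; interaction references rarely carry
    direction) a predicted edge matches a reference pair in either
    orientation.  Self-loops are ignored.  An empty prediction yields a
    report with undefined precision, not an error; recall against the
    reference is deliberately not computed.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError("mode must be 'directed' or 'undirected'")
    if isinstance(network, CausalNetwork):
        predicted = [(u, v) for u, v, _l, _w in network.edges]
    else:
        predicted = list(network)
    predicted = [(u, v) for u, v in predicted if u != v]
    if isinstance(reference, pd.DataFrame):
        if reference.empty:
            raise ValueError("reference edge set is empty")
        ref_pairs = list(zip(reference.iloc[:, 0], reference.iloc[:, 1]))
    else:
        ref_pairs = list(reference)
    if not ref_pairs:
        raise ValueError("reference edge set is empty")
    if mode == "directed":
        ref = set(ref_pairs)
        hit = lambda e: e in ref  # noqa: E731
    else:
        ref = {frozenset(p) for p in ref_pairs}
        hit = lambda e: frozenset(e) in ref  # noqa: E731
    matched = sorted({e for e in predicted if hit(e)})
    unmatched = sorted({e for e in predicted if not hit(e)})
    tp, fp = len(matched), len(unmatched)
    if tp + fp == 0:
        return ValidationReport(0, 0, None, None, [], [], mode)
    return ValidationReport(
        tp=tp,
        fp=fp,
        precision=tp / (tp + fp),
        fdr=fp / (tp + fp),
        matched=matched,
        unmatched=unmatched,
        mode=mode,
    )


def run_phase_networks(
    matrix: ExpressionMatrix,
    segmentation: PhaseSegmentation,
    config: VARConfig | None = None,
    lag_rule: str = "max_coefficient",
) -> list[CausalNetwork]:
    """One independently fitted network per cumulative phase window.

    The windows run from the grid start to each detected boundary (G1;
    G1+S; G1+S+G2/M) and are fitted end-to-end with the same configuration;
    nothing constrains later networks to contain earlier ones.
    """
    if not segmentation.intervals:
        raise ValueError("segmentation has no boundaries")
    cfg = config or VARConfig()
    nets = []
    for window in segmentation.intervals:
        fits = fit_window(matrix, cfg, window=window)
        nets.append(assemble_network(fits, window=window, lag_rule=lag_rule))
    return nets
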