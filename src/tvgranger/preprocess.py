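"""Expression preprocessing: fold change, DE filtering, interpolation, cycle alignment.

The pipeline starts from a gene x time expression table sampled over roughly
two cell cycles.  Raw (normalized-count) values are converted to fold change
against the mean of designated pre-stimulus baseline samples, filtered to
differentially expressed genes, interpolated onto a uniform half-hour grid,
and -- where the recording covers two copies of the cycle -- the two copies
are aligned by cross-correlation and merged into one profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "ExpressionMatrix",
    "compute_fold_change",
    "filter_differentially_expressed",
    "interpolate_to_uniform",
    "estimate_cycle_offset",
    "concatenate_cycles",
]


@dataclass
class ExpressionProfile:
    """One gene's uniformly sampled fold-change series.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    values : ndarray
        Fold-change values (unitless ratios, strictly positive).
    t0 : float
        Time of the first sample, in hours.
    dt : float
        Sampling interval in hours (0.5 after interpolation).
    """

    gene_id: str
    values: np.ndarray
    t0: float = 0.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"{self.gene_id}: profile needs >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.gene_id}: non-finite values in profile")
        if np.any(self.values <= 0):
            raise ValueError(
                f"{self.gene_id}: fold-change values must be > 0 "
                "(ratios of positive normalized counts)"
            )
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def T(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.T)


@dataclass
class ExpressionMatrix:
    """A panel of genes on one shared uniform time grid.

    ``values`` is a (k genes x T samples) array of fold changes;
    ``baseline_columns`` indexes the pre-stimulus samples used as the
    fold-change denominator.
    """

    genes: list[str]
    values: np.ndarray
    t0: float = 0.0
    dt: float = 0.5
    baseline_columns: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.genes = list(self.genes)
        if self.values.shape[0] != len(self.genes):
            raise ValueError("gene list and value rows disagree")
        if not self.baseline_columns:
            raise ValueError("baseline_columns must be non-empty")
        if max(self.baseline_columns) >= self.values.shape[1]:
            raise ValueError("baseline column index out of range")

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def T(self) -> int:
        return int(self.values.shape[1])

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.T)

    def profile(self, gene_id: str) -> ExpressionProfile:
        i = self.genes.index(gene_id)
        return ExpressionProfile(gene_id, self.values[i].copy(), self.t0, self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.times)

    def window(self, start_hour: float, end_hour: float) -> "ExpressionMatrix":
        """Sub-matrix restricted to samples with start_hour <= t <= end_hour."""
        t = self.times
        mask = (t >= start_hour - 1e-9) & (t <= end_hour + 1e-9)
        idx = np.where(mask)[0]
        if idx.size < 2:
            raise ValueError("window contains fewer than 2 samples")
        return ExpressionMatrix(
            self.genes,
            self.values[:, idx].copy(),
            t0=float(t[idx[0]]),
            dt=self.dt,
            baseline_columns=[0],
        )


def compute_fold_change(
    raw: pd.DataFrame | np.ndarray,
    baseline_columns: list[int],
    genes: list[str] | None = None,
    t0: float = 0.0,
    dt: float = 0.5,
) -> ExpressionMatrix:
    """Divide each gene's series by the mean of its baseline samples.

    entry(g, t) = raw(g, t) / mean(raw(g, baseline_columns)).  Raises if any
    raw value is negative or any gene's baseline mean is zero (those genes are
    named in the error).
    """
    if isinstance(raw, pd.DataFrame):
        genes = list(raw.index.astype(str))
        try:
            times = raw.columns.astype(float).to_numpy()
            t0 = float(times[0])
            if len(times) > 1:
                dt = float(times[1] - times[0])
        except (TypeError, ValueError):
            pass
        values = raw.to_numpy(dtype=float)
    else:
        values = np.atleast_2d(np.asarray(raw, dtype=float))
        if genes is None:
            genes = [f"g{i}" for i in range(values.shape[0])]
    if np.any(values < 0):
        raise ValueError("negative raw expression values are not allowed")
    if not baseline_columns:
        raise ValueError("baseline_columns must be non-empty")
    baseline_columns = list(baseline_columns)
    if max(baseline_columns) >= values.shape[1]:
        raise ValueError("baseline column index out of range")
    base = values[:, baseline_columns].mean(axis=1)
    bad = [g for g, b in zip(genes, base) if b <= 0]
    if bad:
        raise ValueError(f"zero baseline mean for genes: {', '.join(bad)}")
    fc = values / base[:, None]
    return ExpressionMatrix(genes, fc, t0=t0, dt=dt, baseline_columns=baseline_columns)


def filter_differentially_expressed(
    matrix: ExpressionMatrix,
    fold_threshold: float = 2.0,
    t0_column: int = 0,
) -> ExpressionMatrix:
    """Keep genes changing >= fold_threshold up or down relative to t = 0.

    A gene passes if value(t)/value(t0) >= fold_threshold or
    <= 1/fold_threshold at one or more time points (inclusive at the
    threshold).  An empty result is a warning, not an error.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    ref = matrix.values[:, t0_column]
    ratio = matrix.values / ref[:, None]
    keep = np.any((ratio >= fold_threshold) | (ratio <= 1.0 / fold_threshold), axis=1)
    if not keep.any():
        warnings.warn("no differentially expressed genes at this threshold")
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.genes = []
        out.values = np.empty((0, matrix.T))
        out.t0, out.dt = matrix.t0, matrix.dt
        out.baseline_columns = matrix.baseline_columns
        return out
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    return ExpressionMatrix(
        genes,
        matrix.values[keep].copy(),
        t0=matrix.t0,
        dt=matrix.dt,
        baseline_columns=matrix.baseline_columns,
    )


def interpolate_to_uniform(
    times: np.ndarray,
    values: np.ndarray,
    target_dt: float = 0.5,
    gene_id: str = "",
) -> ExpressionProfile:
    """Linearly interpolate a (possibly coarser) series onto a uniform grid.

    Native sample times must be strictly increasing; they are preserved
    exactly when they fall on the target grid.  Output length is
    round(span / target_dt) + 1.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size != values.size:
        raise ValueError("times and values must be 1-D and equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    span = times[-1] - times[0]
    n_out = int(round(span / target_dt)) + 1
    grid = times[0] + target_dt * np.arange(n_out)
    out = np.interp(grid, times, values)
    # snap native samples onto the grid exactly (guards against fp drift)
    on_grid = np.round((times - times[0]) / target_dt)
    exact = np.abs(times[0] + on_grid * target_dt - times) < 1e-9
    idx = on_grid[exact].astype(int)
    idx = idx[idx < n_out]
    out[idx] = values[exact][: idx.size]
    return ExpressionProfile(gene_id or "series", out, t0=float(times[0]), dt=target_dt)


def _as_array(x) -> np.ndarray:
    return x.values if isinstance(x, ExpressionProfile) else np.asarray(x, dtype=float)


def estimate_cycle_offset(
    cycle1: ExpressionProfile | np.ndarray,
    cycle2: ExpressionProfile | np.ndarray,
    max_lag: int | None = None,
) -> tuple[int, float]:
    """Integer sample offset between two copies of a cyclic profile.

    Returns ``(offset, peak_correlation)`` where ``offset`` maximizes the
    Pearson correlation between ``cycle1`` shifted by ``offset`` and
    ``cycle2`` over their overlap (``cycle2[t] ~ cycle1[t - offset]``).  The
    lag range is limited to +/- half the shorter series; ties break toward the
    smaller absolute lag.
    """
    x = _as_array(cycle1)
    y = _as_array(cycle2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    if max_lag is None:
        max_lag = min(x.size, y.size) // 2
    best: tuple[float, int] | None = None
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), -l)):
        if lag >= 0:
            a, b = x[: x.size], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size]
        n = min(a.size, b.size)
        if n < 3:
            continue
        a, b = a[:n], b[:n]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if best is None or r > best[0] + 1e-12:
            best = (r, lag)
    if best is None:
        raise ValueError("no overlapping lag with defined correlation")
    return best[1], best[0]


def concatenate_cycles(
    cycle1: ExpressionProfile,
    cycle2: ExpressionProfile,
    offset: int,
) -> ExpressionProfile:
    """Merge two cycle recordings into one profile given their sample offset.

    A positive ``offset`` means the first ``offset`` samples of ``cycle2``
    replay the last ``offset`` samples of ``cycle1``; overlapping samples are
    averaged and the result has length ``len(cycle1) + len(cycle2) - offset``.
    Negative offsets would leave a gap between the recordings and are
    rejected.
    """
    if cycle1.dt != cycle2.dt:
        raise ValueError("cycles must share the sampling interval")
    if offset < 0 or offset >= cycle1.T:
        raise ValueError(f"offset {offset} out of range [0, {cycle1.T})")
    x, y = cycle1.values, cycle2.values
    if offset == 0:
        merged = np.concatenate([x, y])
    else:
        head = x[: x.size - offset]
        overlap = 0.5 * (x[x.size - offset:] + y[:offset])
        merged = np.concatenate([head, overlap, y[offset:]])
    return ExpressionProfile(cycle1.gene_id, merged, t0=cycle1.t0, dt=cycle1.dt)
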