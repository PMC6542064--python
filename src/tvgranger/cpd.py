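"""Sequential SSA subspace-distance change-point detection and aggregation.

For each gene, a base window of ``N`` samples is embedded into ``M``-lagged
vectors whose leading ``l`` eigenvectors span a signal subspace.  The mean
squared distance of the next ``q`` lagged vectors to that subspace,
normalized by the in-window mean distance, feeds a CUSUM-type statistic
``W``; a change point is declared when ``W`` exceeds a per-gene threshold
``h`` calibrated on stationary surrogates of the same series.  The change
time is then refined from a per-sample score (each sample's lagged-vector
distance averaged over the sliding positions that test it), and detection
re-arms ``N`` samples after the reported change point.  Per-gene detections
are aggregated into per-sample counts whose top peaks define the phase
boundaries and the nested cumulative analysis windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import eigh
from scipy.signal import find_peaks

from .preprocess import ExpressionMatrix

__all__ = [
    "CPDConfig",
    "CPDResult",
    "PhaseSegmentation",
    "detect_change_points",
    "aggregate_change_points",
    "detect_panel",
]


@dataclass
class CPDConfig:
    """Tuning constants of the sequential detector.

    N : base-window length in samples (default 20 = 10 h at half-hour
        sampling; short enough that a base window fits inside each regime).
    M : embedding window, M <= N / 2.
    q : test-window length (lagged vectors tested ahead of the base).
    l : retained subspace dimension (default 3).  Set ``l=None`` and a
        ``variance_fraction`` to use a cumulative-eigenvalue rule instead.
    n_surrogates : stationary phase-randomized surrogates used to calibrate;
        ``h`` is the largest surrogate maximum statistic, an exact
        1/(n_surrogates + 1) false-alarm level by exchangeability.
    kappa : slack added to the estimated null drift of the CUSUM increment.
    h : explicit threshold; when None it is calibrated per gene.
    locate_window : half-width of the split-contrast window used to localize
        the change time after a detection.
    onset_fraction : fraction of the pre/post score contrast that the score
        must exceed to mark the change onset when backtracking from the
        contrast split point.
    """

    N: int = 20
    M: int = 10
    q: int = 10
    l: int | None = 3
    variance_fraction: float = 0.95
    n_surrogates: int = 24
    kappa: float = 0.75
    h: float | None = None
    locate_window: int = 8
    onset_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M > self.N // 2:
            raise ValueError("require M <= N / 2")
        if self.M < 2:
            raise ValueError("require M >= 2")
        if self.q < 1:
            raise ValueError("require q >= 1")
        if self.l is not None and not 1 <= self.l < self.M:
            raise ValueError("require 1 <= l < M")


@dataclass
class CPDResult:
    """Per-gene detection statistic trace and change points."""

    gene_id: str
    W: np.ndarray
    threshold: float
    change_points: list[int]
    drift: float = 0.0


@dataclass
class PhaseSegmentation:
    """Aggregated change-point counts, boundary times, cumulative windows."""

    counts: np.ndarray
    boundaries_samples: list[int]
    boundaries_hours: list[float]
    intervals: list[tuple[float, float]] = field(default_factory=list)
    t0: float = 0.5
    dt: float = 0.5


def _distance_trace(x: np.ndarray, cfg: CPDConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-position statistic inputs for one series.

    Position ``n`` fits the subspace on the ``N - M + 1`` base vectors
    starting at ``n`` and tests the next ``q`` vectors (test vector ``j``
    ends at sample ``n + N + j``).  Returns ``S`` (mean normalized test
    distance per position, length n_pos) and the (n_pos x q) matrix of
    per-vector normalized distances.
    """
    T = x.size
    N, M, q = cfg.N, cfg.M, cfg.q
    n_pos = T - N - q + 1
    if n_pos < 1:
        raise ValueError(f"series too short: need T >= {N + q}, got {T}")
    V = sliding_window_view(x, M).T  # (M, T - M + 1)
    norms2 = np.einsum("ij,ij->j", V, V)
    n_base = N - M + 1
    S = np.zeros(n_pos)
    per_vec = np.zeros((n_pos, q))
    d_base_means = np.zeros(n_pos)
    d_tests = np.zeros((n_pos, q))
    degenerate = np.zeros(n_pos, dtype=bool)
    for n in range(n_pos):
        B = V[:, n : n + n_base]
        R = B @ B.T
        evals, evecs = eigh(R)
        evals = np.clip(evals[::-1], 0.0, None)
        evecs = evecs[:, ::-1]
        total = evals.sum()
        if total <= 1e-300:
            degenerate[n] = True
            continue
        if cfg.l is not None:
            l = min(cfg.l, M - 1)
        else:
            share = np.cumsum(evals) / total
            l = int(np.searchsorted(share, cfg.variance_fraction - 1e-12) + 1)
        U = evecs[:, :l]
        proj_b = U.T @ B
        d_base = norms2[n : n + n_base] - np.einsum("ij,ij->j", proj_b, proj_b)
        d_base_means[n] = max(float(d_base.mean()), 0.0)
        if d_base_means[n] <= 1e-12 * max(total, 1.0):
            degenerate[n] = True
            continue
        Tst = V[:, n + n_base : n + n_base + q]
        proj_t = U.T @ Tst
        d_tests[n] = np.clip(
            norms2[n + n_base : n + n_base + q]
            - np.einsum("ij,ij->j", proj_t, proj_t),
            0.0,
            None,
        )
    ok = ~degenerate
    if degenerate.any():
        warnings.warn("degenerate (zero-variance) base window: statistic set to 0")
    if ok.any():
        # floor the denominator at half the series-typical base residual so a
        # locally quiet base window cannot inflate the normalized distances
        floor = 0.5 * float(np.median(d_base_means[ok]))
        denom = np.maximum(d_base_means, floor)
        for n in np.nonzero(ok)[0]:
            per_vec[n] = d_tests[n] / denom[n]
            S[n] = float(d_tests[n].mean() / denom[n])
    return S, per_vec


def _per_sample_score(
    per_vec: np.ndarray, cfg: CPDConfig, T: int, n_min: int = 0
) -> np.ndarray:
    """Median of each sample's normalized vector distance over its test views.

    Test vector ``j`` at position ``n`` ends at sample ``n + N + j``; the
    score of sample ``s`` pools ``per_vec[n, j]`` over all views with
    ``n >= n_min`` (the median resists occasional badly fit base windows).
    Samples with no view get NaN.
    """
    n_pos, q = per_vec.shape
    views: list[list[float]] = [[] for _ in range(T)]
    for n in range(n_min, n_pos):
        for j in range(q):
            views[n + cfg.N + j].append(per_vec[n, j])
    min_views = min(q, max(3, q // 2))
    return np.array(
        [np.median(v) if len(v) >= min_views else np.nan for v in views]
    )


def _phase_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate: same power spectrum, stationarized."""
    T = x.size
    mu = x.mean()
    spec = np.fft.rfft(x - mu)
    phases = rng.uniform(0.0, 2 * np.pi, size=spec.size)
    phases[0] = 0.0
    if T % 2 == 0:
        phases[-1] = 0.0
    return mu + np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=T)


def _cusum(S: np.ndarray, drift: float) -> np.ndarray:
    W = np.zeros(S.size)
    acc = 0.0
    for n, s in enumerate(S):
        acc = max(0.0, acc + s - drift)
        W[n] = acc
    return W


def detect_change_points(
    series: np.ndarray,
    config: CPDConfig | None = None,
    gene_id: str = "series",
) -> CPDResult:
    """Sequential subspace-distance CUSUM detection on one series.

    The drift of the CUSUM increment and the threshold ``h`` (unless fixed
    in the config) are calibrated on phase-randomized surrogates of the same
    series: ``h`` is the largest surrogate maximum statistic, an exact
    1/(n_surrogates + 1) false-alarm level on stationary data.  After a
    crossing, the change time is the first sample of the triggering
    excursion whose per-sample score exceeds the surrogate
    ``onset_quantile`` for two consecutive samples; detection then re-arms
    ``N`` samples later and scanning resumes with a fresh base window just
    past the change.
    """
    cfg = config or CPDConfig()
    x = np.asarray(series, dtype=float)
    if x.size < 2 * cfg.N:
        raise ValueError(f"series too short: need T >= {2 * cfg.N}")
    T = x.size
    rng = np.random.default_rng(cfg.seed)
    W_abs = np.zeros(T)
    taus: list[int] = []
    first_h = None
    first_drift = None
    segment_start = 0
    while T - segment_start >= max(2 * cfg.N, cfg.N + cfg.q + 1):
        seg = x[segment_start:]
        S, per_vec = _distance_trace(seg, cfg)
        if cfg.n_surrogates > 0:
            sur_S = [
                _distance_trace(_phase_surrogate(seg, rng), cfg)[0]
                for _ in range(cfg.n_surrogates)
            ]
            all_sur = np.concatenate(sur_S)
            drift = float(all_sur.mean() + 0.5 * all_sur.std() + cfg.kappa)
            h = cfg.h if cfg.h is not None else max(
                float(max(_cusum(s_i, drift).max() for s_i in sur_S)), 1e-6
            )
        else:
            drift = 1.0 + cfg.kappa
            if cfg.h is None:
                raise ValueError("explicit h required when n_surrogates == 0")
            h = cfg.h
        if first_h is None:
            first_h, first_drift = h, drift
        crossing = None
        acc = 0.0
        excursion_start = 0
        W = np.zeros(S.size)
        for n in range(S.size):
            prev = acc
            acc = max(0.0, acc + S[n] - drift)
            W[n] = acc
            if acc > 0.0 and prev == 0.0:
                excursion_start = n
            if acc > h:
                crossing = n
                break
        W_abs[segment_start : segment_start + W.size] = np.maximum(
            W_abs[segment_start : segment_start + W.size], W
        )
        if crossing is None:
            break
        # narrow the span to the sustained rise: last near-zero W wins
        start = excursion_start
        for m in range(crossing - 1, excursion_start - 1, -1):
            if W[m] <= 0.1 * h:
                start = m + 1
                break
        tau_rel = _locate_onset(
            per_vec, start, crossing, segment_start, cfg, seg.size, drift
        )
        if tau_rel is None:
            # change lies in the segment's blind start and cannot be timed;
            # skip past the elevated region without reporting it
            segment_start = segment_start + cfg.N
            continue
        tau = segment_start + tau_rel
        if tau >= T:
            break
        taus.append(tau)
        # re-arm: the next segment starts just past the change, and its own
        # first N samples are blind, so detections are >= tau + N apart
        segment_start = tau + 1
    return CPDResult(
        gene_id=gene_id,
        W=W_abs,
        threshold=first_h if first_h is not None else float(cfg.h or 0.0),
        change_points=taus,
        drift=first_drift if first_drift is not None else 0.0,
    )


def _locate_onset(
    per_vec: np.ndarray,
    n_start: int,
    n_cross: int,
    segment_start: int,
    cfg: CPDConfig,
    T_seg: int,
    drift: float,
) -> int | None:
    """Refine the change time inside the excursion ending at ``n_cross``.

    On the per-sample score the split point maximizing the mean-after minus
    mean-before contrast marks the new regime; the reported change time
    backtracks along the contiguous elevated run, which corrects for the
    ramp the embedding window spreads the jump over.  Returns None when the
    span is elevated from its first observable sample in a post-detection
    segment: the change then lies in the segment's blind start and cannot
    be timed.  Falls back to the first test sample of the crossing
    position.
    """
    score = _per_sample_score(per_vec, cfg, T_seg)
    s_lo = n_start + cfg.N
    s_hi = min(n_cross + cfg.N + cfg.q - 1, T_seg - 1)
    w = cfg.locate_window
    best: tuple[float, int, float, float] | None = None
    for s in range(s_lo, s_hi + 1):
        pre = score[max(s - w, cfg.N) : s]
        post = score[s : min(s + w, T_seg)]
        pre = pre[np.isfinite(pre)]
        post = post[np.isfinite(post)]
        if pre.size < 3 or post.size < 3:
            continue
        contrast = float(post.mean() - pre.mean())
        if best is None or contrast > best[0]:
            best = (contrast, s, float(pre.mean()), float(post.mean()))
    if best is None:
        return min(n_cross + cfg.N, T_seg - 1)
    _, s_star, m_pre, m_post = best
    if segment_start > 0 and m_pre > 2.0 * drift:
        return None
    # onset threshold: a fraction of the contrast, capped near the null level
    # so strong responses do not stop the backtrack high up the ramp
    thr = m_pre + min(cfg.onset_fraction * (m_post - m_pre), drift)
    # walk left from the split while the score stays elevated (contiguous run)
    s = s_star
    while s - 1 >= s_lo and np.isfinite(score[s - 1]) and score[s - 1] > thr:
        s -= 1
    return s


def detect_panel(
    matrix: ExpressionMatrix,
    config: CPDConfig | None = None,
    log_transform: bool = True,
) -> list[CPDResult]:
    """Run per-gene detection across a panel (on log fold change by default)."""
    cfg = config or CPDConfig()
    results = []
    for i, gene in enumerate(matrix.genes):
        x = matrix.values[i]
        if log_transform:
            x = np.log(x)
        gene_cfg = replace(cfg, seed=cfg.seed + 104729 * (i + 1))
        results.append(detect_change_points(x, gene_cfg, gene_id=gene))
    return results


def aggregate_change_points(
    results: list[CPDResult],
    T: int,
    t0: float = 0.5,
    dt: float = 0.5,
    n_peaks: int = 3,
    min_separation: int = 5,
) -> PhaseSegmentation:
    """Per-sample detection counts, peak boundaries, cumulative windows.

    ``counts[t]`` is the number of genes with a change point at sample t.
    Boundaries are the ``n_peaks`` largest local maxima of the
    lightly pooled counts (each sample plus half its immediate neighbours,
    so one-sample jitter across genes does not split a peak) with a minimum
    separation (default 5 samples = 2.5 h), reported in time order;
    cumulative intervals run from the grid start to each boundary.
    """
    counts = np.zeros(T, dtype=int)
    for r in results:
        for tau in r.change_points:
            if 0 <= tau < T:
                counts[tau] += 1
    # +-1 pooling: per-gene change-time jitter of a sample must not split
    # one boundary's cluster into competing peaks
    kernel = np.array([0.5, 1.0, 0.5])
    pooled = np.convolve(counts.astype(float), kernel, mode="same")
    peaks, props = find_peaks(pooled, distance=min_separation, height=0.99)
    if peaks.size == 0:
        warnings.warn("no change-point peaks found")
        chosen: list[int] = []
    else:
        order = np.argsort(-props["peak_heights"], kind="stable")
        chosen = sorted(int(peaks[i]) for i in order[:n_peaks])
        if len(chosen) < n_peaks:
            warnings.warn(f"only {len(chosen)} peaks found (requested {n_peaks})")
    hours = [t0 + dt * s for s in chosen]
    intervals = [(t0, b) for b in hours]
    return PhaseSegmentation(
        counts=counts,
        boundaries_samples=chosen,
        boundaries_hours=hours,
        intervals=intervals,
        t0=t0,
        dt=dt,
    )
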