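"""Synthetic time-course generators with ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes: a
panel of ~20-60 genes sampled every half hour over about two cell cycles,
piecewise-stationary linear dynamics whose parameters change at a few regime
boundaries, sparse lagged cross-gene dependencies, and multiplicative
fold-change noise (dynamics are simulated in log space and exponentiated so
fold-change positivity holds).  Every scenario returns a ``GroundTruth``
sufficient to score the downstream stages without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, ExpressionProfile

__all__ = [
    "VARSpec",
    "GroundTruth",
    "companion_spectral_radius",
    "simulate_var",
    "make_sparse_spec",
    "make_regime_specs",
    "simulate_three_regime_panel",
    "simulate_two_cycle_profiles",
    "make_reference_network",
    "make_module_map",
    "mef_like_scenario",
]

# Reactome-style process names used for synthetic module maps (chronological).
PROCESS_NAMES = [
    "Mitogenic signalling",
    "G1 cyclin expression",
    "Rb phosphorylation",
    "E2F transcriptional activation",
    "G1/S transition",
    "Pre-replicative complex assembly",
    "Origin licensing",
    "DNA replication initiation",
    "DNA synthesis elongation",
    "Intra-S checkpoint",
    "G2/M DNA replication checkpoint",
    "G2/M transition",
    "Mitotic spindle assembly",
    "Spindle assembly checkpoint",
    "Sister chromatid segregation",
    "Mitotic exit",
]


@dataclass
class VARSpec:
    """Parameters of a k-variable VAR(d) process.

    ``A[l-1][i, j]`` is the effect of variable j at lag l on variable i.
    Stationarity (companion spectral radius < 1) is enforced at construction
    for simulation use.
    """

    k: int
    d: int
    A: list[np.ndarray]
    v: np.ndarray | None = None
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        if len(self.A) != self.d or any(a.shape != (self.k, self.k) for a in self.A):
            raise ValueError("A must hold d matrices of shape (k, k)")
        if self.v is None:
            self.v = np.zeros(self.k)
        self.v = np.asarray(self.v, dtype=float)
        rho = companion_spectral_radius(self.A)
        if rho >= 1.0:
            raise ValueError(f"non-stationary VAR spec (companion radius {rho:.3f})")

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.A)

    def edges(self) -> set[tuple[int, int, int]]:
        """Off-diagonal support as (source j, target i, lag l) triples."""
        out = set()
        for l, a in enumerate(self.A, start=1):
            ii, jj = np.nonzero(a)
            for i, j in zip(ii, jj):
                if i != j:
                    out.add((int(j), int(i), l))
        return out


@dataclass
class GroundTruth:
    """What the generator knows: breaks, edges, orders, cycle offset."""

    change_points: list[int] = field(default_factory=list)
    edges: set[tuple[int, int, int]] = field(default_factory=set)
    orders: dict[int, int] = field(default_factory=dict)
    cycle_offset: int | None = None
    affected: dict[int, list[int]] = field(default_factory=dict)
    latent: np.ndarray | None = None


def companion_spectral_radius(A: list[np.ndarray]) -> float:
    """Spectral radius of the (k d x k d) companion matrix of a VAR(d)."""
    A = [np.asarray(a, dtype=float) for a in A]
    k, d = A[0].shape[0], len(A)
    C = np.zeros((k * d, k * d))
    C[:k] = np.hstack(A)
    if d > 1:
        C[k:, : k * (d - 1)] = np.eye(k * (d - 1))
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def simulate_var(
    spec: VARSpec,
    T: int,
    seed: int,
    burn_in: int | None = None,
    snr: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Iterate the VAR recursion and return a (k x T) matrix plus truth.

    ``burn_in`` (default 10 d, minimum enforced) initial samples are
    discarded so the output starts near the stationary distribution.  With
    ``snr`` set, iid Gaussian measurement noise with standard deviation
    sd(series)/snr is added after simulation.  Bit-reproducible per seed.
    """
    if burn_in is None:
        burn_in = 10 * spec.d
    if burn_in < 10 * spec.d:
        raise ValueError("burn_in must be at least 10 * d")
    rng = np.random.default_rng(seed)
    total = T + burn_in
    x = np.zeros((spec.k, total + spec.d))
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.k, total))
    for t in range(total):
        acc = spec.v + eps[:, t]
        for l, a in enumerate(spec.A, start=1):
            acc = acc + a @ x[:, spec.d + t - l]
        x[:, spec.d + t] = acc
    out = x[:, spec.d + burn_in :].copy()
    if snr is not None:
        sd = out.std(axis=1, keepdims=True)
        out = out + rng.normal(0.0, 1.0, size=out.shape) * (sd / snr)
    truth = GroundTruth(
        edges=spec.edges(), orders={i: spec.d for i in range(spec.k)}
    )
    return out, truth


def make_sparse_spec(
    k: int,
    d: int,
    density: float,
    magnitude_range: tuple[float, float] = (0.25, 0.6),
    seed: int = 0,
    diagonal: float = 0.0,
    target_radius: float = 0.95,
    noise_sd: float = 1.0,
) -> VARSpec:
    """Random stationary sparse VAR spec with exact off-diagonal support size.

    Exactly ``round(density * k**2 * d)`` off-diagonal coefficients are
    placed uniformly at random with random signs and magnitudes drawn from
    ``magnitude_range``; optional lag-1 diagonal terms of size ``diagonal``
    add autoregressive persistence.  If needed, lag matrices are rescaled
    (A_l by c**l, which scales companion eigenvalues by c exactly) so the
    spectral radius is at most ``target_radius``; the default magnitude
    range keeps the raw radius near the cap so rescaling stays mild and the
    placed coefficients keep their drawn scale.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_nz = int(round(density * k * k * d))
    slots = [(l, i, j) for l in range(d) for i in range(k) for j in range(k) if i != j]
    if n_nz > len(slots):
        raise ValueError("density too high for off-diagonal placement")
    chosen = rng.choice(len(slots), size=n_nz, replace=False)
    A = [np.zeros((k, k)) for _ in range(d)]
    for idx in chosen:
        l, i, j = slots[idx]
        mag = rng.uniform(*magnitude_range)
        A[l][i, j] = mag * rng.choice([-1.0, 1.0])
    A[0][np.arange(k), np.arange(k)] = diagonal
    rho = companion_spectral_radius(A)
    if rho > target_radius:
        c = target_radius / rho
        A = [a * c ** (l + 1) for l, a in enumerate(A)]
    return VARSpec(k=k, d=d, A=A, noise_sd=noise_sd)


FREQUENCY_LADDER = (0.35, 1.25, 2.1)  # rad/sample, pairwise separation >= 0.85


def make_regime_specs(
    k: int,
    n_regimes: int,
    seed: int = 0,
    affected_fraction: float = 0.6,
    r_pole: float = 0.95,
    coupling_density: float = 0.0,
    noise_sd: float = 0.15,
    mean_jump: float = 0.8,
) -> tuple[list[VARSpec], dict[int, list[int]]]:
    """Per-regime VAR(2) oscillator specs with gene-wise regime switches.

    Each gene follows a damped AR(2) oscillator x_t = 2 r cos(w) x_{t-1}
    - r^2 x_{t-2} + e_t.  At each regime boundary a random subset of genes
    (at least 40%, expected ``affected_fraction``) hops its frequency w to a
    different rung of a fixed well-separated ladder and shifts its
    stationary mean by ``mean_jump`` stationary standard deviations (phase
    transitions change both expression level and dynamics).  Successive
    boundaries preferentially engage genes quiescent at the previous one,
    mirroring how cell-cycle phases activate largely distinct gene
    programs.  Optionally a sparse set of cross-gene lag-1 couplings is
    added (shared across regimes).

    Returns the specs plus ``affected[boundary_index] -> list of genes``.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(FREQUENCY_LADDER)
    rung = rng.integers(0, levels.size, size=k)
    rungs = [rung.copy()]
    means = [np.zeros(k)]
    affected: dict[int, list[int]] = {}
    prev: set[int] = set()
    for r in range(1, n_regimes):
        n_aff = max(int(np.ceil(0.4 * k)), int(round(affected_fraction * k)))
        n_aff = min(n_aff, k)
        fresh = rng.permutation([g for g in range(k) if g not in prev])
        stale = rng.permutation([g for g in range(k) if g in prev])
        genes = sorted(np.concatenate([fresh, stale])[:n_aff].astype(int).tolist())
        affected[r - 1] = genes
        prev = set(genes)
        new = rungs[-1].copy()
        mu = means[-1].copy()
        for g in genes:
            others = [i for i in range(levels.size) if i != new[g]]
            new[g] = others[rng.integers(0, len(others))]
            mu[g] = mu[g] + mean_jump * 0.4 * rng.choice([-1.0, 1.0])
        rungs.append(new)
        means.append(mu)
    coupling = np.zeros((k, k))
    if coupling_density > 0:
        slots = [(i, j) for i in range(k) for j in range(k) if i != j]
        n_c = int(round(coupling_density * k * k))
        for idx in rng.choice(len(slots), size=min(n_c, len(slots)), replace=False):
            i, j = slots[idx]
            coupling[i, j] = rng.uniform(0.25, 0.45) * rng.choice([-1.0, 1.0])
    specs = []
    for rg, mu in zip(rungs, means):
        om = levels[rg]
        A1 = np.diag(2 * r_pole * np.cos(om)) + coupling
        A2 = np.diag(np.full(k, -(r_pole**2)))
        rho = companion_spectral_radius([A1, A2])
        if rho > 0.97:
            c = 0.97 / rho
            A1, A2 = A1 * c, A2 * c * c
        v = (np.eye(k) - A1 - A2) @ mu  # stationary mean of the regime is mu
        specs.append(VARSpec(k=k, d=2, A=[A1, A2], v=v, noise_sd=noise_sd))
    return specs, affected


def simulate_three_regime_panel(
    k: int,
    boundaries: list[int],
    specs: list[VARSpec],
    noise_sd: float | None = None,
    seed: int = 0,
    T: int = 96,
    log_amplitude: float = 1.0,
    t0: float = 0.5,
    dt: float = 0.5,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Piecewise-stationary panel with state carry-over at regime boundaries.

    ``boundaries`` are the sample indices where the generating VAR spec
    switches (len(specs) == len(boundaries) + 1).  Each regime's intercept
    is realized as its implied stationary mean, applied as an instantaneous
    level shift, while the zero-mean deviation process carries its state
    across the boundary; this keeps each regime exactly stationary from its
    first sample.  The latent log series is exponentiated into positive
    fold-change space (baseline ~ 1) so the preprocessing stage applies
    unchanged.  ``noise_sd`` overrides every spec's innovation scale.
    """
    if len(specs) != len(boundaries) + 1:
        raise ValueError("need one spec per regime (len(boundaries) + 1)")
    if sorted(boundaries) != list(boundaries) or len(set(boundaries)) != len(boundaries):
        raise ValueError("boundaries must be strictly increasing")
    if boundaries and (boundaries[0] <= 0 or boundaries[-1] >= T):
        raise ValueError("boundaries must lie strictly inside (0, T)")
    rng = np.random.default_rng(seed)
    d_max = max(s.d for s in specs)
    starts = [0] + list(boundaries)
    ends = list(boundaries) + [T]
    means = []
    for spec in specs:
        A_sum = np.sum(spec.A, axis=0)
        means.append(np.linalg.solve(np.eye(k) - A_sum, spec.v))
    z = np.zeros((k, T + d_max))  # zero-mean deviation process
    # burn in the first regime so the panel starts stationary
    spec0 = specs[0]
    burn = 10 * spec0.d + 20
    state = np.zeros((k, d_max))
    for t in range(burn):
        acc = rng.normal(0.0, noise_sd if noise_sd is not None else spec0.noise_sd, size=k)
        for l, a in enumerate(spec0.A, start=1):
            acc = acc + a @ state[:, -l]
        state = np.column_stack([state[:, 1:], acc])
    z[:, :d_max] = state[:, -d_max:]
    latent = np.zeros((k, T))
    for spec, mu, s, e in zip(specs, means, starts, ends):
        sd = noise_sd if noise_sd is not None else spec.noise_sd
        for t in range(s, e):
            acc = rng.normal(0.0, sd, size=k)
            for l, a in enumerate(spec.A, start=1):
                acc = acc + a @ z[:, d_max + t - l]
            z[:, d_max + t] = acc
            latent[:, t] = acc + mu
    fold = np.exp(log_amplitude * latent)
    genes = [f"g{i:02d}" for i in range(k)]
    matrix = ExpressionMatrix(genes, fold, t0=t0, dt=dt, baseline_columns=[0])
    edges = set().union(*(s.edges() for s in specs))
    truth = GroundTruth(change_points=list(boundaries), edges=edges, latent=latent)
    return matrix, truth


def simulate_two_cycle_profiles(
    length: int,
    offset: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    smooth_sigma: float = 2.0,
) -> tuple[ExpressionProfile, ExpressionProfile, GroundTruth]:
    """Two noisy recordings of one periodic waveform, the second delayed.

    The base waveform is circularly smoothed unit-variance noise with period
    ``length``; ``cycle2[t] = w[(t - offset) mod length] + noise``, so the
    first ``offset`` samples of cycle2 replay the tail of cycle1 and the
    true full-length series (ground truth ``latent``) has
    ``2 * length - offset`` samples.
    """
    if abs(offset) >= length // 2:
        raise ValueError("|offset| must be < length / 2")
    rng = np.random.default_rng(seed)
    white = rng.normal(size=length)
    # periodic Gaussian smoothing via circular convolution
    idx = np.arange(length)
    dist = np.minimum(idx, length - idx)
    kernel = np.exp(-0.5 * (dist / smooth_sigma) ** 2)
    kernel /= kernel.sum()
    w = np.real(np.fft.ifft(np.fft.fft(white) * np.fft.fft(kernel)))
    w = (w - w.mean()) / w.std()
    c1 = w + rng.normal(0.0, noise_sd, size=length)
    c2 = np.roll(w, offset) + rng.normal(0.0, noise_sd, size=length)
    full = w[np.arange(2 * length - max(offset, 0)) % length]
    p1 = ExpressionProfile("cycle1", np.exp(0.3 * c1), t0=0.5, dt=0.5)
    p2 = ExpressionProfile("cycle2", np.exp(0.3 * c2), t0=0.5, dt=0.5)
    truth = GroundTruth(cycle_offset=offset, latent=np.exp(0.3 * full))
    return p1, p2, truth


def make_reference_network(
    truth: GroundTruth,
    genes: list[str],
    drop_fraction: float = 0.0,
    spurious_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """STRING-style reference edge list derived from ground-truth edges.

    True (source, target) pairs minus a random ``drop_fraction``, plus
    ``spurious_fraction`` (of the true pair count) random non-edges.
    Returned as a two-column DataFrame of gene ids (undirected semantics).
    """
    if not 0 <= drop_fraction < 1 or not 0 <= spurious_fraction < 1:
        raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pairs = sorted({(genes[j], genes[i]) for (j, i, _l) in truth.edges})
    keep = [p for p in pairs if rng.random() >= drop_fraction]
    existing = {frozenset(p) for p in pairs}
    n_spurious = int(round(spurious_fraction * len(pairs)))
    spurious: list[tuple[str, str]] = []
    while len(spurious) < n_spurious:
        a, b = rng.choice(len(genes), size=2, replace=False)
        pair = (genes[a], genes[b])
        if frozenset(pair) not in existing:
            existing.add(frozenset(pair))
            spurious.append(pair)
    rows = keep + spurious
    return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


def make_module_map(genes: list[str], n_modules: int = 4) -> pd.DataFrame:
    """Round-robin assignment of genes to chronologically ordered processes."""
    n_modules = min(n_modules, len(PROCESS_NAMES), len(genes))
    names = PROCESS_NAMES[:n_modules]
    rows = [(g, names[i % n_modules]) for i, g in enumerate(genes)]
    return pd.DataFrame(rows, columns=["gene_id", "process"])


def mef_like_scenario(
    k: int = 20,
    T: int = 96,
    boundaries: tuple[int, ...] = (30, 50, 58),
    seed: int = 0,
    coupling_density: float = 0.05,
    noise_sd: float = 0.15,
    n_modules: int = 4,
) -> dict:
    """Flagship end-to-end scenario mirroring the study's data shape.

    k genes x T half-hour samples, piecewise-stationary oscillator dynamics
    with three regime boundaries, sparse cross-gene couplings, multiplicative
    fold-change noise, a module map and a corrupted reference edge list.
    """
    specs, affected = make_regime_specs(
        k, len(boundaries) + 1, seed=seed, coupling_density=coupling_density,
        noise_sd=noise_sd,
    )
    matrix, truth = simulate_three_regime_panel(
        k, list(boundaries), specs, seed=seed + 1, T=T
    )
    truth.affected = affected
    modules = make_module_map(matrix.genes, n_modules=n_modules)
    reference = make_reference_network(
        truth, matrix.genes, drop_fraction=0.2, spurious_fraction=0.2, seed=seed + 2
    )
    return {
        "matrix": matrix,
        "truth": truth,
        "specs": specs,
        "modules": modules,
        "reference": reference,
    }
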