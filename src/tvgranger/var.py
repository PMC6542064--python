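"""Sparse VAR / Granger inference: LASSO paths, ES-CV selection, MDL order.

Each target gene i is regressed on the lagged history of all genes,
y_i = phi x_i + e, where row t of the design phi is
(1, y(t-1), ..., y(t-d)).  The coefficient vector is estimated on a LASSO
path; the regularization weight is chosen by estimation stability with
cross validation (ES-CV): among the local minima of the normalized
across-fold variance of the fitted values ES(lambda), take the smallest
lambda at or above the one-standard-error cross-validation choice.  The VAR
order d is chosen per target by minimum description length,
DL = (T/2) log RSS + (d/2) log T, over d = 1..d_max on a common effective
sample.  A nonzero penalized coefficient a_ijl is the operational Granger
edge from gene j to gene i at lag l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import lasso_path as _sk_lasso_path

from .preprocess import ExpressionMatrix

__all__ = [
    "VARConfig",
    "DesignSystem",
    "RegularizationPath",
    "ESCVSelection",
    "OrderSelection",
    "SparseVARFit",
    "build_design",
    "lasso_path",
    "cross_validate",
    "es_metric",
    "select_lambda_escv",
    "description_length",
    "select_order",
    "fit_target",
    "fit_window",
]


@dataclass
class VARConfig:
    """Fitting choices for one target regression.

    d_max : maximum VAR order screened by MDL (9 lags = 4.5 h).
    n_lambdas, lambda_min_ratio : geometric grid from lambda_max down.
    V : cross-validation fold count (random folds; ``contiguous_folds``
        switches to time-contiguous blocks).
    rss_source : "escv" scores each order by its ES-CV LASSO fit (coherent
        with the final model); "ols" uses ordinary least squares instead.
    order : fix the VAR order and skip MDL screening entirely.
    """

    d_max: int = 9
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    V: int = 10
    seed: int = 0
    rss_source: str = "escv"
    order: int | None = None
    contiguous_folds: bool = False
    tol: float = 1e-9
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.rss_source not in ("escv", "ols"):
            raise ValueError("rss_source must be 'escv' or 'ols'")
        if self.V < 2:
            raise ValueError("V must be >= 2")


@dataclass
class DesignSystem:
    """Stacked lagged regression for one window.

    ``phi`` has T_eff = (samples in window) - d rows; row t is the intercept
    1 followed by all genes at lag 1, then lag 2, ..., lag d.  ``targets``
    holds the length-T_eff response for every gene (column i is y_i).
    """

    phi: np.ndarray
    targets: np.ndarray
    genes: list[str]
    d: int

    @property
    def T_eff(self) -> int:
        return int(self.phi.shape[0])

    @property
    def k(self) -> int:
        return len(self.genes)

    def y(self, gene: str | int) -> np.ndarray:
        i = gene if isinstance(gene, int) else self.genes.index(gene)
        return self.targets[:, i]

    def column_label(self, c: int) -> tuple[str, int] | str:
        """(source gene, lag) for penalized column c; 'intercept' for c=0."""
        if c == 0:
            return "intercept"
        lag, j = divmod(c - 1, self.k)
        return self.genes[j], lag + 1


@dataclass
class RegularizationPath:
    lambdas: np.ndarray          # decreasing, lambda_max first
    coefficients: np.ndarray     # (n_lambdas, k d + 1); column 0 = intercept
    nnz: np.ndarray


@dataclass
class ESCVSelection:
    lambdas: np.ndarray
    lambda_cv: float
    lambda_escv: float
    es_curve: np.ndarray
    cv_mse: np.ndarray
    idx_cv: int
    idx_escv: int
    local_minima: list[int]
    folds: list[np.ndarray]


@dataclass
class OrderSelection:
    orders: np.ndarray
    rss: np.ndarray
    dl: np.ndarray
    d_opt: int


@dataclass
class SparseVARFit:
    """Selected sparse lagged regression for one target gene."""

    gene_id: str
    d_opt: int
    lambda_cv: float
    lambda_escv: float
    intercept: float
    coefficients: dict[tuple[str, int], float] = field(default_factory=dict)
    nnz_cv: int = 0
    nnz_escv: int = 0
    order_selection: OrderSelection | None = None

    @property
    def nnz(self) -> int:
        return len(self.coefficients)


def build_design(
    matrix: ExpressionMatrix,
    d: int,
    window: tuple[float, float] | None = None,
    first_target: int | None = None,
) -> DesignSystem:
    """Lagged design over a time window (hours, inclusive).

    ``first_target`` overrides the first predicted sample index (relative to
    the window) so designs for different orders can share one effective
    sample; by default it is ``d``.
    """
    sub = matrix if window is None else matrix.window(*window)
    vals = sub.values
    T = vals.shape[1]
    ft = d if first_target is None else first_target
    if ft < d:
        raise ValueError("first_target must be >= d")
    if T - ft < 2:
        raise ValueError(
            f"window too short: need at least {ft + 2} samples, got {T}"
        )
    rows = T - ft
    k = vals.shape[0]
    phi = np.empty((rows, k * d + 1))
    phi[:, 0] = 1.0
    for l in range(1, d + 1):
        phi[:, 1 + (l - 1) * k : 1 + l * k] = vals[:, ft - l : T - l].T
    targets = vals[:, ft:].T.copy()
    return DesignSystem(phi=phi, targets=targets, genes=list(sub.genes), d=d)


def _lambda_grid(phi: np.ndarray, y: np.ndarray, cfg: VARConfig) -> np.ndarray:
    Xc = phi[:, 1:] - phi[:, 1:].mean(axis=0)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xc.T @ yc)))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def lasso_path(
    phi: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    config: VARConfig | None = None,
) -> RegularizationPath:
    """LASSO path for min 1/2 ||y - phi x||^2 + lambda ||x_pen||_1.

    Column 0 of ``phi`` is an unpenalized intercept, handled exactly by
    centering the remaining columns and the response (the lagged predictor
    columns already share the fold-change scale, so no further rescaling
    touches the stated objective).  At the head of the grid
    (lambda >= lambda_max) all penalized coefficients are exactly zero.
    """
    cfg = config or VARConfig()
    if lambdas is None:
        lambdas = _lambda_grid(phi, y, cfg)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0) or np.any(lambdas <= 0):
        raise ValueError("lambda grid must be positive and decreasing")
    n = phi.shape[0]
    X = phi[:, 1:]
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    y_mean = y.mean()
    yc = y - y_mean
    # sklearn objective is (1/2n)||.||^2 + alpha ||.||_1
    alphas = lambdas / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = _sk_lasso_path(
            Xc, yc, alphas=alphas, tol=cfg.tol, max_iter=cfg.max_iter
        )
    coefs = coefs.T  # (n_lambdas, p)
    intercepts = y_mean - coefs @ x_mean
    out = np.column_stack([intercepts, coefs])
    nnz = (np.abs(coefs) > 0).sum(axis=1)
    return RegularizationPath(lambdas=lambdas, coefficients=out, nnz=nnz)


def _make_folds(n: int, cfg: VARConfig) -> list[np.ndarray]:
    if cfg.V > n:
        raise ValueError("more folds than samples")
    idx = np.arange(n)
    if not cfg.contiguous_folds:
        idx = np.random.default_rng(cfg.seed).permutation(n)
    return [np.sort(f) for f in np.array_split(idx, cfg.V)]


def escv_select(
    phi: np.ndarray,
    y: np.ndarray,
    config: VARConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> tuple[ESCVSelection, RegularizationPath]:
    """One pass of CV and estimation stability over a shared lambda grid.

    The V held-out groups give both the per-lambda prediction error (the CV
    choice is the largest lambda within one standard error of the minimum
    mean error) and the V pseudo solutions whose full-design fitted values
    feed the ES metric.  The ES-CV lambda is the smallest local minimum of
    ES(lambda) at or above lambda_cv, falling back to lambda_cv when no such
    minimum exists.
    """
    cfg = config or VARConfig()
    if lambdas is None:
        lambdas = _lambda_grid(phi, y, cfg)
    full = lasso_path(phi, y, lambdas, cfg)
    n = phi.shape[0]
    folds = _make_folds(n, cfg)
    fold_mse = np.empty((cfg.V, lambdas.size))
    yhat = np.empty((cfg.V, n, lambdas.size))
    for j, hold in enumerate(folds):
        train = np.setdiff1d(np.arange(n), hold)
        sub = lasso_path(phi[train], y[train], lambdas, cfg)
        pred_all = phi @ sub.coefficients.T  # (n, n_lambdas)
        yhat[j] = pred_all
        err = pred_all[hold] - y[hold, None]
        fold_mse[j] = np.mean(err**2, axis=0)
    mse = fold_mse.mean(axis=0)
    idx_min = int(np.argmin(mse))
    se = float(fold_mse[:, idx_min].std(ddof=1) / np.sqrt(cfg.V))
    within = np.where(mse <= mse[idx_min] + se)[0]
    idx_cv = int(within[0])  # grid is decreasing: first index = largest lambda
    es = es_metric(yhat)
    nnz_fold_any = (np.abs(full.coefficients[:, 1:]) > 0).any(axis=1)
    minima = _local_minima(es, valid=nnz_fold_any)
    above = [i for i in minima if i <= idx_cv]
    idx_escv = max(above) if above else idx_cv  # smallest lambda >= lambda_cv
    sel = ESCVSelection(
        lambdas=lambdas,
        lambda_cv=float(lambdas[idx_cv]),
        lambda_escv=float(lambdas[idx_escv]),
        es_curve=es,
        cv_mse=mse,
        idx_cv=idx_cv,
        idx_escv=idx_escv,
        local_minima=minima,
        folds=folds,
    )
    return sel, full


def cross_validate(
    phi: np.ndarray,
    y: np.ndarray,
    config: VARConfig | None = None,
    lambdas: np.ndarray | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Seeded V-fold CV with the one-standard-error rule.

    Returns (lambda_cv, fold index arrays).  Same seed, same folds, same
    choice.
    """
    sel, _ = escv_select(phi, y, config, lambdas)
    return sel.lambda_cv, sel.folds


def es_metric(yhat: np.ndarray) -> np.ndarray:
    """Estimation-stability curve from pseudo fitted values.

    ``yhat`` has shape (V, n, n_lambdas): the full-design fitted values of
    each fold's pseudo solution.  ES(lambda) is the mean squared deviation
    of the V fits around their mean, divided by the squared norm of the mean
    fit; a zero mean fit yields +inf.
    """
    if yhat.shape[0] < 2:
        raise ValueError("need >= 2 pseudo solutions")
    mean_fit = yhat.mean(axis=0)  # (n, n_lambdas)
    var = np.mean(np.sum((yhat - mean_fit[None]) ** 2, axis=1), axis=0)
    norm = np.sum(mean_fit**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        es = np.where(norm > 0, var / np.where(norm > 0, norm, 1.0), np.inf)
    return es


def _local_minima(es: np.ndarray, valid: np.ndarray | None = None) -> list[int]:
    """Interior local minima of the ES curve (indices on the lambda grid).

    Indices where the fit is identically null (no nonzero penalized
    coefficient) are excluded: there ES is trivially zero.
    """
    out = []
    for i in range(1, es.size - 1):
        if valid is not None and not valid[i]:
            continue
        if not np.isfinite(es[i]):
            continue
        left, right = es[i - 1], es[i + 1]
        if es[i] <= left and es[i] <= right and (es[i] < left or es[i] < right):
            out.append(i)
    return out


def select_lambda_escv(
    es: np.ndarray,
    lambdas: np.ndarray,
    lambda_cv: float,
    valid: np.ndarray | None = None,
) -> float:
    """Smallest local minimum of ES(lambda) with lambda >= lambda_cv.

    Falls back to lambda_cv when no local minimum lies at or above it, so
    the result is never below the CV choice.
    """
    minima = _local_minima(es, valid=valid)
    cand = [i for i in minima if lambdas[i] >= lambda_cv]
    if not cand:
        return float(lambda_cv)
    return float(lambdas[max(cand)])


def description_length(rss: float, T: int, d: int) -> float:
    """MDL score (T/2) ln RSS + (d/2) ln T; RSS = 0 maps to -inf."""
    if T < 2:
        raise ValueError("T must be >= 2")
    if rss < 0:
        raise ValueError("RSS must be nonnegative")
    if rss == 0:
        return -np.inf
    return 0.5 * T * np.log(rss) + 0.5 * d * np.log(T)


def select_order(
    matrix: ExpressionMatrix,
    target: str | int,
    config: VARConfig | None = None,
    window: tuple[float, float] | None = None,
) -> OrderSelection:
    """Screen VAR orders 1..d_max by MDL on a common effective sample.

    All orders predict the same samples (the first d_max are dropped) so
    their residual sums of squares are comparable.  By default the RSS of
    each order comes from that order's ES-CV LASSO fit; ties break to the
    smaller order.
    """
    cfg = config or VARConfig()
    sub = matrix if window is None else matrix.window(*window)
    orders = np.arange(1, cfg.d_max + 1)
    rss = np.empty(cfg.d_max)
    dl = np.empty(cfg.d_max)
    for d in orders:
        system = build_design(sub, d=int(d), first_target=cfg.d_max)
        y = system.y(target)
        if cfg.rss_source == "ols":
            coef, *_ = np.linalg.lstsq(system.phi, y, rcond=None)
            resid = y - system.phi @ coef
        else:
            sel, path = escv_select(system.phi, y, cfg)
            resid = y - system.phi @ path.coefficients[sel.idx_escv]
        r = float(resid @ resid)
        rss[d - 1] = r
        dl[d - 1] = description_length(r, system.T_eff, int(d))
    d_opt = int(orders[np.argmin(dl)])  # argmin takes the first = smallest d
    return OrderSelection(orders=orders, rss=rss, dl=dl, d_opt=d_opt)


def fit_target(
    matrix: ExpressionMatrix,
    target: str | int,
    config: VARConfig | None = None,
    window: tuple[float, float] | None = None,
) -> SparseVARFit:
    """MDL order selection followed by the ES-CV LASSO fit at that order.

    The final fit uses every usable sample at d_opt (not the truncated
    order-screening sample).  Deterministic for fixed config and seed.
    """
    cfg = config or VARConfig()
    sub = matrix if window is None else matrix.window(*window)
    gene = sub.genes[target] if isinstance(target, int) else target
    if cfg.order is not None:
        order_sel = None
        d_opt = cfg.order
    else:
        order_sel = select_order(sub, gene, cfg)
        d_opt = order_sel.d_opt
    system = build_design(sub, d=d_opt)
    y = system.y(gene)
    sel, path = escv_select(system.phi, y, cfg)
    coefs = path.coefficients[sel.idx_escv]
    coeff_map = {}
    for c in np.nonzero(np.abs(coefs[1:]) > 0)[0] + 1:
        src, lag = system.column_label(int(c))
        coeff_map[(src, lag)] = float(coefs[c])
    nnz_cv = int((np.abs(path.coefficients[sel.idx_cv, 1:]) > 0).sum())
    return SparseVARFit(
        gene_id=gene,
        d_opt=d_opt,
        lambda_cv=sel.lambda_cv,
        lambda_escv=sel.lambda_escv,
        intercept=float(coefs[0]),
        coefficients=coeff_map,
        nnz_cv=nnz_cv,
        nnz_escv=len(coeff_map),
        order_selection=order_sel,
    )


def fit_window(
    matrix: ExpressionMatrix,
    config: VARConfig | None = None,
    window: tuple[float, float] | None = None,
) -> list[SparseVARFit]:
    """Fit every gene in the panel as a target over one window."""
    cfg = config or VARConfig()
    sub = matrix if window is None else matrix.window(*window)
    fits = []
    for i, gene in enumerate(sub.genes):
        gene_cfg = replace(cfg, seed=cfg.seed + 7919 * (i + 1))
        fits.append(fit_target(sub, gene, gene_cfg))
    return fits
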