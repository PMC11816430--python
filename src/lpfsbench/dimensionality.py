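"""Unidimensionality screen for ordinal item batteries.

Polychoric correlations (two-step maximum likelihood), Horn's parallel
analysis and Velicer's minimum-average-partial test on the polychoric
matrix, a minimum-residual one-factor solution, and McDonald's omega from
standardized loadings.

The bivariate-normal rectangle probabilities inside the polychoric
likelihood are evaluated with a vectorized one-dimensional reduction
(outer Gauss-Legendre panel over x, inner univariate normal CDF in y),
which keeps parallel analysis with hundreds of simulated matrices fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .core import ResponseMatrix, ValidationError, log

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_TAIL = 8.0  # effective +/- infinity for standard-normal thresholds


def _bvn_cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized bivariate standard normal.

    tau_x, tau_y are the interior thresholds (lengths Kx-1, Ky-1); the
    result has shape (Kx, Ky) and sums to ~1.  P(cell ij) is reduced to a
    one-dimensional integral over x of phi(x) * [Phi((tau_j - rho x)/s) -
    Phi((tau_{j-1} - rho x)/s)] with s = sqrt(1 - rho^2), evaluated by
    48-point Gauss-Legendre on each x strip.
    """
    rho = float(np.clip(rho, -0.9999, 0.9999))
    s = np.sqrt(1.0 - rho * rho)
    edges_x = np.concatenate([[-_TAIL], np.clip(tau_x, -_TAIL, _TAIL), [_TAIL]])
    half = 0.5 * np.diff(edges_x)  # (Kx,)
    mid = 0.5 * (edges_x[:-1] + edges_x[1:])
    # quadrature points for every strip at once: (Kx, G)
    t = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    w = half[:, None] * _GL_WEIGHTS[None, :]
    phi = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)
    # inner cumulative in y at each quadrature point: (Kx, G, Ky-1)
    inner = special.ndtr((tau_y[None, None, :] - rho * t[:, :, None]) / s)
    cum = np.concatenate(
        [np.zeros(inner.shape[:2] + (1,)), inner, np.ones(inner.shape[:2] + (1,))],
        axis=2,
    )
    cells = np.diff(cum, axis=2)  # (Kx, G, Ky)
    return np.einsum("xg,xg,xgk->xk", w, phi, cells)


def _thresholds(column: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior normal thresholds from marginal cumulative proportions."""
    values, counts = np.unique(column, return_counts=True)
    if len(values) < 2:
        raise ValidationError("column with a single observed category: thresholds undefined")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum), values


def _contingency(x: np.ndarray, y: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    ix = np.searchsorted(vx, x)
    iy = np.searchsorted(vy, y)
    table = np.zeros((len(vx), len(vy)))
    np.add.at(table, (ix, iy), 1.0)
    return table


def _polychoric_from_table(
    table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray
) -> float:
    """Profile-likelihood maximization over rho for fixed thresholds."""

    def neg_ll(rho: float) -> float:
        p = np.clip(_bvn_cell_probs(tau_x, tau_y, rho), 1e-300, None)
        return -float(np.sum(table * np.log(p)))

    res = optimize.minimize_scalar(
        neg_ll, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def polychoric_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step maximum-likelihood polychoric (or tetrachoric) correlation.

    Thresholds come from the marginal inverse-normal cumulative proportions
    of each column; rho then maximizes the bivariate-normal cell likelihood.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValidationError("columns must have equal length")
    tau_x, vx = _thresholds(x)
    tau_y, vy = _thresholds(y)
    table = _contingency(x, y, vx, vy)
    return _polychoric_from_table(table, tau_x, tau_y)


@dataclass(frozen=True)
class PolychoricMatrix:
    """Symmetric unit-diagonal polychoric correlation matrix + thresholds."""

    matrix: np.ndarray
    thresholds: tuple[np.ndarray, ...]
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("polychoric matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("polychoric matrix must have unit diagonal")
        if (np.abs(m) > 1 + 1e-10).any():
            raise ValidationError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)


def _smooth(matrix: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-floor smoothing; rescales back to unit diagonal."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= floor:
        return matrix
    log.warning("smoothing near-singular correlation matrix (min eigenvalue %.2e)", vals.min())
    vals = np.maximum(vals, floor)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def polychoric_matrix(responses: ResponseMatrix | np.ndarray) -> PolychoricMatrix:
    values = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(responses)
    ids = (
        responses.item_ids
        if isinstance(responses, ResponseMatrix)
        else tuple(f"V{i + 1}" for i in range(values.shape[1]))
    )
    m = values.shape[1]
    taus = []
    cats = []
    for j in range(m):
        tau, v = _thresholds(values[:, j])
        taus.append(tau)
        cats.append(v)
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            table = _contingency(values[:, i], values[:, j], cats[i], cats[j])
            corr[i, j] = corr[j, i] = _polychoric_from_table(table, taus[i], taus[j])
    return PolychoricMatrix(matrix=corr, thresholds=tuple(taus), item_ids=ids)


# ---------------------------------------------------------------------------
# Factor retention


@dataclass(frozen=True)
class ParallelAnalysisResult:
    n_factors: int
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray


def parallel_analysis(
    responses: ResponseMatrix,
    n_sims: int = 100,
    seed: int = 0,
    reference: str = "mean",
) -> ParallelAnalysisResult:
    """Horn's parallel analysis on the polychoric matrix.

    Reference eigenvalues come from ``n_sims`` datasets built by permuting
    each column of the observed data independently (preserving marginals,
    destroying dependence); the retained count is the number of leading
    observed eigenvalues exceeding their reference (mean by default,
    95th percentile with reference="p95").
    """
    if n_sims < 100:
        raise ValidationError("parallel analysis requires at least 100 simulations")
    observed = np.sort(np.linalg.eigvalsh(_smooth(polychoric_matrix(responses).matrix)))[::-1]
    rng = np.random.default_rng(seed)
    values = responses.values
    sims = np.empty((n_sims, values.shape[1]))
    for s in range(n_sims):
        permuted = np.column_stack(
            [rng.permutation(values[:, j]) for j in range(values.shape[1])]
        )
        sims[s] = np.sort(
            np.linalg.eigvalsh(_smooth(polychoric_matrix(permuted).matrix))
        )[::-1]
    if reference == "mean":
        ref = sims.mean(axis=0)
    elif reference == "p95":
        ref = np.percentile(sims, 95, axis=0)
    else:
        raise ValidationError(f"unknown reference rule {reference!r}")
    exceeds = observed > ref
    n_factors = int(np.argmin(exceeds)) if not exceeds.all() else len(exceeds)
    if not exceeds[0]:
        n_factors = 0
    return ParallelAnalysisResult(
        n_factors=n_factors, observed_eigenvalues=observed, reference_eigenvalues=ref
    )


@dataclass(frozen=True)
class MapResult:
    n_components: int
    avg_sq_partials: np.ndarray  # index k = components partialled out


def map_test(c: PolychoricMatrix | np.ndarray) -> MapResult:
    """Velicer's minimum average partial test.

    For k = 0..m-2 principal components partialled out, records the mean
    squared off-diagonal partial correlation; the suggested component count
    is the argmin of that profile.
    """
    matrix = c.matrix if isinstance(c, PolychoricMatrix) else np.asarray(c, dtype=float)
    matrix = _smooth(matrix)
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() <= 0:
        raise ValidationError("matrix not positive definite after smoothing")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    m = matrix.shape[0]
    off = ~np.eye(m, dtype=bool)
    profile = np.empty(m - 1)
    profile[0] = np.mean(matrix[off] ** 2)
    for k in range(1, m - 1):
        load = vecs[:, :k] * np.sqrt(vals[:k])
        partial_cov = matrix - load @ load.T
        d = np.sqrt(np.clip(np.diag(partial_cov), 1e-12, None))
        partial_corr = partial_cov / np.outer(d, d)
        profile[k] = np.mean(partial_corr[off] ** 2)
    return MapResult(n_components=int(np.argmin(profile)), avg_sq_partials=profile)


# ---------------------------------------------------------------------------
# One-factor solution and reliability


@dataclass(frozen=True)
class FactorSolution:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    item_ids: tuple[str, ...]
    heywood: bool = False


def extract_one_factor(c: PolychoricMatrix | np.ndarray) -> FactorSolution:
    """Minimum-residual (minres) one-factor solution.

    Minimizes the sum of squared off-diagonal residuals of R - lambda
    lambda'.  Loadings are sign-aligned positive; loadings at the +/-1
    boundary are flagged as Heywood cases and capped.
    """
    if isinstance(c, PolychoricMatrix):
        matrix, ids = c.matrix, c.item_ids
    else:
        matrix = np.asarray(c, dtype=float)
        ids = tuple(f"V{i + 1}" for i in range(matrix.shape[0]))
    matrix = _smooth(matrix)
    m = matrix.shape[0]
    off = ~np.eye(m, dtype=bool)

    # SMC-based start: communality ~ squared multiple correlation, signs from
    # the first eigenvector (zero for an uncorrelated battery)
    _, vecs = np.linalg.eigh(matrix)
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(matrix))
    direction = vecs[:, -1]
    if direction.sum() < 0:
        direction = -direction
    lam0 = np.sign(direction) * np.sqrt(np.clip(smc, 0.0, 0.98))

    def objective(lam: np.ndarray) -> tuple[float, np.ndarray]:
        resid = (matrix - np.outer(lam, lam)) * off
        grad = -4.0 * (resid @ lam)
        # vanishing ridge: selects the null solution when the off-diagonal
        # residual criterion is degenerate (e.g. an identity input)
        return float(np.sum(resid**2) + 1e-9 * np.sum(lam**2)), grad + 2e-9 * lam

    bound = 0.9999
    res = optimize.minimize(
        objective, lam0, jac=True, method="L-BFGS-B",
        bounds=[(-bound, bound)] * m, options={"ftol": 1e-14, "gtol": 1e-10},
    )
    lam = res.x
    if lam.sum() < 0:
        lam = -lam
    heywood = bool((np.abs(lam) >= bound - 1e-6).any())
    if heywood:
        log.warning("Heywood case: loading at the unit boundary, capped")
        lam = np.clip(lam, -bound, bound)
    return FactorSolution(
        loadings=lam, uniquenesses=1.0 - lam**2, item_ids=ids, heywood=heywood
    )


def mcdonalds_omega(solution: FactorSolution | np.ndarray) -> float:
    """McDonald's omega from standardized one-factor loadings.

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2)).
    """
    lam = (
        np.asarray(solution.loadings, dtype=float)
        if isinstance(solution, FactorSolution)
        else np.asarray(solution, dtype=float)
    )
    if (np.abs(lam) >= 1).any():
        raise ValidationError("loadings must lie strictly inside (-1, 1)")
    s = lam.sum() ** 2
    denom = s + np.sum(1.0 - lam**2)
    return float(s / denom) if denom > 0 else 0.0
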