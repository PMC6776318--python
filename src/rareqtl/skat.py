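"""SKAT, SKAT-Burden and SKAT-O on inverse-normal-transformed read counts.

Approach 2 of the package.  Raw gene read counts are mapped to normal
scores by a rank-based inverse normal transformation (Blom offset 3/8,
average ranks for ties):

    y_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))

The transformed outcome is modeled linearly, ``y = a0 + ac'C + ax'X + e``
with ``e ~ N(0, sigma^2)``.  SKAT treats the per-variant effects ``ax_j``
as random with variance ``w_j * tau`` and tests ``tau = 0`` with the
variance-component score statistic

    Q = (y - mu0)' X W^2 X' (y - mu0),      W = diag(w_1..w_J),

where ``w_j = Beta(MAF_j; a1, a2)`` density weights (defaults a1=1, a2=25,
up-weighting the rarest variants).  Note the kernel applies *squared*
Beta-density weights to genotype columns — the convention of the reference
SKAT software; pass ``weight_convention="literal"`` for the unsquared
kernel ``X W X'``.

Under the null, Q follows a weighted mixture of chi-square(1) variables
whose tail probability is computed by numerical inversion of the
characteristic function (Davies/Imhof approach, absolute accuracy ~1e-6),
with the Liu moment-matching approximation as an automatic fallback.
SKAT-Burden collapses to a single weighted burden score (one scaled
chi-square(1)); SKAT-O scans ``Q_rho = (1-rho) Q_SKAT + rho Q_Burden``
over a rho grid and combines the per-rho p-values by the one-dimensional
conditioning integral of Lee et al.'s optimal unified test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import integrate, stats

from .errors import DegenerateInputError, RankDeficientError
from .results import STATUS_DEGENERATE, STATUS_OK, TestResult
from .simdata import CountData, GenotypeMatrix

#: default SKAT-O rho grid (reference-implementation default)
DEFAULT_RHO_GRID: Tuple[float, ...] = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

#: relative threshold below which mixture eigenvalues are discarded
EIGEN_RTOL = 1e-10

#: p-values are clamped into this interval
P_MIN, P_MAX = 1e-12, 1.0


# ---------------------------------------------------------------------------
# inverse normal transform and weights
# ---------------------------------------------------------------------------


def inverse_normal_transform(t: Union[CountData, np.ndarray]) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom (3/8) offset.

    Ties receive average ranks, so tied counts map to equal normal scores.
    Raises :class:`DegenerateInputError` for constant input (no rank
    information) and requires n >= 3.
    """
    x = t.t if isinstance(t, CountData) else np.asarray(t)
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations to transform")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant counts cannot be rank-transformed")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


@dataclass(frozen=True)
class WeightSpec:
    """Beta-density variant weights ``w_j = Beta(MAF_j; a1, a2)``."""

    a1: float
    a2: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("a1 and a2 must be > 0")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be non-negative finite reals")
        object.__setattr__(self, "weights", w)


def beta_weights(
    maf_sample: Union[np.ndarray, Sequence[float]], a1: float = 1.0, a2: float = 25.0
) -> WeightSpec:
    """Evaluate the Beta(a1, a2) density at each sample MAF.

    The default (1, 25) strongly up-weights the rarest variants while
    keeping nonzero weight for MAF 1-5% sites.
    """
    maf = np.asarray(maf_sample, dtype=float)
    if np.any(maf < 0) or np.any(maf > 1):
        raise ValueError("MAF values must lie in [0, 1]")
    if a1 <= 0 or a2 <= 0:
        raise ValueError("a1 and a2 must be > 0")
    w = stats.beta.pdf(maf, a1, a2)
    return WeightSpec(a1=a1, a2=a2, weights=w)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


@dataclass
class SkatNull:
    """Least-squares null model of the transformed outcome.

    Holds the residuals ``y - mu0``, the unbiased variance estimate
    ``sigma2 = RSS / (n - p0)``, and an orthonormal basis of the null
    design column space used to project genotypes.
    """

    residuals: np.ndarray
    sigma2: float
    design: np.ndarray
    qbasis: np.ndarray
    coefficients: np.ndarray

    @property
    def n(self) -> int:
        return int(self.residuals.size)

    @property
    def p0(self) -> int:
        return int(self.design.shape[1])


def fit_null_linear(
    y: np.ndarray, C: Optional[np.ndarray] = None
) -> SkatNull:
    """Fit the null linear model (intercept + covariates) by least squares."""
    y = np.asarray(y, dtype=float)
    n = y.size
    cols = [np.ones(n)]
    if C is not None:
        Cm = np.atleast_2d(np.asarray(C, dtype=float))
        if Cm.shape[0] != n:
            Cm = Cm.T
        if Cm.shape[0] != n:
            raise ValueError("covariate matrix length mismatch")
        cols.extend(Cm[:, j] for j in range(Cm.shape[1]))
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise RankDeficientError("null design matrix is rank deficient")
    if n <= D.shape[1] + 1:
        raise ValueError("need n > number of null design columns + 1")
    Q, R = np.linalg.qr(D)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - D @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - D.shape[1])
    if sigma2 <= 1e-12 * max(float(np.var(y)), 1e-12):
        warnings.warn("null model fits the outcome almost exactly; tests are degenerate", stacklevel=2)
    return SkatNull(residuals=resid, sigma2=sigma2, design=D, qbasis=Q, coefficients=beta)


# ---------------------------------------------------------------------------
# mixture-of-chi-square tail probabilities
# ---------------------------------------------------------------------------


def _liu_params(lam: np.ndarray) -> dict:
    """Moment-matching parameters of Liu-Tang-Zhang (modified version)."""
    c1 = float(np.sum(lam))
    c2 = float(np.sum(lam**2))
    c3 = float(np.sum(lam**3))
    c4 = float(np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2.0 * d
    else:
        d = 0.0
        l = 1.0 / s2
        a = np.sqrt(l)
    return dict(muQ=c1, sigmaQ=np.sqrt(2.0 * c2), muX=l + d, sigmaX=np.sqrt(2.0) * a, l=l, d=d)


def _liu_sf(q: float, lam: np.ndarray) -> float:
    p = _liu_params(lam)
    tstar = (q - p["muQ"]) / p["sigmaQ"]
    x = tstar * p["sigmaX"] + p["muX"]
    if p["d"] > 0:
        return float(stats.ncx2.sf(x, p["l"], p["d"]))
    return float(stats.chi2.sf(x, p["l"]))


def _liu_quantile(p_upper: float, lam: np.ndarray) -> float:
    """Upper-tail quantile of the mixture by Liu moment matching."""
    prm = _liu_params(lam)
    if prm["d"] > 0:
        x = stats.ncx2.isf(p_upper, prm["l"], prm["d"])
    else:
        x = stats.chi2.isf(p_upper, prm["l"])
    return float((x - prm["muX"]) / prm["sigmaX"] * prm["sigmaQ"] + prm["muQ"])


def _imhof_upper_limit(lamn: np.ndarray, tol: float = 1e-11) -> float:
    U = 8.0
    for _ in range(60):
        lu = lamn * U
        amp = 1.0 / (U * np.exp(0.25 * float(np.sum(np.log1p(lu * lu)))))
        heavy = int(np.count_nonzero(lu > 1.0))
        decay = 0.5 * heavy  # local decay exponent beyond 1/u
        if decay >= 1.0 and amp * U / decay < tol:
            return U
        U *= 2.0
    return U


def _imhof_sf_grid(qs: np.ndarray, lam: np.ndarray) -> Optional[np.ndarray]:
    """Vectorized Imhof CF inversion for one or many q.

    Evaluates the inversion integral on a Simpson grid fine enough to
    resolve the sin(theta(u) - q u / 2) oscillation, sharing the
    arctan/log-product terms across all q.  Returns None when the grid
    required for a reliable answer would be too large (slowly decaying
    amplitude from very few / widely separated eigenvalues); callers then
    fall back to an exact convolution (J = 2) or Liu moment matching.
    """
    s = float(lam.max())
    lamn = lam / s
    qsn = np.asarray(qs, dtype=float) / s
    U = _imhof_upper_limit(lamn)
    qmax = float(max(qsn.max(), np.sum(lamn)))
    # ~32 points per oscillation period of sin(theta - q u / 2)
    n_req = int(32 * U * (qmax + np.sum(lamn)) / (4.0 * np.pi))
    if n_req > 2**17 or U > 1e5:
        return None
    N = int(max(4096, n_req))
    if N % 2:
        N += 1
    u = np.linspace(0.0, U, N + 1)
    lu = np.outer(u[1:], lamn)
    base = 0.5 * np.sum(np.arctan(lu), axis=1)
    denom = u[1:] * np.exp(0.25 * np.sum(np.log1p(lu * lu), axis=1))
    out = np.empty(qsn.size)
    f = np.empty(N + 1)
    for i, qn in enumerate(qsn):
        f[0] = 0.5 * (np.sum(lamn) - qn)
        f[1:] = np.sin(base - 0.5 * qn * u[1:]) / denom
        out[i] = 0.5 + integrate.simpson(f, x=u) / np.pi
    return out


def _imhof_sf_osc(q: float, lam: np.ndarray) -> float:
    """Imhof CF inversion via oscillatory-weight quadrature (any J).

    Splits sin(phi(u) - a u) into slowly varying factors sin(phi)/cos(phi)
    times cos(a u)/sin(a u) and integrates the infinite oscillatory tail
    with QAWF; the non-oscillatory head is handled by plain adaptive
    quadrature.  Reliable even for very few eigenvalues, where a fixed
    grid would need an impractical number of points.
    """
    s = float(lam.max())
    lamn = lam / s
    qn = q / s
    a = 0.5 * qn
    sum_lam = float(np.sum(lamn))

    def phi(u):
        return 0.5 * float(np.sum(np.arctan(lamn * u)))

    def inv_urho(u):
        return 1.0 / (u * np.exp(0.25 * float(np.sum(np.log1p((lamn * u) ** 2)))))

    def head(u):
        if u <= 0.0:
            return 0.5 * (sum_lam - qn)
        return np.sin(phi(u) - a * u) * inv_urho(u)

    u0 = min(np.pi / a, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        i1, _ = integrate.quad(head, 0.0, u0, epsabs=1e-10, epsrel=1e-10, limit=200)
        i2, _ = integrate.quad(
            lambda u: np.sin(phi(u)) * inv_urho(u), u0, np.inf,
            weight="cos", wvar=a, epsabs=1e-9, limit=300,
        )
        i3, _ = integrate.quad(
            lambda u: np.cos(phi(u)) * inv_urho(u), u0, np.inf,
            weight="sin", wvar=a, epsabs=1e-9, limit=300,
        )
    return 0.5 + (i1 + i2 - i3) / np.pi


def _clean_lambdas(lambdas: Union[np.ndarray, Sequence[float]]) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0 or np.all(lam <= 0):
        raise ValueError("need at least one positive eigenvalue")
    if np.any(lam < -EIGEN_RTOL * lam.max()):
        raise ValueError("negative eigenvalues in mixture")
    lam = lam[lam > EIGEN_RTOL * lam.max()]
    return np.sort(lam)[::-1]


def _mixture_sf_many(qs: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Davies-style tail probabilities with automatic fallbacks."""
    qs = np.asarray(qs, dtype=float)
    if np.allclose(lam, lam[0], rtol=1e-12):
        return stats.chi2.sf(qs / lam[0], df=lam.size)
    out = _imhof_sf_grid(qs, lam)
    if out is not None and np.all(np.isfinite(out)):
        return np.clip(out, 0.0, 1.0)
    vals = np.array([_imhof_sf_osc(float(q), lam) for q in qs])
    bad = ~np.isfinite(vals) | (vals < -1e-6) | (vals > 1 + 1e-6)
    if np.any(bad):
        vals[bad] = [_liu_sf(float(q), lam) for q in qs[bad]]
    return np.clip(vals, 0.0, 1.0)


def _mixture_sf(q: float, lam: np.ndarray) -> float:
    return float(_mixture_sf_many(np.array([q]), lam)[0])


def quadform_pvalue(
    q: float, lambdas: Union[np.ndarray, Sequence[float]], method: str = "davies"
) -> float:
    """Tail probability ``P(sum_l lambda_l chi2_1 >= q)``.

    ``davies`` inverts the characteristic function numerically (exact
    chi-square closed form when all eigenvalues coincide) and falls back
    to ``liu`` moment matching on numerical fault.  The result is clamped
    to ``[1e-12, 1]``.
    """
    if method not in ("davies", "liu"):
        raise ValueError("method must be 'davies' or 'liu'")
    if q < 0:
        raise ValueError("q must be >= 0")
    lam = _clean_lambdas(lambdas)
    if q == 0:
        return 1.0
    p = _liu_sf(q, lam) if method == "liu" else _mixture_sf(q, lam)
    return float(min(max(p, P_MIN), P_MAX))


# ---------------------------------------------------------------------------
# SKAT statistics and tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkatComponents:
    """Score statistic Q and the eigenvalues of its null mixture."""

    Q: float
    lambdas: np.ndarray
    rho_grid: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be >= 0")


def _weighted_genotypes(
    G: GenotypeMatrix, W: Union[WeightSpec, np.ndarray], weight_convention: str
) -> np.ndarray:
    w = W.weights if isinstance(W, WeightSpec) else np.asarray(W, dtype=float)
    if w.shape != (G.n_variants,):
        raise ValueError("one weight per variant required")
    if np.all(w == 0):
        raise DegenerateInputError("all variant weights are zero")
    if weight_convention == "squared":
        colw = w
    elif weight_convention == "literal":
        colw = np.sqrt(w)
    else:
        raise ValueError("weight_convention must be 'squared' or 'literal'")
    X = G.dosages
    if np.all(np.ptp(X, axis=0) == 0):
        raise DegenerateInputError("no genotype variation in the region")
    return X * colw


def skat_statistic(
    null: SkatNull,
    G: GenotypeMatrix,
    W: Union[WeightSpec, np.ndarray],
    weight_convention: str = "squared",
) -> SkatComponents:
    """Variance-component score statistic and its null eigenvalues.

    ``Q = r' X W^2 X' r`` with ``r`` the null residuals (squared-weight
    kernel by default; see module docstring).  The eigenvalues are those
    of ``sigma2 * (W X' P X W)`` with ``P`` the residual-forming projection
    of the null design, truncated at 1e-10 relative magnitude.
    """
    Z = _weighted_genotypes(G, W, weight_convention)
    r = null.residuals
    S = Z.T @ r
    Q = float(S @ S)
    Z1 = Z - null.qbasis @ (null.qbasis.T @ Z)
    A = (Z1.T @ Z1) * null.sigma2
    lam = np.linalg.eigvalsh(A)
    lam = lam[lam > EIGEN_RTOL * max(lam.max(), 0.0)]
    if lam.size == 0:
        raise DegenerateInputError("projected genotypes carry no variance")
    return SkatComponents(Q=Q, lambdas=np.sort(lam)[::-1])


def skat_test(
    null: SkatNull,
    G: GenotypeMatrix,
    W: Union[WeightSpec, np.ndarray],
    weight_convention: str = "squared",
) -> TestResult:
    """SKAT variance-component test of the region."""
    try:
        comp = skat_statistic(null, G, W, weight_convention)
    except DegenerateInputError:
        return TestResult(method="SKAT", status=STATUS_DEGENERATE)
    p = quadform_pvalue(comp.Q, comp.lambdas)
    return TestResult(method="SKAT", statistic=comp.Q, p_value=p)


def burden_test(
    null: SkatNull,
    G: GenotypeMatrix,
    W: Union[WeightSpec, np.ndarray],
) -> TestResult:
    """Weighted burden test: score test of ``b_i = sum_j w_j x_ij``.

    ``Q_B = (r' b)^2`` follows a single scaled chi-square(1) under the
    null with scale ``sigma2 * b' P b``.
    """
    w = W.weights if isinstance(W, WeightSpec) else np.asarray(W, dtype=float)
    b = G.dosages @ w
    if np.ptp(b) == 0:
        return TestResult(method="SKAT-Burden", status=STATUS_DEGENERATE)
    r = null.residuals
    s = float(r @ b)
    Q = s * s
    b1 = b - null.qbasis @ (null.qbasis.T @ b)
    scale = null.sigma2 * float(b1 @ b1)
    if scale <= 0:
        return TestResult(method="SKAT-Burden", status=STATUS_DEGENERATE)
    p = quadform_pvalue(Q, [scale])
    return TestResult(method="SKAT-Burden", statistic=Q, p_value=p)


def _rho_half(rho: float, J: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + rho * J) - a) / J
    return a * np.eye(J) + b * np.ones((J, J))


def skato_test(
    null: SkatNull,
    G: GenotypeMatrix,
    W: Union[WeightSpec, np.ndarray],
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    weight_convention: str = "squared",
) -> TestResult:
    """SKAT-O: optimal combination of SKAT and the weighted burden test.

    For each rho in the grid, ``Q_rho = (1-rho) Q_SKAT + rho Q_Burden`` is
    referred to its own chi-square mixture; the minimum per-rho p-value is
    then calibrated by the one-dimensional conditioning integral of the
    optimal unified test (rho = 1 capped at 0.999 inside the integral).
    The reported statistic is the minimum per-rho p-value.
    """
    rho = np.asarray(sorted(set(float(r) for r in rho_grid)), dtype=float)
    if rho.size == 0:
        raise ValueError("rho_grid must contain at least one value")
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho_grid must lie in [0, 1]")

    try:
        Z = _weighted_genotypes(G, W, weight_convention)
    except DegenerateInputError:
        return TestResult(method="SKAT-O", status=STATUS_DEGENERATE)

    if rho.size == 1:
        base = (
            skat_test(null, G, W, weight_convention)
            if rho[0] == 0.0
            else burden_test(null, G, W)
            if rho[0] == 1.0
            else None
        )
        if base is not None:
            return TestResult(
                method="SKAT-O",
                statistic=base.p_value,
                p_value=base.p_value,
                status=base.status,
            ) if base.status == STATUS_OK else TestResult(method="SKAT-O", status=base.status)

    r = null.residuals
    sigma2 = null.sigma2
    J = Z.shape[1]
    S = Z.T @ r
    Q_skat = float(S @ S) / sigma2
    Q_burden = float(S.sum()) ** 2 / sigma2
    Z1 = Z - null.qbasis @ (null.qbasis.T @ Z)
    G2 = Z1.T @ Z1

    if J == 1:
        res = skat_test(null, G, W, weight_convention)
        if res.status != STATUS_OK:
            return TestResult(method="SKAT-O", status=res.status)
        return TestResult(method="SKAT-O", statistic=res.p_value, p_value=res.p_value)

    p_rho = np.empty(rho.size)
    lam_max = 0.0
    for i, rh in enumerate(rho):
        Rh = _rho_half(rh, J)
        lam = np.linalg.eigvalsh(Rh @ G2 @ Rh)
        lam = lam[lam > EIGEN_RTOL * max(lam.max(), 0.0)]
        if lam.size == 0:
            return TestResult(method="SKAT-O", status=STATUS_DEGENERATE)
        lam_max = max(lam_max, float(lam.max()))
        q_rho = (1.0 - rh) * Q_skat + rh * Q_burden
        p_rho[i] = quadform_pvalue(q_rho, lam)
    T = float(p_rho.min())

    if rho.size == 1:
        return TestResult(method="SKAT-O", statistic=T, p_value=T)

    # conditioning decomposition of Lee et al.
    rho_eff = np.minimum(rho, 0.999)
    z_bar = Z1.mean(axis=1)
    zz = float(z_bar @ z_bar)
    lo, hi = max(T, P_MIN), min(1.0, rho.size * T)
    if zz <= EIGEN_RTOL * lam_max:
        return TestResult(method="SKAT-O", statistic=T, p_value=hi)
    cof = (z_bar @ Z1) / zz
    Z2 = Z1 - np.outer(z_bar, cof)
    G2_2 = Z2.T @ Z2
    lam_star = np.linalg.eigvalsh(G2_2)
    lam_star = lam_star[lam_star > EIGEN_RTOL * max(lam_star.max(), 0.0)]
    if lam_star.size == 0:
        # burden direction spans the projected genotypes: all rho coincide
        return TestResult(method="SKAT-O", statistic=T, p_value=T)
    mu_q = float(np.sum(lam_star))
    var_remain = 4.0 * float(np.sum(np.outer(cof, cof) * zz * G2_2))
    var_q = 2.0 * float(np.sum(lam_star**2)) + var_remain
    tau = (J**2 * rho_eff + (1.0 - rho_eff) * float(np.sum(cof**2))) * zz

    qmin = np.array(
        [
            _liu_quantile(T, _clean_lambdas(np.linalg.eigvalsh(_rho_half(rh, J) @ G2 @ _rho_half(rh, J))))
            for rh in rho
        ]
    )

    # integrate over the shared chi-square(1) component, x = s^2
    nodes, wts = np.polynomial.legendre.leggauss(48)
    smax = 8.0
    svals = 0.5 * smax * (nodes + 1.0)
    swts = 0.5 * smax * wts
    x = svals**2
    qx = np.min((qmin[None, :] - tau[None, :] * x[:, None]) / (1.0 - rho_eff[None, :]), axis=1)
    adj = np.sqrt(max(var_q - var_remain, 0.0) / var_q) if var_q > 0 else 1.0
    q_adj = (qx - mu_q) * adj + mu_q
    Fvals = np.zeros_like(qx)
    pos = q_adj > 0
    if np.any(pos):
        Fvals[pos] = 1.0 - _mixture_sf_many(q_adj[pos], lam_star)
    Fvals[qx <= 0] = 0.0
    dens = np.sqrt(2.0 / np.pi) * np.exp(-0.5 * x)
    integral = float(np.sum(swts * Fvals * dens))
    p = 1.0 - integral
    p = float(min(max(p, lo), hi))
    return TestResult(method="SKAT-O", statistic=T, p_value=p)
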