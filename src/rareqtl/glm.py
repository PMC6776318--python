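"""Collapsing-based Poisson / negative-binomial regression tests.

Approach 1 of the package: collapse the rare variants of a region into a
single per-subject quantity ``f(x_i)`` — either the sum of minor-allele
dosages or an indicator of carrying at least one rare allele — and test its
association with the gene read count under a log-link count regression

    log mu_i = alpha_0 + alpha_k * log k_i + alpha_c' C_i + alpha_x f(x_i)

with Poisson or NB2 negative-binomial errors (variance ``mu + phi*mu**2``).
The genotype coefficient is tested with a Wald, score, or likelihood-ratio
test of H0: alpha_x = 0.

Fitting is by maximum likelihood: iteratively reweighted least squares for
the regression coefficients, alternated for the negative binomial with
safeguarded 1-D Newton updates of the dispersion on the log scale.
Convergence is declared when the relative log-likelihood change falls below
1e-8 (within 100 outer iterations).  A dispersion estimate that collapses
to the zero boundary re-labels the fit as effectively Poisson with
``dispersion == 0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy import stats
from scipy.special import gammaln, polygamma

from .errors import RankDeficientError
from .results import (
    STATUS_DEGENERATE,
    STATUS_FAILED,
    STATUS_OK,
    TestResult,
)
from .simdata import CountData, GenotypeMatrix

MAX_ITER = 100
LL_RTOL = 1e-8
_ETA_CLIP = 30.0
_PHI_FLOOR = 1e-8  # below this the NB fit is declared effectively Poisson

COLLAPSE_MODES = ("sum", "indicator")
FAMILIES = ("poisson", "negbin")
TEST_TYPES = ("wald", "score", "lrt")
LIBSIZE_MODES = ("none", "offset", "covariate")

GENOTYPE_TERM = "genotype"


@dataclass(frozen=True)
class CollapsedGenotype:
    """Region-collapsed genotype: dosage sum or carrier indicator per subject."""

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in COLLAPSE_MODES:
            raise ValueError(f"mode must be one of {COLLAPSE_MODES}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(v < 0):
            raise ValueError("collapsed values must be non-negative")
        if self.mode == "indicator" and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("indicator values must be 0/1")
        object.__setattr__(self, "values", v)

    @property
    def degenerate(self) -> bool:
        """True when the collapsed predictor carries no variation."""
        return bool(np.ptp(self.values) == 0)


@dataclass
class GlmFit:
    """A fitted log-link count regression.

    ``coefficients`` / ``standard_errors`` are keyed by term name
    (``"intercept"``, ``"log_libsize"``, ``"cov0"``.., ``"genotype"``).
    ``dispersion`` is the NB2 phi-hat (0.0 for the Poisson family or when
    the NB fit hit the zero-dispersion boundary).
    """

    family: str
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    dispersion: float
    loglik: float
    converged: bool
    n_iter: int
    status: str = STATUS_OK
    effectively_poisson: bool = False
    # fitting context retained so score/LRT tests can refit the null
    _y: Optional[np.ndarray] = field(default=None, repr=False)
    _X: Optional[np.ndarray] = field(default=None, repr=False)
    _offset: Optional[np.ndarray] = field(default=None, repr=False)
    _names: Optional[List[str]] = field(default=None, repr=False)


def collapse(G: GenotypeMatrix, mode: str = "sum") -> CollapsedGenotype:
    """Collapse all variants of ``G`` into one per-subject predictor.

    ``sum``: total minor-allele dosage; ``indicator``: 1 iff the subject
    carries at least one minor allele anywhere in the region.  A constant
    result is returned with its ``degenerate`` property set rather than
    raising, so downstream tests can flag the replicate.
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    total = G.dosages.sum(axis=1)
    if mode == "sum":
        values = total
    elif mode == "indicator":
        values = (total > 0).astype(float)
    else:
        raise ValueError(f"mode must be one of {COLLAPSE_MODES}")
    return CollapsedGenotype(values=values, mode=mode)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _build_design(
    t: Union[CountData, np.ndarray],
    f: Optional[Union[CollapsedGenotype, np.ndarray]],
    C: Optional[np.ndarray],
    libsize_mode: str,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str], bool]:
    """Return (y, X, offset, names, f_degenerate)."""
    if libsize_mode not in LIBSIZE_MODES:
        raise ValueError(f"libsize_mode must be one of {LIBSIZE_MODES}")
    if isinstance(t, CountData):
        y = t.t.astype(float)
        k = t.k
    else:
        y = np.asarray(t, dtype=float)
        k = None
    n = y.size
    cols = [np.ones(n)]
    names = ["intercept"]
    offset = np.zeros(n)
    if libsize_mode != "none":
        if k is None:
            raise ValueError(f"libsize_mode={libsize_mode!r} requires library sizes")
        logk = np.log(k.astype(float))
        if libsize_mode == "offset":
            offset = logk
        else:
            cols.append(logk)
            names.append("log_libsize")
    if C is not None:
        Cm = np.atleast_2d(np.asarray(C, dtype=float))
        if Cm.shape[0] != n:
            Cm = Cm.T
        if Cm.shape[0] != n:
            raise ValueError("covariate matrix length mismatch")
        for j in range(Cm.shape[1]):
            cols.append(Cm[:, j])
            names.append(f"cov{j}")
    f_degenerate = False
    if f is not None:
        fv = f.values if isinstance(f, CollapsedGenotype) else np.asarray(f, dtype=float)
        if fv.shape != (n,):
            raise ValueError("collapsed genotype length mismatch")
        f_degenerate = bool(np.ptp(fv) == 0)
        if not f_degenerate:
            cols.append(fv)
            names.append(GENOTYPE_TERM)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("design matrix is rank deficient")
    return y, X, offset, names, f_degenerate


# ---------------------------------------------------------------------------
# likelihoods and fitters
# ---------------------------------------------------------------------------


def _poisson_loglik(y: np.ndarray, eta: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * eta - mu - gammaln(y + 1)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, a: float) -> float:
    # a = 1/phi (NB2 size parameter)
    return float(
        np.sum(
            gammaln(y + a)
            - gammaln(a)
            - gammaln(y + 1)
            + a * np.log(a / (a + mu))
            + y * np.log(mu / (a + mu))
        )
    )


def _irls_step(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    beta: np.ndarray,
    mu: np.ndarray,
    eta: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    z = (eta - offset) + (y - mu) / mu
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ z)


def _fit_poisson_core(y, X, offset):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = _poisson_loglik(y, eta, mu)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        beta_prop = _irls_step(y, X, offset, beta, mu, eta, w=mu)
        # step-halving keeps accepted iterations monotone in log-likelihood
        lam = 1.0
        while True:
            cand = beta + lam * (beta_prop - beta)
            eta_c = np.clip(X @ cand + offset, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            ll_c = _poisson_loglik(y, eta_c, mu_c)
            if ll_c >= ll - 1e-10 or lam < 1e-6:
                break
            lam *= 0.5
        if abs(ll_c - ll) <= 1e-10 * (abs(ll_c) + 1.0):
            if ll_c >= ll:
                beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
            converged = True
            break
        if ll_c < ll:
            break
        beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
    cov = np.linalg.inv((X.T * mu) @ X)
    return dict(beta=beta, cov=cov, mu=mu, eta=eta, loglik=ll, converged=converged, n_iter=it)


def _nb_score_a(y, mu, a):
    return float(
        np.sum(polygamma(0, y + a) - polygamma(0, a) + np.log(a / (a + mu)) + 1.0 - (a + y) / (a + mu))
    )


def _nb_hess_a(y, mu, a):
    return float(
        np.sum(
            polygamma(1, y + a)
            - polygamma(1, a)
            + 1.0 / a
            - 1.0 / (a + mu)
            - (mu - y) / (a + mu) ** 2
        )
    )


def _update_dispersion(y, mu, a, max_inner=8):
    """Safeguarded Newton on log(a), a = 1/phi; never decreases the loglik."""
    ll = _nb_loglik(y, mu, a)
    for _ in range(max_inner):
        g = _nb_score_a(y, mu, a) * a  # d ll / d log a
        h = _nb_hess_a(y, mu, a) * a * a + g  # d2 ll / d (log a)^2
        if h >= 0 or not np.isfinite(h):
            step = np.sign(g) * 0.5
        else:
            step = -g / h
        step = float(np.clip(step, -2.0, 2.0))
        if abs(step) < 1e-12:
            break
        improved = False
        for _ in range(20):
            a_new = a * np.exp(step)
            if not (1e-10 < a_new < 1e10):
                a_new = float(np.clip(a_new, 1e-10, 1e10))
            ll_new = _nb_loglik(y, mu, a_new)
            if ll_new >= ll - 1e-12:
                improved = ll_new > ll
                a, ll = a_new, ll_new
                break
            step *= 0.5
        if not improved:
            break
    return a, ll


def _fit_negbin_core(y, X, offset):
    pois = _fit_poisson_core(y, X, offset)
    mu = pois["mu"]
    # method-of-moments start for phi
    denom = float(np.sum(mu**2))
    phi0 = float(np.sum((y - mu) ** 2 - mu)) / denom if denom > 0 else 0.0
    if phi0 < 1e-4:
        # no sample overdispersion: boundary fit, effectively Poisson
        return dict(pois, a=np.inf, phi=0.0, effectively_poisson=True)
    a = 1.0 / phi0
    beta = pois["beta"].copy()
    eta = pois["eta"]
    ll = _nb_loglik(y, mu, a)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        phi = 1.0 / a
        w = mu / (1.0 + phi * mu)
        beta_prop = _irls_step(y, X, offset, beta, mu, eta, w=w)
        lam = 1.0
        while True:
            cand = beta + lam * (beta_prop - beta)
            eta_c = np.clip(X @ cand + offset, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            ll_c = _nb_loglik(y, mu_c, a)
            if ll_c >= ll - 1e-10 or lam < 1e-6:
                break
            lam *= 0.5
        ll_prev = ll
        if ll_c >= ll:
            beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
        a, ll_new = _update_dispersion(y, mu, a)
        if 1.0 / a < _PHI_FLOOR:
            return dict(_fit_poisson_core(y, X, offset), a=np.inf, phi=0.0, effectively_poisson=True)
        if abs(ll_new - ll_prev) <= LL_RTOL * (abs(ll_new) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    phi = 1.0 / a
    w = mu / (1.0 + phi * mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return dict(
        beta=beta,
        cov=cov,
        mu=mu,
        eta=eta,
        loglik=ll,
        converged=converged,
        n_iter=it,
        a=a,
        phi=phi,
        effectively_poisson=False,
    )


# ---------------------------------------------------------------------------
# public fitting / testing surface
# ---------------------------------------------------------------------------


def fit_glm(
    t: Union[CountData, np.ndarray],
    f: Optional[Union[CollapsedGenotype, np.ndarray]] = None,
    C: Optional[np.ndarray] = None,
    family: str = "poisson",
    libsize_mode: str = "none",
) -> GlmFit:
    """Fit a log-link Poisson or negative-binomial regression of counts.

    ``f`` is the collapsed genotype predictor (``None`` fits the null
    model).  A constant ``f`` yields a fit of the remaining terms with
    ``status == "degenerate"`` so downstream tests can propagate the flag.
    Library sizes from ``t`` enter as a log offset or a free covariate
    depending on ``libsize_mode``.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y, X, offset, names, f_degen = _build_design(t, f, C, libsize_mode)
    try:
        core = _fit_poisson_core(y, X, offset) if family == "poisson" else _fit_negbin_core(y, X, offset)
    except np.linalg.LinAlgError:
        return GlmFit(
            family=family,
            coefficients={},
            standard_errors={},
            dispersion=float("nan"),
            loglik=float("nan"),
            converged=False,
            n_iter=0,
            status=STATUS_FAILED,
            _y=y,
            _X=X,
            _offset=offset,
            _names=names,
        )
    se = np.sqrt(np.diag(core["cov"]))
    eff_pois = bool(core.get("effectively_poisson", False))
    fit = GlmFit(
        family=family,
        coefficients=dict(zip(names, core["beta"].tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        dispersion=0.0 if family == "poisson" else float(core.get("phi", 0.0)),
        loglik=float(core["loglik"]),
        converged=bool(core["converged"]),
        n_iter=int(core["n_iter"]),
        status=STATUS_DEGENERATE if f_degen else (STATUS_OK if core["converged"] else STATUS_FAILED),
        effectively_poisson=eff_pois,
        _y=y,
        _X=X,
        _offset=offset,
        _names=names,
    )
    return fit


def _refit_null(fit: GlmFit, term: str):
    names = list(fit._names)
    idx = names.index(term)
    Xr = np.delete(fit._X, idx, axis=1)
    core = (
        _fit_poisson_core(fit._y, Xr, fit._offset)
        if fit.family == "poisson"
        else _fit_negbin_core(fit._y, Xr, fit._offset)
    )
    return core, Xr, fit._X[:, idx]


def test_coefficient(
    fit: GlmFit,
    term: str = GENOTYPE_TERM,
    test_type: str = "wald",
    method_label: Optional[str] = None,
) -> TestResult:
    """Test H0: coefficient of ``term`` equals zero.

    ``wald``: z = beta-hat / SE, two-sided normal.  ``lrt``: twice the
    log-likelihood difference against chi-square(1).  ``score``: efficient
    score statistic computed from the null fit only (usable even when the
    full fit failed to converge).
    """
    if test_type not in TEST_TYPES:
        raise ValueError(f"test_type must be one of {TEST_TYPES}")
    label = method_label or f"{fit.family}-{test_type}"
    if fit.status == STATUS_DEGENERATE or (fit._names is not None and term not in fit._names):
        return TestResult(method=label, statistic=None, p_value=None, test_type=test_type, status=STATUS_DEGENERATE)
    if fit.status == STATUS_FAILED and test_type != "score":
        return TestResult(method=label, statistic=None, p_value=None, test_type=test_type, status=STATUS_FAILED)

    if test_type == "wald":
        beta = fit.coefficients[term]
        se = fit.standard_errors[term]
        if not np.isfinite(se) or se <= 0:
            return TestResult(method=label, statistic=None, p_value=None, test_type=test_type, status=STATUS_FAILED)
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return TestResult(method=label, statistic=float(z), p_value=float(p), test_type=test_type)

    null_core, Xr, x = _refit_null(fit, term)

    if test_type == "lrt":
        stat = max(2.0 * (fit.loglik - null_core["loglik"]), 0.0)
        p = stats.chi2.sf(stat, df=1)
        return TestResult(method=label, statistic=float(stat), p_value=float(p), test_type=test_type)

    # efficient score test from the null fit
    mu0 = null_core["mu"]
    if fit.family == "poisson" or not np.isfinite(null_core.get("a", np.inf)):
        w = mu0
        u = fit._y - mu0
    else:
        phi0 = null_core["phi"]
        w = mu0 / (1.0 + phi0 * mu0)
        u = (fit._y - mu0) / (1.0 + phi0 * mu0)
    U = float(x @ u)
    xw = x * w
    XtWX = (Xr.T * w) @ Xr
    proj = Xr.T @ xw
    V = float(x @ xw - proj @ np.linalg.solve(XtWX, proj))
    if V <= 0:
        return TestResult(method=label, statistic=None, p_value=None, test_type=test_type, status=STATUS_FAILED)
    stat = U * U / V
    p = stats.chi2.sf(stat, df=1)
    return TestResult(method=label, statistic=float(stat), p_value=float(p), test_type=test_type)


def collapse_test(
    t: Union[CountData, np.ndarray],
    G: GenotypeMatrix,
    mode: str = "sum",
    C: Optional[np.ndarray] = None,
    family: str = "poisson",
    libsize_mode: str = "none",
    test_type: str = "wald",
    method_label: Optional[str] = None,
) -> TestResult:
    """Convenience wrapper: collapse, fit, and test in one call."""
    f = collapse(G, mode=mode)
    fit = fit_glm(t, f, C=C, family=family, libsize_mode=libsize_mode)
    return test_coefficient(fit, GENOTYPE_TERM, test_type=test_type, method_label=method_label)
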