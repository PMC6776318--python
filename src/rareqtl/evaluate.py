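"""Replicate runner and type-I-error / power estimation.

Runs the seven association tests (SKAT, SKAT-O, SKAT-Burden, and the four
collapsing regressions) over a grid of simulation scenarios, estimating
per-cell rejection rates with Monte-Carlo standard errors.  Each replicate
draws a fresh genotype dataset (frequencies -> genotypes -> causal flags ->
common-variant filter) and a fresh count vector; degenerate or failed
tests are excluded from rejection-rate denominators and counted.

The default grid is the full study design: 4 scenarios x mu in {50, 100,
500} x n in {15, 30, 50, 100, 500} x 9 fold changes = 540 cells grouped
into 60 (scenario, mu, n) panels.  The alternative 14-level fold grid
(1 to 2 by 0.1 plus 3, 4, 8) is available via configuration.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import glm, skat
from .errors import DegenerateInputError, EmptyRegionError
from .results import STATUS_DEGENERATE, STATUS_OK, TestResult
from .simdata import (
    ScenarioSpec,
    assign_causal,
    carrier_status,
    filter_common,
    sample_genotypes,
    simulate_counts,
    simulate_site_frequencies,
)

#: the seven approaches, in display order
DEFAULT_METHODS: Tuple[str, ...] = (
    "SKAT",
    "SKAT-O",
    "SKAT-Burden",
    "NB-sum",
    "NB-indicator",
    "Poisson-sum",
    "Poisson-indicator",
)

#: 9-level default fold grid (540-cell design)
FOLD_GRID_DEFAULT: Tuple[float, ...] = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 3.0, 4.0, 8.0)

#: 14-level literal fold grid: 1 to 2 by 0.1, plus 3, 4, 8
FOLD_GRID_LITERAL: Tuple[float, ...] = tuple(np.round(np.arange(1.0, 2.01, 0.1), 1)) + (3.0, 4.0, 8.0)

MU_GRID: Tuple[float, ...] = (50.0, 100.0, 500.0)
N_GRID: Tuple[int, ...] = (15, 30, 50, 100, 500)

_COLLAPSING = {
    "NB-sum": ("negbin", "sum"),
    "NB-indicator": ("negbin", "indicator"),
    "Poisson-sum": ("poisson", "sum"),
    "Poisson-indicator": ("poisson", "indicator"),
}


def _validate_methods(methods: Sequence[str]) -> Tuple[str, ...]:
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    unknown = [m for m in methods if m not in DEFAULT_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    if len(set(methods)) != len(methods):
        raise ValueError("method labels must be unique")
    return methods


def _child_seed(*keys: int) -> int:
    """Deterministic 31-bit seed derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def run_replicate(
    spec: ScenarioSpec,
    methods: Sequence[str] = DEFAULT_METHODS,
    seed: int = 0,
    test_type: str = "wald",
) -> List[TestResult]:
    """Simulate one dataset under ``spec`` and apply every requested method.

    All methods see the same genotypes and counts.  The genotype streams
    depend only on (seed, n, region parameters), so scenario cells sharing
    a replicate seed share genotype datasets.  Per-method failures and
    degeneracies are recorded in the result status, never raised.
    """
    methods = _validate_methods(methods)
    ss = np.random.SeedSequence(int(seed))
    s_freq, s_geno, s_causal, s_counts = ss.spawn(4)

    freqs = simulate_site_frequencies(spec.n_sites, spec.f_min, spec.f_max, seed=s_freq)
    G = sample_genotypes(freqs, spec.n, seed=s_geno)
    G = assign_causal(G, spec.causal_fraction, spec.maf_threshold, seed=s_causal)
    try:
        G = filter_common(G, spec.maf_max)
    except EmptyRegionError:
        return [TestResult(method=m, status=STATUS_DEGENERATE) for m in methods]
    i_rv, n_cv = carrier_status(G)
    counts = simulate_counts(spec, i_rv, n_cv, seed=s_counts)

    results: Dict[str, TestResult] = {}

    skat_requested = [m for m in methods if m not in _COLLAPSING]
    if skat_requested:
        try:
            y = skat.inverse_normal_transform(counts)
            null = skat.fit_null_linear(y)
            W = skat.beta_weights(G.maf_sample)
        except DegenerateInputError:
            for m in skat_requested:
                results[m] = TestResult(method=m, status=STATUS_DEGENERATE)
        else:
            if "SKAT" in methods:
                results["SKAT"] = skat.skat_test(null, G, W)
            if "SKAT-O" in methods:
                results["SKAT-O"] = skat.skato_test(null, G, W)
            if "SKAT-Burden" in methods:
                results["SKAT-Burden"] = skat.burden_test(null, G, W)

    fits: Dict[Tuple[str, str], glm.GlmFit] = {}
    for m in methods:
        if m not in _COLLAPSING:
            continue
        family, mode = _COLLAPSING[m]
        key = (family, mode)
        if key not in fits:
            f = glm.collapse(G, mode=mode)
            fits[key] = glm.fit_glm(counts, f, family=family)
        res = glm.test_coefficient(fits[key], test_type=test_type, method_label=m)
        results[m] = res

    return [results[m] for m in methods]


def summarize_pvalues(
    pvalues: Sequence[Optional[float]],
    statuses: Sequence[str],
    alpha: float,
) -> dict:
    """Rejection rate over valid replicates with Monte-Carlo SE.

    Degenerate and failed replicates are excluded from the denominator;
    their count is reported.  With zero valid replicates the rate is NaN.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    statuses = list(statuses)
    pvalues = list(pvalues)
    ok = [p for p, s in zip(pvalues, statuses) if s == STATUS_OK]
    n_valid = len(ok)
    n_invalid = len(statuses) - n_valid
    if n_valid == 0:
        return dict(rejection_rate=float("nan"), mc_se=float("nan"), n_valid=0, n_degenerate=n_invalid)
    r = float(np.mean([p <= alpha for p in ok]))
    mc_se = float(np.sqrt(r * (1.0 - r) / n_valid))
    return dict(rejection_rate=r, mc_se=mc_se, n_valid=n_valid, n_degenerate=n_invalid)


def estimate_rejection_rates(
    grid: Iterable[ScenarioSpec],
    methods: Sequence[str] = DEFAULT_METHODS,
    alpha: Optional[float] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates for every (scenario cell, method).

    Returns a long-format table with one row per cell and method:
    scenario, n, mu, fold, phi, method, rejection_rate, mc_se, n_valid,
    n_degenerate, is_null.  ``alpha`` defaults to each spec's own level.
    Replicates are independent given their derived seeds, so results do
    not depend on execution order.
    """
    methods = _validate_methods(methods)
    rows = []
    for spec in grid:
        a = alpha if alpha is not None else spec.alpha
        pvals: Dict[str, list] = {m: [] for m in methods}
        stats_: Dict[str, list] = {m: [] for m in methods}
        for rep in range(spec.reps):
            seed = _child_seed(spec.seed, rep)
            for res in run_replicate(spec, methods, seed=seed):
                pvals[res.method].append(res.p_value)
                stats_[res.method].append(res.status)
        for m in methods:
            summary = summarize_pvalues(pvals[m], stats_[m], a)
            rows.append(
                dict(
                    scenario=spec.scenario,
                    n=spec.n,
                    mu=spec.mu,
                    fold=spec.fold,
                    phi=spec.phi if spec.scenario in ("A2", "B2") else 0.0,
                    method=m,
                    is_null=spec.is_null,
                    **summary,
                )
            )
        if progress:
            print(f"done: {spec.scenario} n={spec.n} mu={spec.mu} fold={spec.fold}", flush=True)
    return pd.DataFrame(rows)


def default_scenario_grid(config: Optional[dict] = None) -> List[ScenarioSpec]:
    """Build the scenario grid (540 cells by default; 840 with the literal
    fold grid).  ``config`` keys override: scenarios, mus, ns, folds
    ('default' | 'literal' | iterable), phi, reps, alpha, seed and the
    region parameters (n_sites, causal_fraction, maf_threshold, maf_max).
    """
    cfg = dict(config or {})

    def as_tuple(value):
        if isinstance(value, (str, int, float)):
            return (value,)
        return tuple(value)

    scenarios = as_tuple(cfg.get("scenarios", ("A1", "A2", "B1", "B2")))
    mus = as_tuple(cfg.get("mus", MU_GRID))
    ns = as_tuple(cfg.get("ns", N_GRID))
    folds = cfg.get("folds", "default")
    if isinstance(folds, (int, float)):
        folds = (folds,)
    if isinstance(folds, str):
        if folds == "default":
            folds = FOLD_GRID_DEFAULT
        elif folds == "literal":
            folds = FOLD_GRID_LITERAL
        else:
            raise ValueError("folds must be 'default', 'literal', or an iterable")
    folds = tuple(float(f) for f in folds)
    master = int(cfg.get("seed", 0))
    region_keys = ("n_sites", "causal_fraction", "maf_threshold", "maf_max", "f_min", "f_max")
    region = {k: cfg[k] for k in region_keys if k in cfg}
    specs = []
    for scenario, mu, n, fold in itertools.product(scenarios, mus, ns, folds):
        # seed keyed by panel, not fold: fold levels of one panel share
        # genotype streams, making power curves comparable across fold
        panel = (scenarios.index(scenario), mus.index(mu), ns.index(n))
        specs.append(
            ScenarioSpec(
                scenario=scenario,
                n=int(n),
                mu=float(mu),
                fold=fold,
                phi=float(cfg.get("phi", 1.1)),
                reps=int(cfg.get("reps", 1000)),
                alpha=float(cfg.get("alpha", 0.05)),
                seed=_child_seed(master, *panel),
                **region,
            )
        )
    return specs


def count_panels(grid: Sequence[ScenarioSpec]) -> int:
    """Number of distinct (scenario, mu, n) panels in a grid."""
    return len({(s.scenario, s.mu, s.n) for s in grid})


def plot_power(
    table: pd.DataFrame,
    scenario: str,
    mu: float,
    n: int,
    ax=None,
):
    """Plot rejection rate against fold change for one panel.

    One line per method; the fold = 1 point is the empirical type-I error.
    Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table[(table.scenario == scenario) & (table.mu == mu) & (table.n == n)]
    if sub.empty:
        raise ValueError(f"no rows for panel ({scenario}, mu={mu}, n={n})")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for method, g in sub.groupby("method"):
        g = g.sort_values("fold")
        ax.errorbar(g["fold"], g["rejection_rate"], yerr=2 * g["mc_se"], label=method, marker="o", ms=3)
    ax.set_xlabel("fold change")
    ax.set_ylabel("rejection rate")
    ax.set_title(f"{scenario}, mu={mu:g}, n={n}")
    ax.legend(fontsize=7)
    return ax
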