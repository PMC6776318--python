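"""Synthetic rare-variant genotypes and RNA-seq read counts.

This module generates the study material for the power/type-I-error
simulations: a pool of biallelic sites in a short (~3 kb) region with a
neutral-like site-frequency spectrum, Hardy-Weinberg genotypes drawn under
linkage equilibrium, a causal subset among the very rare (MAF < 0.005)
sites, and per-subject gene-level read counts whose mean depends on causal
carrier status.

Four count scenarios are supported.  With carrier indicator ``I`` and
causal-site count ``n_cv`` per subject:

* ``A1`` — ``t_i ~ Poisson(mu*(1-I) + fold*mu*I)``
* ``A2`` — negative binomial with the same means and dispersion ``phi``
  (variance ``m + phi*m**2``)
* ``B1`` — non-carriers ``Poisson(mu)``; carriers ``Poisson(fold*mu*n_cv)``
* ``B2`` — negative binomial analogue of B1

``fold = 1`` in scenario A is the null (type-I error) configuration.
Negative-binomial draws use the exact gamma-Poisson mixture with gamma
shape ``1/phi``, so ``phi -> 0`` recovers the Poisson.

Site frequencies are drawn from a ``1/f`` density truncated to
``[f_min, f_max]`` — a self-contained stand-in for a neutral spectrum with
CDF ``F(f) = log(f/f_min) / log(f_max/f_min)`` in closed form.  Linkage
disequilibrium is deliberately not modeled.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .errors import EmptyRegionError

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: scenario labels
SCENARIOS = ("A1", "A2", "B1", "B2")

#: length of the simulated region in base pairs
REGION_BP = 3000


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantFrequencies:
    """Per-site population minor-allele frequencies for a simulated region."""

    site_id: np.ndarray
    position: np.ndarray
    freq_pool: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.site_id)
        pos = np.asarray(self.position, dtype=np.int64)
        f = np.asarray(self.freq_pool, dtype=float)
        if not (sid.shape == pos.shape == f.shape) or sid.ndim != 1:
            raise ValueError("site_id, position and freq_pool must be 1-D and equal length")
        if sid.size == 0:
            raise ValueError("empty variant set")
        if len(set(sid.tolist())) != sid.size:
            raise ValueError("site_ids must be unique")
        if np.any(f <= 0) or np.any(f > 0.5):
            raise ValueError("freq_pool must lie in (0, 0.5]")
        object.__setattr__(self, "site_id", sid)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "freq_pool", f)

    @property
    def n_sites(self) -> int:
        return int(self.site_id.size)


@dataclass(frozen=True)
class GenotypeMatrix:
    """An n-subjects x J-variants minor-allele dosage matrix with metadata.

    Dosages are 0/1/2 minor-allele counts for simulated data; matrices read
    from a VCF may contain fractional values in [0, 2] where missing
    genotypes were mean-imputed.  ``maf_sample`` is the folded sample minor
    allele frequency (column mean dosage / 2, folded to <= 0.5) and
    ``causal`` flags the sites used to generate carrier-dependent counts.
    """

    dosages: np.ndarray
    site_id: np.ndarray
    position: np.ndarray
    freq_pool: np.ndarray
    maf_sample: np.ndarray
    causal: np.ndarray
    samples: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if np.any(d < 0) or np.any(d > 2) or not np.all(np.isfinite(d)):
            raise ValueError("dosages must lie in [0, 2]")
        n, J = d.shape
        for name in ("site_id", "position", "freq_pool", "maf_sample", "causal"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (J,):
                raise ValueError(f"{name} must have length J={J}")
        maf = np.asarray(self.maf_sample, dtype=float)
        expect = _fold_maf(d)
        if not np.allclose(maf, expect, atol=1e-9):
            raise ValueError("maf_sample inconsistent with dosage columns")
        if self.samples is not None and len(self.samples) != n:
            raise ValueError("samples must have length n")
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "causal", np.asarray(self.causal, dtype=bool))
        object.__setattr__(self, "maf_sample", maf)

    @property
    def n_subjects(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_variants(self) -> int:
        return int(self.dosages.shape[1])

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the variant columns in ``index``."""
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            site_id=np.asarray(self.site_id)[index],
            position=np.asarray(self.position)[index],
            freq_pool=np.asarray(self.freq_pool)[index],
            maf_sample=self.maf_sample[index],
            causal=self.causal[index],
            samples=self.samples,
        )


def _fold_maf(dosages: np.ndarray) -> np.ndarray:
    p = dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation cell.

    ``phi`` is ignored for the Poisson scenarios A1/B1.  The region
    parameters (``n_sites`` .. ``f_max``) default to the study conditions:
    58 sites in 3 kb, 10% of MAF<0.005 sites causal, common variants
    (sample MAF > 5%) removed before testing.
    """

    scenario: str
    n: int
    mu: float
    fold: float
    phi: float = 1.1
    reps: int = 1000
    alpha: float = 0.05
    seed: int = 0
    n_sites: int = 58
    causal_fraction: float = 0.10
    maf_threshold: float = 0.005
    maf_max: float = 0.05
    f_min: float = 1e-4
    f_max: float = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.fold < 0:
            raise ValueError("fold must be >= 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def is_null(self) -> bool:
        """True when this cell measures type-I error (fold change 1)."""
        return self.fold == 1.0


@dataclass(frozen=True)
class CountData:
    """Per-subject gene read counts ``t`` and optional library sizes ``k``."""

    t: np.ndarray
    k: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("t must be a non-empty 1-D vector")
        if np.any(t < 0) or not np.allclose(t, np.round(t)):
            raise ValueError("t must contain non-negative integers")
        object.__setattr__(self, "t", t.astype(np.int64))
        if self.k is not None:
            k = np.asarray(self.k)
            if k.shape != t.shape:
                raise ValueError("k must have the same length as t")
            if np.any(k <= 0):
                raise ValueError("k must be strictly positive")
            object.__setattr__(self, "k", k.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.t.size)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_site_frequencies(
    n_sites: int,
    f_min: float = 1e-4,
    f_max: float = 0.1,
    seed: SeedLike = None,
) -> VariantFrequencies:
    """Draw site frequencies from a truncated ``1/f`` spectrum.

    The density is proportional to ``1/f`` on ``[f_min, f_max]``, i.e.
    ``F(f) = log(f / f_min) / log(f_max / f_min)``; sampling uses the
    inverse CDF ``f = f_min * (f_max / f_min)**u`` with ``u ~ U(0, 1)``.
    Positions are distinct uniform draws over the 3 kb region.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0.0 < f_min < f_max <= 0.5):
        raise ValueError("require 0 < f_min < f_max <= 0.5")
    if n_sites > REGION_BP:
        raise ValueError(f"n_sites cannot exceed the region length ({REGION_BP} bp)")
    rng = _rng(seed)
    u = rng.random(n_sites)
    freqs = f_min * (f_max / f_min) ** u
    positions = np.sort(rng.choice(REGION_BP, size=n_sites, replace=False) + 1)
    site_ids = np.array([f"site{pos:05d}" for pos in positions])
    return VariantFrequencies(site_id=site_ids, position=positions, freq_pool=freqs)


def sample_genotypes(
    freqs: VariantFrequencies, n_subjects: int, seed: SeedLike = None
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes under linkage equilibrium.

    Dosage at site ``j`` is Binomial(2, freq_pool_j), independent across
    sites and subjects.  Sample MAF is computed from the drawn matrix and
    folded to <= 0.5; causal flags start out all-False.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _rng(seed)
    d = rng.binomial(2, freqs.freq_pool, size=(n_subjects, freqs.n_sites))
    d = d.astype(float)
    return GenotypeMatrix(
        dosages=d,
        site_id=freqs.site_id,
        position=freqs.position,
        freq_pool=freqs.freq_pool,
        maf_sample=_fold_maf(d),
        causal=np.zeros(freqs.n_sites, dtype=bool),
    )


def assign_causal(
    G: GenotypeMatrix,
    causal_fraction: float = 0.10,
    maf_threshold: float = 0.005,
    seed: SeedLike = None,
) -> GenotypeMatrix:
    """Flag ``round(causal_fraction * m)`` of the m sites with
    ``freq_pool < maf_threshold`` as causal, chosen uniformly at random.

    If no site falls below the threshold a warning is emitted and no site
    is flagged.
    """
    if not (0.0 <= causal_fraction <= 1.0):
        raise ValueError("causal_fraction must be in [0, 1]")
    rng = _rng(seed)
    eligible = np.flatnonzero(np.asarray(G.freq_pool) < maf_threshold)
    causal = np.zeros(G.n_variants, dtype=bool)
    m = eligible.size
    if m == 0:
        warnings.warn(
            f"no sites with pool frequency < {maf_threshold}; nothing flagged causal",
            stacklevel=2,
        )
    else:
        n_causal = int(np.floor(causal_fraction * m + 0.5))
        if n_causal > 0:
            chosen = rng.choice(eligible, size=n_causal, replace=False)
            causal[chosen] = True
    return dataclasses.replace(G, causal=causal)


def filter_common(G: GenotypeMatrix, maf_max: float = 0.05) -> GenotypeMatrix:
    """Drop columns with sample MAF strictly above ``maf_max``.

    Raises :class:`EmptyRegionError` if every variant is removed.
    """
    if not (0.0 < maf_max < 0.5):
        raise ValueError("maf_max must be in (0, 0.5)")
    keep = np.flatnonzero(G.maf_sample <= maf_max)
    if keep.size == 0:
        raise EmptyRegionError(
            f"no variants with sample MAF <= {maf_max}; empty test region"
        )
    return G.take_variants(keep)


def carrier_status(G: GenotypeMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Per-subject causal-carrier indicator and causal-site count.

    ``I_RV[i] = 1`` iff subject ``i`` has dosage >= 1 at any causal site;
    ``n_cv[i]`` counts the causal *sites* at which the subject carries at
    least one minor allele (site count, not allele count), so
    ``n_cv >= I_RV`` elementwise.
    """
    carried = G.dosages[:, G.causal] >= 1
    n_cv = carried.sum(axis=1).astype(np.int64)
    i_rv = (n_cv > 0).astype(np.int64)
    return i_rv, n_cv


def simulate_counts(
    spec: ScenarioSpec,
    I_RV: Sequence[int],
    n_cv: Sequence[int],
    seed: SeedLike = None,
) -> CountData:
    """Draw gene read counts for one replicate of a scenario.

    See the module docstring for the four scenario mean structures.  The
    negative binomial draws use the gamma-Poisson mixture with gamma shape
    ``1/phi`` and scale ``phi * mean`` (variance ``mean + phi * mean**2``).
    """
    i_rv = np.asarray(I_RV, dtype=np.int64)
    ncv = np.asarray(n_cv, dtype=np.int64)
    if i_rv.shape != (spec.n,) or ncv.shape != (spec.n,):
        raise ValueError("I_RV and n_cv must have length spec.n")
    if np.any(ncv < i_rv):
        raise ValueError("n_cv must be >= I_RV elementwise")
    rng = _rng(seed)
    if spec.scenario.startswith("A"):
        mean = spec.mu * (1 - i_rv) + spec.fold * spec.mu * i_rv
    else:
        mean = np.where(i_rv == 1, spec.fold * spec.mu * ncv, spec.mu).astype(float)
    if spec.scenario in ("A2", "B2"):
        if spec.phi <= 0:
            raise ValueError("scenarios A2/B2 require phi > 0")
        shape = 1.0 / spec.phi
        lam = rng.gamma(shape=shape, scale=spec.phi * mean)
        t = rng.poisson(lam)
    else:
        t = rng.poisson(mean)
    return CountData(t=t)
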