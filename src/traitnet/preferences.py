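"""Preference functions and the pairwise social-attraction matrix.

Two preference types are modelled:

* **similarity** — individuals prefer partners whose trait value is close
  to their own (homophily). The trait-specific attraction is a kernel of
  the trait distance: exact match → 1, decreasing with distance.
* **popularity** — some trait values are preferred by everyone; higher
  values are more popular. Each individual gets a popularity score in
  [0, 1] (min–max normalised within the population) and a pair's
  attraction is the mean of the two scores.

Each preference carries an *importance* weight ω in [0, 1]. Per trait the
pair attraction ``a`` enters as a blended factor ``(1 - ω) + ω·a``; the
overall social attraction is the product of the factors over all
preferences, floored at a small ε so the weighted edge draw stays
well-defined. ω = 0 for every preference recovers the uniform matrix
(random network structure); ω = 1 lets a single preference dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traits import (
    CATEGORICAL,
    CIRCULAR,
    NORMAL,
    ConfigurationError,
    Population,
    TraitSpec,
)

__all__ = [
    "PreferenceSpec",
    "AttractionMatrix",
    "DegenerateTraitError",
    "similarity_kernel",
    "popularity_score",
    "popularity_scores",
    "combine_attraction",
]

DEFAULT_EPS = 1e-6

SIMILARITY = "similarity"
POPULARITY = "popularity"


class DegenerateTraitError(ValueError):
    """Popularity score requested for a trait constant across the population."""


@dataclass(frozen=True)
class PreferenceSpec:
    """One preference–trait combination.

    Attributes
    ----------
    trait : str
        Name of a trait registered in the population.
    ptype : str
        ``similarity`` or ``popularity``. Circular traits may only be used
        with similarity (circular closeness encodes relatedness; a circle
        has no "higher" end for popularity to prefer).
    importance : float
        ω in [0, 1]; 0 = no influence on attraction, 1 = maximal.
    baseline : float
        κ in [0, 1): attraction assigned to the non-matching (similarity)
        or least-preferred (popularity) case of a *categorical* kernel.
    bandwidth : float or None
        λ for the Gaussian similarity kernel on normal traits; defaults to
        the realised population standard deviation of the trait.
    negate : bool
        Flip the kernel (heterophily / unpopularity): a → 1 - a.
    """

    trait: str
    ptype: str
    importance: float
    baseline: float = 0.0
    bandwidth: float | None = None
    negate: bool = False

    def __post_init__(self) -> None:
        if self.ptype not in (SIMILARITY, POPULARITY):
            raise ConfigurationError(
                f"unknown preference type {self.ptype!r}; "
                f"expected {SIMILARITY!r} or {POPULARITY!r}"
            )
        if not 0.0 <= self.importance <= 1.0:
            raise ConfigurationError(
                f"importance must lie in [0, 1], got {self.importance}"
            )
        if not 0.0 <= self.baseline < 1.0:
            raise ConfigurationError(
                f"baseline must lie in [0, 1), got {self.baseline}"
            )
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ConfigurationError(
                f"bandwidth must be > 0, got {self.bandwidth}"
            )


@dataclass
class AttractionMatrix:
    """Symmetric pairwise social attraction in [ε, 1]; diagonal unused."""

    values: np.ndarray
    eps: float = DEFAULT_EPS

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _circular_distance(xi, xj, circumference: float):
    d = np.abs(np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float))
    return np.minimum(d, circumference - d)


def similarity_kernel(
    x_i,
    x_j,
    spec: TraitSpec,
    population: Population | None = None,
    baseline: float = 0.0,
    bandwidth: float | None = None,
):
    """Trait-specific similarity attraction in [0, 1].

    Equals 1 at zero trait distance and decreases with distance:
    categorical → 1 if same category else ``baseline``; normal →
    Gaussian kernel ``exp(-(Δx)²/(2λ²))`` with λ the population sd of the
    trait unless overridden; circular → linear decay ``1 - d/(C/2)`` in
    the circular distance ``d = min(|Δx|, C - |Δx|)``.

    Accepts scalars or broadcastable arrays; symmetric in ``x_i, x_j``.
    """
    if spec.kind == CATEGORICAL:
        same = np.asarray(x_i) == np.asarray(x_j)
        return np.where(same, 1.0, baseline)
    if spec.kind == NORMAL:
        if bandwidth is None:
            if population is None or spec.name not in population:
                raise ConfigurationError(
                    f"normal similarity kernel for {spec.name!r} needs a "
                    "population context or an explicit bandwidth"
                )
            bandwidth = float(np.std(population[spec.name]))
        if bandwidth == 0.0:
            # constant trait: all pairs coincide
            return np.where(np.asarray(x_i) == np.asarray(x_j), 1.0, 0.0)
        d = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
        return np.exp(-(d**2) / (2.0 * bandwidth**2))
    # circular
    c = spec.circumference
    for x in (x_i, x_j):
        arr = np.asarray(x, dtype=float)
        if np.any(arr < 0) or np.any(arr >= c):
            raise ValueError(
                f"circular trait value outside [0, {c}): {arr!r}"
            )
    d = _circular_distance(x_i, x_j, c)
    return 1.0 - d / (c / 2.0)


def popularity_scores(
    values: np.ndarray, spec: TraitSpec, baseline: float = 0.0
) -> np.ndarray:
    """Per-individual popularity in [0, 1]: min–max over the population.

    The population maximum scores 1. Categorical traits are rescaled to
    ``[baseline, 1]`` so κ sets the attraction of the least-preferred
    category. A constant trait vector leaves popularity undefined and
    raises :class:`DegenerateTraitError`.
    """
    vals = np.asarray(values, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateTraitError(
            f"trait {spec.name!r} is constant across the population; "
            "popularity scores are undefined"
        )
    s = (vals - lo) / (hi - lo)
    if spec.kind == CATEGORICAL and baseline > 0.0:
        s = baseline + (1.0 - baseline) * s
    return s


def popularity_score(
    x_j, spec: TraitSpec, population: Population, baseline: float = 0.0
):
    """Popularity of trait value ``x_j`` relative to the population."""
    vals = np.asarray(population[spec.name], dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateTraitError(
            f"trait {spec.name!r} is constant across the population; "
            "popularity scores are undefined"
        )
    s = (np.asarray(x_j, dtype=float) - lo) / (hi - lo)
    if spec.kind == CATEGORICAL and baseline > 0.0:
        s = baseline + (1.0 - baseline) * s
    return s


def _pair_attraction(pop: Population, pref: PreferenceSpec) -> np.ndarray:
    """n×n trait-specific pair attraction for one preference."""
    spec = pop.traits[pref.trait]
    x = pop[pref.trait]
    if pref.ptype == POPULARITY:
        if spec.kind == CIRCULAR:
            raise ConfigurationError(
                f"circular trait {pref.trait!r} cannot be used with a "
                "popularity preference"
            )
        s = popularity_scores(x, spec, pref.baseline)
        a = 0.5 * (s[:, None] + s[None, :])
    else:
        a = similarity_kernel(
            x[:, None], x[None, :], spec, pop,
            baseline=pref.baseline, bandwidth=pref.bandwidth,
        )
    a = np.asarray(a, dtype=float)
    if pref.negate:
        a = 1.0 - a
    return a


def combine_attraction(
    pop: Population,
    prefs: list[PreferenceSpec],
    eps: float = DEFAULT_EPS,
) -> AttractionMatrix:
    """Combine preference–trait attractions into the social-attraction matrix.

    ``A[i, j] = max(ε, Π_prefs [(1 - ω) + ω · a(i, j)])`` where ``a`` is the
    trait-specific pair attraction. An empty preference list, or all
    importances zero, yields the uniform matrix (every off-diagonal entry 1).
    """
    for pref in prefs:
        if pref.trait not in pop:
            raise ConfigurationError(
                f"preference refers to unregistered trait {pref.trait!r}"
            )
    n = pop.n
    A = np.ones((n, n), dtype=float)
    for pref in prefs:
        a = _pair_attraction(pop, pref)
        A *= (1.0 - pref.importance) + pref.importance * a
    A = np.maximum(A, eps)
    np.fill_diagonal(A, 0.0)
    return AttractionMatrix(values=A, eps=eps)
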