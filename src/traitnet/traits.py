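"""Trait distributions and per-individual trait values.

Three trait kinds are supported, each standing in for a class of traits
known to shape animal social networks:

* ``categorical`` — e.g. sex; values are integer category labels ``0..k-1``
  drawn equiprobably.
* ``continuous_normal`` — e.g. body size; values are draws from a normal
  distribution (location/scale are immaterial downstream because preference
  kernels normalise within the population).
* ``continuous_circular`` — a stand-in for genetic relatedness; values are
  uniform positions on a circle of given circumference, so trait closeness
  corresponds to relatedness on a ring pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitKind",
    "TraitSpec",
    "Population",
    "ConfigurationError",
    "sample_trait",
    "categorical",
    "normal",
    "circular",
]

CATEGORICAL = "categorical"
NORMAL = "continuous_normal"
CIRCULAR = "continuous_circular"
TraitKind = str

_KINDS = (CATEGORICAL, NORMAL, CIRCULAR)


class ConfigurationError(ValueError):
    """Raised when a trait or preference configuration is invalid."""


@dataclass(frozen=True)
class TraitSpec:
    """Distribution of a single trait across the population.

    Parameters not belonging to ``kind`` are ignored.

    Attributes
    ----------
    name : str
        Trait label, used as the column name in trait tables.
    kind : str
        One of ``categorical``, ``continuous_normal``, ``continuous_circular``.
    n_categories : int
        Number of categories (categorical only), at least 2. Default 2,
        matching a two-sex trait.
    mean, sd : float
        Normal parameters (continuous_normal only). Defaults 0 and 1.
    circumference : float
        Circle circumference (continuous_circular only). Default 1.
    """

    name: str
    kind: TraitKind
    n_categories: int = 2
    mean: float = 0.0
    sd: float = 1.0
    circumference: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown trait kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind == CATEGORICAL and self.n_categories < 2:
            raise ConfigurationError(
                f"n_categories must be >= 2, got {self.n_categories}"
            )
        if self.kind == NORMAL and not self.sd > 0:
            raise ConfigurationError(f"sd must be > 0, got {self.sd}")
        if self.kind == CIRCULAR and not self.circumference > 0:
            raise ConfigurationError(
                f"circumference must be > 0, got {self.circumference}"
            )


def categorical(name: str = "sex", n_categories: int = 2) -> TraitSpec:
    return TraitSpec(name=name, kind=CATEGORICAL, n_categories=n_categories)


def normal(name: str = "size", mean: float = 0.0, sd: float = 1.0) -> TraitSpec:
    return TraitSpec(name=name, kind=NORMAL, mean=mean, sd=sd)


def circular(name: str = "relatedness", circumference: float = 1.0) -> TraitSpec:
    return TraitSpec(name=name, kind=CIRCULAR, circumference=circumference)


def sample_trait(
    spec: TraitSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` trait values from ``spec``'s distribution.

    Categorical categories are equiprobable; normal values are
    ``Normal(mean, sd)``; circular values are uniform on
    ``[0, circumference)``. Reproducible given the generator state.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if spec.kind == CATEGORICAL:
        return rng.integers(0, spec.n_categories, size=n)
    if spec.kind == NORMAL:
        return rng.normal(spec.mean, spec.sd, size=n)
    return rng.uniform(0.0, spec.circumference, size=n)


@dataclass
class Population:
    """A set of individuals with one value per registered trait.

    Invariants: every registered trait has exactly ``n`` values; circular
    values lie in ``[0, circumference)``.
    """

    n: int
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigurationError(f"population size must be >= 3, got {self.n}")
        for name in self.traits:
            if name in self.values:
                self._check(name, self.values[name])

    def _check(self, name: str, vals: np.ndarray) -> None:
        if len(vals) != self.n:
            raise ConfigurationError(
                f"trait {name!r} has {len(vals)} values for n={self.n} individuals"
            )
        spec = self.traits[name]
        if spec.kind == CIRCULAR:
            if np.any(vals < 0) or np.any(vals >= spec.circumference):
                raise ConfigurationError(
                    f"circular trait {name!r} has values outside "
                    f"[0, {spec.circumference})"
                )

    def add_trait(
        self,
        spec: TraitSpec,
        values: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> "Population":
        """Register a trait, sampling values with ``rng`` if none are given."""
        if values is None:
            if rng is None:
                raise ConfigurationError(
                    f"trait {spec.name!r}: provide values or an rng to sample them"
                )
            values = sample_trait(spec, self.n, rng)
        values = np.asarray(values)
        self.traits[spec.name] = spec
        self._check(spec.name, values)
        self.values[spec.name] = values
        return self

    def __contains__(self, name: str) -> bool:
        return name in self.traits

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    # -- trait tables -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per individual, one column per trait."""
        return pd.DataFrame({name: self.values[name] for name in self.traits})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, specs: dict[str, TraitSpec] | None = None
    ) -> "Population":
        """Build a population from a trait table.

        Columns without a spec are typed by inspection: integer columns
        become categorical, float columns continuous_normal.
        """
        specs = dict(specs or {})
        pop = cls(n=len(frame))
        for col in frame.columns:
            vals = frame[col].to_numpy()
            if col in specs:
                spec = specs[col]
            elif np.issubdtype(vals.dtype, np.integer):
                spec = TraitSpec(col, CATEGORICAL, n_categories=max(2, int(vals.max()) + 1))
            else:
                spec = TraitSpec(col, NORMAL)
            pop.add_trait(spec, values=vals)
        return pop

    @classmethod
    def from_csv(cls, path, specs: dict[str, TraitSpec] | None = None) -> "Population":
        return cls.from_frame(pd.read_csv(path), specs)

    @classmethod
    def sample(
        cls, n: int, specs: list[TraitSpec], rng: np.random.Generator
    ) -> "Population":
        """Sample a fresh population with one value vector per spec."""
        pop = cls(n=n)
        for spec in specs:
            pop.add_trait(spec, rng=rng)
        return pop
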