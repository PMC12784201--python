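"""Ensemble generation and importance sweeps.

The study design: fix one *popularity trait* and one *similarity trait*,
vary the importance ω of each preference from 0 (no influence — random
structure) to 1 (maximal influence) over a grid, and at every grid point
generate an ensemble of connected networks (default 100 networks of 100
nodes, mean degree 10). Every network is scored with the global structure
measures; optionally each is also run through transmission replicates
(default 10 per subtype, giving 1,000 simulations per subtype per
ensemble of 100) and through all configured node-removal strategies.
Ensemble means and sds per grid point reproduce the structure/function
analyses of the model.

Reproducibility: each network's generator is derived from
``SeedSequence([master_seed, grid_index, replicate_index])`` so any subset
of a sweep can be re-run bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import netgen
from .dynamics import MILESTONES, TransmissionConfig, run_transmissions
from .netmetrics import MetricSet, compute_metrics
from .preferences import POPULARITY, SIMILARITY, PreferenceSpec, combine_attraction
from .robustness import RemovalStrategy, component_break_time, removal_order
from .traits import CIRCULAR, ConfigurationError, Population, TraitSpec

__all__ = [
    "SweepConfig",
    "EnsembleResult",
    "generate_network",
    "run_sweep",
    "count_transmission_runs",
    "structural_space_projection",
    "separate_importance_grid",
    "joint_importance_grid",
]


def separate_importance_grid(ptype: str, points: int = 11) -> list[tuple[float, float]]:
    """Vary one preference's ω over [0, 1]; the other stays at 0."""
    om = np.linspace(0.0, 1.0, points)
    if ptype == POPULARITY:
        return [(float(w), 0.0) for w in om]
    if ptype == SIMILARITY:
        return [(0.0, float(w)) for w in om]
    raise ConfigurationError(f"unknown preference type {ptype!r}")


def joint_importance_grid(points: int = 11) -> list[tuple[float, float]]:
    """Trade relative importance: (ω_pop, ω_sim) = (t, 1 - t)."""
    ts = np.linspace(0.0, 1.0, points)
    return [(float(t), float(1.0 - t)) for t in ts]


@dataclass(frozen=True)
class SweepConfig:
    """Full specification of one importance sweep.

    A circular trait is only admitted in the similarity slot. ``baseline``
    is the κ passed to categorical kernels. Structure measures are always
    computed; transmission and removal blocks run only if configured.
    """

    popularity_trait: TraitSpec | None
    similarity_trait: TraitSpec | None
    importance_grid: Sequence[tuple[float, float]]
    n: int = 100
    mean_degree: float = 10.0
    ensemble_size: int = 100
    transmission: Sequence[TransmissionConfig] = ()
    removal: Sequence[RemovalStrategy] = ()
    reps_per_network: int = 10
    master_seed: int = 0
    weighted: bool = True
    weighted_metrics: bool = True
    collect_degrees: bool = False
    baseline: float = 0.0
    max_retries: int = netgen.DEFAULT_MAX_RETRIES

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")
        if self.popularity_trait is not None and self.popularity_trait.kind == CIRCULAR:
            raise ConfigurationError(
                "the circular trait may only be used as a similarity trait"
            )
        for wp, ws in self.importance_grid:
            if not (0.0 <= wp <= 1.0 and 0.0 <= ws <= 1.0):
                raise ConfigurationError(
                    f"importance grid point ({wp}, {ws}) outside [0, 1]^2"
                )
            if wp > 0 and self.popularity_trait is None:
                raise ConfigurationError(
                    "grid varies popularity importance but no popularity trait is set"
                )
            if ws > 0 and self.similarity_trait is None:
                raise ConfigurationError(
                    "grid varies similarity importance but no similarity trait is set"
                )

    # -- config file -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        def _trait(block):
            if block is None:
                return None
            return TraitSpec(**block)

        grid = d.get("importance_grid")
        if grid is None:
            mode = d.get("grid", {"separate": POPULARITY})
            if "separate" in mode:
                grid = separate_importance_grid(
                    mode["separate"], mode.get("points", 11)
                )
            else:
                grid = joint_importance_grid(mode.get("points", 11))
        else:
            grid = [tuple(p) for p in grid]
        trans = [TransmissionConfig(**t) for t in d.get("transmission", [])]
        rem = [RemovalStrategy(**r) for r in d.get("removal", [])]
        keys = (
            "n", "mean_degree", "ensemble_size", "reps_per_network",
            "master_seed", "weighted", "weighted_metrics", "collect_degrees",
            "baseline", "max_retries",
        )
        kw = {k: d[k] for k in keys if k in d}
        return cls(
            popularity_trait=_trait(d.get("popularity_trait")),
            similarity_trait=_trait(d.get("similarity_trait")),
            importance_grid=grid,
            transmission=trans,
            removal=rem,
            **kw,
        )

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class EnsembleResult:
    """Sweep output: per-grid-point aggregates and per-network rows."""

    table: pd.DataFrame
    per_network: pd.DataFrame
    pooled_degrees: dict[int, np.ndarray] = field(default_factory=dict)
    config: SweepConfig | None = None


def count_transmission_runs(cfg: SweepConfig) -> int:
    """Simulations per transmission subtype per grid point."""
    return cfg.ensemble_size * cfg.reps_per_network


def _preferences(cfg: SweepConfig, omega_pop: float, omega_sim: float):
    specs, prefs = [], []
    if cfg.popularity_trait is not None:
        specs.append(cfg.popularity_trait)
        prefs.append(
            PreferenceSpec(
                cfg.popularity_trait.name, POPULARITY, omega_pop, cfg.baseline
            )
        )
    if cfg.similarity_trait is not None:
        if cfg.similarity_trait.name not in {s.name for s in specs}:
            specs.append(cfg.similarity_trait)
        prefs.append(
            PreferenceSpec(
                cfg.similarity_trait.name, SIMILARITY, omega_sim, cfg.baseline
            )
        )
    return specs, prefs


def generate_network(
    cfg: SweepConfig,
    omega_pop: float,
    omega_sim: float,
    rng: np.random.Generator,
) -> netgen.SocialNetwork:
    """One network at one importance point: traits → attraction → draw."""
    specs, prefs = _preferences(cfg, omega_pop, omega_sim)
    pop = Population.sample(cfg.n, specs, rng)
    A = combine_attraction(pop, prefs)
    return netgen.draw_network(
        A,
        cfg.mean_degree,
        weighted=cfg.weighted,
        rng=rng,
        max_retries=cfg.max_retries,
        population=pop,
    )


def _network_rng(master_seed: int, grid_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, grid_index, rep])
    )


def run_sweep(cfg: SweepConfig) -> EnsembleResult:
    """Run the full sweep: generate, measure, transmit, remove, aggregate.

    Per grid point, ``ensemble_size`` networks are generated (traits
    redrawn per network), measured, and — if configured — run through
    every transmission subtype (``reps_per_network`` replicates each) and
    every removal strategy. Undefined measures are excluded from means
    with a defined-sample count. A generation failure aborts the sweep
    with the offending grid point.
    """
    pname = cfg.popularity_trait.name if cfg.popularity_trait else None
    sname = cfg.similarity_trait.name if cfg.similarity_trait else None

    net_rows: list[dict] = []
    agg_rows: list[dict] = []
    pooled: dict[int, np.ndarray] = {}

    for gi, (wp, ws) in enumerate(cfg.importance_grid):
        trans_times: dict[str, dict[int, list[int]]] = {
            t.label: {p: [] for p in MILESTONES} for t in cfg.transmission
        }
        break_times: dict[str, list[int]] = {s.label: [] for s in cfg.removal}
        degs: list[np.ndarray] = []
        rejections = 0

        for rep in range(cfg.ensemble_size):
            rng = _network_rng(cfg.master_seed, gi, rep)
            try:
                net = generate_network(cfg, wp, ws, rng)
            except netgen.GenerationError as err:
                raise netgen.GenerationError(
                    f"grid point {gi} (omega_pop={wp}, omega_sim={ws}), "
                    f"replicate {rep}: {err}",
                    rejections=err.rejections,
                ) from err
            rejections += net.meta["rejections"]
            ms = compute_metrics(
                net,
                popularity_trait=pname,
                similarity_trait=sname,
                weighted=cfg.weighted and cfg.weighted_metrics,
            )
            row = {"grid_index": gi, "rep": rep, "omega_pop": wp, "omega_sim": ws}
            row.update(ms.as_dict())
            net_rows.append(row)
            if cfg.collect_degrees:
                degs.append(net.degrees())

            for tcfg in cfg.transmission:
                results = run_transmissions(net, tcfg, cfg.reps_per_network, rng)
                for pct in MILESTONES:
                    trans_times[tcfg.label][pct].extend(
                        r.milestone(pct) for r in results
                    )
            for strat in cfg.removal:
                order = removal_order(net, strat, rng)
                break_times[strat.label].append(
                    component_break_time(net, order).break_time
                )

        sub = pd.DataFrame(net_rows[-cfg.ensemble_size:])
        agg = {
            "grid_index": gi,
            "omega_pop": wp,
            "omega_sim": ws,
            "rejections": rejections,
        }
        for col in MetricSet.__dataclass_fields__:
            vals = sub[col].to_numpy()
            ok = np.isfinite(vals)
            agg[f"{col}_mean"] = float(np.mean(vals[ok])) if ok.any() else float("nan")
            agg[f"{col}_sd"] = (
                float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else float("nan")
            )
            agg[f"{col}_n"] = int(ok.sum())
        for label, per_pct in trans_times.items():
            for pct, times in per_pct.items():
                arr = np.asarray(times, dtype=float)
                agg[f"{label}_t{pct}_mean"] = float(arr.mean())
                agg[f"{label}_t{pct}_sd"] = float(arr.std(ddof=1))
                agg[f"{label}_eff{pct}"] = float(1.0 / arr.mean())
        for label, times in break_times.items():
            arr = np.asarray(times, dtype=float)
            agg[f"break_{label}_mean"] = float(arr.mean())
            agg[f"break_{label}_sd"] = (
                float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
            )
        agg_rows.append(agg)
        if cfg.collect_degrees:
            pooled[gi] = np.concatenate(degs)

    return EnsembleResult(
        table=pd.DataFrame(agg_rows),
        per_network=pd.DataFrame(net_rows),
        pooled_degrees=pooled,
        config=cfg,
    )


_SPACES = {
    "small_world": ("clustering_mean", "mean_distance_mean"),
    "degree": ("degree_variation_mean", "degree_assortativity_mean"),
}


def structural_space_projection(result: EnsembleResult, space: str) -> pd.DataFrame:
    """Project ensemble means into a 2-D structural space.

    ``small_world`` pairs clustering with mean distance; ``degree`` pairs
    degree variation with degree assortativity. One point per grid point.
    """
    if space not in _SPACES:
        raise ValueError(f"unknown space {space!r}; expected one of {list(_SPACES)}")
    xcol, ycol = _SPACES[space]
    for col in (xcol, ycol):
        if col not in result.table.columns:
            raise ValueError(f"sweep result lacks {col!r}")
    out = result.table[["omega_pop", "omega_sim", xcol, ycol]].copy()
    out.columns = ["omega_pop", "omega_sim", "x", "y"]
    return out
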