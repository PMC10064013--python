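"""Synthetic split-root experiment generator.

Emulates the full observable output of a split-root study on a perennial
grass: per replicate (one clone in one box) a simulated root system per
compartment, a dated trace series of cumulative traced root length per
compartment, and a per-order trait table.

Two treatments are supported.  ``resource_partitioned`` grows the two
compartments under distinct calibrations ("water": high water, no
nutrients; "nutrient": high nutrients, low water).  ``resource_mixed``
uses one symmetric calibration for both compartments.  Default replicate
counts are 9 (partitioned) and 4 (mixed).

Observation model (both invented plumbing, documented in the methods
note): traced length is true total length times a Beta-distributed
visibility fraction (mean 0.2 — only roots pressed against the plexiglass
front are traceable), constant within a replicate × compartment, with
multiplicative lognormal noise applied to the per-interval increments so
traces stay non-decreasing; biomass carries a lognormal tissue-density
multiplier (CV 10%) per replicate × compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import traits as _traits
from .config import packaged_calibration
from .params import ConfigurationError, GrowthParams
from .rsa import RootSystem

__all__ = [
    "ExperimentConfig",
    "Replicate",
    "default_trace_days",
    "partitioned_config",
    "mixed_config",
    "generate_experiment",
    "allocation_summary",
]

#: Default experiment duration, days (planting to harvest at full leaf
#: development under the packaged calibrations).
DURATION = 25.0
#: Visibility fraction Beta(a, b): mean 0.2, sd ≈ 0.09.
VISIBILITY_BETA = (4.0, 16.0)
#: Lognormal sigma of per-interval trace observation noise.
TRACE_NOISE_SIGMA = 0.05
#: Lognormal sigma of the per-replicate tissue-density multiplier (CV 10%).
BIOMASS_SIGMA = 0.10


def default_trace_days(duration: float = DURATION) -> list[float]:
    """Tracing schedule: three times weekly (days 2, 4, 7 of each week)."""
    days = []
    week = 0
    while True:
        for d in (2.0, 4.0, 7.0):
            day = 7.0 * week + d
            if day > duration:
                return days
            days.append(day)
        week += 1


@dataclass
class ExperimentConfig:
    """Layout of one synthetic split-root experiment.

    ``calibrations`` maps compartment label → per-order growth parameters;
    a partitioned treatment needs two distinct calibrations, a mixed
    treatment two identical ones.
    """

    treatment: str
    n_replicates: int
    calibrations: dict[str, dict[int, GrowthParams]]
    duration: float = DURATION
    trace_days: list[float] | None = None
    visibility_beta: tuple[float, float] = VISIBILITY_BETA
    trace_noise_sigma: float = TRACE_NOISE_SIGMA
    biomass_sigma: float = BIOMASS_SIGMA

    def __post_init__(self) -> None:
        if self.trace_days is None:
            self.trace_days = default_trace_days(self.duration)
        if self.treatment not in ("resource_mixed", "resource_partitioned"):
            raise ConfigurationError(
                f"unknown treatment {self.treatment!r}")
        if len(self.calibrations) != 2:
            raise ConfigurationError("exactly two compartments required")
        if self.n_replicates < 0:
            raise ConfigurationError("n_replicates must be >= 0")
        a, b = self.calibrations.values()
        same = {bn: p.with_(compartment_tag="") for bn, p in a.items()} == \
               {bn: p.with_(compartment_tag="") for bn, p in b.items()}
        if self.treatment == "resource_mixed" and not same:
            raise ConfigurationError(
                "resource_mixed requires identical calibrations for both "
                "compartments")
        if self.treatment == "resource_partitioned" and same:
            raise ConfigurationError(
                "resource_partitioned requires two distinct calibrations")


def partitioned_config(n_replicates: int = 9, **kw) -> ExperimentConfig:
    """The resource-partitioned treatment under the packaged calibrations
    (default n = 9)."""
    return ExperimentConfig(
        treatment="resource_partitioned", n_replicates=n_replicates,
        calibrations={"water": packaged_calibration("water"),
                      "nutrient": packaged_calibration("nutrient")}, **kw)


def mixed_config(n_replicates: int = 4, **kw) -> ExperimentConfig:
    """The resource-mixed treatment: the symmetric packaged calibration in
    both compartments (default n = 4)."""
    return ExperimentConfig(
        treatment="resource_mixed", n_replicates=n_replicates,
        calibrations={"left": packaged_calibration("mixed"),
                      "right": packaged_calibration("mixed")}, **kw)


@dataclass
class Replicate:
    """One synthetic clone: systems, traces and traits per compartment."""

    index: int
    systems: dict[str, RootSystem]
    traces: dict[str, pd.DataFrame]
    traits: pd.DataFrame


def _trace_series(system: RootSystem, days, visibility, noise_sigma,
                  rng) -> pd.DataFrame:
    """Observed cumulative traced length at each tracing day."""
    true_lengths = np.array(
        [sum(a.length_at(d) for a in system.axes) for d in days])
    increments = np.diff(np.concatenate([[0.0], true_lengths]))
    if noise_sigma > 0:
        increments = increments * rng.lognormal(0.0, noise_sigma,
                                                size=len(increments))
    return pd.DataFrame({"day": list(days),
                         "length_cm": np.cumsum(increments) * visibility})


def generate_experiment(config: ExperimentConfig,
                        seed: int | np.random.SeedSequence = 0
                        ) -> list[Replicate]:
    """Generate ``config.n_replicates`` independent synthetic replicates.

    Each replicate simulates both compartments to ``config.duration``
    days (the two sides of the barrier get ``side`` +1 and −1), samples
    its trace series at the tracing days, and tabulates per-order traits.
    The same seed reproduces identical output, byte for byte once
    serialised.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    replicates = []
    rep_seeds = ss.spawn(config.n_replicates)
    for i, rep_ss in enumerate(rep_seeds):
        systems: dict[str, RootSystem] = {}
        traces: dict[str, pd.DataFrame] = {}
        tables = []
        comp_seeds = rep_ss.spawn(len(config.calibrations))
        for (tag, cal), comp_ss, side in zip(config.calibrations.items(),
                                             comp_seeds, (1, -1)):
            sys_ss, obs_ss = comp_ss.spawn(2)
            system = RootSystem(cal, seed=sys_ss, compartment_tag=tag,
                                side=side)
            system.grow(config.duration)
            obs_rng = np.random.default_rng(obs_ss)
            visibility = float(obs_rng.beta(*config.visibility_beta))
            density_factor = float(obs_rng.lognormal(0.0,
                                                     config.biomass_sigma))
            systems[tag] = system
            traces[tag] = _trace_series(system, config.trace_days,
                                        visibility,
                                        config.trace_noise_sigma, obs_rng)
            tables.append(_traits.measure(system, replicate=i,
                                          compartment=tag,
                                          density_factor=density_factor))
        replicates.append(Replicate(
            index=i, systems=systems, traces=traces,
            traits=pd.concat(tables, ignore_index=True)))
    return replicates


def allocation_summary(replicates: list[Replicate], compartment: str,
                       metric: str = "length") -> pd.DataFrame:
    """Mean ± sd allocation proportion toward ``compartment`` per
    branching number, across replicates."""
    rows: dict[int, list[float]] = {}
    for rep in replicates:
        tags = list(rep.systems)
        other = [t for t in tags if t != compartment][0]
        ta = rep.traits[rep.traits["compartment"] == compartment]
        tb = rep.traits[rep.traits["compartment"] == other]
        bns = sorted(rep.traits["branching_number"].unique())
        for bn in bns:
            try:
                p = _traits.allocation_proportions(ta, tb, bn, metric)
            except _traits.UndefinedTraitError:
                continue
            rows.setdefault(int(bn), []).append(p)
    return pd.DataFrame({
        "branching_number": sorted(rows),
        "mean_proportion": [float(np.mean(rows[bn])) for bn in sorted(rows)],
        "sd_proportion": [float(np.std(rows[bn], ddof=1))
                          if len(rows[bn]) > 1 else 0.0
                          for bn in sorted(rows)],
        "n": [len(rows[bn]) for bn in sorted(rows)],
    }).set_index("branching_number")
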