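"""Order-based root trait computation.

Works on per-order trait tables — tidy frames with one row per
(replicate, compartment, branching number), the shape produced by
root-scan software exports and by :func:`measure` on simulated systems —
and on dated trace series of cumulative traced root length.

Trait definitions (b = branching number):

* branching intensity  BI(b) = tips(b) / length(b)          [tips cm⁻¹]
* branching density    BD(b) = tips(b) / length(b−1)        [tips cm⁻¹]
* branching ratio      BR(b) = tips(b) / root count(b−1)    [tips root⁻¹]
* specific root length SRL   = Σ length / Σ biomass         [cm g⁻¹]
* mass fraction              = compartment biomass / total  [g g⁻¹]

Relative elongation rate normalises the absolute tracing-interval rate
(ΔL/Δt, cm day⁻¹) by the traced length at the end of the interval and
scales cm→mm, giving mm cm⁻¹ day⁻¹.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TABLE_COLUMNS",
    "NotApplicableError",
    "UndefinedTraitError",
    "measure",
    "branching_intensity",
    "branching_density",
    "branching_ratio",
    "mean_branch_angle",
    "allocation_proportions",
    "srl",
    "mass_fraction",
    "relative_elongation_rate",
    "trimmed_mean",
    "trait_summary",
]

#: Canonical column order of a per-order trait table (CSV header).
TABLE_COLUMNS = ["replicate", "compartment", "branching_number", "length_cm",
                 "surface_area_cm2", "tips", "axes", "biomass_g",
                 "mean_angle_deg"]


class NotApplicableError(ValueError):
    """The trait is not defined for this branching number (e.g. BD at 0)."""


class UndefinedTraitError(ValueError):
    """The trait's denominator is zero; the value is undefined."""


def measure(system, replicate: int = 0, compartment: str | None = None,
            density_factor: float = 1.0) -> pd.DataFrame:
    """Per-order trait table of a simulated root system at its clock.

    Every axis carries exactly one tip, so tip count equals axis count.
    Surface area treats each root as a cylinder of its order's radius;
    biomass is length × linear density, optionally scaled by
    ``density_factor`` (replicate-level tissue-density variation).
    """
    tag = compartment if compartment is not None else \
        (system.compartment_tag or "compartment")
    rows = []
    by_order: dict[int, list] = {}
    for a in system.axes:
        by_order.setdefault(a.branching_number, []).append(a)
    for bn in sorted(by_order):
        axes = by_order[bn]
        length = float(sum(a.length for a in axes))
        area = float(sum(2 * math.pi * a.radius * a.length for a in axes))
        mass = float(sum(a.linear_density * a.length for a in axes))
        rows.append({
            "replicate": replicate, "compartment": tag,
            "branching_number": bn, "length_cm": length,
            "surface_area_cm2": area, "tips": len(axes), "axes": len(axes),
            "biomass_g": mass * density_factor,
            "mean_angle_deg": float(np.mean([a.axial_angle for a in axes])),
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _sum(table: pd.DataFrame, bn: int, col: str) -> float:
    sel = table.loc[table["branching_number"] == bn, col]
    return float(sel.sum())


def branching_intensity(table: pd.DataFrame, bn: int) -> float:
    """Tips of order ``bn`` per cm of root length of the same order."""
    length = _sum(table, bn, "length_cm")
    if length <= 0:
        raise UndefinedTraitError(
            f"no root length at branching number {bn}")
    return _sum(table, bn, "tips") / length


def branching_density(table: pd.DataFrame, bn: int) -> float:
    """Tips of order ``bn`` per cm of root length of order ``bn − 1``."""
    if bn < 1:
        raise NotApplicableError(
            "branching density is undefined for branching number 0 "
            "(no preceding order)")
    length = _sum(table, bn - 1, "length_cm")
    if length <= 0:
        raise UndefinedTraitError(
            f"no root length at branching number {bn - 1}")
    return _sum(table, bn, "tips") / length


def branching_ratio(table: pd.DataFrame, bn: int) -> float:
    """Tips of order ``bn`` per individual root of order ``bn − 1``."""
    if bn < 1:
        raise NotApplicableError(
            "branching ratio is undefined for branching number 0")
    n_parent = _sum(table, bn - 1, "axes")
    if n_parent <= 0:
        raise UndefinedTraitError(
            f"no roots at branching number {bn - 1}")
    return _sum(table, bn, "tips") / n_parent


def mean_branch_angle(table: pd.DataFrame, bn: int) -> float:
    """Axis-count-weighted mean axial insertion angle of order ``bn``."""
    sel = table[table["branching_number"] == bn]
    n = float(sel["axes"].sum())
    if n <= 0:
        raise UndefinedTraitError(f"no roots at branching number {bn}")
    return float((sel["mean_angle_deg"] * sel["axes"]).sum() / n)


_METRIC_COLS = {"length": "length_cm", "surface_area": "surface_area_cm2",
                "tips": "tips"}


def allocation_proportions(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           bn: int, metric: str) -> float:
    """Fraction of a metric at order ``bn`` allocated to compartment A.

    ``metric`` is one of ``length``, ``surface_area``, ``tips``.  The
    proportions of the two compartments sum to one by construction.
    """
    try:
        col = _METRIC_COLS[metric]
    except KeyError:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLS)}, "
                         f"got {metric!r}") from None
    a = _sum(table_a, bn, col)
    b = _sum(table_b, bn, col)
    if a + b <= 0:
        raise UndefinedTraitError(
            f"{metric} is zero in both compartments at branching number {bn}")
    return a / (a + b)


def srl(table: pd.DataFrame, compartment: str) -> float:
    """Specific root length of a compartment: Σ length / Σ biomass, cm g⁻¹."""
    sel = table[table["compartment"] == compartment]
    mass = float(sel["biomass_g"].sum())
    if mass <= 0:
        raise UndefinedTraitError(f"zero biomass in {compartment!r}")
    return float(sel["length_cm"].sum()) / mass


def mass_fraction(table: pd.DataFrame, compartment: str) -> float:
    """Compartment root biomass over whole-clone root biomass, g g⁻¹."""
    total = float(table["biomass_g"].sum())
    if total <= 0:
        raise UndefinedTraitError("zero total biomass")
    sel = table[table["compartment"] == compartment]
    return float(sel["biomass_g"].sum()) / total


def relative_elongation_rate(series: pd.DataFrame, literal: bool = False
                             ) -> np.ndarray:
    """Per-interval relative elongation rates of a trace series.

    ``series`` needs columns ``day`` (strictly increasing) and
    ``length_cm`` (cumulative traced length, non-decreasing).  For each
    interval the absolute rate is ΔL/Δdays (cm day⁻¹) and the relative
    rate is the absolute rate divided by the traced length at the end of
    the interval, ×10 for the cm→mm unit change (mm cm⁻¹ day⁻¹).

    ``literal=True`` instead evaluates the published formula text
    Li ÷ (absolute rate) × 10 verbatim, which reduces to 10·Δdays; it is
    retained for auditability only, as it is dimensionally inconsistent
    with the stated units.
    """
    days = np.asarray(series["day"], dtype=float)
    length = np.asarray(series["length_cm"], dtype=float)
    if len(days) < 2:
        raise ValueError("need at least two trace records")
    if np.any(np.diff(days) <= 0):
        raise ValueError("trace days must be strictly increasing")
    if np.any(length < 0) or np.any(np.diff(length) < 0):
        raise ValueError("traced lengths must be non-negative and "
                         "non-decreasing")
    d_len = np.diff(length)
    d_day = np.diff(days)
    abs_rate = d_len / d_day
    if literal:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(abs_rate > 0, d_len / abs_rate * 10.0, 0.0)
    end_len = length[1:]
    if np.any(end_len <= 0):
        raise UndefinedTraitError("traced length is zero at an interval end")
    return abs_rate / end_len * 10.0


def trimmed_mean(values, fraction: float = 0.2) -> float:
    """Mean after dropping the lowest and highest ``fraction`` of values.

    ``floor(fraction·n)`` values are removed from each tail.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    if n - 2 * int(math.floor(fraction * n)) < 1:
        raise ValueError("no values left after trimming")
    return float(_sps.trim_mean(values, fraction))


def trait_summary(table: pd.DataFrame) -> pd.DataFrame:
    """BI/BD/BR/BA per (compartment, branching number), aggregated over
    replicates; undefined/not-applicable entries are NaN (printed n/a)."""
    rows = []
    for comp, sub in table.groupby("compartment", sort=True):
        for bn in sorted(sub["branching_number"].unique()):
            def _try(f, *a):
                try:
                    return f(sub, *a)
                except (NotApplicableError, UndefinedTraitError):
                    return float("nan")
            rows.append({
                "compartment": comp, "branching_number": int(bn),
                "branching_intensity": _try(branching_intensity, bn),
                "branching_density": _try(branching_density, bn),
                "branching_ratio": _try(branching_ratio, bn),
                "branching_angle": _try(mean_branch_angle, bn),
            })
    return pd.DataFrame(rows)
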