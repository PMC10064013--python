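"""Lightweight comparisons for allocation proportions and trait means.

The allocation question — does a compartment receive more than half of a
metric at a given branching number? — is cast as an exact two-sided
binomial test against p₀ = 0.5, with continuous metrics (length, surface
area) discretised to 1-mm units to serve as trials.  Group comparisons of
scalar traits (SRL, mass fraction, elongation rates) use classical
one-way ANOVA.  These are deliberately simple stand-ins for the
mixed-model machinery a full field analysis would use; no random effects,
no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import traits as _traits

__all__ = [
    "ComparisonResult",
    "discretize_mm",
    "proportion_test",
    "one_way_anova",
    "compare_compartments",
]

#: Discretisation unit for length/surface-area "trials": 1 mm (or 1 mm²).
MM_PER_CM = 10


@dataclass
class ComparisonResult:
    """Outcome of one per-order comparison."""

    bn: int | None
    metric: str
    estimate: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def discretize_mm(value_cm: float) -> int:
    """A length (cm) or area (cm²) as a count of 1-mm (1-mm²) units."""
    return int(round(value_cm * MM_PER_CM))


def proportion_test(successes: int, total: int, bn: int | None = None,
                    metric: str = "") -> ComparisonResult:
    """Exact two-sided binomial test of an allocation against p₀ = 0.5.

    ``successes`` is the discretised amount in compartment A, ``total``
    the amount in both compartments combined.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    res = _sps.binomtest(successes, total, p=0.5, alternative="two-sided")
    return ComparisonResult(bn=bn, metric=metric,
                            estimate=successes / total,
                            statistic=float(successes),
                            p_value=float(res.pvalue),
                            n_a=successes, n_b=total - successes)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over ≥ 2 groups.

    Returns ``(F, p)`` with (k−1, N−k) degrees of freedom.  When every
    value is identical the contract is F = 0, p = 1 (rather than the
    0/0 indeterminate form).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 value each")
    n_total = sum(len(g) for g in groups)
    if n_total - len(groups) < 1:
        raise ValueError("need >= 1 group with >= 2 values")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    if ss_within == 0:
        return math.inf, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(_sps.f.sf(f, df1, df2))
    return float(f), p


def compare_compartments(table: pd.DataFrame,
                         metrics=("length", "surface_area", "tips")
                         ) -> pd.DataFrame:
    """Per-(metric, branching number) allocation tests on a trait table.

    The table must hold exactly two compartments; compartment A is the
    alphabetically first.  Continuous metrics are discretised to 1-mm
    units, tip counts used as-is.  One row per test, plus one-way ANOVA
    rows comparing per-replicate SRL and mass fraction between
    compartments.
    """
    comps = sorted(table["compartment"].unique())
    if len(comps) != 2:
        raise ValueError("trait table must hold exactly two compartments")
    a, b = comps
    col = {"length": "length_cm", "surface_area": "surface_area_cm2",
           "tips": "tips"}
    rows = []
    for metric in metrics:
        for bn in sorted(table["branching_number"].unique()):
            sel = table[table["branching_number"] == bn]
            va = sel.loc[sel["compartment"] == a, col[metric]].sum()
            vb = sel.loc[sel["compartment"] == b, col[metric]].sum()
            if metric == "tips":
                succ, tot = int(va), int(va + vb)
            else:
                succ, tot = discretize_mm(va), discretize_mm(va + vb)
            if tot <= 0:
                continue
            r = proportion_test(succ, tot, bn=int(bn), metric=metric)
            rows.append({"metric": metric, "branching_number": int(bn),
                         "test": "binomial", "estimate": r.estimate,
                         "statistic": r.statistic, "p_value": r.p_value,
                         "n_a": r.n_a, "n_b": r.n_b})
    for name, fn in (("srl", _traits.srl), ("mass_fraction",
                                            _traits.mass_fraction)):
        ga, gb = [], []
        for _, sub in table.groupby("replicate"):
            try:
                ga.append(fn(sub, a))
                gb.append(fn(sub, b))
            except _traits.UndefinedTraitError:
                continue
        if len(ga) >= 1 and len(gb) >= 1 and len(ga) + len(gb) > 2:
            f, p = one_way_anova([ga, gb])
            rows.append({"metric": name, "branching_number": None,
                         "test": "anova", "estimate": float(np.mean(ga)),
                         "statistic": f, "p_value": p,
                         "n_a": len(ga), "n_b": len(gb)})
    return pd.DataFrame(rows)
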