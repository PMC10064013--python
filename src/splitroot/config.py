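"""TOML configuration loading and the packaged calibrations.

A calibration file holds one ``[order.N]`` table per branching number with
:class:`~splitroot.params.GrowthParams` fields, a ``[calibration]`` table
(name, max_order, optional growth_law) and an optional ``[simulation]``
table (duration, dt, seed, box, replicates) consumed by the CLI.

Three calibrations ship with the package: ``nutrient`` and ``water`` (the
two compartments of the resource-partitioned treatment) and ``mixed``
(both compartments of the resource-mixed treatment).  They are
reverse-engineered from published per-order trait tables of a split-root
experiment on *Panicum virgatum* — not fitted to raw data, which is not
publicly deposited — and are labelled approximations.
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import fields as dc_fields
from importlib import resources
from pathlib import Path

from .params import ConfigurationError, GrowthParams

__all__ = [
    "load_calibration",
    "load_config",
    "packaged_calibrations",
    "packaged_calibration",
    "PACKAGED_NAMES",
]

PACKAGED_NAMES = ("nutrient", "water", "mixed")

_PARAM_FIELDS = {f.name for f in dc_fields(GrowthParams)} - {
    "branching_number", "compartment_tag", "max_order"}

_SIM_KEYS = {"duration", "dt", "seed", "box", "replicates"}


def _build_params(bn: int, entries: dict, name: str, max_order: int,
                  growth_law: str, path: str) -> GrowthParams:
    unknown = set(entries) - _PARAM_FIELDS
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown keys {sorted(unknown)} in order.{bn}",
            stacklevel=3)
    kwargs = {k: v for k, v in entries.items() if k in _PARAM_FIELDS}
    kwargs.setdefault("growth_law", growth_law)
    try:
        return GrowthParams(branching_number=bn, compartment_tag=name,
                            max_order=max_order, **kwargs)
    except ConfigurationError as e:
        raise ConfigurationError(f"{path}: order.{bn}: {e}") from None


def load_calibration(source) -> tuple[dict[int, GrowthParams], dict]:
    """Load a calibration TOML file.

    Returns ``(params_by_order, meta)`` where ``meta`` carries the
    ``[calibration]`` and ``[simulation]`` tables.  All growth-parameter
    invariants are validated; violations raise
    :class:`~splitroot.params.ConfigurationError` naming the field path.
    Unknown keys produce a warning, never an error.
    """
    if isinstance(source, (str, Path)):
        path = str(source)
        with open(source, "rb") as fh:
            doc = tomllib.load(fh)
    else:  # binary file object
        path = getattr(source, "name", "<config>")
        doc = tomllib.load(source)
    cal = doc.get("calibration", {})
    orders = doc.get("order", {})
    if not orders:
        raise ConfigurationError(f"{path}: no [order.N] tables found")
    known_top = {"calibration", "order", "simulation"}
    if set(doc) - known_top:
        warnings.warn(f"{path}: ignoring unknown top-level tables "
                      f"{sorted(set(doc) - known_top)}", stacklevel=2)
    try:
        bns = sorted(int(k) for k in orders)
    except ValueError:
        raise ConfigurationError(
            f"{path}: [order] subtable keys must be integers") from None
    max_order = int(cal.get("max_order", max(bns)))
    growth_law = cal.get("growth_law", "linear")
    name = cal.get("name", Path(path).stem)
    params = {bn: _build_params(bn, orders[str(bn)], name, max_order,
                                growth_law, path)
              for bn in bns}
    sim = dict(doc.get("simulation", {}))
    unknown_sim = set(sim) - _SIM_KEYS
    if unknown_sim:
        warnings.warn(f"{path}: ignoring unknown [simulation] keys "
                      f"{sorted(unknown_sim)}", stacklevel=2)
    meta = {"name": name, "max_order": max_order,
            "simulation": {k: v for k, v in sim.items() if k in _SIM_KEYS}}
    return params, meta


# kept as the generic entry point the CLI uses
load_config = load_calibration


def packaged_calibration(name: str) -> dict[int, GrowthParams]:
    """One packaged calibration (``nutrient``, ``water`` or ``mixed``)."""
    if name not in PACKAGED_NAMES:
        raise ConfigurationError(
            f"unknown calibration {name!r}; packaged: {PACKAGED_NAMES}")
    ref = resources.files("splitroot").joinpath(f"data/{name}.toml")
    with ref.open("rb") as fh:
        params, _ = load_calibration(fh)
    return params


def packaged_calibrations() -> dict[str, dict[int, GrowthParams]]:
    """All packaged calibrations, keyed by name."""
    return {name: packaged_calibration(name) for name in PACKAGED_NAMES}
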