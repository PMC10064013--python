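"""Growth-parameter sets for the stochastic root architecture model.

Each root branching number (centrifugal order: 0 = primary root emerging
from the rhizome, laterals increment their parent's number by one) is
governed by its own :class:`GrowthParams`.  An individual root realises a
private triple ``(r, lmax, ln)`` drawn from truncated normal distributions
around the per-order means, which is what makes repeated simulations an
ensemble of distinct virtual root systems.

Symbols follow the root-architecture modelling literature:

=============  ====================================================  =========
field          meaning                                               units
=============  ====================================================  =========
``r``          tip elongation rate                                   cm day⁻¹
``lmax``       maximum root length                                   cm
``la``         unbranched (axial) zone at the root base              cm
``lb``         unbranched (basal) zone behind the tip                cm
``ln``         interval between successive lateral branch sites      cm
``theta``      axial insertion angle of a lateral on its parent      degrees
``maxB``       number of primary roots (branching number 0 only)     —
=============  ====================================================  =========

Note the ``la``/``lb`` semantics: ``la`` is the unbranched zone at the
*base* and ``lb`` the unbranched zone at the *tip*.  Some ancestral
root-architecture models use the opposite naming; this package follows the
base/tip convention above everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GrowthParams",
    "ConfigurationError",
    "sample_truncated_normal",
    "sample_axis_params",
    "sample_angles",
    "TRUNCATION_FLOOR_FRACTION",
]

#: Default lower truncation of stochastic parameter draws, as a fraction of
#: the mean.  Keeps realised rates/lengths/intervals strictly positive.
TRUNCATION_FLOOR_FRACTION = 0.01


class ConfigurationError(ValueError):
    """A growth-parameter set violates its invariants."""


@dataclass
class GrowthParams:
    """Stochastic growth parameters for one root branching number.

    Parameters with a ``*_mean``/``*_sd`` pair are drawn per root axis from
    a normal distribution truncated below at a small positive floor; an sd
    of zero yields the mean exactly.
    """

    branching_number: int
    compartment_tag: str = ""
    r_mean: float = 1.0
    r_sd: float = 0.0
    lmax_mean: float = 10.0
    lmax_sd: float = 0.0
    la: float = 0.0
    lb: float = 0.0
    ln_mean: float = 1.0
    ln_sd: float = 0.0
    theta_mean: float = 0.0
    theta_sd: float = 0.0
    maxB: int = 1
    radius: float = 0.01
    linear_density: float = 1e-4
    tropism_sigma: float = 0.0
    max_order: int = 0
    #: "linear": length = min(r·t, lmax).  "exponential": the negative
    #: exponential law length = lmax·(1 − exp(−r·t/lmax)) used by ancestral
    #: root models; off by default.
    growth_law: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bn = self.branching_number
        if bn < 0:
            raise ConfigurationError("branching_number must be >= 0")
        for name in ("r_mean", "lmax_mean", "la", "lb", "ln_mean",
                     "radius", "linear_density"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("r_sd", "lmax_sd", "ln_sd", "theta_sd", "tropism_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0 (negative sd)")
        if self.la + self.lb > self.lmax_mean:
            raise ConfigurationError(
                f"la + lb = {self.la + self.lb} exceeds lmax_mean = "
                f"{self.lmax_mean}")
        if self.max_order > bn and self.ln_mean <= 0:
            raise ConfigurationError(
                "ln_mean must be > 0 when laterals may emerge "
                f"(max_order {self.max_order} > branching_number {bn})")
        if not 0 <= self.theta_mean < 180:
            raise ConfigurationError("theta_mean must lie in [0, 180)")
        if bn == 0 and self.maxB < 1:
            raise ConfigurationError("maxB must be >= 1 for branching number 0")
        if bn > 0 and self.maxB > 1:
            raise ConfigurationError("maxB applies to branching number 0 only")
        if self.growth_law not in ("linear", "exponential"):
            raise ConfigurationError(
                f"unknown growth_law {self.growth_law!r}")

    def with_(self, **kw) -> "GrowthParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kw)


def sample_truncated_normal(mean: float, sd: float, rng: np.random.Generator,
                            floor: float | None = None) -> float:
    """One draw from Normal(mean, sd) clamped below at ``floor``.

    ``floor`` defaults to ``TRUNCATION_FLOOR_FRACTION * mean``.  With
    ``sd == 0`` the mean is returned exactly (no rng consumption), so a
    zero-variance configuration is fully deterministic.
    """
    if sd < 0:
        raise ConfigurationError("negative sd")
    if floor is None:
        floor = TRUNCATION_FLOOR_FRACTION * mean
    if sd == 0:
        return float(mean)
    return float(max(rng.normal(mean, sd), floor))


def sample_axis_params(params: GrowthParams, rng: np.random.Generator,
                       floor: float | None = None
                       ) -> tuple[float, float, float]:
    """Realise the per-axis ``(r, lmax, ln)`` triple for one new root."""
    params.validate()
    r = sample_truncated_normal(params.r_mean, params.r_sd, rng, floor)
    lmax = sample_truncated_normal(params.lmax_mean, params.lmax_sd, rng, floor)
    ln = sample_truncated_normal(params.ln_mean, params.ln_sd, rng, floor)
    return r, lmax, ln


def sample_angles(params: GrowthParams, rng: np.random.Generator
                  ) -> tuple[float, float]:
    """Sample the insertion angles of one new root, in degrees.

    The axial insertion angle is normal around ``theta_mean`` (clamped to
    [0, 180)); the radial (roll) angle around the parent axis is uniform on
    [0, 360).  With ``theta_sd == 0`` the axial angle is exact and the
    radial angle is still random.
    """
    if params.theta_sd == 0:
        axial = float(params.theta_mean)
    else:
        axial = float(np.clip(rng.normal(params.theta_mean, params.theta_sd),
                              0.0, math.nextafter(180.0, 0.0)))
    radial = float(rng.uniform(0.0, 360.0))
    return axial, radial
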