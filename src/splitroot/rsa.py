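"""Stochastic 3D root-system-architecture (RSA) growth engine.

The model grows a forest of root axes inside one compartment of a
split-root box.  Primary roots (branching number 0) emerge from the
rhizome planting point; each axis elongates at its realised rate ``r``
until it reaches its realised maximum length ``lmax``, and inserts lateral
branch sites every ``ln`` cm of arc length between an unbranched zone
``la`` at its base and an unbranched zone ``lb`` behind its tip.  A site
spawns its lateral at the moment the parent's length first reaches
``site + lb``, so the zone behind the tip is always branch-free.  Laterals
follow the same rules under the parameter set of their own branching
number, up to ``max_order``.

Because the growth law makes per-axis length a closed-form function of
time, branching is resolved *event-driven*: every branch site has an exact
activation time, and :meth:`RootSystem.grow` simply materialises all
events up to the new clock.  Counts and lengths are therefore independent
of the stepping interval ``dt`` by construction.

Geometry is predetermined per axis at creation: the heading performs a
biased random walk (gravitropic pull toward +z, which points downward,
plus normal perturbation per 0.1-cm arc step) and is reflected at the box
walls and the split-root barrier.  Since the heading recurrence involves
no other axis, precomputing the full eventual polyline is exact; growth
reveals it by arc length.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (ConfigurationError, GrowthParams, sample_angles,
                     sample_axis_params)

__all__ = [
    "RootAxis",
    "RootSystem",
    "branch_sites",
    "activation_time",
    "insert_branches",
    "grow",
    "simulate",
    "run_ensemble",
    "simulate_ensemble",
    "BOX_DIMS",
]

#: Arc length of one geometry step, cm.
STEP = 0.1
#: Fraction of a unit heading pulled toward +z (down) per geometry step.
GRAVITROPIC_BIAS = 0.06
#: Split-root box outer dimensions (x width, y breadth, z depth), cm.
BOX_DIMS = (20.0, 27.0, 107.0)

_EPS_T = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _insertion_direction(base: np.ndarray, axial_deg: float,
                         radial_deg: float) -> np.ndarray:
    """Direction at ``axial_deg`` from ``base``, rolled by ``radial_deg``."""
    u = _unit(np.asarray(base, dtype=float))
    # any vector not parallel to u
    k = np.array([1.0, 0.0, 0.0]) if abs(u[0]) <= 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, k))
    e2 = np.cross(u, e1)
    a = math.radians(axial_deg)
    p = math.radians(radial_deg)
    return math.cos(a) * u + math.sin(a) * (math.cos(p) * e1 + math.sin(p) * e2)


def _grow_path(start, heading, total_length, tropism_sigma_deg, rng, bounds):
    """Trace the full eventual polyline of one axis.

    Returns ``(points, cumlen)`` where ``points`` is an (n, 3) array and
    ``cumlen[i]`` the arc length from the start to ``points[i]``.  Arc
    length is conserved through wall reflections by splitting the step at
    the crossing point.
    """
    if total_length <= 0:
        p = np.asarray(start, dtype=float)
        return np.vstack([p, p]), np.array([0.0, 0.0])
    n_steps = int(math.ceil(total_length / STEP - 1e-9))
    sigma = math.radians(tropism_sigma_deg)
    noise = rng.normal(0.0, sigma, size=(n_steps, 3)) if sigma > 0 else None
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = bounds
    x, y, z = (float(c) for c in start)
    hx, hy, hz = (float(c) for c in heading)
    pts = [(x, y, z)]
    cum = [0.0]
    s = 0.0
    for k in range(n_steps):
        step_len = min(STEP, total_length - k * STEP)
        if step_len <= 1e-12:
            break
        if noise is not None:
            hx += noise[k, 0]
            hy += noise[k, 1]
            hz += noise[k, 2]
        hz += GRAVITROPIC_BIAS
        inv = 1.0 / math.sqrt(hx * hx + hy * hy + hz * hz)
        hx *= inv
        hy *= inv
        hz *= inv
        remaining = step_len
        guard = 0
        while remaining > 1e-12:
            guard += 1
            if guard > 64:  # pathological corner; give up splitting
                break
            # earliest wall crossing along the sub-step, parametric t in (0, 1]
            t = 1.0
            dim = -1
            for i, (c, h, lo, hi) in enumerate(
                    ((x, hx, xlo, xhi), (y, hy, ylo, yhi), (z, hz, zlo, zhi))):
                if h > 0 and c + remaining * h > hi:
                    ti = (hi - c) / (remaining * h)
                elif h < 0 and c + remaining * h < lo:
                    ti = (lo - c) / (remaining * h)
                else:
                    continue
                if ti < t:
                    t = ti
                    dim = i
            if dim < 0:
                x += remaining * hx
                y += remaining * hy
                z += remaining * hz
                s += remaining
                remaining = 0.0
            elif t <= 1e-12:
                # already on the wall, heading outward: just reflect
                if dim == 0:
                    hx = -hx
                elif dim == 1:
                    hy = -hy
                else:
                    hz = -hz
            else:
                d = remaining * t
                x += d * hx
                y += d * hy
                z += d * hz
                s += d
                remaining -= d
                if dim == 0:
                    hx = -hx
                elif dim == 1:
                    hy = -hy
                else:
                    hz = -hz
                pts.append((min(max(x, xlo), xhi), min(max(y, ylo), yhi),
                            min(max(z, zlo), zhi)))
                cum.append(s)
                continue
        pts.append((min(max(x, xlo), xhi), min(max(y, ylo), yhi),
                    min(max(z, zlo), zhi)))
        cum.append(s)
    return np.asarray(pts), np.asarray(cum)


def branch_sites(lmax: float, la: float, lb: float, ln: float) -> np.ndarray:
    """Arc-length positions of the branch sites along a root.

    Sites sit at ``la + i*ln`` within the branched zone; a root whose
    branched zone ``lmax - la - lb`` is not strictly positive never
    branches.  The site exactly at ``lmax - lb`` is admissible — it
    activates the moment the root reaches full length.
    """
    if ln <= 0:
        raise ConfigurationError("ln must be > 0 to insert branches")
    zone = lmax - la - lb
    if zone <= 0:
        return np.empty(0)
    n = int(math.floor(zone / ln + 1e-9)) + 1
    return la + ln * np.arange(n)


def activation_time(site: float, lb: float, r: float, lmax: float,
                    growth_law: str = "linear") -> float:
    """Time after axis birth at which a branch site emits its lateral.

    The lateral appears when the parent's length first reaches
    ``site + lb``.  Under the exponential law a site needing the full
    ``lmax`` never activates (returns ``inf``).
    """
    target = site + lb
    if growth_law == "linear":
        return target / r
    frac = target / lmax
    if frac >= 1.0:
        return math.inf
    return -(lmax / r) * math.log1p(-frac)


@dataclass
class RootAxis:
    """One root: a polyline with realised growth parameters.

    ``polyline``/``length`` reflect the owning system's clock; the full
    eventual path is private.
    """

    axis_id: int
    branching_number: int
    parent_id: int | None
    insertion_arclength: float | None
    axial_angle: float
    radial_angle: float
    birth_time: float
    r: float
    lmax: float
    ln: float
    radius: float
    linear_density: float
    growth_law: str = "linear"
    #: static axes (e.g. re-imported from RSML) expose their stored
    #: polyline verbatim instead of revealing a predetermined path
    static: bool = False
    _points: np.ndarray = field(default=None, repr=False)
    _cumlen: np.ndarray = field(default=None, repr=False)
    _system: "RootSystem" = field(default=None, repr=False)

    def length_at(self, t: float) -> float:
        """Axis length (cm) at absolute time ``t`` (days)."""
        age = max(t - self.birth_time, 0.0)
        if self.growth_law == "exponential":
            return self.lmax * -math.expm1(-self.r * age / self.lmax)
        return min(self.r * age, self.lmax)

    @property
    def length(self) -> float:
        t = self._system.clock if self._system is not None else math.inf
        return self.length_at(t)

    def polyline_at_length(self, length: float) -> np.ndarray:
        """Revealed polyline (cm) once the axis has grown to ``length``."""
        length = min(max(length, 0.0), float(self._cumlen[-1]))
        k = int(np.searchsorted(self._cumlen, length))
        if k == 0:  # zero length: degenerate two-point polyline at the base
            return np.vstack([self._points[0], self._points[0]])
        if abs(self._cumlen[k] - length) <= 1e-12:
            return self._points[:k + 1].copy()
        seg = self._cumlen[k] - self._cumlen[k - 1]
        frac = (length - self._cumlen[k - 1]) / seg
        tip = self._points[k - 1] + frac * (self._points[k] - self._points[k - 1])
        return np.vstack([self._points[:k], tip])

    @property
    def polyline(self) -> np.ndarray:
        if self.static:
            return self._points
        return self.polyline_at_length(self.length)

    def position_at(self, arclength: float) -> np.ndarray:
        """Point on the axis at a given arc length from its base."""
        pts = self.polyline_at_length(arclength)
        return pts[-1]

    def tangent_at(self, arclength: float) -> np.ndarray:
        s = min(max(arclength, 0.0), float(self._cumlen[-1]))
        k = int(np.clip(np.searchsorted(self._cumlen, s, side="right"), 1,
                        len(self._cumlen) - 1))
        d = self._points[k] - self._points[k - 1]
        return _unit(d)


class RootSystem:
    """A simulated root system confined to one split-root compartment.

    The box is 20 × 27 × 107 cm, split by a vertical barrier at ``x = 0``
    with a top gap of ``barrier_top_depth`` cm where the rhizome sits.
    ``side`` selects the compartment: +1 occupies ``x in [0, 10]``, −1
    ``x in [−10, 0]``.  Root geometry never crosses the barrier plane.
    """

    def __init__(self, params_by_order: dict[int, GrowthParams],
                 seed: int | np.random.SeedSequence = 0,
                 compartment_tag: str = "",
                 side: int = 1,
                 box_dims: tuple[float, float, float] = BOX_DIMS,
                 barrier_top_depth: float = 1.0):
        if 0 not in params_by_order:
            raise ConfigurationError("params for branching number 0 required")
        for bn, p in params_by_order.items():
            p.validate()
            if p.branching_number != bn:
                raise ConfigurationError(
                    f"params keyed {bn} carry branching_number "
                    f"{p.branching_number}")
            if p.max_order > bn and (bn + 1) not in params_by_order:
                raise ConfigurationError(
                    f"laterals of branching number {bn + 1} may emerge "
                    f"(max_order {p.max_order}) but no parameter set is "
                    f"defined for them")
        self.params_by_order = params_by_order
        self.box_dims = tuple(float(d) for d in box_dims)
        self.barrier_top_depth = float(barrier_top_depth)
        self.side = 1 if side >= 0 else -1
        self.compartment_tag = compartment_tag
        self.seed = seed
        self.clock = 0.0
        self.axes: list[RootAxis] = []
        self.origin = np.array([self.side * 0.1, 0.0,
                                min(0.5, self.box_dims[2])])
        self._rng = np.random.default_rng(seed)
        self._heap: list[tuple[float, int, int, float]] = []
        self._seq = 0
        bx, by, bz = self.box_dims
        if self.side > 0:
            self._bounds = ((0.0, bx / 2), (-by / 2, by / 2), (0.0, bz))
        else:
            self._bounds = ((-bx / 2, 0.0), (-by / 2, by / 2), (0.0, bz))
        p0 = params_by_order[0]
        for _ in range(p0.maxB):
            self._create_axis(0, None, None, 0.0)

    # -- axis construction -------------------------------------------------

    def _create_axis(self, bn: int, parent: RootAxis | None,
                     insertion_s: float | None, birth: float) -> RootAxis:
        try:
            p = self.params_by_order[bn]
        except KeyError:
            raise ConfigurationError(
                f"no growth parameters for branching number {bn}") from None
        r, lmax, ln = sample_axis_params(p, self._rng)
        axial, radial = sample_angles(p, self._rng)
        if parent is None:
            base_dir = np.array([0.0, 0.0, 1.0])  # straight down
            start = self.origin
        else:
            base_dir = parent.tangent_at(insertion_s)
            start = parent.position_at(insertion_s)
        heading = _insertion_direction(base_dir, axial, radial)
        pts, cum = _grow_path(start, heading, lmax, p.tropism_sigma,
                              self._rng, self._bounds)
        axis = RootAxis(
            axis_id=len(self.axes), branching_number=bn,
            parent_id=None if parent is None else parent.axis_id,
            insertion_arclength=insertion_s, axial_angle=axial,
            radial_angle=radial, birth_time=birth, r=r, lmax=lmax, ln=ln,
            radius=p.radius, linear_density=p.linear_density,
            growth_law=p.growth_law, _points=pts, _cumlen=cum, _system=self)
        self.axes.append(axis)
        if p.max_order > bn and (bn + 1) in self.params_by_order:
            for site in branch_sites(lmax, p.la, p.lb, ln):
                t = birth + activation_time(site, p.lb, r, lmax, p.growth_law)
                if math.isfinite(t):
                    heapq.heappush(self._heap, (t, self._seq, axis.axis_id,
                                                float(site)))
                    self._seq += 1
        return axis

    # -- time stepping -----------------------------------------------------

    def grow(self, dt: float) -> "RootSystem":
        """Advance the clock by ``dt`` days, materialising all laterals
        whose activation falls within the interval."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        t_new = self.clock + dt
        while self._heap and self._heap[0][0] <= t_new + _EPS_T:
            t_act, _, pid, site = heapq.heappop(self._heap)
            parent = self.axes[pid]
            self._create_axis(parent.branching_number + 1, parent, site, t_act)
        self.clock = t_new
        return self

    # -- summaries ---------------------------------------------------------

    def total_length(self, bn: int | None = None) -> float:
        """Total root length (cm) at the current clock, optionally for one
        branching number."""
        return float(sum(a.length for a in self.axes
                         if bn is None or a.branching_number == bn))

    def counts_by_order(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for a in self.axes:
            out[a.branching_number] = out.get(a.branching_number, 0) + 1
        return out

    def children_of(self, axis_id: int) -> list[RootAxis]:
        return [a for a in self.axes if a.parent_id == axis_id]


def grow(system: RootSystem, dt: float) -> RootSystem:
    """Functional alias for :meth:`RootSystem.grow`."""
    return system.grow(dt)


def insert_branches(axis: RootAxis, params_by_order: dict[int, GrowthParams],
                    rng: np.random.Generator,
                    length: float | None = None) -> list[RootAxis]:
    """Laterals emitted by ``axis`` once it has grown to ``length``.

    Standalone counterpart of the event-driven insertion inside
    :meth:`RootSystem.grow`: enumerates the branch sites of ``axis`` and
    creates a lateral for every site whose activation threshold
    ``site + lb`` the given length has reached.  The returned axes are not
    registered with any system.
    """
    p = params_by_order[axis.branching_number]
    if axis.branching_number >= p.max_order:
        return []
    cp = params_by_order[axis.branching_number + 1]
    if length is None:
        length = axis.length
    out = []
    for i, site in enumerate(branch_sites(axis.lmax, p.la, p.lb, axis.ln)):
        if length + 1e-12 < site + p.lb:
            break
        r, lmax, ln = sample_axis_params(cp, rng)
        axial, radial = sample_angles(cp, rng)
        t_birth = axis.birth_time + activation_time(site, p.lb, axis.r,
                                                    axis.lmax, p.growth_law)
        base_dir = axis.tangent_at(site)
        start = axis.position_at(site)
        heading = _insertion_direction(base_dir, axial, radial)
        pts, cum = _grow_path(start, heading, lmax, cp.tropism_sigma, rng,
                              ((-BOX_DIMS[0] / 2, BOX_DIMS[0] / 2),
                               (-BOX_DIMS[1] / 2, BOX_DIMS[1] / 2),
                               (0.0, BOX_DIMS[2])))
        out.append(RootAxis(
            axis_id=-1 - i, branching_number=axis.branching_number + 1,
            parent_id=axis.axis_id, insertion_arclength=float(site),
            axial_angle=axial, radial_angle=radial, birth_time=t_birth,
            r=r, lmax=lmax, ln=ln, radius=cp.radius,
            linear_density=cp.linear_density, growth_law=cp.growth_law,
            _points=pts, _cumlen=cum, _system=axis._system))
    return out


def simulate(params_by_order: dict[int, GrowthParams], duration: float,
             seed: int | np.random.SeedSequence = 0, **kwargs) -> RootSystem:
    """Grow one root system for ``duration`` days."""
    return RootSystem(params_by_order, seed=seed, **kwargs).grow(duration)


def run_ensemble(params_by_order: dict[int, GrowthParams], duration: float,
                 n_replicates: int, seed: int | np.random.SeedSequence = 0,
                 **kwargs):
    """Yield ``n_replicates`` independently seeded simulated systems."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    for child in ss.spawn(n_replicates):
        yield simulate(params_by_order, duration, seed=child, **kwargs)


def simulate_ensemble(params_by_order: dict[int, GrowthParams],
                      duration: float, n_replicates: int,
                      seed: int | np.random.SeedSequence = 0,
                      **kwargs) -> pd.DataFrame:
    """Mean and dispersion of total root length per branching number over
    an ensemble of independently seeded virtual root systems.

    Returns a frame indexed by branching number with the ensemble mean and
    standard deviation of total length (cm) and the mean tip count.  The
    same seed always reproduces the same ensemble.
    """
    orders = sorted(params_by_order)
    lengths = {bn: [] for bn in orders}
    tips = {bn: [] for bn in orders}
    for system in run_ensemble(params_by_order, duration, n_replicates, seed,
                               **kwargs):
        counts = system.counts_by_order()
        for bn in orders:
            lengths[bn].append(system.total_length(bn))
            tips[bn].append(counts.get(bn, 0))
    return pd.DataFrame({
        "branching_number": orders,
        "mean_length_cm": [float(np.mean(lengths[bn])) for bn in orders],
        "sd_length_cm": [float(np.std(lengths[bn], ddof=1)) if n_replicates > 1
                         else 0.0 for bn in orders],
        "mean_tips": [float(np.mean(tips[bn])) for bn in orders],
    }).set_index("branching_number")
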