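"""Deterministic genotype-frequency dynamics of a recessive-lethal sperm-killing
driver (the mouse t haplotype) under monandry and polyandry.

The model tracks the adult genotype distribution (+/+, +/t; t/t dies in utero)
across discrete, non-overlapping generations.  Three parameters govern the
dynamics:

``d``
    drive strength — the probability that a +/t sire transmits the t-bearing
    gamete, absent sperm competition (~0.9 in house mice).
``c``
    sperm competitiveness — the expected paternity share of a +/t male whose
    litter is contested by one +/+ male (~0.113 from laboratory competition
    trials).
``P``
    polyandry rate — the probability that a female's litter has two mates
    rather than one.

Polyandry is modelled as exactly two mates.  Sires are drawn independently,
with replacement, from the adult genotype distribution (random mating, sexes
assumed identical in genotype composition).  Within a sire's paternity share
the drive acts at full strength: competition rescales shares, not
transmission.  t/t conceptions are removed before birth and the newborn
cohort is renormalised; no further viability selection acts, so the viable
newborn distribution is also the next adult generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WW",
    "WT",
    "TT",
    "DriveParams",
    "GenotypeDist",
    "Trajectory",
    "TrajectoryPoint",
    "ThresholdResult",
    "DriveModel",
    "offspring_dist",
    "step",
    "trajectory",
    "monandry_equilibrium",
    "invasion_threshold",
    "phase_surface",
]

WW = "WW"  # +/+ wildtype homozygote
WT = "WT"  # +/t drive heterozygote
TT = "TT"  # t/t homozygote — dies in utero, never observed alive

#: Below this adult +/t frequency the driver is considered extinct.
EXTINCTION_WT = 1e-6

_DIST_TOL = 1e-12


class InvalidGenotypeError(ValueError):
    """A genotype outside the model's state space (e.g. a live t/t parent)."""


class ArityError(ValueError):
    """Wrong number of sires for a mating union."""


@dataclass(frozen=True)
class DriveParams:
    """Parameter triple of the drive model plus numeric controls.

    Defaults are the study-population point estimates: drive strength
    d = 0.9, +/t sperm competitiveness c = 0.113, behavioural polyandry
    rate P = 0.609.
    """

    d: float = 0.9
    c: float = 0.113
    P: float = 0.609
    max_generations: int = 1000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("d", "c", "P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass(frozen=True)
class GenotypeDist:
    """Proportions of the three genotypes; must sum to one.

    Adult distributions additionally have ``tt == 0`` because t/t
    homozygotes perish in utero.
    """

    ww: float
    wt: float
    tt: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ww", "wt", "tt"):
            v = getattr(self, name)
            if not -_DIST_TOL <= v <= 1.0 + _DIST_TOL:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = self.ww + self.wt + self.tt
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype proportions must sum to 1, got {total}")

    @property
    def is_adult(self) -> bool:
        return self.tt <= _DIST_TOL

    def require_adult(self) -> None:
        if not self.is_adult:
            raise InvalidGenotypeError(
                f"adult distribution cannot contain t/t (tt={self.tt}); "
                "t/t homozygotes die in utero"
            )

    def as_dict(self) -> dict[str, float]:
        return {WW: self.ww, WT: self.wt, TT: self.tt}


@dataclass(frozen=True)
class TrajectoryPoint:
    generation: int
    adults: GenotypeDist
    newborns: GenotypeDist
    viable_fraction: float


@dataclass
class Trajectory:
    """Per-generation record of a deterministic run."""

    points: list[TrajectoryPoint] = field(default_factory=list)
    converged: bool = False

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def final(self) -> TrajectoryPoint:
        return self.points[-1]

    @property
    def wt(self) -> np.ndarray:
        """Newborn +/t proportion per generation."""
        return np.array([p.newborns.wt for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [p.generation for p in self.points],
                "ww": [p.newborns.ww for p in self.points],
                "wt": [p.newborns.wt for p in self.points],
                "tt": [p.newborns.tt for p in self.points],
                "viable_fraction": [p.viable_fraction for p in self.points],
            }
        )


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the extinction-threshold search.

    ``threshold_P`` is None when no polyandry rate in [0, 1] prevents
    invasion of the rare driver.
    """

    threshold_P: float | None
    bracket: tuple[float, float] | None
    method: str = "bisection-on-linearised-growth"

    @property
    def exists(self) -> bool:
        return self.threshold_P is not None


# ---------------------------------------------------------------------------
# gamete bookkeeping


def _maternal_t_prob(genotype: str) -> float:
    if genotype == WW:
        return 0.0
    if genotype == WT:
        return 0.5
    raise InvalidGenotypeError(f"mother genotype {genotype!r} cannot breed (t/t is lethal)")


def _paternal_t_prob(genotype: str, d: float) -> float:
    if genotype == WW:
        return 0.0
    if genotype == WT:
        return d
    raise InvalidGenotypeError(f"sire genotype {genotype!r} cannot breed (t/t is lethal)")


def paternity_shares(sires: Sequence[str], c: float) -> tuple[float, ...]:
    """Expected paternity shares for one or two sires of a shared litter.

    A lone sire takes the whole litter; two sires of equal genotype split it
    evenly; in a mixed (+/t vs +/+) pair the +/t male's share is ``c``.
    """
    if len(sires) == 1:
        return (1.0,)
    if len(sires) == 2:
        a, b = sires
        if a == b:
            return (0.5, 0.5)
        return (c, 1.0 - c) if a == WT else (1.0 - c, c)
    raise ArityError(f"a litter has 1 or 2 sires, got {len(sires)}")


def offspring_dist(
    mother: str, sires: Sequence[str], params: DriveParams
) -> tuple[GenotypeDist, float, tuple[float, ...]]:
    """Pre-selection offspring genotype distribution of one mating union.

    Each conceptus independently takes a sire according to the paternity
    shares, a paternal t gamete with probability ``d`` if that sire is +/t,
    and a maternal t gamete with probability 1/2 if the mother is +/t.

    Returns the pre-selection genotype distribution, the viable fraction
    (1 − Pr(t/t)), and the per-sire shares.
    """
    if not sires:
        raise ArityError("at least one sire is required")
    shares = paternity_shares(sires, params.c)
    a = _maternal_t_prob(mother)
    # per-conceptus paternal t probability, mixed over sires by share
    b = sum(s * _paternal_t_prob(g, params.d) for s, g in zip(shares, sires))
    tt = a * b
    wt = a * (1.0 - b) + b * (1.0 - a)
    ww = (1.0 - a) * (1.0 - b)
    return GenotypeDist(ww=ww, wt=wt, tt=tt), 1.0 - tt, shares


# ---------------------------------------------------------------------------
# the recursion


def _newborns(adults: GenotypeDist, params: DriveParams) -> tuple[GenotypeDist, float]:
    """Population-mean pre-selection newborn distribution and viable fraction.

    With mothers and sires drawn independently from the adult distribution,
    the offspring distribution is bilinear in the parental t-gamete
    probabilities, so only their means matter: a_bar = H/2 for mothers and,
    for sires, the share-weighted mean over union types (one sire with
    probability 1 − P, two independent sires with probability P).
    """
    adults.require_adult()
    H = adults.wt
    d, c, P = params.d, params.c, params.P
    a_bar = 0.5 * H
    # E[paternal t prob]: single sire d·H; a two-sire union contributes d for
    # a (+/t, +/t) pair (prob H²) and c·d for a mixed pair (prob 2H(1−H)).
    b_bar = d * ((1.0 - P) * H + P * (H * H + 2.0 * c * H * (1.0 - H)))
    tt = a_bar * b_bar
    wt = a_bar + b_bar - 2.0 * a_bar * b_bar
    ww = (1.0 - a_bar) * (1.0 - b_bar)
    return GenotypeDist(ww=ww, wt=wt, tt=tt), 1.0 - tt


def step(adults: GenotypeDist, params: DriveParams) -> GenotypeDist:
    """Advance the adult genotype distribution by one generation.

    t/t conceptions are removed and the viable newborn distribution is
    renormalised; it doubles as the next adult generation (no adult
    viability selection).
    """
    pre, viable = _newborns(adults, params)
    return GenotypeDist(ww=pre.ww / viable, wt=pre.wt / viable, tt=0.0)


def trajectory(initial: GenotypeDist, params: DriveParams) -> Trajectory:
    """Iterate :func:`step` from ``initial`` until convergence (|Δwt| < tol)
    or ``max_generations``."""
    initial.require_adult()
    traj = Trajectory()
    adults = initial
    for gen in range(params.max_generations + 1):
        pre, viable = _newborns(adults, params)
        nxt = GenotypeDist(ww=pre.ww / viable, wt=pre.wt / viable, tt=0.0)
        traj.points.append(
            TrajectoryPoint(generation=gen, adults=adults, newborns=nxt, viable_fraction=viable)
        )
        if abs(nxt.wt - adults.wt) < params.tol:
            traj.converged = True
            break
        adults = nxt
    return traj


def monandry_equilibrium(d: float, tol: float = 1e-12, max_iter: int = 200_000) -> float:
    """Stable newborn +/t proportion under monandry (P = 0), by fixed-point
    iteration of the recursion.

    For d ≤ 1/2 the lethal driver cannot persist and the equilibrium is 0.
    At d = 0.9 the equilibrium is 2/3 — the classic two-thirds heterozygote
    prediction that wild populations conspicuously fail to meet.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"d must lie in [0, 1], got {d}")
    if d <= 0.5:
        return 0.0
    params = DriveParams(d=d, c=0.5, P=0.0, tol=tol, max_generations=max_iter)
    H = 0.5
    for _ in range(max_iter):
        nxt = step(GenotypeDist(ww=1.0 - H, wt=H), params).wt
        if abs(nxt - H) < tol:
            return nxt
        H = nxt
    return H


def _rare_growth_factor(d: float, c: float, P: float, eps: float = 1e-8) -> float:
    """Per-generation growth factor of +/t at frequency ``eps`` (numerical
    linearisation of the recursion at the wildtype-only state)."""
    params = DriveParams(d=d, c=c, P=P)
    nxt = step(GenotypeDist(ww=1.0 - eps, wt=eps), params)
    return nxt.wt / eps


def invasion_threshold(d: float, c: float, tol: float = 1e-6) -> ThresholdResult:
    """Smallest polyandry rate P at which the rare driver fails to invade.

    Found by bisection on P over [0, 1] of the linearised growth factor
    (evaluated at wt = 1e-8).  Returns a none-sentinel result when no P in
    [0, 1] stops invasion — e.g. when the +/t male suffers no competitive
    disadvantage (c ≥ 1/2).
    """
    if not 0.5 < d <= 1.0:
        raise ValueError(
            f"threshold is defined only for d in (0.5, 1]; got d={d} "
            "(a lethal driver with d <= 1/2 never invades)"
        )
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c}")

    lo, hi = 0.0, 1.0
    g_lo = _rare_growth_factor(d, c, lo)
    g_hi = _rare_growth_factor(d, c, hi)
    if g_lo <= 1.0:
        # already subcritical without polyandry
        return ThresholdResult(threshold_P=0.0, bracket=(0.0, 0.0))
    if g_hi > 1.0:
        return ThresholdResult(threshold_P=None, bracket=None)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _rare_growth_factor(d, c, mid) > 1.0:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(threshold_P=0.5 * (lo + hi), bracket=(lo, hi))


def phase_surface(
    d: float,
    P_grid: Sequence[float],
    c_grid: Sequence[float],
    initial_wt: float = 0.5,
    params: DriveParams | None = None,
) -> pd.DataFrame:
    """Long-run newborn +/t proportion over a (P, c) grid at fixed d.

    Each cell runs the recursion from an interior start; equilibria below
    the extinction cutoff are reported as exactly 0.  Columns: P, c, eq_wt.
    """
    if len(P_grid) == 0 or len(c_grid) == 0:
        raise ValueError("P_grid and c_grid must be nonempty")
    base = params if params is not None else DriveParams(max_generations=5000)
    rows = []
    for P in P_grid:
        for c in c_grid:
            pars = replace(base, d=d, c=c, P=P)
            traj = trajectory(GenotypeDist(ww=1.0 - initial_wt, wt=initial_wt), pars)
            eq = traj.final.newborns.wt
            rows.append({"P": P, "c": c, "eq_wt": 0.0 if eq < EXTINCTION_WT else eq})
    return pd.DataFrame(rows)


class DriveModel:
    """Convenience object bundling :class:`DriveParams` with the model
    operations.

    >>> m = DriveModel(DriveParams(d=0.9, c=0.113, P=0.609))
    >>> m.invasion_threshold().threshold_P  # doctest: +ELLIPSIS
    0.574...
    """

    def __init__(self, params: DriveParams | None = None):
        self.params = params if params is not None else DriveParams()

    def step(self, adults: GenotypeDist) -> GenotypeDist:
        return step(adults, self.params)

    def trajectory(self, initial_wt: float = 0.25) -> Trajectory:
        init = GenotypeDist(ww=1.0 - initial_wt, wt=initial_wt)
        return trajectory(init, self.params)

    def monandry_equilibrium(self) -> float:
        return monandry_equilibrium(self.params.d)

    def invasion_threshold(self, tol: float = 1e-6) -> ThresholdResult:
        return invasion_threshold(self.params.d, self.params.c, tol=tol)

    def long_run_wt(self, initial_wt: float = 0.25) -> float:
        """Limiting newborn +/t proportion; exactly 0 below the extinction
        cutoff."""
        wt = self.trajectory(initial_wt).final.newborns.wt
        return 0.0 if wt < EXTINCTION_WT else wt

    def predicts_extinction(self, initial_wt: float = 0.25) -> bool:
        return self.long_run_wt(initial_wt) == 0.0
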