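"""Slip and tilt stability criteria for the cranked-rod railing model.

Quasi-static force balance of a person leaning over a railing yields a
vertical ground reaction ``GRF`` and a horizontal friction demand ``F`` at
the feet (point A)::

    GRF = G1*(1 - a*sin^2(alpha))
          + G2*(cos^2(alpha) - b*(L2/L1)*sin(alpha)*sin(alpha + beta))
    F   = (a*G1*sin(alpha) + G2*sin(alpha)
          + b*G2*(L2/L1)*sin(alpha + beta)) * cos(alpha)

Two conditions decide stability:

* **anti-slip** — the feet do not slide: ``F <= mu * GRF`` (Coulomb).
* **anti-tilt** — the body does not rotate over the handrail:
  ``b*G2*L2*sin(alpha+beta) <= (a*G1 + G2)*L1*sin(alpha)``.

A fall over the railing is mechanically possible only where *both*
conditions are violated simultaneously.  Both violated sets are intervals
in ``beta`` at fixed ``alpha`` because each condition is monotone in
``sin(alpha + beta)``; the two arcsin branches of a threshold are related
by ``beta_2 = pi - beta_1 - 2*alpha``.

Ground truth throughout is the primitive inequality, evaluated directly
and bracketed by scan + bisection; the closed-form arcsin thresholds are
exposed separately and asserted against the scan in the test suite.  This
keeps the code robust where an arcsin argument leaves [-1, 1] or a branch
falls outside the beta domain.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import (
    Anthropometry,
    PlausibilityConfig,
    Posture,
    RailingScenario,
    SegmentGeometry,
    SegmentWeights,
    anatomical_plausibility,
    derive_segments,
    split_weights,
)

__all__ = [
    "DEFAULT_BETA_MAX",
    "ForceDemand",
    "BranchPair",
    "ConditionInterval",
    "StabilityCategory",
    "StabilityAssessment",
    "ground_reaction",
    "friction_demand",
    "force_demand",
    "anti_slip_holds",
    "anti_tilt_holds",
    "slip_margin",
    "tilt_margin",
    "slip_threshold_sine",
    "tilt_threshold_sine",
    "arcsin_branch_pair",
    "slip_beta_interval",
    "tilt_beta_interval",
    "classify_posture",
]

#: Default upper edge of the beta domain (radians): flexion angles beyond
#: 130 deg are outside the posture range the model is meant for.
DEFAULT_BETA_MAX = math.radians(130.0)

_BISECT_TOL = 1e-12  # rad; endpoint refinement keeps branch identity below 1e-10
_SCAN_POINTS = 256  # initial sign-change scan per alpha


@dataclass(frozen=True)
class ForceDemand:
    """Contact forces at the feet required for equilibrium (newtons)."""

    ground_reaction: float
    friction_demand: float


@dataclass(frozen=True)
class BranchPair:
    """The two beta solutions (radians) of ``sin(beta + alpha) = s``."""

    beta_1: float
    beta_2: float


def ground_reaction(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
):
    """Vertical ground reaction force at the feet (closed form).

    May be negative for extreme postures; callers flag that case since a
    Coulomb contact cannot pull.  Broadcasts over array-valued ``beta``.
    """
    _require_valid(geom)
    a = anthro.cog_fraction_lower
    b = anthro.cog_fraction_upper
    g1, g2 = weights.lower_weight, weights.upper_weight
    ratio = geom.length_ratio
    sa, ca = math.sin(posture.alpha), math.cos(posture.alpha)
    sab = np.sin(posture.alpha + np.asarray(posture.beta))
    grf = g1 * (1.0 - a * sa * sa) + g2 * (ca * ca - b * ratio * sa * sab)
    return float(grf) if np.ndim(grf) == 0 else grf


def friction_demand(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
):
    """Horizontal friction force at the feet required for equilibrium."""
    _require_valid(geom)
    a = anthro.cog_fraction_lower
    b = anthro.cog_fraction_upper
    g1, g2 = weights.lower_weight, weights.upper_weight
    ratio = geom.length_ratio
    sa, ca = math.sin(posture.alpha), math.cos(posture.alpha)
    sab = np.sin(posture.alpha + np.asarray(posture.beta))
    f = (a * g1 * sa + g2 * sa + b * g2 * ratio * sab) * ca
    return float(f) if np.ndim(f) == 0 else f


def force_demand(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
) -> ForceDemand:
    """Both contact-force magnitudes at the feet, as a pair."""
    return ForceDemand(
        ground_reaction=ground_reaction(anthro, weights, geom, posture),
        friction_demand=friction_demand(anthro, weights, geom, posture),
    )


def anti_slip_holds(demand: ForceDemand, mu: float) -> bool:
    """Coulomb anti-slip criterion ``F <= mu * GRF``; boundary is stable."""
    return demand.friction_demand <= mu * demand.ground_reaction


def slip_margin(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
    mu: float,
):
    """``F - mu*GRF``: positive where the slip (instability) condition holds."""
    return friction_demand(anthro, weights, geom, posture) - mu * ground_reaction(
        anthro, weights, geom, posture
    )


def tilt_margin(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
):
    """Tipping-vs-restoring moment difference (N*m).

    ``b*G2*L2*sin(alpha+beta) - (a*G1 + G2)*L1*sin(alpha)``: positive where
    the tilt (instability) condition holds.  Independent of mu and of g up
    to the common factor m*g.
    """
    _require_valid(geom)
    a = anthro.cog_fraction_lower
    b = anthro.cog_fraction_upper
    g1, g2 = weights.lower_weight, weights.upper_weight
    sab = np.sin(posture.alpha + np.asarray(posture.beta))
    m = b * g2 * geom.upper_length * sab - (a * g1 + g2) * geom.lower_length * math.sin(
        posture.alpha
    )
    return float(m) if np.ndim(m) == 0 else m


def anti_tilt_holds(
    anthro: Anthropometry,
    weights: SegmentWeights,
    geom: SegmentGeometry,
    posture: Posture,
) -> bool:
    """True when the restoring moment balances the tipping moment.

    Equality is counted as stable, matching the non-strict inequality of
    the anti-conditions.
    """
    return tilt_margin(anthro, weights, geom, posture) <= 0.0


def slip_threshold_sine(
    anthro: Anthropometry, scenario: RailingScenario, alpha: float
) -> float:
    """Critical value of ``sin(alpha + beta)`` for the slip boundary.

    The slip condition holds exactly where ``sin(alpha+beta)`` exceeds the
    returned value.  Values >= 1 mean anti-slip holds for every beta;
    values < sin(alpha) mean the condition already holds at beta = 0.
    """
    geom = derive_segments(anthro, scenario, alpha)
    _require_valid(geom)
    w = split_weights(anthro, geom)
    a = anthro.cog_fraction_lower
    b = anthro.cog_fraction_upper
    g1, g2 = w.lower_weight, w.upper_weight
    mu = scenario.friction_coefficient
    sa, ca = math.sin(alpha), math.cos(alpha)
    numer = mu * (g1 * (1.0 - a * sa * sa) + g2 * ca * ca) - (a * g1 + g2) * sa * ca
    denom = b * g2 * geom.length_ratio * (ca + mu * sa)
    return numer / denom


def tilt_threshold_sine(
    anthro: Anthropometry, scenario: RailingScenario, alpha: float
) -> float:
    """Critical value of ``sin(alpha + beta)`` for the tilt boundary.

    Equals ``(a*G1 + G2)*L1*sin(alpha) / (b*G2*L2)``; the tilt condition
    holds where ``sin(alpha+beta)`` exceeds it.  Does not depend on mu.
    """
    geom = derive_segments(anthro, scenario, alpha)
    _require_valid(geom)
    w = split_weights(anthro, geom)
    a = anthro.cog_fraction_lower
    b = anthro.cog_fraction_upper
    return (
        (a * w.lower_weight + w.upper_weight)
        * geom.lower_length
        * math.sin(alpha)
        / (b * w.upper_weight * geom.upper_length)
    )


def arcsin_branch_pair(beta_1: float, alpha: float) -> BranchPair:
    """Second arcsin branch: ``beta_2 = pi - beta_1 - 2*alpha`` (radians).

    Both betas solve ``sin(beta + alpha) = s`` for the same s, so every
    instability interval whose endpoints come from an arcsin threshold has
    endpoints forming such a pair.
    """
    return BranchPair(beta_1=beta_1, beta_2=math.pi - beta_1 - 2.0 * alpha)


class _IntervalStatus(enum.Enum):
    EMPTY = "empty"
    ALL = "all"
    INTERVAL = "interval"


@dataclass(frozen=True)
class ConditionInterval:
    """Beta-interval (radians) over which an instability condition holds.

    ``status`` is EMPTY (condition nowhere in the beta domain), ALL
    (everywhere), or INTERVAL with open endpoints ``(lower, upper)``
    clipped to the domain.  ``kind`` names the condition.
    """

    kind: str
    status: _IntervalStatus
    lower: float | None = None
    upper: float | None = None
    domain: tuple[float, float] = (0.0, DEFAULT_BETA_MAX)

    EMPTY = _IntervalStatus.EMPTY
    ALL = _IntervalStatus.ALL
    INTERVAL = _IntervalStatus.INTERVAL

    @classmethod
    def empty(cls, kind: str, domain: tuple[float, float]) -> "ConditionInterval":
        return cls(kind=kind, status=_IntervalStatus.EMPTY, domain=domain)

    @classmethod
    def everywhere(cls, kind: str, domain: tuple[float, float]) -> "ConditionInterval":
        return cls(
            kind=kind,
            status=_IntervalStatus.ALL,
            lower=domain[0],
            upper=domain[1],
            domain=domain,
        )

    @property
    def is_empty(self) -> bool:
        return self.status is _IntervalStatus.EMPTY

    def contains(self, beta: float) -> bool:
        if self.status is _IntervalStatus.EMPTY:
            return False
        if self.status is _IntervalStatus.ALL:
            return self.domain[0] <= beta <= self.domain[1]
        return self.lower < beta < self.upper  # open interval

    def width(self) -> float:
        if self.status is _IntervalStatus.EMPTY:
            return 0.0
        return self.upper - self.lower

    def intersect(self, other: "ConditionInterval", kind: str) -> "ConditionInterval":
        if self.is_empty or other.is_empty:
            return ConditionInterval.empty(kind, self.domain)
        lo = max(self.lower, other.lower)
        hi = min(self.upper, other.upper)
        if lo >= hi:
            return ConditionInterval.empty(kind, self.domain)
        status = (
            _IntervalStatus.ALL
            if self.status is other.status is _IntervalStatus.ALL
            else _IntervalStatus.INTERVAL
        )
        return ConditionInterval(kind, status, lo, hi, self.domain)

    def union_hull(self, other: "ConditionInterval", kind: str) -> "ConditionInterval":
        """Union of two overlapping-or-nested intervals (interval hull)."""
        if self.is_empty:
            return ConditionInterval(kind, other.status, other.lower, other.upper, self.domain)
        if other.is_empty:
            return ConditionInterval(kind, self.status, self.lower, self.upper, self.domain)
        lo = min(self.lower, other.lower)
        hi = max(self.upper, other.upper)
        if math.isclose(lo, self.domain[0], abs_tol=1e-12) and math.isclose(
            hi, self.domain[1], abs_tol=1e-12
        ):
            return ConditionInterval.everywhere(kind, self.domain)
        return ConditionInterval(kind, _IntervalStatus.INTERVAL, lo, hi, self.domain)


def _require_valid(geom: SegmentGeometry) -> None:
    if not geom.valid:
        raise ValueError(
            "invalid geometry: railing pivot at or above the body's free end "
            f"(L1={geom.lower_length:.4f} m, L2={geom.upper_length:.4f} m)"
        )


def _condition_interval(
    margin_of_beta,
    kind: str,
    alpha: float,
    beta_domain: tuple[float, float],
) -> ConditionInterval:
    """Locate the (single) beta-interval where ``margin > 0`` by scan + bisection.

    Both condition margins are affine in ``sin(alpha + beta)``, so their
    positive set within [0, pi - alpha] is one interval; the scan would
    surface any violation of that assumption as multiple sign changes.
    """
    lo, hi = beta_domain
    hi = min(hi, math.pi - alpha)  # posture validity: alpha + beta <= pi
    if hi <= lo:
        return ConditionInterval.empty(kind, beta_domain)

    grid = np.linspace(lo, hi, _SCAN_POINTS)
    vals = margin_of_beta(grid)
    pos = vals > 0.0

    if not pos.any():
        return ConditionInterval.empty(kind, beta_domain)
    if pos.all():
        return ConditionInterval.everywhere(kind, (lo, hi))

    def refine(b_stable: float, b_unstable: float) -> float:
        # bisect on the margin sign; keeps the bracket [stable, unstable]
        while abs(b_unstable - b_stable) > _BISECT_TOL:
            mid = 0.5 * (b_stable + b_unstable)
            if margin_of_beta(np.array([mid]))[0] > 0.0:
                b_unstable = mid
            else:
                b_stable = mid
        return 0.5 * (b_stable + b_unstable)

    changes = np.flatnonzero(pos[:-1] != pos[1:])
    endpoints: list[float] = []
    for i in changes:
        if pos[i + 1]:  # stable -> unstable: lower endpoint
            endpoints.append(refine(grid[i], grid[i + 1]))
        else:  # unstable -> stable: upper endpoint
            endpoints.append(refine(grid[i + 1], grid[i]))

    lower = lo if pos[0] else endpoints.pop(0)
    upper = hi if pos[-1] else endpoints.pop(-1)
    if endpoints:  # pragma: no cover - would contradict the affine structure
        raise RuntimeError(
            f"{kind} condition produced a disconnected beta set at alpha="
            f"{math.degrees(alpha):.2f} deg"
        )
    return ConditionInterval(kind, _IntervalStatus.INTERVAL, lower, upper, (lo, hi))


def slip_beta_interval(
    anthro: Anthropometry,
    scenario: RailingScenario,
    alpha: float,
    beta_domain: tuple[float, float] = (0.0, DEFAULT_BETA_MAX),
) -> ConditionInterval:
    """Beta-interval at fixed alpha where the feet must slip (F > mu*GRF)."""
    geom = derive_segments(anthro, scenario, alpha)
    _require_valid(geom)
    weights = split_weights(anthro, geom)
    mu = scenario.friction_coefficient

    def margin(betas: np.ndarray) -> np.ndarray:
        p = _posture_array(alpha, betas)
        return slip_margin(anthro, weights, geom, p, mu)

    return _condition_interval(margin, "slip", alpha, beta_domain)


def tilt_beta_interval(
    anthro: Anthropometry,
    scenario: RailingScenario,
    alpha: float,
    beta_domain: tuple[float, float] = (0.0, DEFAULT_BETA_MAX),
) -> ConditionInterval:
    """Beta-interval at fixed alpha where the body tips over the rail.

    Identical for every friction coefficient: tipping is a pure moment
    balance.
    """
    geom = derive_segments(anthro, scenario, alpha)
    _require_valid(geom)
    weights = split_weights(anthro, geom)

    def margin(betas: np.ndarray) -> np.ndarray:
        p = _posture_array(alpha, betas)
        return tilt_margin(anthro, weights, geom, p)

    return _condition_interval(margin, "tilt", alpha, beta_domain)


class _PostureArray:
    """Duck-typed Posture carrying an array of betas (internal fast path)."""

    __slots__ = ("alpha", "beta")

    def __init__(self, alpha: float, beta: np.ndarray) -> None:
        self.alpha = alpha
        self.beta = beta


def _posture_array(alpha: float, betas: np.ndarray) -> _PostureArray:
    return _PostureArray(alpha, betas)


class StabilityCategory(enum.Enum):
    STABLE = "STABLE"
    SLIP_ONLY = "SLIP_ONLY"
    TILT_ONLY = "TILT_ONLY"
    FALL_POSSIBLE = "FALL_POSSIBLE"
    INVALID_GEOMETRY = "INVALID_GEOMETRY"


@dataclass(frozen=True)
class StabilityAssessment:
    """Classification of one (alpha, beta) posture with diagnostics."""

    category: StabilityCategory
    grf_negative: bool
    warnings: tuple[str, ...]
    demand: ForceDemand | None
    geometry: SegmentGeometry

    @property
    def fall_possible(self) -> bool:
        return self.category is StabilityCategory.FALL_POSSIBLE


def classify_posture(
    anthro: Anthropometry,
    scenario: RailingScenario,
    posture: Posture,
    plausibility: PlausibilityConfig | None = None,
) -> StabilityAssessment:
    """Total classification of a posture into one stability category.

    A fall over the railing is possible exactly when both the anti-slip
    and the anti-tilt condition are violated.  GRF < 0 does not alter the
    classification algebra (the criteria are applied as written) but is
    flagged, since Coulomb friction against a negative normal force is not
    physically meaningful.
    """
    geom = derive_segments(anthro, scenario, posture.alpha)
    warnings = tuple(anatomical_plausibility(geom, posture, plausibility))
    if not geom.valid:
        return StabilityAssessment(
            category=StabilityCategory.INVALID_GEOMETRY,
            grf_negative=False,
            warnings=warnings,
            demand=None,
            geometry=geom,
        )
    weights = split_weights(anthro, geom)
    demand = force_demand(anthro, weights, geom, posture)
    slips = not anti_slip_holds(demand, scenario.friction_coefficient)
    tilts = not anti_tilt_holds(anthro, weights, geom, posture)
    if slips and tilts:
        category = StabilityCategory.FALL_POSSIBLE
    elif slips:
        category = StabilityCategory.SLIP_ONLY
    elif tilts:
        category = StabilityCategory.TILT_ONLY
    else:
        category = StabilityCategory.STABLE
    return StabilityAssessment(
        category=category,
        grf_negative=demand.ground_reaction < 0.0,
        warnings=warnings,
        demand=demand,
        geometry=geom,
    )
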