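"""Body and railing geometry for the cranked-rod model.

A person leaning over a railing is idealised as a rigid rod with a single
bend ("crank") at the contact point with the handrail.  The lower segment
runs from the feet (point A, on the ground) to the pivot B on the handrail;
the upper segment runs from B to the vertex C.  The segment lengths follow
from body length ``L``, railing height ``Y`` and the lean angle ``alpha``
of the lower segment against the vertical railing plane::

    L1 = Y / cos(alpha)          L2 = L - L1

Assuming a homogeneous mass distribution along the rod, each segment's
weight is proportional to its length and its centre of gravity sits at a
fractional position (``a`` for the lower, ``b`` for the upper segment)
along the segment from its proximal end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Anthropometry",
    "RailingScenario",
    "Posture",
    "SegmentGeometry",
    "SegmentWeights",
    "PlausibilityConfig",
    "derive_segments",
    "split_weights",
    "alpha_validity_limit",
    "anatomical_plausibility",
    "PIVOT_ABOVE_ABDOMEN",
    "LARGE_ALPHA",
]

#: Warning code: the pivot sits above the abdominal region (L1/L too large).
PIVOT_ABOVE_ABDOMEN = "PIVOT_ABOVE_ABDOMEN"
#: Warning code: lean angle too large for feet-on-ground contact.
LARGE_ALPHA = "LARGE_ALPHA"

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class Anthropometry:
    """Whole-body parameters of the person modelled as a homogeneous rod.

    Parameters
    ----------
    total_length : float
        Body length L in metres (> 0).
    mass : float
        Body mass m in kilograms (> 0).
    cog_fraction_lower : float
        Scaling factor ``a`` in (0, 1): the lower segment's centre of
        gravity sits at ``a * L1`` from the feet.
    cog_fraction_upper : float
        Scaling factor ``b`` in (0, 1): the upper segment's centre of
        gravity sits at ``b * L2`` from the pivot.
    gravity : float
        Gravitational acceleration in m/s^2.  Only force magnitudes depend
        on it; the slip/tilt thresholds depend on weight ratios and cancel g.
    """

    total_length: float
    mass: float
    cog_fraction_lower: float = 0.5
    cog_fraction_upper: float = 0.5
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError(f"total_length must be > 0, got {self.total_length}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        for name in ("cog_fraction_lower", "cog_fraction_upper"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.gravity <= 0:
            raise ValueError(f"gravity must be > 0, got {self.gravity}")

    @property
    def weight(self) -> float:
        """Total weight m*g in newtons."""
        return self.mass * self.gravity


@dataclass(frozen=True)
class RailingScenario:
    """Environment: railing height Y (m) and static friction coefficient mu
    at the feet-ground contact."""

    railing_height: float
    friction_coefficient: float

    def __post_init__(self) -> None:
        if self.railing_height <= 0:
            raise ValueError(
                f"railing_height must be > 0, got {self.railing_height}"
            )
        if self.friction_coefficient < 0:
            raise ValueError(
                f"friction_coefficient must be >= 0, got {self.friction_coefficient}"
            )


@dataclass(frozen=True)
class Posture:
    """Body posture angles, stored in radians.

    ``alpha`` is the angle between the (vertical) railing plane and the
    lower body segment; ``beta`` the flexion angle between lower and upper
    segment (0 = straight).  Use :meth:`from_degrees` at user-facing
    boundaries; all internal computation is in radians.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < math.pi / 2:
            raise ValueError(
                f"alpha must lie in [0, pi/2), got {self.alpha} rad"
            )
        if self.beta < 0.0 or self.alpha + self.beta > math.pi + 1e-12:
            raise ValueError(
                "beta must lie in [0, pi - alpha]: the upper segment cannot "
                f"fold back through the lower one (alpha={self.alpha}, "
                f"beta={self.beta} rad)"
            )

    @classmethod
    def from_degrees(cls, alpha_deg: float, beta_deg: float) -> "Posture":
        return cls(math.radians(alpha_deg), math.radians(beta_deg))

    @property
    def alpha_deg(self) -> float:
        return math.degrees(self.alpha)

    @property
    def beta_deg(self) -> float:
        return math.degrees(self.beta)


@dataclass(frozen=True)
class SegmentGeometry:
    """Segment lengths at a given lean angle.

    ``valid`` is False when ``Y / cos(alpha) >= L``: the geometry places the
    pivot beyond the top of the body, so no cranked-rod configuration
    exists.  Invalid geometry is a flag, not an exception — region scans
    must be total over their grids.
    """

    lower_length: float
    upper_length: float
    valid: bool
    pivot_fraction: float

    @property
    def length_ratio(self) -> float:
        """L2/L1, the lever ratio appearing in the force closed forms."""
        return self.upper_length / self.lower_length


@dataclass(frozen=True)
class SegmentWeights:
    """Per-segment weight forces G1 (below pivot) and G2 (above), newtons."""

    lower_weight: float
    upper_weight: float

    @property
    def total(self) -> float:
        return self.lower_weight + self.upper_weight


def alpha_validity_limit(anthro: Anthropometry, scenario: RailingScenario) -> float:
    """Largest lean angle (radians) with a geometrically valid configuration.

    Validity requires ``Y / cos(alpha) < L``, i.e. ``alpha < arccos(Y/L)``.
    Returns pi/2 when the railing is taller than the person (every alpha
    in [0, pi/2) is then invalid and this limit is never reached).
    """
    ratio = scenario.railing_height / anthro.total_length
    if ratio >= 1.0:
        return 0.0
    return math.acos(ratio)


def derive_segments(
    anthro: Anthropometry, scenario: RailingScenario, alpha: float
) -> SegmentGeometry:
    """Split the body at the handrail: L1 = Y/cos(alpha), L2 = L - L1.

    Parameters
    ----------
    alpha : float
        Lean angle in radians, 0 <= alpha < pi/2.

    Returns
    -------
    SegmentGeometry
        With ``valid=False`` (and ``upper_length <= 0``) when the pivot
        would lie above the body's free end.
    """
    if not 0.0 <= alpha < math.pi / 2:
        raise ValueError(f"alpha must lie in [0, pi/2), got {alpha} rad")
    lower = scenario.railing_height / math.cos(alpha)
    upper = anthro.total_length - lower
    return SegmentGeometry(
        lower_length=lower,
        upper_length=upper,
        valid=upper > 0.0,
        pivot_fraction=lower / anthro.total_length,
    )


def split_weights(anthro: Anthropometry, geom: SegmentGeometry) -> SegmentWeights:
    """Length-proportional weight split of the homogeneous rod.

    G1 = m*g*L1/L and G2 = m*g*L2/L; recomputed per alpha since the split
    point moves along the body as the lean angle changes.
    """
    if not geom.valid:
        raise ValueError(
            "cannot split weights on invalid geometry (pivot above body end)"
        )
    w = anthro.weight
    g1 = w * geom.lower_length / anthro.total_length
    g2 = w * geom.upper_length / anthro.total_length
    return SegmentWeights(lower_weight=g1, upper_weight=g2)


@dataclass(frozen=True)
class PlausibilityConfig:
    """Thresholds for anatomical-applicability warnings.

    pivot_fraction_warn : pivot higher than this fraction of body length is
        flagged — the rotation point then sits in the thoracic region where
        no joint allows forward flexion about the handrail.
    alpha_warn : lean angles (radians) beyond this are flagged — they are
        hard to realise while keeping feet-ground contact.
    Values exactly at a threshold count as plausible.
    """

    pivot_fraction_warn: float = 0.65
    alpha_warn: float = field(default=math.radians(30.0))


def anatomical_plausibility(
    geom: SegmentGeometry,
    posture: Posture,
    config: PlausibilityConfig | None = None,
) -> list[str]:
    """Check whether the idealised geometry maps onto a real body.

    The rod model is only meaningful when the pivot corresponds to the
    lower abdominal/pelvic region (where the trunk can flex forward over a
    handrail) and the lean angle is achievable with feet on the ground.
    Returns a list of warning codes; never raises and never blocks
    downstream computation.
    """
    cfg = config or PlausibilityConfig()
    warnings: list[str] = []
    if geom.valid and geom.pivot_fraction > cfg.pivot_fraction_warn:
        warnings.append(PIVOT_ABOVE_ABDOMEN)
    if posture.alpha > cfg.alpha_warn:
        warnings.append(LARGE_ALPHA)
    return warnings
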