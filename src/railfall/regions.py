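"""(alpha, beta) stability-region maps and sensitivity scans.

At each lean angle alpha the slip and tilt criteria carve the beta axis
into stable and unstable stretches; sweeping alpha produces a region map
of the posture plane.  The fall-possible region is the pointwise
intersection of the slip and tilt regions.  Interval endpoints reported
here come from the analytic scan + bisection path, not from the grid, so
they are not aliased to the grid step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .anthropometry import (
    Anthropometry,
    Posture,
    RailingScenario,
    derive_segments,
    split_weights,
)
from .statics import (
    DEFAULT_BETA_MAX,
    ConditionInterval,
    StabilityCategory,
    friction_demand,
    ground_reaction,
    slip_margin,
    slip_beta_interval,
    tilt_beta_interval,
    tilt_margin,
    _posture_array,
)

__all__ = [
    "RegionMap",
    "SensitivityResult",
    "SensitivityEntry",
    "scan_region",
    "fall_interval",
    "instability_union_interval",
    "sensitivity_scan",
]


def fall_interval(
    anthro: Anthropometry,
    scenario: RailingScenario,
    alpha: float,
    beta_domain: tuple[float, float] = (0.0, DEFAULT_BETA_MAX),
) -> ConditionInterval:
    """Beta-interval at fixed alpha where a fall over the railing is possible.

    The intersection of the slip and tilt intervals: both instability
    conditions must hold simultaneously.
    """
    slip = slip_beta_interval(anthro, scenario, alpha, beta_domain)
    tilt = tilt_beta_interval(anthro, scenario, alpha, beta_domain)
    return slip.intersect(tilt, "fall")


def instability_union_interval(
    anthro: Anthropometry,
    scenario: RailingScenario,
    alpha: float,
    beta_domain: tuple[float, float] = (0.0, DEFAULT_BETA_MAX),
) -> ConditionInterval:
    """Beta-interval where at least one instability condition holds.

    Both conditions are threshold criteria on ``sin(alpha + beta)``, so
    their intervals are nested around the same centre and the union is
    again one interval.
    """
    slip = slip_beta_interval(anthro, scenario, alpha, beta_domain)
    tilt = tilt_beta_interval(anthro, scenario, alpha, beta_domain)
    return slip.union_hull(tilt, "instability")


@dataclass(frozen=True)
class RegionMap:
    """Classified posture grid plus per-alpha analytic condition intervals.

    ``classes`` has shape (n_alpha, n_beta) of :class:`StabilityCategory`
    values; ``grf`` and ``friction`` hold the contact forces (NaN where
    the geometry or posture is invalid).  ``slip_intervals`` etc. map each
    alpha grid value (degrees, rounded to 1e-9) to its interval.
    """

    alpha_deg: np.ndarray
    beta_deg: np.ndarray
    classes: np.ndarray
    grf: np.ndarray
    friction: np.ndarray
    slip_intervals: dict[float, ConditionInterval | None]
    tilt_intervals: dict[float, ConditionInterval | None]
    fall_intervals: dict[float, ConditionInterval | None]
    anthro: Anthropometry
    scenario: RailingScenario

    @property
    def fall_mask(self) -> np.ndarray:
        return self.classes == StabilityCategory.FALL_POSSIBLE

    @property
    def fall_region_empty(self) -> bool:
        return not self.fall_mask.any()

    def fall_area_deg2(self) -> float:
        """Cell-count area of the fall region in square degrees."""
        if len(self.alpha_deg) < 2 or len(self.beta_deg) < 2:
            return 0.0
        da = float(self.alpha_deg[1] - self.alpha_deg[0])
        db = float(self.beta_deg[1] - self.beta_deg[0])
        return float(self.fall_mask.sum()) * da * db

    def class_at(self, alpha_deg: float, beta_deg: float) -> StabilityCategory:
        i = int(np.argmin(np.abs(self.alpha_deg - alpha_deg)))
        j = int(np.argmin(np.abs(self.beta_deg - beta_deg)))
        return self.classes[i, j]


def scan_region(
    anthro: Anthropometry,
    scenario: RailingScenario,
    alpha_range_deg: tuple[float, float],
    beta_range_deg: tuple[float, float] = (0.0, 130.0),
    step_deg: float = 1.0,
) -> RegionMap:
    """Classify every posture on a regular (alpha, beta) grid in degrees.

    Grid cells with invalid geometry (pivot above the body's end) or an
    unphysical posture (alpha + beta > 180 deg) are marked
    INVALID_GEOMETRY.  Per-alpha analytic intervals are computed alongside
    (None for invalid alpha columns).
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be > 0")
    a_lo, a_hi = alpha_range_deg
    b_lo, b_hi = beta_range_deg
    if a_hi < a_lo or b_hi < b_lo:
        raise ValueError("empty alpha or beta range")
    alpha_deg = _inclusive_arange(a_lo, a_hi, step_deg)
    beta_deg = _inclusive_arange(b_lo, b_hi, step_deg)
    beta_rad = np.radians(beta_deg)
    beta_domain = (math.radians(b_lo), math.radians(b_hi))

    n_a, n_b = len(alpha_deg), len(beta_deg)
    classes = np.full((n_a, n_b), StabilityCategory.INVALID_GEOMETRY, dtype=object)
    grf = np.full((n_a, n_b), np.nan)
    fric = np.full((n_a, n_b), np.nan)
    slip_iv: dict[float, ConditionInterval | None] = {}
    tilt_iv: dict[float, ConditionInterval | None] = {}
    fall_iv: dict[float, ConditionInterval | None] = {}

    mu = scenario.friction_coefficient
    for i, a_deg in enumerate(alpha_deg):
        alpha = math.radians(a_deg)
        key = round(float(a_deg), 9)
        geom = derive_segments(anthro, scenario, alpha)
        if not geom.valid:
            slip_iv[key] = tilt_iv[key] = fall_iv[key] = None
            continue
        weights = split_weights(anthro, geom)
        physical = alpha + beta_rad <= math.pi + 1e-12
        p = _posture_array(alpha, beta_rad)
        grf_col = ground_reaction(anthro, weights, geom, p)
        fric_col = friction_demand(anthro, weights, geom, p)
        slips = slip_margin(anthro, weights, geom, p, mu) > 0.0
        tilts = tilt_margin(anthro, weights, geom, p) > 0.0

        col = np.where(
            slips & tilts,
            StabilityCategory.FALL_POSSIBLE,
            np.where(
                slips,
                StabilityCategory.SLIP_ONLY,
                np.where(tilts, StabilityCategory.TILT_ONLY, StabilityCategory.STABLE),
            ),
        )
        col = np.where(physical, col, StabilityCategory.INVALID_GEOMETRY)
        classes[i] = col
        grf[i] = np.where(physical, grf_col, np.nan)
        fric[i] = np.where(physical, fric_col, np.nan)

        s = slip_beta_interval(anthro, scenario, alpha, beta_domain)
        t = tilt_beta_interval(anthro, scenario, alpha, beta_domain)
        slip_iv[key] = s
        tilt_iv[key] = t
        fall_iv[key] = s.intersect(t, "fall")

    return RegionMap(
        alpha_deg=alpha_deg,
        beta_deg=beta_deg,
        classes=classes,
        grf=grf,
        friction=fric,
        slip_intervals=slip_iv,
        tilt_intervals=tilt_iv,
        fall_intervals=fall_iv,
        anthro=anthro,
        scenario=scenario,
    )


@dataclass(frozen=True)
class SensitivityEntry:
    """Summary of one (a, b, mu) combination in a sensitivity scan."""

    cog_fraction_lower: float
    cog_fraction_upper: float
    friction_coefficient: float
    fall_region_empty: bool
    fall_area_deg2: float
    fall_intervals: dict[float, ConditionInterval | None]


@dataclass(frozen=True)
class SensitivityResult:
    """Grid of sensitivity entries keyed by (a, b, mu)."""

    entries: dict[tuple[float, float, float], SensitivityEntry]

    def all_empty(self, mu: float) -> bool:
        return all(
            e.fall_region_empty for k, e in self.entries.items() if k[2] == mu
        )

    def all_nonempty(self, mu: float) -> bool:
        return all(
            not e.fall_region_empty for k, e in self.entries.items() if k[2] == mu
        )


def sensitivity_scan(
    anthro: Anthropometry,
    scenario: RailingScenario,
    a_values,
    b_values,
    mu_values,
    alpha_range_deg: tuple[float, float] | None = None,
    beta_range_deg: tuple[float, float] = (0.0, 130.0),
    step_deg: float = 1.0,
) -> SensitivityResult:
    """Region maps over a grid of COG fractions and friction coefficients.

    Probes how the stability-region topology responds to the main unknown
    parameters: where along each segment its mass centre sits (a, b) and
    the shoe-ground friction (mu).  Reports, per combination, whether the
    fall region is empty and its cell-count area.
    """
    entries: dict[tuple[float, float, float], SensitivityEntry] = {}
    for a in a_values:
        for b in b_values:
            varied = replace(
                anthro, cog_fraction_lower=float(a), cog_fraction_upper=float(b)
            )
            if alpha_range_deg is None:
                limit = math.degrees(
                    math.acos(scenario.railing_height / anthro.total_length)
                )
                arange = (0.0, math.floor(limit / step_deg) * step_deg)
            else:
                arange = alpha_range_deg
            for mu in mu_values:
                sc = replace(scenario, friction_coefficient=float(mu))
                rmap = scan_region(varied, sc, arange, beta_range_deg, step_deg)
                entries[(float(a), float(b), float(mu))] = SensitivityEntry(
                    cog_fraction_lower=float(a),
                    cog_fraction_upper=float(b),
                    friction_coefficient=float(mu),
                    fall_region_empty=rmap.fall_region_empty,
                    fall_area_deg2=rmap.fall_area_deg2(),
                    fall_intervals=rmap.fall_intervals,
                )
    return SensitivityResult(entries=entries)


def _inclusive_arange(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    if abs(lo + n * step - hi) > 1e-9:
        n = int(math.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)
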