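"""Case reports and machine-readable output for region maps.

A case report renders, for one person/railing parameter set, the
slip/tilt/fall beta-intervals per lean angle and per friction coefficient,
the plausibility warnings, and (optionally) the equilibrium-oracle
verification status — as a plain dict for downstream tooling plus a short
human-readable text block.  Angles are printed in degrees to 0.1 deg and
forces to 0.1 N; full-precision values stay in the dict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .anthropometry import (
    Anthropometry,
    PlausibilityConfig,
    Posture,
    RailingScenario,
    alpha_validity_limit,
    anatomical_plausibility,
    derive_segments,
)
from .equilibrium import verify_posture
from .regions import RegionMap, scan_region
from .statics import ConditionInterval, StabilityCategory

__all__ = ["ReportConfig", "CaseReport", "case_report", "region_csv", "intervals_json"]


@dataclass(frozen=True)
class ReportConfig:
    """What a case report sweeps over."""

    mu_values: tuple[float, ...] = (0.2, 0.7)
    alpha_step_deg: float = 1.0
    beta_range_deg: tuple[float, float] = (0.0, 130.0)
    verify: bool = True
    plausibility: PlausibilityConfig = field(default_factory=PlausibilityConfig)


@dataclass(frozen=True)
class CaseReport:
    summary: dict
    text: str

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.summary, indent=indent, sort_keys=True)


def _interval_entry(iv: ConditionInterval | None) -> dict | None:
    if iv is None:
        return None
    if iv.is_empty:
        return {"status": "empty"}
    return {
        "status": iv.status.value,
        "lower_deg": math.degrees(iv.lower),
        "upper_deg": math.degrees(iv.upper),
    }


def case_report(
    anthro: Anthropometry,
    scenario: RailingScenario,
    config: ReportConfig | None = None,
) -> CaseReport:
    """Full assessment of one case across the configured friction values.

    The scenario's own friction coefficient is included in the sweep if it
    is not already among ``config.mu_values``.
    """
    cfg = config or ReportConfig()
    mu_values = tuple(
        dict.fromkeys(list(cfg.mu_values) + [scenario.friction_coefficient])
    )
    limit_deg = math.degrees(alpha_validity_limit(anthro, scenario))
    alpha_hi = math.floor(limit_deg / cfg.alpha_step_deg) * cfg.alpha_step_deg
    if alpha_hi >= limit_deg:  # keep the top column strictly valid
        alpha_hi -= cfg.alpha_step_deg

    summary: dict = {
        "parameters": {
            "total_length_m": anthro.total_length,
            "mass_kg": anthro.mass,
            "a": anthro.cog_fraction_lower,
            "b": anthro.cog_fraction_upper,
            "g_m_s2": anthro.gravity,
            "railing_height_m": scenario.railing_height,
            "alpha_validity_limit_deg": limit_deg,
        },
        "per_mu": {},
    }
    lines = [
        "Cranked-rod railing-fall assessment",
        f"  body length {anthro.total_length:.2f} m, mass {anthro.mass:.1f} kg, "
        f"a={anthro.cog_fraction_lower:.2f}, b={anthro.cog_fraction_upper:.2f}",
        f"  railing height {scenario.railing_height:.2f} m; "
        f"valid lean angles alpha < {limit_deg:.1f} deg",
    ]

    for mu in mu_values:
        sc = RailingScenario(
            railing_height=scenario.railing_height, friction_coefficient=mu
        )
        rmap = scan_region(
            anthro, sc, (0.0, alpha_hi), cfg.beta_range_deg, cfg.alpha_step_deg
        )
        per_alpha = {}
        for a_deg in rmap.alpha_deg:
            key = round(float(a_deg), 9)
            geom = derive_segments(anthro, sc, math.radians(a_deg))
            warnings = anatomical_plausibility(
                geom,
                Posture(alpha=math.radians(a_deg), beta=0.0),
                cfg.plausibility,
            )
            per_alpha[f"{a_deg:g}"] = {
                "valid": bool(geom.valid),
                "warnings": warnings,
                "slip": _interval_entry(rmap.slip_intervals[key]),
                "tilt": _interval_entry(rmap.tilt_intervals[key]),
                "fall": _interval_entry(rmap.fall_intervals[key]),
            }
        summary["per_mu"][f"{mu:g}"] = {
            "fall_region_empty": rmap.fall_region_empty,
            "fall_area_deg2": rmap.fall_area_deg2(),
            "per_alpha": per_alpha,
        }
        lines.append(f"  mu = {mu:g}:")
        if rmap.fall_region_empty:
            lines.append(
                "    fall region empty: no (alpha, beta) posture satisfies "
                "slip and tilt simultaneously"
            )
        else:
            lines.append(
                f"    fall region non-empty, area {rmap.fall_area_deg2():.0f} deg^2"
            )
            ten = rmap.fall_intervals.get(10.0)
            if ten is not None and not ten.is_empty:
                lines.append(
                    f"    at alpha = 10 deg: fall possible for beta in "
                    f"({math.degrees(ten.lower):.1f}, {math.degrees(ten.upper):.1f}) deg"
                )

    if cfg.verify:
        probe = Posture.from_degrees(
            min(10.0, max(alpha_hi, 0.0)), 80.0 if alpha_hi > 0 else 0.0
        )
        sol = verify_posture(anthro, scenario, probe)
        scale = anthro.weight * anthro.total_length
        summary["oracle_verification"] = {
            "posture_deg": [probe.alpha_deg, probe.beta_deg],
            "force_residual_N": sol.force_residual,
            "moment_residual_A_Nm": sol.moment_residual_A,
            "moment_residual_B_Nm": sol.moment_residual_B,
            "passed": bool(
                sol.force_residual < 1e-9 * anthro.weight
                and abs(sol.moment_residual_A) < 1e-9 * scale
                and abs(sol.moment_residual_B) < 1e-9 * scale
            ),
        }
        lines.append(
            "  equilibrium oracle: residuals "
            f"|F|={sol.force_residual:.2e} N, "
            f"M_A={sol.moment_residual_A:.2e} N*m, "
            f"M_B={sol.moment_residual_B:.2e} N*m"
        )

    return CaseReport(summary=summary, text="\n".join(lines))


def region_csv(rmap: RegionMap) -> str:
    """Region map as deterministic CSV text.

    Header: ``alpha_deg,beta_deg,class,grf_N,friction_N,grf_negative,warnings``.
    """
    from .anthropometry import anatomical_plausibility as plaus

    rows = ["alpha_deg,beta_deg,class,grf_N,friction_N,grf_negative,warnings"]
    for i, a_deg in enumerate(rmap.alpha_deg):
        geom = derive_segments(rmap.anthro, rmap.scenario, math.radians(a_deg))
        for j, b_deg in enumerate(rmap.beta_deg):
            cls = rmap.classes[i, j]
            grf = rmap.grf[i, j]
            fric = rmap.friction[i, j]
            if cls is StabilityCategory.INVALID_GEOMETRY:
                grf_s = fric_s = ""
                neg = ""
                warn = ""
            else:
                grf_s = f"{grf:.6f}"
                fric_s = f"{fric:.6f}"
                neg = str(bool(grf < 0)).lower()
                warn = ";".join(
                    plaus(
                        geom,
                        Posture(
                            alpha=math.radians(a_deg), beta=math.radians(b_deg)
                        ),
                    )
                )
            rows.append(
                f"{a_deg:g},{b_deg:g},{cls.value},{grf_s},{fric_s},{neg},{warn}"
            )
    return "\n".join(rows) + "\n"


def intervals_json(rmap: RegionMap, indent: int = 2) -> str:
    """Per-alpha slip/tilt/fall interval endpoints as JSON text."""
    payload = {}
    for a_deg in rmap.alpha_deg:
        key = round(float(a_deg), 9)
        payload[f"{a_deg:g}"] = {
            "slip": _interval_entry(rmap.slip_intervals[key]),
            "tilt": _interval_entry(rmap.tilt_intervals[key]),
            "fall": _interval_entry(rmap.fall_intervals[key]),
        }
    return json.dumps(payload, indent=indent, sort_keys=True)
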