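"""Numerical planar equilibrium of the cranked rod, solved as a linear system.

This module is the independent check on the closed-form contact forces: it
never uses those formulas.  The rod is placed in a fixed frame — feet A at
the origin, x horizontal toward the railing, y up — and the three unknown
contact-force magnitudes are solved from force balance and the moment
balance about A:

* vertical ground reaction at A,
* horizontal friction force at A,
* bearing force H at B, constrained perpendicular to the lower segment
  (the handrail contact is modelled frictionless, so H cannot act along
  the segment).

The moment balance about B is *not* used in the solve; its residual is
reported and must vanish, since the three balance equations are consistent
rather than independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import (
    Anthropometry,
    Posture,
    RailingScenario,
    SegmentGeometry,
    SegmentWeights,
    derive_segments,
    split_weights,
)

__all__ = [
    "PlanarConfiguration",
    "EquilibriumSolution",
    "cross2d",
    "build_configuration",
    "solve_equilibrium",
    "force_system",
    "moment_about",
    "verify_posture",
]

Vec = np.ndarray


def cross2d(u, v) -> float:
    """Planar cross product ``(x, y) x (u, v) = x*v - y*u``.

    The scalar moment of a force about a point is ``cross2d(lever, force)``
    with the lever running from the point to the force's application point;
    positive values are counter-clockwise in the (x right, y up) frame.
    """
    return float(u[0] * v[1] - u[1] * v[0])


@dataclass(frozen=True)
class PlanarConfiguration:
    """Geometric layout of the rod in the working frame (metres).

    ``point_A`` is the feet-ground contact (origin), ``point_B`` the pivot
    on the handrail, ``point_C`` the free end (vertex).  ``cog_1`` and
    ``cog_2`` are the segment centres of gravity.
    """

    point_A: Vec
    point_B: Vec
    point_C: Vec
    lower_vector: Vec
    upper_vector: Vec
    cog_1: Vec
    cog_2: Vec


def build_configuration(
    anthro: Anthropometry, scenario: RailingScenario, posture: Posture
) -> PlanarConfiguration:
    """Place the cranked rod in the plane for a given posture.

    The lower segment leaves A at angle alpha from the vertical; the upper
    segment continues at alpha + beta from the vertical, bending further
    over the railing.  By construction ``point_B[1]`` equals the railing
    height.
    """
    geom = derive_segments(anthro, scenario, posture.alpha)
    if not geom.valid:
        raise ValueError("invalid geometry: cannot place the rod")
    a1 = posture.alpha
    a2 = posture.alpha + posture.beta
    lower = geom.lower_length * np.array([math.sin(a1), math.cos(a1)])
    upper = geom.upper_length * np.array([math.sin(a2), math.cos(a2)])
    point_a = np.zeros(2)
    point_b = point_a + lower
    return PlanarConfiguration(
        point_A=point_a,
        point_B=point_b,
        point_C=point_b + upper,
        lower_vector=lower,
        upper_vector=upper,
        cog_1=point_a + anthro.cog_fraction_lower * lower,
        cog_2=point_b + anthro.cog_fraction_upper * upper,
    )


@dataclass(frozen=True)
class EquilibriumSolution:
    """Solved contact forces (newtons) and equilibrium diagnostics.

    ``grf_vector`` and ``friction_vector`` act at A; ``bearing_vector`` is
    the railing's force H at B.  ``weight_orthogonal``/``weight_collinear``
    decompose each segment's weight along and across its segment axis.
    Residuals are the force-balance norm and the moment sums about A and B
    of the complete force system — all should be at rounding level.
    """

    grf_vector: Vec
    friction_vector: Vec
    bearing_vector: Vec
    weight_orthogonal: tuple[Vec, Vec]
    weight_collinear: tuple[Vec, Vec]
    force_residual: float
    moment_residual_A: float
    moment_residual_B: float

    @property
    def vertical_ground_force(self) -> float:
        return float(self.grf_vector[1])

    @property
    def horizontal_force_magnitude(self) -> float:
        return float(abs(self.friction_vector[0]))


def solve_equilibrium(
    config: PlanarConfiguration, weights: SegmentWeights
) -> EquilibriumSolution:
    """Solve the 3x3 linear system for the three contact-force magnitudes.

    Unknowns: signed vertical GRF at A, signed horizontal friction at A,
    signed magnitude of the bearing force along the unit normal of the
    lower segment.  Equations: planar force balance (2) and moment balance
    about A (1).  The system is nonsingular for every valid configuration
    with alpha < pi/2 (asserted).
    """
    g1_vec = np.array([0.0, -weights.lower_weight])
    g2_vec = np.array([0.0, -weights.upper_weight])

    lower_unit = config.lower_vector / np.linalg.norm(config.lower_vector)
    normal = np.array([lower_unit[1], -lower_unit[0]])  # perpendicular to L1

    # columns: GRF direction, friction direction, bearing direction
    dir_grf = np.array([0.0, 1.0])
    dir_fric = np.array([1.0, 0.0])
    lever_b = config.point_B - config.point_A

    system = np.array(
        [
            [dir_grf[0], dir_fric[0], normal[0]],
            [dir_grf[1], dir_fric[1], normal[1]],
            [0.0, 0.0, cross2d(lever_b, normal)],  # GRF, F act at A: no moment
        ]
    )
    rhs = np.array(
        [
            -(g1_vec[0] + g2_vec[0]),
            -(g1_vec[1] + g2_vec[1]),
            -(
                cross2d(config.cog_1 - config.point_A, g1_vec)
                + cross2d(config.cog_2 - config.point_A, g2_vec)
            ),
        ]
    )
    det = np.linalg.det(system)
    assert abs(det) > 1e-12, "equilibrium system unexpectedly singular"
    grf_mag, fric_mag, bearing_mag = np.linalg.solve(system, rhs)

    grf_vec = grf_mag * dir_grf
    fric_vec = fric_mag * dir_fric
    bearing_vec = bearing_mag * normal

    # weight decomposition along / across each segment axis
    upper_unit = config.upper_vector / np.linalg.norm(config.upper_vector)
    g1_col = (g1_vec @ lower_unit) * lower_unit
    g2_col = (g2_vec @ upper_unit) * upper_unit
    decomposition_orth = (g1_vec - g1_col, g2_vec - g2_col)
    decomposition_col = (g1_col, g2_col)

    forces = [
        (config.point_A, grf_vec),
        (config.point_A, fric_vec),
        (config.point_B, bearing_vec),
        (config.cog_1, g1_vec),
        (config.cog_2, g2_vec),
    ]
    force_residual = float(np.linalg.norm(sum(f for _, f in forces)))
    return EquilibriumSolution(
        grf_vector=grf_vec,
        friction_vector=fric_vec,
        bearing_vector=bearing_vec,
        weight_orthogonal=decomposition_orth,
        weight_collinear=decomposition_col,
        force_residual=force_residual,
        moment_residual_A=moment_about(config.point_A, forces),
        moment_residual_B=moment_about(config.point_B, forces),
    )


def force_system(
    config: PlanarConfiguration,
    weights: SegmentWeights,
    solution: EquilibriumSolution,
) -> list[tuple[Vec, Vec]]:
    """The complete ``(application_point, force)`` list of a solved posture.

    Useful for taking moments about arbitrary points with
    :func:`moment_about` — e.g. checking that a balanced system has zero
    moment about the free end C as well.
    """
    return [
        (config.point_A, solution.grf_vector),
        (config.point_A, solution.friction_vector),
        (config.point_B, solution.bearing_vector),
        (config.cog_1, np.array([0.0, -weights.lower_weight])),
        (config.cog_2, np.array([0.0, -weights.upper_weight])),
    ]


def moment_about(point, forces) -> float:
    """Net scalar moment about ``point`` of ``(application_point, force)`` pairs."""
    return float(
        sum(cross2d(np.asarray(app) - np.asarray(point), f) for app, f in forces)
    )


def verify_posture(
    anthro: Anthropometry, scenario: RailingScenario, posture: Posture
) -> EquilibriumSolution:
    """Build, solve and return the equilibrium for one posture (convenience)."""
    config = build_configuration(anthro, scenario, posture)
    geom = derive_segments(anthro, scenario, posture.alpha)
    weights = split_weights(anthro, geom)
    return solve_equilibrium(config, weights)
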