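"""Seeded random scenario generation for property testing.

Draws anthropometry, railing and posture tuples from ranges wide enough to
cover realistic adult bodies and building railings, constrained so that
every generated tuple satisfies the type invariants by construction
(valid geometry, physical posture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import (
    Anthropometry,
    Posture,
    RailingScenario,
    alpha_validity_limit,
)
from .statics import DEFAULT_BETA_MAX

__all__ = ["ScenarioFixture", "generate_fixtures"]


@dataclass(frozen=True)
class ScenarioFixture:
    """One random but physically valid (person, railing, posture) tuple."""

    anthro: Anthropometry
    scenario: RailingScenario
    posture: Posture


def generate_fixtures(seed: int, n: int) -> list[ScenarioFixture]:
    """Generate ``n`` reproducible valid scenario fixtures.

    Ranges: body length 1.4-2.0 m, mass 45-110 kg, railing height
    0.8-1.2 m but below 0.8*L (so the pivot always sits on the torso),
    friction 0.05-1.0, COG fractions 0.3-0.7.  The lean angle is drawn
    strictly inside the validity range and beta inside the default beta
    domain, clipped so alpha + beta stays below 180 degrees.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    out: list[ScenarioFixture] = []
    for _ in range(n):
        length = rng.uniform(1.4, 2.0)
        mass = rng.uniform(45.0, 110.0)
        y_hi = min(1.2, 0.8 * length - 1e-6)
        railing = rng.uniform(0.8, y_hi)
        mu = rng.uniform(0.05, 1.0)
        a = rng.uniform(0.3, 0.7)
        b = rng.uniform(0.3, 0.7)
        anthro = Anthropometry(
            total_length=length,
            mass=mass,
            cog_fraction_lower=a,
            cog_fraction_upper=b,
        )
        scenario = RailingScenario(railing_height=railing, friction_coefficient=mu)
        alpha_max = alpha_validity_limit(anthro, scenario)
        alpha = rng.uniform(0.0, 0.999 * alpha_max)
        beta = rng.uniform(0.0, min(DEFAULT_BETA_MAX, math.pi - alpha))
        out.append(
            ScenarioFixture(
                anthro=anthro,
                scenario=scenario,
                posture=Posture(alpha=alpha, beta=beta),
            )
        )
    return out
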