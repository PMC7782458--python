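# Methods

## Model and assumptions

The package analyses whether a person can fall over a railing *without*
any dynamic contribution — no push, no jump, no initial velocity. The
body is a rigid, homogeneous two-segment rod ("cranked rod") in the
vertical plane containing the lean: the lower segment from the
feet-ground contact A to the handrail pivot B, the upper segment from B
to the free end C. All contacts are analysed at an instant of static
equilibrium; the question is whether equilibrium *can* be maintained, not
how a fall subsequently evolves.

Assumptions, in decreasing order of importance:

* **Quasi-static**: inertial forces are zero. Scenarios with pushing,
  jumping or active balance recovery are outside the model's scope.
* **Rigid, homogeneous rod**: segment weights are length-proportional,
  `G_i = m·g·L_i/L`, recomputed for every lean angle because the split
  point `L1 = Y/cos α` moves along the body as α changes. Segment-wise
  anthropometric mass tables are deliberately not used; the homogeneity
  assumption is what makes the published threshold structure exact.
* **Frictionless pivot**: the railing's bearing force H acts
  perpendicular to the lower segment. This closes the equilibrium system
  (four force components, three balance equations) and is the unique
  closure consistent with neglecting friction at B. Under it, the linear
  system reproduces the closed-form GRF and F expressions identically.
* **Point contacts**: the feet act at a single point with a vertical
  normal force and a horizontal Coulomb friction force; soft tissue does
  not deform.

## Stability criteria

At posture (α, β) the feet need a friction force
`F = (a·G1·sinα + G2·sinα + b·G2·(L2/L1)·sin(α+β))·cosα` against a normal
load `GRF = G1·(1 − a·sin²α) + G2·(cos²α − b·(L2/L1)·sinα·sin(α+β))`.

* **Slip condition** (instability): `F > μ·GRF`.
* **Tilt condition** (instability):
  `b·G2·L2·sin(α+β) > (a·G1 + G2)·L1·sinα`.
  Algebraically this compares, about the foot point A, the gravity moment
  contributed by the upper segment's overhang beyond the rail
  (`b·L2`-lever term) with the moments of the lower segment's weight and
  of the upper segment's weight carried at the rail. It is independent of
  μ and of g.
* **Fall possible**: both conditions hold simultaneously. Equality in
  either criterion counts as the stable (anti-) side, matching the
  non-strict inequalities of the anti-conditions.

Both criteria are affine in `sin(α+β)`, so at fixed α each violated set
is a single β-interval; the two arcsin branches of an endpoint satisfy
`β₂ = π − β₁ − 2α`. The implementation treats the primitive inequalities
as ground truth — endpoints are located by a 256-point scan over the β
domain plus sign bisection to 1e-12 rad — and exposes the closed-form
arcsin thresholds separately (`slip_threshold_sine`,
`tilt_threshold_sine`); the test suite asserts scan and closed form agree
to 1e-8 rad wherever the arcsin argument lies inside (−1, 1). This keeps
interval finding robust where the argument leaves [−1, 1] (condition
empty) or a branch leaves the β domain (interval clipped).

`GRF < 0` can arise for extreme postures; the criteria are still
evaluated as written (the classification algebra is unchanged) but a
`grf_negative` flag is raised, since Coulomb friction against a negative
normal force has no physical meaning.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `total_length` (L) | body length | m | — |
| `mass` (m) | body mass | kg | — |
| `railing_height` (Y) | handrail height above ground | m | — |
| `friction_coefficient` (μ) | static shoe-floor friction | – | — (0.5–0.7 typical for dry concrete, ~0.2 wet/smooth) |
| `cog_fraction_lower` (a) | lower-segment COG position from the feet | – | 0.5 |
| `cog_fraction_upper` (b) | upper-segment COG position from the pivot | – | 0.5 |
| `gravity` (g) | gravitational acceleration | m/s² | 9.81 |
| β domain | flexion range scanned | deg | [0, 130] |
| grid step | region-map resolution | deg | 1.0 |

g cancels from both criteria (they depend only on weight ratios), so it
matters only for reported force magnitudes. The β domain upper edge of
130° covers the flexion range a torso can realise over a handrail;
postures with α + β > 180° are excluded as unphysical. Angles are degrees
at every external interface (CLI, config, CSV, JSON) and radians
internally.

## Geometric and anatomical applicability

The formulae are only meaningful when the idealised geometry maps onto a
real body. Two configurable warnings (never errors) flag doubtful cases:

* `PIVOT_ABOVE_ABDOMEN` when `L1/L` exceeds 0.65 — the pivot then sits in
  the thoracic region, where no joint permits forward flexion about the
  handrail;
* `LARGE_ALPHA` when α exceeds 30° — such leans are hard to hold with
  feet on the ground.

Values exactly at a threshold count as plausible. Geometric validity
(`L1 < L`, i.e. α < arccos(Y/L)) is likewise a flag: invalid cells in a
region map are classified `INVALID_GEOMETRY` rather than raising, so
scans are total over their grids.

## Independent verification

`railfall.equilibrium` solves the planar equilibrium numerically as a
3×3 linear system (unknowns: vertical GRF, horizontal friction, signed
bearing magnitude along the lower segment's normal), using only the
geometric placement and the 2-D cross product `(x,y)×(u,v) = xv − yu` —
never the closed forms. The moment balance about B is excluded from the
solve and reported as a residual; with force balance enforced it must
vanish about *every* point, and the tests check A, B and the free end C
on seeded random configurations (residuals < 1e-9·m·g·L). The oracle
also exposes the per-segment orthogonal/collinear weight decomposition,
verified Pythagorean-complete.

A note on the tilt criterion's moment form: taking moments of G1 and G2
about the pivot B with the literal COG levers (−(1−a)·L1 and b·L2) gives
a *different* threshold, `sin(α+β) = (1−a)·G1·L1·sinα/(b·G2·L2)`, which
does not reproduce the published interval structure this model is built
around (it would put the case's tilt onset near β ≈ 11° instead of 50°).
The implemented criterion is the α-β threshold form stated above, which
does; the discrepancy is inherent to the source formulation, and the test
suite pins the implemented form, not the about-B moment identity.

## Numerical choices

* Endpoint refinement: bisection on the sign of the primitive inequality,
  256-point initial scan per α, tolerance 1e-12 rad — so the branch
  identity `β₂ = π − β₁ − 2α` holds to 1e-10 rad for interval endpoints
  away from domain edges.
* Region maps classify cells by vectorised margin evaluation per α
  column; the analytic per-α intervals are computed alongside, and
  reported endpoints always come from the analytic path, never from the
  grid (printed-degree comparisons round analytic values).
* Fall-region area is cell count × cell area in deg²; "topology" in the
  sensitivity scan is operationalised as emptiness/non-emptiness of the
  fall region per (a, b, μ) combination.
* Ties: equality at any stability, validity or plausibility threshold
  resolves to the stable/valid/plausible side.
* Default problem sizes: 1°-step region maps (0.5° in the global
  no-overlap check), 1000 random scenarios in the oracle-equivalence
  suite — each runs in seconds; endpoints are resolution-independent by
  construction.

## Scenario generator

`generate_fixtures` draws reproducible random (person, railing, posture)
tuples: L ∈ [1.4, 2.0] m, m ∈ [45, 110] kg, Y ∈ [0.8, 1.2] m constrained
below 0.8·L, μ ∈ [0.05, 1.0], a, b ∈ [0.3, 0.7], α strictly inside the
validity range, β inside the domain. These ranges span realistic adults
and building railings, and every tuple satisfies the type invariants by
construction. The generator emulates parameter diversity only — it does
not model posture likelihood, inter-individual mass distribution, or
measurement error in case parameters — so passing property tests certify
the mechanics over the parameter space, not the forensic interpretation
of any single case.

## Known limitations

* Purely quasi-static: it can rule a fall mechanically possible or
  impossible at an instant; it says nothing about fall kinematics,
  landing point or injury severity.
* The homogeneous-rod weight split and the single crank are first-order
  idealisations; real mass distribution and multi-joint articulation
  shift the intervals.
* Conclusions are only as good as the input angles; the plausibility
  warnings are coarse guards, not anatomical modelling.
* Friction at the pivot and soft-tissue deformation are neglected; both
  would enlarge the stable region.
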