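# railfall

Quasi-static biomechanical analysis of falls over railings, for forensic
case work: given a person's anthropometry, the railing height, the
shoe-ground friction coefficient and the body posture, decide whether an
*accidental* fall over the railing is mechanically possible at all.

## The model

A person leaning over a railing is idealised as a rigid **cranked rod** in
the vertical plane: a lower segment from the feet (A, on the ground) to
the pivot on the handrail (B), and an upper segment from B to the vertex
(C). Two posture angles describe the configuration — α, the lean of the
lower segment against the vertical railing plane, and β, the flexion
between the two segments. With body length L and railing height Y,

```
L1 = Y / cos α,    L2 = L − L1,
```

and a homogeneous mass distribution splits the body weight
length-proportionally into segment weights G1 and G2, with centres of
gravity at fractions a and b along each segment (defaults a = b = 0.5).

Static equilibrium (force balance, moment balance about A, bearing force
at B perpendicular to the lower segment) yields the vertical ground
reaction and the horizontal friction demand at the feet:

```
GRF = G1·(1 − a·sin²α) + G2·(cos²α − b·(L2/L1)·sin α·sin(α+β))
F   = (a·G1·sin α + G2·sin α + b·G2·(L2/L1)·sin(α+β))·cos α
```

Two criteria decide stability:

* **anti-slip** — Coulomb friction holds the feet: `F ≤ μ·GRF`;
* **anti-tilt** — the restoring moment beats the tipping moment:
  `b·G2·L2·sin(α+β) ≤ (a·G1 + G2)·L1·sin α`.

A fall over the railing is possible exactly where **both** conditions are
violated. Each violated set is a β-interval at fixed α (both criteria are
thresholds on `sin(α+β)`, whose two arcsin branches are related by
`β₂ = π − β₁ − 2α`), so the package reports per-α slip/tilt/fall intervals
and full (α, β) region maps. An independent numerical equilibrium solver
(the 3×3 linear system) certifies the closed forms at every use.

The model is strictly quasi-static: no pushing, jumping, or active
recovery movements, no soft-tissue deformation, no friction at the pivot.

## Worked example

A small person (1.58 m, 65 kg) and a 0.92 m railing. On a smooth or wet
floor (μ = 0.2), at a lean of α = 10°:

```
$ railfall thresholds --length 1.58 --mass 65 --railing 0.92 --mu 0.2 --alpha 10
slip:  (21.5, 130.0) deg
tilt:  (50.0, 110.0) deg
fall:  (50.0, 110.0) deg
union: (21.5, 130.0) deg
```

The feet must slip for any flexion beyond ≈21.5°, and the body tips over
the handrail for flexion between 50° and 110°; both conditions overlap in
β ∈ (50°, 110°), so an accidental fall is mechanically possible in that
posture band. Classifying one posture inside the band:

```
$ railfall classify --length 1.58 --mass 65 --railing 0.92 --mu 0.2 --alpha 10 --beta 80
class: FALL_POSSIBLE
GRF: 608.5 N
friction demand: 165.5 N
grf_negative: false
```

GRF is the vertical ground reaction at the feet; the friction demand
(165.5 N) exceeds the available friction μ·GRF ≈ 121.7 N, and the posture
also lies inside the tilt interval. With ordinary dry-floor friction
(μ = 0.7) the slip condition can never be met, so no fall-possible
posture exists — only tilting remains, which on its own the feet anchor
against:

```
$ railfall --verify classify --length 1.58 --mass 65 --railing 0.92 --mu 0.7 --alpha 10 --beta 80
class: TILT_ONLY
GRF: 608.5 N
friction demand: 165.5 N
grf_negative: false
oracle residuals: force 0.00e+00 N, M_A 5.68e-14 N*m, M_B 5.68e-14 N*m
```

`railfall map`, `railfall sensitivity` and `railfall case-report` produce
region CSV/JSON/plots, (a, b, μ) sensitivity summaries, and a full
per-case report from a YAML config; see `railfall --help`.

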