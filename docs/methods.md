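# Methods

This note records the models, numerical choices and limitations behind each
component, in the order a full analysis runs them.

## Body segment parameters

Segment shapes are watertight triangle meshes. Volume, COM and inertia are
computed by exact signed-tetrahedron (divergence-theorem) integration —
delegated to `trimesh`, with closed-form solids (spheres, boxes, octagonal
prisms) as independent oracles in the test suite. Watertightness is checked
as edge-closure; winding is repaired and orientation flipped when the signed
volume is negative; open meshes are rejected with the offending edges named.
Inertia is reported both about the COM and about the origin (parallel-axis
transfer). Inertia is computed but nothing downstream consumes it.

Composite segments subtract zero-density air cavities: mass =
ρ·(V_solid − ΣV_cavity), COM by signed volume weighting, and the reported
*net density* mass/V_solid is the diagnostic the air spaces lower (a 5.47%
cavity fraction cuts 1060 kg·m⁻³ tissue to ≈1002, i.e. 95%; 8% cuts it to
92%). Mass conservation (composite + cavity = solid) is exact, not
approximate. Containment of cavities within the solid is checked only by
volume; geometric nesting is the modeller's responsibility.

Fleshed-out shapes are built as stacks of octagonal hoops lofted in series:
vertex *i* of each octagon joins vertex *i* of the next (no twist
minimisation — the input hoops are expected to be consistently ordered),
quad strips are split into triangles and the ends fan-capped. Hoop
inflation scales each octagon about its own centroid in its own plane, so
the skeleton-fitted midline is preserved; inflation multipliers default to
1.0 and are configuration inputs, since published values live in earlier
comparative work rather than in any one model description.

Incompletely preserved caudal series are reconstructed by ordinary least
squares of vertebral length and height on vertebral number, predicting the
missing elements (default 30 vertebrae total), with cylinders whose
diameter is the dorsoventral height and axial gaps of 10% of each length
standing in for intervertebral soft tissue. Negative predictions are
clamped to the smallest measured value with a warning.

Whole-body summaries report total mass, mass-weighted COM, per-segment
fractions (summing to 1 within 1e-9), the COM's projection on the
craniocaudal axis relative to the hip midpoint, and that offset as a
percentage of femur length. Two femur lengths are carried in the packaged
configuration (0.080 m reference-pose, 0.078 m moment-arm normaliser)
because both appear in the source measurements; neither is "corrected".

## Joints

Articular surfaces are point clouds; primitives are fitted by least
squares: total least squares for planes (SVD), algebraic-then-geometric
refinement for spheres, a nonlinear cylinder fit tried from all three
covariance axes as seeds (keeping the lowest-residual solution, which makes
the fit robust for short, partially covered articular cylinders), and a
constrained algebraic quadric fit for ellipsoids. Exact synthetic samplings
are recovered to numerical precision; degenerate configurations (collinear
points, non-ellipsoidal quadrics) raise errors naming the degeneracy.

Joint coordinate systems are right-handed with z along the hinge (cylinder)
axis or, for ball-and-socket pairs, oriented by a mediolateral hint so
flexion/extension lies in the sagittal plane; the origin is the socket
sphere centre or a fitted axis point. Primitive axis sign is canonicalised,
so flipping a fitted axis leaves the JCS unchanged. Per-joint sign
conventions are *data*: each joint carries the anatomical meaning of
positive rotation about each axis (e.g. positive z is extension at the hip
but flexion at the elbow), encoded in `data/gracilisuchus_joints.yaml`
exactly as published, rather than hard-coded.

Posing uses the fixed z-y-x Euler order. Each joint contributes the world
delta T_jcs·Rz·Ry·Rx·T_jcs⁻¹, accumulated root-to-tip; the all-zeros pose
reproduces rest transforms bit-exactly. The z-y-x decomposition clamps
|pitch| to 89.999° with a warning near gimbal lock. Angles outside declared
limits are rejected unless explicitly overridden.

ROM scanning sweeps one DOF outward from 0 in ±5° steps until either bone
meshes interpenetrate beyond a tolerance (default 0.1 mm) or articular
point sets separate beyond a disarticulation tolerance (default 150% of
the rest gap). Collision depth is measured as the maximum distance of one
watertight mesh's contained vertices to the other's surface, with
containment by ray casting and point–triangle distances computed directly
(no spatial index); this is an automated proxy for what is, in practice, a
visual judgement, and the scan reports the last collision-free angle, so a
true stop is recovered within one step. The packaged joint-limit table
carries the published figure-caption limits; where the running text and a
caption disagree (elbow 110° vs 0–120°; hip abduction "90° ROM" vs
−10..90°) the caption value is used and the discrepancy listed in the
config rather than resolved.

## Muscles

Paths are ordered attachment points (origin, vias, insertion), each fixed
in a bone frame, joined by straight segments. A wrapping obstacle assigned
to a chord replaces it by a tangent–geodesic–tangent path whenever the
chord cuts the obstacle. Cylinder wrapping follows the obstacle-set method:
tangent points are found in the projection onto the cylinder's
cross-section, the surface geodesic is a helix, and the axial coordinate is
distributed linearly along the unrolled path, which makes the total length
exactly √(L₂² + Δz²) for planar path length L₂ — the true geodesic.
Sphere wrapping takes the single shortest geodesic in the plane through
both endpoints and the centre. The wrap side is explicit per surface
(`active_side`); sides are never flipped automatically — if the chord
penetrates but the active-side tangents invert, the chord is returned and a
warning logged, because silent side flips are a classic error source. Arcs
are limited to half a turn: at the graze limit the tangent points invert
and the path lifts off, which keeps length continuous through engagement
(verified numerically). Points inside an obstacle are errors naming the
muscle and surface.

Moment arms use tendon excursion, MMA = −dL/dθ, by central finite
difference with h = 0.25° (θ in radians). On straight-line hinge cases this
matches the virtual-work moment arm to 1e-6 m and converges at second
order; on a cylinder coaxial with the hinge the moment arm equals the wrap
radius exactly while the wrap is engaged. The tendon-excursion route was
chosen over the geometric cross-product construction because it extends
unchanged to wrapped paths and mirrors how standard musculoskeletal
software exports moment arms. A per-joint sign factor maps the raw
geometric value onto the anatomical convention so extensor moment arms are
reported positive where the convention says so.

Curves are evaluated on the inclusive 5° ROM grid (the same grid as the ROM
scan); the mean dimensionless moment arm is the unweighted grid mean
divided by the normalising bone length (femur for hip DOFs, tibia for the
knee, metatarsal III for the ankle). Area weighting was considered and
rejected as an undocumented refinement: the grid mean is the stated,
reproducible choice. Dimensionless means are invariant under uniform
geometric scaling (tested at ×2). Third-metatarsophalangeal moment arms
are out of scope, as are muscle forces, architecture and secondary tendons.

## Muscle reconstruction (EPB)

Ancestral states are reconstructed under unordered, unweighted
minimum-change parsimony. Rather than the textbook two-pass Fitch (whose
up-pass set rules assume bifurcating trees), the implementation is a
unit-cost dynamic programme: a post-order pass computes per-state subtree
costs, a pre-order rerooting pass adds the cost of the rest of the tree,
and a node's MPR set is every state achieving the global minimum. This is
exact on arbitrary rooted trees including polytomies, and is verified
against exhaustive enumeration over all internal assignments on trees of up
to 8 tips (100 seeded trials). Missing ("?") and inapplicable ("−") cells
both allow any observed state during optimisation; inapplicable is flagged
separately in reports; all-missing characters are skipped and listed.
Ambiguity is reported as state sets and never resolved arbitrarily — only
unambiguous (singleton) reconstructions feed inference levels.

Inference levels are a pure function of two booleans — singleton
reconstruction? osteological correlate present? — giving I, I′, II, II′,
with unknown bracket states propagating to II′. The packaged 37-muscle
pelvic-limb dictionary carries curated origin/insertion descriptions,
levels and correlate flags; `build_muscle_map` renders it (optionally
re-deriving levels from a parsimony run) in bracket style. The packaged
character-matrix fixtures are synthetic stand-ins shaped like a real
~48-taxon × ~107-character matrix; a real matrix in the same CSV/NEXUS
subset drops in unchanged.

## Stance inference

The allometric mass estimator is the published quadruped equation on
combined humeral + femoral minimum shaft circumference in mm,
log₁₀ BM(g) = 2.749·log₁₀(C_h+C_f) − 1.104, returned in kg. This
coefficient set reproduces the published worked value (14 + 13 mm → 0.68
kg) exactly, which is the packaged verification.

The LDA battery fits a two-class linear discriminant (pooled covariance,
via scikit-learn) per test and reports the focal taxon's posterior
probability of quadrupedalism plus a majority tally. The published battery's
22 test definitions are not printed anywhere usable, so tests are explicit
configuration; the shipped default battery — all 15 non-empty predictor
subsets of {body mass, dimensionless COM, forelimb length, hindlimb length}
plus 7 seeded 75% training subsamples — is clearly labelled non-canonical
and exists so synthetic work has a complete, reproducible battery of the
same size. Class priors are exposed (default: estimated from class
frequencies). A test with a singular pooled covariance is marked failed,
never silently dropped. Posteriors are invariant under affine rescaling of
predictors and sit at 0.5 (within Monte-Carlo error) for a focal point
equidistant between identical class distributions.

The circumference regression is OLS of log₁₀ humeral on log₁₀ femoral
circumference with per-class convex hulls and a point-in-hull report for
the focal taxon. The static-bipedalism criterion divides the COM's cranial
offset by femur length: ≥1 fails (the knee could not be positioned cranial
to the COM, so knee extensors lose their antigravity role), [0.6, 1.0) is
flagged marginal ("pushing the limits"), below passes.

## Synthetic data

The generator emulates the study conditions at desk scale: a ~1.5 kg,
0.08 m-femur quadruped with octagonal-prism segments (closed-form volume
2√2·R²·L), air-cavity fractions of 5.47% (head–neck) and 8% (trunk) chosen
to reproduce the published 95%/92% net-density bookkeeping, the published
hindlimb joint-limit table, muscles with exactly known levers (a 20 mm
hinge strap, a 15 mm coaxial wrap, an axis-parallel zero-lever line, a
sphere-deflected abductor), random ≤8-tip trees with exhaustively solved
character matrices, and two 4-predictor Gaussian morphometric classes
separated by 3σ with 40 draws per class. Every fixture carries its own
oracle answer; all randomness flows from one integer seed and equal seeds
give byte-identical outputs.

What the fixtures do **not** emulate: real bone geometry (no trabecular
detail, no taphonomic deformation), realistic muscle architecture, character
correlation structure in real matrices, or phylogenetic non-independence in
the morphometric classes. Passing tests therefore demonstrate correctness
of the computations, not the anatomical fidelity of any particular fossil
reconstruction; the deposited-model workflow (OBJ + `.osim` inputs) runs
through the same code paths when real files are supplied.

## Pipeline, formats, determinism

Stages run in dependency order (BSP → ROM → moment arms → muscle map →
stance), each logging inputs and outputs; a stage failure halts with the
stage named. OBJ reading preserves vertex order and fan-triangulates
polygons; the `.osim` reader handles bodies, custom-joint rotation axes
(which must be expressible in z-y-x order), path points and wrap
cylinders/spheres, and records every unhandled element in a manifest —
nothing is silently dropped. Lengths in `.osim` are metres; all frames must
be right-handed and left-handed frames are rejected, not repaired. Problem
sizes throughout (two-hoop prisms, ≤8-tip trees, 40-per-class datasets,
5° grids) keep the full suite and pipeline runs in seconds while leaving
every tolerance meaningful at the scale of the real animal.

## Known limitations

* Collision-based ROM uses vertex containment depth, which can understate
  penetration for edge–edge contacts on coarse meshes; fixtures use
  geometry where this cannot occur.
* A single obstacle per chord; wraps of more than half a turn lift off by
  design.
* Cylinder wraps treat the cylinder as infinite (half-length is carried but
  not enforced as an end cap).
* The LDA battery is a stated stand-in, not the published 22 definitions;
  conclusions from it apply to the synthetic datasets only.
* Intervertebral joints carry limits but are not analysed downstream.
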