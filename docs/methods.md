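# Model and methods

## The model

`blastomech` simulates deformable cells as closed triangulated membranes of
particles plus one intracellular particle per cell (a stand-in for the
microtubule-organising centre).  Every interaction is a non-linear spring
derived from a Morse potential: the force particle *j* exerts on particle
*i* is

    F_ji = 2 J ρ (e^{2ρ(r − r_eq)} − e^{ρ(r − r_eq)}) û_ij,

with û_ij the unit vector from *i* toward *j*, so a stretched spring attracts
and a compressed one repels, vanishing exactly at the equilibrium length
r_eq.  Springs live on the edges of each cell's membrane triangulation
(internal neighbours) and between every membrane particle and the
intracellular particle (cytoskeleton).  At construction every equilibrium
length equals the built length: a freshly built cell is exactly at rest.

Motion is first-order overdamped,

    Σ F_int + F_χ + Σ F_ext + F_spe = λ v,

integrated by explicit forward Euler.  Membrane particles use the medium
friction λ_med, the intracellular particle uses λ_χ and receives the exact
reaction of the cytoskeleton springs (Newton's third law), so the net
internal force on an isolated cell is identically zero.

**Cell behaviours are equilibrium-length edits.**  Elongation rebuilds the
target geometry of a cell (e.g. cuboidal h=1 → columnar h=2) and resets all
spring equilibrium lengths to target distances; apical constriction shrinks
the target apical ring radius by *d* ∈ [0, R] (cumulative and reversible:
constricting by *d* then by −*d* restores the targets exactly).  Positions
are never edited; relaxation does the motion.  Lumenogenesis is the one
"specific" force: a Morse-form radial source at the rosette centre with
equilibrium at distance R_lum pushes apical particles outward onto a sphere
after their mutual adhesion is broken.

**Adhesion is force transmission, not an energy term.**  Cells on an integer
lattice may interact only if they are Moore neighbours (≤26).  Within an
approved pair, membrane particles within a cutoff link; each linked particle
receives a copy of its partner's internal + cytoskeleton force sum, so
apposed membranes are submitted to (nearly) equal forces.  The link rule is
mutual-nearest per tissue-relation class with a per-particle cap
(`max_links`, default 2): one bond along a particle's own epithelium plus
one across a tissue interface.  Same-tissue bonds are *junctional* — only
apical–apical particle pairs bond, as in an adherens junction belt.  This
choice matters mechanically: bonds spread over whole lateral faces freeze
the relative geometry of neighbouring cells (linked pairs comove), which
blocks the hinge motion a sheet needs in order to fold by apical
constriction; junctional bonds keep a sheet cohesive while letting basal
sides splay.  They are also exactly the bond class that lumen opening
severs.

## Parameters

All quantities are dimensionless model units; there is no unit conversion.

| parameter | default | meaning |
|---|---|---|
| J_TE, J_EPI | 2.5 | Morse interaction strength per tissue |
| ρ | 1.0 | Morse scale (1/length) |
| λ_med, λ_χ | 2.0 | friction, membrane / intracellular |
| R, h | 0.5, 2.0 | apical radius and height of a columnar cell (aspect 2) |
| d | 0.5 | apical shrinkage of fully constricting cells (= R) |
| R_lum | 0.25 | lumen target radius |
| dt | 0.005 | Euler step |
| link_cutoff | 0.45 | adhesion formation distance (0.9 R) |
| max_links | 2 | adhesion valence cap |
| link_refresh | 10 | steps between link recomputations |
| force_cap_factor | 100 | per-spring force cap = 100·J·ρ |

Numerical choices.  dt = 0.005 keeps forward Euler stable when adhesion
stacks transmitted forces on top of constriction-stiffened springs (the
Morse stiffness grows like e^{2ρΔ}); event times (t = 3000, 4000, 6000,
9000) are step counts.  The force cap guards the exponential blow-up of
transiently near-coincident particles; in healthy runs it is never reached.
The adhesion cutoff 0.9 R is the widest of the range (≈0.16 R, ≈1.2 R)
within which abutting lattice cells adhere across shared faces while
diagonally offset cells do not; the width is needed because the particle
spacings of two different tissue surfaces do not register.  Springs with
r = 0 exert no force (direction undefined); exponents are clipped at ±40
before exponentiation.

## Mesh layout

The published cell has 34 membrane particles; its triangulation is not.  We
use 4 rings of 8 particles (circular rings, 22.5° offset so flats face
lattice neighbours) plus apical and basal pole particles, triangulated with
pole fans and ring-to-ring strips — a closed genus-0 surface, which on 34
vertices necessarily has 3V−6 = 96 edges.  The refined 42-vertex cell uses
5 rings of 8 on a rounded square (superellipse, p = 4) plus poles.  Face
labels: apical = apical ring + pole, basal likewise, lateral = middle
rings.

## Embryo construction

**Epiblast rosette** (default 18 cells): two rings of 8 cells at polar tilt
±40° from the rosette axis plus one polar cap cell per side, polarity
radial with apical faces inward, apical poles anchored 0.15 from the centre
(inside R_lum, so lumen repulsion inflates rather than retracts), the
arrangement stretched ×1.3 along z ("oval").  Each cell is built directly
in its apically constricted rest shape (apical ring radius 0.1 R) so the
wedges pack without interpenetrating — building round cells and
constricting them dynamically in place produces heavily overlapping
membranes whose conflicting adhesion bonds never relax.  Without the polar
caps the surface dips at the poles and the trophectoderm would rest in a
dimple.  The assembled rosette is relaxed under adhesion (1000 steps).

**Trophectoderm sheet**: 5×5 cuboidal cells (h = 1, R = 0.5) on a pitch-2R
lattice, apical side down (the folding direction), each cell lowered until
its closest particle is 0.1 from the epiblast surface.  Cells keep vertical
polarity: a sheet wrapped radially around the epiblast turns apical
constriction into a drawstring that extrudes the epiblast upward instead of
folding onto it.

**Schedule** (steps): t=0 TE elongation targets (cuboidal→columnar);
t=3000 step-profile apical constriction (interior cells d = R, boundary
d = 0); t=4000 lumen opening; t=6000 TE–EPI detachment; end t=9000.  The
pushing-distance experiment omits the detachment (end t=6000) and runs with
and without lumenogenesis; the J_TE sweep additionally disables
lumenogenesis and compresses the schedule ×0.5 (11 grid points spanning
0.3–4.9), which the energy traces show is long enough for each phase to
approach its plateau.

## Measurements

* **Elastic energy** E = Σ_springs (r_eq − r)²; zero exactly at rest.
* **Interface scalars**: the epiblast surface covered by the trophectoderm
  is recorded at t=0 (outer-shell basal particles under the TE footprint,
  plus any particle holding a TE link) and kept fixed so the interface
  remains measurable after detachment.  Particles within a slab of
  half-width R about the mid-sagittal plane are projected onto it, ordered
  by angle about a pivot below the interface and averaged into ≤13 angular
  bins.  θ is the angle at the polyline's central point subtended by its
  endpoints (flat ⇒ 180°, semicircle ⇒ 90°); L is the arc length, D the
  endpoint distance, Ir = L/D (flat ⇒ 1).
* **Pushing distances**: displacement toward the maternal side (−z) of the
  lowest EPI particle, the EPI centre of mass and the population centre of
  mass, relative to t=0.
* **Lumen volume**: convex-hull volume of the repulsion target particles
  (the cavity is star-shaped about the source in all observed regimes);
  zero before activation.
* **Fitness** M(J_TE) = ⅓[((θ−θ_max)/(θ_max−θ_min))² +
  ((Ir−Ir_min)/(Ir_max−Ir_min))² + ((H−H_max)/(H_max−H_min))²] with optima
  taken over the sweep's own data; M ∈ [0,1].  A metric whose range is zero
  across the sweep (every run ties at the optimum) contributes 0, the
  continuous limit of the expression.

## Stiffness calibration

Equal and opposite axial loads are applied to the apical and basal faces of
one isolated cell (total face force split equally over the 9 face
particles, tensile by default), each load relaxed to equilibrium (|ΔE| per
step < 10⁻⁸ for 100 consecutive steps, budget 10⁵ steps), stress σ = F/S
(S = undeformed face area) fitted against strain ε = ΔL/L₀ (pole-to-pole
height).  The force schedule is 10 magnitudes linearly spaced up to the
load producing ≈20% strain, found from a trial load proportional to J.
Because every spring force is linear in J, scaling J and the schedule by c
leaves all equilibrium shapes unchanged: Y(cJ) = c·Y(J) exactly, and Y(J)
is strictly increasing.  A relaxation that does not converge, or a strain
sequence that is non-monotone or jumps by more than 10× its median
increment, flags the parameter set as mechanically compromised — this is
how the friction-ratio sweep detects the critical λ_χ/λ_med below which
the intracellular dynamics destabilise (detected at ≈0.16 with the default
grid).

## What the generator emulates, and what it does not

The synthetic embryo reproduces the qualitative anatomy — an oval rosette
epiblast with convergent apical tips under a cuboidal trophectoderm sheet —
at desk scale (18 + 25 cells, sizes the original work does not publish).
Real tissues bring features the model omits by design: cell division,
stochastic motility, volume conservation, hydraulic lumen pressure and
biochemical signalling.  Passing tissue-level tests therefore shows that
the mechanical transduction chain (equilibrium-length edits → single-cell
shape change → transmitted forces → tissue remodelling) operates as
described, not that the trajectories match live-embryo kinematics.

Known limitations, measured on the default conditions and accepted rather
than tuned away:

* The interface ratio L/D starts near 1.1 (the draped sheet already covers
  a shallow dome) and changes by only ~0.02 over a run, so its "decreases
  toward 1" trend is within measurement noise.
* The lowest epiblast point is mechanically remote from the interface at
  this population size; its pushing distance moves late (lumen-driven) or
  not at all, while the EPI centre-of-mass variant shows the downward
  trend robustly.
* In the J_TE sweep the final metrics vary only weakly with J_TE (the
  desk-scale fold barely reshapes the epiblast without lumenogenesis, and
  the lowest-point pushing distance is identically 0 across the grid), so
  the fitness landscape is flat and its minimum is not localised in the
  stiff band.
* The absolute Young-modulus scale is a property of the mesh: any closed
  triangulation on 34 vertices has exactly 96 edges of rest stiffness
  2Jρ², which pins the axial structural stiffness and hence Y ≈ 73 at
  J = 2.5 under this protocol; the relative statements (linearity in J,
  refinement softening, friction independence, critical ratio ≈ 0.16) are
  the mesh-independent content.
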