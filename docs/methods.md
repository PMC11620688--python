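# Methods

`icrsim` simulates the implantation of an intracorneal ring (ICR) into an
average human cornea with an axisymmetric, total-Lagrangian finite-element
model, extracts the optical and mechanical outcome of the surgery, and runs a
design sweep whose statistics attribute the outcome variance to the basic
ring parameters.  This note records the model, its numerical treatment, and
the design decisions taken where more than one reasonable choice existed.

## Corneal model

**Geometry.** The cornea is the solid of revolution between two spheres on a
common optical axis: anterior radius 7.80 mm, posterior radius 6.78 mm,
apical separation equal to the central thickness 0.52 mm.  The corneoscleral
rim sits where the thickness measured along the anterior normal reaches
0.68 mm (rim radius ≈ 5.58 mm for the defaults).  Coordinates are (r, z) in
mm with z along the optical axis, positive anterior, anterior apex at z = 0.

**Material.** Nearly-incompressible Yeoh hyperelasticity,

    W = C1 (Ī₁ − 3) + C2 (Ī₁ − 3)² + C3 (Ī₁ − 3)³ + (κ/2)(J − 1)²,

with C1 = 35.5 kPa, C2 = 3.2 kPa, C3 = 1.9 kPa, Ī₁ the first invariant of
the isochoric right Cauchy–Green tensor and J = det F.  Incompressibility is
imposed by the volumetric penalty κ = 1000·2C1 (Poisson ratio ≈ 0.4995); at
J = 1 the energy coincides with the incompressible law.  The small-strain
shear modulus is μ = 2C1 = 71 kPa.  The polymeric implant is ~5·10⁴ times
stiffer than the stroma (E = 3600 MPa, ν = 0.4), so it is modelled as a
rigid obstacle rather than an elastic body; its one admissible rigid-body
freedom in axisymmetry — axial translation — is resolved by a force-balance
iteration (below).

**Loads and boundary conditions.** The physiological intraocular pressure
(IOP), 15 mmHg = 1.99983 kPa (1 mmHg = 133.322 Pa, computed not hard-coded),
acts as a follower pressure on the posterior surface throughout.  On the
optical axis u_r = 0.  The corneoscleral rim slides on a plane inclined 40°
to the r-axis, tilted anteriorly outward like the scleral continuation;
the constraint is imposed exactly by a local rotation of the rim dofs.

## Discretization and solver

4-node bilinear quadrilaterals with selective reduced integration: the
isochoric energy at the 2×2 Gauss points, the volumetric penalty at the
element centroid (guards against locking at ν → ½).  Stress and consistent
tangent are evaluated analytically in the reduced 5-component axisymmetric
space (rR, rZ, zR, zZ, hoop); unit tests verify the closed form against
finite differences of the energy and against the general 3×3 implementation.
All integrals carry the axisymmetric weight 2πR.

The default mesh is a structured tensor grid in (polar angle, depth
fraction): columns graded radially so the annulus around the implantation
diameter is refined, and two ultra-thin rows straddling the 75 %-depth
surface so the 15 µm slit is spanned by two element layers.  The production
target is ≈ 2900 elements; the campaign and test runs use ≈ 1200 elements
(a deliberate scale-down; the prestress, inflation and outcome machinery are
identical, and the acceptance prestress check runs at full resolution).
Meshing is deterministic: identical configuration ⇒ bit-identical node
tables.

Newton–Raphson with adaptive load incrementation (cut on failure, grow on
fast convergence), sparse direct linear solves, follower-pressure load
stiffness included, and a trust-region cap (0.15 mm) on the per-iteration
displacement update: the thin tunnel lamellae otherwise overshoot past their
geometric stiffening range.  Convergence demands a relative residual of
1e-8.  Two pragmatic relaxations apply only to contact states:

* chatter floor — penalty contact against faceted rigid polylines flickers
  its active set at a small residual amplitude; an increment that stalls in
  such a limit cycle below 2·10⁻⁴ of the force scale counts as converged;
* automatic stabilization — an increment that fails outright is retried
  with a small artificial spring to its starting state (50 mN/mm,
  escalated ×10 as needed), then relaxed back to a true equilibrium in a
  cascade; the increment only counts if the spring-free solve converges.
  The final reported state must satisfy a strict 1 % unbalanced-force gate
  (typically it is at the 1e-8 tolerance; the gate exists because the seated
  contact configuration can host a marginal flutter mode).

Contact is frictionless node-to-segment penalty contact against rigid
polylines, with the force regularized over a small gap width so its
derivative is continuous at activation.  The penalty stiffness is
auto-scaled, k = 1000 · 2C1 · h · 2πr with h the mean tunnel-face edge
length, and doubled until the maximal penetration is below 0.1 µm.

## Stress-free geometry

The imaged cornea is already under IOP, so the reference configuration is
recovered by the classic fixed-point iteration: inflate the trial geometry,
subtract the nodal discrepancy from the trial coordinates, repeat until the
inflated shape matches the target to < 10⁻² µm at every node (the stricter
all-node reading; surface-only would pass earlier).  The iteration contracts
by roughly ×0.5 per step and converges in ~13 iterations for the default
cornea; divergence triggers 0.5 under-relaxation.  Tunnel carving happens
after the recovery, on the tensioned cornea.

## Implantation protocol

The slit — 15 × 1200 µm at 75 % depth, centred on the implantation
diameter — is removed from the carved topology (element removal, node table
unchanged).  The protocol then runs:

0. inflate the carved stress-free mesh to IOP (the tensioned slit gapes
   open by tens of µm);
1. *crumple*: suction (10 kPa, ramped with early exit) on the slit-tip
   faces until the tunnel lies inside the rigid tool;
2. *tunnel inflation*: 60 kPa (≈ 30 × IOP) on the tunnel faces against the
   rigid tool;
3. *release and seating*: contact switches to the ring and the tunnel
   pressure is released; the walls move back until they rest on the
   implant.

Numerical realization of the tool and of stage 2–3, where the source
protocol leaves latitude:

* The tool is the outward-offset ring cross-section (offset 15 µm) extended
  by thin lateral "lips" spanning the full slit width (half-height 0.1 mm,
  accommodating the natural gape).  The 1200 µm slit is of the order of half
  the ring perimeter, so the tunnel faces can envelop the implant without
  large membrane stretch — the lips keep the tips from ballooning while the
  central cavity opens around the ring outline.
* Pressure-controlled crack opening passes peeling snap-backs that Newton
  continuation cannot cross without arc-length methods; the inflation ramp
  therefore accepts the last converged level when it stalls (recorded per
  run).  The end state of the protocol is an equilibrium of carved cornea +
  IOP + seated ring and does not depend on how much of the ramp was
  realized; a small residual tunnel pressure during seating guides the
  correct wrap topology.
* Seating is an interference-fit continuation: the ring contact surface
  grows from a homothety of the cross-section (starting at the largest
  scale that fits the opened cavity, found by bisection) to full size with
  a cosine ease-out while the pressure ramps down.  A failed configuration
  is retried once on a slower schedule.
* After release the tool may still support tissue (tall implants push the
  anterior lamella against its ceiling); its stiffness is faded to zero
  continuously instead of being switched off.
* Finally the state is re-equilibrated with the ring alone and the implant
  floats axially (secant iteration on its z-position) toward zero net axial
  contact force — a grounded rigid ring would otherwise inject spurious
  reaction forces; net radial line loads are carried by the ring's hoop
  stiffness and require no dof.  The balance is driven to ~0.1 % of the
  contact load at the base penalty stiffness; after the stiffness
  escalation the net force is quantized at the per-node contact force
  (tens of mN for the ~20 contact nodes of the campaign meshes), so the
  residual after escalation is a discretization floor, reported per run as
  a diagnostic.  The penalty stiffness is escalated here until the 0.1 µm
  penetration tolerance holds.  A configuration whose final overlap exceeds
  5× that tolerance, or whose peak contact pressure reaches the MPa scale
  (an order of magnitude above any interference-fit stress, marking a
  pinched wrong-topology contact), is flagged as mis-seated and excluded
  listwise, as is any stage that fails to converge.

## Outcome metrics

* K_mean = (n − 1)/R, n = 1.3375, R in meters the radius of the
  least-squares circle fitted to the anterior surface nodes within the 3 mm
  optical zone, centre constrained to the symmetry axis (an unconstrained
  fit is ill-posed with half-plane data); zone membership by deformed radial
  coordinate.  For the default cornea K_pre = 43.27 D.
* ΔAL: axial displacement of the anterior apex node (µm).
* ΔCCT: change of the anterior–posterior axis-node distance (µm).
* CPRESS: maximal nodal contact pressure, |f|/(2πr·ℓ) with ℓ the tributary
  length on the deformed tunnel surface; contact area as the axisymmetric
  area of edges whose both nodes carry contact force.
* The untreated reference is the intact inflated cornea (identical to the
  imaged shape by the prestress criterion).

## Campaign and statistics

The design registry holds 20 families: 4 aspect-ratio categories (nominal
horizontal/vertical extent ratios 2.0, 1.5, 1.0, 0.5, classified with bin
edges 1.75/1.25/0.75) × 5 cross-sectional primitives (rounded rectangle,
ellipse, trapezoid, triangle, diamond; all corners filleted as on
manufactured implants).  Every family's largest size has the same
cross-sectional area, 0.09 mm² (a Keraring-like wedge of 0.6 × 0.3 mm);
smaller sizes follow the isotropic factors 0.935/0.869/0.793/0.715, except
the Keraring-like family (horizontal trapezoid) whose horizontal dimension
stays fixed and whose vertical dimension scales by the squared factors so
the area series matches.  The full campaign is 20 × 5 sizes × 3 diameters
(5.0/5.5/6.0 mm) = 300 configurations at 75 % depth — a many-hour batch run
driven by the CLI.  The shipped tests and the acceptance script use a
reduced sweep — all families at the largest size, the diamond primitive of
each category at the smallest size (the diamond seats most robustly, making
it the natural carrier of the per-category size dimension), and the
Keraring-like trapezoid at sizes 3 and 5, at one diameter — preserving the
category and size structure of the full design.

The statistical battery: Spearman rank correlations (average-rank
ties, two-sided t-approximated p) between {H, V} and the outcomes; one-way
ANOVA with Tukey HSD pairwise comparisons across categories/diameters;
backward-elimination OLS of each outcome on {H, V, D} with VIF screening at
10 and elimination at p > 0.05; and a variance-contribution decomposition:
adjusted-R² gains averaged over all predictor orderings (LMG-style,
order-invariant; negative increments clipped), with the unexplained share
1 − R²_adj attributed to the detailed implant design, all shares
renormalized to 1.

## What the model does and does not represent

The model is an average, rotationally symmetric cornea with an isotropic
hyperelastic stroma: no collagen anisotropy, no depth-dependent stiffness,
no viscoelasticity, no epithelium/Bowman/Descemet layering, continuous 360°
rings only (no ring segments or segment-angle effects), no incision or
suction-ring mechanics, and a spherical rather than keratoconic starting
shape.  Outcomes are therefore *induced changes* on a standardized healthy
geometry, not patient predictions.  Statistical conclusions from the reduced
sweep show that the category/size structure of the response survives the
scale-down; they do not establish the printed correlation values at the full
300-configuration scale, and configurations excluded for nonconvergence
(predominantly tall vertical designs, which push the posterior lamella near
its stretch limit at this resolution) thin the vertical extreme of the
design space.
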