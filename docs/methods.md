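# Methods

This note records the models, numerical choices and design decisions behind
`cardioem`, and what the synthetic fixtures do and do not demonstrate.
Units are mm / ms / kPa throughout (so 0.6 m/s is stored as 0.6 mm/ms and
forces are kPa·mm²).

## Mesh model and formats

A mesh is linear tetrahedra with integer region tags, per-element
fibre/sheet unit vectors and named per-node/per-element scalar fields.
Elements are canonically oriented (positive signed volume); inverted
elements encountered on read are repaired by swapping two indices, with a
warning, rather than rejected — external meshes are often inconsistently
wound and the repair is loss-free.

The CARP text dialect is: `.pts` = count line then `x y z`; `.elem` = count
line then `Tt i j k l tag` with 0-based indices; `.lon` = a `1`/`2` header
then 3 or 6 reals per element (fibre, or fibre then sheet — the reader
accepts both). Named node fields are sidecar `<prefix>.<name>.dat` files
and element fields `.edat`. The VTK path writes legacy ASCII unstructured
grids and reads ASCII or big-endian binary. Non-ventricular elements carry
the conventional default vectors `[1,0,0]` / `[0,1,0]`, and
ventricular-coordinate fields use the −100 sentinel off-ventricle, matching
the conventions of the published four-chamber cohort; the 24-region label
schema (4 chambers, 2 vessel walls, 7 rings, 4 valve planes, 7 vein planes)
is built in, and 22-label variants (meshes with three pulmonary veins)
validate against the same schema.

**Scaled Jacobian.** At each vertex the determinant of the three incident
edge vectors is normalised by the product of their lengths; the element
value is the vertex minimum scaled by √2 so a regular tetrahedron scores
exactly 1 and a degenerate one 0. This is the standard Verdict-style
normalisation; other normalisations exist, so cross-database comparisons of
absolute quality numbers should be made with the definition in hand.

**Uniform refinement** is red (1→8) subdivision via edge midpoints with the
interior octahedron split along its shortest diagonal. Any diagonal choice
preserves volume exactly; the shortest diagonal preserves element quality
and keeps the mean edge length at half the parent value to within about 1%.
Tags and frames are inherited, node fields interpolated linearly.

**Surface extraction.** The ventricular base is the set of surface nodes
shared between ventricular myocardium and the mitral/tricuspid valve-plane
labels. Removing base nodes splits the remaining ventricular boundary into
connected face components; endocardium and epicardium are told apart by an
area-weighted orientation test of the outward normals against the
myocardial centroid (endocardial normals point back toward it, into a
cavity). In biventricular geometries the RV cavity lining is further split
into the free wall (RV-owned faces) and the septal sheet (LV-owned faces),
which drives the transmural boundary conditions below.

## Synthetic anatomies

The generators are deterministic, structured-parametric (no Delaunay step):
mesh quality is bounded by construction and the mesh is a pure function of
its spec.

* **Slab** — box on a regular grid, six tetrahedra per cell (Kuhn split,
  conforming across cells), uniform fibres; optionally one boundary face
  tagged as a one-element-deep fast layer. This is the conduction-velocity
  calibration fixture: plane waves along the axes propagate along
  axis-aligned edges, so CV recovery is exact up to solver tolerance.
* **Left ventricle** — truncated thick-walled half-ellipsoid on a
  prolate-style grid (pole collapsed at the apex), closed by a valve-plane
  cap one element thick (2 mm) spanning the whole truncation disc, so the
  cap/myocardium contact surface is the anatomical base and the cavity is
  watertight. The default geometry is a dilated, heart-failure-scale
  ventricle: endocardial semi-axes 30/30/75 mm, 9 mm wall, truncation at
  0.25·c, cavity ≈ 190 mL at end-diastole (the published cohort's LV
  end-diastolic volumes average ≈ 270 mL with large spread; the default
  sits inside that population's range while keeping desk-scale meshes).
  `min_transmural_layers` (default 2) keeps at least that many wall layers
  when the in-plane resolution is coarse, for bending fidelity in
  mechanics runs.
* **Biventricular fixture** — an RV free-wall shell (default 3.5 mm, the
  conventional blood-pool dilation thickness) wrapped around a sector of
  the LV epicardium. The cavity gap closes strictly inside the sector so
  the wall attaches to the LV over a solid welded band; this keeps the RV
  cavity lining (free wall + septal surface) a separate closed boundary
  component, as extraction requires. A tricuspid cap closes the crescent
  opening. The septum is LV-tagged; shared seam nodes take the LV value of
  the intraventricular coordinate.

What the fixtures do **not** emulate: atria, outflow tracts and vessels,
patient-specific shape variability, trabeculation, wall-thickness
heterogeneity, and image-segmentation noise. Passing tests on them
demonstrates correctness of the numerics and of the label/surface logic,
not anatomical realism.

## Laplace fields, fibres, coordinates

Harmonic fields use linear (P1) finite elements; Dirichlet rows are
eliminated and the reduced SPD system solved directly. On good-quality
fixtures the discrete maximum principle holds (values stay inside the
Dirichlet range).

The wall frame per element is: transmural axis = normalised gradient of the
transmural field ρ (0 on the LV endocardium and RV free-wall endocardium,
1 on the epicardium and the RV-facing septal sheet); longitudinal axis =
apicobasal gradient orthogonalised against it; circumferential axis = their
cross product. The fibre is the circumferential axis rotated in the tangent
plane by the helix angle α(ρ̃), the sheet is the transmural axis rotated
about the fibre by β(ρ̃); both interpolate linearly from the endocardial to
the epicardial value (+80°→−60°, −65°→+25°). The interpolation law is a
design choice — the surface values are prescribed, the law across the wall
is not — and linear is the simplest monotone option.

**Element transmural anchoring.** Fibres are stored per element, and an
element's centroid never lies exactly on a surface: naively sampling ρ at
centroids biases the first-layer helix angle by (h/2)/T·140° — about 9° for
a 9 mm wall at 1.5 mm resolution — so the *prescribed surface angles would
never be attained at any practical resolution*. The element-sampled
coordinate is therefore re-anchored: ρ̃ = (ρ̄ − lo)/(hi − lo) clipped to
[0,1], with lo/hi the mean element ρ̄ of the endocardium- and
epicardium-face-adjacent layers. Surface-adjacent element layers then carry
the surface angles exactly on average, and interior elements interpolate
smoothly. Elements with a degenerate gradient (e.g. inside the apex
Dirichlet patch, where the apicobasal field is constant) fall back to the
average frame of their node neighbours, with a warning.

**Ventricular coordinates.** Apicobasal z solves Laplace with 1 on the base
and 0 on a small patch (radius ≈ 1.2 mean edge lengths) around the apex —
the epicardial point farthest from the base centroid, or the generator's
pole. Transmural ρ is as above. The rotational coordinate is atan2 of two
auxiliary harmonic fields anchored on four narrow meridian bands (±20°)
located by the geometric angle about the apex–base axis: the septal band
carries cosine value +1, the free-wall band −1 (the ±π branch cut), the
orthogonal bands the sine ±1. For a lone LV the septal direction defaults
to +x; with an RV it points from the LV cavity centroid toward the RV's.
The intraventricular coordinate is −1/+1 from element tags (LV wins shared
septal nodes), and all four fields are −100 off-ventricle. Interior values
of these coordinates are construction-dependent; only the documented
anchors and ranges are contractual.

**Metrics.** Cavity volumes are divergence-theorem integrals of the closed
boundary component containing a chamber's endocardial faces (endocardium
plus valve-cap underside); orientation flips only flip the sign and are
corrected, and a cavity that connects to the exterior raises. The
valve-plane area sums one face sheet (the cavity-facing side) of the label.
The LV long axis runs from the most apical epicardial point to the
area-weighted mitral-sheet centroid; the RV long axis projects that apical
point onto the LV–RV junction ∩ RV epicardium and measures to the
tricuspid centroid. The LV diameter picks, among endocardial nodes with
apicobasal coordinate in [0.78, 0.82] (configurable), the node with
rotational coordinate closest to ±π and the node closest to 0 and returns
their distance.

## Eikonal activation

The per-element squared-velocity metric is M = v_l² ffᵀ + v_t²(I − ffᵀ);
the fast endocardial layer — every active element with at least one node on
an endocardial surface — doubles both speeds (whether the published
simulations doubled one or both components is not stated; both is the
default and the factor is configurable). The solver is a fast-iterative
active-list method: each update minimises arrival over the incident
tetrahedra with an exact local solver (vertex candidates, closed-form edge
minimisation, Newton for the face interior with simplex check), sweeping in
ascending node index so results are bit-reproducible; convergence tolerance
1e−6 ms. Passive (non-ventricular) elements are excluded; their exclusive
nodes stay at +inf and unreached active nodes are reported with a warning.
Stimulus nodes are clamped at onset; the 2 ms stimulus duration does not
affect a first-arrival map and is retained for the protocol record and the
potential reconstruction.

The straight-segment travel time under metric M is √(dᵀM⁻¹d) (the
point-source solution of the anisotropic eikonal equation), so edge-graph
shortest paths with that cost are admissible rays and bound the solver from
above — this is the independent Dijkstra oracle used in the tests. Note
that the *plane-wave* speed √(êᵀMê) along a direction is not the ray
travel-time speed; using it would understate edge costs.

The reaction part reconstructs the transmembrane potential by shifting a
template waveform to each node's arrival time: a smooth sub-millisecond
upstroke from −85 mV to +30 mV and a plateau/repolarisation envelope
(APD ≈ 300 ms). Downstream mechanics consumes only the −60 mV crossing,
which is a fixed offset from arrival for a given template (computed by
bisection); a hook accepts externally computed waveforms. A full ionic ODE
system is intentionally out of scope.

## Mechanics

Total-Lagrangian quasi-statics on linear tetrahedra with single-point
quadrature (exact for constant strain). Per element: F, C = FᵀF,
E = (C − I)/2 rotated into the fibre frame for the Guccione law; the
volumetric penalty κ/2 ln²J acts on all materials; the active stress
Ta f₀⊗f₀ is added on the reference fibre dyad only (no length dependence,
no transverse component), with Ta interpreted as a PK2 magnitude — a
convention that can shift ejection fractions by a few percent relative to
Cauchy-based implementations. Element activation time is the mean of the
finite nodal arrivals.

The non-ventricular (neo-Hookean) law uses the isochoric invariant,
Ψ = c(Ī₁ − 3) + κ/2 ln²J with Ī₁ = J^(−2/3) tr C. The variant with the
full first invariant is not stress-free at the reference configuration
(S(I) = 2cI) — with 1000 kPa valve planes it visibly deforms an unloaded
mesh — so the isochoric form, standard in cardiac solvers, is used.

Residual and consistent tangent are assembled analytically (material +
geometric parts, plus spring/pericardial blocks) and verified against
central finite differences in the test suite. Newton iterations solve with
a sparse LU (minimum-degree ordering), use backtracking that keeps J > 0
and the residual decreasing, and converge on a 1e−6 relative residual
(cap 20 iterations). The contraction driver marches 5 ms steps over a
700 ms horizon by default (covering t_emd + t_dur; the schedule is a
package choice — the source protocol prescribes none), halving the step on
Newton failure down to a minimum before aborting with diagnostics. The
desk-scale test runs use 10 ms steps to 500 ms, which covers the tension
rise and the volume minimum of the default twitch on a ~14k-element
ventricle.

Boundary conditions: omni-directional springs (stiffness in kPa/mm, scaled
by lumped nodal areas so the restraint is a traction per displacement) on
the vein rings in four-chamber settings, or on the base ring for the lone
synthetic LV; a pericardial penalty on epicardial displacement normal to
the reference surface, scaled by a per-node map in [0,1]. The image-derived
penalty map of the source data is accepted as an input field; the default
is an analytic apex-to-base profile (1 at the apex, 0 at the base) with
1 kPa/mm stiffness — a package default, since no published value exists.

**Known limitation — incompressibility at desk scale.** The pure-penalty
displacement formulation with κ = 1 MPa admits volume changes of order
p/κ ≈ 3–5% under the ~40 kPa hydrostatic part of the 125 kPa active
stress — that compliance is intrinsic to the penalty method, not a
discretisation error — and single-point-quadrature P1 elements additionally
checkerboard the element-level pressure, widening the per-element |J−1|
distribution further. The contraction driver records the fraction of
contracting elements within |J−1| ≤ 0.05 at every step; at desk scale this
fraction plateaus well below one even though patch-averaged volume change
is small. Locking-free stabilised formulations would be needed to tighten
element-level incompressibility; they are deliberately not reproduced here.
κ is configurable for users who want stiffer penalties.

## Pipeline and reporting

The pipeline executes synth/ingest → surfaces → fibres → coordinates →
activation → contraction → metrics under a strict nested configuration
(unknown keys rejected; every leaf parameter logged with default/override
provenance). Reports are one row per mesh (counts, scaled-Jacobian and
edge statistics, latest activation times, EF/SV, anatomical metrics) with
fixed four-decimal formatting; cohort summaries use the sample (n−1)
standard deviation, matching the mean ± sd style of published tables.
Identical configurations produce byte-identical reports.

## Problem sizes used in the checks

Conduction-velocity recovery: 60×20×20 mm slab at 1 mm (144k tets).
Fibre-angle recovery: default LV at 1.5 mm (≈ 410k tets). Oracle
comparisons: meshes ≤ 5000 tets. Free contraction: default LV at 6 mm
in-plane with 3 wall layers (≈ 14k tets). These sizes are package choices
balancing fidelity against a laptop-friendly suite.
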