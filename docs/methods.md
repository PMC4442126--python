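# Methods

## Gibbs–Thomson critical radius

The equilibrium radius of an ice embryo at supercooling ΔT = T₀ − T_r is
computed as R = A_g·M_w·σ·T₀ / (L·ρ_i·ΔT), with A_g = 2 for spherical and
1 for cylindrical symmetry; the cylindrical radius is therefore exactly
half the spherical one at equal parameters, and R·ΔT is constant for a
given parameter set. Two presets are built in:

| parameter | real water | TIP4P | units |
| --- | --- | --- | --- |
| M_w | 0.018 | 0.018 | kg/mol |
| σ (ice–water) | 29.1 × 10⁻³ | 23 × 10⁻³ | J/m² |
| L (fusion) | 6.02 × 10³ | 4.4 × 10³ | J/mol |
| ρ_i (ice) | 917 | 944 | kg/m³ |
| T₀ (melting) | 273.15 | 230.5 | K |

Assumptions: σ and L are temperature-independent over the few-kelvin
range of interest, and no Tolman-type curvature correction of σ is
applied. Spherical-embryo bookkeeping (volume, molecule count) uses the
ice density for the embryo mass. User-facing output rounds R to three
significant figures; full precision is kept internally. Custom parameter
sets can be supplied through a YAML `water_models` section. Non-positive
supercooling is a domain error (no finite equilibrium radius exists), as
is ΔT ≥ T₀.

## Ice-Iₕ lattice and proton disorder

Oxygens are placed on the wurtzite-type ice-Iₕ lattice using an
orthorhombic 8-molecule cell of dimensions a × √3·a × c, with the
a-axis along x and the c-axis along z and the ideal internal parameter
3/8 (so the along-c bond is 3c/8 and the other three bonds are
√((a/√3)² + (c/8)²)). Lattice constants default to the rounded prism
repeats a = 4.5 Å, c = 7.4 Å; the crystallographic 4.497/7.324 Å pair is
available as a preset. A c/a ratio outside [1.4, 1.9] triggers a
strained-lattice warning (ideal ≈ 1.63).

Proton placement must satisfy the Bernal–Fowler rules: two covalent
hydrogens per oxygen, one proton per hydrogen bond. These rules are
equivalent to orienting the 4-regular O–O bond graph so that every
vertex has out-degree 2. Instead of repair-style Monte Carlo from a
random start, the orientation is constructed exactly by walking an
Eulerian circuit of the (periodic, possibly multi-edged) bond graph with
seeded random edge choices — every vertex of a closed walk has equal
in- and out-degree, so the rules hold by construction, with zero
defects. Disorder then comes from the seeded circuit plus loop-reversal
moves (reversing any directed cycle preserves both rules) accepted when
they reduce the magnitude of the net cell dipole, until the net dipole
per molecule falls below 0.1 of a single molecular dipole (default;
configurable). The move budget is 500 moves per molecule; failure to
converge raises an error rather than returning a polar lattice. On the
8-molecule periodic cell the generator's configurations lie inside the
brute-force enumeration of all ice-rule states (114 of 2¹⁶ orientations,
verified in the tests).

## Tilted seed slab and periodic consistency

The interface system stacks, bottom to top: a disordered constrained
water layer (default 5 Å, "ice barrier", placed at ice density
940 kg/m³), a constrained crystalline seed slab, free water, and
optionally an AFP. In the slab frame the a-axis lies along x, the
c-axis along y (the long box edge) and prism layers stack along z with
interlayer spacing d = √3·a/2 ≈ 3.897 Å.

For continual step growth the prism plane must reconnect across the
periodic y-boundary an integer number n of layers higher. Writing the
box period as a crystal translation requires m c-repeats and the n-layer
rise to satisfy (m·c)² + (n·d)² = L_y². No exact solution exists for
arbitrary (c, L_y), so the c-repeat is strained to
c_eff = √(L_y² − (n·d)²)/m for the nearest integer m and the tilt angle
snapped to θ = atan(n·d / (m·c_eff)). For the default box
(L_y = 126.6 Å) and n = 1 this gives θ = 1.764° at 0.59% c-strain —
the kind of small commensuration strain any periodic ice slab setup
requires. When an explicit tilt angle is requested instead, it is
validated against the nearest integer layer offset with a tolerance of
0.25 layers and rejected otherwise (validation can be disabled, at the
cost of the growth mechanism). A requested 4.3° on the default box
implies a 2.44-layer rise and is therefore rejected: the printed angle
of the original setup is not derivable from the printed box length and
a single-layer rise, so this package treats the angle as user input and
enforces consistency rather than guessing the unprinted seed extent.

`periodic_consistency` verifies two facts from output coordinates:
(1) closure — the box period equals the rotated lattice translation
(m c-repeats + n layers) to < 10⁻⁶ Å; (2) stacking — translating the
slab by the rotated n-layer stacking vector of ice Iₕ superimposes it
on itself (RMSD ~10⁻¹⁵ Å over matched oxygens). The one-layer stacking
vector carries an a/2 lateral offset (ABAB prism stacking), which the
check includes; the x-boundary is left incommensurate (a does not divide
51.5 Å), which affects neither the growth mechanism nor the y-closure.

The slab is trimmed to whole layers (default thickness 8.5 Å ⇒ 2
layers) plus a one-layer step over a configurable fraction of the box
length (default half) to initiate step growth. Protons are assigned on
the periodic parent lattice and carried through strain/rotation, so
every seed water keeps exactly two hydrogens; ice-rule bookkeeping is
asserted on the parent lattice, where the bonds are defined.

## Water placement and AFP

Barrier and free waters are placed by random sequential insertion with a
2.2 Å O–O clash cutoff on a cell-list grid, with a budget of 10⁴
attempts per molecule (an unreachable density raises an error; the
resulting packing fraction ~0.18 is well below the ~0.38 jamming limit
of random sequential adsorption). The free-water count is set from the
box volume at 970 kg/m³, a supercooled-liquid TIP4P density; with the
default box this yields ≈ 17.6k total waters and ≈ 1.0k barrier waters.
Placement is deterministic under a fixed seed. Hydrogens on disordered
waters get random orientations with the rigid 104.52° H–O–H angle.

AFP placement puts the protein centroid at a configurable height
(default 20 Å) above the topmost seed oxygen; with orientation enabled,
the centroid→IBS-hydroxyl direction is rotated to −z and the hydroxyl
row direction (first principal component of the OG1 positions in the
x–y plane) is aligned with the a-axis. The ice-binding surface defaults
to threonines 7, 23, 39, 54, 69, 84 and 101 (the conserved T-X-T rows
of the spruce budworm AFP β-helix); any PDB can be supplied, and a
synthetic β-helix stand-in with that residue layout is generated in
code for testing. Overlapping free waters (O within 2.4 Å of any
protein atom) are deleted, verified against a brute-force distance scan
in the tests. No force-field or topology assignment is performed: the
written PDB encodes constraint flags in the B-factor column
(1.0 = harmonically restrained) with a companion CSV of reference
positions, and a YAML stub records the MD settings (NPT, Langevin,
TIP4P, PME, SHAKE, 2 fs) a user would hand to an engine.

## Trajectory statistics

**Mobility classification.** A water is ice at frame t if its oxygen
stays within 0.8 Å over a 3-frame window (200 ps at the default 100 ps
capture interval). The phrase "moved less than 0.8 Å over three
frames" admits two readings; the default measures the maximum deviation
from the window-mean position (stable against single-frame vibration),
with the first-to-last displacement available as `mode="endpoint"`.
Windows overlap (slide by one frame), and labels exist only for frames
with a complete window. Displacements are computed on per-molecule
unwrapped coordinates (minimum-image in x and y). The classifier is
monotone in the threshold, and time reversal mirrors the label field.

**Ice fraction and equilibrium.** The fraction of ice-labelled waters
in a region, by default everything above the topmost constrained seed
oxygen (the seed is restrained, so the plane is computed once per
trajectory). Drift over a time window is assessed by OLS; a segment is
"equilibrated" when the 95% CI of the slope covers zero. At least 10
points are required.

**Binding detection.** The AFP centre of mass (unweighted centroid,
unwrapped) is bound in a trailing window (default 20 ns) when its
rolling height SD is below 1.5 Å and it lies within 10 Å of the front
height; the bind time is the start of the first bound window sustained
to the end. The three thresholds are not prescribed by the underlying
observable ("an unchanging z-coordinate") and were chosen so that
pinned and diffusing synthetic tracks separate cleanly; all are exposed
as parameters. With 0.05 Å²/ps track diffusion the rolling SD of a free
walk over 200 frames is ~25 Å versus ~0.3 Å when pinned, so the margin
is wide; measured false-positive rate is 0/100 seeded free tracks.

**Hydrogen bonds.** Standard geometric criterion: donor–acceptor O–O
distance ≤ 3.5 Å and H–donor–acceptor angle ≤ 30°, minimum-image,
explicit hydrogens required (no inference rule). Verified exactly
against an all-pairs brute-force oracle.

**Ordered bridging waters.** Non-ice waters with at least one hydrogen
bond (either direction) to an ice-labelled water and at least one to an
IBS threonine hydroxyl; "fully coordinated" members have ≥ 2 of each —
the fully satisfied tetrahedral arrangement of the bound state. The
report includes nearest-neighbour spacings along the a-axis and each
member's distance to the nearest ideal bulk-ice site, to substantiate
that the bridging layer is structurally distinct from ice.

**Occupancy map and front surface.** The box is voxelised (1 Å) and
each voxel records the fraction of frames in which its centre lies
within a rasterisation radius of a water oxygen (default 1.4 Å, a water
van-der-Waals-like radius mirroring common volume-mapping defaults).
Ice sits at persistent sites (occupancy ≈ 1); diffusing liquid smears
(mean voxel coverage ≈ 0.3 at the default radius), so an 85% threshold
isolates the ice. The front height in each (x, y) column is the top of
the thresholded region connected to the seed, tolerating vertical gaps
up to `max_gap` voxels (default 3 — the open channels of ice Iₕ);
missing columns are interpolated along y and flagged. For quantitative
front-shape work a rasterisation radius of 2.3 Å is used instead: it is
larger than the widest lateral void of the projected lattice (~1.8 Å),
so every column is covered within each layer and the extracted surface
tracks the true front to ~1 Å after mild smoothing, at the cost of
raising liquid coverage to ~0.8 per frame — which is why short-window
extractions should then use a threshold of 1.0 (only waters static for
the entire window count as solid). Columns can still terminate early in
tall frozen regions, biasing the column *mean* low; the median height
is robust and is what the velocity-recovery analysis uses.

**Curvature.** The height field is averaged along the cylinder axis
(x — the AFP rows pin the front along x in the reference geometry) and
a circle is fitted to the y–z profile by least squares (Kåsa algebraic
initialisation, geometric refinement). A best-fit radius exceeding 20×
the profile span is reported as "no finite curvature" — distinct from
failure — and convexity toward the liquid is flagged by the position of
the circle centre. `compare_gibbs_thomson` reports the dimensionless
ratio of the fitted radius to the critical cylindrical radius.

## Synthetic data: what it does and does not emulate

The generator ties every water to an ice-Iₕ lattice site (shared with
the builder's geometry code). While the prescribed front z(y, t) is
above a site, its water diffuses as an uncorrelated Gaussian walk
(default 0.1 Å²/ps) above the front; once the front passes the site the
water freezes onto it and vibrates (Gaussian, default amplitude 0.2 Å).
Front models: flat (optionally advancing at a velocity in Å/ns),
tilted-advancing, and cylindrical arcs pinned at periodic sites (static,
the equilibrated AFP-pinned shape). Waters frozen at frame 0 carry the
constrained-seed role so region selections behave as on real data.
Binding tracks are 1-D reflected random walks pinned with 0.3 Å jitter
after the planted bind time; the never-binding case emulates the
IBS-mutant ensembles.

Ground truth (per-water phase labels, per-frame front heights, bind
time, planted bridge indices) is recorded exactly, and identical seeds
give bit-identical output. The generator has no water–water
interactions, no realistic liquid structure, no latent-heat or
interfacial physics, and freezing teleports a walker onto its site in
one frame. Passing tests therefore demonstrate that the *analyses
recover known structure under the stated noise model* — classifier
separability at the default amplitudes (≥ 99% by contract), curvature
and bind-time recovery within stated tolerances — not that the physics
of any particular MD system is reproduced. Microsecond-scale
observables (equilibrated ice fractions at several temperatures,
binding-event tallies, measured ~50 Å front radii) require cluster MD
with a real engine; the pipeline ingests such trajectories (multi-frame
PDB, the documented XYZ dialect, or DCD plus topology) but this
repository makes no claim about their values.

## Problem sizes and numerical choices

Default test/driver scales: classifier recovery uses ~10⁴ waters ×
100 frames; front work uses ~10³ waters × 200–300 frames on a
12 × 63.3 × 45 Å box (one pin period); binding ensembles use 500–600
frame tracks. These sizes keep every result reproducible on a single
CPU in seconds while leaving the statistics (label agreement, fit
radii, false-positive rates) well away from their acceptance margins.
Tolerances: lattice geometry is exact to ~10⁻⁶ Å before tilting;
critical radii are compared at 1% (printed values are rounded to two or
three figures); cylinder fits on noisy fronts carry ±3 Å; bind times
±1 window. Degenerate inputs (zero supercooling, empty regions, flat
profiles, missing hydrogens, empty IBS sets, windows longer than the
trajectory) raise typed errors rather than returning sentinel numbers,
except the flat-profile cylinder fit, which returns an explicit
"no finite curvature" result.

## Known limitations

- The seed slab's in-plane extent and thickness are only loosely
  constrained by the reference counts; the defaults reproduce them to
  ~15%, not exactly.
- The x-boundary of the seed is incommensurate with the a-repeat for
  the default box; the seam is physically inert for step growth along y
  but would matter for growth statistics resolved at the x-edges.
- Column-wise front extraction degrades on very tall frozen regions
  (early termination) and on single-frame windows (no occupancy
  contrast); use windows ≥ ~100 frames, or threshold 1.0 with the
  larger rasterisation radius for short windows.
- The binding detector assumes an essentially static front height over
  a window; a front advancing many Å per window would need the
  per-frame front input it accepts.
- `write_system` emits 3-site waters (O, H1, H2); 4-site model geometry
  (the massless charge site) is left to the MD engine's tooling.
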