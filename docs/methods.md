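# Methods

This note documents the models behind each analysis, the parameters that
matter, the numerical choices where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Units and conventions

All lengths are nm, times ps, masses amu; PDB ångströms are converted at
the file boundary. Cells are orthorhombic only — triclinic input is
rejected rather than approximated. Coordinates are kept exactly as read:
wrapping into the primary cell is an explicit operation, applied
internally by the water census (so imaging conventions cannot change a
count) and forbidden for mean-squared-displacement analysis (which
requires unwrapped coordinates and rejects trajectories with per-frame
jumps beyond half the box). Atom and residue indices are 1-based in files
and 0-based in memory.

## Leaflet surface fitting

A leaflet's phosphorus atoms are fitted with a periodic height field
z(x, y) on a regular grid_n × grid_n lattice over the lateral cell
(default grid_n = 500; all contracts hold for any grid_n ≥ 4 and the
tests run at 32–128 for speed). Node heights are Gaussian-kernel-weighted
means of the P-atom z values, with the lateral offset taken under the
minimum-image convention so the surface is periodic by construction. The
kernel is separable in x and y, which makes the fit a pair of small
matrix products rather than an O(grid² · N) loop.

Fit quality (`fit_rmsd`) is the RMS difference between each P atom's z
and the bilinearly interpolated surface at its lateral position —
interpolated surface, not nearest node, so the measure is resolution
independent.

The bandwidth ladder for automatic selection is scaled to the mean
lateral point spacing Δ = sqrt(A/N): candidates {1.25, 1.75, 2.5, 3.5}·Δ,
choosing the smallest whose RMSD meets the 0.1 nm quality bar (or the
minimiser if none does). The smallest rung still pools a full shell of
neighbours; a narrower kernel would chase individual points, deflating
the RMSD below the true out-of-surface scatter. With this ladder the
fitted RMSD on a flat sheet with σ = 0.07 nm of injected vertical noise
reports ≈ 0.066 nm, i.e. the noise scale itself.

Leaflet assignment is 1-D two-means clustering on z. The split is
refused when the inter-leaflet gap is non-positive or smaller than half
the mean intra-leaflet spread — a guard against effectively unimodal
distributions, which always contain some accidental gap.

Normals come from central differences with periodic wrap; surface area
sums two triangles per grid cell, with the seam cells wrapping around
the boundary. For non-periodic analytic height fields (a tilted plane)
`surface_area(..., periodic=False)` triangulates interior cells and
rescales by the covered fraction, which is exact for affine surfaces.

## Thickness, order and density maps

Thickness is the vertical P-to-P difference of the two fitted surfaces
at matched lateral nodes — deliberately not a normal-projected thickness,
matching how P-to-P maps are conventionally reported. The surface order
parameter is P₂(cos θ) of the node normal against the box z axis; it is
1 on flat patches, 0 at the magic angle (54.74°), −0.5 perpendicular, and
decreases with local curvature. Frame-averaged maps are element-wise
means of per-frame maps.

Density profiles can be curvature-corrected: each atom is binned by
z′ = z − midsurface(x, y), where the midsurface is the mean of the two
fitted leaflet heights at the atom's lateral position. The midsurface
(rather than the nearer leaflet) was chosen as the single reference so
one profile covers both leaflets consistently; this is the one place the
reference analysis pipeline left the convention open. Densities are
normalised by lateral cell area × bin width × frames; with the bin range
covering all atoms this conserves the species atom count exactly.

## Tension elasticity

The mechanical chain is: P-to-P thickness → hydrocarbon core thickness
(subtract 1.0 nm, i.e. a 0.5 nm phosphate-to-hydrocarbon offset per
leaflet) → relative thinning Δh/h → relative area increment via
incompressibility (Δh/h ≈ −ΔA/A) → surface tension Γ = K_A·ΔA/A. With
the reference values (P-to-P 3.1 nm, local decrement 0.2 nm,
K_A = 200 mN/m) this yields h = 2.1 nm, Δh/h = −0.1 and Γ ≈ 20 mN/m;
conversely Γ = 70 and 60 mN/m imply 35% and 30% area increments.

K_A itself is estimated with the equilibrium fluctuation formula
K_A = k_B T ⟨A⟩ / var(A) (area in nm², result in mN/m). The estimator was
chosen because only the value of K_A, not its derivation, is available
for the reference system; it is validated by self-consistent recovery on
synthetic Gaussian area series (within 10% at n = 10⁴). The quoted
uncertainty is a block-bootstrap standard error (default 200 replicates,
5% block length) so serially correlated series are not over-confident.

## Water census and pore sizing

The census counts selected water oxygens whose wrapped z lies in the
half-open slab [z_min, z_max) — half-open so molecules sitting exactly
on a boundary are never double-counted. The default slab is the 0.5 nm
band about the bilayer midplane (absolute [1.7, 2.2] nm in the reference
geometry).

Plateau statistics: the plateau level is the median of the rolling means
(window 10 frames), which is robust both to the initial filling ramp and
to a pre-collapse blow-up tail; the onset is the first frame whose
rolling mean enters the band max(10% of level, 1 count) around that
level and is still inside one window later. A simple
"rolling-mean-stops-changing" rule was rejected because a census that
starts at zero is flat there too, and would always report onset 0. The
reported mean/sd are median and scaled MAD over the plateau segment,
re-evaluated over [onset, disruption) once a disruption is found.

Disruption is called at the first frame whose count exceeds
plateau_mean + k_sd · max(plateau_sd, 1) for `persistence` consecutive
frames (defaults k_sd = 5, persistence = 5). Both knobs are exposed; the
defaults classify clean step fixtures exactly and noisy blow-up fixtures
within 2 × persistence frames in ≥ 9/10 seeds. The max(·, 1) floor keeps
the threshold meaningful for zero-variance plateaus.

Pore sizing assumes the slab waters fill a cylinder of height
h = 0.5 nm at ρ = 1 g/cm³: V = NW·M_w/(ρ·N_A), d = sqrt(4V/(π h)).
NW = 10 gives d = 0.873 nm and NW = 5 gives 0.617 nm; values are
reported at one decimal (0.9 / 0.6 nm) with the unrounded number always
retained. Since the slab is a bottleneck cross-section of an irregular
pore, d is a limiting estimate. Uncertainty, when requested, is
propagated by evaluating the formula at NW ± sd.

## Interaction statistics

Contacts are counted per atom pair (an atom in several contacts
contributes several counts) under the minimum-image convention, strict
inequality at the cutoff (0.6 nm default). The implementation uses a
periodic k-d tree; its contract is identical to the all-pairs definition
and the test suite holds it to an O(N²) brute-force oracle over 10 seeds.
Overlapping groups count unordered pairs once and never pair an atom
with itself.

Hydrogen bonds use the conventional geometric criterion: donor–acceptor
distance ≤ 0.35 nm and H–D–A angle ≤ 30°, both configurable; the
reference analysis used a standard tool without stating its criteria, so
the de facto convention was adopted. Donor hydrogens are identified by
naming convention (H-prefixed atoms of the same residue within 0.12 nm
in the first frame) or supplied explicitly; donors without hydrogens are
skipped with a warning. The existence map rows are ordered by first
occurrence.

Diffusion coefficients use the Einstein relation D = slope/(2·n_dim)
with an all-origins MSD and a least-squares slope over the 10–50% middle
lag band. Dimensionality (2 for lateral membrane-bound motion, 3 for
solution) is an explicit argument because either convention is
defensible for a surface-bound peptide; a 60-fold solution/bound
mobility ratio is recovered independent of that choice as long as it is
applied consistently. A log-log MSD exponent outside [0.5, 1.5] flags
the motion as non-diffusive (coherent drift grows quadratically).

Charge bookkeeping: monomer charge = #LYS + #ARG − #GLU(deprotonated),
with circular (head-to-tail) backbones contributing no terminal charges;
counterions = n_anionic_lipids − n_monomers × monomer_charge, which
enforces exact electroneutrality.

## Synthetic trajectory generator

The generator emulates exactly the statistical structure the analyses
consume, not membrane physics. Lipids are five-site pseudo-molecules
(P, two carbonyl/glycerol O acceptors, two tail beads); water is a
single O site (optional rigid H pair for H-bond geometry tests);
peptides are rings of labelled residue beads per protomer. Defaults
describe the reference system: 64 lipids per leaflet in a
6.72 × 6.72 × 9 nm cell (0.7056 nm² per lipid), P-to-P 3.1 nm, bulk
water slabs at 1 g/cm³.

Leaflet P heights follow z₀ ± p2p/2 + A·sin(2πn_x x/Lx)·sin(2πn_y y/Ly)
with optional Gaussian positional noise and an optional Gaussian dimple
pressed into the upper leaflet (the footprint of a bound peptide: depth
0.2 nm reproduces the 2.9 nm thickness minimum on the 3.1 nm bilayer).
Undulations are box-commensurate sinusoids so surface fits have analytic
truth. A cylindrical pore places exactly the requested number of water
molecules inside the census slab (a per-frame schedule is accepted, for
plateau/blow-up fixtures) and fills the rest of the cylinder at a chosen
density; with no occupancy given, the count follows from bulk density
and the slab cylinder volume. A per-frame lateral dilation schedule
scales x, y and the lateral cell edges, and in volume-conserving mode
scales z by 1/f² — the incompressible-membrane response that the applied
surface tension produces.

Frames are independent draws around the configured geometry: there is
no dynamics, no correlation structure in time, no energetics, and no
lipid-water interface structure beyond slab placement. Passing tests on
this generator therefore demonstrate correctness of the *analysis
contracts* (geometry, counting, inversion, statistics), not fidelity to
any force field. All randomness derives from the spec seed; identical
specs give bit-identical trajectories.

## Problem sizes in tests and scripts

The test suite runs surfaces at grid 32–128 with 64–2304 fitted points,
census fixtures of ≤ 200 frames, random walks of 200 frames × 60
particles, and K_A series of 10⁴ samples; the acceptance script uses
20-frame pore systems of ≈ 5 × 10³ atoms. These sizes put every
statistical check well inside its stated tolerance while keeping the
whole suite in the tens of seconds.

## Known limitations

- Orthorhombic cells only; no triclinic minimum image.
- Thickness is vertical, not normal-projected; on strongly tilted
  patches the two differ.
- The density-profile volume normalisation uses the flat lateral area;
  for strongly curved surfaces bin volumes deviate by O(|∇h|²).
- The cylindrical pore model inherits its assumptions (bulk density,
  fixed height); diameters are bottleneck estimates.
- The K_A fluctuation estimator assumes a stationary series; drifting
  areas bias it (the block bootstrap reports, but does not remove, this).
- H-bond hydrogen assignment by naming convention assumes conventional
  H-prefixed names; exotic topologies should pass explicit donor-H lists.
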