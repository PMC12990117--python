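# Methods

`cgmem` reimplements, as a tested library, the analysis stack used to study
how imidazolium-based ionic liquids (CmCn cations with BF₄⁻ anions) interact
with and penetrate DPPC bilayers in coarse-grained (Martini-bead) molecular
dynamics: leaflet-surface morphology, tail-contact network centralities,
umbrella-sampling free-energy profiles, and penetration kinetics.  Because
the microsecond trajectories such studies rest on cannot be regenerated at
desk scale, every stage is validated against synthetic configurations with
analytically known ground truth.  This note records the models, the
conventions chosen where the problem is genuinely open, and what the
synthetic validation does and does not establish.

Units are fixed throughout: nm, ps, kJ/mol.  Thermal energy defaults to
kT = R·309 K = 2.569 kJ/mol; temperature is configurable.

## System representation

A `Frame` holds an orthorhombic periodic box and flat arrays of beads
(molecule id, residue name, bead name, position).  Triclinic boxes are
rejected everywhere; all distance logic uses the minimum-image convention
with a half-open `[-L/2, L/2)` displacement range (exactly half a box edge
maps to the negative representative).  Semantic bead roles — phosphate,
lipid_tail, lipid_other, cation_head, cation_tail, anion, water — are
assigned by a user-supplied YAML map from (residue, bead) pairs, so the
analyses never hard-code a force field's naming.

Native I/O is fixed-column GRO (3-decimal nm, multi-frame by
concatenation); velocities are read and discarded.  Coordinates are
printed with printf `%8.3f` rounding (round-half-away-from-zero), so writes
are byte-stable.

## Leaflet surfaces and morphology

Phosphate beads are partitioned into the four leaflets of a two-bilayer
system by the four largest circular gaps in their sorted z values (the z
axis is periodic).  Separability demands the 4th largest gap exceed twice
the 5th; otherwise assignment fails with gap diagnostics.  Which aqueous
gap is the *external* solution cannot be inferred from geometry alone: the
default (`external="auto"`) picks the gap holding more cation-head/anion
beads (the side ions are introduced on), falling back to the wider gap;
`"wrap"` (the gap crossing z = 0) and `"widest"` are available for
generated systems, where the external compartment wraps the boundary by
construction.

Each leaflet's scattered (x, y, z) points are interpolated with scipy's
`LinearNDInterpolator` (piecewise-linear over a Delaunay triangulation)
after augmenting the points with periodic ghost images within a margin of
2·√(Lx·Ly/n); grid nodes sit at i·Lx/nx with nx = ⌈√(2n)⌉ capped at 128
(about two nodes per phosphate) unless overridden.  z values are unwrapped
about their circular mean first so leaflets straddling the periodic z
boundary stay continuous.  Any uncovered node is an error, never silently
filled.

From the four grids:

* **surface area** — the sum of the 2·nx·ny triangles tiling the periodic
  height field; equals Lx·Ly exactly for a flat leaflet and can only
  exceed it;
* **thickness** — mean node-wise *vertical* (z) separation of a bilayer's
  two grids under the periodic minimum image.  Surface-normal distance is
  a deliberate non-goal; the vertical convention is the simplest reading
  of "bilayer thickness" and is recorded here because the two differ for
  strongly undulating membranes;
* **compartment volumes** — per grid column the four heights cut the
  periodic z extent into bilayer1 / internal / bilayer2 / external
  intervals; columns where the cyclic order is violated (crossing
  surfaces) raise an error naming the column.  The four volumes sum to the
  box volume to machine precision by construction;
* **point location** — a position's compartment from bilinear periodic
  interpolation of the four grids at its exact (x, y).

Surfaces are single-valued height fields: pores, overhangs and vesicles
are out of contract.

## Profiles

The reaction coordinate ξ of a site is its signed periodic z offset from a
bilayer midplane, defined per frame as the midpoint of the two leaflet-grid
mean heights (an instantaneous, global midplane — not column-local, and
not time-averaged).  Negative ξ lies on the external-solution side, so the
sign flips between bilayer 1 and bilayer 2.  The bilayer normal is fixed
to +z; curvature-corrected local normals are a non-goal.

Number-density profiles histogram per-frame site ξ values, normalized by
slab volume Lx·Ly·Δξ and frame count; the profile integral therefore
equals the mean site count exactly.  Orientation profiles use
cos θ = v̂ · n̂ with v from a cation's hydrophobic-site centroid to its
hydrophilic-site centroid and n̂ the +z axis flipped to point away from
the bilayer center at the molecule's position; values are binned by the
head-site ξ and smoothed last with a centered 4-bin running mean (window
configurable; 1 disables).  Bins with no samples carry NaN and are never
interpolated.

Radial distribution functions count minimum-image pairs with a periodic
KD-tree into `(r, r+dr]` bins — exactly coincident pairs (self-pairs when
the two groups coincide) never contribute — and normalize by the
ideal-gas shell expectation with N−1 partners for identical groups.  The
contact cutoff is the first local minimum after the first maximum of a
3-bin-smoothed g(r), with both extrema required to have prominence ≥ 5% of
the g(r) range so bin noise cannot masquerade as shell structure.  Default
bin widths: 0.05 nm (density), 0.1 nm (orientation), 0.01 nm (RDF).

## Contact graphs and centralities

Two molecules of one kind (cation or lipid) are in contact when any pair
of their tail beads lies within the cutoff — 0.7 nm by default, the first
minimum of the tail–tail RDF for these bead types.  Nodes are whole
molecules (a DPPC node is identified with its molecule even though its
phosphate marks the leaflet surface; contacts always use tail sites), and
isolated molecules stay in the graph.  Neighbor search is a periodic
KD-tree, so construction is near-linear in bead count and invariant under
rigid translations modulo the box.

Degree is the incident-edge count.  Closeness centrality uses the
Wasserman–Faust reachable-set form, closeness(v) = ((r−1)/(n−1))·((r−1)/Σd)
for r reachable nodes and shortest-path sum Σd, which reduces to (n−1)/Σd
on connected graphs and gives 0 for isolated nodes — so dispersed ions
score near 0 and members of a compact aggregate near 1, making the
closeness histogram a sensitive phase-separation diagnostic.  Time
averages pool per-node per-frame values over an analysis window
(defaulting to the final 20% of frames, the steady-state fraction of a
production run; whether to average over nodes, frames or both is not
canonical — pooling is the recorded choice).  Degree and closeness are
computed by networkx; the test suite checks them against an independent
BFS implementation on random graphs.  Betweenness/Katz/eigenvector
centralities are accessible through networkx on the same graphs but are
not part of the supported surface.

## Umbrella sampling and WHAM

Umbrella windows carry a bias center ξⱼ, a harmonic force constant k
(1000 kJ mol⁻¹ nm⁻² is the conventional default for this reaction
coordinate) and a ξ time series.  The unbiased profile solves the standard
WHAM equations on uniform ξ bins,

    p_b = Σⱼ n_j(b) / Σⱼ N_j exp[(F_j − w_j(ξ_b))/kT],
    F_j = −kT ln Σ_b p_b exp[−w_j(ξ_b)/kT],

with G(ξ) = −kT ln p_b shifted so G = 0 at the aqueous reference
(ξ_ref = 4.5 nm by default; always snapped to the nearest populated bin).
Samples falling outside the binned range are excluded from that window's
N_j — otherwise the likelihood acquires an unbounded gauge direction — and
windows left empty are dropped with a warning.  Empty bins stay NaN.

Numerically the fixed point is found by minimizing the equivalent convex
negative log-likelihood Φ(f) = Σ_b T_b ln Σⱼ N_j e^{f_j − w_jb} − Σⱼ N_j f_j
in the log domain (L-BFGS followed by damped exact-Hessian Newton steps,
gauge F₁ = 0).  Plain self-consistent iteration is *not* used as the
solver: when window overlap is weak its contraction rate approaches 1 and
the per-iteration change drops below any tolerance while the profile is
still far from converged.  Convergence is instead certified by the
self-consistency residual max_j |F_j + kT ln Σ_b p_b e^{−w_jb/kT}|, default
tolerance 10⁻⁷ kJ/mol.  Default bins are 0.1 nm over [0, 4.5] nm for
production-style profiles; the recovery tests use 0.02 nm because with
k = 1000 the biased distributions are only ~0.05 nm wide.

Errors follow the five-block bootstrap: each window's series is cut into
five contiguous, time-ordered blocks (respecting autocorrelation; trailing
remainders dropped and logged), one PMF is computed per block index, and
the per-bin standard deviation (ddof = 1) across block PMFs is reported.

ΔG summaries report G(global minimum) − G(ξ_solution),
G(ξ_center) − G(ξ_solution) and their difference (the re-crossing barrier),
with nearest-bin lookups at ξ_solution = 4.5 nm and ξ_center = 0.  The
chain-length regression is ordinary least squares of ΔG against the alkyl
carbon count, returning slope (kJ/mol per CH₂), intercept and R².

## Kinetics

Trajectories are unwrapped by accumulating minimum-image frame-to-frame
increments; rewrapping reproduces the input exactly.  An increment within
1% of half a box edge is treated as temporal undersampling and rejected
with the bead and frame named (a genuine jump of more than half a box is
undetectable in principle from wrapped data — this guard catches the
boundary).

MSD uses every sliding time origin via the standard FFT decomposition
(MSD = S₁ − 2·S₂ with S₂ the autocorrelation), restricted to the chosen
axes: lateral (xy, d = 2) is the convention for lipids in a bilayer, xyz
(d = 3) for free ions; both modes are exposed because published diffusion
coefficients are reported under either convention and the choice rescales
D.  D comes from a least-squares slope over lags in 10–50% of the maximum
lag (skipping the short-time regime and the noisy tail), D = slope/(2d),
reported in nm²/ps and cm²/s (1 nm²/ps = 10⁻² cm²/s).

Compartment tracking assigns each molecule's reference site (anion bead;
imidazolium-ring centroid for cations) to
external/bilayer1/internal/bilayer2 per frame with no dwell-time
hysteresis, using that frame's surfaces.  Concentrations are
N/(N_A·V) = N/(0.6022·V[nm³]) mol/L with the frame's compartment volume,
smoothed by a centered 12-frame running mean.  Counts are conserved by
construction and checked per frame.

## Synthetic ground truth

The generator exists so that every stage above has an oracle; it evaluates
no force field and is not an equilibration tool.

* **Two-bilayer systems** place each lipid as one phosphate bead on its
  leaflet sheet plus two 4-bead tails stepping toward the midplane.
  Sheets sit at z_center ± thickness/2 plus an undulation
  A·sin(2πp_x x/Lx)·cos(2πp_y y/Ly) with *integer* period counts, so the
  surface is exactly periodic and its area has a clean quadrature oracle.
  Defaults mirror a DPPC-like state: 0.64 nm² per lipid, 4 nm leaflet
  separation; the lipid lattice must match the box cross-section within
  1%.  Water beads fill the aqueous compartments on a jittered lattice at
  a configurable density (default 1.5 nm⁻³ — enough to exercise selection
  and compartment logic, deliberately far below a realistic bead density
  to keep tests fast) and never fall inside a bilayer.
* **Ion placement** realizes the penetration regimes: dispersed ions (on
  an xy lattice with > 1 nm guaranteed molecule separation, chains along
  +z), micelles and core nanodroplets (tails radially packed so the
  innermost beads sit within 0.3 nm of the center — the aggregate is one
  connected component at any cutoff ≥ 0.6 nm by construction), an
  interfacial layer, and internal-solution ions.  Ground-truth
  compartment and cluster labels are returned in a sidecar table, never
  encoded in bead names.
* **Brownian walkers** take i.i.d. Gaussian steps of variance 2·D·dt per
  axis; wrapped frames and unwrapped ground truth are both returned.
* **Umbrella samples** come from random-walk Metropolis chains per window
  (proposal width √(kT/k), 10³-draw burn-in, acceptance logged), so the
  sampled biased densities are exact up to Monte-Carlo error.  Analytic
  target potentials: flat, harmonic, double-well h·((ξ−x₀)²/a² − 1)², and
  Gaussian barrier.

What passing on these systems shows: the geometry, estimators and
bookkeeping are correct against exact oracles.  What it does not show:
behavior on real MD output with thermal disorder in the tails, protrusion
defects, non-sinusoidal undulation spectra, correlated umbrella samples
with long memory, or leaflets that merge or porate — the assignment and
surface steps will raise errors rather than guess in those regimes.

## Validation experiment sizes

The recovery experiments run at: 100 random undulated two-bilayer systems
(volume closure), 100 random graphs of n ≤ 50 (centrality oracle), 20
umbrella windows × 5000 samples for the harmonic (κ = 50 kJ mol⁻¹ nm⁻²)
and double-well recoveries — windows spanning ξ ∈ [−1, 1] nm, i.e. ±4.4
thermal widths √(kT/κ) of the κ = 50 well, so adjacent biased
distributions overlap properly (spanning well beyond the thermally
populated region with the same 20 windows would leave ~4.6σ between
neighbors and the window-join random walk, not the estimator, would
dominate the error) — and 500 Brownian walkers × 10⁴ steps for diffusion.
Measured outcomes: harmonic PMF RMSE ≈ 0.15–0.3 kT, planted D recovered
within ~2%, all geometric and graph oracles exact to machine precision.

## Known limitations

* Thickness is vertical, not normal; the two diverge for large-amplitude
  undulations.
* ξ uses a global instantaneous midplane; a column-local variant would
  differ for strongly bent membranes.
* Closeness on disconnected graphs follows one (the Wasserman–Faust)
  of several published conventions; absolute values are only comparable
  across datasets using the same convention.
* Bootstrap blocks are contiguous fifths of each window; no
  autocorrelation-time estimation is attempted.
* MBAR/umbrella integration, 2-D PMFs, pore/vesicle geometry and
  permeability from flux counting are out of scope.
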