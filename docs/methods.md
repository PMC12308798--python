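# Methods

This note documents the models, conventions and numerical choices behind
`lamella`, and what its synthetic tests do and do not demonstrate about
real membrane trajectories.

## Scope and data model

All analyses operate on an in-memory trajectory (`TrajectoryData`):
per-frame coordinates in ångström, per-frame orthorhombic box, times in
picoseconds, and a lipid name map following the O1–O5 / C1–C35 numbering
of branched-tail monoacyl glycerolipids (glycerol C1–C3 with primary
hydroxyl O1, ester O2 / carbonyl C4=O4, branching carbon C5,
hydroxyl-bearing C6–O5, tails C7–C20 and C21–C35). Coordinates are never
wrapped on load; each analysis declares its own periodic-image policy.
Membranes are assumed planar with the normal along z, which matches the
lamellar systems this package targets; none of the estimators correct for
curvature or undulations.

Leaflets are assigned per frame by deterministic 1D k-means on the z
coordinate of a marker atom (default O1, the primary hydroxyl oxygen)
with the cluster count fixed by the configuration (2 for a single
bilayer, 4 for stacked or interdigitated doubles) and quantile
initialisation. Bands closer than 2 Å (centre-to-centre) raise a
degenerate-geometry error rather than returning an arbitrary split. The
marker-z rule is this package's choice of operational definition; it is
exact for the planar synthetic systems and should be checked (e.g.
against a graph-based assignment) on strongly deformed membranes.

## Membrane geometry

*APL_xy* is the box area over the per-leaflet lipid count, frame by
frame. *APL_vor* tessellates the xy-projected, mass-weighted headgroup
centres of outer leaflets (those in contact with water), with
periodicity handled by explicit 3×3 image replication before calling the
Voronoi builder — the simplest provably correct treatment; per-leaflet
cell areas sum to the box area to ~1e-15 relative. The distribution mode
is read from a 0.5 Å² histogram (the bin width is a documented choice;
reported maxima depend on it at the ±0.25 Å² level). Sites that are
exactly collinear raise a tessellation error by an explicit rank check;
under periodic replication such inputs would otherwise tessellate, but
they signal a degenerate configuration upstream.

Density profiles histogram selected atoms along z (wrapped into the box)
with number, mass, or electron weights; electron counts are atomic
numbers, optionally minus force-field partial charges when supplied
(both conventions exist in common tools; the default is charge-free).
Thickness is measured between density peaks located by local-maximum
search with quadratic sub-bin refinement: outermost-peak separation for
the whole membrane, outer-to-central peak (averaged over the two sides)
for per-bilayer thickness in stacked configurations. Block averaging
uses five equal frame blocks by convention; with fewer frames than
blocks the empty blocks are dropped.

## Chain order and dynamics

S_CD uses hydrogens reconstructed from the two neighbouring carbons
assuming ideal tetrahedral methylene geometry (H–C–H = 109.47°, the H
plane perpendicular to the C(i−1)···C(i+1) axis). Terminal carbons are
excluded — the reconstruction needs both neighbours, and terminal
methyls are not methylenes. When the two neighbours are collinear (a
degenerate local geometry) the H plane is undefined; the implementation
substitutes an orthonormal pair perpendicular to the local axis, whose
two-vector average equals the azimuth-averaged value, keeping the
estimator unbiased there. Reference limits used as oracles: −0.5 for an
all-trans chain with its zigzag axis along z; 0 for isotropic
orientations; +0.25 for a chain axis at 90° to z averaged over spin.
Error bars come from five equal blocks of the analysis window and are
standard deviations over blocks (not standard errors), labelled as such.

Tilt angles are measured against leaflet-outward normals (the sign of
O1 relative to C5 per lipid — robust for interdigitated slabs) and
folded to [0°, 90°]; splay is the unfolded vertex angle at C5; the
head–tail angle is unfolded [0°, 180°]. Orientational ACFs use every
frame as a time origin with lags up to half the window — the standard
bias/variance compromise — and normalise to C(0)=1. The in-plane RDF
uses minimum-image distances of per-lipid centres of mass, normalised by
the ideal-gas annulus expectation per leaflet and averaged over leaflets
and frames.

## Conformational motifs (g₃ → SSIM → t-SNE → HDBSCAN)

Each lipid is fingerprinted in isolation: for every atom B of the
lipid-acid carbon selection (C5, C6, C7–C35; the carbonyl C4 is
excluded), its nearest selection neighbour A fixes a reference
direction, and every other selection atom C within 15 Å deposits unit
weight at (r_BC, cos θ_ABC). C ranges over all selection atoms except B
itself — the nearest neighbour contributes the first peak at one bond
length near cos θ = 1. Nearest-neighbour ties resolve to the lowest atom
index for determinism. The grid is 201 radial × 101 angular bins
(uniform in cos θ, matching how the peaks concentrate near cos θ = ±1),
frame-averaged and normalised to unit mass so fingerprints of different
lipids are comparable.

Pairwise similarity is mean local SSIM over 7×7 uniform windows with the
standard stabilisation constants (K₁=0.01, K₂=0.03) on the data set's
global value range; the in-package implementation agrees with
scikit-image's to ~1e-9 and is vectorised over pair batches because the
half-million pairs of a 1000-lipid system dominate the runtime.
Embedding converts similarity to dissimilarity as 1 − SSIM (the simplest
monotone conversion), runs randomly initialised t-SNE (perplexity 100,
early exaggeration 4) and clusters the 2D embedding with HDBSCAN
(min cluster size 50, single-cluster solutions allowed so a homogeneous
ensemble reports one population rather than all-noise). A 2D PCA of the
same dissimilarities provides independent validation of the cluster
separation; this cross-check is meaningful precisely because t-SNE is
randomly initialised.

Clusters are mapped onto the four-motif taxonomy — 0 closed-ordered,
1 tightly-closed-ordered, 2 splayed-disordered, 3 splayed-ordered — from
two scores of the cluster-mean fingerprint:

- *trans/gauche ratio*: mass in r ∈ [3.60, 4.15] Å, cos θ ∈ [0.85, 1]
  over mass in r ∈ [2.80, 3.20] Å, cos θ ∈ [0.35, 0.75]. The windows
  come from the ideal rotamer geometry of a 1.53 Å / 111° chain: the
  third-bond neighbour on the nearest-neighbour side sits at
  (3.88 Å, cos 0.93) for a trans dihedral and (2.99 Å, cos 0.54) for
  gauche.
- *packing score*: total mass in the inter-tail band 4 < r < 6 Å,
  where atoms of the opposing tail of the same lipid accumulate.

Assignment: trans/gauche ≤ 3.3 → motif 2 (disorder dominates the
taxonomy); otherwise packing ≥ 0.13 → closed (motif 1 if trans/gauche
> 19, else 0), packing < 0.13 → motif 3. The thresholds are geometric
midpoints between the cluster-mean scores of the four pure-motif
reference ensembles of the synthetic generator and are fixed constants;
on real trajectories they should be re-examined against the annotated
fingerprints before trusting per-motif percentages.

## Interfacial hydrogen bonding and rotational dynamics

A hydrogen bond exists when donor and acceptor oxygens are within 3.5 Å
and the acceptor–donor–hydrogen angle is ≤ 30°, with minimum-image
distances. Donor–hydrogen pairing comes from the topology: hydroxyls
(O1–H, O3–H, O5–H) donate and accept; ester/carbonyl oxygens (O2, O4)
accept only; waters do both (water–water bonds are not reported).
Per-molecule counts divide by the number of lipids; the per-group water
table credits a hydroxyl group through both its donor and acceptor
roles.

Bond stability uses the intermittent indicator h(t) of every
donor–acceptor pair ever bonded: C(t) = ⟨h(τ)h(τ+t)⟩/⟨h⟩, so C(0)=1.
"Tail correction" is interpreted as subtraction of the long-lag plateau
(mean over the final fifth of the lags) followed by renormalisation; the
plateau value is logged, and the uncorrected curve is available behind a
flag — the interpretation is an assumption of this package, not a claim
about any particular upstream implementation.

Rotational decay curves are fitted with a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + b by
trust-region least squares with multi-start initialisation over an
8-point log-spaced τ grid spanning the lag range (two-exponential fits
are notoriously initialisation-sensitive). Parameters are reported with
τ₁ ≤ τ₂ (fast/slow); fits with τ₂/τ₁ < 1.05 or a vanishing amplitude
(< 1e-6) are flagged degenerate rather than rejected. The offset b is
fitted freely and reported.

## The synthetic-membrane generator

The generator emulates statistical structure, not physics: no energies,
no excluded volume, no thermostat.

- **Tails** are rotamer chains (bonds 1.53 Å, angles 111°, dihedrals
  trans with probability 1 − p_g, else ±60° equiprobably). The first
  stem carbons of both tails lie on rays from C5 separated by the
  splay-1 target, so the C9–C5–C22 angle echoes it exactly; the chain
  continuations aim for a lateral tail separation at depth. With tail
  dynamics enabled (default) the continuations are re-drawn
  independently every frame — memoryless trans/gauche hopping — so
  frame-averaged fingerprints converge to each motif's expected
  distribution. Averaging over several frames is what makes the two
  closely related ordered-closed motifs separable, for the same reason
  real protocols average g₃ over hundreds of frames: a single rotamer
  realisation is a noisy estimate of a chain's dihedral statistics.
- **Motif library** (the four study conditions): gauche probabilities
  {0.12, 0.02, 0.40, 0.05}, splay-1 {95°, 95°, 135°, 135°}, tail
  separations {5.5, 4.2, 13, 13} Å, mean tilts {8°, 5°, 12°, 8°} for
  motifs 0–3. Values were chosen once to realise the taxonomy's
  qualitative contrasts at gel-phase-like magnitudes (splay modes near
  95°, tilts below ~15°).
- **Arrangements**: single bilayer (2 leaflets, tails meeting at the
  midplane), double bilayer (two stacked bilayers with a thin water
  gap — poorly hydrated lamellar stacks), interdigitated (two slabs in
  which opposing leaflets interleave on offset lattices and share one
  tail slab, giving roughly half the per-bilayer height and roughly
  double the area per lipid at matched composition).
- **Headgroup dynamics** act directly on the glycerol C1→C3 vector: per
  frame the C2/C3 rotor turns by a fixed angle α = arccos(e^(−Δt/τ))
  about a random axis perpendicular to the current direction, making
  the per-lag expectation of û(0)·û(t) exactly e^(−t/τ). Lipids are
  partitioned deterministically into fast (τ₁), slow (τ₂) and static
  classes with weights a₁, a₂, 1 − a₁ − a₂, so the ensemble P1 ACF is
  the planted double exponential by construction. Defaults (τ₁ = 2.1 ns,
  τ₂ = 57.3 ns, a₁ = 0.23, a₂ = 0.12) are the literature-reported
  glycerol rotation modes of a gel-phase single bilayer. Only the rotor
  carbons move; oxygens stay on the template so the sweep cannot
  fabricate hydrogen-bond geometries.
- **Hydrogen bonds** exist only where planted. The headgroup template
  points all hydroxyl hydrogens toward the water, which provably keeps
  accidental intra- and inter-lipid contacts outside the 30° cone.
  Planted lipid–lipid bonds relocate the donor O5–H and the acceptor O4
  to an isolated vertical dumbbell in the solvent above the pair
  (stylised geometry — bond counts, not conformations, are the planted
  observable); planted lipid–water bonds stack a water on the group's
  O–H axis at the lipid's solvent apex. Bond-count bookkeeping is exact
  by construction, which the statistics tests rely on.
- **Determinism**: one `numpy` Generator seeded from the spec drives
  everything; a fixed seed reproduces the trajectory bit for bit.

What passing the synthetic battery shows: the estimators implement their
definitions correctly (against closed forms, brute-force enumerations
and planted parameters) and the full pipeline can recover known
composition under realistic geometric magnitudes. What it does not
show: robustness to thermal positional noise beyond conformational
disorder, to partial interdigitation or membrane deformations, to
force-field-specific headgroup conformations, or to flip-flop; real
trajectories also correlate frames in time, while the generator's tail
dynamics are memoryless.

## Problem sizes used in tests and the acceptance script

The motif-recovery study uses 1000 lipids (250 per motif, the spec of
the `motif4` fixture) with 8 frames of tail dynamics; the SSIM stage
computes all 499 500 pairs. Parameter-recovery studies use 600 lipids ×
1000 frames (a 500 ns window, ~9 slow periods) for the glycerol round
trip and 800-point decay curves for direct fits. Geometry orderings use 4×36-lipid stacked systems. These
sizes keep the full battery in the minutes range on a single CPU while
leaving each estimate's sampling error well inside the asserted
tolerances.
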