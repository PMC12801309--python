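# Methods

This note records the models, conventions and numerical choices behind
`cdnakit`, and what its synthetic tests do and do not demonstrate.

## Units and conventions

All in-memory lengths are nm, angles degrees; PDB/XYZ files are Å on disk
and converted at the boundary.  Residues are 1-based, frames 0-based.
Van der Waals radii are the Bondi set (C 0.170, N 0.155, O 0.152, H 0.110,
P 0.180 nm), overridable per call.  Frame triads store axes as columns;
rotations are proper throughout (the Kabsch branch with det = −1 is
rejected explicitly, and near-collinear point sets fall back to a flagged
translation-only fit).

## Carbon-dot models

A CD layer is a member of the coronene homologous series: the ring-order-n
flake has 6n² carbons and 6n edge hydrogens, generated from the honeycomb
lattice by collecting the vertices of all hexagons whose centres lie within
hexagonal ring n−1 (1, 7, 19, 37 … hexagons).  With the default C–C bond of
0.142 nm the circumcoronene (n = 3) flake spans 1.238 nm atom-to-atom
(brute-force maximum over all pairs).  Layers stack on a common axis at
0.35 nm spacing (graphitic), with an alternating one-bond in-plane offset
(AB-like registry; AA available).  Reported *effective* dimensions add one
carbon vdW diameter (0.34 nm): the five-layer stack [2,3,3,3,2] is
4×0.35 + 0.34 = 1.74 nm tall and 1.238 + 0.34 ≈ 1.58 nm across; the
seven-layer stack [3,4,5,5,5,4,3] is 2.44 nm tall.

Functionalization replaces randomly chosen edge hydrogens (uniform, without
replacement, fully determined by the seed) with idealized groups: NH₃⁺
(C–N 0.147 nm, tetrahedral hydrogens, +1 e on N) or COO⁻ (C–C 0.152 nm,
C–O 0.126 nm at ±120°, −1 e on one oxygen).  No relaxation is performed —
these are analysis inputs, not force-field topologies.  When a coverage
fraction is given instead of a count, the denominator is all perimeter
carbons (H-bearing edge plus junction carbons); at 10 % this yields 13
groups on the five-layer CD, so explicit counts (9, 11, 26) are used to
reproduce the catalogued CD⁺/CD⁻/CD7⁺ models — a random builder with ~10 %
coverage naturally scatters around these values.

## Nucleotide templates and the synthetic generator

Bases are embedded as planar coordinates in the standard base reference
frame (origin at the pairing centre, x toward the major groove, z along
the stack).  The sugar + reduced backbone (P, O5′, C5′, ring, O3′) is one
canonical, letter-independent coordinate set: the ribose ring is built
with a prescribed Altona–Sundaralingam pseudorotation (C2′-endo, P = 162°,
τm = 36°, solved numerically from the displacement pattern), the glycosidic
torsion is anti (χ ≈ −105°), and the phosphorus is pinned at a B-like
cylindrical position (r = 0.95 nm, azimuth 75°).  Making the backbone
letter-independent keeps groove widths exactly sequence-uniform on ideal
duplexes.  The absolute coordinates are idealizations; because the
generator and the analyzer share the same templates, parameter round-trips
are exact by construction, which is the property the tests rely on.

Duplexes are grown by composing base-pair mid-frames with the requested
step parameters (defaults: B 34.3°/0.338 nm — the 10.5 bp/turn solution
value — and A 32.7°/0.281 nm) and splitting each mid-frame into the two
base frames with the requested intra-bp parameters; the second strand is
the 180°-about-x flip.  Per-bp overrides are applied in exactly the frame
convention the analyzer inverts.  3′ overhang bases are generated bare
(base + C1′ only), mimicking a frayed end and leaving the stacking face
clear.  The nucleosomal superhelix places bp frames on the left-handed
curve (defaults: radius 4.18 nm, pitch 2.39 nm, 1.7 turns, 146 bp, local
twist 35.3° per step — canonical nucleosome values; the source study gives
none).  The two-tetrad mock arranges eight guanine bases in two stacked
C4-symmetric quartets 0.34 nm apart; it carries quartet annotations but no
Hoogsteen geometry or backbone — enough surface for stacking analysis,
nothing more.

CD poses are rigid placements: groove modes approach along ±x of the
anchor bp frame to vdW contact (bisection on the minimum gap ratio
d/(rᵢ+rⱼ) to 1.0); the backbone mode rides a phosphate edge-on (stacking
axis along the helix); stacking modes put the nearest flake plane parallel
to the target ring plane at the requested separation (0.34 nm default),
centred laterally, with a deterministic azimuthal spin search if an edge
group clashes; unbound places the CD ≥ 2 nm from every NA atom.  Poses are
rejected if any pair overlaps below 0.8 (rᵢ+rⱼ).  Trajectories add seeded
per-atom isotropic Gaussian noise (frame 0 noise-free); a binding event
moves the CD linearly from bulk into its pose over 10 frames.

## Analysis conventions

*Base frames* are Kabsch fits of the standard base (ring atoms + C1′) onto
observed residues; fit RMSD is reported and is ~0 on generator output.
*Intra-bp and step parameters* use the mid-frame hinge decomposition
(flip the partner 180° about x; hinge angle split half-and-half; twist
about the mid z; roll/tilt from the hinge-axis phase; translations in the
mid frame) — the convention of the common structural-DNA tools, so signs
transfer.  *bp/turn* is 360°/mean twist.  *Backbone torsions* are the
standard four-atom dihedrals; *sugar pucker* uses the
Altona–Sundaralingam phase/amplitude from ν₀…ν₄.  *Groove widths* are
cross-strand P–P distances at sequence register ±3, smaller = minor,
larger = major, each minus a 0.58 nm phosphate correction; termini lacking
the register get no value.

*SASA* is Shrake–Rupley with a deterministic Fibonacci sphere (default 960
points/atom, probe 0.14 nm); results are bit-reproducible, converge to
<1 % against 3840 points on the five-layer CD, and are rotation-invariant
to sampling resolution (~1 %), not machine precision, because the point
set is space-fixed.  *Contact area* is SASA(A)+SASA(B)−SASA(A∪B), clamped
at 0.  *Hydrogen bonds* use donor–acceptor ≤ 0.35 nm and D–H···A ≥ 135°
(a common trajectory-analysis default; the source study names none).
*RDFs* are normalized by the ideal-gas shell density of the partner group
within the analysis sphere — the natural convention for finite,
non-periodic synthetic systems (periodic simulation boxes would use the
box density instead).  *Stacking* fits both ring planes by SVD and gates
separation ∈ [0.25, 0.45] nm, normal angle ≤ 30°, lateral offset
≤ 0.20 nm; CH–π edge contacts fail the offset gate and are reported as
contact, non-stacking.

### Binding-mode classifier

Visual mode assignment does not transfer to code, so the decision
procedure is this package's own: (1) frames with minimum CD–NA heavy-atom
distance > 0.50 nm are unbound — the gate sits a few noise lengths above
vdW contact (~0.34 nm) and far below any genuinely detached placement;
(2) stacking geometry is tested against annotated quartet, unpaired and
terminal-bp ring systems, in that precedence, using the nearest CD layer
as the partner plane; (3) otherwise the azimuth of the contact centroid in
the nearest bp frame decides: |az| ≤ 50° major groove, |az| ≥ 115° minor
groove, backbone between (phosphates sit near ±75°).  Contact counts
against the chemical minor-edge/major-edge/backbone atom sets are kept in
the evidence record; they were found non-discriminating for a flat rigid
CD, which touches mostly phosphates whichever groove it faces.  The
dominant mode of a trajectory is the modal label over the trailing 20 % of
frames, echoing late-window averaging of long simulations.  Planted-pose
recovery is exact at zero noise and 140/140 trajectories at σ = 0.05 nm
across all seven modes.

### CD shape, nucleosome metrics

Layer descriptors come from per-layer SVD plane fits, all referenced to
the middle layer: tilt (normal–normal angle), in-plane rotation of an
internal marker (layer centroid → lowest-serial edge carbon) relative to
the middle layer's marker and to frame 0, lateral offset perpendicular to
the middle normal, undulation (out-of-plane RMS), and adjacent-centroid
interlayer distances along the middle normal.  The reference normal's sign
follows the first→last layer direction, so every descriptor is invariant
under global rigid motion.  Detachment is an outer layer whose
nearest-neighbour centroid distance exceeds 0.60 nm for ≥ 5 consecutive
frames — a qualitative observable given a concrete, documented gate.

Gyre distances: for each bp, the minimum centre-of-mass distance to any bp
more than 10 bp away in sequence (COM over all atoms of both residues).
On a straight helix this is (exclusion+1)·rise exactly; on the 146-bp
superhelix the minimum is ≈ the pitch, low by up to ~0.2 nm because bp
COMs ride up to ~0.2 nm off the ideal path with the backbone mass
distribution.  RMSF superposes all frames on the raw time-average of the
alignment selection (permutation-invariant by construction; the CD is
excluded by default so a binding event cannot drag the fit) and reduces to
σ√3 for isotropic per-coordinate noise.  Event-aligned RMSD takes the
event frame from the first ≥10-frame persistent bound state of a
classifier timeline and compares per-residue RMSD of the pre- and
post-event windows against the pre-event average; the whole protocol is
package-defined.

## Problem sizes and determinism

Synthetic studies use 12–20 bp duplexes, 25–60 frame trajectories,
σ ∈ {0, 0.05} nm, 20 seeds per planted mode, and a 501-frame run for RMSF
calibration — sizes chosen so planted-truth statistics are stable while a
full suite plus the acceptance script completes in about a minute.  All
randomness (functionalization sites, trajectory noise, pose jitter) flows
from explicit integer seeds; same seed ⇒ bitwise-identical output.

## Known limitations

* Rigid poses cannot reproduce ensemble contact statistics: a flat CD
  touches a curved duplex near-tangentially, so a groove pose here buries
  *less* area than a terminal stack, whereas relaxed simulation ensembles
  (CD and DNA mutually adapted) show the opposite ordering.  Contact-area
  comparisons across modes should only be made within one placement
  convention.
* The synthetic noise model is isotropic and uncorrelated; real
  trajectories have collective motions, solvent damping and sequence
  effects.  Passing planted-truth tests shows the estimators are correct,
  not that real data are this easy.
* Base templates are idealized; absolute helical parameters from
  *external* structures carry template error of order 0.01 nm / 1°,
  while generator round-trips are exact.
* No mmCIF or binary trajectory formats, no periodic-boundary imaging, no
  energetics; the histone core is not modelled (gyre metrics only need
  the DNA path).
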