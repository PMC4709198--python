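# Methods

This note records what `amphitraj` computes, the conventions it adopts where
the underlying quantities admit more than one reading, and what the
synthetic test systems do and do not establish.

## Data model and geometry

Internal units are Å and ns throughout; conversions (GRO nanometres,
trajectory picosecond timestamps) happen only at the I/O boundary.  Boxes
are orthorhombic; triclinic inputs are rejected outright rather than
silently mishandled.  Atom indices are 0-based; residue ids are kept
verbatim from the input file because region maps (helix S1–S4 ranges, the
S3–S4 linker, extracellular halves) are naturally declared in author
numbering.  All distance computations use the minimum-image convention; the
periodic KD-tree used for neighbour search is *defined* to equal the
brute-force all-pairs computation and is property-tested against it.

Roles (protein / lipid / ligand / ion / solvent) are assigned from a
shipped residue-name dictionary, overridable per reader call.  Unknown
residue names become `ligand` with a warning — never a silent drop, so an
unrecognised small molecule stays visible in every analysis.

## Chain descriptors

* **Deuterium order parameter.**  S_CD(i) = ⟨(3 cos²θ − 1)/2⟩ over frames,
  ligand copies and the C–H bonds of carbon i; θ is measured against the
  membrane normal, fixed to the z axis (the bilayer convention of both the
  generator and typical membrane setups) rather than fitted from lipid
  coordinates.  Explicit (pseudo-)hydrogens are required by default; an
  optional fallback uses the C(i−1)→C(i+1) axis and flags itself in the
  output, since a vector-based surrogate is not the same observable.
* **Radius of gyration** is unweighted over tail carbons only (head-group
  oxygens excluded): the quantity of interest is the shape of the acyl
  chain, not of the whole molecule.  The streaming form is checked against
  the O(N²) identity Rg² = (1/2N²) ΣΣ d²ᵢⱼ to 1e-9.
* **Head-to-tail distance** is the minimum-image distance from the
  schema-designated carboxyl oxygen (`O1`) to the terminal carbon.  Summary
  statistics pool ligands and frames by default; a per-ligand-means mode
  exists because the two averages differ when ligand counts or trajectory
  spans are unbalanced.

## Contact analysis

A residue contacts ligand part p (head or tail, by atom name from the
ligand schema) at a frame iff the minimum over (residue atom, part atom)
minimum-image distances is ≤ the cutoff (default 3.5 Å).  Distances use
heavy atoms by default — hydrogen positions are a modelling convention in
the synthetic systems and frequently reconstructed in real ones; `all` is
available.

Persistence filtering interprets "resided … for more than the threshold"
as **cumulative** occupancy (default 300 ns): contact *frequencies* are the
reported observable, and a frequency is a cumulative quantity.  A
longest-continuous-run mode is provided, and the mode in force is recorded
in the table.  The filter is strict: a row at exactly the threshold is
excluded.  Per-frame time weights are the interval to the next frame, the
last frame carrying the preceding interval (a trapezoid rule was rejected
as spurious precision on a uniform grid).  All ligand copies are pooled per
part — any copy's head counts — matching how a many-copy system is
fingerprinted; per-ligand resolution is a flag.

Region summaries report per-part counts and fractions by region, residue
chemical class (hydrophobic/polar/charged from a fixed hydropathy-style
dictionary), the tail:head row ratio, and the fraction of qualifying
residues on helices S3/S4 (with an extracellular-half variant).

## Distances, residency, RMSD

Segment-wise minimum distances support the five-part sectioning (HEAD,
TAIL-A = C2–6, TAIL-B = C7–11, TAIL-C = C12–16, TAIL-D = C17–22) and the
coarser head vs C12–22 split used to discriminate head from tail near
designated residues.  Summaries are per-subunit time means; the reported
error is the standard error across subunits (n = number of subunits), i.e.
subunits — not frames — are the independent units.  Frames are pooled
within a subunit first because frames are strongly autocorrelated.

Residency treats a probe molecule as resident while any of its atoms is
within the cutoff (default 2 Å) of the target; intervals live on the frame
grid, and a gap tolerance of g frames (default 0, strict) can bridge brief
interruptions, since interruption handling is otherwise undefined.

Backbone RMSD uses a two-pass procedure: superpose every frame onto frame 0
(unweighted Kabsch), average the superposed coordinates, then superpose each
original frame onto that average and report the RMSD.  The reference
protocol is recorded in the output; the series is invariant under rigid
motion of any frame (tested to 1e-9 against an independent quaternion
superposition).

## Density and diffusion

An occupancy grid voxelises the fraction of frames in which ≥ 1 selected
atom lies in each voxel (default edge 1 Å).  "X % occupancy" iso-surfaces
are level sets of that fraction — one defensible reading of a
viewer-dependent phrase, and the one recorded in the file metadata.  Frames
can be superposed on a protein selection before binning so the map lives in
the protein-centred frame.  Surfaces come from marching cubes; volumetric
output is OpenDX text (written by a small in-package serializer), surfaces
Wavefront OBJ.

Lateral diffusion: per-molecule centre-of-geometry xy tracks are unwrapped
across the box (valid while per-frame displacements stay below half a box
edge), optionally re-expressed relative to a reference (protein) centre,
combined into a time- and ensemble-averaged MSD with overlapping origins
(FFT algorithm, exactly equal to the direct sum), and fitted by least
squares over a lag window; D = slope/4, reported in Å²/ns and cm²/s.  The
default window is 10–50 % of the maximum lag — a conventional compromise
for real data, where short lags are contaminated by localisation noise and
fast non-diffusive motion.  For *noise-free* synthetic Brownian tracks the
statistical error of the time-averaged MSD grows with lag, so the recovery
tests fit lags at 0.1–1 % of the trajectory instead; with 8 molecules ×
10⁴ frames this recovers a planted 4 × 10⁻⁹ cm²/s to a few percent,
whereas the long-lag window scatters by tens of percent.  A log–log slope
over the window serves as a curvature diagnostic and flags super-diffusive
(drift-dominated) tracks.

## The synthetic generator

The generator emulates the *shape* of a membrane-channel system, not its
physics: a 4-subunit protein of rigid helix bundles (one backbone and one
side-chain bead per residue; S1–S4 at the corners of each subunit, loop and
linker arcs above, pore helices toward the axis), static two-leaflet lipid
rods, and amphipathic ligands with a carboxyl head triad (O1/O2/C1) and a
C2–C22 tail carrying two pseudo-hydrogens per carbon, placed perpendicular
to the local C–C–C plane.  Ground truths are planted as follows.

* **Tail disorder.**  Tail conformations are resampled each frame from a
  trans/gauche± dihedral model (bond 1.53 Å, angle 111°, gauche
  probability 0.5 × flexibility) built by internal-to-Cartesian chain
  construction, plus a whole-chain axis wobble (σ = 20° × flexibility)
  emulating molecular-axis fluctuation — without it the first two carbons
  are conformationally rigid by construction and could not disorder.  At
  flexibility 0 every dihedral is exactly 180° and S_CD is exactly −0.5 on
  every carbon; mean Rg, mean |S_CD| and the head-to-C22 distance all
  decrease strictly and monotonically with flexibility under a shared-seed
  protocol (the same uniform draws decide the dihedral states at every
  flexibility value).  The trans/gauche populations are a stand-in, not a
  claim about real torsional statistics; absolute order-parameter profiles
  of real chains are force-field-dependent and out of scope.
* **Contacts.**  Planted (chain, residue, ligand, part, intervals) contacts
  are realised by positional override: during an interval the ligand is
  laid out all-trans with its anchor atom (head O1 or terminal tail carbon)
  exactly `contact_distance` (default 3 Å) from the residue's side-chain
  bead, the chain leaving along a direction chosen from a fixed candidate
  list so that every non-anchor atom clears every other residue by more
  than the contact cutoff.  Outside planted intervals ligands are kept at
  least twice the cutoff from the protein (reflected random walk plus a
  per-frame push-out for chains that lean in).  A contact analysis at the
  generator's cutoff must therefore recover exactly the planted set —
  sensitivity and specificity 1.0, verified exhaustively for every residue
  of the default scaffold and over randomized configurations.
* **Diffusion.**  Ligand head positions follow a seeded 2-D Brownian walk
  with the planted D (default 4 × 10⁻⁹ cm²/s ≙ 0.04 Å²/ns); step σ =
  √(2 D Δt) per axis.
* **Two-state pairs.**  `generate_state_pair` plants one head contact per
  subunit at `base_distance` and `base_distance + offset` (default 0.5 Å)
  in two otherwise identical systems, so the cross-subunit HEAD
  minimum-distance shift is known exactly.

All randomness flows through a single seeded generator; identical configs
give bitwise-identical trajectories.

What passing tests on these systems shows: the *estimators* are correct —
they recover known truths exactly or within quantified statistical error.
What they do not show: anything about force fields, sampling convergence,
or the absolute values real systems would produce; the generator has no
energetics, no solvent, no protein dynamics (backbone RMSD validation uses
separately constructed perturbed trajectories), and its lipids are inert
scaffolding.

## Default problem sizes

Tests and the acceptance script run at deliberately small scale: toy
systems of ~950 protein beads, 4–8 ligands and ≤ 500 frames for recovery
and contrast checks, 100 randomized instances for oracle equivalence, and
8 molecules × 10⁴ frames for diffusion recovery.  These sizes put every
statistical check comfortably inside its tolerance while keeping the whole
battery under a minute.

## Known limitations

* Orthorhombic boxes only; selections have no distance-based terms
  ("around"-style) — analyses that need proximity go through the dedicated
  functions.
* Hydrogen-bond analysis is approximated by proximity; no donor–H–acceptor
  angle criterion is applied (none is defined for the contact fingerprint).
* Ion-mediated bridging (e.g. Na⁺ between carboxylates) is expressible
  only as two chained proximity counts, not as a joint two-step criterion.
* The plaintext trajectory dialect carries no atom metadata and exists for
  fixtures and interchange, not for large production trajectories.
* Parse errors report line numbers for the plaintext dialect; PDB/GRO
  errors surface the underlying reader's message with the file path.
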