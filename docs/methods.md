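# Methods

This note documents the models, conventions and numerical choices behind
`tcrmkit`, in the spirit of the model documentation of simulation packages:
what each stage assumes, which knobs matter, and what the synthetic-data
generators do and do not emulate.

## Structure model and chain roles

Structures are parsed with gemmi into a flat atom table keeping author
numbering and insertion codes; nothing is renumbered, because the residue
labels used in the field (e.g. light-chain Q32, HLA R65/K146/H151) are author
numbers. Alternate locations are resolved at load time to the
highest-occupancy conformer, ties broken alphabetically by alt-loc id — the
common single-conformer convention. Hydrogens are kept in the table but
excluded from all distance work by default; crystal structures at typical
resolutions are deposited without them, and including them would change
contact counts between otherwise identical depositions.

Chain roles are assigned by length/content heuristics: the peptide is the
unique polymer chain of 8–12 residues (class I groove ligands are 8–11-mers;
lengths outside that range warn), β2-microglobulin is ~95–105 residues, the
class I heavy-chain ectodomain ~270–290. The two remaining V-domain-bearing
chains are split into heavy and light by their FR4 J-segment motif (`WGxG`
heavy, `FGxG` light). Every heuristic can be overridden with explicit hints,
and ambiguity is an error rather than a guess. CDR intervals come either
from the standard Kabat/Chothia tables applied to author numbering — valid
only when the deposition is numbered in that scheme, which the user must
confirm per structure — or from manual ranges taken verbatim; the scheme used
is recorded in provenance.

## Contacts and the P/M/P-M footprint

A *contact* is an antibody-atom/target-atom pair within the cutoff,
**inclusive** at the boundary (≤ 4.0 Å by default, matching the "within 4 Å"
convention). Residue-level statements ("contacts seven MHC residues") are
distinct-residue projections of the same atom-pair set; keeping both views in
one table is what lets a single computation reproduce both per-atom tallies
and per-residue counts. The `side_chain_only` criterion — used for designs
keyed to peptide side chains — removes backbone atoms N, CA, C, O on the
*target peptide only* (glycine CA counts as side chain, since it is the
entire side chain); antibody and MHC atoms are always all-atom. OXT is not
in the backbone list, a deliberate literal reading of the four-atom backbone
definition, recorded here because terminal-carboxylate contacts would be
affected.

Published integer contact counts are sensitive to the counting convention of
the original software (CCP4 Contact vs PyMOL differ in hydrogen handling and
boundary inclusion). The package's convention is fixed and documented; when
a recomputed count deviates by one or two atom pairs from a published figure
the deviation should be reported alongside the convention, never absorbed by
retuning the cutoff.

Polar classification is geometric, not energetic: N/O–N/O pairs within 3.5 Å
are hydrogen bonds; opposite-charge side-chain group pairs (Arg/Lys/His
N-groups vs Asp/Glu carboxylates) within 4.0 Å are salt bridges, overriding
the hydrogen-bond label. No angle criterion is applied — at the resolutions
involved, donor hydrogens are not observed.

## SASA and buried surface

Solvent-accessible surface area is Shrake–Rupley sphere sampling with a
probe of 1.4 Å and a **fixed Fibonacci point set of 960 points per atom**, so
results are bit-for-bit reproducible run to run; the van der Waals radii
table (Bondi-style) is versioned with the package. An isolated atom
reproduces 4π(r+1.4)² to ~0.1%, and the implementation is cross-checked in
the tests against biotite's independent SASA to within 5%. Buried surface of
the pMHC upon antibody binding is BSA(x) = SASA(pMHC alone) − SASA(pMHC in
complex) summed over the atoms of x ∈ {peptide, MHC heavy chain};
β2-microglobulin occludes in both states but is not reported.

## Docking geometry

The groove frame is built from the α1/α2 helix Cα atoms (author-numbering
windows 50–86 and 138–176, configurable for numbering drift between
alleles): the groove axis is their first principal component, oriented from
the peptide N- to C-terminus; the normal is the smallest principal
component, oriented toward the antibody; the origin is the centroid of the
platform Cαs (residues 1–180 minus the helix windows), which sits beneath
the peptide. The antibody axis runs from the VL to the VH Cα centroid
(first ~115 residues of each chain, the V domains). The docking angle is
measured between the groove axis and the antibody axis *projected into the
groove plane*, because footprint rotation over the groove is an in-plane
notion; a projection shorter than 10⁻⁸ (antibody axis along the normal) is a
degenerate-geometry error.

The rotation between two complexes sharing an MHC scaffold superposes the
query's platform Cαs (residues 1–180, matched by author number) onto the
reference's by a least-squares rigid fit; superposition RMSD above 3 Å means
the scaffolds are not comparable and is an error. The reported angle is
between the two projected antibody axes, **positive = clockwise for an
observer on the antibody side looking down the groove normal with the groove
axis pointing peptide N→C**. The sign convention is this package's own (the
field rarely states one); magnitudes are convention-free, and
antisymmetry (swap reference and query, flip the sign) holds to 0.1°.

## Library design

The design rule is mechanical once the footprint exists: randomize class-P
positions, preserve class-M positions. Positions contacting both (P/M) are
randomized by default (`include_PM=True`) — the mouse-template design
randomized all nine peptide-proximal positions including P/M ones, while the
human-template design was described as peptide-side-chain keyed — so the
flag is exposed rather than hard-coded. Theoretical diversity is the exact
big-integer `alphabet^n`; it is deliberately labelled *theoretical*, since
published library sizes (~10⁸) are realized transformant counts, a property
of the transformation, not of the design. Oligo fragmentation and codon
chemistry are out of scope.

## Single-molecule simulator

The generator emulates the statistical structure of dual-color TIRF
acquisitions of antibody-labeled cell-surface antigens at the acquisition
settings the pipeline targets: 32 ms per frame, 150-frame stacks. Molecule
numbers are Poisson in the field area; mobile molecules perform 2D Brownian
steps (per-axis N(0, 2DΔt)) with reflective boundaries (molecules are
confined to the cell); an immobile population models surface-adsorbed
label; each tag photobleaches in a single step with geometric lifetime;
detections occur per frame per unbleached tag with fixed probability, and
localizations add Gaussian noise (default σ = 20 nm). Dual-color labeling
gives each molecule `tags_per_molecule` tags (default 2, an IgG carrying two
nanobody-binding tags; the valence is a config knob, not a measured fact)
colored independently. Everything is driven by one integer-seeded PCG64
generator with a fixed draw order, so a seed reproduces output exactly.

Not emulated: blinking photophysics (single-step bleaching only), 3D
membrane topology, intensity heterogeneity, drift, or spatially varying
detection efficiency. Passing tests therefore demonstrate correctness of
the *analysis contracts* under the stated noise model, not robustness to
every artifact of real data. Movie rendering (Gaussian spots, optional shot
and read noise) exists so the spot-detection path can be exercised, but the
localization-table path is primary.

## Quantification pipeline

Linking is frame-to-frame assignment gated at `max_disp` per elapsed frame,
resolved per frame by minimal total displacement (Hungarian assignment),
with gap closing up to `max_gap` missed frames; ties are deterministic given
input order. On noiseless, well-separated input the tracker reproduces
ground-truth trajectories exactly (asserted in tests).

Immobile background removal is a track-level median rule: a track is
immobile when ≥ 80% of its localizations lie within `immobile_radius`
(default 75 nm) of its median position. This replaces the spatiotemporal
clustering of the original analysis chain with a simpler rule having the
same contract — remove stationary adsorbed emitters. Tracks shorter than
4 localizations are *not* classified and stay in the mobile pool: short
fragments (early bleaching, detection dropouts) are statistically
indistinguishable from immobile molecules under the median rule, and
removing them biases the early part of the decay curve downward by several
percent — measured during development and eliminated by this guard.

Counts per frame default to *track spans* (a track counts in every frame
between its first and last localization) rather than raw localizations;
spans are insensitive to the per-frame detection probability (~0.9 in the
simulated conditions), which would otherwise propagate directly into a ~10%
density underestimate. The initial mobile count N₀ is extrapolated by a
single-exponential fit N(t) = N₀e^(−kt) (nonlinear least squares,
log-linear initialization, frame 0 excluded by default since span starts
are detection-limited); a non-decreasing series returns the mean with a
warning flag instead of a fit. Bleaching in the simulator is geometric, so
the single exponential is the matched model.

The counting equations are applied exactly as printed: ρ = N₀/vCSA;
dual-color N = A + B − 0.5·AB with AB the number of cotrajectories (same-
frame pairs within 150 nm, one-to-one matched, sustaining ≥10 consecutive
steps, each underlying pair counted once); copies/cell = ρ·tCSA with tCSA
defaulting to 3900 µm² and alternatively derived from a 2D contour area by
the factor-2 rule. vCSA can be supplied or segmented from background
fluorescence (Otsu threshold on the smoothed image, largest connected
component). Channel registration fits a similarity transform to ≥3
non-collinear bead pairs; round-trip residuals on synthetic beads are below
5 nm RMS.

**Known bias of the dual-color correction.** Under stochastic two-tag
labeling, a molecule with two same-color tags produces two near-coincident
localizations in one channel, inflating that channel's count toward the tag
count rather than the molecule count; and the strict 10-consecutive-step
cotrack rule undercounts AB when per-frame detection is below 1. The
equation is implemented exactly as stated, and the pipeline quantifies its
bias against simulated ground truth (reported by `analysis/04` and the
acceptance script) instead of silently replacing the formula with an
unbiased estimator.

## Enrichment profiling and proteome scan

Position frequency matrices are computed over **unique** peptides (selection
output is clone-redundant; abundance per position is a property of distinct
sequences), with an optional pseudocount added before column normalization.
The proteome scan scores each length-L window by Σ log(freq + ε) with
ε = 10⁻⁶, optionally excluding fixed anchor positions; ranking is
deterministic with ties broken by protein id then offset. This scorer is a
simple, documented motif-match stand-in for the original target-prediction
scripts, whose algorithm is not recoverable; it is validated by
planted-consensus recovery in decoy proteomes, not by claiming equivalence.

## Problem sizes and defaults used in checks

Synthetic recovery checks run at densities 0.05/0.2/0.8 µm⁻² (the span of
densities the counting method is used for), D = 0.1 µm²/s, bleach
probability 0.02/frame, detection probability 0.9, 150 frames, 20 seeds per
condition on a 20 × 20 µm field — sizes chosen so each condition carries a
few hundred to several thousand molecules while a full run stays fast on one
CPU. Mean recovered density is within a few percent of truth (the
acceptance band is 10%). The photobleach-extrapolation check uses N₀ = 200
tags over 20 replicates (within 5%). The structural suite runs on planted
toy complexes where counts are exact by construction; the deposited-entry
worked examples additionally require the cached coordinates described in the
README.
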