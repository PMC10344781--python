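# tcrmkit

Computational toolkit for **structure-guided re-engineering of TCR-mimic
(TCRm) antibodies** and for **counting antigens on cell surfaces by
single-molecule imaging**.

TCRm antibodies bind a peptide presented by an MHC class I molecule the way a
T-cell receptor does. A TCRm template with a canonical, TCR-like docking
footprint can be repurposed toward new peptides by a simple structural rule:
**randomize the antibody positions that contact the peptide, preserve the
positions that contact the MHC helices**. This package implements the
computations that support such a campaign, plus the downstream quantification
of how many antigen copies the resulting antibody finds per cell:

- `tcrmkit.structure` — PDB/mmCIF parsing (via gemmi), chain-role assignment
  (MHC heavy chain, β2-microglobulin, peptide, antibody heavy/light) and CDR
  annotation in author numbering.
- `tcrmkit.footprint` — atom-pair contacts within a cutoff (default 4 Å,
  inclusive, hydrogens excluded), classification of antibody residues as
  peptide (P), MHC (M) or both (P/M), per-CDR and per-MHC-residue contact
  shares, polar-contact calls, and buried-surface decomposition via a
  deterministic Shrake–Rupley SASA.
- `tcrmkit.geometry` — a groove-fixed frame from the α1/α2 helices, the
  docking angle of the antibody axis over the groove, and the signed in-plane
  rotation between two complexes sharing an MHC scaffold.
- `tcrmkit.library_design` — the randomize-P / preserve-M rule and exact
  theoretical diversity `alphabet^positions`.
- `tcrmkit.toy_complex` — synthetic antibody–pMHC complexes with *planted*
  contacts, so every structural operation is testable against known truth.
- `tcrmkit.smlm` — single-molecule simulation and quantification:
  Brownian/bleaching/dual-color simulator, trajectory linking, immobile
  background removal, photobleaching extrapolation of the initial mobile
  count N₀, and the counting equations

  ρ = N₀ / vCSA  (surface density),
  N = A + B − 0.5·AB (dual-color correction),
  copies/cell = ρ × tCSA (default tCSA = 3900 µm²),

  with colocalization at a strict 150 nm threshold and a minimum of 10
  consecutive cotracked steps.
- `tcrmkit.profiling` — position frequency matrices over unique selected
  peptides, a log-frequency proteome scan, and the reporter-assay
  cytotoxicity formula.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end and write
their tables to `results/`. For example, antigen counting on a simulated
dual-color dataset (`analysis/03_simulate_imaging.py` then
`analysis/04_antigen_density.py`) prints:

```
{
  "A_channel1_N0": 24.228124949065663,
  "B_channel2_N0": 34.66925807117566,
  "AB_cotrajectories": 4,
  "dual_corrected_count": 56.89738302024132,
  "vCSA_um2": 100.0,
  "density_per_um2": 0.5689738302024132,
  "per_cell_at_tCSA_3900": 2218.9979377894115,
  "true_mobile_molecules": 30,
  "count_bias_vs_truth_pct": 89.6579434008044
}
```

A and B are the photobleach-extrapolated initial mobile counts in the two
spectral channels, AB the number of cotrajectories (≥10 consecutive
colocalized steps within 150 nm). The density is the corrected count divided
by the visible cell surface area, and the per-cell figure scales it by the
mean total cell surface area. The bias line compares against the simulation's
ground truth: with stochastic two-tag labeling, molecules carrying two
same-color tags are counted twice within a channel, so the printed correction
over-counts — the simulator makes that bias measurable (see
`docs/methods.md`).

The footprint/design stage (`analysis/01_footprint_and_library.py`) prints
the P/M/P-M classification table and the resulting library plan, e.g. on the
synthetic planted complex:

```
residue  cdr  class  n_pep  n_mhc  peptide_positions
H53   H2   M         0     1
H98   H3   PM        1     1  P6
H100  H3   P         1     0  P5
L27   L1   P         1     0  P2
L32   L1   P         4     0  P4,P5,P7,P8
L50   L2   M         0     2
```

→ 4 positions randomized (P and P/M), 2 preserved (M), theoretical diversity
20⁴ = 1.6 × 10⁵.

## Deposited structures

The structural worked examples run on the deposited complexes 3CVH
(25-D1.16–OVA/H2-Kb), 3GJF (3M4E5–NY-ESO1/HLA-A*02:01) and 7TR4
(MA2–MART1/HLA-A*02:01). Coordinates are not bundled; cache them once with

```bash
python scripts/fetch_structures.py        # requires network access
```

after which `analysis/01`, `analysis/02` and the structural acceptance checks
operate on the real interfaces (peptide-contact position counts, distinct
contacted HLA residues, hotspot contact shares, and the template-to-
reengineered docking rotation).

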