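# Methods

## Scope and model

`epimap` analyses the immunological surface of small globular allergens
from two kinds of input: a 3D structure (fixed-column PDB) and a multiple
sequence alignment of isoforms. The central quantity is per-residue
*relative* solvent accessibility, which drives conformational epitope
prediction and gates antigenicity region calls; alignment statistics
quantify how isoform polymorphism redistributes over those surfaces.

## Solvent accessibility

Per-atom SASA uses the Shrake–Rupley construction: each atom's
solvent-expanded sphere (van der Waals radius + probe radius, probe
1.4 Å = water) is sampled with a deterministic golden-spiral point set
(default 960 points, seed-free), and the accessible fraction is the
fraction of points outside every neighbouring expanded sphere. The point
set is global (it does not rotate with the body), so rigid motion can
change an atom's area by up to the sampling tolerance; with 960 points
this is ≤ 1% of the sphere area, and the two-sphere closed form is
reproduced to < 0.5%. Radii are element-based Bondi-style values
(`data/atomic_radii.tsv`, configurable).

Residue SASA is the sum over the residue's atoms (conserving the atom
total exactly). Relative SASA divides by the residue type's Gly-X-Gly
tripeptide standard-state area; we ship the Miller et al. (1987) table as
the default and keep the table configurable, because published relative
accessibilities depend materially on which reference table a tool used.
Values above 100% occur at termini and protrusions and are *not* clamped;
classes are computed from the unclamped value. Class thresholds: buried
< 20%, partially accessible ≥ 20%, surface ≥ 25%, protruding > 75%.

## Conformational epitope prediction

Three rules, applied in order on one chain:

1. **Centers.** Residues with relative SASA strictly > 75% seed epitopes.
   Centers closer than 0.5 nm combine into one epitope; combination is
   single-linkage (chains of close centers merge transitively — the rule's
   published wording does not specify chaining, and single linkage is the
   only transitive closure of the stated pair condition).
2. **Expansion.** Every residue with relative SASA strictly > 20% whose
   distance to *any* residue of the center group is < 1 nm joins the
   epitope. The 1 nm radius reflects the typical footprint of an
   antigen–antibody contact surface. Distance is Cα–Cα by default;
   minimum heavy-atom distance is available (`distance_basis`).
3. **Gap fill.** A single residue whose both sequence neighbours (chain
   file order) are members is added. The rule applies once, after
   expansion, and only to gaps of exactly one residue.

Epitopes are numbered ascending by their smallest center residue number
(author numbering). Distinct epitopes may share expansion members but
never centers. All threshold comparisons are strict, matching the
wording of the rules ("> 75%", "> 20%", "closer than 0.5 nm"); boundary
ties therefore fall outside.

A built-in `parameter_sweep` reports epitope counts and size ranges
across exposure configurations (e.g. alternative reference tables) and
parameter sets, since the prediction is sensitive to the GXG table and
distance basis.

## Variability and variant tables

Wu–Kabat variability per alignment column: `V = N·k/n` over non-gap
residues (gaps excluded from all three counts; configurable behaviour was
considered and rejected to keep V ≥ 1 interpretable). Because raw V is
bounded below by 1 while the published low/intermediate/high convention
places a class boundary *below* 1, the classification index normalises by
the per-alignment median: `viv = V / median(V)`, class low < 1 ≤
intermediate ≤ 3 < high, with `viv = 1` documented as intermediate. Raw V
is always reported alongside; the normalisation is this package's
documented stand-in for an index whose published definition is not
available, and downstream analyses should treat the classes, not the
numeric viv, as meaningful.

Region variants are keyed by the alignment columns spanned by the
reference-coordinate region, so indels inside a region appear as
length-variant strings. Sequences with unknown residues (X) in the region
are excluded and logged. Suffix 0 is the designated template's variant;
suffixes 1..m order the rest by descending frequency, ties broken by
first occurrence in input order. Frequencies are unweighted sequence
counts over the included sequences and sum to 100% ± 0.01.

T-cell (HLA-DR class II) anchor positions are *inputs* (matrix-based
anchor prediction is out of scope); the anchor matrix reports per-group
presence frequencies with classes high (> 70%), low (< 30%, present),
absent (0%), intermediate otherwise, and shared/specific flags (high in
all groups / in exactly one).

## Antigenicity profiles and regions

Profiles are windowed means (default window 7, odd, configurable per
scale) of three published per-residue scales shipped as data files:
Kyte–Doolittle hydropathy, Welling antigenicity, Parker hydrophilicity.
Terminal positions average over the truncated window and are flagged, as
are windows containing X (excluded from the mean). "Antigenic direction"
is value > 0 for Welling and Parker and value < 0 (hydrophilic) for
Kyte–Doolittle; no numeric cutoffs beyond the sign are imposed. A
position is positive when ≥ 2 scales agree (configurable); maximal runs
of ≥ 5 positives become regions labelled A1, A2, ... left to right; with
exposures supplied, a region must additionally have mean relative SASA
> 25%. The exact published combination rule for such regions is not
stated anywhere we could verify, so region boundaries should be read as
operational, not canonical.

## Structure comparison

Superposition is least-squares (Kabsch) with a proper rotation enforced,
delegated to Biopython's SVD superimposer behind the package interface.
Chain pairs are mapped by global sequence alignment (match +1, mismatch
0, gap −1, configurable) with Cα pairs taken at aligned non-gap columns;
by default all mapped pairs enter the fit (no outlier rejection), with an
optional iterative 2σ trimming mode that mimics the refinement cycles of
interactive alignment tools. Both modes are exposed because published
inter-template RMSD values depend on which residues a tool kept.

Disulfide screening lists all cysteine Cα–Cα distances; the feasibility
window 3.0–7.5 Å brackets canonical cystine stereochemistry (~4.5–6.5 Å)
with margin. Charge summaries count Asp/Glu as −1 and Lys/Arg as +1,
histidine optional and off by default, termini ignored — the only
bookkeeping that makes count-based percentages self-consistent.

## Linear/conformational overlap

Linear epitopes are localised by exhaustive ungapped Hamming scan (best
mismatch count, ties leftmost, default tolerance 2), never by foreign
sequence coordinates — the monoclonal-defined profilin epitopes were
characterised on a different (sunflower) profilin whose numbering does
not transfer. T-cell epitopes are 9-mers from the anchor start (length
configurable). Overlap of a conformational member set with a mapped span:
*total* when the span is fully contained in the member set, *none* when
disjoint, *partial* otherwise; the reverse containment (conformational
epitope inside a longer linear span) reports partial with full shared
count. Rollups per conformational epitope: overlaps-B-only /
overlaps-T-only / both / neither.

## Synthetic data

`make_globule` builds idealized single-chain models rather than
physically realistic folds, because every algorithm under test depends
only on distances and exposure: a densely packed spherical shell
(~22 Å² of shell surface per residue) of two-atom residues whose mutual
occlusion pins them between the 20% and 75% thresholds; designated
residues displaced 7 Å outward (their vacated shell slot kept filled by a
dummy atom so neighbours stay occluded) are provably protruding; cysteine
pairs are placed at exact Cα separations just off the shell; an optional
core residue is caged by an icosahedral shell of dummy atoms at 2 Å
carried by its sequence neighbours, which occludes a probe-expanded
carbon sphere completely (any sphere point is within 37.4° of a cage
direction, hence inside a cage atom's expanded sphere). Ground truth
(planted protruding residue numbers, exact pair distances, buried
residue) is emitted alongside and is recovered exactly by the pipeline in
the test suite and acceptance script.

`make_msa` plants region variants at exact largest-remainder quota counts
(ties by entry order), shuffles assignments with the seed, and swaps one
assignment so the first record always carries the template variant in
every region (preserving counts). Variants must keep the region length —
planting indels would require an explicit gap-column convention the
generator does not define; indel *analysis* is still covered because
`extract_region_variants` operates on alignment columns. Both generators
are deterministic under (spec, seed) down to byte-identical output files.

What the synthetic data does not emulate: real packing irregularity,
side-chain rotamers, correlated substitutions between regions, or
phylogenetic structure among sequences. Passing tests therefore
demonstrate algorithmic correctness against the stated definitions, not
predictive accuracy on crystal structures.

## Problem sizes and numerics

Tests and the acceptance script run the SASA engine at 240–960 sphere
points and globules of 30–100 residues — sizes chosen so the full suite
exercises ~100 seeded structures while each oracle comparison stays
exact. Variant recovery is checked at 10 000 sequences. All randomness
flows from explicit seeds (`numpy.random.default_rng`); no global RNG
state is touched. PDB coordinate round-trips are exact to the format's
3-decimal precision, which bounds planted-distance recovery error by
~0.002 Å against the ±0.01 Å contract.

## Known limitations

- The two structure-level results on the profilin crystal templates
  (epitope counts 11/9/10 and inter-template Cα RMSD 0.79/0.79/0.87 Å)
  require the PDB entries 1g5u/1cqa/3nul, which are not redistributable
  with the package; the corresponding acceptance tests fail with an
  explicit message until the files are placed under `tests/data/pdb/`.
  Reproducing those numbers also depends on the GXG table and the
  superposition residue set of the original tools (GETAREA, PyMOL), which
  are not fully specified; the parameter sweep and trimming option exist
  to probe that sensitivity.
- The median-normalised variability index is a documented stand-in (see
  above); published per-residue variability classifications are not
  reproduced claim-for-claim.
- Antigenic region boundaries are operational (sign-based support rule);
  they are not calibrated against experimentally mapped epitopes.
- mmCIF input, NMR ensembles beyond single-model selection, electrostatic
  potential maps and HLA-DR binding prediction are out of scope.
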