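# Methods

This note records the models, conventions and numerical choices behind
`mtoc-atlas`, what the synthetic generators do and do not emulate, and the
design decisions taken where the procedures admitted more than one reading.

## Ortholog conservation mapping

**Model.** Orthology inference itself (OrthoFinder, BUSCO, HMM/BLAST
curation) is upstream of this package; the pipeline consumes its tabular
outputs. The bespoke steps implemented here are:

1. *BUSCO filter*: species with completeness strictly below the threshold
   (default 80%) are removed; a species exactly at the threshold is kept.
2. *Anchoring*: a bait cluster anchors every orthogroup containing at least
   one exact (species, protein) bait member. Matching is by identifier, not
   sequence similarity — curation happened upstream, so the curated IDs are
   the ground truth here. Unplaced baits give an empty merged orthogroup
   and are reported, not raised.
3. *Merging and fragment filtering*: the merged orthogroup is the union of
   the anchored orthogroups' members; members shorter than
   `fraction × mean(bait lengths)` (default fraction 0.5, arithmetic mean,
   lengths in residues, strict `<`) are removed. The filter is applied
   *before* species presence is scored, and this ordering is written to the
   output metadata: the filter exists to stop protein fragments from
   counting as presence, so a species whose only members are fragments
   scores absent.
4. *Binarization and clade rollup*: presence means ≥ 1 post-filter member;
   a clade is present iff any member species is. Outgroup species keep
   their own columns, placed first; rows are ordered by bait category.

No cap is imposed on how many orthogroups one bait may anchor. Overlapping
bait clusters that anchor the same orthogroup are allowed and produce rows
sharing members, with a warning.

**Invariants.** Protein counts are conserved per merged orthogroup
(members + filtered = anchored union); loosening either threshold never
removes proteins or species; merging is idempotent on its own output.

## Synthetic proteomes

`gen_proteome_set` plants families directly in the orthogroup table —
protein sequences are random amino-acid strings labelled by family, because
the downstream steps act on tabular orthology, not on similarity. Per
family the generator can plant:

- *clade-structured loss* (the family absent from whole clades);
- *over-splitting* into 2–3 orthogroups. Every split part retains at least
  one bait-species member: in real curation, over-split orthogroups are
  only discoverable because the curated baits span them, so an unanchored
  split part would model a curation failure, not an orthology-pipeline
  artifact;
- *fragment contamination*: one member replaced by a fragment strictly
  shorter than 50% of the family's bait mean length, giving the length
  filter an unambiguous target. Truth presence (`present_in`) counts only
  full-length members, so the matrix comparison checks that fragments never
  create presence.

Bait clusters hold 2–5 full-length members from designated bait species
(default: the two outgroups; analyses that plant 3-way splits add one
in-clade species, mirroring curated baits that include chytrid members).
BUSCO scores are sampled in a configured range with designated species
forced below any requested threshold. All outputs (FASTA per species,
`Orthogroups.tsv` dialect, BUSCO TSV, clade map, bait FASTAs + YAML
category map, truth JSON) are byte-deterministic for a fixed seed.

## Synthetic centriole volumes

Scenes are rendered on a (z, y, x) voxel grid (physical units nm; isotropic
by default, anisotropic z supported since real confocal stacks use 0.4 µm
z-spacing). Each centriole is a filled cylinder drawn at its *expanded*
size (length × E, width × E for expansion factor E). Edges are
anti-aliased with a one-voxel linear ramp centered on the true surface so
that the half-intensity level sits exactly on the geometric boundary —
without this, voxel quantization of the circular cross-section biases FWHM
width measurements by up to one voxel per side. The volume is then
convolved with an isotropic Gaussian (`psf_sigma`, default 90 nm) as a
point-spread proxy, and noise is added: Poisson shot noise (optional,
`photons_per_unit`) plus Gaussian read noise (`read_sigma`; SNR 10 means
read_sigma = 0.1 at unit signal amplitude). Optional curved microtubule
bundles are quadratic Bézier tubes radiating from the first centriole.
Cylinders extending outside the volume raise an error naming the centriole;
rendered widths under 3 voxels are rejected as unmeasurable. TIFFs are
32-bit float with ImageJ-style voxel-size metadata and round-trip through
`read_volume`.

What the simulator does **not** emulate: realistic vectorial optics,
centriole wall substructure (triplet microtubules, cartwheel), rhizoids or
cell walls, stage-dependent background. Passing recovery tests therefore
show that the *measurement chain* is unbiased on idealized barrels, not
that it would segment real micrographs (detection in real data stays
manual, as does TEM distal-endpoint fiducial choice — TEM-mode inputs are
pre-measured CSV tables).

## Morphometry conventions

- *Linescans* mirror an image-tool line profile: both endpoints must share
  a z-plane; samples are bilinearly interpolated at ≤ half-voxel spacing
  and averaged over `width_px` one-pixel-spaced perpendicular offsets.
- *Normalization*: subtract the profile minimum, divide by the largest
  difference; flat profiles are an error, not NaN.
- *Extent*: manual endpoint calls are replaced by an operational edge rule
  — the distance between the two outermost half-height crossings of the
  normalized profile, linearly interpolated (background-anchored FWHM).
  The rule is recorded in output metadata. Width is measured on a
  perpendicular scan at the longitudinal midpoint (the barrel position for
  width is otherwise unspecified).
- *Expansion factor*: ratio of mean U-ExM width to mean TEM width
  (ratio-of-means; a mean-of-ratios variant is switchable and the choice is
  flagged). Spread is first-order error propagation of the two sample SDs,
  reported as mean ± std.
- *Angles*: each line's angle to horizontal in (−180, 180] (image
  convention, y down); the centriole–spindle angle is ||θ_c| − |θ_s||,
  folded to 180 − x above 90°. This reproduces the reading-off-the-tool
  procedure including its known quadrant assumption: the value is only a
  geometric inter-line angle when both lines read out with the same sign,
  which the tests respect. Centriole "1" of a pair is the member with the
  smaller spindle angle; ties go to the first-listed member and are
  flagged.
- *Bundle classes*: filaments (polylines or connected supra-threshold
  components) count as bundles when they intersect a spherical shell
  (configurable inner/outer radius, default 500–5000 nm) around the MTOC;
  at metaphase, filaments entirely within a cone (default 30°) around the
  spindle axis are treated as gathered into the spindle and excluded.
  Counts 0 / 1 / ≥2 map to no / single / multiple bundles; the exact count
  above 1 is deliberately not reported.
- *Summaries*: sample SD (n−1), SEM = SD/√n.

## Expression-stage math

FPKM tables are gene × (stage, replicate) with the four lifecycle stages in
fixed order. A gene is "expressed" at a stage when its replicate-mean FPKM
is strictly above the threshold (default 1.0) — the mean-vs-any-replicate
choice is a declared convention. The heatmap transform is
ln(x + pseudocount) (default pseudocount 0 with an explicit error on
nonpositive entries), row centering, and division by the sample SD (n−1);
zero-variance rows are centered, left unscaled and flagged. UPGMA is
implemented as the literal definition — inter-cluster distance is the mean
of all pairwise Euclidean distances between original rows, recomputed each
merge, ties broken by smallest original index — because the contract here
is exact agreement with a brute-force recomputation and a reproducible
dendrogram; scipy's average-linkage implementation serves as an independent
cross-check in the tests. Per-gene heatmaps bypass clustering; group
heatmaps cluster rows and columns. Differential-expression calling is
consumed, never computed.

The synthetic generator programs per-group fold-change profiles (cilium
peaking at 17.5 h; centriole elevated at 13 h and 17.5 h; accessory rising
at ciliogenesis; housekeeping flat; stage-unique single-stage) with
multiplicative lognormal noise parameterised to unit mean, so zero-noise
tables equal the programmed means exactly.

## Problem sizes and runtime

Defaults are desk-scale: 14-species rosters (4 clades + 2 outgroups),
10–20 families, 1–20 rendered scenes of ~25 × 40 × 110 voxels at 130 nm
(U-ExM) or 25 nm (TEM-scale) voxels, 100 angle scenes, 36–100-gene
expression tables with 3 replicates. The full acceptance script completes
in a few seconds on one CPU; these sizes were chosen so each recovery
check is statistically meaningful while the suite stays instantaneous to
iterate on.

## Known limitations

- The angle convention is faithful to the manual procedure, including its
  quadrant assumption; it is not a general line-to-line angle.
- FWHM width of a blurred cylinder carries a curvature bias of order
  σ²/(2R); at the default PSF and barrel sizes this is ≈ 1% and is left
  uncorrected.
- The orthogroup generator plants identity-based orthology; it cannot
  probe sequence-similarity failure modes of upstream inference.
- `RunConfig` validation covers known keys and documented ranges only; the
  manifest records parameters and SHA-256 hashes but not library versions
  of transitive dependencies.
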