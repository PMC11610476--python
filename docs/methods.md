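# Methods

This note documents the models and procedures `zfx` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Finger grammar and scanning

A C2H2-type zinc finger is modelled purely by spacing: two cysteines
separated by *a* residues, an inner spacer (the finger "helix") of *b*
residues, and two terminal coordinating residues separated by *c*
residues. The default grammar accepts a ∈ [1, 4], b ∈ [12, 20],
c ∈ [3, 7] and terminal residues in {H, C} with at least one histidine
required per finger. The bounds are the union of the canonical consensus
(Cys-X2-4-Cys-X12-His-X3-5-His) and the degenerate fingers that occur in
the A1 four-finger template (inner spacers up to 20, terminal spacers up
to 7, terminal cysteines); a pure H/H grammar would miss the degenerate
third and fourth A1 fingers. All bounds are exposed on `FingerGrammar`
and in the run config so alternative calls can be reproduced.

Scanning is leftmost-first and non-overlapping. Where one window admits
several parses, the canonical (H,H)-terminated parse is preferred, then
the shortest, then the lexicographically smallest gap triple; this makes
the scan fully deterministic. The property test suite checks the scanner
against an independent brute-force enumeration of all grammar-compatible
residue quadruples followed by the same selection rule.

Linkers are measured between bounding coordinating residues: the residue
count strictly between the last terminal of one finger and the first
cysteine of the next. Consecutive fingers with linker ≤ 10 merge
transitively into tandem arrays (the threshold is configurable); runs of
size one are reported as isolated fingers.

## Classification rules

- **Set B** (TFIIIA-like): ≥ 6 fingers organised in ≥ 2 tandem arrays.
  A pure finger-count rule would misclassify large set-A proteins, so the
  array condition is part of the trigger; both values are configurable.
- **Set A**: any tandem array of ≥ 2 fingers (and not B).
- **Set C**: everything else with ≥ 1 finger. Zero fingers yields an
  explicit `unclassified` outcome, never a set label.
- **Set C subgroups** use the per-finger H-gap (residues between the two
  terminal coordinating residues): all 3 → C1, all 4 → C2, all 5 → C3;
  a protein mixing 3- and 4-gap fingers is the C1C2mixed subset kept
  inside C1. Pure C1 proteins take subset C1-k where k is the finger
  count. H-gaps outside 3–5 are recorded as atypical and resolved by
  majority vote with a warning — silently dropping such proteins would
  break the partition invariant.
- **A1 template**: exactly four fingers with finger 1 = CX2CX12HX3H and a
  4-residue cysteine spacer on finger 2. Subsets are decided in order:
  SATALL block → A1a; PCYCC → A1d; finger-2 inner spacer 20 together with
  finger 3 = CX2CX13HX3C → A1c; otherwise A1b. Motif priority matters
  because A1d shares the A1c finger-2 spacing.
- **A2 vs A4** is a documented heuristic (the underlying taxonomy gives
  member lists, not a rule): ≥ 3 fingers spread over more than one run →
  A2; otherwise A4, with ambiguous layouts flagged and defaulted to A4.
  Both thresholds sit in the config.
- **Q-type** (QALGGH inside a finger helix) is descriptive metadata, not
  a classification key, since it is reported for "most", not all, C1
  members.

## Physicochemical profiles

Profiles are computed with Biopython's ProtParam machinery, which uses
the ExPASy constants these attributes are defined by: average atomic
masses for MW, the Bjellqvist pKa set (including residue-specific
terminal refinements) with bisection for pI, the Guruprasad DIWV
dipeptide table for the instability index, and Kyte–Doolittle values for
GRAVY. Atomic composition is tabulated per residue in-package (C/H/N/O/S
of the free amino acid, minus one water per peptide bond). An independent
hand-written Henderson–Hasselbalch bisection serves as the pI oracle in
tests. `X` residues count toward length and composition but are excluded
from all numeric sums with a per-protein warning; any other non-standard
letter is an input error.

## Genomics

Gene names are assigned `prefix-1…N` by (chromosome, start) with natural
chromosome ordering (numeric suffix; unplaced scaffolds after
chromosomes, alphabetically). Ties on (chromosome, start) are broken by
end then gene id, with a warning. Coordinates are 1-based inclusive
(GFF3); multi-transcript genes keep the exons of the longest mRNA by
summed exon length (ties: more exons, then transcript id) — the choice of
transcript collapse is the package's own.

Tandem duplicates are same-chromosome family gene pairs with ≤ 1
intervening family gene and global protein identity ≥ 70% (both
configurable). Identity uses a Needleman–Wunsch alignment with BLOSUM62,
gap open 10, extend 0.5, and is matches / alignment length; the scoring
is pinned for determinism. Intron count is exon count − 1; subset means
are reported to one decimal.

## Expression

Expressed genes are those whose maximum FPKM across conditions strictly
exceeds 1 (a gene expressed in any stage is kept). The transform is
log2(FPKM + 1) — the pseudo-count keeps zero at zero and is the standard
resolution of log2(0). Profile grouping z-scores each gene, computes
correlation distances, builds an average-linkage dendrogram and cuts it
into k = 7 groups, mirroring the a1–a7/b1–b7 grouping convention; the
algorithm, distance and linkage are pinned in config and recorded in the
result object, as the original grouping method is not specified anywhere.
Constant rows cannot be z-scored; they are set aside with a warning and
assigned to the nearest group centroid. Group labels are ordered by the
peak position of the group's mean profile, which makes labelling
deterministic and order-invariant.

qPCR fold changes use 2^−ΔΔCt with ΔCt = target − reference per sample.
Replicates: the calibrator ΔCt is its replicate mean; fold changes are
computed per treated replicate and reported as mean ± sd, since the
original triplicate aggregation rule is not stated.

## Stress statistics

Panels are long-format (treatment, replicate, analyte, value).
Summaries are arithmetic mean ± sample sd (n − 1). Percent change is
100 × (treated − control)/control to two decimals. Letter displays run a
one-way ANOVA first (if not significant at α all treatments share "a"),
then pairwise Tukey HSD; maximal cliques of the non-significance graph
each receive one letter, issued in descending order of the clique's best
mean so the largest mean always carries "a". Tukey HSD is the pinned
post-hoc choice; the published table shows letters but names no test.
With zero variance everywhere, letters fall back to distinct means with a
warning.

Correlations are Pearson r with the two-sided t-test, computed for every
(gene, analyte) and (analyte, analyte) pair over matched sample columns.
Pairing can be replicate-level or treatment-mean-level depending on the
matrices supplied; n is recorded per pair and pairs with n < 3 are
emitted without a p-value and a low-n warning. Significance defaults to
unadjusted p < 0.05 across the grid, with an optional Benjamini–Hochberg
flag — whether the original screen adjusted is unknown, so both modes
exist and neither is claimed to be the original.

## Synthetic data

The generator's defaults are the study conditions: a 77-protein proteome
with composition A1a/A1b/A1c/A1d = 13/1/3/7, A2 = 2, A4 = 3, B = 2,
C1-1…C1-5 = 19/11/1/2/1, C1C2mixed = 2, C2 = 9, C3 = 1 (sets 29/2/46, 31
tandem-array proteins); the B architecture is the nine-finger TFIIIA
layout with linkers (20, 5, 5, 30, 5, 5, 5, 5); expression matrices
default to 77 genes with 34 planted below the FPKM threshold (43
expressed, matching the stress correlation set) and k = 7 profile
archetypes; enzyme panels default to the reference water-stress means and
sds with three replicates.

Background residues are drawn from the 18-letter alphabet excluding C and
H, so no unplanned finger can arise; motif placement is constrained
(QALGGH at the start of a helix, PCYCC with a ≥ 21-residue buffer before
the first finger) so that planted motifs cannot combine with coordinating
residues into spurious parses. Every generated protein is re-scanned and
re-classified at generation time; a mismatch raises. Flank lengths are
jittered per protein (25–60 residues) so copies are not identical.

What passing round-trip tests show: the scanner and classifier are
mutually consistent and implement the stated rules exactly. What they do
not show: real proteomes contain fingers at the edge of (or outside) the
grammar bounds, background C/H residues, and motif variants; recovery on
real data therefore depends on grammar configuration in a way the
noise-free round trip cannot probe. The FPKM generator draws Gaussian
noise on the linear scale truncated at zero and plants disjoint
archetypes; real expression has correlated noise, library-size effects
and overlapping profiles. The enzyme panel assumes Normal replicates.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: 77- and
225-protein synthetic proteomes, 1,000 random sequences (≤ 200 aa) for
the scanner/oracle comparison, 35-gene clustering matrices, 1,000
independent null pairs at n = 12 for type-I calibration, and 100
simulated panels for the letter-display pattern rate. pI bisection runs
to 1e-4 pH; reported tables round MW/pI/instability to 2 decimals and
GRAVY to 3. All randomness flows from explicit integer seeds; reports are
written in stable sort order so repeated runs are byte-identical.

## Known limitations

- The A2/A4 discriminator is heuristic; the taxonomy's original
  discriminator (and the absence of A3) is not derivable from a rule.
- Whether inter-finger distance is measured between coordinating
  residues or domain envelopes is a convention; this package uses
  coordinating residues, configurable only via the grammar/threshold.
- HMM-based detection, phylogeny, de-novo motif discovery, synteny and
  cis-element annotation are out of scope; the grammar scanner is the
  detection stage.
- The published 77-protein FASTA is not bundled; the full supplementary
  reproduction test requires downloading it (see README).
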