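# Methods

This note documents the models, conventions and design choices behind
`heg-atlas`, in the order the pipeline runs them, followed by what the
synthetic cohorts do and do not emulate.

## Coordinates, identifiers and I/O

Gene coordinates are 0-based half-open on the forward strand everywhere
inside the package; GenBank's 1-based inclusive convention exists only at
the file boundary (Biopython converts on read/write). Gene identifiers are
`<genome_id>|<locus_tag-or-index>`, unique cohort-wide without renaming the
inputs. Genomes are treated as linear in the orientation deposited; the
only re-orientation happens in the core-scaffold step (below). Compound
(join) CDS locations are rejected — the phages in scope have no spliced
genes, and silently flattening a join would corrupt coordinates. Metadata
(starter culture, factory, year) always carries all three keys, with the
string `unknown` for missing values, so downstream grouping code never
branches on key presence.

## Pairwise alignment conventions

All protein comparisons share one scoring scheme: BLOSUM62, affine gap cost
11 + k for a gap of length k (open −12, extend −1), Smith–Waterman for
similarity/classification, Needleman–Wunsch (end gaps penalized) for
distances. Percent identity is counted over all columns of the aligned
region, gap columns in the denominator; coverage of a sequence is its
aligned span divided by its length; the phylogenetic p-distance excludes
gap columns. Nucleotide comparisons (flank-to-reference) use match +2 /
mismatch −3, gap open −7 / extend −2. These are defined once in
`heg_atlas._align` and mirrored nowhere else; the test suite carries an
independently written quadratic-DP Gotoh aligner and checks scores and
kept-edge decisions against it.

## Ortholog families

An edge between two proteins requires ≥ 50% identity and ≥ 50% coverage **of
both sequences** ("bi-directional": the criterion is deliberately
symmetric; requiring coverage of only the query would glue domain-sharing
multi-domain proteins into one family). `all_vs_all_similarity` is
exhaustive by default. For cohort-scale runs the pipeline enables a word
seed (`prescreen=True`): pairs sharing no exact 5-mer are skipped. At the
identity levels that matter in a cohort (orthologs at ≥ 60% identity share
dozens of 5-mers) the false-drop probability is negligible; at exactly 50%
identity it is not, which is why the seed is opt-in rather than the
default.

Markov Clustering is implemented from scratch on the dense column-stochastic
flow matrix: self-loop per node equal to its maximum incident edge weight
(1 for isolated nodes), expansion = matrix power 2, inflation = entry-wise
power 2.0 with column renormalisation, pruning of entries below 1e-5,
convergence when the largest entry change falls below 1e-8 (hard cap 200
iterations, with a warning on non-convergence). Clusters are read as
attractor-connected components: every node whose column puts mass on an
attractor row joins that attractor, and attractors sharing members merge.
Inflation 2.0 is the customary default of MCL protein-clustering pipelines
and is exposed. Cluster ids `OC0001…` are assigned by size (descending),
then lexicographically smallest member — deterministic across runs and
input orders.

Phage clustering binarises the genome × family count matrix and runs
average-linkage agglomeration on Jaccard distances (counts carry little
signal beyond presence for these cohorts and are kept for display). Rows
are sorted before linkage, and cluster letters follow each cluster's
smallest genome id, so the labelling is invariant to input order. The
number of clusters k is always user-supplied; `suggest_k` reports a
silhouette-based suggestion but never applies it.

## Core scaffold and functional modules

Core families default to single-copy presence in 100% of genomes
(`presence_fraction` is exposed for degraded real cohorts, where 0.9–0.95
is a reasonable relaxation). The pipeline additionally excludes any cluster
containing a classified HNHE gene from the core set: a universally present
HEG — the DNA-packaging-associated one is in every genome — would otherwise
satisfy the core rule, and a mobile element cannot serve as its own
coordinate system.

Each genome's core genes are projected to a cluster sequence, rotated so the
anchor cluster comes first and reads forward (the anchor defaults to the
terminase large subunit, a universal landmark adjacent to the
DNA-packaging HNHE), and the consensus is the order seen in a plurality of
genomes; disagreeing genomes are reported with their breakpoint counts
rather than silently averaged, and a tie for plurality is an error.

Functional modules are marker-driven: terminase/portal mark morphogenesis,
DNA polymerase replication, a transcriptional regulator regulation.
Between markers of different modules the boundary sits at the midpoint of
their ranks (downstream module starting at ⌈(p₁+p₂)/2⌉); spans flanked by
same-module markers inherit the module; first and last modules extend to
the scaffold ends; a module with no marker is never assigned. No
transcriptomics is in scope, so expression-based module calls are
deliberately out.

## HNHE classification

HNHE detection and typing score each gene against three packaged reference
proteins (I-HmuI-like, PacI-like, GVE2-like). Because the true reference
sequences could not be redistributed here, the shipped FASTA
(`data/synthetic_reference_hnhe.faa`) contains **synthetic stand-ins**:
fixed-seed sequences carrying the documented catalytic geometry — on the
I-HmuI-like reference, D74/H75/N96 plus the downstream H117 that completes
the H-x(21)-N-x(21)-H motif — with a homologous catalytic segment shared
across the three families and family-specific remainders. Everything the
pipeline measures (scores, coverages, motif positions) is computed, never
looked up, so swapping in real reference sequences is a drop-in change.

The classifier replaces profile-profile search (HHPred in comparable
workflows) with deterministic pairwise scoring — the one place the package
knowingly trades sensitivity for self-containment and reproducibility.
Decision rule: candidates are genes whose annotation mentions HNH *or*
whose best reference alignment scores ≥ 75 (the floor; raw Smith–Waterman
score, calibrated so that random ~200-aa proteins sit far below and even a
20%-length fragment of a true HEG sits above). A candidate is assigned the
best-scoring family if the alignment covers ≥ 60% of the reference *and*
the motif scanner finds a spacing-valid H-x-N-x-(H/N) window (spacing
bounds [10, 35] bracket the canonical 21); reference similarity without
coverage or motif means TRUNCATED; below the floor, UNCLASSIFIED. The
motif scanner scores candidate windows by alignment to the reference
catalytic region and prefers the window consistent with that alignment's
residue mapping — raw window scores tie across windows that merely contain
the aligned region.

## Insertion loci

Each HNHE gene is walked outward along its genome's gene order to the
nearest core gene on each side; genome ends anchor as `terminus`. Flank
pairs are consolidated cohort-wide: pairs whose intervals on the consensus
order are nested merge (a genome that lost one core gene anchors to the
next one out; containment absorbs this without splitting the locus), and
the tightest observed pair names the locus. Loci are numbered H1…Hn by the
consensus position of the upstream flank — genome order, matching how such
loci are presented in the field. Truncated HNHEs are anchored and counted
per locus but do not found loci on their own (configurable); terminus-
anchored HEGs form their own loci rather than merging inward.

## Phylogeny and association

Distances are gap-excluded p-distances from global alignments (a Poisson
correction −ln(1−p) is available; the default is the plain p-distance, the
common choice for protein NJ at these divergences). Neighbour joining is
the standard Saitou–Nei agglomeration with the Q-criterion, two-point
branch-length formulas, negative branch lengths clipped to zero with the
deficit moved to the sister branch, and ties broken on the
lexicographically smallest pair of subtree-minimum labels — fully
deterministic. On additive matrices the implementation is exact (tested to
1e-9 against randomly generated additive trees and cross-checked against
scikit-bio's NJ).

Bootstrap requires an equal-length multiple alignment: columns are
resampled with replacement, distances and trees recomputed, and an internal
edge's support is the percentage of replicates containing the same
bipartition. Pairwise-distance mode has no shared column set to resample,
so bootstrap deliberately refuses unaligned input.

Tree clusters are maximal edge-sides (subtrees of the unrooted tree —
both sides of every edge are considered, so the arbitrary rooting of the
NJ representation cannot split a clade) whose leaf-to-leaf path lengths
all stay within a stated cut, named I, II, … by decreasing size. The cut
is a declared parameter, not an inferred one; the pipeline default of 0.21
sits between the within-lineage (~0.15) and between-lineage (~0.27)
distance scales implied by the generator's 8% per-level divergence.
Cluster–metadata association uses Cramér's V with a permutation p-value
((count ≥ observed) + 1)/(n_perm + 1).

## Efficiency of plaquing

Titres use only plates in the countable range (3–300 plaques, the standard
practice band; configurable), each plate contributing
plaques / (volume × 10^dilution), combined as a plaque-count-weighted mean.
EOP is the test/control titre ratio; replicate EOPs are reduced by
geometric mean (EOP is a ratio; an arithmetic option exists for comparison
with common lab practice). Real assay EOPs are recordable inputs — plaque
count tables — not constants in the code.

## The synthetic cohort generator

`SyntheticConfig` defaults describe a cohort like the real ones this
pipeline targets: 89 genomes in 3 starter-culture lineages, 40 core
families of 120–300 aa, 11 insertion loci with the GVE2-like
(DNA-packaging) locus between TerL and portal present in every genome and
a rare PacI-like locus, ~50% per-locus HEG presence otherwise, ~20%
truncation, 8% per-residue divergence applied at the lineage and again at
the genome level, and lineage-specific accessory families driving
gene-content structure. Genomes come out at ~30 kb with ~45–60 genes.
Scaled-down configurations (fewer genomes/core genes) are what the test
suite and acceptance script run; the flagship recovery run uses 20 genomes,
3 lineages, 25 core families and 4 loci.

Generator mechanics worth knowing:

* HEG ancestors are the packaged references mutated per locus by a
  family-level divergence (default 0.25), so different loci of one family
  form distinct clades — phylogenetic clusters then track loci, as
  observed in real cohorts.
* The three catalytic residues are protected from substitution at every
  mutation step (purifying selection on the active site). Without this,
  compounded divergence would destroy the motif in most copies and the
  premise that intact HNHEs carry their active site could not be emulated.
  `mutate_protein` itself is pure uniform iid substitution; the protection
  is a separate masked variant used only for HEGs.
* Truncation keeps a uniform 20–55% N-terminal fraction, which always
  removes the motif region — truncated calls in tests therefore exercise
  the coverage rule, not borderline motif loss.
* Module truth is defined by the marker-midpoint rule applied to the
  planted marker positions (truth and recovery share the geometry; the
  generator does not define a second, independent module notion).
* Back-translation uses uniform synonymous codons and random short
  intergenic spacers; accessory genes get random strands.

What the generator does **not** emulate — and what green tests therefore do
not certify about real data: insertions/deletions within proteins (all
divergence is substitution), genome rearrangements (available to tests by
editing gene lists, never drawn), codon bias and realistic intergenic
sequence, annotation errors, homing dynamics over time, and profile-level
remote homology (the classifier's floor score is calibrated against the
packaged references, not against HHPred-scale sensitivity). Recovery rates
on real cohorts will be bounded by annotation quality and by how far real
HNHEs sit from the packaged references.

## Numerical and determinism notes

Every stochastic routine takes an explicit seed (`numpy.random.Generator`);
cohorts are byte-identical across runs of the same seed. All orderings that
could depend on hash or input order are pinned (sorted ids, deterministic
tie-breaks in MCL numbering, HCL letters, NJ joins, cluster naming).
Degenerate inputs fail loudly: empty cores advise threshold relaxation,
plurality ties in core order are errors, single-category association is an
error, all-confluent dilution series are errors. Problem sizes in the test
suite and acceptance script (20-genome flagship cohort, ≤ 30-node MCL
graphs, 4–8-taxon NJ metrics, 100 bootstrap replicates) were chosen to
exercise every code path at comfortably interactive runtimes.
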