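# Methods

This note documents the models, procedures and numerical choices behind
ltrkit, and what the synthetic benchmarks do and do not demonstrate.

## Domain-vote classification and filtering

Each candidate element is translated in all six reading frames (partial
codons trimmed) and every frame is aligned locally (Smith–Waterman via
Biopython's `PairwiseAligner`, BLOSUM62, gap open −11 / extend −1) against
a reference peptide library of the five canonical LTR-RT coding domains —
GAG, AP (aspartic protease), INT (integrase), RT (reverse transcriptase)
and RNaseH — each reference labeled with its lineage and superfamily.  Per
domain class, only the single best-scoring (frame, reference) pair is
realigned with traceback and kept if it reaches ≥ 50 % identity over ≥ 30
aligned residues (both configurable; elements shorter than 3 × 30 nt are
skipped rather than rejected).

The superfamily is the majority superfamily of the hits and the lineage is
the top lineage count.  Two flags matter downstream: *chimeric* (hits from
both superfamilies) and *ambiguous* (the two most frequent lineages tie).
A strict majority with minority dissent is accepted but logged; requiring
unanimity was the plausible alternative, but plurality with tie-flagging
keeps elements whose single aberrant hit is most often alignment noise.

Filters run in a fixed order, F1 → F5, and the first failure is reported:

| filter | rejects | parameters |
|---|---|---|
| F1 | chimeric superfamily vote | — |
| F2 | tied lineage vote | — |
| F3 | length outside lineage reference ± tolerance | tolerance 0.20 |
| F4 | fewer than 3 distinct domain classes hit | — |
| F5 | nested class II (DNA transposon) insertion | ≥ 80 % identity over ≥ 80 bp |

F3's per-lineage reference lengths ship as an editable two-column TSV; the
packaged synthetic bundles write the generating profile's target lengths
there, and users curating real libraries must supply values they trust
(e.g. from the Gypsy Database).  F5's thresholds are this package's own
defaults: the nested-insertion concept constrains only "a confident local
match to a class II reference"; 80 %/80 bp is deliberately permissive for
diverged nested copies while never firing on random sequence (a chance
80-bp window at 80 % identity is ~10⁻²⁰ per position).  F5 scans each
class II reference as a semi-global infix of the element (edlib `HW`), so
it detects whole nested references; a fragmentary insertion shorter than
the reference may be missed.

## Redundancy removal

Elements are clustered by single linkage on the graph with an edge wherever
pairwise identity ≥ 90 % and coverage ≥ 95 %.  Identity is matched columns
over all aligned columns excluding terminal gap runs; coverage is the
non-terminal aligned span over the length of the shorter sequence (the
"minimum length of the shorter" convention).  Alignment is exact global
alignment by bit-parallel edit distance (edlib) with an extended-CIGAR
traceback.  Optimal global alignments are not always unique — two adjacent
substitutions can be co-optimally explained as an indel pair — so identity
is well-defined only up to a fraction of a percentage point; the clustering
thresholds sit far from the regimes where this matters.

Candidate pairs are prefiltered by shared distinct 12-mers (default ≥ 20
shared; the threshold scales down automatically for short or highly
repetitive sequences with few distinct 12-mers).  At 90 % identity two
sequences still share roughly 8 % of their 12-mers (0.9²⁴ ≈ 0.08 per
window), thousands for kb-scale elements, while two unrelated 10-kb
sequences share only ~6 by chance — the prefilter is therefore effectively
lossless at the clustering thresholds while avoiding a quadratic number of
alignments.

Each multi-member cluster is aligned center-star against its longest
member by merging the pairwise global alignments of every member to the
star.  This is exact for the near-identical copies that clustering
produces and is not intended as a general-purpose MSA; columns where all
rows but one are gaps are then removed, and the consensus takes the
plurality non-gap base per column (ties broken A < C < G < T; columns won
by a gap are omitted).  Gap-excluding plurality was chosen over
gap-including majority because a deletion present in half the copies
should not delete the column from the family representative.  Singleton
clusters pass through unchanged.  Mixed-lineage clusters emit a warning
and are labeled by the plurality lineage of their members.

## Features

The feature vector concatenates k-mer counts for k = 1…6 in lexicographic
order within each k-block (4 + 16 + … + 4096 = 5460 columns).  Windows
containing N are skipped rather than expanded over IUPAC possibilities —
deterministic and conventional.  Counts are the default reading of "k-mer
frequencies"; a per-k normalization flag (counts / valid windows) exists
for length-confounded designs.  Reverse-complement collapsing is
deliberately not applied.

Preprocessing is per-column standardization followed by PCA, both fitted
on training rows only and reused as frozen state for validation, test and
new data; refitting across splits is structurally impossible through the
public API.  Zero-variance columns are dropped (logged) before scaling.
The retained dimension is a variance fraction (default 0.95) or a fixed
count, with an optional cap.  A `whiten` option rescales PCA scores to
unit variance: raw k-mer counts give leading components with standard
deviations in the tens, which saturate a softmax output layer and stall
MSE-loss training, so the network pipeline whitens by default.  The
benchmark pipeline caps the PCA width at 128 components, which keeps the
convolutional stack's cost proportionate to the desk-scale problem while
retaining essentially all class-relevant variance.

## Classifiers

Both networks consume the (scaled, PCA-reduced) feature vector and emit
softmax probabilities over the 13 canonical angiosperm lineages — the
merged vocabulary ALE/RETROFIT, ANGELA, BIANCA, IKEROS, IVANA/ORYCO,
TORK/TAR, SIRE (Copia) and ATHILA, CRM, DEL/TEKAY, GALADRIEL, REINA, TAT
(Gypsy), with Tork+Tar, Ivana+Oryco and Ogre+Retand folded into their
merged groups and non-angiosperm lineages (Chlamyvir, Tcn1, Gymco, …)
rejected outright.

* **FNN**: dense 200–200–200 with ReLU, softmax output, mean squared error
  on one-hot targets, Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸).
  SGD (lr 0.01) is available by config.  MSE-on-softmax is the default on
  purpose; cross-entropy is one switch away.
* **CNN**: the feature vector as a single-channel 1-D signal through
  conv(100, k3)–pool(2)–conv(150, k3)–pool(2)–conv(225, k3)–pool(2)–
  dropout(0.5)–dense(128)–softmax, categorical cross-entropy, Adam
  (lr 0.001).  The 1-D single-channel layout is this package's choice of
  input tensor shape.

Training runs a fixed 25 epochs (200 via config) with mini-batches of 128
and no early stopping; the weights of the epoch with the best validation
macro-F1 are retained.  The layer stack is implemented in numpy with
explicit backprop (float32, fully seeded); a divergent (non-finite) loss
aborts with a diagnostic rather than continuing.  The data protocol is a
stratified 80/10/10 train/validation/test split, deterministic under its
seed; classes with fewer than three members fall back to proportional
random placement with a warning.

Evaluation computes the confusion matrix directly and derives per-class
precision, recall, F1 and support from it, plus macro and weighted
averages (both are reported since averaging conventions differ across
studies); tests cross-check these numbers against scikit-learn.

## Dataset comparison harness

`balanced_subsample` downsamples every (library, lineage) cell to the
global per-lineage minimum, removing abundance as a confounder.  Each
dataset then runs stratified 10-fold cross-validation over eight classical
classifiers (LR, LDA, KNN, one-layer MLP, RF, DT, NB, SVM — thin seeded
adapters around scikit-learn defaults; their internals are not part of
this package's contribution).  Inference across datasets is nonparametric:
a tie-corrected Kruskal–Wallis test over the pooled per-fold F1 scores
(with the degenerate all-identical case defined as H = 0, p = 1), followed
by pairwise two-sided Mann–Whitney rank tests with Bonferroni correction
(raw p × number of pairs, capped at 1; symmetric matrix, unit diagonal).
Normality and homoscedasticity pre-tests are deliberately not implemented:
the harness goes straight to the nonparametric path.  Fold stratification
by lineage is applied.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
assumes, with controllable strength:

* one profile per lineage: a target element length (evenly spread over
  5–15 kb across the requested lineages, so the length filter is
  exercised), a 300-nt LTR, five random 80-aa domain peptides, and 40
  enriched hexamers (weight 8 by default, disjoint across lineages);
* elements assembled as LTR + spacer/domain interleaving + LTR, spacers
  drawn from the profile's hexamer distribution, domains back-translated
  with a fixed sense-codon table, point substitutions at a configurable
  rate (3 % default), no indels;
* family structure (founder + mutated copies) for redundancy tests;
* defect classes that each violate exactly one filter: mixed-superfamily
  domains (F1), a 2+2 same-superfamily domain split (F2), 0.7×/1.3× length
  (F3), only two domains (F4), a spliced DNA-transposon decoy that is also
  emitted as the class II library (F5);
* a null mode drawing every sequence from a single profile with labels
  assigned round-robin — the exact label-signal-free control.  (Merely
  setting the hexamer weight to 1 is not a clean null: per-lineage target
  lengths and domain peptides would still leak label information through
  raw counts.)

What the generator does **not** emulate: phylogenetic autocorrelation
between lineages, codon usage, indel mutation, nested LTR-in-LTR
insertions, solo LTRs, or the severe class imbalance of real libraries.
Passing benchmarks therefore demonstrate that the pipeline's machinery is
correct and well-conditioned — filters fire on what they should, families
are recovered exactly, classifiers extract composition signal at realistic
divergence — not that real-library accuracy will match the synthetic
numbers.  Real lineages are distinguished by correlated, phylogenetically
structured composition, which is both harder (overlapping signal) and
easier (more of it) than 40 disjoint hexamers.

## Problem sizes and determinism

The standard benchmark is 13 lineages × 200 elements (2600 sequences of
5–15 kb), PCA to ≤ 128 whitened components, both networks at 25 epochs;
the redundancy benchmark is 50 families × 6 copies at 3 % divergence; the
filter benchmark is 50 seeded defect replicates plus the 12-element
fixture.  These sizes were chosen as the point where every recovery
property is measured with comfortable margins on a single CPU.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
reruns are bit-identical for data generation, splits and TSV outputs, and
reproducible to numerical tolerance for training metrics.

## Known limitations

* The domain scanner keeps one best hit per domain class; tandemly
  duplicated domains within one element are not separately reported.
* Center-star alignment degrades for clusters whose members diverge far
  beyond the clustering thresholds (not reachable through the normal
  pipeline, which clusters at 90 % identity); an external MSA can be
  substituted upstream of `trim_alignment`/`majority_consensus`.
* F5 detects whole nested class II references, not fragments.
* The pairwise-identity prefilter can, in principle, miss a qualifying
  pair of sequences shorter than ~32 nt; library elements are kb-scale.
* FASTA has no comment syntax, so provenance (version, seed, config hash)
  is embedded in the tabular artifacts and the per-stage sidecar files,
  not in FASTA outputs.
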