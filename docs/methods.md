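# Methods

`mitocompare` re-implements the analysis stages of a comparative fungal
mitogenomics study as a reusable, testable pipeline. This note documents the
models and procedures, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Annotation model and coordinates

All features live in one 1-based inclusive coordinate frame, the convention
of the GenBank flat files consumed and produced. On circular molecules an
origin-spanning interval is stored as a single `Interval` with
`start > end` and re-emitted as `join(x..L,1..y)`. Exons are kept in
transcription order (descending genomic coordinates for minus-strand
genes), so CDS extraction is "slice each exon, reverse-complement on '-',
concatenate". Translation uses NCBI genetic code 4 (TGA = Trp), the code
under which fungal mitochondrial genomes are annotated; terminal stops are
stripped, internal stops are preserved as `*` with a warning rather than
silently hidden.

Gene names are normalized through a synonym table (cytb→cob, rrnL→rnl,
nd4L→nad4L, …) so the 15 core protein-coding genes (atp6/8/9, cob, cox1–3,
nad1–6, nad4L, rps3) and the two rRNAs are comparable across records.
Intron-hosted ORFs are recognized either from their own annotation or by
interval containment within an annotated intron — containment is the only
signal available in records that do not label them.

## Composition and region partition

Strand asymmetry uses AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C),
computed on the deposited strand; a zero denominator yields an explicit
undefined flag rather than NaN. GC percent excludes N from the denominator.

The region partition assigns every genomic position exactly one of four
classes with precedence coding > RNA > intron > intergenic. Two choices
matter:

* intron-hosted ORF coding sequence counts as *intronic*, not coding —
  the published coding/intronic shares of intron-rich mitogenomes are only
  consistent under this convention;
* tRNA and rRNA genes together form one "RNA" class.

The precedence order is configurable but defaulted; totals tile the genome
length exactly by construction (checked on 200 random synthetic
annotations).

Codon usage is tallied over exon-concatenated CDSs under code 4. By
default intron-hosted ORFs are excluded (`include="all_pcgs"` adds them);
whether published tallies include them is not stated in the source
analyses, so exclusion is the conservative default.

## Repeat detection

**Maximal exact repeats** are found per orientation class by comparing the
genome against a transformed copy of itself — identity (forward), reverse,
complement, and reverse complement (palindromic) — via k-mer seeding with
left-maximality filtering and greedy right extension. A pair is reported
once (unordered, canonical order), the trivial forward self-match is
excluded, and maximality means non-extendability on either side. The
implementation is property-tested for exact equality against a brute-force
full diagonal scan on sequences up to 300 bp.

**Interspersed repeats** use a BLASTN-like engine: exact word seeds
(default word 11), ungapped X-drop extension (X=20), match +1 / mismatch
−2, and Karlin–Altschul E-values E = K·m·n·e^(−λS). λ is solved
numerically from Σ pᵢpⱼe^(λsᵢⱼ) = 1 on a uniform background (λ ≈ 1.3327
for +1/−2); K is the standard tabulated 0.621 for this ungapped scheme.
Gap open 5 / extend 2 are declared in the scoring configuration for
completeness; extension is ungapped, which recovers substitution-diverged
duplications (the planted-truth regime) without a gapped DP. The default
significance threshold is E < 1e-10. A dust-like entropy filter on seeds
(< 1.0 bit) is on by default here — AT-rich genomes otherwise drown in
homopolymer seeds — and off for exact repeats.

Circularity: the sequence is doubled for subject/query construction with
seeds restricted to the original length, so an origin-spanning repeat is
found once at full length.

Monte-Carlo calibration: on i.i.d. random sequences the mean number of
hits per sequence approximates the E-value threshold, within a factor of
three, provided the threshold's score cutoff exceeds the seed word length
— below that cutoff the detector cannot observe hits at all (the same
sensitivity floor real seeded aligners have), so the calibration property
is probed at word 8 and e = 0.02.

**Tandem repeats** (arrays of ≥ 2 adjacent motif copies, total > 10 bp,
period ≤ 500) are detected from maximal exact runs of lag-p agreement
(`s[i] == s[i+p]`), vectorized per period. Runs are merged across ≤ 2
mismatches only when both sides carry at least two full periods of
structure and merged identity stays ≥ 80% — greedy mismatch absorption
was rejected because chance background matches smear array boundaries.
Overlapping calls are reduced best-score-first (span × identity, ties to
the smaller period); a call is dropped when half its span is already
claimed, which removes harmonic duplicates (a period-2p call over a
period-p array) while keeping genuine neighbours. Copy number is reported
to 0.1.

**Mito↔nuclear transfer fragments** reuse the interspersed engine across
genomes, both nuclear strands, and annotate each fragment with the
mitochondrial genes and introns it overlaps.

**Repeat coverage** is the union of covered positions across all hit
intervals (both members), never a sum of hit lengths — sums double-count
overlapping families.

## Intron position classes (Pcls)

A cox1 intron's insertion site is expressed as a nucleotide coordinate in
a reference cox1 CDS; identical labels across species are treated as
homologous introns. The procedure:

1. count coding nucleotides preceding the insertion in the query CDS
   (exon-concatenated, strand-corrected);
2. phase = offset mod 3; query codon = ⌈offset/3⌉;
3. globally align the query protein to the reference protein (BLOSUM62,
   affine gaps 10/1, deterministic first-optimal tie-breaking) and read
   the reference residue aligned to that codon;
4. ref position = 3·(ref_codon − 1) + (phase if phase > 0 else 3).

Labels render as `P<pos>` with a `+1`/`+2` suffix available for in-codon
insertions (both bare and suffixed forms are exposed, since published
figures use both conventions). Alignment at the protein level is
deliberate: across phyla, nucleotide alignment of cox1 is unreliable while
the protein is strongly conserved, and phase carries over arithmetically.
A site falling in a reference-gap column anchors to the nearest reference
residue on the left and is flagged inexact — deterministic and stable.

A class is *common* when present in strictly more than one fifth of the
surveyed species ("more than 1/5" read literally; the threshold fraction
is a parameter). Robustness, measured on 200 simulated introns at anchors
P383/P1107/P1281: 100% label recovery under 20% protein divergence without
indels, and ≥ 95% with a 2-aa deletion planted more than 5 codons from the
site.

The bundled reference CDS is a deterministic *synthetic* stand-in
(534 codons, clean code-4 translation) long enough to carry position
classes up to P1281 and beyond; a real reference CDS can be supplied as
FASTA.

## Gene order and rearrangement

Orders cover the 17-gene comparison set (15 core PCGs + rnl + rns; tRNAs
excluded), signed by strand, circular, canonicalized to start at +cox1 —
if cox1 lies on the minus strand the whole order is reflected (reversed
with signs flipped) first, so a mirrored record canonicalizes identically.

Rearrangement between two species is the breakpoint count on the
intersection of their gene sets: a signed adjacency (a, b) is identified
with its mirror (−b, −a), and breakpoints are adjacencies of one order
missing from the other. On equal gene sets the measure is symmetric and a
single block inversion changes at most two adjacencies. Missing genes are
dropped pairwise rather than refusing comparison (refusal only below 3
shared genes). Species grouping is by identical canonical order, with
singletons flagged unique.

## Supermatrix and NJ sanity tree

The combined gene set exports the 15 core PCGs as code-4 translations
(nucleotide optional) and the rRNAs as nucleotide. Per-gene alignment
goes either through an external aligner command template (e.g. `mafft`)
or the built-in deterministic center-star aligner (longest sequence as
center, pairwise global alignments merged under "once a gap, always a
gap") — adequate for the low-divergence synthetic regime the tests run
offline, not a general MSA replacement. Genes concatenate in alphabetical
order with gap-fill for missing taxa; partitions are contiguous, 1-based,
and tile all columns. Writers: per-gene FASTA, relaxed PHYLIP, NEXUS with
charsets, and a RAxML-style partition file (model tokens configurable,
default WAG for protein and GTR for RNA blocks). External ML/BI inference
consumes these; in-package tree building is limited to neighbor-joining
on p-distances (shared non-gap columns) with taxa fed in label-sorted
order for reproducibility, which provably recovers the topology on
additive matrices (verified on 20 random 8-taxon trees).

## Synthetic data

The generator realizes the study regime, not cosmetic realism: circular
AT-rich genomes (default GC 0.27, default length 60 kb, test scale
25–45 kb), the 17-gene complement in a chosen signed order with random
intergenic spacers, introns planted at chosen reference-CDS coordinates
(cox1 defaults to the reference CDS itself, so planted coordinates are
reference coordinates by identity), optional LAGLIDADG-token ORFs inside
introns, repeat pairs and tandem arrays planted in intergenic space, tRNAs
scattered in spacers, and a nuclear sequence carrying diverged copies of
mitogenome segments at recorded positions and identities.

Numerical details worth knowing:

* CDS base composition is generated from codon weights fixed-point-
  adjusted so that *sense-codon-conditioned* GC hits the target (naive
  conditioning inflates GC by ~1 point at GC 0.27); a 100 kb genome
  realizes its target within 0.8 points.
* Planted repeats and tandem arrays get boundary guard bases chosen to
  break extendability/periodicity at their ends; without them the planted
  feature's maximal extent is genuinely ambiguous against a random
  background, and ground truth would not be well defined. Tandem motifs
  are required to be primitive (not a repetition of a shorter unit).
* Clade simulation evolves protein sequences (per-residue substitutions,
  back-translated under code 4 with AT-biased codon choice), rRNAs
  (nucleotide substitutions), cox1 intron presence per position class
  (gain/loss per branch), and gene order (Poisson block inversions) along
  a random bifurcating tree. An explicit membership plan can replace
  stochastic intron evolution when a prevalence pattern must be exact.
* Everything is driven by one integer seed; identical specs give
  byte-identical GenBank output (fixed record date).

What the generator does **not** emulate: selection, codon-usage bias
beyond base composition, intron secondary structure and splice-site
motifs, realistic tRNA sequences, and genome-size heterogeneity within a
clade. Passing tests therefore demonstrate correctness of the
computations under known ground truth, not robustness to every feature of
real records — notably, real annotations with inconsistent intron/exon
bookkeeping will surface as validation errors rather than silently wrong
labels.

## Problem sizes in the test suite

The bundled checks run at these scales, chosen to exercise each property
well past its edge cases while staying desk-sized: 200 random annotations
for partition conservation; 50 random ≤ 300 bp sequences for exact-repeat
oracle equivalence and 100 planted tandem fixtures; 53 identity sites and
200 diverged introns for Pcl recovery; a 10-species clade for prevalence
logic; 100 random signed 17-permutations for breakpoint equivalence; 20
additive 8-taxon matrices for NJ recovery. `scripts/acceptance.py`
recomputes all of these from scratch under a caller-supplied seed.

## Known limitations

* The interspersed-repeat engine is ungapped; indel-diverged repeat copies
  longer than the X-drop tolerance fragment into multiple HSPs.
* E-values use raw sequence lengths (no edge-effect correction); for the
  genome sizes involved the bias is negligible relative to the 1e-10
  working threshold.
* The center-star fallback aligner degrades on deep divergence; use the
  external-aligner adapter for real cross-phylum data.
* Pcl mapping assumes the insertion site itself is alignable; sites inside
  reference gaps are flagged inexact rather than resolved.
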