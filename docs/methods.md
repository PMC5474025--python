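# Methods

## Pipeline model and assumptions

`intsite` models an integration-site (IS) survey as a pure function of four
inputs: junction-fragment reads, the two library-preparation primer
sequences, a reference genome, and a gene BED. The read model assumes
directional amplicons — every informative read starts with (a suffix of)
the 3' terminal-repeat (TR) primer and continues into host genomic DNA on
the integration strand; no reverse-complement primer search is performed.
Alignment is ungapped and end-to-end, which encodes the stringency the
pipeline is built around (100 % span coverage, mismatches only, no indels):
a read either places intact within a small mismatch budget or it does not
count. Base qualities are carried through parsing but never used; no
quality-based filtering or trimming is applied.

All internal coordinates are 0-based half-open (BED convention). Only the
user-facing IS position is 1-based: for a forward placement it is the
nucleotide preceding the alignment start, for a reverse placement the last
aligned nucleotide, so that in both orientations the reported coordinate is
the genomic base abutting the vector end. A forward read flush with a
contig start has no preceding base; such calls are dropped with a warning
rather than clamped (0 is not a valid 1-based coordinate).

## Read selection and trimming

The TR search considers every suffix of the primer of length ≥ 5 at every
offset where it ends inside the read. The mismatch ladder (≥ 20 bases → 2
mismatches, 10–19 → 1, < 10 → 0) governs qualification; preference is
longest suffix, then fewest mismatches, then leftmost end — the semantics
of common adapter trimmers. The 5-base floor is a design choice: the ladder
gives no lower bound and 1–2 nt "matches" would be noise. N bases count as
mismatches everywhere (conservative).

Distal-adaptor trimming matches prefixes of the adaptor's read-strand form
(reverse complement of the distal primer as given, unless flagged
pre-oriented) against the read's 3' end, minimum overlap 3, mismatch rate
≤ 10 % of the matched length (floored) — the defaults of mainstream
adapter-trimming tools. Absence of the adaptor leaves the read eligible.
After trimming, reads shorter than 30 bp are eliminated; 30 bp is the
shortest query that still maps essentially uniquely in a mammalian-scale
genome. In paired-end mode a pair is kept only when mate 1 carries the TR
primer and mate 2 the read-2 adaptor (same ladder) and both trimmed mates
reach 30 bp.

## Alignment and the progressive unique filter

The internal aligner is exhaustive: it enumerates every ungapped placement
of the query (and its reverse complement) within the mismatch budget. On
contigs ≥ 100 kb it uses pigeonhole seeding — the query is split into
`budget + 1` chunks, so any qualifying placement contains a mismatch-free
chunk whose first 10 bases hit a sorted k-mer index exactly; candidates are
then verified in full. Smaller contigs use a vectorised sliding Hamming
scan. Both paths are exact, and the test suite holds them to a brute-force
oracle. An external SAM-producing aligner can be substituted through a
command template; the internal aligner defines ground truth, and backend
equivalence is asserted on small genomes in tests.

The single-end filter runs three rounds with budgets 0, 1, 2. Each round
keeps only reads with *exactly one* placement within its budget, and each
round's input is the previous round's survivors. Under this reading the
relaxed rounds can only remove reads — a read unique at 0 mismatches but
with a 1- or 2-mismatch near-duplicate elsewhere is discarded — so round
counts are monotone non-increasing. The alternative reading (realigning
unaligned reads at higher budgets to rescue erroneous reads) was rejected
because it cannot produce strictly decreasing per-round counts, which the
funnel semantics require. A consequence worth stating plainly: a read with
even one sequencing error in its genomic portion has no zero-mismatch
placement and is lost in round 1; deep duplication (a site's reads rarely
*all* carry errors) is what keeps site-level recovery high.

Paired-end mode applies a single zero-mismatch round: a pair survives iff
exactly one concordant placement exists (same contig, opposite strands,
inward-facing, outer span within the insert window). The default insert
window is [50, 500] bp: the span measured after trimming is the genomic
portion only, so a 100 bp physical fragment — the lower end of the 100–400
bp size-selection window, primers included — has a genomic span near 55 bp.

Uniqueness is always "exactly one (contig, start, strand)"; there is no
fuzz-merging of nearby sites (distance tolerance 0 bp), and duplicate calls
merge only at identical coordinates. The deduplication key includes strand:
opposite-strand calls at one coordinate stay distinct, since merged
reporting can be derived from stranded sites but not vice versa.

## Annotation

The transcription start site of a gene is `start + 1` for '+' genes and
`end` for '−' genes (1-based). Classification precedence: TSS-proximal
(|position − TSS| ≤ window, default 2500 bp, bounds inclusive — "within"
includes the boundary), then intragenic (inside the transcript span
`[start+1, end]`, strand-irrelevant for containment), then intergenic. The
reported gene is the nearest-TSS gene among qualifying genes, ties broken
by lexicographic accession; the signed TSS distance is oriented by gene
strand (positive = downstream). Site strand plays no role in
classification. Isoforms are independent records; gene-level IS counts
aggregate by symbol, and only TSS-proximal and intragenic sites count as
"IS-containing" for the gene ranking. A deliberately plain linear-scan
classifier (`classify_site_bruteforce`) ships alongside the indexed one and
anchors both the simulator's truth annotations and the equivalence tests.

## Statistics

Mean IS read coverage is final aligned reads (or concordant pairs) divided
by unique ISs, rounded half-up to 1 decimal. Percentages are computed
half-up at a configurable precision (0 decimals for own-data reporting, 2
for literature-style comparison). Fisher's exact test is two-sided by the
probability-mass definition: with margins fixed, sum the hypergeometric
probabilities of all tables no more likely than the observed one, computed
from log-space pmf values (stable for totals ≤ 10^6) with a 1e-7 relative
tolerance on the comparison; when every outcome qualifies the p-value is
exactly 1. Dataset comparisons build, per category, the 2×2 table
in-category vs rest × dataset A vs B. Category-vs-rest (not
category-vs-category) was chosen as the natural reading of a pairwise
comparison of a three-way distribution. p-values are reported raw, without
multiple-testing correction.

## Simulator

The generator's defaults are the study conditions the acceptance checks
run under: a 1 Mb uniform-random genome in 2 contigs; 200 non-overlapping
genes of 0.5–4 kb (≈ 45 % genic occupancy, chosen as a human-like density
scaled to a 1 Mb toy genome); 150 planted sites ≥ 1 kb from contig ends;
per-site duplication factors uniform in 1–50; 30 % into-vector decoys;
zero sequencing error; fragments 100–400 bp including primers; reads
100–300 bp. Gene placement splits each contig's free space into random
gaps (a multinomial composition), which places even dense gene sets
deterministically and raises a configuration error when the drawn gene
lengths cannot fit.

Fragments are `TR primer + genomic + distal adaptor (reverse-complement
form)`; a read is the fragment prefix at the drawn read length. When the
drawn length would leave a 1–2 bp adaptor tail — below any trimmer's
minimum overlap, hence unmappable trailing bases — the read ends at the
junction instead; real reads ending mid-adaptor at such overlaps are
genuinely unrecoverable under a zero-mismatch first round, and the
generator's contract is that noiseless libraries are recovered exactly.
The vector sequence is resampled until it shares no exact 30-mer (either
strand) with the genome, guaranteeing — not assuming — that decoys cannot
align. Errors are substitution-only, matching the ungapped aligner
contract; indels, chimeric amplicons, quality-score structure, barcode
demultiplexing and non-uniform genome composition (repeats!) are *not*
modelled. Passing the recovery tests therefore demonstrates correctness of
the pipeline's logic, not robustness to repetitive real genomes, where the
unique-mapping filter is exactly the component expected to discard reads.

Paired mode emits mate 2 as `read-2 adaptor + reverse-complement genomic`
from the fragment's far end. Only 3'-TR-side junctions are planted; a
dual-primer (5' and 3') library is emulated by two pipeline runs with
swapped primer sets, mirroring how such pooled libraries are analysed.

## Problem sizes and determinism

Tests and the acceptance script run the full study conditions (≈ 4–6
thousand reads against the 1 Mb genome) in seconds on one CPU; property
suites use 0.8–2 kb genomes for the thousands-of-trials oracle
comparisons. Every stochastic component draws from a seeded generator
(`numpy.random.default_rng` with derived streams), and fixtures are
byte-reproducible from their configuration.

## Known limitations

- No gapped or quality-aware alignment; reads spanning indel variants
  against the chosen reference are lost by design.
- The internal aligner targets genomes up to a few Mb; genome-scale runs
  require the external backend.
- PCR-bias correction, clone tracking across samples, diversity indices
  and oncogene-proximity analyses are out of scope; read counts are
  reported raw.
- The progressive filter's strict zero-mismatch first round discards all
  erroneous reads of a site; sites supported by a single erroneous read are
  unrecoverable.
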