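# Methods

## Gene search model

The unit of analysis is the (contig, reference) pair. The input is a set
of BLASTx-style HSPs: local alignments of a translated stretch of the
contig against one protein of the reference's CDS set, each carrying
1-based inclusive nucleotide coordinates on the contig (`q_start ≤ q_end`
always; strand lives in the frame sign), a bit score, an E-value and a
reading frame in {−3…−1, +1…+3}.

**Groups** are connected components of the interval-overlap graph on the
contig: two HSPs are joined when their query intervals share at least one
base. Overlap is judged purely on nucleotide coordinates — frame and
subject gene identity are ignored, so two different genes hit by the same
stretch of contig fall in one group. Internally intervals become 0-based
half-open at the grouping boundary and components are found by a sweep
over start-sorted intervals; a brute-force transitive-closure oracle checks
this in the tests.

**The N cap.** A group retains at most N − 1 hits. The ranking is
descending bit score, with ascending E-value, then descending alignment
length, then input order as tie-breaks. Bit score as the primary key with
E-value as first tie-break reconciles the two natural orderings (score and
E-value rank identically in the common case); this was a genuinely open
design point and is frozen here. N = 1 legally keeps zero hits per group —
the CLI warns because it empties every report. The cap is applied after
group formation on all hits; discarded members do not shrink the group
span.

**The M threshold.** Survivors of all groups are pooled; the pair is valid
iff the count ≥ M. Validity is per (contig, reference) pair, not per
contig globally: a contig can be valid against one reference and invalid
against another. `count ≥ M ⇒ valid` is the reading under which the worked
example's counts (5, 7 valid; 3, 1 invalid at M = 4) come out right.

Pairs with no HSP at all produce no report, so "no hits" and "hits that
failed M" are distinguishable in the output.

## Report files

`.sorted` contains every reported pair (pre-M); `.regsp` only valid pairs.
Per block: a contig/reference header with the total gene count, then per
gene its id, the matching query nucleotide subsequence (when the query
sequences are available to the writer), a metrics line
(`qstart qend alen bitscore evalue frame`), and the aligned
translated-query/subject pair. Genes are ordered by descending bit score
inside a block. The precise token layout is this package's own dialect
(the upstream format is only partially documented), frozen by golden-file
tests; `.regsp` blocks are by construction a subset of `.sorted` blocks.

## Dot plot (cPlot)

Exact k-mer matching only, k ∈ [10, 30], default 13. The reference is
indexed once (hash of every pure-ACGT k-mer to its positions); each query
window is looked up directly and via its reverse complement. A reverse
match at (q, r) means the query window equals the reverse complement of
the plus-strand reference window starting at r; its anti-diagonal constant
is r + q. Windows containing ambiguity codes never match — this sacrifices
a little sensitivity in exchange for not exploding on N-runs in draft
assemblies. Low-complexity self-matches are not masked; they appear as
off-diagonal clutter and are a known visual caveat.

Consecutive matches on one (anti)diagonal merge into segments (run of L
matches → segment of L − 1 + k bases). Overlapping candidate segments are
resolved per (contig, reference): clusters of query-overlapping segments
are scanned from the start of the reference and the longest member wins
(ties: smallest reference start, then forward before reverse). Among
equal-length exact segments "most similar to the reference" is vacuous —
all are 100% identical — so length is the whole criterion. Resolution is
independent per reference; by default only resolved segments are drawn,
with `--show-all-matches` to draw every merged segment.

Contigs are reordered along the shared query axis: by the first reference
(input order) in which a contig has any segment, then by the reference
start of its longest segment there, then input order; contigs with no
segment go last. Raising k can only remove matched positions, so total
matched coverage is non-increasing in k — the "fade-out" used to tune k
visually.

Rendering is a pure function of (layout, style): tests assert on the
drawn-primitive inventory (line endpoints per panel and orientation), never
on PDF bytes, which carry font/timestamp noise. Panels are laid out on a
near-square grid (stacking vs grid was unspecified upstream; grid chosen).

## Built-in translated search

`minisearch` exists so the pipeline is testable end to end with no
external binary: six-frame translation (standard code, stops as `*`),
exact peptide words of `word_size` (default 5) as seeds, ungapped
two-sided extension maximizing cumulative BLOSUM62 score with X-drop 20,
report threshold 50 (raw score). Coordinates map back frame-aware:
`q_start = 3·aa_start + frame_offset + 1` on the plus strand, reflected
through the contig length on the minus strand. Raw scores are stored in
the bit-score field and the E-value field holds 2^(−score) — a rank
surrogate, not a statistic. No gapped extension, no Karlin–Altschul
statistics, no low-complexity filtering; absolute scores are not
comparable to NCBI bit scores, and report headers record the HSP source.
An integration test cross-checks it against a real `blastx` run on exact
synthetic CDS inserts.

## Synthetic data

The generator emulates a small organellar-scale locus: `n_genes` (default
8) intronless ORFs of 150–450 bp (ATG start, sense codons, single terminal
stop), intergenic spacers of 60–150 bp, concatenated into one reference
genome whose protein set is the ORF translations. Contigs are cut from a
point-substituted copy (default rate 5%, the divergence scale of
congeneric organellar references) at spacer midpoints, so every gene lies
wholly inside one contig; a fraction (default 25%) of contigs is
reverse-complemented. The genome is built to fit its genes, so no packing
failure mode exists. A single seeded NumPy generator drives all
randomness; fixed seeds give byte-identical outputs.

What this does **not** emulate: inverted repeats, introns, RNA genes,
indels, sequencing error profiles, uneven coverage, chimeric contigs.
Passing the recovery tests therefore shows the search-and-filter machinery
is correct under point divergence, not that sensitivity on real diverged
organellar data matches BLASTx.

The worked-example fixture freezes one concrete realization of the
two-contig/three-reference scenario: only the overlap topology and score
order are constrained by the scenario, so coordinates and scores were
invented once and are held fixed by a golden file.

## Problem sizes and numerical choices

Oracle-equivalence tests run 500 random grouping instances (≤ 20 HSPs) and
50 random dot-plot pairs (≤ 2 kb) against brute-force evaluators — sizes at
which exhaustive oracles stay exact and the suite completes in seconds.
The recovery regression uses 20 seeded replicates at 5% substitution with
seed word size 4 and requires ≥ 90% of truth-table genes back (observed:
100%). Tie-breaks everywhere are total orders ending in input order, so
every result is deterministic given the input; replaying a run reproduces
the report files byte for byte.

## Limitations

- Gapped HSPs come only from external BLASTx; the built-in search is
  ungapped.
- Exact reproduction of published hit counts on real accessions depends on
  the BLAST version and unstated cutoffs, and is out of scope; the
  external-blastx mode exposes its E-value cutoff (default 1e-5) instead.
- The protein-domain (PROmer/MUMmer) plot is delegated to an optional
  external-tool hook (`--mummer-hook`), not reimplemented.
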