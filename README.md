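# regsp

Homology-based gene search for assembled contigs against **multiple
reference sequences**, with a k-mer dot-plot view of nucleotide similarity.

## The problem

When annotating a newly assembled organellar genome (a plastid or
mitochondrion), the quickest route to gene content is homology: run the
contigs through a translated search (BLASTx) against the protein CDS sets
of one or more related reference genomes, then decide which contigs carry a
credible complement of genes. Raw BLASTx output is noisy — a single gene
often shatters into several overlapping high-scoring segment pairs (HSPs),
and spurious short hits litter the genome. This package implements the
two-parameter filtering scheme that turns raw HSPs into per-contig gene
reports, and a dot-plot engine that shows where each contig sits on each
reference at the nucleotide level.

## The method

For every (contig, reference) pair:

1. **Grouping.** HSPs whose query intervals overlap (by at least one base)
   are merged transitively into *groups* — each group is a contiguous
   section of the contig with BLAST matches.
2. **The N cap.** A group may keep at most **N − 1** hits. Over-full groups
   are ranked by descending bit score (ties: ascending E-value, descending
   alignment length, input order) and the excess lowest-ranked hits are
   discarded.
3. **The M threshold.** The hits surviving all groups are the contig's
   *sub-genes*. The pair is **valid** when the sub-gene count is ≥ **M**.

Two reports are written: `.sorted` holds every pair *before* the M filter,
`.regsp` only the valid ones. In parallel, the dot-plot branch (cPlot)
finds exact shared k-mers between each contig and each reference on both
strands (k configurable in 10–30, default 13), merges consecutive matches
on a diagonal into segments, keeps the longest segment per cluster of
query-overlapping candidates, and reorders the contigs along the query axis
to follow the reference. The PDF shows one panel per reference; forward
matches are purple, reverse matches cyan.

HSPs can come from an external NCBI `blastx`, from a precomputed BLAST
tabular file, or from the built-in six-frame seed-and-extend translated
search (`regsp.minisearch`) — a deterministic, dependency-free engine meant
for testing and small jobs, not a BLAST replacement.

## Worked example

`examples/gene_search_worked_example.py` replays the canonical two-contig,
three-reference configuration with N = 4, M = 4 (also available from the
shell as `regsp demo --out demo_out`):

```
contig     reference     sub-genes  valid
Contig_1   Reference_1           5  True
Contig_2   Reference_1           7  True
Contig_2   Reference_2           3  False
Contig_1   Reference_3           4  True
Contig_2   Reference_3           1  False
```

Contig 2 has 8 hits against Reference 1, four of them mutually overlapping:
that group keeps only its top N − 1 = 3 hits, so the weakest is discarded
and 7 sub-genes remain (valid, 7 ≥ M). Against Reference 2 the same contig
has only 3 disjoint hits — below M, so the pair appears in `.sorted` but is
dropped from `.regsp`. With N = 4 and M = 4, 3 of the 5 reported pairs are
valid.

A full shell run looks like:

```sh
regsp run --query contigs.fna --ref-nt refs.fna --ref-aa refs.faa \
          -N 4 -M 4 --k 13 --use-minisearch --out run_out
```

`refs.faa` holds the protein CDS sets of all references in input order,
separated by a line of three or more `*` characters. Outputs:
`results.sorted`, `results.regsp`, `cplot.pdf`, `hits.tsv`, `run.log`,
`summary.jsonl`. Soft limits (warnings only): at most 30 query entries and
fewer than 10 references for a readable plot.

See `examples/` for the dot-plot and translated-search walkthroughs.

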