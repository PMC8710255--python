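#!/bin/sh
# Full pipeline from the shell: the built-in worked example, then a run on
# files you provide.  Outputs: results.sorted (pre-M), results.regsp
# (post-M), cplot.pdf, hits.tsv, run.log, summary.jsonl.

regsp demo --out demo_out

# With your own data (query contigs, reference nucleotide multi-FASTA, and
# the per-reference protein CDS sets separated by a line of three or more
# '*' characters):
#
#   regsp run --query contigs.fna --ref-nt refs.fna --ref-aa refs.faa \
#             -N 4 -M 4 --k 13 --use-minisearch --out run_out
#
# Use --use-blastx to call an external NCBI blastx instead, or
# --hsp-table hits.tsv to reuse a precomputed BLAST tabular file.
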