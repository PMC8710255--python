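"""The two-contig, three-reference worked example of the N/M gene search.

Builds the built-in HSP fixture (two query contigs searched against the CDS
sets of three references), applies the two filtering parameters N=4 (max
hits per overlap group, i.e. at most N-1 = 3 kept per group) and M=4
(minimum sub-gene count for a contig to be valid), and prints the per-pair
outcome.
"""

from regsp.grouping import SearchParams, run_gene_search
from regsp.synth import worked_example_hsps

reports = run_gene_search(worked_example_hsps(), SearchParams(N=4, M=4))

print(f"{'contig':<10} {'reference':<13} {'sub-genes':>9}  valid")
for r in reports:
    print(f"{r.contig_id:<10} {r.ref_id:<13} {r.subgene_count:>9}  {r.valid}")

# Contig 2 vs Reference 1 starts with 8 hits; four of them overlap, so the
# weakest of that group is discarded (7 remain, valid).  Contig 2 vs
# Reference 2 has only 3 disjoint hits, below M=4, so the pair is invalid
# and will appear in the .sorted report but not in the final .regsp one.
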