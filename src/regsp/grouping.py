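"""The two-parameter gene-search computation.

HSPs on a contig are partitioned into *groups*: connected components of the
graph whose edges join hits with intersecting query nucleotide intervals
(intersection of at least one base).  A group may keep at most ``N - 1``
hits; over-full groups are ranked by descending bit score and the excess
lowest-ranked hits are discarded.  The hits surviving all groups of one
(contig, reference) pair are the contig's *sub-genes*; the pair is valid when
the sub-gene count reaches the minimum ``M``.

Overlap is measured on contig nucleotide coordinates only — frame and
subject gene identity play no role in group formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import HSP

__all__ = [
    "SearchParams",
    "HitGroup",
    "ContigReport",
    "find_groups",
    "cap_group",
    "evaluate_contig",
    "run_gene_search",
]


@dataclass(frozen=True)
class SearchParams:
    """The two user parameters of the search.

    N : maximum number of matched BLAST hits per group; a group keeps at
        most ``N - 1`` hits (so ``N = 1`` keeps none).
    M : minimum number of sub-gene counts per contig; a (contig, reference)
        pair is valid when its surviving hit count is ``>= M``.
    """

    N: int
    M: int

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 1:
            raise ValueError("N and M must be natural numbers (>= 1)")


@dataclass
class HitGroup:
    """A maximal set of HSPs on one contig connected by query-interval overlap."""

    contig_id: str
    ref_id: str
    members: list[HSP]
    q_span: tuple[int, int]  # 0-based half-open union of member intervals


@dataclass
class ContigReport:
    """Per (contig, reference) outcome of the N/M filtering."""

    contig_id: str
    ref_id: str
    surviving: list[HSP]  # sorted by descending bit score
    subgene_count: int
    valid: bool


def _rank_key(indexed_hsp: tuple[int, HSP]) -> tuple:
    """Ranking used everywhere a 'top hits' decision is made.

    Descending bit score; ties broken by ascending E-value, then descending
    alignment length, then input order.
    """
    i, h = indexed_hsp
    return (-h.bitscore, h.evalue, -h.align_len, i)


def find_groups(hsps: Sequence[HSP]) -> list[HitGroup]:
    """Partition one (contig, reference) pair's HSPs into overlap groups.

    Groups are connected components of pairwise query-interval intersection
    (>= 1 base).  Found by a sweep over intervals sorted by start: on
    half-open intervals, a hit joins the open group while its start is
    strictly below the running maximum end.  Members keep input order.
    """
    if not hsps:
        return []
    ids = {(h.contig_id, h.ref_id) for h in hsps}
    if len(ids) > 1:
        raise ValueError(f"find_groups expects one (contig, reference) pair, got {ids}")
    contig_id, ref_id = next(iter(ids))

    order = sorted(range(len(hsps)), key=lambda i: hsps[i].q_interval)
    groups: list[HitGroup] = []
    current: list[int] = []
    span_start = span_end = 0
    for i in order:
        s, e = hsps[i].q_interval
        if current and s < span_end:
            current.append(i)
            span_end = max(span_end, e)
        else:
            if current:
                groups.append(
                    HitGroup(contig_id, ref_id,
                             [hsps[j] for j in sorted(current)],
                             (span_start, span_end))
                )
            current = [i]
            span_start, span_end = s, e
    groups.append(
        HitGroup(contig_id, ref_id,
                 [hsps[j] for j in sorted(current)],
                 (span_start, span_end))
    )
    return groups


def cap_group(group: HitGroup, N: int) -> list[HSP]:
    """Apply the per-group cap: keep the top ``N - 1`` hits by rank.

    If the group has at most ``N - 1`` members all are kept.  ``N = 1``
    legally yields an empty survivor list.  Output is sorted by rank
    (descending bit score first).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    ranked = sorted(enumerate(group.members), key=_rank_key)
    return [h for _, h in ranked[: N - 1]]


def evaluate_contig(hsps: Sequence[HSP], params: SearchParams) -> ContigReport:
    """Run grouping + capping for one (contig, reference) pair.

    Survivors from every group are pooled, re-sorted by rank, counted, and
    the count compared against M.
    """
    groups = find_groups(hsps)
    contig_id = hsps[0].contig_id
    ref_id = hsps[0].ref_id
    survivors: list[HSP] = []
    for g in groups:
        survivors.extend(cap_group(g, params.N))
    # global rank order for the report; input order index recovered from hsps
    pos = {id(h): i for i, h in enumerate(hsps)}
    survivors.sort(key=lambda h: _rank_key((pos[id(h)], h)))
    count = len(survivors)
    return ContigReport(
        contig_id=contig_id,
        ref_id=ref_id,
        surviving=survivors,
        subgene_count=count,
        valid=count >= params.M,
    )


def run_gene_search(hsps: Iterable[HSP], params: SearchParams) -> list[ContigReport]:
    """Evaluate every (contig, reference) pair present in the HSP stream.

    Pairs with no HSP produce no report.  Reports follow first-appearance
    order of the pair in the input, which for pipeline-produced HSP streams
    means references in input order within each contig.
    """
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_pair.setdefault((h.contig_id, h.ref_id), []).append(h)
    return [evaluate_contig(pair_hsps, params) for pair_hsps in by_pair.values()]
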