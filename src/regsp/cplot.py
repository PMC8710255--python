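"""The cPlot engine: exact k-mer dot-plot computation.

For each (contig, reference) pair, shared k-mers are found on both strands
via a reference k-mer index, consecutive matches on one diagonal are merged
into segments, overlapping candidate segments are resolved by keeping the
longest per overlap cluster, and contigs are reordered along the query axis
to follow the reference.

Exact matching only: similarity at coarser scale emerges from segment
density, and raising k filters the picture down to highly similar regions.
Windows containing ambiguity codes (N etc.) never match anything, which
avoids quadratic blowup on N-runs in draft contigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import SeqRecord

__all__ = [
    "KmerParams",
    "MatchSegment",
    "DotPlotLayout",
    "revcomp",
    "find_kmer_matches",
    "merge_matches",
    "resolve_overlaps",
    "order_contigs",
    "build_layout",
]

K_MIN, K_MAX, K_DEFAULT = 10, 30, 13

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class KmerParams:
    """k-mer size for the dot plot; allowed range 10-30, default 13."""

    k: int = K_DEFAULT

    def __post_init__(self) -> None:
        if not (K_MIN <= self.k <= K_MAX):
            raise ValueError(
                f"k-mer size must be between {K_MIN} and {K_MAX}, got {self.k}"
            )


@dataclass(frozen=True)
class MatchSegment:
    """A merged run of exact k-mer matches.

    Intervals are 0-based half-open; ``q_end - q_start == r_end - r_start``.
    Forward segments lie on the diagonal ``r_start - q_start``; reverse
    segments on the anti-diagonal ``r_end + q_start`` (the reference interval
    is the plus-strand region whose reverse complement matches the query run).
    """

    contig_id: str
    ref_id: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    orientation: str  # "forward" | "reverse"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class DotPlotLayout:
    """Per-reference dot-plot panels plus the contig ordering of the query axis."""

    ref_ids: list[str]
    panels: dict[str, list[MatchSegment]]
    contig_order: list[str]
    offsets: dict[str, int]  # cumulative start of each contig on the query axis
    contig_lengths: dict[str, int]
    ref_lengths: dict[str, int]
    k: int = K_DEFAULT

    @property
    def query_span(self) -> int:
        return sum(self.contig_lengths.values())


def _valid_starts(seq: str, k: int) -> list[bool]:
    """Window validity: True where seq[i:i+k] is pure ACGT (rolling count)."""
    n = len(seq)
    ok = [c in "ACGT" for c in seq]
    out = [False] * max(n - k + 1, 0)
    bad = sum(1 for i in range(min(k, n)) if not ok[i])
    for i in range(len(out)):
        out[i] = bad == 0
        if i + k < n:
            bad += (not ok[i + k]) - (not ok[i])
    return out


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Index every pure-ACGT k-mer of ``seq`` to its start positions."""
    idx: dict[str, list[int]] = {}
    valid = _valid_starts(seq, k)
    for i, v in enumerate(valid):
        if v:
            idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def find_kmer_matches(
    query: SeqRecord, reference: SeqRecord, params: KmerParams
) -> list[tuple[int, int, str]]:
    """All exact shared k-mers between query and reference, both strands.

    Returns ``(q_pos, r_pos, orientation)`` triples: forward where the query
    window equals the reference window at ``r_pos``, reverse where it equals
    the reverse complement of that window (i.e. matches the reference read on
    the minus strand).  Built via a reference k-mer index.
    """
    k = params.k
    if len(query.seq) < k or len(reference.seq) < k:
        warnings.warn(
            f"sequence shorter than k={k} "
            f"({query.id}: {len(query)} nt, {reference.id}: {len(reference)} nt); "
            "no matches possible",
            stacklevel=2,
        )
        return []
    idx = kmer_index(reference.seq, k)
    out: list[tuple[int, int, str]] = []
    valid = _valid_starts(query.seq, k)
    for q in range(len(query.seq) - k + 1):
        if not valid[q]:
            continue
        w = query.seq[q : q + k]
        for r in idx.get(w, ()):
            out.append((q, r, "forward"))
        for r in idx.get(revcomp(w), ()):
            out.append((q, r, "reverse"))
    return out


def merge_matches(
    matches: Iterable[tuple[int, int, str]],
    k: int,
    contig_id: str = "",
    ref_id: str = "",
) -> list[MatchSegment]:
    """Merge consecutive same-diagonal matches into maximal segments.

    Forward runs keep ``r - q`` constant with q stepping by +1; reverse runs
    keep ``r + q`` constant with q stepping by +1 (r stepping by -1).  A run
    of ``L`` matches becomes one segment of ``L - 1 + k`` bases.
    """
    by_diag: dict[tuple[str, int], list[int]] = {}
    for q, r, orient in matches:
        diag = r - q if orient == "forward" else r + q
        by_diag.setdefault((orient, diag), []).append(q)
    segments: list[MatchSegment] = []
    for (orient, diag), qs in by_diag.items():
        qs.sort()
        run_start = prev = qs[0]
        runs: list[tuple[int, int]] = []
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
            else:
                runs.append((run_start, prev))
                run_start = prev = q
        runs.append((run_start, prev))
        for q0, q1 in runs:
            q_start, q_end = q0, q1 + k
            if orient == "forward":
                r_start, r_end = q0 + diag, q1 + k + diag
            else:
                r_start, r_end = diag - q1, diag - q0 + k
            segments.append(
                MatchSegment(contig_id, ref_id, q_start, q_end, r_start, r_end, orient)
            )
    segments.sort(key=lambda s: (s.q_start, s.r_start, s.orientation))
    return segments


def _orient_rank(orientation: str) -> int:
    return 0 if orientation == "forward" else 1


def resolve_overlaps(segments: Sequence[MatchSegment]) -> list[MatchSegment]:
    """Keep one optimal segment per cluster of query-overlapping candidates.

    Candidates are scanned in order of ascending reference start; segments
    whose query intervals overlap form a cluster, and the longest member is
    kept (ties: smallest ``r_start``, then forward before reverse).  Since
    segments are exact matches, equal-length candidates are equally similar
    to the reference, so length is the whole criterion.  Kept segments have
    pairwise disjoint query intervals.
    """
    if not segments:
        return []
    # connected components of query-interval overlap, via a sweep
    order = sorted(range(len(segments)), key=lambda i: segments[i].q_start)
    clusters: list[list[int]] = []
    current: list[int] = []
    span_end = -1
    for i in order:
        s = segments[i]
        if current and s.q_start < span_end:
            current.append(i)
            span_end = max(span_end, s.q_end)
        else:
            if current:
                clusters.append(current)
            current = [i]
            span_end = s.q_end
    clusters.append(current)

    kept = [
        min(
            (segments[i] for i in cluster),
            key=lambda s: (-s.length, s.r_start, _orient_rank(s.orientation)),
        )
        for cluster in clusters
    ]
    kept.sort(key=lambda s: s.r_start)
    return kept


def order_contigs(
    contig_ids: Sequence[str],
    ref_ids: Sequence[str],
    segments: Iterable[MatchSegment],
) -> list[str]:
    """Order contigs along the query axis to follow the references.

    Sort key per contig: index of the first reference (in input order) where
    the contig has any segment, then the reference start of its longest
    segment in that reference (ties: input order).  Contigs with no segment
    anywhere go last, in input order.
    """
    ref_index = {r: i for i, r in enumerate(ref_ids)}
    best: dict[str, tuple[int, int]] = {}
    per: dict[tuple[str, str], list[MatchSegment]] = {}
    for s in segments:
        per.setdefault((s.contig_id, s.ref_id), []).append(s)
    for contig in contig_ids:
        hit_refs = sorted(
            (ref_index[r] for (c, r) in per if c == contig and r in ref_index)
        )
        if not hit_refs:
            continue
        first = hit_refs[0]
        segs = per[(contig, ref_ids[first])]
        longest = min(segs, key=lambda s: (-s.length, s.r_start))
        best[contig] = (first, longest.r_start)
    order = sorted(
        range(len(contig_ids)),
        key=lambda i: (*best.get(contig_ids[i], (len(ref_ids), 0)), i),
    )
    return [contig_ids[i] for i in order]


def build_layout(
    queries: Sequence[SeqRecord],
    references: Sequence[SeqRecord],
    params: KmerParams | None = None,
    show_all_matches: bool = False,
) -> DotPlotLayout:
    """Run find -> merge -> resolve per (contig, reference) and assemble panels.

    One panel per reference, in input order; the contig ordering of the query
    axis is shared by all panels.  ``show_all_matches`` skips the overlap
    resolution and draws every merged segment.
    """
    if not queries or not references:
        raise ValueError("need at least one query and one reference")
    params = params or KmerParams()
    k = params.k
    if all(len(q) < k for q in queries) or all(len(r) < k for r in references):
        warnings.warn(f"all sequences shorter than k={k}; layout will be empty",
                      stacklevel=2)
    panels: dict[str, list[MatchSegment]] = {r.id: [] for r in references}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-pair short-seq warnings already summarized
        for ref in references:
            for query in queries:
                matches = find_kmer_matches(query, ref, params)
                segs = merge_matches(matches, k, contig_id=query.id, ref_id=ref.id)
                if not show_all_matches:
                    segs = resolve_overlaps(segs)
                panels[ref.id].extend(segs)
    all_segments = [s for segs in panels.values() for s in segs]
    contig_order = order_contigs(
        [q.id for q in queries], [r.id for r in references], all_segments
    )
    offsets: dict[str, int] = {}
    lengths = {q.id: len(q) for q in queries}
    pos = 0
    for cid in contig_order:
        offsets[cid] = pos
        pos += lengths[cid]
    return DotPlotLayout(
        ref_ids=[r.id for r in references],
        panels=panels,
        contig_order=contig_order,
        offsets=offsets,
        contig_lengths=lengths,
        ref_lengths={r.id: len(r) for r in references},
        k=k,
    )
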