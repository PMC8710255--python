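"""The dot-plot engine: k-mer matching, diagonal merging, overlap
resolution, contig ordering — checked against a naive window-comparison
oracle and the identity / reverse-complement / k-monotonicity invariants."""

import random

import numpy as np
import pytest

from regsp.cplot import (
    KmerParams,
    MatchSegment,
    build_layout,
    find_kmer_matches,
    merge_matches,
    order_contigs,
    resolve_overlaps,
    revcomp,
)
from regsp.formats import SeqRecord


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def naive_matches(q: str, r: str, k: int):
    """Independent oracle: compare every query window against every
    reference window directly (both strands), no index."""
    out = set()
    for i in range(len(q) - k + 1):
        w = q[i : i + k]
        if set(w) - set("ACGT"):
            continue
        for j in range(len(r) - k + 1):
            win = r[j : j + k]
            if set(win) - set("ACGT"):
                continue
            if w == win:
                out.add((i, j, "forward"))
            if w == revcomp(win):
                out.add((i, j, "reverse"))
    return out


def _seg(q0, q1, r0, r1, orient="forward", contig="c", ref="r"):
    return MatchSegment(contig, ref, q0, q1, r0, r1, orient)


class TestFindKmerMatches:
    def test_identity_short(self):
        s = SeqRecord("s", "ACGTACGTACGTAC")  # len 14
        matches = find_kmer_matches(s, s, KmerParams(13))
        assert set(matches) == {(0, 0, "forward"), (1, 1, "forward")}

    def test_reverse_complement_only(self):
        rng = random.Random(3)
        while True:
            s = _rand_seq(rng, 20)
            k = 13
            if not any(
                m[2] == "forward" for m in naive_matches(s, revcomp(s), k)
            ):
                break
        q = SeqRecord("q", s)
        r = SeqRecord("r", revcomp(s))
        matches = find_kmer_matches(q, r, KmerParams(13))
        assert len(matches) == 8  # 20 - 13 + 1 windows, all reverse
        assert all(o == "reverse" for _, _, o in matches)

    def test_matches_naive_oracle(self):
        rng = random.Random(17)
        for _ in range(5):
            base = _rand_seq(rng, 300)
            # plant shared material so matches exist
            q = base[:150] + _rand_seq(rng, 50) + revcomp(base[200:260])
            r = base
            got = set(find_kmer_matches(SeqRecord("q", q), SeqRecord("r", r),
                                        KmerParams(13)))
            assert got == naive_matches(q, r, 13)

    def test_ambiguity_codes_never_match(self):
        s = "ACGTACGTACGTA"
        q = SeqRecord("q", s[:6] + "N" + s[7:])
        r = SeqRecord("r", s)
        matches = find_kmer_matches(q, r, KmerParams(13))
        assert matches == []

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter than k"):
            out = find_kmer_matches(
                SeqRecord("q", "ACGT"), SeqRecord("r", "ACGTACGTACGTAC"),
                KmerParams(13),
            )
        assert out == []

    def test_transpose_symmetry_forward(self):
        rng = random.Random(23)
        base = _rand_seq(rng, 200)
        a, b = base[:150], base[50:]
        fa = {(q, r) for q, r, o in
              find_kmer_matches(SeqRecord("a", a), SeqRecord("b", b), KmerParams(12))
              if o == "forward"}
        fb = {(q, r) for q, r, o in
              find_kmer_matches(SeqRecord("b", b), SeqRecord("a", a), KmerParams(12))
              if o == "forward"}
        assert fa == {(r, q) for q, r in fb}


class TestMergeMatches:
    def test_identity_run_merges_to_one_segment(self):
        matches = [(0, 0, "forward"), (1, 1, "forward")]
        (seg,) = merge_matches(matches, k=13)
        assert (seg.q_start, seg.q_end, seg.r_start, seg.r_end) == (0, 14, 0, 14)
        assert seg.length == 14

    def test_mismatch_breaks_run(self):
        rng = random.Random(9)
        block1, block2 = _rand_seq(rng, 30), _rand_seq(rng, 30)
        r = block1 + "A" + block2
        q = block1 + "C" + block2  # one substituted base between the blocks
        if r[30] == q[30]:  # ensure an actual mismatch
            q = block1 + "G" + block2
        matches = find_kmer_matches(SeqRecord("q", q), SeqRecord("r", r),
                                    KmerParams(13))
        segs = [s for s in merge_matches(matches, 13) if s.orientation == "forward"
                and s.r_start - s.q_start == 0]
        assert sorted((s.q_start, s.q_end) for s in segs) == [(0, 30), (31, 61)]

    def test_reverse_antidiagonal_constant(self):
        rng = random.Random(31)
        s = _rand_seq(rng, 60)
        q, r = s, revcomp(s)
        matches = find_kmer_matches(SeqRecord("q", q), SeqRecord("r", r),
                                    KmerParams(13))
        for seg in merge_matches(matches, 13):
            assert seg.orientation == "reverse"
            assert seg.q_end - seg.q_start == seg.r_end - seg.r_start
            # anti-diagonal: r_end + q_start is the constant of the run
            assert seg.r_end + seg.q_start == len(s)

    def test_empty_input(self):
        assert merge_matches([], 13) == []

    def test_merge_chain_equals_naive_runs(self):
        """find -> merge on random mutated pairs equals runs extracted from
        the naive all-window oracle."""
        rng = random.Random(77)
        for _ in range(3):
            r = _rand_seq(rng, 400)
            q = list(r)
            for _ in range(8):  # sprinkle substitutions
                i = rng.randrange(len(q))
                q[i] = rng.choice([b for b in "ACGT" if b != q[i]])
            q = "".join(q)
            k = 13
            got = {
                (s.q_start, s.q_end, s.r_start, s.r_end, s.orientation)
                for s in merge_matches(
                    find_kmer_matches(SeqRecord("q", q), SeqRecord("r", r),
                                      KmerParams(k)), k)
            }
            expected = set()
            naive = naive_matches(q, r, k)
            for orient in ("forward", "reverse"):
                diag = {}
                for qq, rr, oo in naive:
                    if oo == orient:
                        d = rr - qq if orient == "forward" else rr + qq
                        diag.setdefault(d, []).append(qq)
                for d, qs in diag.items():
                    qs.sort()
                    start = prev = qs[0]
                    runs = []
                    for x in qs[1:]:
                        if x == prev + 1:
                            prev = x
                        else:
                            runs.append((start, prev))
                            start = prev = x
                    runs.append((start, prev))
                    for a, b in runs:
                        if orient == "forward":
                            expected.add((a, b + k, a + d, b + k + d, orient))
                        else:
                            expected.add((a, b + k, d - b, d - a + k, orient))
            assert got == expected


class TestResolveOverlaps:
    def test_longest_wins_in_cluster(self):
        long = _seg(0, 40, 100, 140)
        short = _seg(30, 55, 10, 35)
        assert resolve_overlaps([short, long]) == [long]

    def test_disjoint_all_kept(self):
        a, b = _seg(0, 20, 50, 70), _seg(30, 50, 0, 20)
        assert resolve_overlaps([a, b]) == [b, a]  # sorted by r_start

    def test_tie_smaller_r_start_then_forward(self):
        a = _seg(0, 20, 100, 120, "reverse")
        b = _seg(10, 30, 50, 70, "forward")
        assert resolve_overlaps([a, b]) == [b]
        c = _seg(0, 20, 50, 70, "reverse")
        d = _seg(10, 30, 50, 70, "forward")
        assert resolve_overlaps([c, d]) == [d]  # forward before reverse

    def test_matches_exhaustive_cluster_scan(self):
        rng = random.Random(13)
        for _ in range(100):
            n = rng.randint(0, 12)
            segs = []
            for _ in range(n):
                q0 = rng.randrange(0, 300)
                length = rng.randrange(10, 80)
                r0 = rng.randrange(0, 300)
                segs.append(
                    _seg(q0, q0 + length, r0, r0 + length,
                         rng.choice(["forward", "reverse"]))
                )
            kept = resolve_overlaps(segs)
            # oracle: connected components by repeated pairwise merging
            clusters = [{i} for i in range(n)]
            merged = True
            while merged:
                merged = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        if any(
                            segs[a].q_start < segs[b].q_end
                            and segs[b].q_start < segs[a].q_end
                            for a in clusters[i] for b in clusters[j]
                        ):
                            clusters[i] |= clusters[j]
                            del clusters[j]
                            merged = True
                            break
                    if merged:
                        break
            expected = sorted(
                (
                    min(
                        (segs[i] for i in cl),
                        key=lambda s: (-s.length, s.r_start,
                                       0 if s.orientation == "forward" else 1),
                    )
                    for cl in clusters
                ),
                key=lambda s: s.r_start,
            )
            assert kept == expected
            # kept segments pairwise disjoint on the query
            iv = sorted((s.q_start, s.q_end) for s in kept)
            for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
                assert e1 <= s2


class TestOrderContigs:
    def test_sorted_by_reference_position(self):
        s1 = _seg(0, 50, 5000, 5050, contig="c1", ref="R")
        s2 = _seg(0, 50, 100, 150, contig="c2", ref="R")
        assert order_contigs(["c1", "c2"], ["R"], [s1, s2]) == ["c2", "c1"]

    def test_single_contig(self):
        s = _seg(0, 50, 0, 50, contig="c1", ref="R")
        assert order_contigs(["c1"], ["R"], [s]) == ["c1"]

    def test_unmatched_contigs_last_in_input_order(self):
        s = _seg(0, 50, 0, 50, contig="c2", ref="R")
        assert order_contigs(["c3", "c2", "c1"], ["R"], [s]) == ["c2", "c3", "c1"]

    def test_first_reference_takes_priority(self):
        a = _seg(0, 50, 9000, 9050, contig="c1", ref="R1")
        b = _seg(0, 80, 10, 90, contig="c2", ref="R2")
        assert order_contigs(["c1", "c2"], ["R1", "R2"], [a, b]) == ["c1", "c2"]


class TestBuildLayout:
    def test_identity_full_diagonal(self):
        rng = random.Random(1)
        s = _rand_seq(rng, 500)
        for k in (10, 13, 30):
            layout = build_layout([SeqRecord("c", s)], [SeqRecord("R", s)],
                                  KmerParams(k))
            (seg,) = layout.panels["R"]
            assert (seg.q_start, seg.q_end) == (0, 500)
            assert seg.orientation == "forward"

    def test_reverse_complement_reverse_only(self):
        rng = random.Random(2)
        s = _rand_seq(rng, 300)
        layout = build_layout([SeqRecord("c", s)], [SeqRecord("R", revcomp(s))],
                              KmerParams(13))
        orients = {seg.orientation for seg in layout.panels["R"]}
        assert orients == {"reverse"}

    def test_five_references_five_panels_in_order(self):
        rng = random.Random(4)
        s = _rand_seq(rng, 200)
        refs = [SeqRecord(f"R{i}", _rand_seq(rng, 200)) for i in range(5)]
        layout = build_layout([SeqRecord("c", s)], refs, KmerParams(13))
        assert layout.ref_ids == [f"R{i}" for i in range(5)]

    def test_offsets_cover_contigs_without_overlap(self):
        rng = random.Random(6)
        queries = [SeqRecord(f"c{i}", _rand_seq(rng, 100 + 30 * i)) for i in range(4)]
        ref = SeqRecord("R", queries[2].seq + queries[0].seq)
        layout = build_layout(queries, [ref], KmerParams(13))
        spans = sorted(
            (layout.offsets[c], layout.offsets[c] + layout.contig_lengths[c])
            for c in layout.contig_order
        )
        assert spans[0][0] == 0
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2
        assert spans[-1][1] == layout.query_span

    def test_coverage_non_increasing_in_k(self):
        """Raising k filters the dot plot down: matched diagonal positions at
        k+1 are a subset of those at k, so total coverage only shrinks."""
        rng = random.Random(8)
        r = _rand_seq(rng, 1000)
        q = list(r)
        for _ in range(30):
            i = rng.randrange(len(q))
            q[i] = rng.choice([b for b in "ACGT" if b != q[i]])
        q = "".join(q)
        qr, rr = SeqRecord("q", q), SeqRecord("R", r)
        coverages = []
        prev_positions = None
        for k in (10, 13, 20, 30):
            matches = find_kmer_matches(qr, rr, KmerParams(k))
            positions = {(qq, rr_) for qq, rr_, o in matches if o == "forward"}
            if prev_positions is not None:
                assert positions <= prev_positions
            prev_positions = positions
            segs = merge_matches(matches, k)
            covered = set()
            for s in segs:
                covered.update(range(s.q_start, s.q_end))
            coverages.append(len(covered))
        assert coverages == sorted(coverages, reverse=True)

    def test_all_short_sequences_warns(self):
        with pytest.warns(UserWarning, match="shorter than k"):
            layout = build_layout([SeqRecord("c", "ACGT")],
                                  [SeqRecord("R", "ACGTAC")], KmerParams(13))
        assert all(not segs for segs in layout.panels.values())

    def test_k_range_enforced(self):
        for bad in (9, 31, 0):
            with pytest.raises(ValueError, match="between 10 and 30"):
                KmerParams(bad)
        assert KmerParams().k == 13
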