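"""Self-contained translated homology search (BLASTx-like).

Six-frame translation of the contig, exact peptide word seeding against the
reference CDS set, and ungapped score-maximizing extension with X-drop
termination under BLOSUM62.  Produces :class:`~regsp.formats.HSP` records in
contig nucleotide coordinates so the rest of the pipeline is agnostic to the
HSP source.

This is a test-grade search engine, not a BLAST replacement: extensions are
ungapped, no Karlin-Altschul statistics are computed (the E-value field
carries a monotone transform of the raw score, usable only for ranking), and
raw scores are stored in the bitscore field.  Real analyses should feed the
pipeline genuine BLASTx output instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .cplot import revcomp
from .formats import HSP, SeqRecord

__all__ = ["MiniSearchParams", "six_frame_translate", "search"]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {aa: i for i, aa in enumerate(_BLOSUM62.alphabet)}


def _pair_score(a: str, b: str) -> int:
    """BLOSUM62 score; letters outside the matrix alphabet score like X."""
    ia = _B62_INDEX.get(a, _B62_INDEX["X"])
    ib = _B62_INDEX.get(b, _B62_INDEX["X"])
    return int(_BLOSUM62[ia, ib])


@dataclass(frozen=True)
class MiniSearchParams:
    """Seeding/extension parameters.

    word_size : exact peptide seed length (>= 3).
    x_drop : extension stops once the running score falls this far below
        the best score seen.
    score_threshold : minimum raw extension score for a reported HSP.
    """

    word_size: int = 5
    x_drop: int = 20
    score_threshold: int = 50

    def __post_init__(self) -> None:
        if self.word_size < 3:
            raise ValueError("word_size must be >= 3")
        if self.x_drop <= 0 or self.score_threshold <= 0:
            raise ValueError("x_drop and score_threshold must be positive")


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate a nucleotide string in all six frames (standard code).

    Frames +1..+3 read the sequence at offsets 0..2; frames -1..-3 read the
    reverse complement the same way.  Stops are ``*``.  Sequences shorter
    than 3 nt yield an empty mapping.
    """
    seq = seq.upper()
    if len(seq) < 3:
        return {}
    out: dict[int, str] = {}
    rc = revcomp(seq)
    for off in range(3):
        n = (len(seq) - off) // 3 * 3
        if n:
            out[off + 1] = str(Seq(seq[off : off + n]).translate())
            out[-(off + 1)] = str(Seq(rc[off : off + n]).translate())
    return out


def _aa_to_nt(frame: int, aa_start: int, aa_end: int, contig_len: int) -> tuple[int, int]:
    """Map a 0-based half-open aa interval in a frame translation to 1-based
    inclusive nucleotide coordinates on the forward contig."""
    off = abs(frame) - 1
    if frame > 0:
        return 3 * aa_start + off + 1, 3 * aa_end + off
    # interval lives on the reverse complement; reflect back
    return contig_len - (3 * aa_end + off) + 1, contig_len - (3 * aa_start + off)


def _extend(
    pep: str, prot: str, qa: int, sa: int, w: int, x_drop: int
) -> tuple[int, int, int, int]:
    """Ungapped two-sided extension of an exact word seed.

    Returns the best-scoring aa interval as (q_aa_start, q_aa_end, s_start,
    score); the subject interval has the same length on the same diagonal.
    """
    score = sum(_pair_score(pep[qa + i], prot[sa + i]) for i in range(w))
    # rightward
    best, run = score, score
    right = qa + w
    i, j = qa + w, sa + w
    while i < len(pep) and j < len(prot):
        run += _pair_score(pep[i], prot[j])
        if run > best:
            best, right = run, i + 1
        if best - run > x_drop:
            break
        i += 1
        j += 1
    # leftward
    left = qa
    run = best
    i, j = qa - 1, sa - 1
    while i >= 0 and j >= 0:
        run += _pair_score(pep[i], prot[j])
        if run > best:
            best, left = run, i
        if best - run > x_drop:
            break
        i -= 1
        j -= 1
    return left, right, sa - (qa - left), best


def search(
    contig: SeqRecord,
    proteins: list[SeqRecord],
    params: MiniSearchParams | None = None,
    ref_id: str = "",
) -> list[HSP]:
    """Search one contig against one reference's protein CDS set.

    For every exact ``word_size`` peptide word shared between a frame
    translation and a protein, extend ungapped in both directions and report
    each distinct extension scoring at least the threshold as an HSP.
    Deterministic: no randomness anywhere in the search.
    """
    params = params or MiniSearchParams()
    w = params.word_size
    translations = six_frame_translate(contig.seq)
    hsps: list[HSP] = []
    for prot in proteins:
        # word index over this protein
        index: dict[str, list[int]] = {}
        pseq = prot.seq.rstrip("*")
        for s in range(len(pseq) - w + 1):
            index.setdefault(pseq[s : s + w], []).append(s)
        for frame, pep in translations.items():
            # extensions already computed per diagonal (qa - sa), as q-aa
            # intervals; a seed inside one would re-derive the same alignment
            done: dict[int, list[tuple[int, int]]] = {}
            for qa in range(len(pep) - w + 1):
                word = pep[qa : qa + w]
                if "*" in word:
                    continue
                for sa in index.get(word, ()):
                    diag = qa - sa
                    if any(a <= qa and qa + w <= b for a, b in done.get(diag, ())):
                        continue
                    left, right, s_left, score = _extend(
                        pep, pseq, qa, sa, w, params.x_drop
                    )
                    done.setdefault(diag, []).append((left, right))
                    if score < params.score_threshold:
                        continue
                    qseq = pep[left:right]
                    sseq = pseq[s_left : s_left + (right - left)]
                    matches = sum(a == b for a, b in zip(qseq, sseq))
                    q_start, q_end = _aa_to_nt(frame, left, right, len(contig.seq))
                    hsps.append(
                        HSP(
                            contig_id=contig.id,
                            ref_id=ref_id,
                            gene_id=prot.id,
                            q_start=q_start,
                            q_end=q_end,
                            s_start=s_left + 1,
                            s_end=s_left + (right - left),
                            frame=frame,
                            align_len=right - left,
                            pident=100.0 * matches / (right - left),
                            evalue=2.0 ** (-score),
                            bitscore=float(score),
                            qseq_aa=qseq,
                            sseq_aa=sseq,
                        )
                    )
    hsps.sort(key=lambda h: (-h.bitscore, h.evalue, h.q_start, h.gene_id))
    return hsps
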