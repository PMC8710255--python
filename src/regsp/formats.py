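"""Readers and writers for every file the pipeline touches.

FASTA / multi-FASTA input (nucleotide and protein), the ``***``-separated
multi-reference protein CDS format, BLAST tabular HSP files, and the
``.sorted`` / ``.regsp`` plain-text gene reports.

Coordinate convention: HSPs keep BLAST's 1-based inclusive coordinates on
disk and in the :class:`HSP` record; interval arithmetic downstream converts
to 0-based half-open at the boundary of the grouping module.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "ReferenceSet",
    "HSP",
    "FastaFormatError",
    "AlphabetError",
    "ReferenceCountError",
    "TabularParseError",
    "read_fasta",
    "write_fasta",
    "read_protein_reference_sets",
    "read_blast_tabular",
    "write_blast_tabular",
    "write_report",
    "report_blocks",
]

# IUPAC nucleotide codes (ambiguity allowed) and amino acids with '*' stop.
_NUC_LETTERS = frozenset("ACGTUNRYSWKMBDHV")
_PROT_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_SEPARATOR_RE = re.compile(r"^\*{3,}$")


class FastaFormatError(ValueError):
    """Raised when a file is not parseable FASTA."""


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside its declared alphabet."""


class ReferenceCountError(ValueError):
    """Raised when the number of protein sets differs from the expected count."""


class TabularParseError(ValueError):
    """Raised on a malformed BLAST tabular line."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence: id is the first whitespace-delimited header token."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """One reference: its nucleotide sequence plus the protein CDS set.

    ``proteins`` may be empty only in plot-only runs, where no translated
    search is performed.
    """

    ref_id: str
    nucleotide: SeqRecord
    proteins: list[SeqRecord] = field(default_factory=list)


@dataclass
class HSP:
    """One BLASTx-style local alignment (high-scoring segment pair).

    ``q_start``/``q_end`` are 1-based inclusive nucleotide positions on the
    contig with ``q_start <= q_end`` regardless of strand; the strand lives in
    the sign of ``frame``.  ``s_start``/``s_end`` are 1-based positions on the
    subject protein.
    """

    contig_id: str
    ref_id: str
    gene_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int
    align_len: int
    pident: float
    evalue: float
    bitscore: float
    qseq_aa: str = ""
    sseq_aa: str = ""

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"HSP {self.contig_id}/{self.gene_id}: q_start {self.q_start} "
                f"> q_end {self.q_end}"
            )
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if self.qseq_aa and self.sseq_aa and len(self.qseq_aa) != len(self.sseq_aa):
            raise ValueError("aligned qseq/sseq must have equal length")

    @property
    def q_interval(self) -> tuple[int, int]:
        """Query interval as 0-based half-open ``(start, end)``."""
        return (self.q_start - 1, self.q_end)


def _check_alphabet(rec: SeqRecord, alphabet: str) -> None:
    letters = _NUC_LETTERS if alphabet == "nucleotide" else _PROT_LETTERS
    bad = set(rec.seq) - letters
    if bad:
        raise AlphabetError(
            f"record {rec.id!r}: illegal {alphabet} letters {sorted(bad)!r}"
        )


def _parse_fasta_text(text: str, alphabet: str, origin: str) -> list[SeqRecord]:
    if ">" not in text:
        raise FastaFormatError(f"{origin}: no FASTA header ('>') found")
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{origin}: record with empty id")
        if rec.id in seen:
            raise FastaFormatError(f"{origin}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{origin}: record {rec.id!r} has empty sequence")
        sr = SeqRecord(id=rec.id, seq=seq, description=rec.description)
        _check_alphabet(sr, alphabet)
        out.append(sr)
    if not out:
        raise FastaFormatError(f"{origin}: no records parsed")
    return out


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SeqRecord]:
    """Read a (multi-)FASTA file into :class:`SeqRecord` objects, in file order.

    Sequences are uppercased with line breaks removed.  Duplicate ids are
    rejected because ids key every downstream join.

    Parameters
    ----------
    path:
        FASTA file.
    alphabet:
        ``"nucleotide"`` (IUPAC codes, ambiguity allowed) or ``"protein"``
        (amino acids plus ``*`` stop).
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    text = Path(path).read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty file")
    return _parse_fasta_text(text, alphabet, str(path))


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_protein_reference_sets(
    path: str | Path, n_expected: int
) -> list[list[SeqRecord]]:
    """Read an amino-acid FASTA holding the CDS sets of several references.

    Consecutive references are separated by a line of three or more ``*``
    characters and nothing else.  Returns one protein-record list per
    reference, in file order.

    Raises
    ------
    ReferenceCountError
        If the number of sets found differs from ``n_expected``.
    FastaFormatError
        If a separator delimits an empty set.
    """
    text = Path(path).read_text()
    chunks: list[list[str]] = [[]]
    for line in text.splitlines():
        if _SEPARATOR_RE.match(line.strip()):
            chunks.append([])
        else:
            chunks[-1].append(line)
    sets: list[list[SeqRecord]] = []
    for i, chunk in enumerate(chunks):
        body = "\n".join(chunk)
        if not body.strip():
            raise FastaFormatError(
                f"{path}: empty reference set at position {i + 1} "
                "(nothing between separators)"
            )
        sets.append(_parse_fasta_text(body, "protein", f"{path} (set {i + 1})"))
    if len(sets) != n_expected:
        raise ReferenceCountError(
            f"{path}: found {len(sets)} protein set(s) but {n_expected} "
            "reference(s) were provided"
        )
    return sets


# BLAST tabular dialect: outfmt-6-style columns, with the query frame and
# optionally the aligned sequences appended.
TABULAR_COLUMNS = (
    "qseqid sseqid pident length qstart qend sstart send "
    "evalue bitscore qframe qseq sseq"
).split()


def _split_subject(sseqid: str, ref_map: Mapping[str, str] | None) -> tuple[str, str]:
    """Resolve (ref_id, gene_id) for a subject id.

    Subject ids of the form ``ref::gene`` are split directly; otherwise the
    gene is looked up in ``ref_map`` (gene id -> reference id) built from the
    multi-reference protein file.  With neither, the reference is unknown and
    left empty for the caller to assign.
    """
    if "::" in sseqid:
        ref_id, gene_id = sseqid.split("::", 1)
        return ref_id, gene_id
    if ref_map is not None and sseqid in ref_map:
        return ref_map[sseqid], sseqid
    return "", sseqid


def read_blast_tabular(
    path: str | Path, ref_map: Mapping[str, str] | None = None
) -> list[HSP]:
    """Parse a BLAST tabular (outfmt-6-style) file into HSPs, in file order.

    Expected columns: ``qseqid sseqid pident length qstart qend sstart send
    evalue bitscore qframe [qseq sseq]``.  Lines starting with ``#`` are
    comments (outfmt-7 style) and skipped.  When ``qstart > qend`` in the raw
    line (minus-strand BLASTx convention) the two are swapped; orientation is
    carried by the frame sign.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (11, 13):
                raise TabularParseError(
                    f"{path}:{lineno}: expected 11 or 13 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[4]), int(fields[5])
                sstart, send = int(fields[6]), int(fields[7])
                evalue = float(fields[8])
                bitscore = float(fields[9])
                frame = int(fields[10])
            except ValueError as exc:
                raise TabularParseError(f"{path}:{lineno}: {exc}") from exc
            qseq, sseq = (fields[11], fields[12]) if len(fields) == 13 else ("", "")
            if qstart > qend:
                qstart, qend = qend, qstart
            ref_id, gene_id = _split_subject(sseqid, ref_map)
            hsps.append(
                HSP(
                    contig_id=qseqid,
                    ref_id=ref_id,
                    gene_id=gene_id,
                    q_start=qstart,
                    q_end=qend,
                    s_start=sstart,
                    s_end=send,
                    frame=frame,
                    align_len=length,
                    pident=pident,
                    evalue=evalue,
                    bitscore=bitscore,
                    qseq_aa=qseq,
                    sseq_aa=sseq,
                )
            )
    return hsps


def write_blast_tabular(hsps: Iterable[HSP], path: str | Path) -> None:
    """Write HSPs in the tabular dialect read by :func:`read_blast_tabular`.

    The subject column is emitted as ``ref::gene`` so the reference assignment
    survives a round trip.
    """
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(TABULAR_COLUMNS[:11]) + "\n")
        for h in hsps:
            sseqid = f"{h.ref_id}::{h.gene_id}" if h.ref_id else h.gene_id
            row = [
                h.contig_id,
                sseqid,
                f"{h.pident:.1f}",
                str(h.align_len),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
                f"{h.frame:+d}",
            ]
            fh.write("\t".join(row) + "\n")


def _format_frame(frame: int) -> str:
    return f"{frame:+d}"


def write_report(
    reports: Sequence,
    stage: str,
    path: str | Path,
    contig_seqs: Mapping[str, str] | None = None,
    provenance: str = "",
) -> None:
    """Write the ``.sorted`` / ``.regsp`` plain-text gene report.

    ``stage="sorted"`` includes every (contig, reference) report — the state
    before the minimum sub-gene count M is applied; ``stage="regsp"`` keeps
    only M-valid ones.  Each block carries, in order: the contig header with
    the reference and the total gene count, then per gene its id, the matched
    query nucleotide subsequence (when contig sequences are supplied), one
    metrics line (query positions, alignment length, bit score, E-value,
    translation frame), and the aligned translated-query/subject pair.  Genes
    within a block are sorted by descending bit score; blocks follow the
    report order (references in input order).
    """
    if stage not in ("sorted", "regsp"):
        raise ValueError(f"unknown report stage {stage!r}")
    lines: list[str] = [f"# regsp gene search report | stage={stage}"]
    if provenance:
        lines.append(f"# hsp source: {provenance}")
    for rep in reports:
        if stage == "regsp" and not rep.valid:
            continue
        lines.append(
            f">{rep.contig_id} [reference {rep.ref_id}] genes={rep.subgene_count}"
        )
        for h in rep.surviving:
            lines.append(f"gene={h.gene_id}")
            if contig_seqs and h.contig_id in contig_seqs:
                lines.append(f"query_nt={contig_seqs[h.contig_id][h.q_start - 1 : h.q_end]}")
            lines.append(
                f"qstart={h.q_start} qend={h.q_end} alen={h.align_len} "
                f"bitscore={h.bitscore:g} evalue={h.evalue:g} "
                f"frame={_format_frame(h.frame)}"
            )
            if h.qseq_aa:
                lines.append(f"q_aa={h.qseq_aa}")
                lines.append(f"s_aa={h.sseq_aa}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines).rstrip("\n") + "\n")


def report_blocks(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse block headers out of a report file.

    Returns ``(contig_id, ref_id, gene_count)`` per block, in file order.
    """
    blocks: list[tuple[str, str, int]] = []
    pat = re.compile(r"^>(.+) \[reference (.+)\] genes=(\d+)$")
    with open(path) as fh:
        for line in fh:
            m = pat.match(line.rstrip("\n"))
            if m:
                blocks.append((m.group(1), m.group(2), int(m.group(3))))
    return blocks
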