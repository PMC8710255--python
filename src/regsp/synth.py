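"""Synthetic fixtures: the worked two-contig/three-reference HSP example and
randomized genome/contig generators for end-to-end and property tests.

``worked_example_fixture`` freezes one concrete realization of the worked
example that motivates the N/M parameters: only the overlap topology and the score order
are fixed by the scenario, so coordinates and scores here are invented but
deterministic.  ``make_genome_and_contigs`` builds a reference genome of
valid ORFs, fragments mutated copies into contigs, and reports the ground
truth of which genes each contig carries — the substrate for recovery tests
of the translated search plus grouping pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cplot import revcomp
from .formats import HSP, ReferenceSet, SeqRecord

__all__ = ["SynthConfig", "worked_example_fixture", "WORKED_EXAMPLE_EXPECTED", "make_genome_and_contigs"]

# (contig, reference, sub-gene count, valid) at N=4, M=4 for the fixture below
WORKED_EXAMPLE_EXPECTED: list[tuple[str, str, int, bool]] = [
    ("Contig_1", "Reference_1", 5, True),
    ("Contig_2", "Reference_1", 7, True),
    ("Contig_2", "Reference_2", 3, False),
    ("Contig_1", "Reference_3", 4, True),
    ("Contig_2", "Reference_3", 1, False),
]

# qseqid, sseqid, pident, alen, qstart, qend, sstart, send, evalue, bitscore, frame
_WORKED_EXAMPLE_ROWS: list[tuple] = [
    # Contig 1 vs Reference 1: hits a,b overlap (350-400); c,d,e disjoint -> 5 survive
    ("Contig_1", "Reference_1::psaA", 92.0, 100, 101, 400, 1, 100, 1e-55, 210.0, 2),
    ("Contig_1", "Reference_1::psaB", 90.0, 117, 350, 700, 1, 117, 1e-50, 195.0, -1),
    ("Contig_1", "Reference_1::psbA", 88.0, 66, 801, 1000, 10, 75, 1e-40, 150.0, 2),
    ("Contig_1", "Reference_1::psbB", 85.0, 66, 1101, 1300, 5, 70, 1e-35, 140.0, 2),
    ("Contig_1", "Reference_1::psbC", 83.0, 66, 1401, 1600, 1, 66, 1e-30, 120.0, -3),
    # Contig 2 vs Reference 1: hits 1-4 disjoint; 5,6,7,8 mutually overlap,
    # hit 8 scores lowest and is the one discarded at N=4 -> 7 survive
    ("Contig_2", "Reference_1::atpA", 91.0, 66, 101, 300, 1, 66, 1e-45, 180.0, 2),
    ("Contig_2", "Reference_1::atpB", 90.0, 66, 401, 600, 1, 66, 1e-44, 175.0, 2),
    ("Contig_2", "Reference_1::atpI", 89.0, 66, 701, 900, 1, 66, 1e-41, 160.0, -2),
    ("Contig_2", "Reference_1::petA", 88.0, 66, 1001, 1200, 1, 66, 1e-39, 155.0, 2),
    ("Contig_2", "Reference_1::petB", 95.0, 100, 1301, 1600, 1, 100, 1e-60, 220.0, 2),
    ("Contig_2", "Reference_1::rbcL", 93.0, 100, 1350, 1650, 1, 100, 1e-52, 200.0, 3),
    ("Contig_2", "Reference_1::rpl2", 92.0, 100, 1400, 1700, 1, 100, 1e-48, 190.0, -1),
    ("Contig_2", "Reference_1::psbD", 61.0, 100, 1450, 1750, 1, 100, 1e-20, 90.0, 2),
    # Contig 1 vs Reference 2: no hits at all
    # Contig 2 vs Reference 2: three disjoint hits -> 3 < M, invalid
    ("Contig_2", "Reference_2::psaA", 80.0, 66, 101, 300, 1, 66, 1e-33, 130.0, 2),
    ("Contig_2", "Reference_2::psbA", 79.0, 66, 501, 700, 1, 66, 1e-31, 125.0, 2),
    ("Contig_2", "Reference_2::rbcL", 76.0, 66, 901, 1100, 1, 66, 1e-27, 110.0, -1),
    # Contig 1 vs Reference 3: four disjoint hits -> valid at M=4
    ("Contig_1", "Reference_3::psaA", 84.0, 66, 101, 300, 1, 66, 1e-42, 170.0, 2),
    ("Contig_1", "Reference_3::psbA", 84.0, 66, 501, 700, 1, 66, 1e-41, 165.0, 2),
    ("Contig_1", "Reference_3::atpA", 82.0, 66, 901, 1100, 1, 66, 1e-38, 150.0, 3),
    ("Contig_1", "Reference_3::rbcL", 81.0, 66, 1301, 1500, 1, 66, 1e-36, 145.0, 2),
    # Contig 2 vs Reference 3: a single hit -> 1 < M, invalid
    ("Contig_2", "Reference_3::petB", 72.0, 66, 201, 400, 1, 66, 1e-22, 100.0, 2),
]


def worked_example_fixture() -> tuple[str, list[tuple[str, str, int, bool]]]:
    """The worked two-contig/three-reference example, as BLAST tabular text.

    Returns the tabular text (the dialect of
    :func:`regsp.formats.read_blast_tabular`, subjects as ``ref::gene``) and
    the expected per-pair (contig, reference, sub-gene count, valid) table
    for N=4, M=4.  Deterministic; frozen by a golden-file test.
    """
    header = (
        "# qseqid\tsseqid\tpident\tlength\tqstart\tqend\tsstart\tsend"
        "\tevalue\tbitscore\tqframe\n"
    )
    lines = []
    for row in _WORKED_EXAMPLE_ROWS:
        q, s, pid, alen, qs, qe, ss, se, ev, bs, fr = row
        lines.append(
            f"{q}\t{s}\t{pid:.1f}\t{alen}\t{qs}\t{qe}\t{ss}\t{se}"
            f"\t{ev:.0e}\t{bs:.1f}\t{fr:+d}"
        )
    return header + "\n".join(lines) + "\n", list(WORKED_EXAMPLE_EXPECTED)


def worked_example_hsps() -> list[HSP]:
    """The fixture rows as in-memory HSP records (file round trip skipped)."""
    out = []
    for q, s, pid, alen, qs, qe, ss, se, ev, bs, fr in _WORKED_EXAMPLE_ROWS:
        ref_id, gene_id = s.split("::", 1)
        out.append(
            HSP(
                contig_id=q, ref_id=ref_id, gene_id=gene_id,
                q_start=qs, q_end=qe, s_start=ss, s_end=se, frame=fr,
                align_len=alen, pident=pid, evalue=ev, bitscore=bs,
            )
        )
    return out


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic genome/contig generator.

    Defaults emulate a small organellar-scale locus: a handful of
    single-exon ORFs (organellar protein genes are intronless in the common
    case) of 150-450 bp separated by short intergenic spacers, cut into a
    couple of contigs with point substitutions at the divergence typical of
    congeneric organellar references (5%), a fraction of contigs assembled
    in reverse orientation.
    """

    seed: int = 0
    n_genes: int = 8
    gene_len_range: tuple[int, int] = (150, 450)
    intergenic_len_range: tuple[int, int] = (60, 150)
    contig_count: int = 2
    substitution_rate: float = 0.05
    revcomp_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        if not (0.0 <= self.revcomp_fraction <= 1.0):
            raise ValueError("revcomp_fraction must be in [0, 1]")
        if self.n_genes < 1 or self.contig_count < 1:
            raise ValueError("n_genes and contig_count must be >= 1")
        for lo, hi in (self.gene_len_range, self.intergenic_len_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.contig_count > self.n_genes:
            raise ValueError("cannot cut more contigs than genes")


_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_orf(rng: np.random.Generator, lo: int, hi: int) -> str:
    """An ORF: ATG start, random sense codons, one terminal stop; length a
    multiple of 3 within [lo, hi]."""
    n_codons = int(rng.integers(lo, hi + 1)) // 3
    n_codons = max(n_codons, 3)
    inner = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in inner) + stop


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def make_genome_and_contigs(
    config: SynthConfig,
) -> tuple[ReferenceSet, list[SeqRecord], dict[str, list[tuple[str, int, int]]]]:
    """Build a synthetic reference and query contigs with known gene content.

    The reference genome alternates intergenic spacers and non-overlapping
    ORFs; its protein set is the ORF translations (stop excluded).  Contigs
    are cut between genes from a mutated copy of the genome, so every gene
    is fully contained in exactly one contig; a random subset of contigs is
    reverse-complemented.

    Returns ``(reference, contigs, truth)`` where ``truth`` maps each contig
    id to ``(gene_id, start, end)`` triples in 0-based half-open contig
    coordinates (post-orientation).
    """
    from Bio.Seq import Seq  # local import: only needed for translation here

    rng = np.random.default_rng(config.seed)
    glo, ghi = config.gene_len_range
    ilo, ihi = config.intergenic_len_range

    parts: list[str] = [_random_seq(rng, int(rng.integers(ilo, ihi + 1)))]
    gene_intervals: list[tuple[str, int, int]] = []  # genome coords, half-open
    proteins: list[SeqRecord] = []
    pos = len(parts[0])
    for g in range(config.n_genes):
        orf = _random_orf(rng, glo, ghi)
        gid = f"gene_{g + 1:02d}"
        gene_intervals.append((gid, pos, pos + len(orf)))
        proteins.append(SeqRecord(id=gid, seq=str(Seq(orf[:-3]).translate())))
        parts.append(orf)
        pos += len(orf)
        spacer = _random_seq(rng, int(rng.integers(ilo, ihi + 1)))
        parts.append(spacer)
        pos += len(spacer)
    genome = "".join(parts)

    # cut points between genes: pick contig_count-1 distinct gene boundaries
    if config.contig_count > 1:
        boundaries = sorted(
            rng.choice(
                np.arange(1, config.n_genes), size=config.contig_count - 1,
                replace=False,
            )
        )
    else:
        boundaries = []
    # gene index ranges per contig
    edges = [0, *boundaries, config.n_genes]
    mutated = _mutate(rng, genome, config.substitution_rate)

    contigs: list[SeqRecord] = []
    truth: dict[str, list[tuple[str, int, int]]] = {}
    for c in range(config.contig_count):
        first, last = edges[c], edges[c + 1]
        # contig spans from midpoint of spacer before first gene to midpoint
        # of spacer after the last gene (genome ends for outermost contigs)
        start = 0 if c == 0 else (gene_intervals[first - 1][2] + gene_intervals[first][1]) // 2
        end = (
            len(genome)
            if c == config.contig_count - 1
            else (gene_intervals[last - 1][2] + gene_intervals[last][1]) // 2
        )
        seq = mutated[start:end]
        cid = f"contig_{c + 1}"
        flipped = bool(rng.random() < config.revcomp_fraction)
        entries = []
        for gid, gs, ge in gene_intervals[first:last]:
            a, b = gs - start, ge - start
            if flipped:
                a, b = len(seq) - b, len(seq) - a
            entries.append((gid, a, b))
        if flipped:
            seq = revcomp(seq)
            entries.reverse()
        contigs.append(SeqRecord(id=cid, seq=seq))
        truth[cid] = entries

    reference = ReferenceSet(
        ref_id="reference_1",
        nucleotide=SeqRecord(id="reference_1", seq=genome),
        proteins=proteins,
    )
    return reference, contigs, truth
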