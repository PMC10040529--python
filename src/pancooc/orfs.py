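"""Six-frame ORF prediction on nucleotide contigs.

Each of the six reading frames is scanned stop-to-stop; within each
stop-bounded segment the first start codon opens at most one ORF, which is
kept if its translated product reaches the minimum length.  Coordinates are
always reported 1-based inclusive on the forward strand (GFF3 convention),
and the reported span includes the terminal stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nucleotide(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"ambiguous or invalid nucleotide characters: {sorted(bad)}"
        )


class MalformedCdsError(ValueError):
    """Raised when a putative CDS contains an internal stop codon."""


def translate(cds: str) -> str:
    """Translate a CDS under the standard code, dropping a trailing stop.

    Internal stop codons and ambiguous bases are errors: this translator
    is for exact coding sequences, not for scanning.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds:
        raise ValueError("empty CDS")
    _check_nucleotide(cds)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise MalformedCdsError(f"internal stop codon at codon {i + 1}")
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


@dataclass(frozen=True)
class OrfParams:
    """Thresholds for the six-frame scan."""

    min_protein_length: int = 100
    start_codons: frozenset[str] = frozenset({"ATG"})
    require_stop: bool = True

    def __post_init__(self) -> None:
        if self.min_protein_length < 1:
            raise ValueError("min_protein_length must be >= 1")
        bad = {c for c in self.start_codons if len(c) != 3 or set(c) - set("ACGT")}
        if bad or not self.start_codons:
            raise ValueError("start_codons must be non-empty ACGT triplets")


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF with forward-strand coordinates.

    ``start``/``end`` are 1-based inclusive on the forward strand whatever
    the coding strand; ``frame`` is 0|1|2 relative to the coding strand.
    The span includes the terminal stop codon when present, so
    ``len(protein) == (end - start + 1) // 3 - 1`` for stop-terminated ORFs.
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def orf_id(self) -> str:
        return (
            f"{self.genome_id}|{self.contig_id}|{self.start}|{self.end}|{self.strand}"
        )


def genome_of(orf_id: str) -> str:
    """Recover the genome id from the canonical orf_id convention."""
    return orf_id.split("|", 1)[0]


def _scan_strand(
    seq: str, params: OrfParams
) -> Iterable[tuple[int, int, int, str]]:
    """Yield (start0, end0_exclusive, frame, protein) on the given strand."""
    n = len(seq)
    for frame in range(3):
        seg_start: int | None = None  # 0-based position of the opening ATG
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if seg_start is not None:
                    protein = translate(seq[seg_start : pos + 3])
                    if len(protein) >= params.min_protein_length:
                        yield seg_start, pos + 3, frame, protein
                    seg_start = None
            elif seg_start is None and codon in params.start_codons:
                seg_start = pos
            pos += 3
        if seg_start is not None and not params.require_stop:
            cds = seq[seg_start : pos]
            protein = translate(cds)
            if len(protein) >= params.min_protein_length:
                yield seg_start, pos, frame, protein


def find_orfs(
    contig: str,
    params: OrfParams | None = None,
    genome_id: str = "genome",
    contig_id: str = "contig",
) -> list[OrfRecord]:
    """Predict ORFs on both strands of a contig.

    Output is sorted by (contig_id, start, end, strand) — a pure function
    of coordinates, never of discovery order.
    """
    params = params or OrfParams()
    if not contig:
        raise ValueError("empty contig")
    contig = contig.upper()
    _check_nucleotide(contig)
    L = len(contig)
    records: list[OrfRecord] = []
    for s0, e0, frame, protein in _scan_strand(contig, params):
        records.append(
            OrfRecord(genome_id, contig_id, s0 + 1, e0, "+", frame, protein)
        )
    rc = reverse_complement(contig)
    for s0, e0, frame, protein in _scan_strand(rc, params):
        # position i (0-based) on the reverse complement is forward L-1-i
        records.append(
            OrfRecord(genome_id, contig_id, L - e0 + 1, L - s0, "-", frame, protein)
        )
    records.sort(key=lambda r: (r.contig_id, r.start, r.end, r.strand))
    return records


def find_orfs_in_genome(
    contigs: Mapping[str, str],
    params: OrfParams | None = None,
    genome_id: str = "genome",
) -> list[OrfRecord]:
    records: list[OrfRecord] = []
    for contig_id in sorted(contigs):
        records.extend(
            find_orfs(contigs[contig_id], params, genome_id, contig_id)
        )
    records.sort(key=lambda r: (r.contig_id, r.start, r.end, r.strand))
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(records: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.orf_id}\n")
            for i in range(0, len(rec.protein), 70):
                fh.write(rec.protein[i : i + 70] + "\n")


def write_gff3(records: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "pancooc",
                        "ORF",
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        "0",
                        f"ID={rec.orf_id}",
                    ]
                )
                + "\n"
            )
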