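"""Synthetic genome generator with planted gene families.

Emulates the input side of the halotolerance screen: a handful of closely
related strains whose genomes carry gene families in chosen per-genome copy
numbers, so the association between family abundance and the maximum-NaCl
phenotype is known in advance.  Defaults mirror the six-strain study design:
phenotype vector (10, 9, 9, 5, 4, 3) % w/v NaCl in decreasing order, planted
families whose abundance patterns reproduce the printed co-occurrence values
(0.97, 0.81, 0.84), a constant core family, an anti-correlated family, and
unrelated background families.

Design notes
------------
* Within a family, copies are the prototype protein mutated at a small
  per-residue substitution rate, far below the clustering threshold;
  distinct families are independent random proteins, far above it.
* The gene's initial Met is never mutated, so the ATG-start ORF caller
  recovers every planted gene exactly.
* The default reverse-translation codon table is chosen so that the five
  non-coding reading frames of a gene are rich in stop codons, and spacer
  DNA carries TTAATTAATTAA guard blocks (which read as stops in all six
  frames and equal their own reverse complement).  Every planted gene is
  additionally validated to carry no shadow ORF in any other frame
  (deterministic redraws from the same rng stream otherwise), so the ORF
  caller finds exactly the planted genes and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import PhenotypeTable, pearson_cooccurrence
from .orfs import STOP_CODONS, OrfParams, find_orfs, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One codon per residue, chosen to maximise stop-codon density in the five
#: non-coding reading frames of a random coding sequence: TTA (L) and TCA (S)
#: read as stops on the reverse strand, and the codon suffixes/prefixes make
#: cross-junction triplets hit a stop in every shifted frame with probability
#: about 0.07-0.11 per codon.
DEFAULT_CODON_TABLE: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAG", "F": "TTT",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAG", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "AGA",
    "S": "TCA", "T": "ACT", "V": "GTA", "W": "TGG", "Y": "TAT",
}

#: Self-reverse-complementary block containing a stop codon in all six frames.
GUARD_BLOCK = "TTAATTAATTAA"

#: Table-1 phenotype: maximum NaCl (%, w/v) per strain, decreasing.
DEFAULT_PHENOTYPE = (10.0, 9.0, 9.0, 5.0, 4.0, 3.0)
DEFAULT_STRAINS = (
    "aestiaquae",
    "gangjinensis",
    "luteolus",
    "aquaemixtae",
    "sediminis",
    "confluentis",
)


def mutate_protein(protein: str, rate: float, seed: int | np.random.Generator) -> str:
    """Substitute each residue independently with probability ``rate``.

    A substituted position always receives a *different* residue, drawn
    uniformly from the remaining 19, so rate=1 changes every position.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = rng.random(len(protein)) < rate
    out = list(protein)
    for i in np.flatnonzero(hits):
        alternatives = AMINO_ACIDS.replace(out[i], "")
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def reverse_translate(
    protein: str, codon_table: Mapping[str, str] | None = None
) -> str:
    """Deterministic coding sequence for a protein: codons plus a TAA stop.

    With the default table a Met-initial protein yields an ATG-led CDS of
    length 3*(len+1); ``translate`` round-trips it exactly.
    """
    table = codon_table or DEFAULT_CODON_TABLE
    stops = set(table.values()) & STOP_CODONS
    if stops:
        raise ValueError(f"codon table maps residues to stop codons: {sorted(stops)}")
    try:
        body = "".join(table[r] for r in protein)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from codon table") from exc
    if not protein:
        raise ValueError("empty protein")
    return body + "TAA"


@dataclass(frozen=True)
class FamilySpec:
    """A gene family to plant: per-strain copy numbers and protein length."""

    family_id: str
    copy_counts: tuple[int, ...]
    protein_length: int = 120
    role: str = "planted"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copy_counts):
            raise ValueError("copy counts must be non-negative")
        if not any(self.copy_counts):
            raise ValueError(f"family {self.family_id}: all-zero copy counts")
        if self.protein_length < 2:
            raise ValueError("protein_length must be >= 2 (Met + body)")
        if self.role not in ("planted", "background"):
            raise ValueError("role must be 'planted' or 'background'")


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic dataset."""

    strains: tuple[str, ...] = DEFAULT_STRAINS
    phenotype_values: tuple[float, ...] = DEFAULT_PHENOTYPE
    families: tuple[FamilySpec, ...] = ()
    substitution_rate: float = 0.05
    spacer_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        if len(self.strains) != len(self.phenotype_values):
            raise ValueError("strains and phenotype_values length mismatch")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be non-negative")
        for fam in self.families:
            if len(fam.copy_counts) != len(self.strains):
                raise ValueError(
                    f"family {fam.family_id}: copy_counts length != n strains"
                )

    @property
    def phenotype(self) -> PhenotypeTable:
        return PhenotypeTable(strains=self.strains, values=self.phenotype_values)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one family: counts and their expected co-occurrence."""

    family_id: str
    copy_counts: tuple[int, ...]
    expected_cooccurrence: float | None


@dataclass(frozen=True)
class SimulatedDataset:
    """Genomes (one contig per strain by default), phenotype and truth."""

    config: SimConfig
    genomes: dict[str, dict[str, str]]  # strain -> contig_id -> sequence
    phenotype: PhenotypeTable
    truth: tuple[TruthRecord, ...]
    prototypes: dict[str, str]  # family_id -> prototype protein
    #: strain -> planted (family_id, protein) pairs in genome placement order
    planted: dict[str, tuple[tuple[str, str], ...]]


def default_families(
    n_background: int = 30, protein_length: int = 120, seed: int = 0
) -> tuple[FamilySpec, ...]:
    """The default family panel: five planted patterns plus background.

    Planted patterns are the abundance vectors whose correlation with the
    default phenotype reproduces the study's printed values: presence in
    the three most tolerant strains (0.97), in the top four (0.81), a
    two-copy variant (0.84), a constant core family (undefined) and an
    anti-correlated family (-0.97).  Background families get random copy
    counts in {0, 1, 2} per strain.
    """
    planted = (
        FamilySpec("planted_top3", (1, 1, 1, 0, 0, 0), protein_length),
        FamilySpec("planted_top4", (1, 1, 1, 1, 0, 0), protein_length),
        FamilySpec("planted_top3_dup", (1, 1, 2, 0, 0, 0), protein_length),
        FamilySpec("planted_core", (1, 1, 1, 1, 1, 1), protein_length),
        FamilySpec("planted_inverse", (0, 0, 0, 1, 1, 1), protein_length),
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBAC]))
    background = []
    for k in range(1, n_background + 1):
        while True:
            counts = tuple(
                int(c) for c in rng.choice(3, size=6, p=(0.35, 0.50, 0.15))
            )
            if any(counts):
                break
        background.append(
            FamilySpec(f"background_{k:02d}", counts, protein_length, role="background")
        )
    return planted + tuple(background)


def default_config(seed: int = 0, n_background: int = 30) -> SimConfig:
    return SimConfig(families=default_families(n_background, seed=seed), seed=seed)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length - 1))
    return "M" + body


#: Shadow-ORF validation bound: no spurious ORF of >= this many residues may
#: survive in any frame of a planted gene (matches the ORF caller's default
#: minimum protein length).
_VALIDATE_MIN_LEN = 100
_MAX_DRAWS = 100


def _gene_is_clean(protein: str) -> bool:
    """True iff the guarded CDS of ``protein`` yields exactly the gene itself.

    Scans guard + CDS + guard with the six-frame ORF caller; the planted
    gene must be the only ORF found.  Because spacer guard blocks stop every
    frame on both strands, per-gene cleanliness implies genome-wide exact
    recovery.
    """
    cds = reverse_translate(protein)
    seq = GUARD_BLOCK + cds + GUARD_BLOCK
    params = OrfParams(min_protein_length=min(_VALIDATE_MIN_LEN, len(protein)))
    records = find_orfs(seq, params)
    return (
        len(records) == 1
        and records[0].strand == "+"
        and records[0].protein == protein
    )


def _draw_clean(draw, what: str) -> str:
    """Redraw from the rng stream until the gene passes shadow validation."""
    for _ in range(_MAX_DRAWS):
        protein = draw()
        if _gene_is_clean(protein):
            return protein
    raise RuntimeError(f"could not draw a shadow-free {what} in {_MAX_DRAWS} tries")


def _spacer(rng: np.random.Generator, nominal: int) -> str:
    """Random intergenic DNA with guard blocks every <= 72 nt.

    Always starts and ends with a guard block so the codon immediately
    upstream of a gene, in the gene's frame, is a stop on both strands.
    """
    parts = [GUARD_BLOCK]
    remaining = max(0, nominal - len(GUARD_BLOCK))
    while remaining > len(GUARD_BLOCK):
        chunk = int(min(60, remaining - len(GUARD_BLOCK)))
        parts.append("".join("ACGT"[i] for i in rng.integers(4, size=chunk)))
        parts.append(GUARD_BLOCK)
        remaining -= chunk + len(GUARD_BLOCK)
    if len(parts) == 1:
        parts.append(GUARD_BLOCK)
    return "".join(parts)


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate genomes, phenotype and truth ledger from a SimConfig.

    Fully reproducible: all randomness flows from ``config.seed``.  Each
    strain's single contig carries, for every family with count k there,
    k mutated copies of the family prototype in randomised order,
    separated by guarded spacer DNA.
    """
    if not config.families:
        raise ValueError("config lists no families")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    prototypes = {
        fam.family_id: _draw_clean(
            lambda: _random_protein(rng, fam.protein_length),
            f"prototype for {fam.family_id}",
        )
        for fam in config.families
    }
    y = config.phenotype.y
    truth = tuple(
        TruthRecord(
            family_id=fam.family_id,
            copy_counts=fam.copy_counts,
            expected_cooccurrence=pearson_cooccurrence(fam.copy_counts, y),
        )
        for fam in config.families
    )
    genomes: dict[str, dict[str, str]] = {}
    planted: dict[str, tuple[tuple[str, str], ...]] = {}
    for gi, strain in enumerate(config.strains):
        genes: list[tuple[str, str]] = []  # (family_id, mutated protein)
        for fam in config.families:
            proto = prototypes[fam.family_id]
            for _ in range(fam.copy_counts[gi]):
                mutated = _draw_clean(
                    lambda: "M"
                    + mutate_protein(proto[1:], config.substitution_rate, rng),
                    f"copy of {fam.family_id}",
                )
                genes.append((fam.family_id, mutated))
        order = rng.permutation(len(genes))
        parts = [_spacer(rng, config.spacer_length)]
        for idx in order:
            parts.append(reverse_translate(genes[idx][1]))
            parts.append(_spacer(rng, config.spacer_length))
        genomes[strain] = {f"{strain}_contig1": "".join(parts)}
        planted[strain] = tuple(genes[idx] for idx in order)
    return SimulatedDataset(
        config=config,
        genomes=genomes,
        phenotype=config.phenotype,
        truth=truth,
        prototypes=prototypes,
        planted=planted,
    )


def write_genome_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig_id in sorted(contigs):
            fh.write(f">{contig_id}\n")
            seq = contigs[contig_id]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "family_id": t.family_id,
                "copy_counts": ",".join(map(str, t.copy_counts)),
                "expected_cooccurrence": (
                    "NA"
                    if t.expected_cooccurrence is None
                    else f"{t.expected_cooccurrence:.6f}"
                ),
            }
            for t in truth
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> tuple[TruthRecord, ...]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        val = row["expected_cooccurrence"]
        records.append(
            TruthRecord(
                family_id=row["family_id"],
                copy_counts=tuple(int(c) for c in row["copy_counts"].split(",")),
                expected_cooccurrence=None if val == "NA" else float(val),
            )
        )
    return tuple(records)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write per-strain FASTA, phenotype TSV and truth TSV; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for strain in dataset.config.strains:
        p = outdir / f"{strain}.fna"
        write_genome_fasta(dataset.genomes[strain], p)
        paths[strain] = p
    phen = outdir / "phenotype.tsv"
    dataset.phenotype.to_tsv(phen)
    paths["phenotype"] = phen
    truth = outdir / "truth.tsv"
    write_truth_tsv(dataset.truth, truth)
    paths["truth"] = truth
    return paths
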