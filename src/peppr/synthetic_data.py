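"""Planted-structure generators for families and genomes.

``generate_family`` plants disjoint hexapeptide vocabularies into random
protein backgrounds at a controlled conservation level, emulating a CAZy
family whose subfamily structure is known exactly.  ``generate_genome``
reverse-translates planted proteins with random synonymous codons and embeds
them in random intergenic DNA on both strands, with the true gene coordinates
recorded.  Backgrounds are uniform over the 20 amino acids (respectively GC-
parameterized over the 4 bases), which keeps the chance of an accidental
hexapeptide match analytically small (20^-6 per window per peptide).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .ppr_core import AA_LETTERS, AnnotatedProtein
from .seqio import SequenceRecord, reverse_complement

_AA = np.array(list(AA_LETTERS))
_DNA = np.array(list("ACGT"))

# amino acid -> sorted synonymous codons, standard genetic code
_SYNONYMOUS: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in sorted(unambiguous_dna_by_id[1].forward_table.items()):
    _SYNONYMOUS[_aa].append(_codon)
_STOP_CODONS = sorted(unambiguous_dna_by_id[1].stop_codons)


class SpecError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint of a protein family with planted subfamilies.

    Each subfamily gets ``vocabulary_size`` unique hexapeptides (disjoint
    between subfamilies); each peptide is planted into exactly
    ``ceil(conservation * members_per_subfamily)`` members at random
    non-overlapping slots.  Decoys are pure random background.
    """

    family_name: str = "GH5"
    n_subfamilies: int = 3
    members_per_subfamily: int = 20
    vocabulary_size: int = 70
    conservation: float = 1.0
    protein_length: int = 500
    decoy_count: int = 10
    peptide_length: int = 6
    ec_labels: tuple[str, ...] | None = None
    labeled_per_subfamily: int = 3
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.conservation <= 1:
            raise SpecError("conservation must be in (0, 1]")
        if self.vocabulary_size * self.peptide_length > self.protein_length:
            raise SpecError(
                "planted peptides cannot fit: vocabulary_size * peptide_length "
                f"({self.vocabulary_size * self.peptide_length}) exceeds "
                f"protein_length ({self.protein_length})"
            )
        if self.ec_labels is not None and len(self.ec_labels) != self.n_subfamilies:
            raise SpecError("ec_labels must provide one label per subfamily")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth of a generated family."""

    assignments: dict[str, int]  # member id -> 1-based subfamily (decoys absent)
    vocabularies: tuple[tuple[str, ...], ...]
    decoy_ids: tuple[str, ...]


def _random_peptides(rng: np.random.Generator, count: int, k: int) -> list[str]:
    peptides: list[str] = []
    seen: set[str] = set()
    while len(peptides) < count:
        pep = "".join(rng.choice(_AA, size=k))
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    return peptides


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def insert_peptides(
    seq: str, peptides: list[str], rng: np.random.Generator, k: int
) -> str:
    """Overwrite random non-overlapping k-aligned slots with the peptides."""
    slots = len(seq) // k
    if len(peptides) > slots:
        raise SpecError(f"cannot place {len(peptides)} peptides in {slots} slots")
    chosen = rng.choice(slots, size=len(peptides), replace=False)
    out = list(seq)
    for slot, pep in zip(chosen, peptides):
        out[slot * k : slot * k + k] = pep
    return "".join(out)


def generate_family(spec: PlantSpec) -> tuple[list[AnnotatedProtein], FamilyTruth]:
    """Generate a family of planted subfamilies plus decoys, with ground truth."""
    rng = np.random.default_rng(spec.random_seed)
    k = spec.peptide_length
    all_peptides = _random_peptides(
        rng, spec.n_subfamilies * spec.vocabulary_size, k
    )
    vocabularies = tuple(
        tuple(all_peptides[j * spec.vocabulary_size : (j + 1) * spec.vocabulary_size])
        for j in range(spec.n_subfamilies)
    )

    proteins: list[AnnotatedProtein] = []
    assignments: dict[str, int] = {}
    m = spec.members_per_subfamily
    carriers_per_peptide = math.ceil(spec.conservation * m)
    for j, vocabulary in enumerate(vocabularies, start=1):
        member_peptides: list[list[str]] = [[] for _ in range(m)]
        for pep in vocabulary:
            for member_idx in rng.choice(m, size=carriers_per_peptide, replace=False):
                member_peptides[member_idx].append(pep)
        ec = (
            frozenset({spec.ec_labels[j - 1]})
            if spec.ec_labels is not None and spec.ec_labels[j - 1]
            else frozenset()
        )
        for i in range(m):
            pid = f"{spec.family_name}.sf{j}.m{i:03d}"
            seq = insert_peptides(
                random_protein(rng, spec.protein_length), member_peptides[i], rng, k
            )
            labels = ec if i < spec.labeled_per_subfamily else frozenset()
            proteins.append(AnnotatedProtein(pid, seq, labels))
            assignments[pid] = j

    decoy_ids = []
    for i in range(spec.decoy_count):
        pid = f"{spec.family_name}.decoy.{i:03d}"
        proteins.append(AnnotatedProtein(pid, random_protein(rng, spec.protein_length)))
        decoy_ids.append(pid)

    return proteins, FamilyTruth(assignments, vocabularies, tuple(decoy_ids))


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    family: str
    subfamily: int
    protein_seq: str
    strand: str | None = None  # None -> random strand


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint of a synthetic assembly with planted CAZyme genes.

    ``intergenic_length`` is the total intergenic DNA accompanying each gene:
    an int, a (low, high) range sampled uniformly, or ``None`` for "equal to
    the gene length" (i.e. a 50% intergenic genome).  The default contig
    policy places each gene on its own contig flanked by intergenic halves,
    emulating a fragmented assembly; ``"single"`` concatenates everything
    onto one contig.
    """

    genes: tuple[PlantedGene, ...]
    intergenic_length: int | tuple[int, int] | None = None
    gc_content: float = 0.5
    contig_policy: str = "per_gene"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.contig_policy not in ("per_gene", "single"):
            raise SpecError(f"unknown contig policy {self.contig_policy!r}")
        if not 0 < self.gc_content < 1:
            raise SpecError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class GeneLocus:
    """True coordinates of one planted gene (0-based half-open, bases)."""

    contig_id: str
    start: int
    end: int
    strand: str
    family: str
    subfamily: int
    gene_id: str


def random_dna(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    return "".join(rng.choice(_DNA, size=length, p=[at, gc, gc, at]))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> coding DNA with uniformly random synonymous codons."""
    return "".join(rng.choice(_SYNONYMOUS[aa]) for aa in protein)


def _intergenic_len(spec: GenomeSpec, rng: np.random.Generator, gene_len: int) -> int:
    if spec.intergenic_length is None:
        return gene_len
    if isinstance(spec.intergenic_length, tuple):
        low, high = spec.intergenic_length
        return int(rng.integers(low, high + 1))
    return int(spec.intergenic_length)


def generate_genome(spec: GenomeSpec) -> tuple[list[SequenceRecord], list[GeneLocus]]:
    """Build contigs of intergenic DNA and planted genes, with true coordinates."""
    rng = np.random.default_rng(spec.random_seed)
    records: list[SequenceRecord] = []
    loci: list[GeneLocus] = []

    def place(gene: PlantedGene) -> tuple[str, str, int]:
        """Returns (placed DNA incl. stop codon, strand, cds length)."""
        cds = reverse_translate(gene.protein_seq, rng)
        stop = str(rng.choice(_STOP_CODONS))
        strand = gene.strand or str(rng.choice(["+", "-"]))
        dna = cds + stop if strand == "+" else reverse_complement(cds + stop)
        return dna, strand, len(cds)

    if spec.contig_policy == "per_gene":
        for i, gene in enumerate(spec.genes):
            dna, strand, cds_len = place(gene)
            intergenic = _intergenic_len(spec, rng, len(dna))
            left = intergenic // 2
            contig_id = f"contig_{i:03d}"
            seq = (
                random_dna(rng, left, spec.gc_content)
                + dna
                + random_dna(rng, intergenic - left, spec.gc_content)
            )
            start = left if strand == "+" else left + len(dna) - cds_len
            loci.append(
                GeneLocus(
                    contig_id, start, start + cds_len, strand,
                    gene.family, gene.subfamily, gene.gene_id,
                )
            )
            records.append(SequenceRecord(contig_id, seq))
    else:
        parts: list[str] = []
        offset = 0
        contig_id = "contig_000"
        for gene in spec.genes:
            dna, strand, cds_len = place(gene)
            lead = _intergenic_len(spec, rng, len(dna)) // 2
            parts.append(random_dna(rng, lead, spec.gc_content))
            offset += lead
            start = offset if strand == "+" else offset + len(dna) - cds_len
            loci.append(
                GeneLocus(
                    contig_id, start, start + cds_len, strand,
                    gene.family, gene.subfamily, gene.gene_id,
                )
            )
            parts.append(dna)
            offset += len(dna)
        parts.append(random_dna(rng, _intergenic_len(spec, rng, 1000) // 2, spec.gc_content))
        records.append(SequenceRecord(contig_id, "".join(parts)))

    return records, loci


# ---------------------------------------------------------------------------
# Plain-text fixture output
# ---------------------------------------------------------------------------

def write_family_truth(truth: FamilyTruth, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("protein_id\tsubfamily\n")
        for pid, sf in sorted(truth.assignments.items()):
            handle.write(f"{pid}\t{sf}\n")
        for pid in truth.decoy_ids:
            handle.write(f"{pid}\t0\n")


def write_genome_truth(loci: list[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("contig\tstart\tend\tstrand\tfamily\tsubfamily\tgene_id\n")
        for locus in loci:
            handle.write(
                f"{locus.contig_id}\t{locus.start}\t{locus.end}\t{locus.strand}\t"
                f"{locus.family}\t{locus.subfamily}\t{locus.gene_id}\n"
            )


def write_ec_annotations(proteins: list[AnnotatedProtein], path: str | Path) -> None:
    with open(path, "w") as handle:
        for protein in proteins:
            if protein.ec_labels:
                handle.write(f"{protein.id}\t{';'.join(sorted(protein.ec_labels))}\n")
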