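"""Sequence I/O, contig filtering, genome fragmentation and six-frame translation.

Coordinates are 0-based half-open everywhere in memory; exported annotation
tables use 1-based inclusive coordinates.  Stop codons and codons whose IUPAC
ambiguity expansion does not resolve to a unique amino acid translate to the
sentinel ``*``, which can never be part of a peptide match because peptides
contain only the 20 standard amino-acid letters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from pathlib import Path

from Bio import SeqIO
from Bio.Data import IUPACData
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: sentinel emitted for stop codons and unresolvable ambiguous codons
SENTINEL = "*"

#: the six reading frames in canonical order (forward offsets, then reverse)
FRAMES = (1, 2, 3, -1, -2, -3)

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_DNA_LETTERS = frozenset(IUPACData.ambiguous_dna_letters)


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: a contig or a protein."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def is_nucleotide(self) -> bool:
        return set(self.seq) <= _DNA_LETTERS


@dataclass(frozen=True)
class FragmentationParams:
    """Window parameters for splitting contigs before translation.

    Defaults follow the published protocol: 2000-base fragments with a
    100-base overlap, discarding contigs shorter than 500 bases.
    """

    fragment_length: int = 2000
    overlap_length: int = 100
    min_contig_length: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_length < self.fragment_length:
            raise ValueError("require 0 <= overlap_length < fragment_length")
        if self.min_contig_length <= 0:
            raise ValueError("min_contig_length must be positive")

    @property
    def step(self) -> int:
        return self.fragment_length - self.overlap_length


@dataclass(frozen=True)
class GenomeFragment:
    """A window of one contig; ``start``/``end`` are contig offsets in bases."""

    contig_id: str
    start: int
    end: int
    seq: str


@dataclass(frozen=True)
class FrameTranslation:
    """Conceptual translation of one fragment in one reading frame.

    ``frame`` is +1/+2/+3 for the forward strand (offset ``frame - 1``) and
    -1/-2/-3 for the same offsets on the reverse complement.
    """

    fragment: GenomeFragment
    frame: int
    aa_seq: str

    def aa_to_genomic(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map a residue span [aa_start, aa_end) to a genomic base span."""
        offset = abs(self.frame) - 1
        if self.frame > 0:
            start = self.fragment.start + offset + 3 * aa_start
            end = self.fragment.start + offset + 3 * aa_end
        else:
            flen = len(self.fragment.seq)
            end = self.fragment.start + flen - offset - 3 * aa_start
            start = self.fragment.start + flen - offset - 3 * aa_end
        return start, end


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and the header token before the first whitespace
    becomes the record id.  An entry with no sequence raises
    :class:`FastaParseError` naming the offending header; an empty file yields
    an empty list with a logged warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if len(rec.seq) == 0:
                raise FastaParseError(
                    f"FASTA entry {rec.description!r} in {path} has no sequence"
                )
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def filter_contigs(
    records: list[SequenceRecord], params: FragmentationParams = FragmentationParams()
) -> list[SequenceRecord]:
    """Keep contigs of length >= ``min_contig_length``, preserving order."""
    return [r for r in records if len(r.seq) >= params.min_contig_length]


def fragment_genome(
    record: SequenceRecord, params: FragmentationParams = FragmentationParams()
) -> list[GenomeFragment]:
    """Split one contig into overlapping windows.

    Windows start at multiples of ``fragment_length - overlap_length``; the
    final window may be shorter, and a trailing window fully contained in the
    previous one is not emitted.
    """
    length = len(record.seq)
    if length < params.min_contig_length:
        raise ValueError(
            f"contig {record.id!r} ({length} bases) is shorter than "
            f"min_contig_length={params.min_contig_length}"
        )
    fragments: list[GenomeFragment] = []
    start = 0
    while start < length:
        end = min(start + params.fragment_length, length)
        if not fragments or end > fragments[-1].end:
            fragments.append(
                GenomeFragment(record.id, start, end, record.seq[start:end])
            )
        if end == length:
            break
        start += params.step
    return fragments


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code.

    IUPAC ambiguity codes are expanded; if every expansion agrees on one amino
    acid that residue is returned, otherwise (including stops and invalid
    letters) the sentinel.
    """
    if len(codon) != 3:
        return SENTINEL
    try:
        expansions = product(*(IUPACData.ambiguous_dna_values[b] for b in codon))
    except KeyError:
        return SENTINEL
    residues = set()
    for bases in expansions:
        triplet = "".join(bases)
        if triplet in _STANDARD_TABLE.stop_codons:
            residues.add(SENTINEL)
        else:
            residues.add(_STANDARD_TABLE.forward_table[triplet])
    return residues.pop() if len(residues) == 1 else SENTINEL


def _translate(seq: str, offset: int) -> str:
    n_codons = (len(seq) - offset) // 3
    return "".join(
        translate_codon(seq[offset + 3 * i : offset + 3 * i + 3]) for i in range(n_codons)
    )


def translate_six_frames(fragment: GenomeFragment) -> list[FrameTranslation]:
    """Translate a fragment in all six reading frames (standard code)."""
    forward = fragment.seq.upper()
    reverse = str(Seq(forward).reverse_complement())
    translations = []
    for frame in FRAMES:
        strand_seq = forward if frame > 0 else reverse
        translations.append(
            FrameTranslation(fragment, frame, _translate(strand_seq, abs(frame) - 1))
        )
    return translations


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
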