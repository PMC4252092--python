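"""Homology-to-peptide-pattern annotation of genomes and proteins.

Translated genome fragments (or full-length proteins) are scored against
subfamily peptide profiles.  A reading frame is a significant hit for a
subfamily when it (1) contains at least ``min_peptide_hits`` conserved
peptides, (2) their frequency sum exceeds ``min_freq_sum`` (strictly), and
(3) the peptides cover at least ``min_residues_covered`` residues.  Within a
family a frame is assigned to the subfamily with the highest frequency sum;
scores are never compared between families, so one fragment can hit several
families (CAZymes are modular).  Hits of one family whose fragments lie less
than ``merge_distance`` bases apart on the contig are merged into a single
gene call, which inherits the subfamily of its best-scoring hit and the
function assigned to that subfamily.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from itertools import groupby
from pathlib import Path

import pandas as pd

from .ppr_core import (
    LPMO_FAMILIES,
    AnnotatedProtein,
    PeptideProfile,
    SubfamilyInfo,
)
from .seqio import (
    FRAMES,
    FragmentationParams,
    FrameTranslation,
    GenomeFragment,
    SequenceRecord,
    filter_contigs,
    fragment_genome,
    translate_six_frames,
)


@dataclass(frozen=True)
class HotpepParams:
    """Hit thresholds and the merge distance, at the published defaults."""

    min_peptide_hits: int = 3
    min_freq_sum: float = 1.0
    min_residues_covered: int = 10
    merge_distance: int = 5800

    def __post_init__(self) -> None:
        if min(self.min_peptide_hits, self.min_residues_covered, self.merge_distance) <= 0:
            raise ValueError("HotpepParams fields must be positive")
        if self.min_freq_sum <= 0:
            raise ValueError("min_freq_sum must be positive")


@dataclass(frozen=True)
class FrameScore:
    """Match statistics of one sequence/frame against one subfamily profile.

    ``matched_peptides`` maps each matched peptide to all its occurrence
    start positions (residue offsets).  A peptide counts once in
    ``n_peptides`` and ``freq_sum`` however often it occurs, but every
    occurrence span contributes to ``residues_covered``.
    """

    subfamily_ref: tuple[str, int]
    matched_peptides: dict[str, tuple[int, ...]]
    n_peptides: int
    freq_sum: float
    residues_covered: int


@dataclass(frozen=True)
class Hit:
    """Best-scoring significant frame of one fragment for one family.

    In genome mode the span is the fragment's genomic span in bases and
    ``frame`` is one of +-1..3; in protein mode the span is the residue span
    of the full-length protein and ``frame`` is ``None``.
    """

    contig_id: str
    start: int
    end: int
    frame: int | None
    family_name: str
    subfamily: int
    score: FrameScore


@dataclass(frozen=True)
class GeneCall:
    """A chain of same-family hits closer than the merge distance."""

    contig_id: str
    family_name: str
    start: int
    end: int
    hits: tuple[Hit, ...]
    subfamily: int
    strands: frozenset[str]
    strand_conflict: bool
    predicted_function: frozenset[str] = frozenset()

    @property
    def best_hit(self) -> Hit:
        return max(self.hits, key=lambda h: (h.score.freq_sum, -h.start))


def _union_coverage(matched: dict[str, tuple[int, ...]], k: int) -> int:
    spans = sorted(
        (pos, pos + k) for positions in matched.values() for pos in positions
    )
    covered = 0
    current_end = -1
    for start, end in spans:
        if start >= current_end:
            covered += end - start
            current_end = end
        elif end > current_end:
            covered += end - current_end
            current_end = end
    return covered


def score_frame(
    translation: FrameTranslation | str,
    profile: PeptideProfile,
    subfamily_ref: tuple[str, int] = ("", 0),
) -> FrameScore:
    """Score one translated frame (or plain protein sequence) on one profile.

    Matches are exact substring occurrences of profile peptides; they can
    never span the stop sentinel because peptides contain only amino-acid
    letters.
    """
    if not profile.peptides:
        raise ValueError("cannot score against an empty profile")
    aa = translation.aa_seq if isinstance(translation, FrameTranslation) else translation
    k = profile.peptide_length
    matched: dict[str, list[int]] = defaultdict(list)
    for i in range(len(aa) - k + 1):
        window = aa[i : i + k]
        if window in profile.peptides:
            matched[window].append(i)
    matched_t = {pep: tuple(pos) for pep, pos in matched.items()}
    return FrameScore(
        subfamily_ref=subfamily_ref,
        matched_peptides=matched_t,
        n_peptides=len(matched_t),
        freq_sum=sum(profile.peptides[p] for p in matched_t),
        residues_covered=_union_coverage(matched_t, k),
    )


def passes_thresholds(score: FrameScore, params: HotpepParams = HotpepParams()) -> bool:
    """All three hit conditions; the frequency-sum condition is strict."""
    return (
        score.n_peptides >= params.min_peptide_hits
        and score.freq_sum > params.min_freq_sum
        and score.residues_covered >= params.min_residues_covered
    )


def best_subfamily(
    scores: list[FrameScore], params: HotpepParams = HotpepParams()
) -> FrameScore | None:
    """Highest-frequency-sum score among those passing the thresholds.

    Ties go to the lower subfamily index (discovery order reflects group
    size).  Returns ``None`` when nothing passes.
    """
    passing = [s for s in scores if passes_thresholds(s, params)]
    if not passing:
        return None
    return min(passing, key=lambda s: (-s.freq_sum, s.subfamily_ref[1]))


class ProfileSet:
    """All subfamily profiles indexed for one-pass window scanning."""

    def __init__(self, profiles: dict[tuple[str, int], SubfamilyInfo]):
        if not profiles:
            raise ValueError("ProfileSet requires at least one profile")
        lengths = {info.profile.peptide_length for info in profiles.values()}
        if len(lengths) != 1:
            raise ValueError(f"profiles mix peptide lengths: {sorted(lengths)}")
        self.k = lengths.pop()
        self.profiles = profiles
        self.index: dict[str, list[tuple[str, int, float]]] = defaultdict(list)
        for (family, idx), info in sorted(profiles.items()):
            for pep, freq in info.profile.peptides.items():
                self.index[pep].append((family, idx, freq))

    def functions(self) -> dict[tuple[str, int], frozenset[str]]:
        return {key: info.function for key, info in self.profiles.items()}

    def scan(self, aa_seq: str) -> dict[tuple[str, int], FrameScore]:
        """Score one amino-acid sequence against every profile at once."""
        per_subfamily: dict[tuple[str, int], dict[str, list[int]]] = defaultdict(
            lambda: defaultdict(list)
        )
        freqs: dict[tuple[str, int], dict[str, float]] = defaultdict(dict)
        for i in range(len(aa_seq) - self.k + 1):
            window = aa_seq[i : i + self.k]
            entries = self.index.get(window)
            if not entries:
                continue
            for family, idx, freq in entries:
                per_subfamily[(family, idx)][window].append(i)
                freqs[(family, idx)][window] = freq
        scores = {}
        for ref, matched in per_subfamily.items():
            matched_t = {pep: tuple(pos) for pep, pos in matched.items()}
            scores[ref] = FrameScore(
                subfamily_ref=ref,
                matched_peptides=matched_t,
                n_peptides=len(matched_t),
                freq_sum=sum(freqs[ref].values()),
                residues_covered=_union_coverage(matched_t, self.k),
            )
        return scores


def _best_per_family(
    frame_scores: dict[tuple[str, int], FrameScore], params: HotpepParams
) -> dict[str, FrameScore]:
    by_family: dict[str, list[FrameScore]] = defaultdict(list)
    for (family, _), score in frame_scores.items():
        by_family[family].append(score)
    best = {}
    for family, scores in by_family.items():
        winner = best_subfamily(scores, params)
        if winner is not None:
            best[family] = winner
    return best


def annotate_fragments(
    fragments: list[GenomeFragment],
    profile_set: ProfileSet,
    params: HotpepParams = HotpepParams(),
) -> list[Hit]:
    """Score six frames of every fragment; at most one hit per fragment and family.

    Within a family, the best frame wins by frequency sum, then residue
    coverage, then canonical frame order (+1,+2,+3,-1,-2,-3).  No scores are
    compared between families.
    """
    hits: list[Hit] = []
    for fragment in fragments:
        best_by_family: dict[str, tuple[tuple, int, FrameScore]] = {}
        for translation in translate_six_frames(fragment):
            frame_order = FRAMES.index(translation.frame)
            for family, score in _best_per_family(
                profile_set.scan(translation.aa_seq), params
            ).items():
                key = (-score.freq_sum, -score.residues_covered, frame_order)
                incumbent = best_by_family.get(family)
                if incumbent is None or key < incumbent[0]:
                    best_by_family[family] = (key, translation.frame, score)
        for family in sorted(best_by_family):
            _, frame, score = best_by_family[family]
            hits.append(
                Hit(
                    contig_id=fragment.contig_id,
                    start=fragment.start,
                    end=fragment.end,
                    frame=frame,
                    family_name=family,
                    subfamily=score.subfamily_ref[1],
                    score=score,
                )
            )
    return hits


def annotate_genome(
    records: list[SequenceRecord],
    profile_set: ProfileSet,
    params: HotpepParams = HotpepParams(),
    frag_params: FragmentationParams = FragmentationParams(),
) -> list[Hit]:
    """Filter contigs, fragment, translate in six frames and score."""
    fragments: list[GenomeFragment] = []
    for record in filter_contigs(records, frag_params):
        fragments.extend(fragment_genome(record, frag_params))
    return annotate_fragments(fragments, profile_set, params)


def merge_hits(hits: list[Hit], params: HotpepParams = HotpepParams()) -> list[GeneCall]:
    """Chain same-contig same-family hits whose spans lie < merge_distance apart.

    Chaining is transitive; hits of different families never merge.  The gene
    call takes the subfamily of its highest-frequency-sum constituent hit.
    Opposite-strand hits are allowed to merge (the rule is purely family and
    distance) but the call is flagged.
    """
    calls: list[GeneCall] = []
    ordered = sorted(hits, key=lambda h: (h.contig_id, h.family_name, h.start, h.end))
    for _, group in groupby(ordered, key=lambda h: (h.contig_id, h.family_name)):
        chain: list[Hit] = []
        chain_end = 0
        for hit in group:
            if chain and hit.start - chain_end < params.merge_distance:
                chain.append(hit)
                chain_end = max(chain_end, hit.end)
            else:
                if chain:
                    calls.append(_make_call(chain))
                chain = [hit]
                chain_end = hit.end
        if chain:
            calls.append(_make_call(chain))
    return calls


def _strand(frame: int | None) -> str:
    if frame is None:
        return "."
    return "+" if frame > 0 else "-"


def _make_call(chain: list[Hit]) -> GeneCall:
    best = max(chain, key=lambda h: (h.score.freq_sum, -h.start))
    strands = frozenset(_strand(h.frame) for h in chain)
    return GeneCall(
        contig_id=chain[0].contig_id,
        family_name=chain[0].family_name,
        start=min(h.start for h in chain),
        end=max(h.end for h in chain),
        hits=tuple(chain),
        subfamily=best.subfamily,
        strands=strands,
        strand_conflict=len(strands - {"."}) > 1,
    )


def transfer_function(
    call: GeneCall, subfamily_table: dict[tuple[str, int], frozenset[str]]
) -> GeneCall:
    """Copy the subfamily's predicted function onto the gene call.

    AA9/AA10/AA11 calls are labeled "LPMO"; an unknown subfamily key raises.
    """
    if call.family_name in LPMO_FAMILIES:
        return replace(call, predicted_function=frozenset({"LPMO"}))
    key = (call.family_name, call.subfamily)
    if key not in subfamily_table:
        raise KeyError(f"unknown subfamily {key} in function table")
    return replace(call, predicted_function=subfamily_table[key])


def call_genes(
    records: list[SequenceRecord],
    profile_set: ProfileSet,
    params: HotpepParams = HotpepParams(),
    frag_params: FragmentationParams = FragmentationParams(),
) -> list[GeneCall]:
    """Full genome pipeline: annotate, merge, and transfer functions."""
    hits = annotate_genome(records, profile_set, params, frag_params)
    table = profile_set.functions()
    return [transfer_function(c, table) for c in merge_hits(hits, params)]


def annotate_proteins(
    proteins: list[AnnotatedProtein | SequenceRecord],
    profile_set: ProfileSet,
    params: HotpepParams = HotpepParams(),
) -> list[Hit]:
    """Protein-mode screening: score full-length sequences directly.

    The same thresholds apply, with no fragmentation and no merging; spans
    are residue spans and ``frame`` is ``None``.
    """
    hits: list[Hit] = []
    for protein in proteins:
        for family, score in sorted(
            _best_per_family(profile_set.scan(protein.seq), params).items()
        ):
            hits.append(
                Hit(
                    contig_id=protein.id,
                    start=0,
                    end=len(protein.seq),
                    frame=None,
                    family_name=family,
                    subfamily=score.subfamily_ref[1],
                    score=score,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Exported annotation formats (1-based inclusive coordinates).
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "contig",
    "start",
    "end",
    "strand",
    "family",
    "subfamily",
    "n_peptides",
    "freq_sum",
    "residues_covered",
    "function",
]


def _function_string(call: GeneCall) -> str:
    return ";".join(sorted(call.predicted_function)) or "-"


def write_annotation_table(calls: list[GeneCall], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for call in sorted(calls, key=lambda c: (c.contig_id, c.start, c.family_name)):
            best = call.best_hit
            strand = _strand(best.frame)
            if call.strand_conflict:
                strand = "."
            handle.write(
                "\t".join(
                    [
                        call.contig_id,
                        str(call.start + 1),
                        str(call.end),
                        strand,
                        call.family_name,
                        str(call.subfamily),
                        str(best.score.n_peptides),
                        f"{best.score.freq_sum:.4f}",
                        str(best.score.residues_covered),
                        _function_string(call),
                    ]
                )
                + "\n"
            )


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str, "function": str})


def write_gff3(calls: list[GeneCall], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, call in enumerate(
            sorted(calls, key=lambda c: (c.contig_id, c.start, c.family_name)), 1
        ):
            best = call.best_hit
            strand = "." if call.strand_conflict else _strand(best.frame)
            ec = ",".join(sorted(call.predicted_function)) or "-"
            attrs = (
                f"ID=gene_call_{i};Family={call.family_name};"
                f"Subfamily={call.subfamily};EC={ec}"
            )
            handle.write(
                "\t".join(
                    [
                        call.contig_id,
                        "peppr",
                        "gene_call",
                        str(call.start + 1),
                        str(call.end),
                        f"{best.score.freq_sum:.4f}",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
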