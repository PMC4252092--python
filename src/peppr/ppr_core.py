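"""Peptide Pattern Recognition: subfamily discovery inside a protein family.

A subfamily is a group of at least ``min_group_size`` proteins that each carry
at least ``min_peptides_per_protein`` peptides from the group's list of at
most ``list_size`` conserved hexapeptides, where "conserved" means present in
at least ``conservation_threshold`` (default 20%) of the group's members.
Groups are peeled off greedily: the largest such group becomes subfamily 1,
the largest group among the remaining proteins subfamily 2, and so on until
fewer than ``min_group_size`` proteins can be grouped.

Each candidate group is found by alternating two updates to a fixed point:
rebuild the conserved-peptide profile from the current members, then redefine
the members as every unassigned protein holding enough profile peptides.
Candidates are seeded from the most widely shared peptides, which makes the
search deterministic and checkable by brute force on small instances.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

#: the 20 standard amino-acid letters; peptides are drawn from these only
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_LETTERS)

#: CAZy auxiliary-activity families treated as lytic polysaccharide monooxygenases
LPMO_FAMILIES = frozenset({"AA9", "AA10", "AA11"})

_EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")


class ProfileFormatError(ValueError):
    """Raised when a peptide-profile file cannot be parsed."""


@dataclass(frozen=True)
class AnnotatedProtein:
    """A family member: sequence plus optional EC-number activity labels."""

    id: str
    seq: str
    ec_labels: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PPRParams:
    """Grouping parameters; defaults follow the published protocol.

    peptide_length
        Length of the conserved peptides (hexamers).
    list_size
        Maximum number of conserved peptides kept per group (70).
    min_peptides_per_protein
        Minimum profile peptides a protein must hold to be a member (10).
    conservation_threshold
        Minimum fraction of members that must carry a peptide for it to be
        conserved (0.20).
    min_group_size
        Smallest group reported as a subfamily (5).
    seed_peptides
        Number of widely shared peptides used to seed candidate groups.
    """

    peptide_length: int = 6
    list_size: int = 70
    min_peptides_per_protein: int = 10
    conservation_threshold: float = 0.20
    min_group_size: int = 5
    max_iterations: int = 100
    seed_peptides: int = 50
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0, 1]")
        if self.min_peptides_per_protein > self.list_size:
            raise ValueError("min_peptides_per_protein must not exceed list_size")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be at least 2")


@dataclass(frozen=True)
class PeptideProfile:
    """Conserved-peptide list of one subfamily: peptide -> member frequency."""

    peptides: dict[str, float]

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    @property
    def peptide_length(self) -> int:
        return len(next(iter(self.peptides)))

    def frequency_sum(self) -> float:
        return sum(self.peptides.values())


@dataclass(frozen=True)
class Subfamily:
    family_name: str
    index: int
    members: frozenset[str]
    profile: PeptideProfile
    predicted_function: frozenset[str] = frozenset()
    majority_function: tuple[str, ...] = ()
    ambiguous_function: bool = False


def extract_peptides(protein: AnnotatedProtein | str, k: int = 6) -> frozenset[str]:
    """All distinct length-``k`` windows made only of amino-acid letters."""
    seq = protein.seq if isinstance(protein, AnnotatedProtein) else protein
    if k < 1:
        raise ValueError("peptide length must be >= 1")
    out = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if _AA_SET.issuperset(window):
            out.add(window)
    return frozenset(out)


def build_profile(members: list[AnnotatedProtein], params: PPRParams = PPRParams()) -> PeptideProfile:
    """Conserved-peptide profile of a group of proteins.

    Presence frequencies (not occurrence counts) are computed for every
    peptide across the members; peptides below the conservation threshold are
    removed and at most ``list_size`` of the rest are kept, most frequent
    first with lexicographic tie-breaking.
    """
    if not members:
        raise ValueError("cannot build a profile from an empty group")
    counts: Counter[str] = Counter()
    for member in members:
        counts.update(extract_peptides(member, params.peptide_length))
    n = len(members)
    conserved = {
        pep: cnt / n
        for pep, cnt in counts.items()
        if cnt / n + 1e-12 >= params.conservation_threshold
    }
    top = sorted(conserved.items(), key=lambda kv: (-kv[1], kv[0]))[: params.list_size]
    return PeptideProfile(dict(top))


def _smaller(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    return min((a, b), key=lambda m: (len(m), tuple(sorted(m))))


def _alternate_to_fixed_point(
    initial: frozenset[str],
    by_id: dict[str, AnnotatedProtein],
    peptide_sets: dict[str, frozenset[str]],
    params: PPRParams,
) -> tuple[frozenset[str], PeptideProfile] | None:
    """Alternate profile/membership updates from a seed member set.

    Converges to a fixed point, or — on a detected oscillation or iteration
    cap — falls back to the smaller of the last two member sets.
    """
    members = initial
    previous: frozenset[str] | None = None
    for _ in range(params.max_iterations):
        if not members:
            return None
        profile = build_profile([by_id[i] for i in sorted(members)], params)
        keys = set(profile.peptides)
        if not keys:
            return None
        new_members = frozenset(
            pid
            for pid, peps in peptide_sets.items()
            if len(peps & keys) >= params.min_peptides_per_protein
        )
        if new_members == members:
            return members, profile
        if new_members == previous:  # 2-cycle: keep the conservative choice
            members = _smaller(members, new_members)
            break
        previous, members = members, new_members
    else:
        members = _smaller(previous, members) if previous else members
    if not members:
        return None
    profile = build_profile([by_id[i] for i in sorted(members)], params)
    return members, profile


def find_largest_group(
    family: list[AnnotatedProtein],
    params: PPRParams = PPRParams(),
    family_name: str = "",
    index: int = 1,
) -> Subfamily | None:
    """Largest group of proteins sharing enough conserved peptides.

    One candidate group is seeded per top-``seed_peptides`` most widely
    shared peptide (initial members = every protein containing it), each is
    driven to a profile/membership fixed point, and the largest valid fixed
    point wins.  Ties go to the higher total profile frequency, then to the
    lowest-sorted member-id tuple.  Returns ``None`` when no group reaches
    ``min_group_size``.
    """
    eligible = [p for p in family if len(p.seq) >= params.peptide_length]
    if len(eligible) < params.min_group_size:
        return None
    by_id = {p.id: p for p in eligible}
    peptide_sets = {p.id: extract_peptides(p, params.peptide_length) for p in eligible}

    shared: Counter[str] = Counter()
    for peps in peptide_sets.values():
        shared.update(peps)
    seeds = [
        pep
        for pep, _ in sorted(shared.items(), key=lambda kv: (-kv[1], kv[0]))[
            : params.seed_peptides
        ]
    ]

    candidates: list[tuple[frozenset[str], PeptideProfile]] = []
    seen_initials: set[frozenset[str]] = set()
    for pep in seeds:
        initial = frozenset(pid for pid, peps in peptide_sets.items() if pep in peps)
        if initial in seen_initials:
            continue
        seen_initials.add(initial)
        result = _alternate_to_fixed_point(initial, by_id, peptide_sets, params)
        if result is not None and len(result[0]) >= params.min_group_size:
            candidates.append(result)
    if not candidates:
        return None
    members, profile = min(
        candidates,
        key=lambda c: (-len(c[0]), -c[1].frequency_sum(), tuple(sorted(c[0]))),
    )
    return Subfamily(family_name, index, members, profile)


def partition_family(
    family: list[AnnotatedProtein],
    params: PPRParams = PPRParams(),
    family_name: str = "FAM",
) -> tuple[list[Subfamily], list[str]]:
    """Peel off subfamilies greedily until no group of min size remains.

    Returns the subfamilies numbered 1, 2, ... in discovery order (with
    functions assigned from their members' EC labels) and the ids of the
    proteins left ungrouped.
    """
    remaining = list(family)
    subfamilies: list[Subfamily] = []
    index = 1
    while True:
        subfamily = find_largest_group(remaining, params, family_name, index)
        if subfamily is None:
            break
        members = [p for p in remaining if p.id in subfamily.members]
        subfamilies.append(assign_function(subfamily, members))
        remaining = [p for p in remaining if p.id not in subfamily.members]
        index += 1
    return subfamilies, [p.id for p in remaining]


def assign_function(subfamily: Subfamily, members: list[AnnotatedProtein]) -> Subfamily:
    """Transfer EC labels from characterized members to the whole subfamily.

    The function set is the union of the members' EC labels and the majority
    label is the most frequent one (all tied labels are reported and the
    subfamily flagged ambiguous on a tie).  Subfamilies of the AA9/AA10/AA11
    families are always labeled "LPMO".
    """
    if subfamily.family_name in LPMO_FAMILIES:
        return replace(
            subfamily,
            predicted_function=frozenset({"LPMO"}),
            majority_function=("LPMO",),
            ambiguous_function=False,
        )
    label_counts: Counter[str] = Counter()
    for member in members:
        label_counts.update(member.ec_labels)
    if not label_counts:
        return replace(
            subfamily,
            predicted_function=frozenset(),
            majority_function=(),
            ambiguous_function=False,
        )
    best = max(label_counts.values())
    majority = tuple(sorted(ec for ec, cnt in label_counts.items() if cnt == best))
    return replace(
        subfamily,
        predicted_function=frozenset(label_counts),
        majority_function=majority,
        ambiguous_function=len(majority) > 1,
    )


# ---------------------------------------------------------------------------
# External interfaces: EC sidecar annotations and peptide-profile files.
#
# Profile file (one per subfamily, tab-separated):
#   line 1:  family <TAB> subfamily <TAB> n_members <TAB> function
#   then one line per peptide:  peptide <TAB> frequency (4 decimals)
# An empty function set is written as "-"; multiple ECs are ";"-joined.
# ---------------------------------------------------------------------------

def read_ec_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a sidecar TSV mapping protein id -> semicolon-separated ECs."""
    annotations: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>ec1;ec2', got {raw!r}")
            labels = frozenset(ec for ec in fields[1].split(";") if ec)
            for ec in labels:
                if not _EC_PATTERN.match(ec):
                    raise ValueError(f"{path}:{lineno}: invalid EC number {ec!r}")
            annotations[fields[0]] = labels
    return annotations


def attach_annotations(records, annotations: dict[str, frozenset[str]]) -> list[AnnotatedProtein]:
    """Pair FASTA records with their sidecar EC labels (missing ids -> empty)."""
    return [
        AnnotatedProtein(r.id, r.seq, annotations.get(r.id, frozenset()))
        for r in records
    ]


def _function_string(subfamily: Subfamily) -> str:
    return ";".join(sorted(subfamily.predicted_function)) or "-"


def profile_filename(family_name: str, index: int) -> str:
    return f"{family_name}_{index:02d}.peptides.tsv"


def write_profiles(subfamilies: list[Subfamily], outdir: str | Path) -> list[Path]:
    """Write one peptide-profile file per subfamily; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sf in subfamilies:
        path = outdir / profile_filename(sf.family_name, sf.index)
        with open(path, "w") as handle:
            handle.write(
                f"{sf.family_name}\t{sf.index}\t{len(sf.members)}\t{_function_string(sf)}\n"
            )
            for pep, freq in sorted(sf.profile.peptides.items(), key=lambda kv: (-kv[1], kv[0])):
                handle.write(f"{pep}\t{freq:.4f}\n")
        paths.append(path)
    return paths


@dataclass(frozen=True)
class SubfamilyInfo:
    """One loaded profile file: the scoring reference for a subfamily."""

    family_name: str
    index: int
    n_members: int
    function: frozenset[str]
    profile: PeptideProfile


def _parse_profile_file(path: Path) -> SubfamilyInfo:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ProfileFormatError(f"{path}: empty profile file")
    header = lines[0].split("\t")
    if len(header) != 4:
        raise ProfileFormatError(f"{path}: malformed header line {lines[0]!r}")
    family, index_s, n_members_s, function_s = header
    try:
        index, n_members = int(index_s), int(n_members_s)
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: non-numeric header fields") from exc
    peptides: dict[str, float] = {}
    for raw in lines[1:]:
        fields = raw.split("\t")
        if len(fields) != 2 or not _AA_SET.issuperset(fields[0]):
            raise ProfileFormatError(f"{path}: malformed peptide line {raw!r}")
        try:
            peptides[fields[0]] = float(fields[1])
        except ValueError as exc:
            raise ProfileFormatError(f"{path}: bad frequency in {raw!r}") from exc
    if not peptides:
        raise ProfileFormatError(f"{path}: profile has no peptides")
    function = frozenset() if function_s == "-" else frozenset(function_s.split(";"))
    return SubfamilyInfo(family, index, n_members, function, PeptideProfile(peptides))


def load_profiles(directory: str | Path) -> dict[tuple[str, int], SubfamilyInfo]:
    """Load every ``*.peptides.tsv`` profile in a directory."""
    directory = Path(directory)
    profiles: dict[tuple[str, int], SubfamilyInfo] = {}
    for path in sorted(directory.glob("*.peptides.tsv")):
        info = _parse_profile_file(path)
        profiles[(info.family_name, info.index)] = info
    if not profiles:
        raise ProfileFormatError(f"no *.peptides.tsv profiles found in {directory}")
    return profiles
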