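"""Per-genome enzyme profiles and genome clustering.

Gene calls are aggregated into counts per CAZy family and per predicted
function (EC number or "LPMO"), genomes are laid out as a count matrix, and
the matrix is clustered with Ward's agglomerative method on Euclidean
distances — the pairing under which Ward's variance criterion is exact.
Function counts can further be collapsed into cellulose / hemicellulose /
other activity classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .hotpep import GeneCall

ACTIVITY_CLASSES = ("cellulose", "hemicellulose", "other")

#: ECs of the core cellulolytic activities: endoglucanase, beta-glucosidase
#: and the two cellobiohydrolases.
CELLULOSE_ECS = frozenset({"3.2.1.4", "3.2.1.21", "3.2.1.91", "3.2.1.176"})

HEMICELLULOSE_ECS = frozenset(
    {
        "3.2.1.37", "3.2.1.151", "3.2.1.8", "3.2.1.55", "3.2.1.23", "3.2.1.59",
        "3.2.1.131", "3.2.1.177", "3.2.1.78", "3.2.1.67", "2.4.1.183", "3.2.1.25",
        "3.2.1.31", "3.2.1.15", "3.2.1.39", "3.2.1.58", "3.2.1.63", "3.2.1.22",
        "3.2.1.99", "3.2.1.75", "3.2.1.52", "3.2.1.6", "3.2.1.106", "3.2.1.51",
        "3.2.1.113", "2.4.1.18", "2.4.1.25", "3.2.1.28", "3.2.1.45", "3.2.1.18",
        "3.2.1.3", "3.2.1.26", "3.2.1.24", "2.4.1.20", "3.2.1.40", "3.2.1.171",
    }
)


@dataclass(frozen=True)
class GenomeProfile:
    """Enzyme repertoire of one genome as gene counts."""

    genome_id: str
    family_counts: dict[str, int]
    function_counts: dict[str, int]
    n_total: int
    n_assigned_function: int


@dataclass(frozen=True)
class ActivityClassMap:
    """Routing of predicted functions into broad activity classes.

    ECs missing from both lists fall into "other".  LPMO-labeled calls are
    routed by family: cellulose-active LPMO families (AA9 by default) count
    as cellulose, the rest (chitin-active AA11, bacterial AA10) as other.
    """

    cellulose_ecs: frozenset[str] = CELLULOSE_ECS
    hemicellulose_ecs: frozenset[str] = HEMICELLULOSE_ECS
    lpmo_cellulose_families: frozenset[str] = frozenset({"AA9"})

    def class_of(self, ec: str) -> str:
        if ec in self.cellulose_ecs:
            return "cellulose"
        if ec in self.hemicellulose_ecs:
            return "hemicellulose"
        return "other"


def build_profile(calls: list[GeneCall], genome_id: str) -> GenomeProfile:
    """Count gene calls per family and per predicted function.

    A call with several predicted ECs contributes one count to each; calls
    with an empty function count toward ``n_total`` only.
    """
    family_counts: dict[str, int] = {}
    function_counts: dict[str, int] = {}
    n_assigned = 0
    for call in calls:
        family_counts[call.family_name] = family_counts.get(call.family_name, 0) + 1
        if call.predicted_function:
            n_assigned += 1
            for label in call.predicted_function:
                function_counts[label] = function_counts.get(label, 0) + 1
    return GenomeProfile(
        genome_id=genome_id,
        family_counts=family_counts,
        function_counts=function_counts,
        n_total=len(calls),
        n_assigned_function=n_assigned,
    )


def profile_from_table(table: pd.DataFrame | str | Path, genome_id: str) -> GenomeProfile:
    """Build a profile from an exported annotation table (TSV or DataFrame)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"contig": str, "function": str})
    family_counts: dict[str, int] = {}
    function_counts: dict[str, int] = {}
    n_assigned = 0
    for _, row in table.iterrows():
        family_counts[row["family"]] = family_counts.get(row["family"], 0) + 1
        function = row["function"]
        if isinstance(function, str) and function not in ("-", ""):
            n_assigned += 1
            for label in function.split(";"):
                function_counts[label] = function_counts.get(label, 0) + 1
    return GenomeProfile(genome_id, family_counts, function_counts, len(table), n_assigned)


def profile_matrix(
    profiles: list[GenomeProfile], mode: str = "families", normalize: bool = False
) -> pd.DataFrame:
    """Genomes x features count matrix (union of observed features; missing = 0).

    ``mode`` selects family counts or function counts.  With ``normalize``
    each row is divided by its genome's total gene count (an alternative to
    raw counts for clustering).
    """
    if len(profiles) < 2:
        raise ValueError("profile_matrix requires at least two genomes")
    if mode == "families":
        rows = [p.family_counts for p in profiles]
    elif mode == "functions":
        rows = [p.function_counts for p in profiles]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    columns = sorted(set().union(*rows)) if any(rows) else []
    data = [[row.get(col, 0) for col in columns] for row in rows]
    matrix = pd.DataFrame(data, index=[p.genome_id for p in profiles], columns=columns)
    if normalize:
        totals = np.array([max(p.n_total, 1) for p in profiles], dtype=float)
        matrix = matrix.div(totals, axis=0)
    return matrix


def cluster_genomes(matrix: pd.DataFrame, method: str = "ward") -> np.ndarray:
    """Agglomerative linkage of the genome rows (Ward on Euclidean distance)."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least two genomes")
    return linkage(matrix.to_numpy(dtype=float), method=method)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with genome leaves."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    buffer = StringIO()
    tree.write(buffer)
    return buffer.getvalue().strip()


def top_bipartition(Z: np.ndarray, labels: list[str]) -> tuple[frozenset[str], frozenset[str]]:
    """Leaf sets of the two subtrees below the root merge."""
    from scipy.cluster.hierarchy import fcluster

    assignments = fcluster(Z, t=2, criterion="maxclust")
    side1 = frozenset(l for l, a in zip(labels, assignments) if a == 1)
    side2 = frozenset(l for l, a in zip(labels, assignments) if a == 2)
    return side1, side2


def summarize_activity_classes(
    profiles: list[GenomeProfile],
    class_map: ActivityClassMap = ActivityClassMap(),
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genome gene counts in the cellulose/hemicellulose/other classes.

    Every counted EC maps to exactly one class, so the class sums partition
    the function-count totals.  With a genome -> group labeling (e.g.
    degrader / non-degrader) the returned table is the per-group mean
    instead.
    """
    records = []
    for profile in profiles:
        sums = dict.fromkeys(ACTIVITY_CLASSES, 0)
        for ec, count in profile.function_counts.items():
            if ec == "LPMO":
                continue  # routed by family below
            sums[class_map.class_of(ec)] += count
        # every AA-family call is LPMO-labeled, so family counts split the
        # aggregate "LPMO" function count by family
        for family, count in profile.family_counts.items():
            if not family.startswith("AA"):
                continue
            target = (
                "cellulose" if family in class_map.lpmo_cellulose_families else "other"
            )
            sums[target] += count
        records.append({"genome_id": profile.genome_id, **sums})
    table = pd.DataFrame(records).set_index("genome_id")
    if groups is not None:
        table = table.assign(group=[groups[g] for g in table.index])
        table = table.groupby("group").mean()
    return table


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a genome_id TAB group labeling TSV."""
    labels: dict[str, str] = {}
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genome_id, group = line.split("\t")
            labels[genome_id] = group
    return labels
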