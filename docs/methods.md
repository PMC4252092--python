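# Methods

## Subfamily discovery

A protein family is partitioned into subfamilies defined by shared
hexapeptide vocabularies. The operative definitions:

- *conserved peptide*: a length-`peptide_length` (default 6) window present
  in at least `conservation_threshold` (default 0.20) of a group's members.
  Presence per protein is what is counted, not occurrence multiplicity.
- *profile*: the at most `list_size` (default 70) most frequent conserved
  peptides of a group. When the frequency-ordered candidate list crosses the
  threshold inside the top 70 — e.g. one candidate sits at 15% — the profile
  simply ends up shorter (69).
- *subfamily*: ≥ `min_group_size` (default 5) proteins, each containing
  ≥ `min_peptides_per_protein` (default 10) profile peptides.

The defaults (6, 70, 10, 0.20, 5) are the values empirically established for
GH families and are the package defaults throughout, exposed on `PPRParams`.

Candidate groups are found by a deterministic seeded alternation. For each
of the `seed_peptides` (default 50) most widely shared peptides, the initial
member set is every protein containing that peptide; then profile and
membership are recomputed alternately until they stop changing. Duplicate
initial sets are evaluated once. The largest fixed point of size ≥ 5 wins;
ties break by higher total profile frequency, then by the lexicographically
smallest sorted member-id tuple, so a partition is a pure function of the
input. A detected 2-cycle or hitting `max_iterations` (100) falls back to
the smaller of the last two member sets — the conservative choice; in that
(never observed on planted data) case the returned group is not certified
as a fixed point. `PPRParams.random_seed` exists for interface completeness;
the search itself uses no randomness.

Greedy peeling assigns subfamily numbers in discovery order. Functions are
transferred as the union of member EC labels with the most frequent label as
the majority call; ties report all tied labels and flag the subfamily.
AA9/AA10/AA11 subfamilies are always labeled `LPMO` regardless of member
labels.

## Genome annotation

Contigs shorter than 500 bases are discarded, the rest split into 2000-base
windows stepping by 1900 (100-base overlap). A trailing window that would be
fully contained in its predecessor is not emitted, so no sequence is scored
twice. Windows are translated in all six frames with the standard genetic
code (fungal nuclear genes use it; no alternative table is offered). Stop
codons, and ambiguous codons whose IUPAC expansions disagree, become the
sentinel `*`; since profile peptides contain only the 20 amino-acid letters,
no match can span a stop or an ambiguous codon — frames need not be split
into ORFs.

Scoring a frame against a profile records, per matched peptide, every
occurrence position. `freq_sum` counts each distinct peptide once;
`residues_covered` is the length of the union of all occurrence spans (so a
twice-occurring hexapeptide contributes up to 12 residues of coverage but
only one frequency term). The three hit conditions are `n_peptides >= 3`,
`freq_sum > 1.0` (strictly) and `residues_covered >= 10`.

Per fragment and family at most one hit is kept: the best subfamily per
frame by `freq_sum` (ties to the lower subfamily index), then the best frame
by `freq_sum`, `residues_covered`, and canonical frame order
(+1,+2,+3,−1,−2,−3). Hits of one family on one contig are chained
transitively whenever the gap between their fragment spans is < 5800 bases
(adjacent fragments and fragments with one fragment in between both
qualify, with steps of 1900 and 3800). The merge rule deliberately ignores
strand: opposite-strand hits merge but the call is flagged
(`strand_conflict`) and exported with strand `.`. The merged call takes the
subfamily of its highest-scoring constituent hit and that subfamily's
function (AA-family calls always `LPMO`).

Protein mode applies identical scoring and thresholds to full-length
amino-acid sequences with no fragmentation or merging; spans in its output
are residue spans.

## Genome comparison

Profiles count gene calls per family and per predicted function; a call
carrying several ECs increments each (so function counts are per-activity,
not per-gene). Matrices take the union of observed features as columns with
absent features as 0. Clustering is agglomerative Ward linkage on Euclidean
distances over raw counts — Ward's variance criterion is exact for that
metric, and raw counts are the default with per-genome normalization
available as an option. Dendrograms are exported as Newick. Activity-class
summaries route ECs through a fixed cellulose / hemicellulose / other map;
`LPMO` counts are routed by family, AA9 to cellulose and AA10/AA11 to other
by default (AA11 LPMOs are chitin-active as far as characterized), both
overridable via `ActivityClassMap`.

## Synthetic data

`generate_family` plants `n_subfamilies` pairwise-disjoint vocabularies of
`vocabulary_size` (default 70) random hexapeptides into uniform-random
protein backgrounds of `protein_length` (default 500) residues; each peptide
is written into `ceil(conservation × members)` members at random
non-overlapping hexamer-aligned slots, and decoys are pure background. The
uniform background makes accidental matches analytically rare (per window
and peptide, 20⁻⁶ ≈ 1.6 × 10⁻⁸), which is why planted recovery can be
asserted exactly; real families have biased residue composition, homologous
background similarity and indels, so perfect recovery on planted data shows
correctness of the grouping machinery, not expected field accuracy.

`generate_genome` reverse-translates planted member proteins with uniform
random synonymous codons (plus a stop codon), places them on either strand,
and surrounds them with random intergenic DNA of specified GC content
totalling the gene length by default (a 50% intergenic genome). The default
contig policy is one gene per contig with flanking intergenic halves,
emulating a fragmented assembly: with ~1.5 kb genes and 50% intergenic DNA
on a single contig, two same-family genes would lie within the 5800-base
merge distance and the published merge rule itself would fuse them, so
"one call per planted gene" would be unattainable by construction. The merge
rule is still exercised, because every gene longer than the 1900-base
fragment step spans fragment boundaries and its per-fragment hits must be
merged. A `single`-contig policy remains available for tests that need
genes in one sequence. Fixing the seeds reproduces every fixture byte for
byte.

## Problem sizes used in the checks

Planted-partition recovery runs 3 subfamilies × 20 members with 70-peptide
vocabularies at full conservation plus 10 decoys, over 20 seeds; end-to-end
genome recovery plants 20 genes (~1.5 kb each, 50% intergenic DNA) per seed
over 20 seeds. Oracle equivalences use 1000 random hit sets for merging and
≤ 8 genomes for the independent Lance–Williams Ward agglomeration. These
sizes make the whole suite run in well under a minute while leaving every
combinatorial path (multi-fragment genes, both strands, multi-subfamily
families, decoys) exercised.

## Known limitations

- Subfamily discovery assumes peptide vocabularies distinguish subfamilies;
  families whose subfamilies share most hexapeptides will collapse into one
  group, and highly divergent singleton lineages end up ungrouped.
- Gene calls are fragment-resolution intervals, not gene models: no
  intron/exon structure, no precise boundaries, and two genuinely distinct
  same-family genes closer than 5800 bases are reported as one call — the
  stated merge semantics.
- Function transfer is only as good as the EC labels of characterized
  members; unlabeled subfamilies yield calls without function.
- The standard genetic code is assumed throughout.
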