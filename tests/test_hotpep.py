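import random

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from peppr.hotpep import (
    FrameScore,
    Hit,
    HotpepParams,
    ProfileSet,
    annotate_fragments,
    annotate_proteins,
    best_subfamily,
    call_genes,
    merge_hits,
    passes_thresholds,
    read_annotation_table,
    score_frame,
    transfer_function,
    write_annotation_table,
    write_gff3,
)
from peppr.ppr_core import AA_LETTERS, AnnotatedProtein, PeptideProfile, SubfamilyInfo
from peppr.synthetic_data import GenomeSpec, PlantedGene, generate_genome

WORKED_PROFILE = PeptideProfile(
    {"FGTFHL": 0.30, "GTFHLY": 0.34, "YIKSLD": 0.62}
)


def random_protein(rng, n):
    return "".join(rng.choice(AA_LETTERS) for _ in range(n))


class TestScoreFrame:
    def test_frequency_score_worked_example(self):
        seq = "MK" + "FGTFHLY" + "WWWW" + "YIKSLD" + "MK"
        score = score_frame(seq, WORKED_PROFILE)
        assert score.n_peptides == 3
        assert score.freq_sum == pytest.approx(1.26)

    def test_positional_coverage_worked_example(self):
        seq = list("A" * 130)
        seq[64:70] = "YIKSLD"
        seq[110:117] = "FGTFHLY"
        score = score_frame("".join(seq), WORKED_PROFILE)
        assert score.matched_peptides == {
            "FGTFHL": (110,),
            "GTFHLY": (111,),
            "YIKSLD": (64,),
        }
        assert score.residues_covered == 13

    def test_two_overlapping_peptides_cover_seven(self):
        profile = PeptideProfile({"FGTFHL": 0.30, "GTFHLY": 0.34})
        score = score_frame("AAAFGTFHLYAAA", profile)
        assert score.residues_covered == 7

    def test_no_shared_peptides(self):
        score = score_frame("MKMKMKMKMKMK", WORKED_PROFILE)
        assert (score.n_peptides, score.freq_sum, score.residues_covered) == (0, 0.0, 0)

    def test_repeated_peptide_counted_once_but_covers_twice(self):
        profile = PeptideProfile({"FGTFHL": 0.30})
        score = score_frame("FGTFHLWWWFGTFHL", profile)
        assert score.n_peptides == 1
        assert score.freq_sum == pytest.approx(0.30)
        assert score.residues_covered == 12

    def test_match_never_spans_stop_sentinel(self):
        profile = PeptideProfile({"FGTFHL": 0.30})
        assert score_frame("FGT*FHL", profile).n_peptides == 0

    def test_score_additivity_under_peptide_removal(self):
        rng = random.Random(0)
        seq = random_protein(rng, 150) + "FGTFHL" + random_protein(rng, 20) + "YIKSLD"
        full = score_frame(seq, WORKED_PROFILE)
        reduced_profile = PeptideProfile(
            {p: f for p, f in WORKED_PROFILE.peptides.items() if p != "YIKSLD"}
        )
        reduced = score_frame(seq, reduced_profile)
        assert full.freq_sum - reduced.freq_sum == pytest.approx(0.62)

    @given(st.lists(st.integers(0, 30), min_size=3, max_size=3, unique=True),
           st.integers(0, 2**31 - 1))
    def test_three_peptides_cover_between_8_and_18(self, starts, seed):
        """Three distinct single-occurrence hexapeptides cover 8..18 residues."""
        rng = random.Random(seed)
        seq = random_protein(rng, 42)
        peptides = {seq[s : s + 6] for s in starts}
        assume(len(peptides) == 3)
        assume(all(seq.count(p) == 1 for p in peptides))
        profile = PeptideProfile({p: 0.5 for p in peptides})
        score = score_frame(seq, profile)
        assert score.n_peptides == 3
        assert 8 <= score.residues_covered <= 18


class TestThresholds:
    @pytest.mark.parametrize(
        "n,freq,cov,expected",
        [
            (3, 1.26, 13, True),   # the worked example: all three conditions
            (2, 1.50, 12, False),  # too few peptides
            (3, 0.90, 13, False),  # frequency sum too low
            (3, 1.26, 9, False),   # coverage too low
            (2, 0.90, 13, False),
            (2, 1.50, 9, False),
            (3, 0.90, 9, False),
            (2, 0.90, 9, False),
            (3, 1.00, 12, False),  # "higher than 1.0" is strict
            (3, 1.0000001, 10, True),
        ],
    )
    def test_truth_table(self, n, freq, cov, expected):
        score = FrameScore(("GH5", 1), {}, n, freq, cov)
        assert passes_thresholds(score) is expected


class TestBestSubfamily:
    def make(self, idx, freq, n=3, cov=13):
        return FrameScore(("GH5", idx), {}, n, freq, cov)

    def test_highest_frequency_sum_wins(self):
        assert best_subfamily([self.make(1, 1.26), self.make(2, 2.10)]).subfamily_ref == ("GH5", 2)

    def test_none_when_nothing_passes(self):
        assert best_subfamily([self.make(1, 0.8), self.make(2, 1.9, n=2)]) is None

    def test_ties_prefer_lower_index(self):
        assert best_subfamily([self.make(3, 1.5), self.make(1, 1.5)]).subfamily_ref == ("GH5", 1)

    def test_matches_linear_scan_oracle(self):
        rng = random.Random(1)
        scores = [self.make(i, round(rng.uniform(1.1, 3.0), 3)) for i in range(1, 11)]
        rng.shuffle(scores)
        expected = max(scores, key=lambda s: s.freq_sum)
        assert best_subfamily(scores) is expected


def make_hit(contig, start, end, family="GH5", sub=1, freq=1.5, frame=1):
    score = FrameScore((family, sub), {}, 3, freq, 13)
    return Hit(contig, start, end, frame, family, sub, score)


class TestMergeHits:
    def test_adjacent_fragments_merge(self):
        hits = [make_hit("c", 0, 2000), make_hit("c", 1900, 3900)]
        calls = merge_hits(hits)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (0, 3900)

    def test_one_fragment_in_between_merges(self):
        hits = [make_hit("c", 0, 2000), make_hit("c", 3800, 5800)]
        assert len(merge_hits(hits)) == 1

    def test_distant_hits_stay_separate(self):
        hits = [make_hit("c", 0, 2000), make_hit("c", 8000, 10000)]
        assert len(merge_hits(hits)) == 2

    def test_different_families_never_merge(self):
        hits = [make_hit("c", 0, 2000, family="GH5"), make_hit("c", 0, 2000, family="GH10")]
        assert len(merge_hits(hits)) == 2

    def test_call_takes_subfamily_of_best_hit(self):
        hits = [
            make_hit("c", 0, 2000, sub=1, freq=1.2),
            make_hit("c", 1900, 3900, sub=2, freq=2.4),
        ]
        call = merge_hits(hits)[0]
        assert call.subfamily == 2

    def test_strand_conflict_flagged(self):
        hits = [make_hit("c", 0, 2000, frame=1), make_hit("c", 1900, 3900, frame=-2)]
        call = merge_hits(hits)[0]
        assert call.strand_conflict

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(2)
        params = HotpepParams()
        for _ in range(200):
            hits = []
            for i in range(rng.randint(0, 12)):
                start = rng.randrange(0, 40_000, 1900)
                hits.append(
                    make_hit(
                        rng.choice("ab"),
                        start,
                        start + 2000,
                        family=rng.choice(["GH5", "GH10"]),
                    )
                )
            calls = merge_hits(hits, params)
            assert sum(len(c.hits) for c in calls) == len(hits)
            expected = transitive_closure_oracle(hits, params.merge_distance)
            got = {frozenset((h.start, h.end) for h in c.hits) for c in calls}
            assert got == expected


def transitive_closure_oracle(hits, merge_distance):
    """O(n^2) chaining: repeatedly unite same-contig same-family close spans."""
    groups = [{i} for i in range(len(hits))]

    def close(a, b):
        if (a.contig_id, a.family_name) != (b.contig_id, b.family_name):
            return False
        gap = max(a.start, b.start) - min(a.end, b.end)
        return gap < merge_distance

    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] and groups[j] and any(
                    close(hits[a], hits[b]) for a in groups[i] for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return {
        frozenset((hits[i].start, hits[i].end) for i in g) for g in groups if g
    }


class TestTransferFunction:
    def test_labeled_subfamily_transfers(self):
        call = merge_hits([make_hit("c", 0, 2000, family="GH3")])[0]
        table = {("GH3", 1): frozenset({"3.2.1.21"})}
        assert transfer_function(call, table).predicted_function == {"3.2.1.21"}

    def test_unlabeled_subfamily_empty(self):
        call = merge_hits([make_hit("c", 0, 2000, family="GH3")])[0]
        assert transfer_function(call, {("GH3", 1): frozenset()}).predicted_function == frozenset()

    def test_lpmo_families(self):
        call = merge_hits([make_hit("c", 0, 2000, family="AA9", sub=4)])[0]
        assert transfer_function(call, {}).predicted_function == {"LPMO"}

    def test_unknown_subfamily_raises(self):
        call = merge_hits([make_hit("c", 0, 2000, family="GH3", sub=9)])[0]
        with pytest.raises(KeyError):
            transfer_function(call, {("GH3", 1): frozenset()})


@pytest.fixture(scope="module")
def planted_genome(planted_family):
    proteins, truth = planted_family
    by_sf = {}
    for p in proteins:
        sf = truth.assignments.get(p.id)
        if sf is not None:
            by_sf.setdefault(sf, []).append(p)
    genes = tuple(
        PlantedGene(f"gene_{i:03d}", "GH5", (i % 3) + 1, by_sf[(i % 3) + 1][i // 3].seq)
        for i in range(20)
    )
    return generate_genome(GenomeSpec(genes=genes, random_seed=21))


class TestGenomeAnnotation:
    def test_planted_genes_called_once_in_their_family(self, planted_genome, profile_set):
        records, loci = planted_genome
        calls = call_genes(records, profile_set)
        by_contig = {}
        for call in calls:
            by_contig.setdefault(call.contig_id, []).append(call)
        assert len(calls) == len(loci)
        for locus in loci:
            contig_calls = by_contig.get(locus.contig_id, [])
            assert len(contig_calls) == 1
            call = contig_calls[0]
            assert call.family_name == locus.family
            assert call.subfamily == locus.subfamily
            assert call.start < locus.end and locus.start < call.end
            assert call.predicted_function  # subfamilies carry EC labels

    def test_intergenic_dna_yields_no_hits(self, profile_set):
        rng = np.random.default_rng(5)
        from peppr.seqio import GenomeFragment
        from peppr.synthetic_data import random_dna

        fragments = [
            GenomeFragment("junk", 0, 2000, random_dna(rng, 2000)) for _ in range(5)
        ]
        assert annotate_fragments(fragments, profile_set) == []

    def test_fragment_offset_robustness(self, planted_family, profile_set):
        """Shifting a gene by less than the fragment step keeps the same call."""
        proteins, truth = planted_family
        member = next(p for p in proteins if truth.assignments.get(p.id) == 2)
        gene = PlantedGene("g", "GH5", 2, member.seq, strand="+")
        outcomes = set()
        for shift in (0, 700, 1400):
            spec = GenomeSpec(
                genes=(gene,), intergenic_length=3000 + 2 * shift,
                contig_policy="single", random_seed=9,
            )
            records, _ = generate_genome(spec)
            calls = call_genes(records, profile_set)
            assert len(calls) == 1
            outcomes.add((calls[0].family_name, calls[0].subfamily))
        assert outcomes == {("GH5", 2)}

    def test_two_domain_sequence_hits_two_families(self, tmp_path):
        rng = random.Random(4)
        vocab_a = [random_protein(rng, 6) for _ in range(20)]
        vocab_b = [random_protein(rng, 6) for _ in range(20)]
        profiles = {
            ("GH10", 1): SubfamilyInfo(
                "GH10", 1, 5, frozenset(), PeptideProfile({p: 0.9 for p in vocab_a})
            ),
            ("GH43", 1): SubfamilyInfo(
                "GH43", 1, 5, frozenset(), PeptideProfile({p: 0.9 for p in vocab_b})
            ),
        }
        ps = ProfileSet(profiles)
        protein = "".join(vocab_a[:10]) + random_protein(rng, 30) + "".join(vocab_b[:10])
        hits = annotate_proteins([AnnotatedProtein("two_domain", protein)], ps)
        assert sorted(h.family_name for h in hits) == ["GH10", "GH43"]


class TestProteinMode:
    def test_member_passes_against_own_profile(self, planted_family, profile_set):
        proteins, truth = planted_family
        member = next(p for p in proteins if truth.assignments.get(p.id) == 1)
        hits = annotate_proteins([member], profile_set)
        assert len(hits) == 1
        assert hits[0].subfamily == 1
        assert hits[0].frame is None

    def test_single_peptide_protein_fails(self, profile_set):
        pep = next(iter(profile_set.index))
        assert annotate_proteins([AnnotatedProtein("tiny", pep)], profile_set) == []

    def test_shuffled_members_fail(self, planted_family, profile_set):
        proteins, truth = planted_family
        member = next(p for p in proteins if truth.assignments.get(p.id) == 1)
        rng = random.Random(6)
        for _ in range(50):
            shuffled = "".join(rng.sample(member.seq, len(member.seq)))
            assert annotate_proteins([AnnotatedProtein("s", shuffled)], profile_set) == []

    def test_genome_and_protein_mode_agree(self, planted_family, profile_set):
        proteins, truth = planted_family
        member = next(p for p in proteins if truth.assignments.get(p.id) == 3)
        records, _ = generate_genome(
            GenomeSpec(genes=(PlantedGene("g", "GH5", 3, member.seq),), random_seed=13)
        )
        genome_calls = call_genes(records, profile_set)
        protein_hits = annotate_proteins([member], profile_set)
        assert [(c.family_name, c.subfamily) for c in genome_calls] == [("GH5", 3)]
        assert [(h.family_name, h.subfamily) for h in protein_hits] == [("GH5", 3)]


class TestExports:
    def test_annotation_table_roundtrip(self, tmp_path, planted_genome, profile_set):
        records, loci = planted_genome
        calls = call_genes(records, profile_set)
        path = tmp_path / "ann.tsv"
        write_annotation_table(calls, path)
        table = read_annotation_table(path)
        assert len(table) == len(calls)
        assert list(table.columns) == [
            "contig", "start", "end", "strand", "family", "subfamily",
            "n_peptides", "freq_sum", "residues_covered", "function",
        ]
        assert (table["start"] >= 1).all()
        assert set(table["family"]) == {"GH5"}

    def test_gff3_output(self, tmp_path, planted_genome, profile_set):
        records, _ = planted_genome
        calls = call_genes(records, profile_set)
        path = tmp_path / "ann.gff3"
        write_gff3(calls, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        body = [l for l in lines[1:]]
        assert len(body) == len(calls)
        assert all(l.split("\t")[2] == "gene_call" for l in body)
        assert all("Family=GH5" in l for l in body)
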