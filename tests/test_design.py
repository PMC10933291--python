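"""Edit-plan compilation, fragment planning and chew-back assembly simulation."""

import numpy as np
import pytest

from phagelink import (Deletion, EditPlan, Insertion, OverlapSpec, Substitution,
                       apply_edit_plan, crosstalk_matrix, make_genome_fixture,
                       plan_fragments, simulate_assembly, wallace_tm)
from phagelink.design import _longest_complementary_match, _revcomp


@pytest.fixture(scope="module")
def genome40k():
    seq, _ = make_genome_fixture(40_000, seed=21)
    return seq


@pytest.fixture(scope="module")
def genome399(  ):
    seq, _ = make_genome_fixture(39_937, seed=22)
    return seq


class TestApplyEditPlan:
    def test_empty_plan_is_identity(self, genome40k):
        edited = apply_edit_plan(EditPlan(genome40k))
        assert edited.sequence == genome40k
        assert edited.ref_to_edited(123) == 123

    def test_length_bookkeeping(self, genome40k):
        plan = EditPlan(genome40k, [
            Deletion(5_000, 9_000, "del-A"),
            Insertion(20_000, "A" * 1_000, "cassette"),
        ])
        edited = apply_edit_plan(plan)
        assert len(edited.sequence) == 40_000 - 4_000 + 1_000

    def test_minimized_genome_arithmetic(self):
        # three deletions totalling 4.1 kbp on a 39.9-kbp genome -> 35.8 kbp
        seq, _ = make_genome_fixture(39_900, seed=3)
        plan = EditPlan(seq, [Deletion(1_000, 2_500), Deletion(5_000, 6_600),
                              Deletion(12_000, 13_000)])
        assert len(apply_edit_plan(plan).sequence) == 35_800

    def test_coordinate_map(self, genome40k):
        edited = apply_edit_plan(EditPlan(genome40k, [Deletion(100, 200)]))
        assert edited.ref_to_edited(50) == 50
        assert edited.ref_to_edited(150) is None     # deleted
        assert edited.ref_to_edited(200) == 100
        assert edited.sequence[100] == genome40k[200]

    def test_substitution_checks_reference_base(self, genome40k):
        base = genome40k[77]
        alt = "A" if base != "A" else "C"
        edited = apply_edit_plan(EditPlan(genome40k, [Substitution(77, base, alt)]))
        assert edited.sequence[77] == alt
        with pytest.raises(ValueError, match="reference has"):
            apply_edit_plan(EditPlan(genome40k, [Substitution(77, alt, base)]))

    def test_overlapping_edits_rejected(self, genome40k):
        plan = EditPlan(genome40k, [Deletion(100, 300), Deletion(200, 400)])
        with pytest.raises(ValueError, match="overlap"):
            apply_edit_plan(plan)


class TestPlanFragments:
    def test_four_part_split_spans(self, genome399):
        # junction midpoints at the published four-part design coordinates
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        assert len(plan.fragments) == 4
        spans = [(f.start, f.end) for f in plan.fragments]
        # junction-to-junction spans 10.7 / 9.8 / 10.1 / 9.3 kbp +/- overlap
        assert spans[0][0] == 0 and spans[-1][1] == len(genome399)
        assert len(plan.fragments[0]) == 10_700 + 25
        assert len(plan.fragments[1]) == 9_800 + 50
        assert all(len(f) <= 12_000 for f in plan.fragments)

    def test_junctions_share_exact_overlap(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        for left, right in zip(plan.fragments, plan.fragments[1:]):
            assert left.sequence[-50:] == right.sequence[:50]

    def test_fragments_reconstruct_genome(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        rebuilt = plan.fragments[0].sequence
        for frag in plan.fragments[1:]:
            rebuilt += frag.sequence[50:]
        assert rebuilt == genome399

    def test_two_fragments_within_limit(self):
        seq, _ = make_genome_fixture(13_000, seed=4)
        plan = plan_fragments(seq, breakpoints=[6_500])
        assert all(len(f) <= 12_000 for f in plan.fragments)

    def test_oversize_fragment_rejected(self):
        seq, _ = make_genome_fixture(13_000, seed=4)
        with pytest.raises(ValueError, match="12000"):
            plan_fragments(seq, breakpoints=[])

    def test_max_len_auto_split(self, genome40k):
        plan = plan_fragments(genome40k, max_len=12_000)
        assert all(len(f) <= 12_000 for f in plan.fragments)
        rebuilt = plan.fragments[0].sequence
        for frag in plan.fragments[1:]:
            rebuilt += frag.sequence[50:]
        assert rebuilt == genome40k

    def test_orthogonal_tags_at_junctions(self, rng):
        seq, _ = make_genome_fixture(6_000, seed=8)
        tags = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(2)]
        plan = plan_fragments(seq, breakpoints=[2_000, 4_000],
                              overlap=OverlapSpec.orthogonal(tags))
        for i, (left, right) in enumerate(zip(plan.fragments, plan.fragments[1:])):
            assert left.sequence[-20:] == tags[i]
            assert right.sequence[:20] == tags[i]
        # tags are incorporated once each into the expected product
        assert len(plan.expected_product) == 6_000 + 2 * 20

    def test_primer_annealing_regions(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        for frag in plan.fragments:
            p = frag.primers
            assert frag.sequence.startswith(p.sense)
            assert _revcomp(frag.sequence).startswith(p.antisense)
            assert wallace_tm(p.sense) >= 60 or len(p.sense) == 30


class TestCrosstalk:
    def test_identical_nonpartners_flagged(self):
        ends = ["ACGTACGTACGTACGTACGT"] * 2
        score, flagged = crosstalk_matrix(ends)
        # a self-complementary-by-identity pair scores the full revcomp match
        assert flagged and flagged[0][:2] == (0, 1)
        assert score[0, 1] >= 10

    def test_partner_pairs_excluded(self):
        ends = ["ACGTACGTACGTACGTACGT"] * 2
        _, flagged = crosstalk_matrix(ends, partners=[(0, 1)])
        assert flagged == []

    def test_random_20mers_stay_below_threshold(self, rng):
        ends = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(8)]
        score, flagged = crosstalk_matrix(ends, threshold=10)
        assert flagged == []
        off_diag = score[~np.eye(len(ends), dtype=bool)]
        assert off_diag.max() <= 9

    def test_matches_brute_force_substring_scan(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=20))
        b = "".join(rng.choice(list("ACGT"), size=20))
        rb = _revcomp(b)
        brute = max((k for k in range(0, 21)
                     for i in range(21 - k) if a[i:i + k] in rb), default=0)
        assert _longest_complementary_match(a, b) == brute


class TestSimulateAssembly:
    def test_complete_plan_roundtrip(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        result = simulate_assembly(plan.fragments, chewback_length=60)
        assert result.complete
        assert result.product == genome399

    def test_dropping_any_fragment_breaks_assembly(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        seqs = plan.sequences()
        for drop in range(len(seqs)):
            subset = [s for i, s in enumerate(seqs) if i != drop]
            result = simulate_assembly(subset, chewback_length=60)
            # no full-length genome from any three fragments
            assert all(len(p) < len(genome399) for p in result.products)
            if 0 < drop < len(seqs) - 1:    # interior drop also breaks the chain
                assert not result.complete

    def test_order_and_orientation_invariance(self, genome399, rng):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        seqs = plan.sequences()
        rng.shuffle(seqs)
        seqs[1] = _revcomp(seqs[1])
        result = simulate_assembly(seqs, chewback_length=60)
        assert result.complete
        assert result.matches(genome399)

    def test_chewback_shorter_than_overlap_fails(self, genome399):
        plan = plan_fragments(genome399, breakpoints=[10_700, 20_500, 30_600])
        result = simulate_assembly(plan.sequences(), chewback_length=40)
        assert not result.complete    # 50-bp junctions never exposed

    def test_orthogonal_plan_assembles_with_tags(self, rng):
        seq, _ = make_genome_fixture(6_000, seed=8)
        tags = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(2)]
        plan = plan_fragments(seq, breakpoints=[2_000, 4_000],
                              overlap=OverlapSpec.orthogonal(tags))
        result = simulate_assembly(plan.sequences(), chewback_length=30,
                                   min_anneal=12)
        assert result.complete
        assert result.product == plan.expected_product

    def test_deletion_bridging_excludes_deleted_bases(self, genome40k):
        edited = apply_edit_plan(EditPlan(genome40k, [Deletion(15_000, 18_000)]))
        plan = plan_fragments(edited.sequence, max_len=11_000)
        deleted = genome40k[15_000 + 50:18_000 - 50]
        for frag in plan.fragments:
            assert deleted not in frag.sequence
        result = simulate_assembly(plan.sequences(), chewback_length=60)
        assert result.complete and result.product == edited.sequence


class TestRoundTripProperty:
    def test_random_edit_plans_roundtrip(self):
        """Randomized edit plans survive plan -> fragment -> assembly."""
        rng = np.random.default_rng(314)
        for trial in range(25):
            n = int(rng.integers(5_000, 40_000))
            seq, _ = make_genome_fixture(n, seed=1000 + trial)
            edits = []
            if n > 12_000:
                start = int(rng.integers(1_000, n // 2))
                edits.append(Deletion(start, start + int(rng.integers(100, 2_000))))
            locus = int(rng.integers(n // 2 + 2_500, n - 1_000))
            cassette = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 800))))
            edits.append(Insertion(locus, cassette))
            edited = apply_edit_plan(EditPlan(seq, edits))
            plan = plan_fragments(edited.sequence, max_len=11_000)
            result = simulate_assembly(plan.sequences(), chewback_length=60)
            assert result.complete
            assert result.product == edited.sequence
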