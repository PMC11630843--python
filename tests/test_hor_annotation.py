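"""Region segmentation, canonical-unit calling, copy tiling and summaries."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import grmhor as g
from grmhor.grm_core import assign_types, build_next_similar
from grmhor.hor_annotation import (
    CASCADING,
    WILLARD,
    CanonicalUnit,
    HORArraySummary,
    HORCopy,
    HORRegion,
    annotate_array,
    call_canonical_unit,
    enumerate_hor_copies,
    label_edit_ops,
    region_tail,
    repeated_subblocks,
    segment_hor_regions,
    summarize_arrays,
)
from grmhor.monomer_model import MonomerArray


@pytest.fixture(scope="module")
def canonical_types(canonical100, canonical_vector):
    return assign_types(canonical100, canonical_vector)


@pytest.fixture(scope="module")
def case2_types(case2_array, case2_vector):
    return assign_types(case2_array, case2_vector)


class TestSegmentation:
    def test_canonical_array_yields_one_full_region(self, canonical_vector):
        regions = segment_hor_regions(canonical_vector)
        assert len(regions) == 1
        r = regions[0]
        assert (r.first, r.last, r.dominant_period, r.support) == (1, 100, 10, 90)

    def test_random_tail_yields_no_region(self, canonical100, base10):
        tail_pool = g.gen_divergent_monomers(g.FixtureSpec(seed=99))
        tail = g.build_random_array(tail_pool, 50, seed=4)
        combined = MonomerArray.from_sequences(
            canonical100.sequences + tail.sequences
        )
        regions = segment_hor_regions(build_next_similar(combined))
        assert len(regions) == 1
        assert regions[0].dominant_period == 10
        assert regions[0].first == 1
        assert regions[0].last <= 105  # region never reaches into the tail

    def test_all_dissimilar_array_has_no_regions(self, pool12):
        arr = MonomerArray.from_sequences(pool12 * 3)
        # 12 types repeated 3x IS periodic; use truly dissimilar monomers:
        arr = MonomerArray.from_sequences(pool12)
        assert segment_hor_regions(build_next_similar(arr)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_random_arrays_have_no_regions(self, base10, seed):
        arr = g.build_random_array(base10, 100, seed=seed)
        assert segment_hor_regions(build_next_similar(arr)) == []

    def test_short_array_has_no_window(self, canonical_vector, base10):
        arr = g.build_canonical_array(base10, 1)
        assert segment_hor_regions(build_next_similar(arr)) == []

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            HORRegion(first=5, last=4, dominant_period=10, support=3)
        with pytest.raises(ValueError):
            HORRegion(first=1, last=10, dominant_period=1, support=3)


class TestCanonicalUnit:
    def test_canonical_fixture_is_willard(self, canonical100, canonical_types):
        region = HORRegion(1, 100, 10, 90)
        unit = call_canonical_unit(canonical100, canonical_types, region)
        assert unit.n == 10 and unit.tau == 10
        assert unit.hor_class == WILLARD
        assert unit.type_sequence == tuple(f"t{i}" for i in range(1, 11))

    def test_cascading_fixture_unit(self, cascading110):
        ann = annotate_array(cascading110)
        assert len(ann.units) == 1
        unit = ann.units[0]
        assert unit.n == 11 and unit.tau == 10
        assert unit.hor_class == CASCADING
        assert unit.type_sequence.count("t2") == 2
        assert unit.duplicated_types == ["t2"]

    def test_identical_monomer_degenerate_unit(self, base10):
        arr = MonomerArray.from_sequences([base10[0]] * 30)
        v = build_next_similar(arr)
        types = assign_types(arr, v)
        region = HORRegion(1, 30, 2, support=29)
        unit = call_canonical_unit(arr, types, region)
        assert unit.type_sequence == ("t1", "t1")
        assert unit.tau == 1 and unit.hor_class == CASCADING

    def test_region_too_short_for_unit(self, canonical100, canonical_types):
        with pytest.raises(ValueError):
            call_canonical_unit(
                canonical100, canonical_types, HORRegion(1, 5, 10, 3)
            )

    def test_willard_rule_equals_bruteforce_duplicate_check(self):
        labels = ["a", "b", "c", "d"]
        for n in (2, 3, 4):
            for combo in itertools.product(labels, repeat=n):
                unit = CanonicalUnit(type_sequence=combo)
                has_dup = any(combo.count(x) > 1 for x in combo)
                assert (unit.hor_class == CASCADING) == has_dup


class TestCopies:
    def test_canonical_fixture_all_copies_canonical(
        self, canonical100, canonical_types
    ):
        region = HORRegion(1, 100, 10, 90)
        unit = call_canonical_unit(canonical100, canonical_types, region)
        copies = enumerate_hor_copies(canonical100, canonical_types, region, unit)
        assert len(copies) == 10
        assert all(c.status == "canonical" for c in copies)
        assert [c.start for c in copies] == list(range(1, 100, 10))

    def test_variant_fixture_copy_calls(self, case2_array, case2_types):
        region = HORRegion(1, 100, 10, support=46)
        unit = call_canonical_unit(case2_array, case2_types, region)
        assert unit.hor_class == WILLARD and unit.n == 10
        copies = enumerate_hor_copies(case2_array, case2_types, region, unit)
        assert len(copies) == 10
        lengths = sorted(c.n_monomers for c in copies)
        assert lengths == [8, 8, 10, 10, 10, 10, 10, 10, 12, 12]
        variants = [c for c in copies if c.status == "variant"]
        assert len(variants) == 4
        deletions = [c for c in variants if c.n_monomers == 8]
        insertions = [c for c in variants if c.n_monomers == 12]
        assert len(deletions) == 2 and len(insertions) == 2
        assert all(
            sorted(op[0] for op in c.edit_ops) == ["del", "del"] for c in deletions
        )
        assert all(
            sorted(op[0] for op in c.edit_ops) == ["ins", "ins"] for c in insertions
        )

    def test_single_deletion_yields_one_variant(self, base10):
        seqs = g.build_canonical_array(base10, 10).sequences
        del seqs[14]  # drop one monomer from the second copy
        arr = MonomerArray.from_sequences(seqs)
        ann = annotate_array(arr)
        assert len(ann.regions) == 1
        copies = ann.copies[0]
        variants = [c for c in copies if c.status == "variant"]
        assert len(variants) == 1
        assert [op[0] for op in variants[0].edit_ops] == ["del"]

    def test_reconstruction_of_region_labels(self, case2_array, case2_types):
        region = HORRegion(1, 100, 10, support=46)
        unit = call_canonical_unit(case2_array, case2_types, region)
        copies = enumerate_hor_copies(case2_array, case2_types, region, unit)
        rebuilt = tuple(
            lab for c in copies for lab in c.type_sequence
        ) + region_tail(case2_types, region, copies)
        assert rebuilt == case2_types.labels[region.first - 1 : region.last]

    def test_copy_status_invariant(self):
        with pytest.raises(ValueError):
            HORCopy(1, ("t1",), "canonical", (("del", 1, "t2"),))


class TestSummaries:
    def test_canonical_summary_row(self, canonical100):
        ann = annotate_array(canonical100)
        assert len(ann.summaries) == 1
        s = ann.summaries[0]
        assert (s.n, s.tau, s.total_copies, s.canonical_copies, s.hor_class) == (
            10, 10, 10, 10, WILLARD,
        )

    def test_cascading_summary_row(self, cascading110):
        ann = annotate_array(cascading110)
        s = ann.summaries[0]
        assert (s.n, s.tau, s.hor_class) == (11, 10, CASCADING)
        assert s.total_copies == 10 and s.canonical_copies >= 9

    def test_empty_annotation_gives_empty_table(self, pool12):
        arr = MonomerArray.from_sequences(pool12)
        ann = annotate_array(arr)
        assert ann.summaries == ()
        assert summarize_arrays([]) == []

    def test_canonical_never_exceeds_total(self):
        with pytest.raises(ValueError):
            HORArraySummary(
                region=HORRegion(1, 30, 5, 10),
                n=5, tau=5, total_copies=3, canonical_copies=4, hor_class=WILLARD,
            )


class TestLabelEditOps:
    @pytest.mark.parametrize(
        "observed,unit,dist,kinds",
        [
            (list("abc"), list("abc"), 0, []),
            (list("ac"), list("abc"), 1, ["del"]),
            (list("abxc"), list("abc"), 1, ["ins"]),
            (list("axc"), list("abc"), 1, ["sub"]),
            (list("x"), list("abc"), 3, ["del", "del", "sub"]),
        ],
    )
    def test_known_alignments(self, observed, unit, dist, kinds):
        d, ops = label_edit_ops(observed, unit)
        assert d == dist
        assert sorted(op[0] for op in ops) == sorted(kinds)

    @given(
        a=st.lists(st.sampled_from("abcd"), max_size=8),
        b=st.lists(st.sampled_from("abcd"), min_size=1, max_size=8),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_op_count_equals_distance(self, a, b):
        d, ops = label_edit_ops(a, b)
        assert len(ops) == d


def test_repeated_subblocks_decompose_interleaved_unit():
    unit = CanonicalUnit(type_sequence=tuple("abcabcdede"))
    blocks = dict(repeated_subblocks(unit))
    assert blocks[tuple("abc")] == 2
    assert blocks[tuple("de")] == 2
    # pure Willard units contain no repeated block
    willard = CanonicalUnit(type_sequence=tuple("abcdef"))
    assert repeated_subblocks(willard) == []
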