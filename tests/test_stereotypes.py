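import pytest
from hypothesis import given, strategies as st

from stereorep.stereotypes import (
    ClanTable,
    SequenceComparisonError,
    SimilarityGroups,
    StereotypeAssignment,
    SubsetDefinition,
    aa_identity,
    aa_similarity,
    assign_subset,
    classify_typical,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_strings = st.text(alphabet=AA, min_size=1, max_size=30)
aa_pairs = st.integers(1, 30).flatmap(
    lambda n: st.tuples(
        st.text(alphabet=AA, min_size=n, max_size=n),
        st.text(alphabet=AA, min_size=n, max_size=n),
    )
)


class TestIdentity:
    def test_identical(self):
        assert aa_identity("ARDANGMDV", "ARDANGMDV") == 1.0

    def test_three_of_four(self):
        assert aa_identity("QWLA", "QWMA") == 0.75

    def test_single_mismatch(self):
        assert aa_identity("A", "V") == 0.0

    def test_length_mismatch(self):
        with pytest.raises(SequenceComparisonError, match="length"):
            aa_identity("AA", "AAA")

    def test_invalid_residue_names_position(self):
        with pytest.raises(SequenceComparisonError, match="position 1"):
            aa_identity("AXA", "AAA")


class TestSimilarity:
    def test_identical(self, groups):
        assert aa_similarity("QWLA", "QWLA", groups) == 1.0

    def test_aliphatic_pair(self, groups):
        assert aa_similarity("L", "I", groups) == 1.0

    def test_grouped_vs_identity(self, groups):
        assert aa_similarity("QWLA", "QWIA", groups) == 1.0
        assert aa_identity("QWLA", "QWIA") == 0.75

    @given(aa_pairs)
    def test_identity_le_similarity_le_one(self, pair):
        a, b = pair
        groups = SimilarityGroups()
        ident = aa_identity(a, b)
        simil = aa_similarity(a, b, groups)
        assert 0.0 <= ident <= simil <= 1.0

    @given(aa_pairs)
    def test_singleton_groups_degenerate_to_identity(self, pair):
        a, b = pair
        singles = SimilarityGroups.singletons()
        assert aa_similarity(a, b, singles) == aa_identity(a, b)

    def test_partition_must_cover_alphabet(self):
        with pytest.raises(ValueError, match="not covered"):
            SimilarityGroups({"a": "GAVLI"})

    def test_partition_must_be_disjoint(self):
        classes = dict(SimilarityGroups().classes)
        classes["extra"] = "G"
        del classes["aliphatic"]
        classes["aliphatic"] = "GAVLI"
        with pytest.raises(ValueError, match="both"):
            SimilarityGroups(classes)


class TestClanTable:
    def test_defaults(self, clans):
        assert clans.clan_of("IGHV1-69") == "I"
        assert clans.clan_of("IGHV3-23*01") == "III"
        assert clans.clan_of("IGHV4-34") == "II"

    def test_unknown_gene_raises_with_name(self, clans):
        with pytest.raises(KeyError, match="IGHV9-99"):
            clans.clan_of("IGHV9-99")

    def test_gene_override(self):
        table = ClanTable(gene_overrides={"IGHV1-x": "III"})
        assert table.clan_of("IGHV1-x") == "III"
        assert table.clan_of("IGHV1-69") == "I"


class TestSubsetDefinition:
    def test_window_must_fit(self):
        with pytest.raises(ValueError, match="window"):
            SubsetDefinition(
                subset_id="#X", cdr3_length_aa=5, pattern="ARDLGW",
                pattern_offset=2, clan="I",
                typical_v_genes=frozenset({"IGHV1-69"}),
            )

    def test_identity_le_similarity(self):
        with pytest.raises(ValueError, match="min_identity"):
            SubsetDefinition(
                subset_id="#X", cdr3_length_aa=13, pattern="ARDLGW",
                pattern_offset=2, clan="I",
                typical_v_genes=frozenset({"IGHV1-69"}),
                min_identity=0.8, min_similarity=0.7,
            )


def _cdr3_for(subset, window=None):
    """CDR3 of the right length carrying `window` (default the consensus)."""
    window = window if window is not None else subset.pattern
    prefix = "A" * subset.pattern_offset
    suffix = "A" * (subset.cdr3_length_aa - subset.pattern_offset - len(window))
    return prefix + window + suffix


class TestAssignSubset:
    def test_exact_consensus_match(self, demo_subsets, clans, groups):
        sd = demo_subsets[0]
        res = assign_subset(
            _cdr3_for(sd), "IGHV1-69", demo_subsets, clans, groups
        )
        assert res.subset_id == "#A"
        assert res.identity == 1.0
        assert res.similarity == 1.0
        assert res.typical is True

    def test_wrong_length_gives_none(self, demo_subsets, clans, groups):
        res = assign_subset("ARDLGW", "IGHV1-69", demo_subsets, clans, groups)
        assert res.subset_id is None
        assert res.typical is None

    def test_identity_rule_is_conjunctive(self, clans, groups):
        # window similar everywhere (same-group changes) but identity < 0.5
        sd = SubsetDefinition(
            subset_id="#X", cdr3_length_aa=10, pattern="LLLLLLLL",
            pattern_offset=1, clan="I",
            typical_v_genes=frozenset({"IGHV1-69"}),
            min_identity=0.5, min_similarity=0.7,
        )
        window = "IIIIILLL"  # 3/8 identity, 8/8 similarity
        res = assign_subset(_cdr3_for(sd, window), "IGHV1-69", [sd],
                            clans, groups)
        assert aa_identity(window, sd.pattern) == 0.375
        assert aa_similarity(window, sd.pattern, groups) == 1.0
        assert res.subset_id is None

    def test_clan_mismatch_excludes(self, demo_subsets, clans, groups):
        sd = demo_subsets[0]
        res = assign_subset(
            _cdr3_for(sd), "IGHV3-23", demo_subsets, clans, groups
        )
        assert res.subset_id is None

    def test_unknown_gene_raises(self, demo_subsets, clans, groups):
        with pytest.raises(KeyError, match="IGHV8"):
            assign_subset(
                "A" * 13, "IGHV8-51", demo_subsets, clans, groups
            )

    def test_ambiguity_tie_break_deterministic(self, clans, groups):
        mk = lambda sid: SubsetDefinition(
            subset_id=sid, cdr3_length_aa=10, pattern="ARDL",
            pattern_offset=2, clan="I",
            typical_v_genes=frozenset({"IGHV1-69"}),
        )
        defs = [mk("#Z"), mk("#Y")]
        cdr3 = _cdr3_for(defs[0])
        results = [
            assign_subset(cdr3, "IGHV1-69", order, clans, groups)
            for order in (defs, defs[::-1])
        ]
        assert results[0] == results[1]
        assert results[0].subset_id == "#Y"  # lexicographic tie-break
        assert set(results[0].ambiguous_candidates) == {"#Y", "#Z"}

    def test_threshold_monotonicity(self, clans, groups, rng):
        base = SubsetDefinition(
            subset_id="#M", cdr3_length_aa=12, pattern="ARDLGWQK",
            pattern_offset=2, clan="I",
            typical_v_genes=frozenset({"IGHV1-69"}),
            min_identity=0.3, min_similarity=0.3,
        )
        cdr3s = [
            "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                    for i in rng.integers(0, 20, 12))
            for _ in range(300)
        ]

        def n_assigned(mi, ms):
            sd = SubsetDefinition(
                subset_id="#M", cdr3_length_aa=12, pattern="ARDLGWQK",
                pattern_offset=2, clan="I",
                typical_v_genes=frozenset({"IGHV1-69"}),
                min_identity=mi, min_similarity=ms,
            )
            return sum(
                assign_subset(c, "IGHV1-69", [sd], clans, groups).subset_id
                is not None
                for c in cdr3s
            )

        counts = [
            n_assigned(mi, max(mi, ms))
            for mi in (0.1, 0.3, 0.5)
            for ms in (0.3, 0.5, 0.7)
        ]
        for mi_lo, mi_hi in [(0.1, 0.3), (0.3, 0.5)]:
            assert n_assigned(mi_hi, 0.5) <= n_assigned(mi_lo, 0.5)
        for ms_lo, ms_hi in [(0.3, 0.5), (0.5, 0.7)]:
            assert n_assigned(0.3, ms_hi) <= n_assigned(0.3, ms_lo)
        assert all(c >= 0 for c in counts)

    def test_no_definitions_raises(self, clans, groups):
        with pytest.raises(ValueError):
            assign_subset("AAAA", "IGHV1-69", [], clans, groups)


class TestClassifyTypical:
    def test_typical_gene(self, demo_subsets):
        assert classify_typical("IGHV1-69", demo_subsets[0]) is True

    def test_non_typical_gene(self, demo_subsets):
        assert classify_typical("IGHV1-2", demo_subsets[0]) is False

    def test_empty_typical_set_is_precondition_error(self):
        sd = SubsetDefinition(
            subset_id="#E", cdr3_length_aa=13, pattern="ARDLGW",
            pattern_offset=2, clan="I", typical_v_genes=frozenset(),
        )
        with pytest.raises(ValueError, match="empty"):
            classify_typical("IGHV1-69", sd)


class TestAssignment:
    def test_none_subset_forbids_typical(self):
        with pytest.raises(ValueError):
            StereotypeAssignment("s1", None, typical=True)

    def test_identity_gt_similarity_rejected(self):
        with pytest.raises(ValueError):
            StereotypeAssignment("s1", "#A", identity=0.9, similarity=0.5)
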