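"""Catalog operations against brute-force oracles and the naming grammar."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirweave.catalog import (TagCount, VariantName, collapse_reads,
                              derive_variant, expression_tier,
                              filter_by_length, length_distribution,
                              match_known, remove_contaminants)
from mirweave.synthetic import revcomp

BASES = "ACGT"


def random_tag(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


class TestCollapse:
    def test_duplicates_collapse_with_per_library_counts(self):
        catalog = collapse_reads([["ACGT", "ACGT"], [], ["TTTT"]])
        by_tag = {t.tag: t.counts for t in catalog}
        assert by_tag == {"ACGT": [2, 0, 0], "TTTT": [0, 0, 1]}

    def test_empty_input(self):
        assert collapse_reads([]) == []
        assert collapse_reads([[], []]) == []

    def test_hand_enumerated_toy_partition(self):
        # 5 reads, 3 libraries with disjoint tags -> indicator count vectors
        libs = [["AAAA", "AAAA"], ["CCCC"], ["GGGG", "GGGG"]]
        catalog = collapse_reads(libs)
        assert {t.tag: t.counts for t in catalog} == {
            "AAAA": [2, 0, 0], "CCCC": [0, 1, 0], "GGGG": [0, 0, 2]}

    def test_non_nucleotide_records_skipped(self):
        catalog = collapse_reads([["ACGT", "ACNT", "acgu"]])
        assert {t.tag: t.total for t in catalog} == {"ACGT": 2}

    def test_order_total_desc_then_lexicographic(self):
        catalog = collapse_reads([["TT", "TT", "AA", "CC"]])
        assert [t.tag for t in catalog] == ["TT", "AA", "CC"]


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(16, False), (17, True),
                                             (25, True), (26, False)])
    def test_inclusive_bounds(self, length, kept):
        catalog = [TagCount("A" * length, [1])]
        assert bool(filter_by_length(catalog)) is kept

    def test_matches_bruteforce_scan(self, rng):
        catalog = [TagCount(random_tag(rng, int(rng.integers(10, 32))), [1])
                   for _ in range(300)]
        got = {t.tag for t in filter_by_length(catalog)}
        expected = {t.tag for t in catalog if 17 <= len(t.tag) <= 25}
        assert got == expected


class TestContaminants:
    def test_exact_substring_removed_both_strands(self):
        trna = "GCCGTGATCGTATAGTGGTTAGTACTCTGCG"
        catalog = [TagCount(trna[:20], [3]), TagCount(revcomp(trna)[5:25], [1]),
                   TagCount("A" * 20, [2])]
        kept, removed = remove_contaminants(catalog, {"tRNA1": trna})
        assert {t.tag for t in removed} == {trna[:20], revcomp(trna)[5:25]}
        assert {t.tag for t in kept} == {"A" * 20}

    def test_empty_contaminant_set_keeps_everything(self):
        catalog = [TagCount("ACGTACGTACGTACGTA", [1])]
        kept, removed = remove_contaminants(catalog, {})
        assert kept == catalog and removed == []

    def test_partition_matches_quadratic_oracle(self, rng):
        contaminants = {f"c{i}": random_tag(rng, 120) for i in range(10)}
        catalog = []
        for i in range(1000):
            if i % 5 == 0:  # plant true fragments
                src = contaminants[f"c{int(rng.integers(10))}"]
                s = int(rng.integers(0, 100))
                catalog.append(TagCount(src[s:s + 20] + str(i), [1]))
                catalog[-1] = TagCount(src[s:s + 20], [1])
            else:
                catalog.append(TagCount(random_tag(rng, 20), [1]))
        # de-duplicate tags (catalog invariant)
        seen, uniq = set(), []
        for t in catalog:
            if t.tag not in seen:
                seen.add(t.tag)
                uniq.append(t)
        kept, removed = remove_contaminants(uniq, contaminants)
        strands = list(contaminants.values()) + [revcomp(c) for c in contaminants.values()]
        oracle_removed = {t.tag for t in uniq
                          if any(t.tag in c for c in strands)}
        assert {t.tag for t in removed} == oracle_removed
        assert {t.tag for t in kept} == {t.tag for t in uniq} - oracle_removed


class TestVariantNomenclature:
    def test_identity_match_has_no_suffix(self, rng):
        ref = random_tag(rng, 21)
        v = derive_variant(ref, "miR1", ref)
        assert v.render() == "miR1"

    def test_table_style_suffix(self):
        """Right extension by 1 plus G->A at reference position 15."""
        rng = np.random.default_rng(0)
        ref = random_tag(rng, 21)
        ref = ref[:14] + "G" + ref[15:]
        tag = ref[:14] + "A" + ref[15:] + "C"
        v = derive_variant(tag, "ptc-miR156a", ref)
        assert v.render() == "ptc-miR156a_R+1_1ss15GA"

    @pytest.mark.parametrize("name", [
        "miR1", "miR1_L+1", "miR1_R-2", "miR1_L-1_R+2",
        "miR1_1ss15GA", "miR1_L+2_R+1_2ss3CT19AG",
        "PC-5p-3760_2402_R+1_1ss4TC",
    ])
    def test_render_parse_identity(self, name):
        assert VariantName.parse(name).render() == name

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sampled_variant_round_trip(self, seed):
        """apply(name, reference) then re-derive -> the same name."""
        rng = np.random.default_rng(seed)
        ref = random_tag(rng, int(rng.integers(20, 23)))
        left = int(rng.integers(-2, 3))
        right = int(rng.integers(-2, 3))
        n_sub = int(rng.integers(0, 3))
        lo = 1 + max(0, -left)
        hi = len(ref) - max(0, -right)
        positions = rng.choice(np.arange(lo, hi + 1), size=n_sub, replace=False)
        subs = []
        for p in sorted(int(p) for p in positions):
            alt = rng.choice([b for b in BASES if b != ref[p - 1]])
            subs.append((p, ref[p - 1], str(alt)))
        v = VariantName("miR9000", left, right, subs)
        tag = v.apply(ref, left_ext=random_tag(rng, 2), right_ext=random_tag(rng, 2))
        got = derive_variant(tag, "miR9000", ref)
        assert got.render() == v.render()

    def test_apply_rejects_wrong_reference_base(self):
        with pytest.raises(ValueError, match="mismatch"):
            VariantName("m", 0, 0, [(1, "G", "A")]).apply("ATTTTTTTTTTTTTTTTTTTT")


class TestMatchKnown:
    def test_planted_matures_matched_exactly(self, small_study):
        libs = [[(s, c) for (_n, s, c) in lib] for lib in small_study.srna_libraries]
        catalog = filter_by_length(collapse_reads(libs))
        matches = match_known(catalog, small_study.mirnas)
        for mid, mature, _pre, _arm in small_study.manifest.planted_mirnas:
            m = matches[mature]
            assert m.variant is not None and m.is_exact
            assert m.variant.ref_id == mid

    def test_unmatched_tags_are_novel_candidates(self):
        catalog = [TagCount("A" * 21, [5])]
        matches = match_known(catalog, {"m1": "CGCGCGTATATACGCGTATAT"})
        assert matches["A" * 21].variant is None


class TestSummaries:
    def test_single_tag_histogram(self):
        hist = length_distribution([TagCount("A" * 21, [5])])
        assert hist.loc[21, "redundant"] == 5
        assert hist.loc[21, "unique"] == 1

    def test_histogram_conservation(self, rng):
        catalog = [TagCount(random_tag(rng, int(rng.integers(17, 26))),
                            [int(rng.integers(1, 9))]) for _ in range(100)]
        hist = length_distribution(catalog)
        assert hist["redundant"].sum() == sum(t.total for t in catalog)
        assert hist["unique"].sum() == len(catalog)

    @pytest.mark.parametrize("total,mean,tier", [
        (5, 100, "low"), (9, 5, "low"), (10, 100, "middle"),
        (50, 50, "middle"), (51, 50, "high"),
    ])
    def test_tier_rules(self, total, mean, tier):
        assert expression_tier(total, mean) == tier

    def test_tier_partition_matches_bruteforce(self, rng):
        totals = rng.integers(0, 200, size=500)
        mean = float(np.mean(totals))
        for t in totals:
            expected = "low" if t < 10 else ("high" if t > mean else "middle")
            assert expression_tier(int(t), mean) == expected
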