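"""Degradome target calling against independent brute-force oracles."""

import numpy as np
import pytest

from mirweave.degradome import (align_mirna, call_targets,
                                canonical_cleavage_position, classify_category,
                                map_degradome, tplot_data)
from mirweave.synthetic import revcomp

BASES = "ACGT"
WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def oracle_penalty(a, b):
    if (a, b) in WC:
        return 0.0
    if (a, b) in GU:
        return 0.5
    return 1.0


def oracle_mult(i):
    return 2.0 if 2 <= i <= 13 else 1.0


def oracle_align(mirna, transcript, max_score=4.0, max_gap=1):
    """Independent all-offset scorer: plain string walking, early abort."""
    L = len(mirna)
    found = []
    # ungapped: miRNA position i pairs transcript base s + L - i (0-based s)
    for s in range(len(transcript) - L + 1):
        score = 0.0
        for i in range(1, L + 1):
            score += oracle_penalty(mirna[i - 1], transcript[s + L - i]) * oracle_mult(i)
            if score > max_score:
                break
        if score <= max_score:
            found.append((s + 1, s + L, score))
    if max_gap >= 1:
        # one bulged transcript base between miRNA positions g and g+1
        for s in range(len(transcript) - L):
            window = transcript[s:s + L + 1][::-1]
            for g in range(1, L):
                score = 2.0 * oracle_mult(g + 1)
                for i in range(1, L + 1):
                    tb = window[i - 1] if i <= g else window[i]
                    score += oracle_penalty(mirna[i - 1], tb) * oracle_mult(i)
                    if score > max_score:
                        break
                if score <= max_score:
                    found.append((s + 1, s + L + 1, score))
        # one bulged (unpaired) miRNA base at position g
        for s in range(len(transcript) - L + 2):
            window = transcript[s:s + L - 1][::-1]
            for g in range(2, L):
                score = 2.0 * oracle_mult(g)
                for i in range(1, L + 1):
                    if i == g:
                        continue
                    tb = window[i - 1] if i < g else window[i - 2]
                    score += oracle_penalty(mirna[i - 1], tb) * oracle_mult(i)
                    if score > max_score:
                        break
                if score <= max_score:
                    found.append((s + 1, s + L - 1, score))
    return sorted(found)


def rand_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestAlign:
    def test_perfect_duplex_scores_zero(self, rng):
        m = rand_seq(rng, 21)
        t = rand_seq(rng, 100) + revcomp(m) + rand_seq(rng, 100)
        sites = align_mirna(m, t, max_score=0.0, max_gap=0)
        assert [(s.t_start, s.t_end, s.score) for s in sites] == [(101, 121, 0.0)]

    def test_gu_wobble_outside_seed_scores_half(self, rng):
        m = rand_seq(rng, 21)
        m = m[:14] + "G" + m[15:]          # position 15 = G
        site = list(revcomp(m))
        # the transcript base paired to miRNA position 15 is site index L-15
        site[21 - 15] = "T"                # G:U wobble
        t = rand_seq(rng, 50) + "".join(site) + rand_seq(rng, 50)
        sites = align_mirna(m, t, max_score=1.0, max_gap=0)
        assert min(s.score for s in sites) == 0.5

    def test_seed_mismatch_scores_double(self, rng):
        m = rand_seq(rng, 21)
        m = m[:4] + "A" + m[5:]            # position 5 = A
        site = list(revcomp(m))
        site[21 - 5] = "C"                 # A:C mismatch inside positions 2-13
        t = rand_seq(rng, 50) + "".join(site) + rand_seq(rng, 50)
        sites = align_mirna(m, t, max_score=2.0, max_gap=0)
        assert min(s.score for s in sites) == 2.0

    def test_short_transcript_gives_no_sites(self):
        assert align_mirna("ACGT" * 5 + "A", "ACGTACG") == []

    def test_added_mismatch_never_decreases_score(self, rng):
        m = rand_seq(rng, 21)
        perfect = revcomp(m)
        base = align_mirna(m, perfect, max_score=99, max_gap=0)[0].score
        for pos in (1, 8, 20):
            mutated = list(perfect)
            mutated[pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[mutated[pos]]
            worse = align_mirna(m, "".join(mutated), max_score=99, max_gap=0)
            assert min(s.score for s in worse) >= base

    @pytest.mark.parametrize("max_gap", [0, 1])
    def test_matches_bruteforce_oracle(self, rng, max_gap):
        """Vectorised scorer equals the plain all-offsets oracle."""
        for _ in range(25):
            m = rand_seq(rng, int(rng.integers(19, 23)))
            t = rand_seq(rng, int(rng.integers(60, 260)))
            if rng.random() < 0.5:  # plant a near-complementary site
                ins = list(revcomp(m))
                for _k in range(int(rng.integers(0, 4))):
                    j = int(rng.integers(len(ins)))
                    ins[j] = str(rng.choice(list(BASES)))
                p = int(rng.integers(0, len(t) - len(ins)))
                t = t[:p] + "".join(ins) + t[p + len(ins):]
            got = sorted((s.t_start, s.t_end, s.score)
                         for s in align_mirna(m, t, 4.0, max_gap))
            assert got == oracle_align(m, t, 4.0, max_gap)


class TestCanonicalSite:
    def test_rule_arithmetic(self, rng):
        m = rand_seq(rng, 21)
        t = rand_seq(rng, 1579) + revcomp(m) + rand_seq(rng, 30)
        site = align_mirna(m, t, 0.0, 0)[0]
        assert site.t_end == 1600          # miRNA position 1 pairs here
        assert canonical_cleavage_position(site) == 1591

    def test_independent_of_mirna_length_when_gap_free(self, rng):
        for L in (19, 21, 24):
            m = rand_seq(rng, L)
            t = rand_seq(rng, 100) + revcomp(m) + rand_seq(rng, 100)
            site = align_mirna(m, t, 0.0, 0)[0]
            assert canonical_cleavage_position(site) == site.t_end - 9

    def test_planted_interactions_recover_manifest_site(self, small_study):
        for mid, tid, pos, _peak in small_study.manifest.planted_interactions:
            sites = align_mirna(small_study.mirnas[mid],
                                small_study.transcripts[tid], 0.0, 0)
            assert canonical_cleavage_position(sites[0]) == pos


class TestProfiles:
    def test_single_tag_profile(self):
        t = {"t1": "C" * 100 + "ACGTACGTACGTACGTACGT" + "C" * 100}
        profiles = map_degradome([("ACGTACGTACGTACGTACGT", 5)], t)
        assert profiles["t1"][101] == 5

    def test_no_match_no_profile(self):
        profiles = map_degradome([("A" * 20, 3)], {"t1": "CG" * 100})
        assert profiles == {}

    def test_multimapping_counts_everywhere(self):
        block = "ACGTTGCAACGGATCGATCA"
        t = {"t1": block + "C" * 50 + block}
        profiles = map_degradome([(block, 2)], t)
        assert profiles["t1"] == {1: 2, 71: 2}


class TestCategories:
    @pytest.mark.parametrize("profile,pos,expected", [
        ({100: 1}, 100, 4),
        ({100: 7, 200: 3}, 100, 0),
        ({100: 7, 200: 7, 300: 2}, 100, 1),
        ({100: 5, 200: 9, 300: 2, 400: 2}, 100, 2),
        ({100: 2, 200: 9, 300: 5, 400: 5}, 100, 3),
    ])
    def test_rule_examples(self, profile, pos, expected):
        assert classify_category(profile[pos], profile) == expected

    def test_absent_site_rejected(self):
        with pytest.raises(ValueError):
            classify_category(9, {100: 1})

    def test_all_mode_median_includes_zeros(self):
        profile = {1: 2, 2: 9}
        # nonzero median 5.5 -> category 3; over 200 positions median 0 -> 2
        assert classify_category(2, profile, "nonzero") == 3
        assert classify_category(2, profile, "all", transcript_length=200) == 2

    def test_oracle_equivalence_on_random_profiles(self, rng):
        """Classifier agrees with a rule-by-rule oracle case by case."""
        from statistics import median
        for _ in range(2000):
            n = int(rng.integers(1, 12))
            positions = rng.choice(np.arange(1, 51), size=n, replace=False)
            profile = {int(p): int(rng.integers(1, 21)) for p in positions}
            pos = int(rng.choice(list(profile)))
            c = profile[pos]
            if c == 1:
                expected = 4
            elif c == max(profile.values()):
                expected = 0 if list(profile.values()).count(c) == 1 else 1
            elif c > median(profile.values()):
                expected = 2
            else:
                expected = 3
            assert classify_category(c, profile) == expected


class TestCallTargets:
    def test_planted_hits_category_zero_and_no_decoys(self, small_study):
        tags = [(s, c) for _i, s, c, _t, _p in small_study.degradome]
        profiles = map_degradome(tags, small_study.transcripts)
        hits = call_targets(small_study.mirnas, small_study.transcripts, profiles)
        planted = {(m, t, p) for m, t, p, _c in small_study.manifest.planted_interactions}
        got = {(h.small_rna, h.target, h.cleavage_site) for h in hits.itertuples()}
        assert planted <= got
        assert not any(h.target.startswith("DCY") for h in hits.itertuples())
        cat0 = hits.set_index(["small_rna", "target"])["category"]
        planted_cats = [cat0.get((m, t)) for m, t, _p, _c in
                        small_study.manifest.planted_interactions]
        assert all(c == 0 for c in planted_cats)

    def test_tplot_flags_exactly_one_row(self):
        profile = {5: 3, 10: 9, 20: 1}
        tp = tplot_data(10, profile)
        assert tp["is_cleavage_site"].sum() == 1
        assert int(tp.loc[tp["is_cleavage_site"], "count"].iloc[0]) == 9
        assert list(tp["position"]) == sorted(profile)

    def test_empty_profile_empty_tplot(self):
        assert tplot_data(10, {}).empty
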