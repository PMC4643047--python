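"""Locus classification: completeness rule, LTR pairing, screens."""

import numpy as np
import pytest

from ervfossil import (Interval, RepeatHit, SearchHit, ShortCandidateError,
                       assign_family, copy_number, filter_cst_hits,
                       is_complete_solo_ltr, pair_ltrs)
from ervfossil.annotate import ErvLocus, merge_fragmented_hits


def ltr_hit(contig="c1", start=0, length=600, strand="+",
            cons_start=1, cons_len=600, family="LTR1", score=2000.0):
    cons_end = min(cons_start + length - 1, cons_len)
    return RepeatHit(score, Interval(contig, start, start + length, strand),
                     family, cons_start, cons_end, cons_len - cons_end)


class TestCompletenessRule:
    def test_full_length_hit_is_complete(self):
        h = ltr_hit(cons_start=1, length=600)
        assert is_complete_solo_ltr(h, 600)

    def test_missing_exactly_150_at_5p_fails(self):
        # "missing less than 150 bp" is strict: cons_start 151 = 150 lost
        h = ltr_hit(cons_start=151, length=450)
        assert not is_complete_solo_ltr(h, 600)

    def test_missing_149_at_5p_passes(self):
        h = ltr_hit(cons_start=150, length=451)
        assert is_complete_solo_ltr(h, 600)

    def test_missing_9_at_3p_passes(self):
        h = ltr_hit(cons_start=1, length=591)  # cons_end = 591 of 600
        assert is_complete_solo_ltr(h, 600)

    def test_missing_10_at_3p_fails(self):
        h = ltr_hit(cons_start=1, length=590)
        assert not is_complete_solo_ltr(h, 600)

    def test_inconsistent_consensus_length_raises(self):
        h = ltr_hit(cons_start=1, length=600)
        with pytest.raises(ValueError):
            is_complete_solo_ltr(h, 500)


def _max_pairing_oracle(hits):
    """Exhaustive maximum-provirus matching by recursion (<= 8 hits)."""
    from ervfossil.annotate import _eligible_gap

    n = len(hits)

    def best(avail):
        avail = [i for i in avail]
        if not avail:
            return 0
        first, rest = avail[0], avail[1:]
        top = best(rest)  # leave `first` unpaired
        for j in rest:
            if _eligible_gap(hits[first], hits[j]) is not None:
                top = max(top, 1 + best([k for k in rest if k != j]))
        return top

    return best(list(range(n)))


class TestPairLtrs:
    def test_pair_at_five_kb(self):
        hits = [ltr_hit(start=0), ltr_hit(start=5600)]
        loci = pair_ltrs(hits)
        assert [l.kind for l in loci] == ["provirus"]
        assert loci[0].internal_gap_bp == 5000
        assert loci[0].extent == Interval("c1", 0, 6200)

    def test_gap_bounds_inclusive(self):
        for gap, expect in [(2999, 0), (3000, 1), (10000, 1), (10001, 0)]:
            hits = [ltr_hit(start=0), ltr_hit(start=600 + gap)]
            loci = pair_ltrs(hits)
            assert sum(l.kind == "provirus" for l in loci) == expect, gap

    def test_two_kb_apart_yields_solos_not_provirus(self):
        hits = [ltr_hit(start=0), ltr_hit(start=2600)]
        loci = pair_ltrs(hits)
        assert sum(l.kind == "provirus" for l in loci) == 0
        assert sum(l.kind == "solo_ltr" for l in loci) == 2

    def test_opposite_strands_never_pair(self):
        hits = [ltr_hit(start=0, strand="+"), ltr_hit(start=5600,
                                                      strand="-")]
        assert all(l.kind == "solo_ltr" for l in pair_ltrs(hits))

    def test_different_contigs_never_pair(self):
        hits = [ltr_hit(contig="c1", start=0), ltr_hit(contig="c2",
                                                       start=5600)]
        assert all(l.kind == "solo_ltr" for l in pair_ltrs(hits))

    def test_chain_of_three_gives_one_provirus_one_solo(self):
        hits = [ltr_hit(start=0), ltr_hit(start=5600),
                ltr_hit(start=11200)]
        loci = pair_ltrs(hits)
        kinds = sorted(l.kind for l in loci)
        assert kinds == ["provirus", "solo_ltr"]
        # tie-break towards the smaller total gap = leftmost-first pair
        pro = next(l for l in loci if l.kind == "provirus")
        assert pro.extent.start == 0

    def test_incomplete_unpaired_hits_are_dropped(self):
        hits = [ltr_hit(start=0, cons_start=200, length=401)]
        assert pair_ltrs(hits) == []

    def test_matching_equals_exhaustive_oracle_on_random_instances(self,
                                                                   rng):
        for _ in range(300):
            n = int(rng.integers(0, 9))
            hits = []
            for _ in range(n):
                start = int(rng.integers(0, 40000))
                strand = "+" if rng.random() < 0.8 else "-"
                hits.append(ltr_hit(start=start, strand=strand,
                                    length=int(rng.integers(500, 700))))
            got = sum(l.kind == "provirus"
                      for l in pair_ltrs(hits, merge_fragments=False))
            assert got == _max_pairing_oracle(hits)

    def test_fragmented_ltr_hits_merge_then_pair(self):
        # one LTR split into two consecutive rows by the annotator
        frag_a = RepeatHit(900.0, Interval("c1", 0, 300), "LTR1",
                           1, 300, 300)
        frag_b = RepeatHit(900.0, Interval("c1", 300, 600), "LTR1",
                           301, 600, 0)
        other = ltr_hit(start=5600)
        loci = pair_ltrs([frag_a, frag_b, other])
        assert [l.kind for l in loci] == ["provirus"]

    def test_merge_overlapping_duplicate_rows(self):
        a = ltr_hit(start=0, length=600)
        b = ltr_hit(start=100, length=500, cons_start=101)
        merged = merge_fragmented_hits([a, b])
        assert len(merged) == 1
        assert merged[0].genome_iv == Interval("c1", 0, 600)


class TestFilterCstHits:
    def _hit(self, ident, length):
        return SearchHit("q", Interval("s", 0, length), ident, length,
                         1e-90)

    def test_strong_full_length_hit_retained(self):
        assert filter_cst_hits([self._hit(0.85, 642)], 642)

    def test_half_length_hit_removed(self):
        assert filter_cst_hits([self._hit(0.85, 321)], 642) == []

    def test_low_identity_hit_removed(self):
        assert filter_cst_hits([self._hit(0.79, 642)], 642) == []

    def test_thresholds_inclusive(self):
        hits = [self._hit(0.80, 514)]  # 514 > 0.8 * 642
        assert filter_cst_hits(hits, 642) == hits

    def test_empty_input(self):
        assert filter_cst_hits([], 100) == []

    def test_tightening_thresholds_is_monotone(self, rng):
        hits = [self._hit(float(rng.uniform(0.5, 1.0)),
                          int(rng.integers(50, 642)))
                for _ in range(100)]
        base = set(id(h) for h in filter_cst_hits(hits, 642))
        for ident, frac in [(0.9, 0.8), (0.8, 0.9), (0.95, 0.95)]:
            tighter = set(id(h) for h in
                          filter_cst_hits(hits, 642, ident, frac))
            assert tighter <= base


class TestAssignFamily:
    def test_identical_member(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert assign_family(seq, [seq])

    def test_every_third_base_substituted_rejected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = "".join(rot[c] if i % 3 == 0 else c
                          for i, c in enumerate(seq))
        assert not assign_family(mutated, [seq])

    def test_exactly_eighty_percent_is_inclusive(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated = "".join(rot[c] if i % 5 == 0 else c
                          for i, c in enumerate(seq))  # 60/300 changed
        assert assign_family(mutated, [seq])

    def test_truncated_copy_not_penalised(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        assert assign_family(seq[100:], [seq])

    def test_short_candidate_raises_distinct_signal(self):
        with pytest.raises(ShortCandidateError):
            assign_family("ACGT" * 10, ["ACGT" * 100])

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            assign_family("ACGT" * 30, [])


class TestCopyNumber:
    def _loci(self, n_pro, n_solo, family="fam"):
        out = []
        pos = 0
        for _ in range(n_pro):
            iv5 = Interval("c1", pos, pos + 600)
            iv3 = Interval("c1", pos + 5600, pos + 6200)
            out.append(ErvLocus(f"p{pos}", "provirus",
                                Interval("c1", pos, pos + 6200), family,
                                ltr5=iv5, ltr3=iv3, internal_gap_bp=5000))
            pos += 20000
        for _ in range(n_solo):
            iv = Interval("c1", pos, pos + 600)
            out.append(ErvLocus(f"s{pos}", "solo_ltr", iv, family,
                                ltr5=iv))
            pos += 20000
        return out

    @pytest.mark.parametrize("n_pro,n_solo", [(2, 27), (204, 1638)])
    def test_total_is_sum(self, n_pro, n_solo):
        # mirrors the pangolin (2 + 27 = 29) and M. lucifugus
        # (204 + 1638 = 1842) copy-number arithmetic
        table = copy_number(self._loci(n_pro, n_solo), "sp")
        row = table.iloc[0]
        assert row.proviruses == n_pro
        assert row.solo_ltrs == n_solo
        assert row.total == n_pro + n_solo

    def test_empty_input_gives_empty_table(self):
        assert copy_number([], "sp").empty
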