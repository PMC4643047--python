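"""Nei-Gojobori counting, the neutrality bootstrap, integrity stats."""

import math

import numpy as np
import pytest

from ervfossil import (InsufficientDataError, codon_path_diffs,
                       codon_sites, integrity, ng_dnds,
                       omega_neutrality_test, poisson_ci,
                       shared_breakpoints)
from ervfossil.simulate import (simulate_codon_alignment,
                                simulate_env_deletion_family,
                                simulate_integrity_family)

# independent statement of the standard genetic code for the oracle
_CODE = {}
_BASES = "TCAG"
_AA_TABLE = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
             "VVVVAAAADDEEGGGG")
for _i, _aa in enumerate(_AA_TABLE):
    codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODE[codon] = _aa
_ORACLE_STOPS = {c for c, a in _CODE.items() if a == "*"}
_ORACLE_SENSE = sorted(c for c, a in _CODE.items() if a != "*")


def _site_oracle(codon):
    """Enumerate all 9 single-base neighbours; stop targets excluded."""
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _ORACLE_STOPS:
                continue
            if _CODE[alt] == _CODE[codon]:
                syn += 1
            else:
                non += 1
        if syn + non:
            s += syn / (syn + non)
            n += non / (syn + non)
    return s, n


class TestSiteCounts:
    def test_all_61_sense_codons_match_enumeration_oracle(self):
        assert len(_ORACLE_SENSE) == 61
        for codon in _ORACLE_SENSE:
            s, n = codon_sites(codon)
            es, en = _site_oracle(codon)
            assert s == pytest.approx(es, abs=1e-12), codon
            assert n == pytest.approx(en, abs=1e-12), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")


class TestPathDiffs:
    def test_synonymous_single_step(self):
        assert codon_path_diffs("AAA", "AAG") == (1.0, 0.0)  # Lys->Lys

    def test_nonsynonymous_single_step(self):
        assert codon_path_diffs("TTT", "TTA") == (0.0, 1.0)  # Phe->Leu

    def test_identical_codons(self):
        assert codon_path_diffs("ATG", "ATG") == (0.0, 0.0)

    def test_two_step_path_averages_orders(self):
        # TTT -> TTA -> CTA and TTT -> CTT -> CTA; both avoid stops
        sd, nd = codon_path_diffs("TTT", "CTA")
        assert sd + nd == pytest.approx(2.0)

    def test_paths_through_stops_are_excluded(self):
        # TAT <-> TGA-adjacent neighbourhoods: check against brute force
        for ca in ("TAT", "TCA", "TGT"):
            for cb in ("TGC", "AGA", "TTA"):
                got = codon_path_diffs(ca, cb)
                exp = _path_oracle(ca, cb)
                assert got == exp or (
                    got is not None and exp is not None
                    and got == pytest.approx(exp, abs=1e-12))


def _path_oracle(ca, cb):
    from itertools import permutations
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    res = []
    for order in permutations(pos):
        cur, sd, nd, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if nxt in _ORACLE_STOPS:
                ok = False
                break
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            res.append((sd, nd))
    if not res:
        return None
    return (sum(r[0] for r in res) / len(res),
            sum(r[1] for r in res) / len(res))


class TestNgDnds:
    def _pad(self, core_a, core_b, n=40):
        pad = "GGC" * n  # Gly: 4-fold degenerate third position
        return [core_a + pad, core_b + pad]

    def test_identical_sequences_undefined_omega(self):
        aln = ["ATGGCT" * 30] * 3
        res = ng_dnds(aln)
        assert res.dN == res.dS == 0.0
        assert res.omega is None and res.p_value is None
        assert res.verdict == "undefined"

    def test_synonymous_only_difference(self):
        res = ng_dnds(self._pad("AAA", "AAG"))
        assert res.dN == 0.0 and res.dS > 0.0
        assert res.omega == 0.0

    def test_nonsynonymous_only_difference_undefined(self):
        res = ng_dnds(self._pad("TTT", "TTA"))
        assert res.dS == 0.0 and res.dN > 0.0
        assert res.omega is None  # dS = 0

    def test_fewer_than_30_codons_refused(self):
        with pytest.raises(InsufficientDataError):
            ng_dnds(["ATGGCTAAA", "ATGGCGAAA"])

    def test_single_sequence_refused(self):
        with pytest.raises(InsufficientDataError):
            ng_dnds(["ATG" * 40])

    @pytest.mark.parametrize("omega_true", [0.2, 0.5, 1.0])
    def test_omega_recovery_within_tenth(self, omega_true):
        rng = np.random.default_rng(int(omega_true * 100))
        ests = [ng_dnds(simulate_codon_alignment(rng, omega=omega_true),
                        replicates=50, seed=i).omega
                for i in range(12)]
        assert np.mean(ests) == pytest.approx(omega_true, abs=0.1)


class TestNeutralityTest:
    def test_undefined_for_identical_pair(self):
        assert omega_neutrality_test(["ATG" * 40] * 2) is None

    def test_deterministic_given_seed(self, rng):
        aln = simulate_codon_alignment(rng, n_seqs=6, n_codons=120)
        assert omega_neutrality_test(aln, seed=3) == \
            omega_neutrality_test(aln, seed=3)

    def test_power_against_strong_purifying_selection(self):
        rng = np.random.default_rng(5)
        rejected = 0
        for i in range(20):
            aln = simulate_codon_alignment(rng, omega=0.2)
            p = omega_neutrality_test(aln, seed=i)
            rejected += p is not None and p < 0.05
        assert rejected >= 18

    def test_roughly_calibrated_under_neutrality(self):
        rng = np.random.default_rng(6)
        rejected = 0
        n = 60
        for i in range(n):
            aln = simulate_codon_alignment(rng, omega=1.0)
            p = omega_neutrality_test(aln, seed=i)
            rejected += p is not None and p < 0.05
        assert rejected / n <= 0.15


class TestPoissonCi:
    def test_zero_events_upper_bound_closed_form(self):
        lo, hi = poisson_ci(0, 1000)
        assert lo == 0.0
        assert hi == pytest.approx(-math.log(0.025) / 1000, rel=1e-6)
        assert hi * 1000 == pytest.approx(3.68888, abs=1e-5)

    def test_five_events_in_500_codons(self):
        lo, hi = poisson_ci(5, 500)
        assert lo == pytest.approx(1.623 / 500, abs=2e-6)
        assert hi == pytest.approx(11.668 / 500, abs=2e-6)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            k = int(rng.integers(0, 50))
            n = int(rng.integers(10, 2000))
            lo, hi = poisson_ci(k, n)
            assert lo <= k / n <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_ci(-1, 10)
        with pytest.raises(ValueError):
            poisson_ci(1, 0)


class TestIntegrity:
    def test_intact_copies_have_zero_events(self, rng):
        rows, ref, _, _ = simulate_integrity_family(rng, n_stops=0,
                                                    n_frameshifts=0)
        st = integrity(rows, ref)
        assert st.n_stops == st.n_frameshifts == 0
        assert st.freq == 0.0
        assert st.ci95[0] == 0.0

    def test_planted_events_counted_exactly(self, rng):
        rows, ref, stops, fss = simulate_integrity_family(
            rng, n_stops=7, n_frameshifts=5)
        st = integrity(rows, ref)
        assert st.n_stops == stops == 7
        assert st.n_frameshifts == fss == 5
        assert st.freq == pytest.approx(12 / st.n_codons)
        assert st.ci95[0] <= st.freq <= st.ci95[1]

    def test_one_indel_run_is_one_event_regardless_of_length(self):
        ref = "ATGGCTAAA" * 20
        row = ref[:30] + "-" * 4 + ref[34:]  # one 4-bp deletion run
        st = integrity([row], ref)
        assert st.n_frameshifts == 1

    def test_in_frame_indel_is_not_a_frameshift(self):
        ref = "ATGGCTAAA" * 20
        row = ref[:30] + "-" * 6 + ref[36:]
        st = integrity([row], ref)
        assert st.n_frameshifts == 0

    def test_natural_terminator_exempt(self):
        ref = "ATGGCT" * 20 + "TAA"
        row = ref
        assert integrity([row], ref, domain_ends_orf=True).n_stops == 0
        assert integrity([row], ref, domain_ends_orf=False).n_stops == 1

    def test_undeterminable_frame_is_an_error(self):
        with pytest.raises(ValueError, match="frame"):
            integrity(["ATGG"], "ATGG")


class TestSharedBreakpoints:
    def test_29_of_43_share_one_envelope_deletion(self, rng):
        rows, ref = simulate_env_deletion_family(rng)
        clusters = shared_breakpoints(rows, ref)
        assert len(clusters) == 1
        assert clusters[0].n_sharing == 29

    def test_all_full_length_yields_nothing(self, rng):
        rows, ref = simulate_env_deletion_family(rng, n_deleted=0)
        assert shared_breakpoints(rows, ref) == []

    def test_two_deletion_lineages_give_two_clusters(self, rng):
        rows, ref = simulate_env_deletion_family(
            rng, n_members=20, n_deleted=8,
            second_breakpoint=(600, 1100, 6))
        clusters = shared_breakpoints(rows, ref)
        assert sorted(c.n_sharing for c in clusters) == [6, 8]

    def test_small_deletions_ignored(self):
        ref = "ACGT" * 100
        row = ref[:100] + "-" * 50 + ref[150:]
        assert shared_breakpoints([row, row], ref) == []

    def test_breakpoint_jitter_within_tolerance_clusters(self):
        ref = "ACGT" * 200
        a = ref[:100] + "-" * 200 + ref[300:]
        b = ref[:108] + "-" * 200 + ref[308:]
        (cluster,) = shared_breakpoints([a, b], ref)
        assert cluster.n_sharing == 2
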