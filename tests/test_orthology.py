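"""Flank probes, hit pairing, state calls and Dollo branch assignment."""

import dendropy
import numpy as np
import pytest

from ervfossil import (Interval, GenomeIndex, call_orthology,
                       call_state, make_probes, orthology_matrix,
                       pair_flank_hits, reverse_complement)
from ervfossil.annotate import ErvLocus
from ervfossil.orthology import (FlankHit, STATE_ABSENT, STATE_PROVIRUS,
                                 STATE_SOLO, STATE_UNRESOLVED)
from ervfossil.simulate import InsertionEvent, SimConfig, simulate


def _provirus(contig="c1", start=1000, end=8000, strand="+",
              ltr_len=600):
    return ErvLocus(
        "P1", "provirus", Interval(contig, start, end, strand), "fam",
        ltr5=Interval(contig, start, start + ltr_len, strand),
        ltr3=Interval(contig, end - ltr_len, end, strand),
        internal_gap_bp=end - start - 2 * ltr_len)


class TestMakeProbes:
    def test_plus_strand_coordinates(self, tiny_genome):
        seq = tiny_genome[0].sequence
        p5, p3 = make_probes(_provirus(), tiny_genome)
        assert p5.probe_seq == seq[800:1200]
        assert p5.junction_offset == 200
        assert p3.probe_seq == seq[7800:8200]
        assert p3.junction_offset == 200

    def test_truncated_probe_near_contig_start(self, tiny_genome, caplog):
        import logging
        seq = tiny_genome[0].sequence
        locus = _provirus(start=50, end=7050)
        with caplog.at_level(logging.WARNING):
            p5, _ = make_probes(locus, tiny_genome)
        assert p5.probe_seq == seq[0:250]
        assert p5.junction_offset == 50
        assert any("truncated" in r.message for r in caplog.records)

    def test_locus_at_contig_edge_is_unresolvable(self, tiny_genome):
        locus = _provirus(start=5, end=7005)
        p5, p3 = make_probes(locus, tiny_genome)
        assert p5 is None and p3 is not None

    def test_minus_strand_probes_in_element_orientation(self, tiny_genome):
        seq = tiny_genome[0].sequence
        p5, p3 = make_probes(_provirus(strand="-"), tiny_genome)
        # element 5' end is the genomic right end, reverse-complemented
        assert p5.probe_seq == reverse_complement(seq[7800:8200])
        assert p5.junction_offset == 200
        assert p3.probe_seq == reverse_complement(seq[800:1200])
        assert p3.junction_offset == 200


def _hit(side, t_start, t_end, contig="t1", strand="+", score=380.0,
         flank=190, q_start=0, q_end=400):
    return FlankHit("P1", side, contig, strand, t_start, t_end,
                    q_start, q_end, score, int(score / 2) * 2,
                    flank, 0.95)


class TestPairFlankHits:
    def test_pair_six_kb_apart(self):
        pair = pair_flank_hits([_hit("5p", 1000, 1400)],
                               [_hit("3p", 7000, 7400)])
        assert len(pair) == 1

    def test_hits_on_different_contigs_do_not_pair(self):
        assert pair_flank_hits([_hit("5p", 1000, 1400, contig="t1")],
                               [_hit("3p", 7000, 7400, contig="t2")]) == []

    def test_span_cap(self):
        assert pair_flank_hits([_hit("5p", 0, 400)],
                               [_hit("3p", 30000, 30400)]) == []

    def test_best_pair_by_flank_matches_then_score(self):
        good = _hit("5p", 1000, 1400, flank=190)
        weak = _hit("5p", 50000, 50400, flank=120)
        h3a = _hit("3p", 7000, 7400, flank=185)
        h3b = _hit("3p", 56000, 56400, flank=186)
        (chosen,) = pair_flank_hits([good, weak], [h3a, h3b])
        assert chosen[0] is good and chosen[1] is h3a

    def test_element_only_pairs_rejected_as_uninformative(self):
        # both hits match only the element halves of the probes
        pair = pair_flank_hits([_hit("5p", 1000, 1200, flank=3)],
                               [_hit("3p", 9000, 9200, flank=2)])
        assert pair == []


class TestCallState:
    def _target(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30000))
        return {"t1": seq}

    def test_no_pair_is_unresolved(self):
        call = call_state(None, _provirus(), 600)
        assert call.state == STATE_UNRESOLVED

    def test_full_element_gap_is_present_provirus(self, rng):
        pair = (_hit("5p", 800, 1200, q_end=400),
                _hit("3p", 8000, 8400, q_start=0))
        # junctions at 1200 and 8000 -> gap 7000 = donor extent length
        call = call_state(pair, _provirus(), 600, self._target(rng))
        assert call.state == STATE_PROVIRUS

    def test_ltr_sized_gap_is_present_solo(self, rng):
        pair = (_hit("5p", 800, 1200), _hit("3p", 1400, 1800))
        # junctions at 1000 and 1600 -> gap 600 = ltr_len
        call = call_state(pair, _provirus(), 600, self._target(rng))
        assert call.state == STATE_SOLO

    def test_contiguous_flanks_are_absent_with_tsd(self, rng):
        target = self._target(rng)
        # element halves unaligned: both hits are flank-only
        h5 = _hit("5p", 1000, 1200, q_start=0, q_end=200)
        h3 = _hit("3p", 1196, 1396, q_start=200, q_end=400)
        # j5 = 1200, j3 = 1196: flanks overlap by the 4 bp TSD
        call = call_state((h5, h3), _provirus(), 600, target)
        assert call.state == STATE_ABSENT
        assert call.gap == -4
        assert call.tsd_seq == target["t1"][1196:1200]

    def test_intermediate_gap_is_unresolved(self, rng):
        pair = (_hit("5p", 800, 1200), _hit("3p", 2600, 3000))
        call = call_state(pair, _provirus(), 600, self._target(rng))
        assert call.state == STATE_UNRESOLVED

    def test_solo_donor_with_provirus_sized_gap_not_misread(self, rng):
        # for a solo donor the provirus threshold uses the minimum
        # provirus length, not the solo extent
        iv = Interval("c1", 1000, 1600)
        solo = ErvLocus("S", "solo_ltr", iv, "fam", ltr5=iv)
        pair = (_hit("5p", 800, 1200), _hit("3p", 1400, 1800))
        call = call_state(pair, solo, 600, self._target(rng))
        assert call.state == STATE_SOLO


class TestEndToEndRecovery:
    @pytest.fixture(scope="class")
    def sim(self):
        events = tuple(
            [InsertionEvent(12e6, "infection", "ancestral")] * 4
            + [InsertionEvent(3e6, "retrotransposition", "A")] * 4
            + [InsertionEvent(3e6, "retrotransposition", "B")] * 4)
        cfg = SimConfig(seed=11, genome_len=300_000,
                        split_time_years=10e6, insertion_events=events,
                        solo_fraction=0.25)
        return simulate(cfg)

    def test_states_match_planted_truth(self, sim):
        index = GenomeIndex(sim.genome_b)
        truth = sim.truth.set_index("locus_id")
        for locus in sim.loci_a:
            lid = locus.locus_id.rsplit("_", 1)[0]
            row = truth.loc[lid]
            call = call_orthology(locus, sim.genome_a, index,
                                  sim.config.ltr_len, "B")
            if row.present_b:
                expect = STATE_PROVIRUS if row.kind == "provirus" \
                    else STATE_SOLO
            else:
                expect = STATE_ABSENT
            assert call.state == expect, lid

    def test_absent_sites_contiguous_with_recoverable_tsd(self, sim):
        index = GenomeIndex(sim.genome_b)
        truth = sim.truth.set_index("locus_id")
        seen = 0
        for locus in sim.loci_a:
            lid = locus.locus_id.rsplit("_", 1)[0]
            row = truth.loc[lid]
            if row.present_b:
                continue
            call = call_orthology(locus, sim.genome_a, index,
                                  sim.config.ltr_len, "B")
            assert call.state == STATE_ABSENT
            assert call.gap is not None and call.gap <= 25
            site = sim.genome_b[0].sequence[int(row.start_b):
                                            int(row.end_b)]
            assert call.tsd_seq == site and len(site) == 4
            seen += 1
        assert seen >= 3


class TestOrthologyMatrix:
    @pytest.fixture
    def tree(self):
        return dendropy.Tree.get(
            data="((cat,tiger),(dog,(ferret,panda)));",
            schema="newick")

    def test_shared_felid_insertion_on_ancestral_branch(self, tree):
        presence = {"L1": {"cat": "present", "tiger": "present_provirus",
                           "dog": "absent_empty", "ferret": "absent"}}
        counts, conflicts = orthology_matrix(presence, tree)
        assert counts == {("cat", "tiger"): 1}
        assert conflicts == []

    def test_species_specific_insertion_on_terminal_branch(self, tree):
        presence = {"L1": {"cat": "present_solo"}}
        counts, _ = orthology_matrix(presence, tree)
        assert counts == {("cat",): 1}

    def test_pattern_requiring_loss_is_flagged_not_assigned(self, tree):
        presence = {"L1": {"dog": "present_provirus",
                           "panda": "present_provirus",
                           "ferret": "absent_empty"}}
        counts, conflicts = orthology_matrix(presence, tree)
        assert counts == {}
        assert conflicts == ["L1"]

    def test_single_species_input_degenerates_to_terminal(self, tree):
        presence = {f"L{i}": {"cat": "present_solo"} for i in range(5)}
        counts, _ = orthology_matrix(presence, tree)
        assert counts == {("cat",): 5}
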