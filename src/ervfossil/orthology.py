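"""Cross-species orthology of ERV insertions.

The chance that the same retrovirus integrates twice at the same host
position is negligible, so an element found at the orthologous position
in two species predates their split, while a single-copy "empty" site
(pre-integration allele) in one species means the insertion postdates it.
For each donor locus this module extracts two probes - 200 bp of element
terminus plus 200 bp of host flank across each junction - searches them
against the target genome, pairs the best 5'/3' hits, and reads the
orthology state off the distance between the element-side junctions:

* gap comparable to the full element  -> provirus present;
* gap comparable to one LTR           -> solo LTR present (the provirus
  was deleted by inter-LTR recombination after the split);
* flanks contiguous (within 25 bp)    -> empty pre-insertion site, with
  the single copy of the 4-bp target-site duplication recoverable.

The search backend is pluggable behind the hit contract: the built-in
seed-and-extend aligner (exact 16-mer seeds, local Smith-Waterman
extension) suffices at desk scale, and externally produced BLAST tabular
hits can be converted with :func:`flank_hit_from_search_hit`.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from . import _align
from .core_io import (GenomeSeq, Interval, SearchHit, genome_dict,
                      reverse_complement)
from .annotate import ErvLocus, MIN_INTERNAL_BP

log = logging.getLogger(__name__)

PROBE_FLANK = 200  # bp of host flank per probe
PROBE_ELEMENT = 200  # bp of element terminus per probe
MIN_FLANK = 20  # below this the side is unresolvable
MAX_PAIR_SPAN = 20000  # bp between paired junctions in the target
EMPTY_SITE_MAX_GAP = 25  # flank contiguity bound for an empty site
SEED_K = 16

STATE_PROVIRUS = "present_provirus"
STATE_SOLO = "present_solo"
STATE_ABSENT = "absent_empty"
STATE_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class FlankProbe:
    """Junction probe: element terminus plus host flank.

    ``junction_offset`` is the probe position of the element/host
    boundary: for a 5' probe the flank occupies [0, junction) and the
    element [junction, len); for a 3' probe the element occupies
    [0, junction) and the flank [junction, len).
    """

    locus_id: str
    side: str  # "5p" | "3p"
    probe_seq: str
    junction_offset: int

    def __post_init__(self):
        if self.side not in ("5p", "3p"):
            raise ValueError(f"unknown probe side {self.side!r}")
        if not 0 < self.junction_offset < len(self.probe_seq):
            raise ValueError("junction_offset outside probe")


@dataclass(frozen=True)
class FlankHit:
    """One alignment of a probe to the target genome."""

    locus_id: str
    side: str
    contig_id: str
    strand: str  # target strand of the alignment
    t_start: int  # target, 0-based half-open, forward coordinates
    t_end: int
    q_start: int  # probe coordinates in probe orientation
    q_end: int
    score: float
    matches: int
    flank_matches: int  # matches falling on the host-flank side
    identity: float

    @property
    def aln_len(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class OrthologyCall:
    locus_id: str
    target_species: str
    state: str
    target_iv: Optional[Interval] = None
    tsd_seq: Optional[str] = None
    gap: Optional[int] = None  # element-side junction distance


def make_probes(locus: ErvLocus,
                genome: Sequence[GenomeSeq] | dict[str, str],
                flank: int = PROBE_FLANK,
                element: int = PROBE_ELEMENT
                ) -> tuple[Optional[FlankProbe], Optional[FlankProbe]]:
    """Extract the 5' and 3' junction probes of a locus.

    Probes are emitted in element orientation (reverse-complemented for
    minus-strand loci), so the 5' probe always reads flank-then-element.
    Probes are truncated with a warning near contig edges; a side with
    less than 20 bp of flank is returned as None (unresolvable).
    """
    if not isinstance(genome, dict):
        genome = genome_dict(genome)
    iv = locus.extent
    seq = genome[iv.contig_id]
    elem5 = min(element, len(iv))
    left_flank = min(flank, iv.start)
    right_flank = min(flank, len(seq) - iv.end)
    if left_flank < flank or right_flank < flank:
        log.warning("%s: probe truncated at contig edge", locus.locus_id)

    def fwd_left() -> Optional[FlankProbe]:
        if left_flank < MIN_FLANK:
            return None
        probe = seq[iv.start - left_flank:iv.start + elem5]
        return probe, left_flank

    def fwd_right() -> Optional[FlankProbe]:
        if right_flank < MIN_FLANK:
            return None
        probe = seq[iv.end - elem5:iv.end + right_flank]
        return probe, elem5

    left, right = fwd_left(), fwd_right()
    if iv.strand == "+":
        p5 = None if left is None else FlankProbe(
            locus.locus_id, "5p", left[0], left[1])
        p3 = None if right is None else FlankProbe(
            locus.locus_id, "3p", right[0], right[1])
    else:
        # element orientation: genomic right end is the element 5' end
        p5 = None if right is None else FlankProbe(
            locus.locus_id, "5p", reverse_complement(right[0]),
            len(right[0]) - right[1])
        p3 = None if left is None else FlankProbe(
            locus.locus_id, "3p", reverse_complement(left[0]),
            len(left[0]) - left[1])
    return p5, p3


class GenomeIndex:
    """Exact k-mer index of a target genome for seed-and-extend search."""

    def __init__(self, genome: Sequence[GenomeSeq] | dict[str, str],
                 k: int = SEED_K):
        if not isinstance(genome, dict):
            genome = genome_dict(genome)
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self._index[kmer].append((contig, i))

    def seeds(self, query: str):
        k = self.k
        for q in range(len(query) - k + 1):
            for contig, t in self._index.get(query[q:q + k], ()):
                yield contig, q, t


def _hit_from_local_alignment(aln, probe: FlankProbe, contig: str,
                              strand: str, window_start: int,
                              probe_len: int) -> Optional[FlankHit]:
    """Convert a Bio.Align local alignment (target, query) into a
    FlankHit with flank-side match accounting."""
    if aln is None or aln.score <= 0:
        return None
    blocks_t, blocks_q = aln.aligned
    if len(blocks_q) == 0:
        return None
    matches = flank_matches = 0
    target_seq = aln.target
    query_seq = aln.query
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        for off in range(te - ts):
            if target_seq[ts + off] == query_seq[qs + off]:
                matches += 1
                # probe coordinate in probe orientation
                qpos = qs + off if strand == "+" else \
                    probe_len - 1 - (qs + off)
                if probe.side == "5p":
                    if qpos < probe.junction_offset:
                        flank_matches += 1
                else:
                    if qpos >= probe.junction_offset:
                        flank_matches += 1
    q_lo, q_hi = int(blocks_q[0][0]), int(blocks_q[-1][1])
    t_lo, t_hi = int(blocks_t[0][0]), int(blocks_t[-1][1])
    if strand == "+":
        q_start, q_end = q_lo, q_hi
    else:
        q_start, q_end = probe_len - q_hi, probe_len - q_lo
    aln_len = q_hi - q_lo
    return FlankHit(probe.locus_id, probe.side, contig, strand,
                    window_start + t_lo, window_start + t_hi,
                    q_start, q_end, float(aln.score), matches,
                    flank_matches, matches / max(aln_len, 1))


def search_probe(probe: FlankProbe, index: GenomeIndex,
                 max_hits: int = 50, band: int = 60) -> list[FlankHit]:
    """Seed-and-extend search of one probe against an indexed genome.

    Seed hits on a common diagonal (within ``band``) are grouped into a
    candidate window and each window is locally aligned to the probe.
    Hits are ranked by flank matches plus score before capping: the
    element half of a probe matches every family member in the target,
    so a cap on raw score alone would crowd out the flank-only hit at an
    empty pre-insertion site.
    """
    hits: list[FlankHit] = []
    probe_len = len(probe.probe_seq)
    for strand in ("+", "-"):
        query = probe.probe_seq if strand == "+" else \
            reverse_complement(probe.probe_seq)
        groups: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(
            list)
        for contig, q, t in index.seeds(query):
            groups[(contig, (t - q) // band)].append((q, t))
        # merge adjacent diagonal buckets into windows
        windows: dict[tuple[str, int], tuple[int, int]] = {}
        for (contig, bucket), seeds in groups.items():
            t_min = min(t - q for q, t in seeds)
            t_max = max(t - q for q, t in seeds)
            key = (contig, bucket)
            windows[key] = (t_min, t_max)
        merged: dict[str, list[list[int]]] = defaultdict(list)
        for (contig, _), (t_min, t_max) in sorted(windows.items()):
            spans = merged[contig]
            if spans and t_min <= spans[-1][1] + band:
                spans[-1][1] = max(spans[-1][1], t_max)
            else:
                spans.append([t_min, t_max])
        for contig, spans in merged.items():
            seq = index.genome[contig]
            for t_min, t_max in spans:
                w_start = max(0, t_min - band)
                w_end = min(len(seq), t_max + probe_len + band)
                aln = _align.local_alignment(query, seq[w_start:w_end])
                hit = _hit_from_local_alignment(
                    aln, probe, contig, strand, w_start, probe_len)
                if hit is not None:
                    hits.append(hit)
    hits.sort(key=lambda h: -(h.flank_matches + h.score))
    return hits[:max_hits]


def flank_hit_from_search_hit(hit: SearchHit, probe: FlankProbe
                              ) -> FlankHit:
    """Adapt an external (e.g. BLAST tabular) hit to the FlankHit
    contract.  Flank-side matches are estimated from the query interval's
    overlap with the flank region times the reported identity."""
    j = probe.junction_offset
    if probe.side == "5p":
        overlap = max(0, min(hit.q_end, j) - hit.q_start)
    else:
        overlap = max(0, hit.q_end - max(hit.q_start, j))
    matches = int(round(hit.pct_identity * hit.aln_len))
    return FlankHit(probe.locus_id, probe.side, hit.subject_iv.contig_id,
                    hit.subject_iv.strand, hit.subject_iv.start,
                    hit.subject_iv.end, hit.q_start, hit.q_end,
                    hit.bitscore, matches,
                    int(round(hit.pct_identity * overlap)),
                    hit.pct_identity)


def _junction_target(hit: FlankHit, junction_offset: int) -> int:
    """Target coordinate of the probe's junction offset.

    Linear extrapolation from the alignment's query/target anchors
    (exact in the absence of indels), clamped to stay near the hit.
    """
    if hit.strand == "+":
        return hit.t_start + (junction_offset - hit.q_start)
    return hit.t_end - (junction_offset - hit.q_start)


def pair_flank_hits(hits5: Sequence[FlankHit], hits3: Sequence[FlankHit],
                    probe5: Optional[FlankProbe] = None,
                    probe3: Optional[FlankProbe] = None,
                    max_span: int = MAX_PAIR_SPAN,
                    min_flank_matches: int = 100
                    ) -> list[tuple[FlankHit, FlankHit]]:
    """Pair the 5' and 3' probe hits of one locus in one target genome.

    Candidate pairs lie on the same contig with consistent orientation,
    the 3' junction downstream of the 5' junction in element orientation
    (small negative gaps are allowed - that is the empty-site
    configuration where the flanks overlap by the TSD), within
    ``max_span``.  The best pair maximises summed host-flank matches
    (the locus-specific part of the signal; the element halves match
    every family member in the target), tie-broken by summed score.
    A pair whose summed flank matches fall below ``min_flank_matches``
    carries no locus-specific information (element-only hits at
    unrelated family members) and is rejected, so such loci come out
    unresolved rather than spuriously present.  Returns at most one
    pair.
    """
    j5 = probe5.junction_offset if probe5 else PROBE_FLANK
    j3 = probe3.junction_offset if probe3 else PROBE_ELEMENT
    best = None
    best_key = None
    for h5 in hits5:
        for h3 in hits3:
            if h5.contig_id != h3.contig_id or h5.strand != h3.strand:
                continue
            sign = 1 if h5.strand == "+" else -1
            gap = sign * (_junction_target(h3, j3)
                          - _junction_target(h5, j5))
            if not -50 <= gap <= max_span:
                continue
            if h5.flank_matches + h3.flank_matches < min_flank_matches:
                continue
            key = (h5.flank_matches + h3.flank_matches,
                   h5.score + h3.score)
            if best_key is None or key > best_key:
                best, best_key = (h5, h3), key
    return [best] if best is not None else []


def call_state(pair: Optional[tuple[FlankHit, FlankHit]],
               locus: ErvLocus, ltr_len: int,
               target_genome: Optional[dict[str, str]] = None,
               target_species: str = "",
               probe5: Optional[FlankProbe] = None,
               probe3: Optional[FlankProbe] = None) -> OrthologyCall:
    """Interpret a paired hit as presence/absence of the donor locus.

    With g the distance between the element-side junctions in the target:
    g >= 0.8 x the expected provirus length -> present_provirus;
    |g - ltr_len| <= 0.2 x ltr_len -> present_solo; g <= 25 bp ->
    absent_empty (with the duplicated target site recorded when the two
    flanks overlap by 2-10 bp); anything else, or no pair, is unresolved.
    """
    if ltr_len <= 0:
        raise ValueError("ltr_len must be positive")
    if pair is None or len(pair) == 0:
        return OrthologyCall(locus.locus_id, target_species,
                             STATE_UNRESOLVED)
    h5, h3 = pair if isinstance(pair, tuple) else pair[0]
    j5 = probe5.junction_offset if probe5 else PROBE_FLANK
    j3 = probe3.junction_offset if probe3 else PROBE_ELEMENT
    t5 = _junction_target(h5, j5)
    t3 = _junction_target(h3, j3)
    sign = 1 if h5.strand == "+" else -1
    gap = sign * (t3 - t5)
    lo, hi = min(t5, t3), max(t5, t3)
    iv = Interval(h5.contig_id, max(lo, 0), max(hi, lo + 1), h5.strand)
    expected_len = len(locus.extent) if locus.kind == "provirus" else \
        2 * ltr_len + MIN_INTERNAL_BP
    if gap >= 0.8 * expected_len:
        return OrthologyCall(locus.locus_id, target_species,
                             STATE_PROVIRUS, iv, gap=gap)
    if abs(gap - ltr_len) <= 0.2 * ltr_len:
        return OrthologyCall(locus.locus_id, target_species, STATE_SOLO,
                             iv, gap=gap)
    if gap <= EMPTY_SITE_MAX_GAP:
        tsd = None
        if target_genome is not None and -10 <= gap <= -2:
            site = target_genome[h5.contig_id][lo:hi]
            if site:
                tsd = site
        return OrthologyCall(locus.locus_id, target_species, STATE_ABSENT,
                             iv, tsd_seq=tsd, gap=gap)
    return OrthologyCall(locus.locus_id, target_species,
                         STATE_UNRESOLVED, iv, gap=gap)


def call_orthology(locus: ErvLocus, donor_genome, index: GenomeIndex,
                   ltr_len: int, target_species: str = "") -> OrthologyCall:
    """Probe extraction, search, pairing and state call for one locus."""
    p5, p3 = make_probes(locus, donor_genome)
    if p5 is None or p3 is None:
        return OrthologyCall(locus.locus_id, target_species,
                             STATE_UNRESOLVED)
    hits5 = search_probe(p5, index)
    hits3 = search_probe(p3, index)
    pair = pair_flank_hits(hits5, hits3, p5, p3)
    return call_state(pair[0] if pair else None, locus, ltr_len,
                      index.genome, target_species, p5, p3)


# ---------------------------------------------------------------------------
# per-branch insertion counts (Dollo parsimony)


def orthology_matrix(presence: dict[str, dict[str, str]],
                     species_tree: dendropy.Tree
                     ) -> tuple[dict[tuple[str, ...], int], list[str]]:
    """Assign each locus to the most recent branch consistent with its
    presence/absence pattern under Dollo parsimony (one gain, no loss).

    ``presence`` maps locus_id -> {species: state}; states are the
    OrthologyCall states plus implicit presence in the donor species.
    A locus whose pattern would require a loss (an absent species inside
    the clade of present species) is reported as a conflict, not
    assigned.  Returns (branch -> count, conflicts); a branch is keyed by
    the sorted tuple of leaf labels of the clade it subtends.
    """
    counts: dict[tuple[str, ...], int] = defaultdict(int)
    conflicts: list[str] = []
    label_of = {t.label: t for t in species_tree.taxon_namespace}
    for locus_id, states in presence.items():
        present = sorted(sp for sp, st in states.items()
                         if st in (STATE_PROVIRUS, STATE_SOLO)
                         or st == "present")
        absent = {sp for sp, st in states.items()
                  if st in (STATE_ABSENT, "absent")}
        if not present:
            continue
        missing = [sp for sp in present if sp not in label_of]
        if missing:
            raise KeyError(f"species {missing} not in tree")
        if len(present) == 1:
            counts[(present[0],)] += 1
            continue
        mrca = species_tree.mrca(taxon_labels=present)
        clade = sorted(leaf.taxon.label for leaf in mrca.leaf_iter())
        if any(sp in absent for sp in clade):
            conflicts.append(locus_id)
            continue
        counts[tuple(clade)] += 1
    return dict(counts), conflicts
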