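"""Classify repeat-annotation hits into ERV loci.

An integrated provirus leaves the signature LTR-internal-LTR structure:
two long terminal repeats in the same orientation separated by the viral
coding region.  After integration, recombination between the two LTRs can
delete the internal region, leaving a solo LTR.  This module turns a table
of LTR-library hits into classified loci:

* putative full-length proviruses: two same-strand LTR hits on one contig
  whose intervening sequence (exclusive of the LTRs themselves) is between
  3 kb and 10 kb;
* complete solo LTRs: unpaired hits missing less than 150 bp at the
  consensus 5' terminus and less than 10 bp at the 3' terminus.

It also houses the two sequence-level screens used when sweeping many
genomes for relatives of a family: the 80%-identity / 80%-length filter on
homology-search hits, and the 80%-similarity family-membership rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import _align
from .core_io import Interval, RepeatHit, SearchHit

log = logging.getLogger(__name__)

# intervening-sequence window that defines a provirus (bounds inclusive)
MIN_INTERNAL_BP = 3000
MAX_INTERNAL_BP = 10000

# solo-LTR completeness rule: strict "missing less than" bounds
MAX_MISSING_5P = 150
MAX_MISSING_3P = 10


class ShortCandidateError(ValueError):
    """Candidate sequence too short for family assignment (< 50 bp)."""


@dataclass(frozen=True)
class ErvLocus:
    """A classified element: solo LTR or putative full-length provirus."""

    locus_id: str
    kind: str  # "solo_ltr" | "provirus"
    extent: Interval
    family_id: str
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    internal_gap_bp: int = 0

    def __post_init__(self):
        if self.kind == "provirus":
            if self.ltr5 is None or self.ltr3 is None:
                raise ValueError("provirus requires both LTR intervals")
            if self.ltr5.strand != self.ltr3.strand:
                raise ValueError("provirus LTRs must share a strand")
            if not MIN_INTERNAL_BP <= self.internal_gap_bp <= MAX_INTERNAL_BP:
                raise ValueError(
                    f"internal gap {self.internal_gap_bp} outside "
                    f"[{MIN_INTERNAL_BP},{MAX_INTERNAL_BP}]")
        elif self.kind == "solo_ltr":
            if (self.ltr5 is None) == (self.ltr3 is None):
                raise ValueError("solo LTR requires exactly one LTR interval")
        else:
            raise ValueError(f"unknown locus kind {self.kind!r}")

    @property
    def ltr(self) -> Interval:
        """The single LTR of a solo locus."""
        iv = self.ltr5 if self.ltr5 is not None else self.ltr3
        assert iv is not None
        return iv


def is_complete_solo_ltr(hit: RepeatHit, consensus_len: int) -> bool:
    """Completeness rule for a solo LTR candidate.

    True iff the hit misses less than 150 bp at the consensus 5' terminus
    and less than 10 bp at the 3' terminus (both strict).  5'/3' refer to
    consensus ends, independent of genomic strand.
    """
    if consensus_len < hit.cons_end:
        raise ValueError(
            f"consensus length {consensus_len} < hit cons_end {hit.cons_end}")
    missing5 = hit.cons_start - 1
    missing3 = consensus_len - hit.cons_end
    return missing5 < MAX_MISSING_5P and missing3 < MAX_MISSING_3P


def merge_fragmented_hits(hits: Sequence[RepeatHit],
                          min_overlap_frac: float = 0.5) -> list[RepeatHit]:
    """Merge same-family, same-strand hits that overlap by more than half
    of the shorter hit, or that abut as consecutive fragments of one copy
    (genomically adjacent within 100 bp with compatible, advancing
    consensus coordinates).  RepeatMasker routinely splits one element
    across rows; pairing operates on merged copies.
    """
    by_group: dict[tuple, list[RepeatHit]] = {}
    for h in hits:
        by_group.setdefault(
            (h.genome_iv.contig_id, h.genome_iv.strand, h.family_id),
            []).append(h)
    merged: list[RepeatHit] = []
    for group in by_group.values():
        group.sort(key=lambda h: h.genome_iv.start)
        cur = group[0]
        for nxt in group[1:]:
            overlap = min(cur.genome_iv.end, nxt.genome_iv.end) - \
                max(cur.genome_iv.start, nxt.genome_iv.start)
            shorter = min(len(cur.genome_iv), len(nxt.genome_iv))
            gap = nxt.genome_iv.start - cur.genome_iv.end
            consecutive = (
                -100 <= gap <= 100 and nxt.cons_start >= cur.cons_start
                and nxt.cons_end > cur.cons_end)
            if overlap > min_overlap_frac * shorter or consecutive:
                iv = Interval(cur.genome_iv.contig_id,
                              min(cur.genome_iv.start, nxt.genome_iv.start),
                              max(cur.genome_iv.end, nxt.genome_iv.end),
                              cur.genome_iv.strand)
                cons_start = min(cur.cons_start, nxt.cons_start)
                cons_end = max(cur.cons_end, nxt.cons_end)
                cons_left = cur.consensus_len - cons_end
                cur = RepeatHit(max(cur.score, nxt.score), iv, cur.family_id,
                                cons_start, cons_end, max(cons_left, 0))
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda h: (h.genome_iv.contig_id, h.genome_iv.start))
    return merged


def _eligible_gap(a: RepeatHit, b: RepeatHit) -> Optional[int]:
    """Intervening bp between two hits if they could delimit a provirus."""
    ia, ib = a.genome_iv, b.genome_iv
    if ia.contig_id != ib.contig_id or ia.strand != ib.strand:
        return None
    if ia.start > ib.start:
        ia, ib = ib, ia
    gap = ib.start - ia.end
    if MIN_INTERNAL_BP <= gap <= MAX_INTERNAL_BP:
        return gap
    return None


def pair_ltrs(hits: Sequence[RepeatHit],
              merge_fragments: bool = True) -> list[ErvLocus]:
    """Pair LTR hits into proviruses; classify the rest as solo LTRs.

    Pairing is an exact maximum-cardinality matching over all eligible
    pairs (same contig, same strand, intervening sequence within the
    3-10 kb window, bounds inclusive), tie-broken towards the smallest
    total intervening length, so a chain of equidistant hits resolves to
    the leftmost-first pairing.  Each hit is used in at most one locus.
    Unpaired hits that fail the completeness rule are dropped with a
    logged count.
    """
    if merge_fragments:
        hits = merge_fragmented_hits(hits)
    hits = sorted(hits, key=lambda h: (h.genome_iv.contig_id,
                                       h.genome_iv.start, h.genome_iv.end))
    g = nx.Graph()
    g.add_nodes_from(range(len(hits)))
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if hits[j].genome_iv.contig_id != hits[i].genome_iv.contig_id:
                break
            if hits[j].genome_iv.start - hits[i].genome_iv.end \
                    > MAX_INTERNAL_BP:
                break
            gap = _eligible_gap(hits[i], hits[j])
            if gap is not None:
                # weight favours max cardinality first, then small total
                # gap; the epsilon term (total < 1, so it can never
                # override a gap improvement) breaks remaining ties
                # towards leftmost-first pairs, keeping output
                # order-independent and deterministic
                eps = (1.0 - (i + j) / (2.0 * len(hits))) / (len(hits) + 2)
                g.add_edge(i, j,
                           weight=float(MAX_INTERNAL_BP + 1 - gap) + eps)
    matching = nx.max_weight_matching(g, maxcardinality=True)
    paired: dict[int, int] = {}
    for i, j in matching:
        i, j = min(i, j), max(i, j)
        paired[i] = j

    loci: list[ErvLocus] = []
    used = set()
    dropped = 0
    for i, j in sorted(paired.items()):
        a, b = hits[i], hits[j]
        used.update((i, j))
        iv5, iv3 = a.genome_iv, b.genome_iv
        extent = Interval(iv5.contig_id, iv5.start, iv3.end, iv5.strand)
        loci.append(ErvLocus(
            locus_id=f"{a.family_id}_{iv5.contig_id}_{iv5.start}",
            kind="provirus", extent=extent, family_id=a.family_id,
            ltr5=iv5, ltr3=iv3, internal_gap_bp=iv3.start - iv5.end))
    for i, h in enumerate(hits):
        if i in used:
            continue
        if is_complete_solo_ltr(h, h.consensus_len):
            iv = h.genome_iv
            loci.append(ErvLocus(
                locus_id=f"{h.family_id}_{iv.contig_id}_{iv.start}",
                kind="solo_ltr", extent=iv, family_id=h.family_id, ltr5=iv))
        else:
            dropped += 1
    if dropped:
        log.info("pair_ltrs: dropped %d incomplete unpaired LTR hits",
                 dropped)
    loci.sort(key=lambda l: (l.extent.contig_id, l.extent.start))
    return loci


def filter_cst_hits(hits: Sequence[SearchHit],
                    query_len: int,
                    min_identity: float = 0.80,
                    min_len_frac: float = 0.80) -> list[SearchHit]:
    """Cross-species screening filter: retain hits with >= 80% identity
    covering >= 80% of the query, dropping non-specific hits."""
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    return [h for h in hits
            if h.pct_identity >= min_identity
            and h.aln_len >= min_len_frac * query_len]


def assign_family(candidate_seq: str, members: Sequence[str],
                  threshold: float = 0.80) -> bool:
    """Family-membership rule: does the candidate reach 80% nucleotide
    identity (inclusive) to at least one existing family member?

    Identity is computed on a global alignment with free terminal gaps,
    matches over aligned columns excluding terminal gaps, so genuinely
    truncated copies are not penalised for missing ends.
    """
    if not members:
        raise ValueError("members must be non-empty")
    if len(candidate_seq) < 50:
        raise ShortCandidateError(
            f"candidate of {len(candidate_seq)} bp is below the 50 bp "
            "minimum for family assignment")
    best = 0.0
    for m in members:
        row_a, row_b = _align.align_overlap(candidate_seq, m)
        best = max(best, _align.identity_no_terminal_gaps(row_a, row_b))
        if best >= threshold:
            return True
    return best >= threshold


def copy_number(loci: Sequence[ErvLocus], species: str) -> pd.DataFrame:
    """Per-family copy-number table for one species.

    Columns: species, family_id, proviruses, solo_ltrs, total (the layout
    of a full-length/solo/total summary table).
    """
    rows: dict[str, dict[str, int]] = {}
    for locus in loci:
        fam = rows.setdefault(locus.family_id,
                              {"proviruses": 0, "solo_ltrs": 0})
        if locus.kind == "provirus":
            fam["proviruses"] += 1
        else:
            fam["solo_ltrs"] += 1
    records = [
        {"species": species, "family_id": fam,
         "proviruses": c["proviruses"], "solo_ltrs": c["solo_ltrs"],
         "total": c["proviruses"] + c["solo_ltrs"]}
        for fam, c in sorted(rows.items())
    ]
    return pd.DataFrame(
        records,
        columns=["species", "family_id", "proviruses", "solo_ltrs", "total"])
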