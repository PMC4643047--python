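"""Shared pairwise-alignment helpers (thin wrappers around Bio.Align).

One scoring scheme is used throughout: match +1, mismatch -1, gap open -5,
gap extend -1.  Two flavours are exposed: a fully penalised global
alignment (LTR pairs, which are near-equal length) and an overlap
alignment with free terminal gaps (family membership of truncated copies),
plus a local aligner for probe-vs-window searches.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -5, -1


@lru_cache(maxsize=None)
def _aligner(mode: str, free_end_gaps: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    if free_end_gaps:
        try:
            al.end_insertion_score = 0.0
            al.end_deletion_score = 0.0
        except AttributeError:  # older Bio.Align naming
            al.target_end_gap_score = 0.0
            al.query_end_gap_score = 0.0
    return al


def align_global(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped rows."""
    aln = _aligner("global", False).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_overlap(a: str, b: str) -> tuple[str, str]:
    """Global alignment with unpenalised terminal gaps."""
    aln = _aligner("global", True).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def local_alignment(query: str, target: str):
    """Best local alignment object of query against target (Smith-Waterman
    via Bio.Align); returns None when nothing scores above zero."""
    alns = _aligner("local", False).align(target, query)
    try:
        return alns[0]
    except IndexError:
        return None


def identity_no_terminal_gaps(row_a: str, row_b: str) -> float:
    """Fraction of matching columns, excluding terminal-gap columns.

    The denominator counts all aligned columns between the first and last
    column where both rows have a residue (internal gaps count as
    mismatches); identity of truncated-but-otherwise-identical copies is
    therefore not penalised for the truncation.
    """
    n = len(row_a)
    assert n == len(row_b)
    first, last = None, None
    for i in range(n):
        if row_a[i] != "-" and row_b[i] != "-":
            if first is None:
                first = i
            last = i
    if first is None:
        return 0.0
    matches = cols = 0
    for i in range(first, last + 1):
        cols += 1
        if row_a[i] == row_b[i] and row_a[i] != "-":
            matches += 1
    return matches / cols
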