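"""LTR-divergence insertion dating and sliding-window identity profiles.

A provirus integrates with two identical LTRs; each then accumulates host
mutations independently, so the corrected divergence d between the 5' and
3' LTR clocks the insertion: age = d / (2 r), where r is the host neutral
substitution rate per site per year (the factor 2 because both LTRs
mutate).  Divergence is the Kimura 2-parameter distance

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over usable
(ungapped, non-N) aligned sites.  Methylated CpG dinucleotides are
hypermutable and would inflate d, so every alignment column that is part
of a CpG in *either* sequence is masked before counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _align
from .core_io import GenomeSeq, extract, genome_dict
from .annotate import ErvLocus

#: neutral substitution rates per site per year used in this analysis
RATE_VESPER_BAT = 2.7e-9
RATE_FELID = 1.8e-9
RATE_MAMMAL_AVG = 2.2e-9

MIN_USABLE_SITES = 50

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two aligned rows of equal length over {A,C,G,T,N,-}."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows differ in length")
        for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b)):
            if a == "-" and b == "-":
                raise ValueError(f"column {i} is gapped in both rows")

    def __len__(self) -> int:
        return len(self.seq_a)

    @classmethod
    def from_seqs(cls, a: str, b: str) -> "PairwiseAlignment":
        """Build by global alignment of two unaligned sequences."""
        ra, rb = _align.align_global(a.upper(), b.upper())
        return cls(ra, rb)


@dataclass(frozen=True)
class K2PResult:
    """Kimura 2-parameter distance with its transition/transversion parts."""

    P: float
    Q: float
    d: float  # nan when saturated
    usable_sites: int
    saturated: bool = False
    low_confidence: bool = False

    @property
    def defined(self) -> bool:
        return not self.saturated


@dataclass(frozen=True)
class AgeEstimate:
    locus_id: str
    divergence: K2PResult
    rate_per_year: float
    age_years: float  # nan when divergence undefined

    @property
    def flagged(self) -> bool:
        return (self.divergence.saturated
                or self.divergence.low_confidence
                or math.isnan(self.age_years))


@dataclass(frozen=True)
class WindowProfile:
    """Per-window identity along an alignment (window/step in columns)."""

    window: int
    step: int
    window_start: np.ndarray
    window_mid: np.ndarray
    identity: np.ndarray
    k2p_identity: np.ndarray

    def __len__(self) -> int:
        return len(self.window_start)


def _cpg_columns(row: str) -> set[int]:
    """Alignment columns that are part of a CpG in one gapped row.

    CpG context is read on the ungapped sequence, so a C and G adjacent in
    the sequence but separated by gap columns still form a CpG.
    """
    cols = [i for i, ch in enumerate(row) if ch != "-"]
    out: set[int] = set()
    for a, b in zip(cols, cols[1:]):
        if row[a] == "C" and row[b] == "G":
            out.update((a, b))
    return out


def mask_cpg(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Mask (with N, in both rows) every column belonging to a CpG
    dinucleotide in either sequence.

    The ancestral state at a diverged site is unknown: a CpG in either row
    marks both the intact and the decayed (TpG/CpA) configuration, which
    is exactly the C->T/G->A decay the exclusion targets.
    """
    masked = _cpg_columns(aln.seq_a) | _cpg_columns(aln.seq_b)
    if not masked:
        return aln

    def apply(row: str) -> str:
        return "".join("N" if i in masked and ch != "-" else ch
                       for i, ch in enumerate(row))

    return PairwiseAlignment(apply(aln.seq_a), apply(aln.seq_b))


def k2p(aln: PairwiseAlignment) -> K2PResult:
    """Kimura 2-parameter distance over usable columns.

    Columns containing a gap or N in either row are skipped and do not
    count towards ``usable_sites``.  When the logarithm's argument is
    non-positive (P, Q too large) the distance is saturated and ``d`` is
    returned as nan with the flag set.
    """
    usable = transitions = transversions = 0
    for a, b in zip(aln.seq_a, aln.seq_b):
        if a not in _BASES or b not in _BASES:
            continue
        usable += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        return K2PResult(0.0, 0.0, float("nan"), 0,
                         saturated=True, low_confidence=True)
    P = transitions / usable
    Q = transversions / usable
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return K2PResult(P, Q, float("nan"), usable, saturated=True,
                         low_confidence=usable < MIN_USABLE_SITES)
    d = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return K2PResult(P, Q, d, usable,
                     low_confidence=usable < MIN_USABLE_SITES)


def ltr_divergence(ltr5_seq: str, ltr3_seq: str,
                   exclude_cpg: bool = True) -> K2PResult:
    """Align two LTR sequences, optionally mask CpG, return K2P."""
    aln = PairwiseAlignment.from_seqs(ltr5_seq, ltr3_seq)
    if exclude_cpg:
        aln = mask_cpg(aln)
    return k2p(aln)


def age_from_divergence(d: float, rate_per_year: float) -> float:
    """Two-LTR molecular clock: age = d / (2 r)."""
    return d / (2.0 * rate_per_year)


def date_provirus(locus: ErvLocus,
                  genome: Sequence[GenomeSeq] | dict[str, str],
                  rate_per_year: float,
                  exclude_cpg: bool = True) -> AgeEstimate:
    """Estimate the insertion age of one provirus from its LTR pair."""
    if locus.kind != "provirus":
        raise ValueError(f"{locus.locus_id}: dating requires a provirus")
    if not isinstance(genome, dict):
        genome = genome_dict(genome)
    assert locus.ltr5 is not None and locus.ltr3 is not None
    seq5 = extract(genome, locus.ltr5)
    seq3 = extract(genome, locus.ltr3)
    div = ltr_divergence(seq5, seq3, exclude_cpg=exclude_cpg)
    age = float("nan") if div.saturated else \
        age_from_divergence(div.d, rate_per_year)
    return AgeEstimate(locus.locus_id, div, rate_per_year, age)


def sliding_identity(aln: PairwiseAlignment,
                     window: int = 300, step: int = 50) -> WindowProfile:
    """Per-window identity and K2P-corrected identity along an alignment.

    Windows are alignment columns starting at 0, step, 2*step, ... while
    start + window <= length (the trailing partial window is dropped).  An
    alignment shorter than one window collapses, with a warning, to a
    single whole-alignment window.
    """
    n = len(aln)
    if n < window:
        warnings.warn(
            f"alignment of {n} columns shorter than window {window}; "
            "reporting one whole-alignment window")
        starts = [0]
        window = n
    else:
        starts = list(range(0, n - window + 1, step))
    identity = np.empty(len(starts))
    k2p_identity = np.empty(len(starts))
    for w, s in enumerate(starts):
        sub = PairwiseAlignment(aln.seq_a[s:s + window],
                                aln.seq_b[s:s + window])
        usable = matches = 0
        for a, b in zip(sub.seq_a, sub.seq_b):
            if a in _BASES and b in _BASES:
                usable += 1
                if a == b:
                    matches += 1
        identity[w] = matches / usable if usable else float("nan")
        res = k2p(sub)
        k2p_identity[w] = 1.0 - res.d if res.defined else float("nan")
    starts_arr = np.asarray(starts)
    return WindowProfile(window, step, starts_arr, starts_arr + window / 2.0,
                         identity, k2p_identity)
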