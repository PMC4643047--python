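"""Inter-LTR gene-conversion detection via quartet topology.

For a provirus orthologous in two species A and B, the four LTRs
(5'A, 3'A, 5'B, 3'B) carry a phylogenetic signal.  Without gene
conversion, divergence accumulated between the 5' and 3' LTR before
speciation makes the LTRs cluster *by position* ({5'A,5'B} | {3'A,3'B}).
Conversion after speciation homogenises the two LTRs within each lineage,
erasing the pre-speciation signal, so the LTRs cluster *by provirus*
({5'A,3'A} | {5'B,3'B}) - the signature of conversion.

The unrooted quartet is resolved with the four-point condition on
CpG-masked K2P distances: the true split minimises the sum of
intra-group distances.  Support is the proportion of alignment-column
bootstrap replicates recovering the point-estimate split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _align
from .core_io import extract, genome_dict
from .annotate import ErvLocus
from .dating import _cpg_columns

BY_PROVIRUS = "by_provirus"
BY_LTR_POSITION = "by_ltr_position"
CROSS = "cross"
STAR = "star"

# ingroup index order used throughout: 5A, 3A, 5B, 3B
_SPLITS = {
    BY_PROVIRUS: ((0, 1), (2, 3)),
    BY_LTR_POSITION: ((0, 2), (1, 3)),
    CROSS: ((0, 3), (1, 2)),
}
_SPLIT_ORDER = (BY_PROVIRUS, BY_LTR_POSITION, CROSS)


@dataclass(frozen=True)
class QuartetCase:
    locus_id: str
    ltr5_a: str
    ltr3_a: str
    ltr5_b: str
    ltr3_b: str
    outgroup_ltr: Optional[str] = None

    @property
    def ingroup(self) -> tuple[str, str, str, str]:
        return (self.ltr5_a, self.ltr3_a, self.ltr5_b, self.ltr3_b)


@dataclass(frozen=True)
class ConversionVerdict:
    locus_id: str
    topology: str  # by_provirus | by_ltr_position | cross | star
    converted: bool
    support: float

    def __post_init__(self):
        assert self.converted == (self.topology == BY_PROVIRUS)


def star_msa(seqs: Sequence[str]) -> list[str]:
    """Reference-anchored multiple alignment.

    Each sequence is aligned pairwise to the first (reference) sequence
    and projected onto reference columns; insertions relative to the
    reference are dropped.  Adequate for the highly similar LTR sets this
    module consumes; a better external alignment can be supplied instead
    by passing pre-aligned equal-length sequences downstream.
    """
    ref = seqs[0].upper()
    rows = [ref]
    for seq in seqs[1:]:
        ra, rb = _align.align_overlap(ref, seq.upper())
        projected = [b for a, b in zip(ra, rb) if a != "-"]
        rows.append("".join(projected))
    return rows


def _pair_classes(rows: Sequence[str]) -> np.ndarray:
    """Per-pair, per-column site classes for the 6 ingroup pairs.

    0 = unusable (gap/N/CpG-masked in that pair), 1 = match,
    2 = transition, 3 = transversion.  CpG masking is pair-specific:
    a column in CpG context in either member of the pair is unusable for
    that pair.
    """
    n = len(rows[0])
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    cpg = [_cpg_columns(r) for r in rows]
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    cls = np.zeros((6, n), dtype=np.int8)
    ts_pairs = {(b"A", b"G"), (b"G", b"A"), (b"C", b"T"), (b"T", b"C")}
    bases = (b"A", b"C", b"G", b"T")
    for p, (i, j) in enumerate(pairs):
        a, b = arrs[i], arrs[j]
        ok = np.isin(a, bases) & np.isin(b, bases)
        masked = np.zeros(n, dtype=bool)
        idx = list(cpg[i] | cpg[j])
        if idx:
            masked[idx] = True
        ok &= ~masked
        match = ok & (a == b)
        ts = np.zeros(n, dtype=bool)
        for x, y in ts_pairs:
            ts |= (a == x) & (b == y)
        ts &= ok
        tv = ok & ~match & ~ts
        cls[p, match] = 1
        cls[p, ts] = 2
        cls[p, tv] = 3
    return cls


def _k2p_from_counts(usable, ts, tv) -> np.ndarray:
    """Vectorised K2P distance from per-pair counts (nan = undefined)."""
    usable = np.asarray(usable, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(usable > 0, ts / usable, np.nan)
        Q = np.where(usable > 0, tv / usable, np.nan)
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        d = np.where((arg1 > 0) & (arg2 > 0),
                     -0.5 * np.log(np.maximum(arg1, 1e-300)
                                   * np.sqrt(np.maximum(arg2, 1e-300))),
                     np.nan)
    return d


_PAIR_INDEX = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4,
               (2, 3): 5}


def _split_sums(d6) -> np.ndarray:
    """Sums of intra-group distances for the three splits.

    ``d6`` has the 6 pair distances in _PAIR_INDEX order, optionally with
    a trailing replicate axis.
    """
    sums = []
    for name in _SPLIT_ORDER:
        (a, b), (c, e) = _SPLITS[name]
        sums.append(d6[_PAIR_INDEX[(a, b)]] + d6[_PAIR_INDEX[(c, e)]])
    return np.stack(sums)


def _resolve(sums: np.ndarray, tol: float = 1e-12) -> str:
    """Pick the split with strictly minimal intra-group distance sum."""
    if np.any(np.isnan(sums)):
        return STAR
    order = np.argsort(sums)
    if sums[order[1]] - sums[order[0]] <= tol:
        return STAR
    return _SPLIT_ORDER[order[0]]


def quartet_topology(case: QuartetCase,
                     replicates: int = 1000,
                     seed: int = 0,
                     aligned: bool = False) -> ConversionVerdict:
    """Resolve one 4-LTR quartet and bootstrap its support.

    With ``aligned=True`` the four ingroup sequences are taken as already
    aligned rows of equal length; otherwise a reference-anchored multiple
    alignment is built internally.  Saturated (undefined) distances yield
    a star topology with support 0.
    """
    seqs = list(case.ingroup)
    if aligned:
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("aligned=True requires equal-length rows")
        rows = [s.upper() for s in seqs]
    else:
        rows = star_msa(seqs)
    cls = _pair_classes(rows)
    n = cls.shape[1]

    usable = (cls > 0).sum(axis=1)
    ts = (cls == 2).sum(axis=1)
    tv = (cls == 3).sum(axis=1)
    d = _k2p_from_counts(usable, ts, tv)
    topology = _resolve(_split_sums(d))
    if topology == STAR:
        return ConversionVerdict(case.locus_id, STAR, False, 0.0)

    rng = np.random.default_rng(seed)
    w = rng.multinomial(n, np.full(n, 1.0 / n), size=replicates)  # (B, n)
    wt = w.T.astype(float)
    usable_b = ((cls > 0).astype(float) @ wt)  # (6, B)
    ts_b = ((cls == 2).astype(float) @ wt)
    tv_b = ((cls == 3).astype(float) @ wt)
    d_b = _k2p_from_counts(usable_b, ts_b, tv_b)
    sums_b = _split_sums(d_b)  # (3, B)
    agree = 0
    target = _SPLIT_ORDER.index(topology)
    nan_cols = np.any(np.isnan(sums_b), axis=0)
    mins = np.argmin(np.where(np.isnan(sums_b), np.inf, sums_b), axis=0)
    strict = np.sort(sums_b, axis=0)
    resolved = ~nan_cols & (strict[1] - strict[0] > 1e-12)
    agree = int(np.sum(resolved & (mins == target)))
    support = agree / replicates
    return ConversionVerdict(case.locus_id, topology,
                             topology == BY_PROVIRUS, support)


def build_quartet_case(locus_a: ErvLocus, locus_b: ErvLocus,
                       genome_a, genome_b,
                       outgroup_ltr: Optional[str] = None) -> QuartetCase:
    """Extract the four LTR sequences of an orthologous provirus pair."""
    for locus in (locus_a, locus_b):
        if locus.kind != "provirus":
            raise ValueError(f"{locus.locus_id}: quartet requires proviruses")
    ga = genome_a if isinstance(genome_a, dict) else genome_dict(genome_a)
    gb = genome_b if isinstance(genome_b, dict) else genome_dict(genome_b)
    return QuartetCase(
        locus_id=locus_a.locus_id,
        ltr5_a=extract(ga, locus_a.ltr5), ltr3_a=extract(ga, locus_a.ltr3),
        ltr5_b=extract(gb, locus_b.ltr5), ltr3_b=extract(gb, locus_b.ltr3),
        outgroup_ltr=outgroup_ltr)


def conversion_screen(pairs: Sequence[tuple[ErvLocus, ErvLocus]],
                      genome_a, genome_b,
                      outgroup_ltr: Optional[str] = None,
                      replicates: int = 1000,
                      seed: int = 0,
                      max_n_frac: float = 0.5):
    """Run the quartet test over a cohort of orthologous provirus pairs.

    Returns (verdicts, skipped) where ``skipped`` is a list of
    (locus_id, reason) for loci whose LTRs could not be used (e.g. mostly
    assembly gap).  Verdict seeds are derived deterministically from
    ``seed`` and the locus index.
    """
    ga = genome_a if isinstance(genome_a, dict) else genome_dict(genome_a)
    gb = genome_b if isinstance(genome_b, dict) else genome_dict(genome_b)
    verdicts: list[ConversionVerdict] = []
    skipped: list[tuple[str, str]] = []
    for i, (la, lb) in enumerate(pairs):
        try:
            case = build_quartet_case(la, lb, ga, gb, outgroup_ltr)
        except (KeyError, ValueError) as exc:
            skipped.append((la.locus_id, str(exc)))
            continue
        if any(s.count("N") > max_n_frac * len(s) for s in case.ingroup):
            skipped.append((la.locus_id, "LTR mostly assembly gap"))
            continue
        verdicts.append(quartet_topology(case, replicates=replicates,
                                         seed=seed + i))
    return verdicts, skipped
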