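"""Selection (dN/dS) and ORF-integrity statistics on coding domains.

dN/dS (omega) is estimated by Nei-Gojobori counting: per codon,
synonymous and nonsynonymous *sites* are the fractions of single-base
changes (mutational paths through stop codons excluded) that preserve or
change the encoded amino acid; observed per-pair differences are averaged
over the equally weighted shortest mutational paths between the two
codons.  Proportions are Jukes-Cantor corrected and averaged over all
sequence pairs; omega = dN / dS.  Departure from omega = 1 is tested by a
codon-column bootstrap (the counting analogue of a likelihood-ratio test
against neutrality).

ORF integrity is the frequency of disruption events (in-frame stop codons
plus frameshifting indel runs) per codon, with an exact Poisson 95%
confidence interval on the event count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)

DOMAIN_IDS = ("Gag_MA", "Gag_p30", "RVP", "RVT_1", "RnaseH", "rve",
              "TLV_coat")

MIN_CODONS = 30


class InsufficientDataError(ValueError):
    """Fewer shared ungapped codons than the method can support."""


@dataclass(frozen=True)
class SelectionResult:
    domain_id: str
    subfamily_id: str
    dN: float
    dS: float
    omega: Optional[float]  # None when dS == 0 (undefined)
    p_value: Optional[float]
    verdict: str  # purifying | neutral_or_relaxed | undefined
    n_codons: int = 0
    n_pairs: int = 0


@dataclass(frozen=True)
class IntegrityStats:
    domain_id: str
    subfamily_id: str
    n_codons: int  # total codon exposure summed over sequences
    n_stops: int
    n_frameshifts: int
    freq: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class DeletionBreakpoint:
    subfamily_id: str
    start: int  # alignment columns
    end: int
    n_sharing: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("breakpoint end must exceed start")
        if self.n_sharing < 2:
            raise ValueError("a shared breakpoint needs >= 2 members")


# ---------------------------------------------------------------------------
# Nei-Gojobori codon machinery


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes 1 site, split by the fraction of its three
    single-base changes that are synonymous; changes creating a stop codon
    are excluded from the fraction (a position whose every change creates
    a stop contributes no sites).
    """
    if codon in STOP_CODONS or codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = n = 0.0
    for pos in range(3):
        syn = non = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if _AA[alt] == _AA[codon]:
                syn += 1
            else:
                non += 1
        total = syn + non
        if total:
            s += syn / total
            n += non / total
    return s, n


@lru_cache(maxsize=None)
def codon_path_diffs(codon_a: str, codon_b: str) \
        -> Optional[tuple[float, float]]:
    """(synonymous, nonsynonymous) observed differences between two sense
    codons, averaged over all shortest mutational paths that avoid stop
    codons.  None when every path passes through a stop codon."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _codons_of(row: str) -> list[str]:
    if len(row) % 3:
        raise ValueError("codon alignment length must be divisible by 3")
    return [row[i:i + 3] for i in range(0, len(row), 3)]


def pair_codon_stats(aln: Sequence[str]) -> np.ndarray:
    """Per-pair, per-codon-column NG86 quantities.

    Returns an array of shape (n_pairs, n_codons, 4) holding
    (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs); columns where
    either codon is ambiguous (gap or N), a stop, or where every
    mutational path is blocked contribute zeros.  This is the unit the
    codon bootstrap resamples.
    """
    rows = [s.upper() for s in aln]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    codons = [_codons_of(r) for r in rows]
    n_seq = len(rows)
    n_cod = len(codons[0])
    pairs = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    out = np.zeros((len(pairs), n_cod, 4))
    for p, (i, j) in enumerate(pairs):
        for c in range(n_cod):
            ca, cb = codons[i][c], codons[j][c]
            if ca not in _AA or cb not in _AA:
                continue
            diffs = codon_path_diffs(ca, cb)
            if diffs is None:
                continue
            sa, na = codon_sites(ca)
            sb, nb = codon_sites(cb)
            out[p, c] = ((sa + sb) / 2.0, (na + nb) / 2.0,
                         diffs[0], diffs[1])
    return out


def _jc(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor correction of a proportion; nan when saturated."""
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 1.0 - 4.0 * p / 3.0
        return np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)),
                        np.nan)


def _omega_from_sums(sums: np.ndarray):
    """dN-bar, dS-bar and omega from summed pair stats.

    ``sums`` has shape (n_pairs, 4[, B]).  Pair distances are averaged
    over pairs (nan-aware); omega is nan where dS-bar is 0 or undefined,
    +inf where dS-bar == 0 but dN-bar > 0.
    """
    s_sites, n_sites = sums[:, 0], sums[:, 1]
    sd, nd = sums[:, 2], sums[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = np.where(s_sites > 0, sd / np.maximum(s_sites, 1e-300), np.nan)
        pN = np.where(n_sites > 0, nd / np.maximum(n_sites, 1e-300), np.nan)
    with warnings.catch_warnings():
        # all-pair saturation legitimately yields an all-nan mean
        warnings.simplefilter("ignore", RuntimeWarning)
        dS = np.nanmean(_jc(pS), axis=0)
        dN = np.nanmean(_jc(pN), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(dS > 0, dN / np.where(dS > 0, dS, 1.0),
                         np.where(dN > 0, np.inf, np.nan))
    return dN, dS, omega


def omega_neutrality_test(aln: Sequence[str],
                          replicates: int = 1000,
                          seed: int = 0,
                          stats_arr: Optional[np.ndarray] = None
                          ) -> Optional[float]:
    """Two-sided codon-column bootstrap p-value for omega != 1.

    Codon columns are resampled with replacement; each replicate's omega
    is compared to 1 and p = 2 * min(P(omega* >= 1), P(omega* <= 1)) over
    the defined replicates.  Deterministic given ``seed``.  Returns None
    when omega is undefined (dS = 0) in the point estimate.
    """
    if stats_arr is None:
        stats_arr = pair_codon_stats(aln)
    n_cod = stats_arr.shape[1]
    _, dS0, omega0 = _omega_from_sums(stats_arr.sum(axis=1))
    if not np.isfinite(omega0):
        return None
    rng = np.random.default_rng(seed)
    w = rng.multinomial(n_cod, np.full(n_cod, 1.0 / n_cod),
                        size=replicates).T.astype(float)  # (n_cod, B)
    n_pairs = stats_arr.shape[0]
    flat = stats_arr.transpose(0, 2, 1).reshape(n_pairs * 4, n_cod)
    sums = (flat @ w).reshape(n_pairs, 4, replicates)
    _, _, omega_b = _omega_from_sums(sums)
    defined = ~np.isnan(omega_b)
    n_def = int(defined.sum())
    if n_def == 0:
        return None
    ge = int(np.sum(omega_b[defined] >= 1.0))
    le = int(np.sum(omega_b[defined] <= 1.0))
    p = 2.0 * min(ge, le) / n_def
    return min(max(p, 1.0 / n_def), 1.0)


def ng_dnds(aln: Sequence[str],
            domain_id: str = "",
            subfamily_id: str = "",
            replicates: int = 1000,
            seed: int = 0) -> SelectionResult:
    """Nei-Gojobori dN/dS over all sequence pairs of a codon alignment,
    with the bootstrap neutrality test.

    Requires >= 2 sequences sharing >= 30 ungapped codon columns.  When no
    synonymous divergence is observed (dS = 0) omega is undefined and the
    verdict is "undefined".
    """
    if len(aln) < 2:
        raise InsufficientDataError("need at least two sequences")
    stats_arr = pair_codon_stats(aln)
    shared = int(np.min((stats_arr[:, :, 0] + stats_arr[:, :, 1] > 0)
                        .sum(axis=1)))
    if shared < MIN_CODONS:
        raise InsufficientDataError(
            f"only {shared} shared ungapped codons (< {MIN_CODONS})")
    dN, dS, omega = _omega_from_sums(stats_arr.sum(axis=1))
    dN, dS = float(dN), float(dS)
    if not np.isfinite(omega):
        return SelectionResult(domain_id, subfamily_id, dN, dS, None, None,
                               "undefined", stats_arr.shape[1],
                               stats_arr.shape[0])
    p = omega_neutrality_test(aln, replicates=replicates, seed=seed,
                              stats_arr=stats_arr)
    omega = float(omega)
    verdict = "purifying" if (omega < 1.0 and p is not None and p < 0.05) \
        else "neutral_or_relaxed"
    return SelectionResult(domain_id, subfamily_id, dN, dS, omega, p,
                           verdict, stats_arr.shape[1], stats_arr.shape[0])


# ---------------------------------------------------------------------------
# ORF integrity


def poisson_ci(events: int, exposure: float,
               level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a rate.

    Bounds are chi-square quantiles: lower = chi2(alpha/2, 2k)/2,
    upper = chi2(1-alpha/2, 2k+2)/2, divided by the exposure; for k = 0
    the upper bound reduces to -ln(alpha/2)/exposure.
    """
    if events < 0 or exposure <= 0:
        raise ValueError("events must be >= 0 and exposure > 0")
    alpha = 1.0 - level
    lo = 0.0 if events == 0 else \
        stats.chi2.ppf(alpha / 2.0, 2 * events) / 2.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * events + 2) / 2.0
    return lo / exposure, hi / exposure


def _indel_runs(seq_row: str, ref_row: str) -> list[tuple[int, int, int]]:
    """Maximal indel runs between one sequence and the in-frame reference.

    Returns (start_col, end_col, indel_len) for maximal runs of deletion
    columns (sequence gapped where the reference is not) and insertion
    columns (reference gapped where the sequence is not).
    """
    runs = []
    state = None  # None | "del" | "ins"
    start = 0
    for i, (s, r) in enumerate(zip(seq_row, ref_row)):
        if s == "-" and r != "-":
            cur = "del"
        elif s != "-" and r == "-":
            cur = "ins"
        else:
            cur = None
        if cur != state:
            if state is not None:
                runs.append((start, i, i - start, state))
            state = cur
            start = i
    if state is not None:
        runs.append((start, len(seq_row), len(seq_row) - start, state))
    return [(a, b, ln) for a, b, ln, _ in runs]


def integrity(aln: Sequence[str], reference: str,
              domain_id: str = "", subfamily_id: str = "",
              domain_ends_orf: bool = False) -> IntegrityStats:
    """Stop-codon and frameshift frequency per codon against an in-frame
    reference.

    The reference row defines the reading frame (its ungapped length must
    be a multiple of 3).  Per sequence: an in-frame stop codon read at
    fully ungapped reference codon positions is one event (the natural
    terminator of an ORF-ending domain is exempt via
    ``domain_ends_orf``); each maximal indel run whose length is not a
    multiple of 3 is one frameshift event, regardless of length.  The
    frequency denominator is the summed codon exposure (reference codons
    x sequences).
    """
    ref = reference.upper()
    ref_cols = [i for i, ch in enumerate(ref) if ch != "-"]
    if len(ref_cols) % 3:
        raise ValueError("reference frame undeterminable: ungapped length "
                         "not a multiple of 3")
    codon_cols = [tuple(ref_cols[i:i + 3])
                  for i in range(0, len(ref_cols), 3)]
    n_stops = n_fs = 0
    for row in aln:
        row = row.upper()
        if len(row) != len(ref):
            raise ValueError("row length differs from reference")
        for k, cols in enumerate(codon_cols):
            bases = [row[c] for c in cols]
            if "-" in bases:
                continue
            codon = "".join(bases)
            if codon in STOP_CODONS:
                if domain_ends_orf and k == len(codon_cols) - 1:
                    continue
                n_stops += 1
        for _, _, ln in _indel_runs(row, ref):
            if ln % 3:
                n_fs += 1
    exposure = len(codon_cols) * len(aln)
    events = n_stops + n_fs
    return IntegrityStats(domain_id, subfamily_id, exposure, n_stops, n_fs,
                          events / exposure, poisson_ci(events, exposure))


def shared_breakpoints(aln: Sequence[str], reference: str,
                       subfamily_id: str = "",
                       min_deletion_bp: int = 100,
                       tolerance: int = 10) -> list[DeletionBreakpoint]:
    """Cluster large deletions by breakpoint coordinates.

    Deletions are maximal runs of sequence-gap columns spanning at least
    ``min_deletion_bp`` reference bases; two deletions share a breakpoint
    when both endpoints lie within ``tolerance`` columns of the cluster
    anchor (the first member seen).  Only clusters of >= 2 members are
    reported.  Coordinates are alignment columns.
    """
    ref = reference.upper()
    deletions: list[tuple[int, int]] = []
    for row in aln:
        row = row.upper()
        for start, end, _ in _indel_runs(row, ref):
            if row[start] != "-":
                continue  # insertion run
            ref_span = sum(1 for c in range(start, end) if ref[c] != "-")
            if ref_span >= min_deletion_bp:
                deletions.append((start, end))
    clusters: list[list[tuple[int, int]]] = []
    for dele in sorted(deletions):
        for cluster in clusters:
            a0, e0 = cluster[0]
            if abs(dele[0] - a0) <= tolerance and \
                    abs(dele[1] - e0) <= tolerance:
                cluster.append(dele)
                break
        else:
            clusters.append([dele])
    out = []
    for cluster in clusters:
        if len(cluster) >= 2:
            a0, e0 = cluster[0]
            out.append(DeletionBreakpoint(subfamily_id, a0, e0,
                                          len(cluster)))
    return out
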