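"""Two-species synthetic genomes with fully known ERV ground truth.

The generative model mirrors the assumptions under which the pipeline's
statistics are valid, so every stage can be tested against planted truth:

* host background: i.i.d. bases at a chosen GC content, diverging
  neutrally along the two species lineages after the split;
* each insertion places TSD-LTR-internal-LTR-TSD (or a single LTR for a
  solo locus) with the two LTRs identical at integration, the hallmark of
  retroviral integration;
* every sequence then mutates under a per-site Kimura 2-parameter process
  at the host neutral rate; CpG dinucleotides can mutate at a configurable
  multiple of the base rate (context re-evaluated every 0.1 MY step);
* ancestral insertions occupy orthologous positions in both genomes and
  keep mutating independently after the split; lineage-specific
  insertions leave a single-copy pre-insertion site in the other genome;
* gene-conversion events overwrite a tract of one LTR with the other at a
  stated time; envelope deletions remove a stated interval of the
  internal region from affected copies.

No indel process runs in LTRs or host background except these explicit
events, so parameter-recovery experiments are clean tests of the
estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeSeq, Interval, RepeatHit
from .annotate import ErvLocus, MIN_INTERNAL_BP, MAX_INTERNAL_BP

_BASES = "ACGT"
_A, _C, _G, _T = 0, 1, 2, 3
_TRANSITION = np.array([_G, _T, _A, _C], dtype=np.uint8)
# two transversion targets per base
_TRANSVERSION = np.array([[_C, _T], [_A, _G], [_C, _T], [_A, _G]],
                         dtype=np.uint8)

DEFAULT_STEP_YEARS = 1e5  # CpG-context re-evaluation step (0.1 MY)


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, ch in enumerate(_BASES):
        out[arr == ord(ch)] = i
    return out


def decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode()


def random_dna(length: int, gc_content: float,
               rng: np.random.Generator) -> np.ndarray:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return rng.choice(np.arange(4, dtype=np.uint8), size=length,
                      p=[p_at, p_gc, p_gc, p_at])


def _apply_events(arr: np.ndarray, sites: np.ndarray,
                  rng: np.random.Generator, ti_tv: float) -> None:
    """Apply one K2P substitution event at each listed site, in place."""
    if sites.size == 0:
        return
    cur = arr[sites]
    is_ts = rng.random(sites.size) < ti_tv / (ti_tv + 1.0)
    new = np.where(is_ts, _TRANSITION[cur],
                   _TRANSVERSION[cur, rng.integers(0, 2, sites.size)])
    arr[sites] = new.astype(np.uint8)


def mutate_arr(arr: np.ndarray, years: float, rate: float,
               rng: np.random.Generator, ti_tv: float = 2.0,
               cpg_multiplier: float = 1.0,
               step_years: float = DEFAULT_STEP_YEARS) -> np.ndarray:
    """Evolve a sequence for ``years`` under the per-site K2P process.

    With no CpG effect the number of events per site is Poisson(rate x
    years) and events are applied sequentially, so multiple hits (and
    reversions) occur exactly as the distance corrections assume.  With
    ``cpg_multiplier != 1`` the process is discretised into
    ``step_years`` steps; at each step the C and G of every current CpG
    dinucleotide mutate at multiplier x rate.  N sites never mutate.
    """
    arr = arr.copy()
    if years <= 0:
        return arr
    mutable = arr < 4
    if cpg_multiplier == 1.0:
        k = rng.poisson(rate * years, size=arr.size)
        k[~mutable] = 0
        while True:
            sites = np.nonzero(k > 0)[0]
            if sites.size == 0:
                break
            _apply_events(arr, sites, rng, ti_tv)
            k[sites] -= 1
    else:
        n_steps = max(1, math.ceil(years / step_years))
        dt = years / n_steps
        for _ in range(n_steps):
            mult = np.ones(arr.size)
            cpg = (arr[:-1] == _C) & (arr[1:] == _G)
            idx = np.nonzero(cpg)[0]
            mult[idx] = cpg_multiplier
            mult[idx + 1] = cpg_multiplier
            p = rate * dt * mult
            hit = (rng.random(arr.size) < p) & mutable
            _apply_events(arr, np.nonzero(hit)[0], rng, ti_tv)
    return arr


def mutate_sequence(seq: str, years: float, rate: float,
                    rng: np.random.Generator, ti_tv: float = 2.0,
                    cpg_multiplier: float = 1.0,
                    step_years: float = DEFAULT_STEP_YEARS) -> str:
    return decode(mutate_arr(encode(seq), years, rate, rng, ti_tv,
                             cpg_multiplier, step_years))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class InsertionEvent:
    time_years: float
    mode: str = "retrotransposition"  # or "infection"
    lineage: str = "A"  # "ancestral" | "A" | "B"
    kind: Optional[str] = None  # "provirus" | "solo_ltr" | None
    # None: drawn from SimConfig.solo_fraction

    def __post_init__(self):
        if self.time_years < 0:
            raise ValueError("insertion time must be >= 0")
        if self.mode not in ("retrotransposition", "infection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lineage not in ("ancestral", "A", "B"):
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.kind not in (None, "provirus", "solo_ltr"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class ConversionEvent:
    locus_index: int
    lineage: str  # "ancestral" | "A" | "B"
    time_years: float
    tract_fraction: float
    direction: str = "5to3"  # which LTR overwrites which

    def __post_init__(self):
        if not 0.0 < self.tract_fraction <= 1.0:
            raise ValueError("tract_fraction must be in (0, 1]")
        if self.direction not in ("5to3", "3to5"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class EnvDeletion:
    """Removal of consensus interval [start, end) of the internal region
    from the listed loci (mimicking a shared envelope deletion)."""
    start: int
    end: int
    affected_loci: tuple[int, ...]


@dataclass(frozen=True)
class SimConfig:
    seed: int
    genome_len: int
    split_time_years: float
    insertion_events: tuple[InsertionEvent, ...]
    gc_content: float = 0.42
    ltr_len: int = 600
    internal_len: int = 7000
    tsd_len: int = 4
    rate_per_year: float = 2.7e-9
    ti_tv_ratio: float = 2.0
    cpg_multiplier: float = 1.0
    solo_fraction: float = 0.0
    conversion_events: tuple[ConversionEvent, ...] = ()
    env_deletion: Optional[EnvDeletion] = None
    family_id: str = "ERVSIM1"
    min_host_gap: int = MAX_INTERNAL_BP + 1000
    edge_margin: int = 500

    def __post_init__(self):
        if not MIN_INTERNAL_BP <= self.internal_len <= MAX_INTERNAL_BP:
            raise ValueError("internal_len outside the provirus window")
        for ev in self.insertion_events:
            if ev.lineage in ("A", "B") and \
                    ev.time_years >= self.split_time_years:
                raise ValueError(
                    "lineage-specific insertion predates the split")
            if ev.lineage == "ancestral" and \
                    ev.time_years < self.split_time_years:
                raise ValueError("ancestral insertion younger than split")


@dataclass
class SimResult:
    config: SimConfig
    genome_a: list[GenomeSeq]
    genome_b: list[GenomeSeq]
    rm_out_a: list[RepeatHit]
    rm_out_b: list[RepeatHit]
    loci_a: list[ErvLocus]
    loci_b: list[ErvLocus]
    truth: pd.DataFrame
    ltr_consensus: str
    internal_consensus: str


# ---------------------------------------------------------------------------
# per-locus element evolution


@dataclass
class _ElementState:
    ltr5: np.ndarray
    ltr3: Optional[np.ndarray]  # None for solo loci
    internal: Optional[np.ndarray]

    def copy(self) -> "_ElementState":
        return _ElementState(
            self.ltr5.copy(),
            None if self.ltr3 is None else self.ltr3.copy(),
            None if self.internal is None else self.internal.copy())

    def concat(self) -> np.ndarray:
        if self.ltr3 is None:
            return self.ltr5
        return np.concatenate([self.ltr5, self.internal, self.ltr3])


def _apply_conversion(state: _ElementState, ev: ConversionEvent,
                      rng: np.random.Generator) -> None:
    if state.ltr3 is None:
        return  # solo locus: nothing to convert
    n = state.ltr5.size
    tract = max(1, round(ev.tract_fraction * n))
    start = 0 if tract >= n else int(rng.integers(0, n - tract + 1))
    if ev.direction == "5to3":
        state.ltr3[start:start + tract] = state.ltr5[start:start + tract]
    else:
        state.ltr5[start:start + tract] = state.ltr3[start:start + tract]


def _evolve_phase(state: _ElementState, t_from: float, t_to: float,
                  conversions: Sequence[ConversionEvent],
                  cfg: SimConfig, rng: np.random.Generator) -> None:
    """Mutate an element from ``t_from`` back to ``t_to`` (years before
    present, t_from > t_to), applying conversions at their stated times."""

    def mut(t0: float, t1: float):
        if t0 <= t1:
            return
        for name in ("ltr5", "ltr3", "internal"):
            arr = getattr(state, name)
            if arr is not None:
                setattr(state, name,
                        mutate_arr(arr, t0 - t1, cfg.rate_per_year, rng,
                                   cfg.ti_tv_ratio, cfg.cpg_multiplier))

    t = t_from
    for ev in sorted(conversions, key=lambda e: -e.time_years):
        if not t_to <= ev.time_years <= t_from:
            raise ValueError(
                f"conversion at {ev.time_years} outside phase "
                f"[{t_to}, {t_from}]")
        mut(t, ev.time_years)
        _apply_conversion(state, ev, rng)
        t = ev.time_years
    mut(t, t_to)


# ---------------------------------------------------------------------------
# simulate


def _draw_positions(n: int, cfg: SimConfig, max_elem: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Site positions in ancestral coordinates with a guaranteed minimum
    separation, so no two elements can be mistaken for one provirus and
    every flank probe is element-free."""
    min_sep = max_elem + cfg.min_host_gap
    usable = cfg.genome_len - 2 * cfg.edge_margin - max_elem
    slack = usable - n * min_sep
    if slack <= 0:
        raise ValueError(
            f"genome_len {cfg.genome_len} too small for {n} insertions "
            f"(needs > {n * min_sep + 2 * cfg.edge_margin + max_elem})")
    extra = np.sort(rng.uniform(0, slack, size=n))
    return (cfg.edge_margin + extra
            + min_sep * np.arange(n)).astype(np.int64)


def simulate(config: SimConfig) -> SimResult:
    """Generate the two genomes, repeat tables and the truth ledger."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ltr0 = random_dna(cfg.ltr_len, cfg.gc_content, rng)
    internal0 = random_dna(cfg.internal_len, cfg.gc_content, rng)
    events = list(cfg.insertion_events)
    n = len(events)

    max_elem = cfg.internal_len + 2 * cfg.ltr_len
    positions = _draw_positions(n, cfg, max_elem, rng)
    order = rng.permutation(n)  # random assignment of events to positions
    solo_draw = rng.random(n) < cfg.solo_fraction
    solo = np.array([
        events[order[k]].kind == "solo_ltr" if events[order[k]].kind
        else solo_draw[k] for k in range(n)])
    conv_by_locus: dict[int, list[ConversionEvent]] = {}
    for ev in cfg.conversion_events:
        if not 0 <= ev.locus_index < n:
            raise ValueError(f"conversion references locus {ev.locus_index}"
                             f" of {n}")
        conv_by_locus.setdefault(ev.locus_index, []).append(ev)
    env_affected = set(cfg.env_deletion.affected_loci) \
        if cfg.env_deletion else set()

    # evolve each element to its present-day state in each lineage
    loci_meta = []
    for k in range(n):
        ev = events[order[k]]
        idx = order[k]  # index in the event list = locus index for config
        convs = conv_by_locus.get(idx, [])
        internal = internal0.copy()
        if idx in env_affected:
            d = cfg.env_deletion
            internal = np.concatenate([internal[:d.start], internal[d.end:]])
        if solo[k]:
            state = _ElementState(ltr0.copy(), None, None)
        else:
            state = _ElementState(ltr0.copy(), ltr0.copy(), internal)
        states: dict[str, Optional[np.ndarray]] = {"A": None, "B": None}
        if ev.lineage == "ancestral":
            anc = [c for c in convs if c.lineage == "ancestral"]
            _evolve_phase(state, ev.time_years, cfg.split_time_years,
                          anc, cfg, rng)
            for lin in ("A", "B"):
                st = state.copy()
                _evolve_phase(st, cfg.split_time_years, 0.0,
                              [c for c in convs if c.lineage == lin],
                              cfg, rng)
                states[lin] = st.concat()
        else:
            lin_convs = [c for c in convs if c.lineage == ev.lineage]
            _evolve_phase(state, ev.time_years, 0.0, lin_convs, cfg, rng)
            states[ev.lineage] = state.concat()
        loci_meta.append({
            "locus_index": idx, "position": int(positions[k]),
            "event": ev, "solo": bool(solo[k]),
            "converted": bool(convs), "env_deleted": idx in env_affected,
            "elem_a": states["A"], "elem_b": states["B"]})

    # host backbone diverges after the split
    background = random_dna(cfg.genome_len, cfg.gc_content, rng)
    backbones = {
        lin: mutate_arr(background, cfg.split_time_years, cfg.rate_per_year,
                        rng, cfg.ti_tv_ratio, cfg.cpg_multiplier)
        for lin in ("A", "B")}

    genomes: dict[str, list[GenomeSeq]] = {}
    rm_out: dict[str, list[RepeatHit]] = {"A": [], "B": []}
    loci: dict[str, list[ErvLocus]] = {"A": [], "B": []}
    coords: dict[str, dict[int, tuple[int, int]]] = {"A": {}, "B": {}}
    site_map: dict[str, dict[int, int]] = {"A": {}, "B": {}}
    contig = "contig_1"

    for lin in ("A", "B"):
        bg = backbones[lin]
        parts: list[np.ndarray] = []
        prev = 0
        total = 0
        for meta in loci_meta:
            elem = meta[f"elem_{lin.lower()}"]
            pos = meta["position"]
            if elem is None:
                # record where the single-copy pre-insertion site lands
                site_map[lin][meta["locus_index"]] = None  # fill below
                continue
            left = bg[prev:pos + cfg.tsd_len]
            parts.append(left)
            total += left.size
            start = total
            parts.append(elem)
            total += elem.size
            coords[lin][meta["locus_index"]] = (start, start + elem.size)
            prev = pos
        parts.append(bg[prev:])
        seq = np.concatenate(parts) if parts else bg
        genomes[lin] = [GenomeSeq(contig, decode(seq))]

        # map ancestral coordinates of absent loci to this genome
        present = sorted(
            (m["position"], m[f"elem_{lin.lower()}"].size)
            for m in loci_meta if m[f"elem_{lin.lower()}"] is not None)
        for meta in loci_meta:
            if meta[f"elem_{lin.lower()}"] is not None:
                continue
            pos = meta["position"]
            shift = sum(cfg.tsd_len + size for p, size in present if p < pos)
            site_map[lin][meta["locus_index"]] = pos + shift

    # classified truth loci + repeat hits
    truth_rows = []
    ltr_fam = f"{cfg.family_id}-LTR"
    int_fam = f"{cfg.family_id}-int"
    for meta in sorted(loci_meta, key=lambda m: m["position"]):
        idx = meta["locus_index"]
        ev = meta["event"]
        locus_id = f"L{idx:04d}"
        row = {
            "locus_id": locus_id, "lineage": ev.lineage, "mode": ev.mode,
            "kind": "solo_ltr" if meta["solo"] else "provirus",
            "true_age_years": ev.time_years,
            "orthologous": ev.lineage == "ancestral",
            "converted": meta["converted"],
            "env_deleted": meta["env_deleted"],
        }
        for lin in ("A", "B"):
            gseq = genomes[lin][0].sequence
            key = lin.lower()
            if idx in coords[lin]:
                start, end = coords[lin][idx]
                row[f"present_{key}"] = True
                row[f"start_{key}"], row[f"end_{key}"] = start, end
                row[f"tsd_{key}"] = gseq[start - cfg.tsd_len:start]
                internal_len = (end - start) - 2 * cfg.ltr_len
                if meta["solo"]:
                    iv = Interval(contig, start, end, "+")
                    loci[lin].append(ErvLocus(
                        f"{locus_id}_{lin}", "solo_ltr", iv, cfg.family_id,
                        ltr5=iv))
                    rm_out[lin].append(RepeatHit(
                        2000.0, iv, ltr_fam, 1, cfg.ltr_len, 0))
                else:
                    iv5 = Interval(contig, start, start + cfg.ltr_len, "+")
                    iv3 = Interval(contig, end - cfg.ltr_len, end, "+")
                    extent = Interval(contig, start, end, "+")
                    loci[lin].append(ErvLocus(
                        f"{locus_id}_{lin}", "provirus", extent,
                        cfg.family_id, ltr5=iv5, ltr3=iv3,
                        internal_gap_bp=iv3.start - iv5.end))
                    rm_out[lin].append(RepeatHit(
                        2000.0, iv5, ltr_fam, 1, cfg.ltr_len, 0))
                    rm_out[lin].append(RepeatHit(
                        1500.0,
                        Interval(contig, iv5.end, iv3.start, "+"),
                        int_fam, 1, internal_len,
                        max(cfg.internal_len - internal_len, 0)))
                    rm_out[lin].append(RepeatHit(
                        2000.0, iv3, ltr_fam, 1, cfg.ltr_len, 0))
            else:
                site = site_map[lin][idx]
                row[f"present_{key}"] = False
                row[f"start_{key}"] = site
                row[f"end_{key}"] = site + cfg.tsd_len
                row[f"tsd_{key}"] = gseq[site:site + cfg.tsd_len]
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return SimResult(cfg, genomes["A"], genomes["B"],
                     rm_out["A"], rm_out["B"], loci["A"], loci["B"],
                     truth, decode(ltr0), decode(internal0))


# ---------------------------------------------------------------------------
# targeted generators for single-stage experiments


def simulate_ltr_pair(age_years: float, rng: np.random.Generator,
                      ltr_len: int = 1000, rate: float = 2.7e-9,
                      ti_tv: float = 2.0, cpg_multiplier: float = 1.0,
                      gc_content: float = 0.5) -> tuple[str, str]:
    """One provirus's LTR pair: identical at integration, then each LTR
    mutates independently for ``age_years``."""
    anc = random_dna(ltr_len, gc_content, rng)
    l5 = mutate_arr(anc, age_years, rate, rng, ti_tv, cpg_multiplier)
    l3 = mutate_arr(anc, age_years, rate, rng, ti_tv, cpg_multiplier)
    return decode(l5), decode(l3)


def simulate_quartet(rng: np.random.Generator,
                     insertion_years: float = 16e6,
                     split_years: float = 10e6,
                     conversion: Optional[tuple[float, float]] = None,
                     conversion_lineages: str = "both",
                     ltr_len: int = 600, rate: float = 2.7e-9,
                     ti_tv: float = 2.0,
                     gc_content: float = 0.5):
    """LTR quartet of a provirus orthologous in two species.

    ``conversion`` = (time_years, tract_fraction) applies a 5'->3'
    conversion at that time in the lineages named by
    ``conversion_lineages`` ("both", "a" or "b"); None gives the
    no-conversion speciation signal.  Returns (QuartetCase, converted
    flag).
    """
    from .conversion import QuartetCase

    anc = random_dna(ltr_len, gc_content, rng)

    def mut(arr, years):
        return mutate_arr(arr, years, rate, rng, ti_tv)

    # ancestor: LTRs diverge from insertion to the split
    l5 = mut(anc, insertion_years - split_years)
    l3 = mut(anc, insertion_years - split_years)
    out = {}
    for lin in ("a", "b"):
        if conversion is None or \
                (conversion_lineages != "both"
                 and lin != conversion_lineages):
            out[f"ltr5_{lin}"] = decode(mut(l5, split_years))
            out[f"ltr3_{lin}"] = decode(mut(l3, split_years))
        else:
            t_c, frac = conversion
            b5 = mut(l5, split_years - t_c)
            b3 = mut(l3, split_years - t_c)
            tract = max(1, round(frac * ltr_len))
            start = 0 if tract >= ltr_len else \
                int(rng.integers(0, ltr_len - tract + 1))
            b3 = b3.copy()
            b3[start:start + tract] = b5[start:start + tract]
            out[f"ltr5_{lin}"] = decode(mut(b5, t_c))
            out[f"ltr3_{lin}"] = decode(mut(b3, t_c))
    outgroup = decode(mut(anc, 2 * insertion_years))
    case = QuartetCase("Q", out["ltr5_a"], out["ltr3_a"],
                       out["ltr5_b"], out["ltr3_b"], outgroup)
    return case, conversion is not None


_SENSE = None


def _sense_codons() -> list[str]:
    global _SENSE
    if _SENSE is None:
        from .selection import SENSE_CODONS
        _SENSE = list(SENSE_CODONS)
    return _SENSE


def simulate_codon_alignment(rng: np.random.Generator,
                             n_seqs: int = 10, n_codons: int = 300,
                             omega: float = 1.0,
                             branch_sub_rate: float = 0.08) -> list[str]:
    """Codon alignment evolved on a star tree under a counting-friendly
    codon model.

    From a random sense-codon ancestor, each tip receives
    Poisson(branch_sub_rate x sites) proposed single-base changes at
    uniformly chosen sites with a uniform alternative base; proposals
    creating stop codons are discarded, nonsynonymous proposals are
    accepted with probability ``omega``, synonymous ones always - so the
    instantaneous dN/dS of the generating process is exactly ``omega``.
    """
    from .selection import STOP_CODONS, _AA

    sense = _sense_codons()
    anc = [str(rng.choice(sense)) for _ in range(n_codons)]
    seqs = []
    n_sites = 3 * n_codons
    for _ in range(n_seqs):
        seq = list(anc)  # list of codons
        n_prop = rng.poisson(branch_sub_rate * n_sites)
        for _ in range(n_prop):
            site = int(rng.integers(0, n_sites))
            ci, pos = divmod(site, 3)
            codon = seq[ci]
            alts = [b for b in _BASES if b != codon[pos]]
            new_codon = codon[:pos] + alts[int(rng.integers(0, 3))] + \
                codon[pos + 1:]
            if new_codon in STOP_CODONS:
                continue
            if _AA[new_codon] != _AA[codon] and rng.random() >= omega:
                continue
            seq[ci] = new_codon
        seqs.append("".join(seq))
    return seqs


def simulate_integrity_family(rng: np.random.Generator,
                              n_seqs: int = 20, n_codons: int = 200,
                              n_stops: int = 0, n_frameshifts: int = 0
                              ) -> tuple[list[str], str, int, int]:
    """Aligned domain copies with planted ORF disruptions.

    Stops replace random codons with TAA/TAG/TGA; frameshifts are
    deletion runs of length 1, 2 or 4 (never a multiple of 3).  Events are
    spread over random sequences.  Returns (rows, reference, planted
    stops, planted frameshifts).
    """
    sense = _sense_codons()
    ref = "".join(rng.choice(sense) for _ in range(n_codons))
    rows = [list(ref) for _ in range(n_seqs)]
    stops = ["TAA", "TAG", "TGA"]
    used: set[tuple[int, int]] = set()
    for _ in range(n_stops):
        while True:
            s = int(rng.integers(0, n_seqs))
            c = int(rng.integers(0, n_codons))
            if (s, c) not in used:
                used.add((s, c))
                break
        rows[s][3 * c:3 * c + 3] = list(stops[int(rng.integers(0, 3))])
    for _ in range(n_frameshifts):
        ln = int(rng.choice([1, 2, 4]))
        while True:
            s = int(rng.integers(0, n_seqs))
            c = int(rng.integers(0, n_codons - 2))
            if all((s, c + d) not in used for d in range(3)):
                for d in range(3):
                    used.add((s, c + d))
                break
        start = 3 * c
        rows[s][start:start + ln] = ["-"] * ln
    return ["".join(r) for r in rows], ref, n_stops, n_frameshifts


def simulate_env_deletion_family(rng: np.random.Generator,
                                 n_members: int = 43, n_deleted: int = 29,
                                 domain_len: int = 1800,
                                 del_start: int = 300, del_end: int = 1500,
                                 second_breakpoint: Optional[
                                     tuple[int, int, int]] = None
                                 ) -> tuple[list[str], str]:
    """Family alignment in which ``n_deleted`` members share one identical
    envelope deletion (same breakpoints) and the rest are full length.

    ``second_breakpoint`` = (start, end, n) optionally adds a second
    deletion lineage.  Returns (rows, reference).
    """
    ref = decode(random_dna(domain_len, 0.45, rng))
    rows = []
    second = second_breakpoint or (0, 0, 0)
    for i in range(n_members):
        row = list(ref)
        if i < n_deleted:
            row[del_start:del_end] = ["-"] * (del_end - del_start)
        elif i < n_deleted + second[2]:
            row[second[0]:second[1]] = ["-"] * (second[1] - second[0])
        rows.append("".join(row))
    return rows, ref


def degrade_rm_out(hits: Sequence[RepeatHit],
                   frag_prob: float = 0.0,
                   end_loss_dist: Optional[
                       Callable[[np.random.Generator],
                                tuple[int, int]]] = None,
                   seed: int = 0) -> list[RepeatHit]:
    """Stress a clean hit table the way real repeat annotation degrades.

    Each hit is independently fragmented into two rows (with probability
    ``frag_prob``, split at a random internal point) and/or truncated at
    its consensus termini by ``end_loss_dist(rng) -> (loss5, loss3)``
    bases.  Deterministic per seed; ``frag_prob=0`` with no loss
    distribution is the identity.
    """
    rng = np.random.default_rng(seed)
    out: list[RepeatHit] = []
    for h in hits:
        iv = h.genome_iv
        loss5, loss3 = end_loss_dist(rng) if end_loss_dist else (0, 0)
        span = h.cons_end - h.cons_start + 1
        loss5 = min(loss5, span - 1)
        loss3 = min(loss3, span - 1 - loss5)
        cons_start = h.cons_start + loss5
        cons_end = h.cons_end - loss3
        if iv.strand == "+":
            g_start, g_end = iv.start + loss5, iv.end - loss3
        else:
            g_start, g_end = iv.start + loss3, iv.end - loss5
        base = RepeatHit(h.score, Interval(iv.contig_id, g_start, g_end,
                                           iv.strand),
                         h.family_id, cons_start, cons_end,
                         h.cons_left + loss3)
        if frag_prob > 0 and rng.random() < frag_prob and \
                (g_end - g_start) > 60:
            cut = int(rng.integers(20, g_end - g_start - 20))
            c_cut = base.cons_start + cut
            out.append(RepeatHit(
                base.score,
                Interval(iv.contig_id, g_start, g_start + cut, iv.strand),
                h.family_id, base.cons_start, c_cut - 1,
                base.consensus_len - (c_cut - 1)))
            out.append(RepeatHit(
                base.score,
                Interval(iv.contig_id, g_start + cut, g_end, iv.strand),
                h.family_id, c_cut, base.cons_end, base.cons_left))
        else:
            out.append(base)
    return out
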