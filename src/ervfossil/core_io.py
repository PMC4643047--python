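"""Flat-file I/O and the shared coordinate model.

Every coordinate held in memory is 0-based, half-open, on the forward
strand.  Conversions to and from the 1-based inclusive conventions of
RepeatMasker ``.out`` tables and BLAST tabular output happen here, at the
I/O boundary, and nowhere else.  BED already matches the internal
convention and is written verbatim.

The one deliberate exception is the *consensus* coordinate pair carried by
:class:`RepeatHit` (``cons_start``/``cons_end``), which stays 1-based
inclusive as in the source dialect because the solo-LTR completeness rule
is stated in those terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: characters accepted in a genome sequence; everything else becomes N
DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSeq:
    """One contig of a genome assembly, uppercased, alphabet {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatHit:
    """One row of a repeat-annotation table.

    ``cons_start``/``cons_end`` are 1-based inclusive positions on the
    repeat consensus, normalised so that ``cons_start <= cons_end``
    regardless of genomic strand; ``cons_left`` is the number of consensus
    bases beyond ``cons_end`` (so ``cons_end + cons_left`` is the
    consensus length).
    """

    score: float
    genome_iv: Interval
    family_id: str
    cons_start: int
    cons_end: int
    cons_left: int

    def __post_init__(self):
        if self.cons_start > self.cons_end:
            raise ValueError("cons_start > cons_end after normalisation")
        if self.cons_left < 0:
            raise ValueError("negative cons_left")

    @property
    def consensus_len(self) -> int:
        return self.cons_end + self.cons_left


@dataclass(frozen=True)
class SearchHit:
    """One row of a tabular homology search (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_iv: Interval
    pct_identity: float  # fraction in [0, 1]
    aln_len: int
    evalue: float
    bitscore: float = 0.0
    q_start: int = 0  # 0-based half-open on the query
    q_end: int = 0

    def __post_init__(self):
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.pct_identity <= 1.0:
            raise ValueError("pct_identity must be a fraction in [0,1]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, aligned: bool = False) -> list[GenomeSeq]:
    """Read a FASTA file into :class:`GenomeSeq` records.

    Sequences are uppercased; characters outside {A,C,G,T,N} (IUPAC
    ambiguity codes, ...) are mapped to N and the total count is logged,
    because WGS assemblies routinely contain them and downstream
    statistics simply skip N sites.  With ``aligned=True`` the gap
    character '-' is preserved (alignment FASTA).
    """
    keep = DNA_ALPHABET | {"-"} if aligned else DNA_ALPHABET
    path = Path(path)
    text = path.read_text()
    records: list[GenomeSeq] = []
    name: str | None = None
    chunks: list[str] = []
    n_mapped = 0
    seen: set[str] = set()

    def flush(line_no: int):
        nonlocal n_mapped
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}: record {name!r} has no sequence "
                             f"(line {line_no})")
        cleaned = []
        for ch in seq:
            if ch in keep:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_mapped += 1
        records.append(GenomeSeq(name, "".join(cleaned)))

    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise ParseError(f"{path}: empty FASTA header at line {i}")
            if name in seen:
                raise ParseError(f"{path}: duplicate contig id {name!r} "
                                 f"at line {i}")
            seen.add(name)
            chunks = []
        else:
            if name is None:
                raise ParseError(
                    f"{path}: line {i} precedes any FASTA header")
            chunks.append(line)
    flush(-1)
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    if n_mapped:
        log.warning("%s: %d non-ACGTN characters mapped to N", path, n_mapped)
    return records


def write_fasta(seqs: Iterable[GenomeSeq], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def genome_dict(seqs: Iterable[GenomeSeq]) -> dict[str, str]:
    return {s.contig_id: s.sequence for s in seqs}


def extract(genome: dict[str, str], iv: Interval, oriented: bool = True) -> str:
    """Sequence of an interval; reverse-complemented for '-' when oriented."""
    seq = genome[iv.contig_id][iv.start:iv.end]
    if oriented and iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` hit table.

    Header lines (anything before the first row whose leading token is
    numeric) are skipped.  Minus-strand rows give the consensus position
    triple as ``(left) end begin``; it is normalised here so that
    ``cons_start <= cons_end`` always holds.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tok = line.split()
            if not tok[0].replace(".", "").isdigit():
                continue  # header
            if len(tok) < 14:
                raise ParseError(
                    f"{path}: line {line_no}: expected >=14 columns, "
                    f"got {len(tok)}")
            score = float(tok[0])
            contig, qbegin, qend = tok[4], int(tok[5]), int(tok[6])
            strand = "-" if tok[8] in ("C", "-") else "+"
            family = tok[9]
            if strand == "+":
                r1, r2, r3 = tok[11], tok[12], tok[13]
                cons_start, cons_end = int(r1), int(r2)
                cons_left = int(r3.strip("()"))
            else:
                r1, r2, r3 = tok[11], tok[12], tok[13]
                cons_left = int(r1.strip("()"))
                cons_end, cons_start = int(r2), int(r3)
            iv = Interval(contig, qbegin - 1, qend, strand)
            hits.append(RepeatHit(score, iv, family,
                                  cons_start, cons_end, cons_left))
    return hits


def write_repeatmasker_out(hits: Sequence[RepeatHit], path) -> None:
    """Write hits back out in the ``.out`` dialect (for fixtures and the
    simulator; divergence columns are filled with zeros)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, start=1):
            iv = h.genome_iv
            if iv.strand == "+":
                rcols = f"{h.cons_start} {h.cons_end} ({h.cons_left})"
                strand = "+"
            else:
                rcols = f"({h.cons_left}) {h.cons_end} {h.cons_start}"
                strand = "C"
            fh.write(
                f"{h.score:.0f} 0.0 0.0 0.0 {iv.contig_id} "
                f"{iv.start + 1} {iv.end} (0) {strand} {h.family_id} "
                f"LTR/ERV1 {rcols} {i}\n")


# ---------------------------------------------------------------------------
# BED6


def write_bed(loci, path) -> None:
    """Write classified loci as BED6 (0-based half-open, like internal
    coordinates).  Accepts anything with ``locus_id`` and ``extent``."""
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.extent
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t"
                     f"{locus.locus_id}\t0\t{iv.strand}\n")


def read_bed(path) -> list[tuple[Interval, str]]:
    """Read BED6 (or BED4+) into (interval, name) pairs."""
    out: list[tuple[Interval, str]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split("\t")
            if len(tok) < 4:
                raise ParseError(f"{path}: line {line_no}: expected >=4 "
                                 "BED columns")
            strand = tok[5] if len(tok) >= 6 else "+"
            out.append((Interval(tok[0], int(tok[1]), int(tok[2]), strand),
                        tok[3]))
    return out


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)


def read_blast_tab(path) -> list[SearchHit]:
    """Read BLAST tabular output (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    ``sstart > send`` denotes a minus-strand subject alignment; the
    interval is flipped to forward-strand 0-based half-open and the strand
    recorded.  ``pident`` is converted from percent to a fraction.
    """
    hits: list[SearchHit] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")
            if len(tok) < 12:
                raise ParseError(
                    f"{path}: line {line_no}: expected 12 columns, "
                    f"got {len(tok)}")
            qid, sid = tok[0], tok[1]
            pident = float(tok[2]) / 100.0
            length = int(tok[3])
            qstart, qend = int(tok[6]), int(tok[7])
            sstart, send = int(tok[8]), int(tok[9])
            if sstart <= send:
                iv = Interval(sid, sstart - 1, send, "+")
            else:
                iv = Interval(sid, send - 1, sstart, "-")
            hits.append(SearchHit(qid, iv, pident, length,
                                  float(tok[10]), float(tok[11]),
                                  q_start=qstart - 1, q_end=qend))
    return hits
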