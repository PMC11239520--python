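"""5'RACE long-read TSS pipeline.

Retains uniquely-mapped primary reads carrying the L1-specific primer at
one terminus and the 5'RACE universal primer at the other, assigns them to
overlapped full-length L1 loci whose body contains the alignment's 3'
terminus, records the 5' terminus as the putative TSS (categorized as
upstream / 5'UTR / body), and summarizes the full-length (>6 kbp) mRNA
fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import RetroElement, revcomp

log = logging.getLogger(__name__)

FULL_LENGTH_MRNA_BP = 6000
DEFAULT_UPSTREAM_WINDOW = 1000
DEFAULT_TERMINAL_SEARCH_BP = 40
DEFAULT_MAX_MISMATCH = 2

CATEGORIES = ("upstream", "utr5", "body")


@dataclass
class Alignment:
    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]  # sorted, non-overlapping, genome coords
    score: float
    primary: bool
    n_best: int

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class RaceRead:
    read_id: str
    sequence: str
    alignment: Alignment
    l1_primer_at_terminus: bool = False
    universal_primer_at_terminus: bool = False


@dataclass
class TssCall:
    read_id: str
    element_id: str
    tss_pos: int
    category: str
    transcript_len: int

    @property
    def full_length(self) -> bool:
        return self.transcript_len > FULL_LENGTH_MRNA_BP


def read_block_table(path: str | Path) -> list[Alignment]:
    """Block-table TSV: read_id, chrom, strand, blocks, score, primary, n_best.

    ``blocks`` is comma-separated ``start-end`` half-open intervals.
    """
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        blocks = [tuple(map(int, b.split("-"))) for b in str(row.blocks).split(",")]
        out.append(Alignment(
            read_id=row.read_id, chrom=row.chrom, strand=row.strand,
            blocks=blocks, score=float(row.score), primary=bool(row.primary),
            n_best=int(row.n_best)))
    return out


def read_bam_alignments(path: str | Path) -> list[Alignment]:
    """Spliced alignments from BAM/SAM (M/=/X/D/N consume reference).

    Unique placement is inferred from NH (if present) else from secondary
    flags sharing the read name at the primary's alignment score.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    out = []
    best_scores: dict[str, list[float]] = {}
    records = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                log.info("read %s unaligned, dropped", rec.query_name)
                continue
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0
            best_scores.setdefault(rec.query_name, []).append(score)
            records.append((rec.query_name, rec.reference_name,
                            "-" if rec.is_reverse else "+",
                            rec.get_blocks(), score,
                            not (rec.is_secondary or rec.is_supplementary),
                            rec.get_tag("NH") if rec.has_tag("NH") else None))
    for name, chrom, strand, blocks, score, primary, nh in records:
        if not primary:
            continue
        if nh is not None:
            n_best = int(nh)
        else:
            n_best = sum(1 for s in best_scores[name] if s >= score)
        merged = _merge_adjacent(blocks)
        out.append(Alignment(read_id=name, chrom=chrom, strand=strand,
                             blocks=merged, score=score, primary=True,
                             n_best=n_best))
    return out


def _merge_adjacent(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def _primer_in_window(window: str, primer: str, max_mismatch: int) -> bool:
    primer = primer.upper()
    for probe in (primer, revcomp(primer)):
        L = len(probe)
        for off in range(0, max(0, len(window) - L) + 1):
            seg = window[off:off + L]
            if len(seg) < L:
                break
            mism = sum(x != y for x, y in zip(seg, probe))
            if mism <= max_mismatch:
                return True
    return False


def filter_race_reads(
    sequences: Mapping[str, str],
    alignments: Iterable[Alignment],
    l1_primer: str,
    universal_primer: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    terminal_bp: int = DEFAULT_TERMINAL_SEARCH_BP,
) -> list[RaceRead]:
    """Unique-primary, dual-primer read retention.

    A read survives iff its alignment is primary with a single best
    placement, and the L1-specific primer matches one read terminus while
    the universal primer matches the other (either orientation, at most
    ``max_mismatch`` mismatches, searched within the terminal
    ``terminal_bp`` nucleotides).
    """
    if not (10 <= len(l1_primer) <= 40 and 10 <= len(universal_primer) <= 40):
        raise ValueError("primer lengths outside plausible range")
    retained = []
    for aln in alignments:
        if not aln.primary or aln.n_best != 1:
            continue
        seq = sequences.get(aln.read_id)
        if seq is None:
            log.info("read %s has alignment but no sequence, dropped", aln.read_id)
            continue
        seq = seq.upper()
        head, tail = seq[:terminal_bp], seq[-terminal_bp:]
        l1_head = _primer_in_window(head, l1_primer, max_mismatch)
        l1_tail = _primer_in_window(tail, l1_primer, max_mismatch)
        uni_head = _primer_in_window(head, universal_primer, max_mismatch)
        uni_tail = _primer_in_window(tail, universal_primer, max_mismatch)
        ok = (l1_head and uni_tail) or (l1_tail and uni_head)
        if ok:
            retained.append(RaceRead(
                read_id=aln.read_id, sequence=seq, alignment=aln,
                l1_primer_at_terminus=True, universal_primer_at_terminus=True))
    return retained


def _oriented_termini(aln: Alignment, element_strand: str) -> tuple[int, int]:
    """(5' terminus, 3' terminus) of the alignment on the element strand."""
    lo, hi = aln.span
    if element_strand == "+":
        return lo, hi - 1
    return hi - 1, lo


def assign_tss(
    read: RaceRead,
    elements: Sequence[RetroElement],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> TssCall | None:
    """Assign a retained read to a full-length L1 whose body contains its
    3' terminus; record the 5' terminus as the TSS.

    Category: ``upstream`` if the TSS lies 5' of the element within
    ``upstream_window``; ``utr5`` if inside the element 5'UTR; ``body`` if
    inside the element downstream of the 5'UTR.  Reads overlapping two
    qualifying elements go to the one containing the 3' terminus; ties are
    unassigned.
    """
    aln = read.alignment
    lo, hi = aln.span
    candidates = []
    for el in elements:
        if not (el.full_length and el.superfamily == "L1"):
            continue
        if el.chrom != aln.chrom:
            continue
        if hi <= el.start or lo >= el.end:
            continue
        _tss, three_prime = _oriented_termini(aln, el.strand)
        if el.start <= three_prime < el.end:
            candidates.append(el)
    if not candidates:
        return None
    if len(candidates) > 1:
        log.info("read %s 3' terminus inside %d elements, unassigned",
                 read.read_id, len(candidates))
        return None
    el = candidates[0]
    tss, _ = _oriented_termini(aln, el.strand)
    category = _categorize_tss(tss, el, upstream_window)
    if category is None:
        return None
    return TssCall(read_id=read.read_id, element_id=el.element_id,
                   tss_pos=tss, category=category,
                   transcript_len=aln.aligned_length)


def _categorize_tss(tss: int, el: RetroElement, upstream_window: int) -> str | None:
    if el.strand == "+":
        upstream = el.start - upstream_window <= tss < el.start
    else:
        upstream = el.end <= tss < el.end + upstream_window
    if upstream:
        return "upstream"
    if el.utr5 and el.utr5[0] <= tss < el.utr5[1]:
        return "utr5"
    if el.start <= tss < el.end:
        return "body"
    return None


def assign_all(
    reads: Iterable[RaceRead],
    elements: Sequence[RetroElement],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[TssCall]:
    calls = []
    for read in reads:
        call = assign_tss(read, elements, upstream_window)
        if call is not None:
            calls.append(call)
    return calls


def summarize_tss(calls: Sequence[TssCall]) -> dict[str, float]:
    """Category fractions and full-length (>6 kbp) mRNA fraction."""
    if not calls:
        raise ValueError("no TSS calls to summarize")
    n = len(calls)
    summary = {f"frac_{cat}": sum(c.category == cat for c in calls) / n
               for cat in CATEGORIES}
    summary["frac_full_length"] = sum(c.full_length for c in calls) / n
    summary["n_calls"] = n
    return summary


def tss_calls_frame(calls: Iterable[TssCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.read_id, c.element_id, c.tss_pos, c.category, c.transcript_len,
          c.full_length) for c in calls],
        columns=["read_id", "element_id", "tss_pos", "category",
                 "transcript_len", "full_length"])
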