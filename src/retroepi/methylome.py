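"""Per-CpG methylation call aggregation and locus-level differential methylation.

Consumes nanopolish-style per-read per-CpG log-likelihood-ratio calls,
aggregates them over genome bins or element 5'UTRs (ambiguous calls
excluded, primary alignments only), and calls per-locus differential
methylation between two cell populations with a two-sided Fisher exact
test and Bonferroni correction (significance: corrected P < 0.01).
Coverage filter: every compared population needs >= 4 reads and >= 20
non-ambiguous calls per element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .annotate import RetroElement, extract_cpg_sites, GenomeIndex

log = logging.getLogger(__name__)

DEFAULT_LLR_THRESHOLD = 2.0
DEFAULT_MIN_READS = 4
DEFAULT_MIN_CALLS = 20
DEFAULT_ALPHA = 0.01

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"

NANOPOLISH_COLUMNS = [
    "chromosome", "strand", "start", "end", "read_name", "log_lik_ratio",
    "log_lik_methylated", "log_lik_unmethylated", "num_calling_strands",
    "num_motifs", "sequence",
]
SIMPLE_COLUMNS = ["read_id", "chrom", "pos", "llr", "primary"]


@dataclass(frozen=True)
class MethCall:
    read_id: str
    chrom: str
    pos: int  # forward-strand CpG position
    llr: float
    state: str
    population: str
    primary: bool = True


@dataclass
class SegmentMethylation:
    segment_id: str
    population: str
    n_reads: int
    n_calls: int
    n_meth: int
    n_unmeth: int

    @property
    def fraction(self) -> float:
        return self.n_meth / self.n_calls if self.n_calls else float("nan")


@dataclass
class DMResult:
    element_id: str
    n_meth_a: int
    n_unmeth_a: int
    n_meth_b: int
    n_unmeth_b: int
    p: float
    p_adj: float
    significant: bool
    delta: float  # fraction(popB) - fraction(popA)

    @property
    def direction(self) -> str:
        if self.delta > 0:
            return "hypomethylated_in_A"
        if self.delta < 0:
            return "hypomethylated_in_B"
        return "none"


def classify_llr(llr: float, threshold: float = DEFAULT_LLR_THRESHOLD) -> str:
    if llr >= threshold:
        return METHYLATED
    if llr <= -threshold:
        return UNMETHYLATED
    return AMBIGUOUS


def load_meth_calls(
    path: str | Path,
    population: str,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
) -> list[MethCall]:
    """Load per-CpG calls from a nanopolish TSV or the simplified dialect.

    Nanopolish grouped calls (num_motifs = k > 1) expand to k per-CpG calls
    sharing the group's llr/state, at the CpG positions located by scanning
    the row's sequence context (the first CG in the context corresponds to
    the row's start coordinate).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if set(SIMPLE_COLUMNS) <= set(header):
        return _load_simple(path, population, llr_threshold)
    missing = [c for c in ("chromosome", "start", "read_name", "log_lik_ratio")
               if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return _load_nanopolish(path, population, llr_threshold)


def _load_simple(path, population, llr_threshold) -> list[MethCall]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    bad = pd.to_numeric(df["llr"], errors="coerce").isna()
    if bad.any():
        log.warning("%s: %d rows with non-numeric llr rejected", path, int(bad.sum()))
        df = df[~bad]
    calls = []
    for row in df.itertuples(index=False):
        llr = float(row.llr)
        calls.append(MethCall(
            read_id=row.read_id, chrom=row.chrom, pos=int(row.pos), llr=llr,
            state=classify_llr(llr, llr_threshold), population=population,
            primary=bool(row.primary)))
    return calls


def _load_nanopolish(path, population, llr_threshold) -> list[MethCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "read_name": str})
    bad = pd.to_numeric(df["log_lik_ratio"], errors="coerce").isna()
    if bad.any():
        log.warning("%s: %d rows with non-numeric llr rejected", path, int(bad.sum()))
        df = df[~bad]
    calls = []
    for row in df.itertuples(index=False):
        llr = float(row.log_lik_ratio)
        state = classify_llr(llr, llr_threshold)
        start = int(row.start)
        k = int(getattr(row, "num_motifs", 1))
        if k <= 1:
            positions = [start]
        else:
            seq = str(row.sequence)
            cg_offsets = []
            idx = seq.find("CG")
            while idx != -1:
                cg_offsets.append(idx)
                idx = seq.find("CG", idx + 1)
            if len(cg_offsets) < k:
                log.warning("%s: grouped row at %s:%d has %d CGs in context, "
                            "expected %d", path, row.chromosome, start,
                            len(cg_offsets), k)
            positions = [start + off - cg_offsets[0] for off in cg_offsets[:k]]
        for pos in positions:
            calls.append(MethCall(
                read_id=row.read_name, chrom=row.chromosome, pos=pos, llr=llr,
                state=state, population=population, primary=True))
    return calls


Segment = tuple[str, str, int, int]  # (segment_id, chrom, start, end)


def elements_as_segments(
    elements: Sequence[RetroElement],
    utr5_only: bool = True,
) -> list[Segment]:
    """Element segments; full-length L1s contribute their 5'UTR interval only."""
    segments = []
    for el in elements:
        if utr5_only and el.superfamily == "L1" and el.full_length and el.utr5:
            segments.append((el.element_id, el.chrom, el.utr5[0], el.utr5[1]))
        else:
            segments.append((el.element_id, el.chrom, el.start, el.end))
    return segments


def segment_methylation(
    calls: Iterable[MethCall],
    segments: Sequence[Segment],
    excl_ambig: bool = True,
    primary_only: bool = True,
) -> list[SegmentMethylation]:
    """Aggregate per-CpG calls over segments.

    Each retained call increments every segment containing its position.
    Returns one row per segment per population, in segment order; segments
    with zero retained calls are included with zero counts.
    """
    trees: dict[str, IntervalTree] = {}
    for seg_id, chrom, start, end in segments:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, seg_id)

    # (segment_id, population) -> [reads set, n_meth, n_unmeth]
    acc: dict[tuple[str, str], list] = {}
    populations: list[str] = []
    for call in calls:
        if call.population not in populations:
            populations.append(call.population)
        if primary_only and not call.primary:
            continue
        if excl_ambig and call.state == AMBIGUOUS:
            continue
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        for iv in tree.at(call.pos):
            key = (iv.data, call.population)
            slot = acc.setdefault(key, [set(), 0, 0])
            slot[0].add(call.read_id)
            if call.state == METHYLATED:
                slot[1] += 1
            elif call.state == UNMETHYLATED:
                slot[2] += 1

    out = []
    for seg_id, _chrom, _start, _end in segments:
        for pop in populations:
            reads, n_meth, n_unmeth = acc.get((seg_id, pop), (set(), 0, 0))
            out.append(SegmentMethylation(
                segment_id=seg_id, population=pop, n_reads=len(reads),
                n_calls=n_meth + n_unmeth, n_meth=n_meth, n_unmeth=n_unmeth))
    return out


def segmeth_frame(rows: Iterable[SegmentMethylation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.segment_id, r.population, r.n_reads, r.n_calls, r.n_meth,
          r.n_unmeth, r.fraction) for r in rows],
        columns=["segment_id", "population", "n_reads", "n_calls",
                 "n_meth", "n_unmeth", "fraction"])


def coverage_filter(
    rows: Iterable[SegmentMethylation],
    populations: Sequence[str],
    min_reads: int = DEFAULT_MIN_READS,
    min_calls: int = DEFAULT_MIN_CALLS,
) -> set[str]:
    """Elements with >= min_reads reads and >= min_calls calls in EVERY population."""
    by_seg: dict[str, dict[str, SegmentMethylation]] = {}
    for r in rows:
        by_seg.setdefault(r.segment_id, {})[r.population] = r
    retained = set()
    for seg_id, pops in by_seg.items():
        if all(p in pops and pops[p].n_reads >= min_reads
               and pops[p].n_calls >= min_calls for p in populations):
            retained.add(seg_id)
    return retained


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability rule: sum hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's (with a small relative tolerance for ties).
    """
    return float(fisher_exact_batch(
        np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0])


def fisher_exact_batch(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher exact test over parallel count arrays."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if np.any(n == 0):
        raise ValueError("all-zero table has no defined Fisher p-value")
    n1 = a + b  # row 1 total
    k = a + c   # column 1 total
    out = np.empty(len(a), dtype=float)
    cache: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}
    for i in range(len(a)):
        key = (int(n[i]), int(n1[i]), int(k[i]))
        entry = cache.get(key)
        if entry is None:
            nn, nn1, kk = key
            lo = max(0, kk - (nn - nn1))
            hi = min(kk, nn1)
            pmf = hypergeom.pmf(np.arange(lo, hi + 1), nn, nn1, kk)
            entry = cache[key] = (lo, pmf)
        lo, pmf = entry
        p_obs = pmf[int(a[i]) - lo]
        out[i] = min(float(pmf[pmf <= p_obs * (1 + 1e-7)].sum()), 1.0)
    return out


def differential_methylation(
    pop_a: Sequence[SegmentMethylation],
    pop_b: Sequence[SegmentMethylation],
    alpha: float = DEFAULT_ALPHA,
    min_reads: int = DEFAULT_MIN_READS,
    min_calls: int = DEFAULT_MIN_CALLS,
    apply_coverage_filter: bool = True,
) -> list[DMResult]:
    """Per-element Fisher exact test on methylated/unmethylated call counts.

    Bonferroni correction over the number of elements actually tested
    (post coverage filter).  Output sorted by |delta| descending to support
    top-N absolute-change rankings.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    a_by_id = {r.segment_id: r for r in pop_a}
    b_by_id = {r.segment_id: r for r in pop_b}
    shared = [sid for sid in a_by_id if sid in b_by_id]
    for sid in set(a_by_id) ^ set(b_by_id):
        log.info("element %s missing in one population, skipped", sid)
    if apply_coverage_filter:
        pops = [pop_a[0].population if pop_a else "A",
                pop_b[0].population if pop_b else "B"]
        retained = coverage_filter(list(pop_a) + list(pop_b), pops,
                                   min_reads, min_calls)
        shared = [sid for sid in shared if sid in retained]
    if not shared:
        return []
    ra = [a_by_id[s] for s in shared]
    rb = [b_by_id[s] for s in shared]
    ps = fisher_exact_batch(
        [r.n_meth for r in ra], [r.n_unmeth for r in ra],
        [r.n_meth for r in rb], [r.n_unmeth for r in rb])
    m = len(shared)
    results = []
    for sid, xa, xb, p in zip(shared, ra, rb, ps):
        p_adj = min(1.0, p * m)
        results.append(DMResult(
            element_id=sid, n_meth_a=xa.n_meth, n_unmeth_a=xa.n_unmeth,
            n_meth_b=xb.n_meth, n_unmeth_b=xb.n_unmeth, p=float(p),
            p_adj=p_adj, significant=p_adj < alpha,
            delta=xb.fraction - xa.fraction))
    results.sort(key=lambda r: abs(r.delta), reverse=True)
    return results


def dm_frame(results: Iterable[DMResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.element_id, r.n_meth_a, r.n_unmeth_a, r.n_meth_b, r.n_unmeth_b,
          r.p, r.p_adj, r.significant, r.delta, r.direction) for r in results],
        columns=["element_id", "n_meth_a", "n_unmeth_a", "n_meth_b",
                 "n_unmeth_b", "p", "p_adj", "significant", "delta",
                 "direction"])


def composite_profile(
    elements: Sequence[RetroElement],
    calls: Iterable[MethCall],
    span: int = 2000,
    monomers_required: int = 6,
    min_calls: int = 5,
) -> pd.DataFrame:
    """Position-wise mean methylation over the first ``span`` bp of
    six-monomer full-length elements, strand-oriented.

    Positions covered by fewer than ``min_calls`` calls are masked (NaN).
    Returns a frame with columns position / mean_methylation / n_calls /
    n_elements.
    """
    chosen = [el for el in elements
              if el.full_length and el.monomer_count == monomers_required]
    if not chosen:
        log.warning("composite profile: no qualifying elements")
        return pd.DataFrame(columns=["position", "mean_methylation",
                                     "n_calls", "n_elements"])
    trees: dict[str, IntervalTree] = {}
    for el in chosen:
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end, el)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    contributors: dict[int, set] = {}
    for call in calls:
        if call.state == AMBIGUOUS or not call.primary:
            continue
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        for iv in tree.at(call.pos):
            el = iv.data
            # calls sit at the forward-strand C of a CpG; on '-' elements the
            # element-sense C of that CpG is the complement of the G at pos+1
            rel = (call.pos - el.start if el.strand == "+"
                   else el.end - 2 - call.pos)
            if not 0 <= rel < span:
                continue
            sums[rel] = sums.get(rel, 0.0) + (call.state == METHYLATED)
            counts[rel] = counts.get(rel, 0) + 1
            contributors.setdefault(rel, set()).add(el.element_id)
    rows = []
    for pos in sorted(counts):
        n = counts[pos]
        mean = sums[pos] / n if n >= min_calls else float("nan")
        rows.append((pos, mean, n, len(contributors[pos])))
    return pd.DataFrame(rows, columns=["position", "mean_methylation",
                                       "n_calls", "n_elements"])


def locus_profile(
    element: RetroElement,
    calls: Iterable[MethCall],
    genome: GenomeIndex,
    flank: int = 1000,
    window: int = 28,
) -> dict[str, pd.DataFrame]:
    """Methylation profile of one locus in genome space and CpG space.

    Genome space: at each CpG position of element +/- flank, the fraction
    of non-ambiguous calls within a centered ``window`` bp sliding window.
    CpG space: per-CpG fraction indexed by CpG ordinal within the region.
    """
    start = max(0, element.start - flank)
    end = min(genome.lengths[element.chrom], element.end + flank)
    sites = extract_cpg_sites(genome, element.chrom, start, end)
    by_pos: dict[int, list[int]] = {}
    for call in calls:
        if call.state == AMBIGUOUS or not call.primary:
            continue
        if call.chrom == element.chrom and start <= call.pos < end:
            by_pos.setdefault(call.pos, []).append(call.state == METHYLATED)
    positions = sorted(by_pos)
    half = window / 2.0
    genome_rows = []
    for site in sites:
        lo, hi = site.pos - half, site.pos + half
        meth = tot = 0
        for p in positions:
            if lo <= p <= hi:
                states = by_pos[p]
                meth += sum(states)
                tot += len(states)
        genome_rows.append((site.pos, meth / tot if tot else float("nan"), tot))
    cpg_rows = []
    for ordinal, site in enumerate(sites):
        states = by_pos.get(site.pos, [])
        frac = sum(states) / len(states) if states else float("nan")
        cpg_rows.append((ordinal, site.pos, frac, len(states)))
    return {
        "genome_space": pd.DataFrame(
            genome_rows, columns=["pos", "smoothed_fraction", "n_calls"]),
        "cpg_space": pd.DataFrame(
            cpg_rows, columns=["cpg_index", "pos", "fraction", "n_calls"]),
    }
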