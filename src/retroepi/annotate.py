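"""Genome, repeat and gene annotation handling.

Reads RepeatMasker ``.out`` / BED repeat annotations and GTF gene models,
derives element structure (full-length status, tandem 5'UTR monomer count,
5'UTR interval) and extracts CpG site catalogs.  All internal coordinates
are 0-based half-open; RepeatMasker's 1-based inclusive convention is
converted at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

# Full-length thresholds (bp, strict '>') per superfamily.
FULL_LENGTH_MIN_BP: dict[str, int] = {
    "L1": 6000,
    "SINE_B1": 140,
    "SINE_B2": 185,
    "ERVL_MT2": 470,
    "IAP": 320,
}

# RepeatMasker repeat-name prefixes -> (superfamily, subfamily).  Editable:
# pass a custom mapping to parse_repeatmasker / parse_bed_elements.
DEFAULT_SUBFAMILY_MAP: dict[str, tuple[str, str]] = {
    "L1MdTf_I": ("L1", "TFI"),
    "L1MdTf_II": ("L1", "TFII"),
    "L1MdTf_III": ("L1", "TFIII"),
    "L1MdGf": ("L1", "GF"),
    "L1MdA": ("L1", "A"),
    "L1MdF": ("L1", "F"),
    "B1": ("SINE_B1", "B1"),
    "B2": ("SINE_B2", "B2"),
    "MT2": ("ERVL_MT2", "MT2"),
    "IAP": ("IAP", "IAP"),
}

YOUNG_L1_SUBFAMILIES = frozenset({"TFI", "TFII", "TFIII", "GF", "A"})

# canonical RepeatMasker-style name per subfamily, for BED emission
SUBFAMILY_TO_REPEAT_NAME: dict[str, str] = {
    "TFI": "L1MdTf_I", "TFII": "L1MdTf_II", "TFIII": "L1MdTf_III",
    "GF": "L1MdGf", "A": "L1MdA", "F": "L1MdF",
    "B1": "B1", "B2": "B2", "MT2": "MT2", "IAP": "IAP",
}

ELEMENT_TSV_COLUMNS = [
    "element_id", "chrom", "start", "end", "strand", "superfamily",
    "subfamily", "length", "full_length", "monomers", "utr5_start", "utr5_end",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """In-memory or faidx-backed genome with uppercase sequence access."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {name: str(seq).upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        fa = Fasta(str(path), sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} off chromosome "
                f"(length {self.lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]


@dataclass
class RetroElement:
    """An annotated repeat locus."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    superfamily: str
    subfamily: str = ""
    full_length: bool = False
    utr5: tuple[int, int] | None = None
    monomer_count: int = 0
    orf_intact: bool | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.element_id}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"{self.element_id}: bad strand {self.strand!r}")
        if self.utr5 is not None:
            u0, u1 = self.utr5
            if not (self.start <= u0 < u1 <= self.end):
                raise ValueError(f"{self.element_id}: utr5 outside element")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genome position of the element's 5' terminus on its own strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class CpGSite:
    chrom: str
    pos: int  # forward-strand position of the C of the CpG


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genome coords, sorted 5'->3' on gene strand
    cds: tuple[int, int] | None = None  # transcript coordinates

    def __post_init__(self) -> None:
        key = (lambda e: e[0]) if self.strand == "+" else (lambda e: -e[1])
        self.exons = sorted(self.exons, key=key)
        tlen = sum(e - s for s, e in self.exons)
        if self.cds is not None:
            c0, c1 = self.cds
            if not (0 <= c0 < c1 <= tlen):
                raise ValueError(f"{self.transcript_id}: cds outside transcript")
            if (c1 - c0) % 3 != 0:
                raise ValueError(f"{self.transcript_id}: cds length not divisible by 3")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: GenomeIndex) -> str:
        parts = [genome.fetch(self.chrom, s, e) for s, e in sorted(self.exons)]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def _map_repeat_name(name: str, subfamily_map: Mapping[str, tuple[str, str]]):
    # longest-prefix match so L1MdTf_III wins over L1MdTf_I
    best = None
    for prefix, tag in subfamily_map.items():
        if name.startswith(prefix) and (best is None or len(prefix) > best[0]):
            best = (len(prefix), tag)
    return best[1] if best else None


def parse_repeatmasker(
    path: str | Path,
    genome: GenomeIndex | None = None,
    subfamily_map: Mapping[str, tuple[str, str]] | None = None,
) -> list[RetroElement]:
    """Parse a standard RepeatMasker ``.out`` file into RetroElements.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    strand 'C' becomes '-'.  Rows whose repeat name is not in the subfamily
    map are skipped (counted in the log); rows on chromosomes absent from
    the genome index are rejected with a warning.
    """
    subfamily_map = subfamily_map or DEFAULT_SUBFAMILY_MAP
    elements: list[RetroElement] = []
    skipped_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            # header lines of .out start with 'SW'/'score' banner text
            if fields[0] in ("SW", "score") or fields[0].startswith("perc"):
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}: malformed RepeatMasker row at line {lineno}")
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                repeat_name = fields[9]
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker row at line {lineno}"
                ) from exc
            tag = _map_repeat_name(repeat_name, subfamily_map)
            if tag is None:
                skipped_unknown += 1
                continue
            if genome is not None and chrom not in genome.sequences:
                log.warning("line %d: unknown chromosome %s, element rejected",
                            lineno, chrom)
                continue
            superfamily, subfamily = tag
            elements.append(RetroElement(
                element_id=f"{repeat_name}_{chrom}_{begin - 1}",
                chrom=chrom, start=begin - 1, end=end, strand=strand,
                superfamily=superfamily, subfamily=subfamily,
            ))
    if skipped_unknown:
        log.info("%s: skipped %d rows with unmapped repeat names",
                 path, skipped_unknown)
    return elements


def parse_bed_elements(
    path: str | Path,
    subfamily_map: Mapping[str, tuple[str, str]] | None = None,
) -> list[RetroElement]:
    """Parse BED6 repeat annotations (name column holds the repeat name)."""
    subfamily_map = subfamily_map or DEFAULT_SUBFAMILY_MAP
    elements: list[RetroElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}: malformed BED row at line {lineno}")
            chrom, start, end, name, _score, strand = fields[:6]
            tag = _map_repeat_name(name, subfamily_map)
            if tag is None:
                log.info("line %d: unmapped repeat name %s, skipped", lineno, name)
                continue
            superfamily, subfamily = tag
            elements.append(RetroElement(
                element_id=f"{name}_{chrom}_{start}",
                chrom=chrom, start=int(start), end=int(end), strand=strand,
                superfamily=superfamily, subfamily=subfamily,
            ))
    return elements


def select_full_length(elements: Sequence[RetroElement]) -> list[RetroElement]:
    """Retain elements above their superfamily's strict length threshold.

    L1 > 6000 bp, B1 > 140 bp, B2 > 185 bp, MT2 > 470 bp, IAP > 320 bp.
    Order-preserving; retained copies get full_length=True.
    """
    out: list[RetroElement] = []
    for el in elements:
        thr = FULL_LENGTH_MIN_BP.get(el.superfamily)
        if thr is not None and el.length > thr:
            out.append(replace(el, full_length=True))
    return out


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def detect_monomers(
    element: RetroElement,
    genome: GenomeIndex,
    monomer_consensus: str,
    min_identity: float = 0.75,
    orf1_start_offset: int | None = None,
) -> tuple[int, tuple[int, int] | None]:
    """Count tandem 5'UTR monomers by 5'-anchored gap-free matching.

    Walks from the element's 5' terminus on its own strand, accepting each
    consecutive consensus-length window with identity >= ``min_identity``.
    The 5'UTR interval runs from the 5' terminus through the end of the
    last monomer, extended to ``orf1_start_offset`` (bp from the 5'
    terminus, i.e. through the nonmonomeric linker) when given.
    Returns ``(0, None)`` when the element is shorter than one consensus.
    """
    L = len(monomer_consensus)
    if not (100 <= L <= 300):
        raise ValueError("monomer consensus length outside 100-300 bp")
    seq = genome.fetch(element.chrom, element.start, element.end)
    if element.strand == "-":
        seq = revcomp(seq)
    consensus = monomer_consensus.upper()
    count = 0
    off = 0
    while off + L <= len(seq) and _identity(seq[off:off + L], consensus) >= min_identity:
        count += 1
        off += L
    if count == 0:
        return 0, None
    utr_len = off
    if orf1_start_offset is not None and orf1_start_offset > utr_len:
        utr_len = min(orf1_start_offset, element.length)
    if element.strand == "+":
        utr5 = (element.start, element.start + utr_len)
    else:
        utr5 = (element.end - utr_len, element.end)
    return count, utr5


def annotate_structure(
    elements: Sequence[RetroElement],
    genome: GenomeIndex,
    monomer_consensus: str,
    orf1_start_offset: int | None = None,
) -> list[RetroElement]:
    """Attach monomer count and 5'UTR interval to every full-length L1."""
    out = []
    for el in elements:
        if el.superfamily == "L1" and el.full_length:
            count, utr5 = detect_monomers(
                el, genome, monomer_consensus, orf1_start_offset=orf1_start_offset)
            el = replace(el, monomer_count=count, utr5=utr5)
        out.append(el)
    return out


def extract_cpg_sites(genome: GenomeIndex, chrom: str, start: int, end: int) -> list[CpGSite]:
    """All forward-strand CG dinucleotides in [start, end).

    Reverse-strand CpGs collapse to the forward-strand C position; a CG
    whose C sits at ``end - 1`` counts when its G lies at ``end`` on the
    chromosome (site position must be inside the interval).
    """
    hi = min(end + 1, genome.lengths[chrom])
    seq = genome.fetch(chrom, start, hi)
    sites = []
    idx = seq.find("CG")
    while idx != -1:
        if start + idx < end:
            sites.append(CpGSite(chrom, start + idx))
        idx = seq.find("CG", idx + 1)
    return sites


def genome_bins(genome: GenomeIndex, width: int = 10_000) -> list[tuple[str, str, int, int]]:
    """Half-open windows tiling each chromosome; final partial window kept.

    Returns (segment_id, chrom, start, end) tuples.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins = []
    for chrom in sorted(genome.lengths):
        length = genome.lengths[chrom]
        for start in range(0, length, width):
            end = min(start + width, length)
            bins.append((f"{chrom}:{start}-{end}", chrom, start, end))
    return bins


def elements_to_frame(elements: Iterable[RetroElement]) -> pd.DataFrame:
    rows = []
    for el in elements:
        u0, u1 = el.utr5 if el.utr5 is not None else (-1, -1)
        rows.append((el.element_id, el.chrom, el.start, el.end, el.strand,
                     el.superfamily, el.subfamily, el.length, el.full_length,
                     el.monomer_count, u0, u1))
    return pd.DataFrame(rows, columns=ELEMENT_TSV_COLUMNS)


def write_elements_tsv(elements: Iterable[RetroElement], path: str | Path) -> None:
    elements_to_frame(elements).to_csv(path, sep="\t", index=False)


def read_elements_tsv(path: str | Path) -> list[RetroElement]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        utr5 = None
        if row.utr5_start >= 0:
            utr5 = (int(row.utr5_start), int(row.utr5_end))
        out.append(RetroElement(
            element_id=row.element_id, chrom=row.chrom, start=int(row.start),
            end=int(row.end), strand=row.strand, superfamily=row.superfamily,
            subfamily=row.subfamily, full_length=bool(row.full_length),
            utr5=utr5, monomer_count=int(row.monomers),
        ))
    return out


def write_elements_bed(elements: Iterable[RetroElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            name = SUBFAMILY_TO_REPEAT_NAME.get(el.subfamily,
                                                el.subfamily or el.superfamily)
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t{name}\t0\t{el.strand}\n")


def parse_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models (exon + CDS features) from a GTF file."""
    exons: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            attr = {}
            for item in attrs.strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr[key] = val.strip().strip('"')
            tid = attr.get("transcript_id", "")
            gid = attr.get("gene_id", tid)
            iv = (int(start) - 1, int(end))
            if feature == "exon":
                rec = exons.setdefault(tid, {"gene_id": gid, "chrom": chrom,
                                             "strand": strand, "exons": []})
                rec["exons"].append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
    models = []
    for tid, rec in exons.items():
        model_cds = None
        if tid in cds:
            model_cds = _cds_to_transcript_coords(
                rec["exons"], cds[tid], rec["strand"])
        models.append(GeneModel(
            gene_id=rec["gene_id"], transcript_id=tid, chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"], cds=model_cds))
    return models


def _cds_to_transcript_coords(exons, cds_blocks, strand) -> tuple[int, int]:
    exs = sorted(exons)
    if strand == "-":
        exs = exs[::-1]
    cds_lo = min(s for s, _ in cds_blocks)
    cds_hi = max(e for _, e in cds_blocks)
    offset = 0
    t0 = t1 = None
    for s, e in exs:
        if strand == "+":
            if s <= cds_lo < e:
                t0 = offset + (cds_lo - s)
            if s < cds_hi <= e:
                t1 = offset + (cds_hi - s)
        else:
            if s < cds_hi <= e:
                t0 = offset + (e - cds_hi)
            if s <= cds_lo < e:
                t1 = offset + (e - cds_lo)
        offset += e - s
    if t0 is None or t1 is None:
        raise ValueError("CDS blocks not contained in exons")
    return t0, t1
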