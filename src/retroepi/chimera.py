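"""Chimeric L1-promoter -> gene transcript detection and ORF frame analysis.

A chimeric transcript initiates inside an L1 5'UTR (canonically antisense
to the element, i.e. from the L1 antisense promoter), runs on the same
strand as a neighboring gene, and splices into an annotated exon of that
gene.  The frame check asks whether the chimera's longest AUG-initiated
ORF ends with the canonical protein's sequence from the first shared exon
onward, i.e. whether the novel N-terminus is fused in frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotate import GeneModel, GenomeIndex, RetroElement, revcomp
from .race import Alignment

log = logging.getLogger(__name__)

DEFAULT_ACCEPTOR_TOLERANCE_BP = 2
DEFAULT_MIN_ORF_CODONS = 50
DEFAULT_YOUNG_SUBFAMILIES = frozenset({"TFI", "TFII", "TFIII", "GF", "A"})


@dataclass
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genome coords, sorted ascending

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)

    def five_prime(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) genome positions in transcript 5'->3' order.

        Donor is the last transcribed base of the upstream exon; acceptor
        is the first transcribed base of the downstream exon.
        """
        pairs = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                pairs.append((e1 - 1, s2))
            else:
                pairs.append((s2, e1 - 1))
        return pairs if self.strand == "+" else pairs[::-1]

    def spliced_sequence(self, genome: GenomeIndex) -> str:
        seq = "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


def transcript_from_alignment(aln: Alignment) -> TranscriptModel:
    return TranscriptModel(transcript_id=aln.read_id, chrom=aln.chrom,
                           strand=aln.strand, exons=list(aln.blocks))


@dataclass
class ChimericTranscript:
    transcript_id: str
    element_id: str
    gene_id: str
    tss_pos: int
    antisense_to_element: bool
    sense_with_gene: bool
    junctions: list[tuple[int, int]]
    first_gene_exon_joined: int  # 1-based ordinal in gene 5'->3' order
    model: TranscriptModel = field(repr=False)
    orf: tuple[int, int] | None = None  # transcript coordinates
    in_frame_with_canonical: bool | None = None
    novel_nterm_aa: int | None = None
    frame_reason: str = ""


def _gene_acceptor_positions(gene: GeneModel) -> list[tuple[int, int]]:
    """(acceptor genome position, exon ordinal) per gene exon, 5'->3'."""
    out = []
    for ordinal, (s, e) in enumerate(gene.exons, start=1):
        acceptor = s if gene.strand == "+" else e - 1
        out.append((acceptor, ordinal))
    return out


def find_chimeric_transcripts(
    transcripts: Iterable[TranscriptModel],
    elements: Sequence[RetroElement],
    genes: Sequence[GeneModel],
    acceptor_tolerance: int = DEFAULT_ACCEPTOR_TOLERANCE_BP,
) -> list[ChimericTranscript]:
    """Detect element-5'UTR-initiated transcripts spliced into gene exons.

    Requires: (i) the transcript's 5' terminus inside an element 5'UTR,
    (ii) transcript strand equal to the gene strand, and (iii) at least one
    splice-junction acceptor coinciding (within ``acceptor_tolerance`` bp)
    with an annotated exon start of the gene.  Sense-promoter events
    (transcript on the element's own strand) are retained but flagged with
    ``antisense_to_element=False``.
    """
    utr_elements = [el for el in elements if el.utr5 is not None]
    found = []
    for tx in transcripts:
        if len(tx.exons) < 2:
            continue  # unspliced: not chimeric by definition
        tss = tx.five_prime()
        host = None
        for el in utr_elements:
            if el.chrom == tx.chrom and el.utr5[0] <= tss < el.utr5[1]:
                host = el
                break
        if host is None:
            continue
        junctions = tx.junctions()
        for gene in genes:
            if gene.chrom != tx.chrom or gene.strand != tx.strand:
                continue
            hit = None
            for acceptor_pos, ordinal in _gene_acceptor_positions(gene):
                for _donor, acceptor in junctions:
                    if abs(acceptor - acceptor_pos) <= acceptor_tolerance:
                        hit = ordinal
                        break
                if hit is not None:
                    break
            if hit is None:
                continue
            found.append(ChimericTranscript(
                transcript_id=tx.transcript_id, element_id=host.element_id,
                gene_id=gene.gene_id, tss_pos=tss,
                antisense_to_element=tx.strand != host.strand,
                sense_with_gene=True, junctions=junctions,
                first_gene_exon_joined=hit, model=tx))
    return found


def _longest_aug_orf(seq: str, min_codons: int) -> tuple[int, int] | None:
    """Longest AUG-initiated ORF (start, end) half-open, stop included."""
    best = None
    n = len(seq)
    start = seq.find("ATG")
    while start != -1:
        end = None
        for i in range(start, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                end = i + 3
                break
        if end is not None and (end - start) // 3 - 1 >= min_codons:
            if best is None or end - start > best[1] - best[0]:
                best = (start, end)
        start = seq.find("ATG", start + 1)
    return best


def orf_frame_check(
    chimeric: ChimericTranscript,
    canonical: GeneModel,
    genome: GenomeIndex,
    min_codons: int = DEFAULT_MIN_ORF_CODONS,
) -> tuple[bool, int]:
    """Check the chimeric ORF's frame against the canonical transcript.

    The chimeric ORF is the longest AUG-initiated ORF of the spliced
    chimeric transcript.  in_frame is true iff the translated chimeric ORF
    ends with the canonical protein from the first codon fully encoded in
    the shared exons onward; novel_nterm_aa is the chimeric protein length
    minus that shared suffix length.  Updates the ChimericTranscript in
    place and returns (in_frame, novel_nterm_aa).
    """
    if canonical.cds is None:
        raise ValueError(f"{canonical.transcript_id}: no canonical CDS")
    tx_seq = chimeric.model.spliced_sequence(genome).upper()
    orf = _longest_aug_orf(tx_seq, min_codons)
    if orf is None:
        chimeric.in_frame_with_canonical = False
        chimeric.novel_nterm_aa = 0
        chimeric.frame_reason = f"no AUG-initiated ORF >= {min_codons} codons"
        return False, 0
    chimeric.orf = orf
    chim_prot = str(Seq(tx_seq[orf[0]:orf[1]]).translate(to_stop=True))

    cds0, cds1 = canonical.cds
    canon_seq = canonical.spliced_sequence(genome).upper()
    canon_prot = str(Seq(canon_seq[cds0:cds1]).translate(to_stop=True))

    # transcript-coordinate offset of the first shared exon in the canonical
    shared_offset = sum(
        e - s for s, e in canonical.exons[:chimeric.first_gene_exon_joined - 1])
    s = max(0, shared_offset - cds0)
    first_full_codon = (s + 2) // 3  # ceil(s / 3)
    expected_suffix = canon_prot[first_full_codon:]
    if not expected_suffix:
        chimeric.in_frame_with_canonical = False
        chimeric.novel_nterm_aa = 0
        chimeric.frame_reason = "canonical CDS ends before shared exons"
        return False, 0
    in_frame = chim_prot.endswith(expected_suffix)
    novel = len(chim_prot) - len(expected_suffix) if in_frame else 0
    chimeric.in_frame_with_canonical = in_frame
    chimeric.novel_nterm_aa = novel
    if not in_frame:
        chimeric.frame_reason = "chimeric ORF out of frame with canonical protein"
    return in_frame, novel


def screen_genome(
    transcripts: Iterable[TranscriptModel],
    elements: Sequence[RetroElement],
    genes: Sequence[GeneModel],
    young_subfamilies: frozenset[str] = DEFAULT_YOUNG_SUBFAMILIES,
    min_support: int = 1,
    acceptor_tolerance: int = DEFAULT_ACCEPTOR_TOLERANCE_BP,
) -> pd.DataFrame:
    """Per-element table of chimera-supporting transcripts over young L1s.

    One row per element with >= ``min_support`` supporting transcripts;
    duplicate reads of the same transcript each count toward support.
    """
    young = [el for el in elements
             if el.superfamily == "L1" and el.subfamily in young_subfamilies]
    hits = find_chimeric_transcripts(transcripts, young, genes,
                                     acceptor_tolerance)
    by_element: dict[str, list[ChimericTranscript]] = {}
    for hit in hits:
        by_element.setdefault(hit.element_id, []).append(hit)
    rows = []
    for element_id in sorted(by_element):
        support = by_element[element_id]
        if len(support) < min_support:
            continue
        gene_ids = sorted({h.gene_id for h in support})
        antisense = any(h.antisense_to_element for h in support)
        rows.append((element_id, len(support), ",".join(gene_ids), antisense))
    return pd.DataFrame(rows, columns=["element_id", "support", "gene_ids",
                                       "antisense_promoter"])


def chimeras_frame(hits: Iterable[ChimericTranscript]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.transcript_id, h.element_id, h.gene_id, h.tss_pos,
          h.antisense_to_element, h.first_gene_exon_joined,
          h.in_frame_with_canonical, h.novel_nterm_aa, h.frame_reason)
         for h in hits],
        columns=["transcript_id", "element_id", "gene_id", "tss_pos",
                 "antisense_to_element", "first_gene_exon_joined",
                 "in_frame_with_canonical", "novel_nterm_aa", "frame_reason"])
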