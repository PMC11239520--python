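"""Synthetic genomes, methylomes, 5'RACE reads, chimeric transcripts and
bisulfite amplicons with recorded ground truth.

The generator plants full-length L1 elements with tandem-monomer 5'UTRs
(toy ~210 bp monomer consensus bundled below, not a RepBase extract),
SINE B1/B2 and MT2/IAP LTR decoys, a gene with an intronic antisense L1
driving a chimeric spliced transcript, and two cell populations with
distinct per-locus 5'UTR methylation including unmethylated "escapee"
loci.  Default parameters mirror the study conditions the pipeline is
meant to recover: population means 83.9% (PV+) and 91.8% (PV-) 5'UTR
methylation, 5'RACE full-length mRNA shares of 76.0% (sorted PV) and
63.8% (bulk hippocampus), 10 reads per locus over ~30 5'UTR CpGs, and 20
escapee loci among 500.

Every sub-generator draws from its own child of a single SeedSequence, so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import (GeneModel, GenomeIndex, RetroElement, revcomp)
from .chimera import TranscriptModel
from .race import Alignment

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Bundled toy sequences (synthetic; authored for this package, not database
# extracts).  The monomer carries five CpGs, so a six-monomer 5'UTR plus
# linker holds ~33 CpG sites.
TOY_MONOMER = (
    "CGACCGACTAGATCATACTAGCACCTTAGACTGCTAGGGGTGGAGGCAAAACCAGTCAACTAGTTATAC"
    "AAAGTATTTTAGAAGAGTCATTCCGCACAAATGCAGCCTAGGTTGACTAGGCAATGGGGAAGCTAGAGA"
    "GGCAGCAATCTGAGACAATACACTACACAAAACCGTCATGATGCGGGCTATAATTTGTGTTAAGTACTAACC"
)
TOY_LINKER = (
    "TCTAACCGTGGTACATCACTAGCCTGTCGTGCATACTAGAACTCAGGTCAAGGTGTGGAGGAAGAAATC"
    "CCATATTTTTGATAATAAACAAGGGACTGTTGTTGACAAGATCATCCCCCAGCTAGTCATACCGGTTTCTC"
)
# Fixed site near the L1 3' end where the RACE L1-specific primer anneals.
PRIMER_SITE = "TTTAAAGCTACTGGTAGGCTCAACT"
L1_RACE_PRIMER = revcomp(PRIMER_SITE)
UNIVERSAL_PRIMER = "CTAATACGACTCACTATAGGGCAAG"

# Novel-N-terminus cassette of the planted chimeric transcript: an ATG
# followed by 59 stop-free codons with no internal ATG in any frame.
CASSETTE_PAD = "TGTCGCAATCTT"
CASSETTE_CODING = "ATG" + (
    "CCTCCATCTCAACCTTCTCCACAATCCAAACCTAAGGATCTCTCCGGAGCTGCCGGTGCCACCGCCACC"
    "GAGCCTCTTGGCGATCCAGAGACCTCCGGAGACGCTACCACCTCTGAACAAGAAGCTTCCAAAGGACCT"
    "CTTCAGAAGGGAGAGGACGCCGCACTTGCAGCACAGGCA"
)

MONOMER_LEN = len(TOY_MONOMER)
UTR5_LEN = 6 * MONOMER_LEN + len(TOY_LINKER)  # 1400 bp
PRIMER_TAIL_BP = 30  # bases 3' of the primer site inside the element

# Study-condition presets.
METHYLATION_PRESETS = {"PVpos": 0.839, "PVneg": 0.918}
ESCAPEE_METHYLATION_PROB = 0.02
RACE_FULL_LENGTH_PRESETS = {"pv_sorted": 0.760, "bulk": 0.638}

_SAFE_CODONS = ("GCT GCC GCA GAA GAG GAT GAC AAA AAG CAA CAG CTT CTC CCT "
                "CCA ACT ACC TCT TCC GGT GGC GGA").split()
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition defaults for every sub-generator."""

    seed: int = 0
    # genome / element census
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_l1: int = 500
    l1_subfamilies: tuple[str, ...] = ("TFI", "TFII", "TFIII")
    monomer_count: int = 6
    l1_length_range: tuple[int, int] = (7200, 7400)
    n_b1: int = 20
    n_b2: int = 20
    n_mt2: int = 8
    n_iap: int = 8
    n_truncated_l1: int = 20
    n_chimera: int = 1
    chimera_in_frame: bool = True
    # methylation calls
    depth: int = 10
    llr_magnitude: float = 5.0
    ambiguous_rate: float = 0.05
    n_escapees: int = 20
    escapee_prob: float = ESCAPEE_METHYLATION_PROB
    # 5'RACE
    race_n_reads: int = 1000
    race_upstream_share: float = 0.1
    n_race_contaminants: int = 20
    n_race_multimapped: int = 10
    # bisulfite
    bisulfite_reads: int = 300
    conversion_failure_rate: float = 0.005


@dataclass
class SimulatedGenome:
    genome: GenomeIndex
    elements: list[RetroElement]
    genes: list[GeneModel]
    transcripts: list[TranscriptModel]  # planted chimeric + decoy models
    chimera_truth: pd.DataFrame
    element_truth: pd.DataFrame
    escapee_ids: list[str]
    config: SimConfig

    @property
    def full_length_l1(self) -> list[RetroElement]:
        return [el for el in self.elements
                if el.superfamily == "L1" and el.full_length]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _l1_sequence(rng: np.random.Generator, length: int,
                 monomer_count: int) -> str:
    """Element-sense sequence: tandem monomers + linker + body + primer site."""
    utr = TOY_MONOMER * monomer_count + TOY_LINKER
    body_len = length - len(utr) - len(PRIMER_SITE) - PRIMER_TAIL_BP
    if body_len < 0:
        raise ValueError("L1 length too short for its 5'UTR")
    return utr + _random_seq(rng, body_len) + PRIMER_SITE + _random_seq(
        rng, PRIMER_TAIL_BP)


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Random substitutions at the given per-base rate (no indels)."""
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    subs = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
    arr[hits] = subs
    return "".join(arr)


def build_genome(config: SimConfig) -> SimulatedGenome:
    """Plant the configured element census and chimera loci; record truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_decoy, rng_chim, rng_esc = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    sequences: dict[str, str] = {}
    elements: list[RetroElement] = []
    truth_rows = []

    # --- L1 cohort chromosomes -------------------------------------------
    per_chrom = int(np.ceil(config.n_l1 / config.n_chromosomes))
    planted = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        chunks: list[str] = []
        pos = 0
        while planted < config.n_l1 and planted < (ci + 1) * per_chrom:
            gap = int(rng_genome.integers(100, 300))
            length = int(rng_genome.integers(*config.l1_length_range))
            if pos + gap + length + 200 > config.chrom_length:
                raise ValueError("element census exceeds genome capacity")
            strand = "+" if rng_genome.random() < 0.5 else "-"
            subfam = config.l1_subfamilies[planted % len(config.l1_subfamilies)]
            sense = _l1_sequence(rng_genome, length, config.monomer_count)
            chunks.append(_random_seq(rng_genome, gap))
            pos += gap
            start, end = pos, pos + length
            chunks.append(sense if strand == "+" else revcomp(sense))
            pos = end
            utr5 = ((start, start + UTR5_LEN) if strand == "+"
                    else (end - UTR5_LEN, end))
            eid = f"L1Md{subfam}_{chrom}_{start}"
            elements.append(RetroElement(
                element_id=eid, chrom=chrom, start=start, end=end,
                strand=strand, superfamily="L1", subfamily=subfam,
                full_length=True, utr5=utr5,
                monomer_count=config.monomer_count))
            truth_rows.append((eid, chrom, start, end, strand, "L1", subfam,
                               length, config.monomer_count))
            planted += 1
        chunks.append(_random_seq(rng_genome, 500))
        sequences[chrom] = "".join(chunks)

    # --- decoy chromosome -------------------------------------------------
    decoys = ([("SINE_B1", "B1", 150)] * config.n_b1
              + [("SINE_B2", "B2", 190)] * config.n_b2
              + [("ERVL_MT2", "MT2", 500)] * config.n_mt2
              + [("IAP", "IAP", 350)] * config.n_iap
              + [("L1", "TFI", 800)] * config.n_truncated_l1)
    if decoys:
        chrom = "chrD"
        chunks, pos = [], 0
        for superfam, subfam, length in decoys:
            gap = int(rng_decoy.integers(100, 300))
            chunks.append(_random_seq(rng_decoy, gap))
            pos += gap
            strand = "+" if rng_decoy.random() < 0.5 else "-"
            chunks.append(_random_seq(rng_decoy, length))
            eid = f"{subfam}_{chrom}_{pos}"
            elements.append(RetroElement(
                element_id=eid, chrom=chrom, start=pos, end=pos + length,
                strand=strand, superfamily=superfam, subfamily=subfam))
            truth_rows.append((eid, chrom, pos, pos + length, strand,
                               superfam, subfam, length, 0))
            pos += length
        chunks.append(_random_seq(rng_decoy, 300))
        sequences[chrom] = "".join(chunks)

    # --- chimera loci ------------------------------------------------------
    genes: list[GeneModel] = []
    transcripts: list[TranscriptModel] = []
    chim_rows = []
    if config.n_chimera:
        chrom = "chrG"
        chunks, offset = [], 0
        for gi in range(config.n_chimera):
            locus = _plant_chimera_locus(
                rng_chim, gi, chrom, offset, in_frame=config.chimera_in_frame)
            chunks.append(locus["sequence"])
            offset += len(locus["sequence"])
            elements.append(locus["element"])
            genes.append(locus["gene"])
            transcripts.extend(locus["transcripts"])
            el = locus["element"]
            truth_rows.append((el.element_id, chrom, el.start, el.end,
                               el.strand, "L1", el.subfamily, el.length,
                               config.monomer_count))
            chim_rows.append((locus["chimeric_id"], el.element_id,
                              locus["gene"].gene_id, locus["tss"],
                              True, 3, config.chimera_in_frame))
        sequences[chrom] = "".join(chunks)

    element_truth = pd.DataFrame(
        truth_rows, columns=["element_id", "chrom", "start", "end", "strand",
                             "superfamily", "subfamily", "length", "monomers"])
    chimera_truth = pd.DataFrame(
        chim_rows, columns=["transcript_id", "element_id", "gene_id",
                            "tss_pos", "antisense_to_element",
                            "first_gene_exon_joined", "in_frame"])

    genome = GenomeIndex(sequences)
    full = [el for el in elements
            if el.superfamily == "L1" and el.full_length
            and el.chrom.startswith("chr") and el.chrom not in ("chrD", "chrG")]
    n_esc = min(config.n_escapees, len(full))
    esc_idx = rng_esc.choice(len(full), size=n_esc, replace=False)
    escapee_ids = sorted(full[i].element_id for i in esc_idx)

    return SimulatedGenome(genome=genome, elements=elements, genes=genes,
                           transcripts=transcripts,
                           chimera_truth=chimera_truth,
                           element_truth=element_truth,
                           escapee_ids=escapee_ids, config=config)


def _plant_chimera_locus(rng: np.random.Generator, index: int, chrom: str,
                         offset: int, in_frame: bool) -> dict:
    """A gene on + with an intronic antisense full-length L1 whose 5'UTR
    drives a chimeric transcript spliced into gene exon 3."""
    l1_len = 7200
    cassette = CASSETTE_CODING
    if not in_frame:
        cassette = cassette[:100] + cassette[104:]  # 4 bp deletion

    # canonical CDS: ATG + 328 stop-free codons + TAA (990 bp)
    cds_seq = "ATG" + "".join(
        rng.choice(_SAFE_CODONS) for _ in range(328)) + "TAA"
    e1_utr, e1_cds = _random_seq(rng, 120), cds_seq[:180]
    e2_cds = cds_seq[180:330]
    e3_cds = cds_seq[330:730]
    e4_cds, e4_utr = cds_seq[730:990], _random_seq(rng, 240)

    parts: list[tuple[str, str]] = [
        ("pad0", _random_seq(rng, 200)),
        ("exon1", e1_utr + e1_cds),
        ("pad1", _random_seq(rng, 300)),
        ("l1", revcomp(_l1_sequence(rng, l1_len, 6))),  # antisense element
        ("cpad", CASSETTE_PAD),
        ("cassette", cassette),
        ("pad3", _random_seq(rng, 400)),
        ("exon2", e2_cds),
        ("intron2", _random_seq(rng, 500)),
        ("exon3", e3_cds),
        ("intron3", _random_seq(rng, 450)),
        ("exon4", e4_cds + e4_utr),
        ("pad_end", _random_seq(rng, 200)),
    ]
    coords: dict[str, tuple[int, int]] = {}
    pos = offset
    for name, seq in parts:
        coords[name] = (pos, pos + len(seq))
        pos += len(seq)
    sequence = "".join(seq for _, seq in parts)

    l1s, l1e = coords["l1"]
    element = RetroElement(
        element_id=f"L1MdTFIII_{chrom}_{l1s}", chrom=chrom, start=l1s,
        end=l1e, strand="-", superfamily="L1", subfamily="TFIII",
        full_length=True, utr5=(l1e - UTR5_LEN, l1e), monomer_count=6,
        orf_intact=True)

    exons = [coords["exon1"], coords["exon2"], coords["exon3"],
             coords["exon4"]]
    cds0 = 120
    cds1 = cds0 + 990
    gene = GeneModel(gene_id=f"geneG{index}", transcript_id=f"canonG{index}",
                     chrom=chrom, strand="+", exons=exons, cds=(cds0, cds1))

    # chimeric TSS: longest ATG-free tail of the L1 5'UTR on the + strand
    utr_fwd = sequence[l1e - UTR5_LEN - offset:l1e - offset]
    k = 20
    for cand in range(80, 19, -1):
        if "ATG" not in utr_fwd[-cand:]:
            k = cand
            break
    tss = l1e - k
    chim_id = f"chimG{index}"
    chimeric = TranscriptModel(
        transcript_id=chim_id, chrom=chrom, strand="+",
        exons=[(tss, coords["cassette"][1]), coords["exon3"],
               coords["exon4"]])
    # decoys: the canonical model (5' terminus outside the L1) and an
    # unspliced utr5-initiated fragment (no junction -> not chimeric)
    canonical_model = TranscriptModel(
        transcript_id=f"canonG{index}", chrom=chrom, strand="+", exons=exons)
    unspliced = TranscriptModel(
        transcript_id=f"fragG{index}", chrom=chrom, strand="+",
        exons=[(tss, tss + 400)])
    return {"sequence": sequence, "element": element, "gene": gene,
            "transcripts": [chimeric, canonical_model, unspliced],
            "chimeric_id": chim_id, "tss": tss}


# ---------------------------------------------------------------------------
# methylation calls


def simulate_meth_calls(
    sim: SimulatedGenome,
    population: str,
    seed: int,
    meth_prob: float | None = None,
    escapees: bool = False,
    elements: Sequence[RetroElement] | None = None,
) -> pd.DataFrame:
    """Per-read per-CpG call table (simplified dialect) over L1 5'UTRs.

    Each full-length L1 contributes ``depth`` reads covering every 5'UTR
    CpG; each call is methylated with the locus probability (population
    preset unless ``meth_prob`` given; escapee loci drop to the escapee
    probability when ``escapees`` is true), ambiguous at the configured
    rate, with llr magnitudes ~ N(llr_magnitude, 1) clipped above the call
    threshold.
    """
    from .annotate import extract_cpg_sites

    cfg = sim.config
    if meth_prob is None:
        meth_prob = METHYLATION_PRESETS[population]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    escapee_set = set(sim.escapee_ids) if escapees else set()
    targets = elements if elements is not None else [
        el for el in sim.full_length_l1 if el.chrom not in ("chrD",)]
    rows = []
    for el in targets:
        if el.utr5 is None:
            continue
        sites = extract_cpg_sites(sim.genome, el.chrom, el.utr5[0], el.utr5[1])
        if not sites:
            continue
        p = cfg.escapee_prob if el.element_id in escapee_set else meth_prob
        positions = np.array([s.pos for s in sites])
        n_sites = len(positions)
        for ri in range(cfg.depth):
            read_id = f"{el.element_id}_r{ri}"
            ambig = rng.random(n_sites) < cfg.ambiguous_rate
            meth = rng.random(n_sites) < p
            mags = np.maximum(np.abs(rng.normal(cfg.llr_magnitude, 1.0,
                                                n_sites)), 2.01)
            llrs = np.where(meth, mags, -mags)
            llrs[ambig] = rng.uniform(-1.9, 1.9, int(ambig.sum()))
            for pos, llr in zip(positions, llrs):
                rows.append((read_id, el.chrom, int(pos), round(float(llr), 3),
                             True))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "llr",
                                       "primary"])


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def simulate_segment_counts(
    n_loci: int,
    p: float,
    seed: int,
    population: str = "pop",
    depth: int = 10,
    calls_per_read: int = 30,
    escapee_indices: Sequence[int] = (),
    escapee_prob: float = ESCAPEE_METHYLATION_PROB,
):
    """Count-level cohort: per-locus binomial methylated-call counts.

    A lightweight stand-in for the full TSV round trip, used for large
    seeded cohort studies (null calibration, sensitivity).  Returns
    SegmentMethylation rows.
    """
    from .methylome import SegmentMethylation

    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    esc = set(escapee_indices)
    n_calls = depth * calls_per_read
    rows = []
    for i in range(n_loci):
        prob = escapee_prob if i in esc else p
        n_meth = int(rng.binomial(n_calls, prob))
        rows.append(SegmentMethylation(
            segment_id=f"locus{i}", population=population, n_reads=depth,
            n_calls=n_calls, n_meth=n_meth, n_unmeth=n_calls - n_meth))
    return rows


# ---------------------------------------------------------------------------
# 5'RACE reads


def simulate_race_reads(
    sim: SimulatedGenome,
    seed: int,
    full_length_fraction: float | None = None,
    preset: str | None = None,
    n_reads: int | None = None,
) -> tuple[dict[str, str], list[Alignment], pd.DataFrame]:
    """RACE reads over planted full-length L1 TFI loci with known truth.

    The full-length share is planted exactly (stratified allocation of
    read categories, randomized over loci and start positions): reads
    initiating upstream or in the 5'UTR span >6 kbp to the primer site,
    body-initiated reads are truncated below it.  Primerless contaminants
    and multi-mapped reads are appended to exercise the retention filter.

    Returns (sequences by read id, alignments, truth table).
    """
    cfg = sim.config
    if full_length_fraction is None:
        full_length_fraction = RACE_FULL_LENGTH_PRESETS[preset or "pv_sorted"]
    n = n_reads if n_reads is not None else cfg.race_n_reads
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    loci = [el for el in sim.full_length_l1
            if el.subfamily == "TFI" and el.chrom not in ("chrD", "chrG")]
    if not loci:
        raise ValueError("no full-length L1 TFI loci to transcribe")

    n_full = int(round(full_length_fraction * n))
    n_up = int(round(cfg.race_upstream_share * n_full))
    categories = (["upstream"] * n_up + ["utr5"] * (n_full - n_up)
                  + ["body"] * (n - n_full))
    rng.shuffle(categories)

    sequences: dict[str, str] = {}
    alignments: list[Alignment] = []
    truth = []
    for i, category in enumerate(categories):
        el = loci[int(rng.integers(0, len(loci)))]
        elem_len = el.length
        prim_end = elem_len - PRIMER_TAIL_BP
        if category == "upstream":
            # inter-element gaps are >=100 bp, so stay within them
            tss_elem = -int(rng.integers(1, 100))
        elif category == "utr5":
            tss_elem = int(rng.integers(0, 1100))
        else:
            tss_elem = int(rng.integers(UTR5_LEN, UTR5_LEN + 1400))
        if el.strand == "+":
            block = (el.start + tss_elem, el.start + prim_end)
        else:
            block = (el.end - prim_end, el.end - tss_elem)
        frag = sim.genome.fetch(el.chrom, *block)
        if el.strand == "-":
            frag = revcomp(frag)
        read_id = f"race{i}"
        sequences[read_id] = UNIVERSAL_PRIMER + frag
        alignments.append(Alignment(
            read_id=read_id, chrom=el.chrom, strand=el.strand,
            blocks=[block], score=float(block[1] - block[0]), primary=True,
            n_best=1))
        span = block[1] - block[0]
        truth.append((read_id, el.element_id, category, span, span > 6000))

    for j in range(cfg.n_race_contaminants):
        read_id = f"contam{j}"
        el = loci[int(rng.integers(0, len(loci)))]
        sequences[read_id] = _random_seq(rng, 500)
        alignments.append(Alignment(
            read_id=read_id, chrom=el.chrom, strand="+",
            blocks=[(el.start, el.start + 500)], score=500.0, primary=True,
            n_best=1))
        truth.append((read_id, "", "contaminant", 500, False))
    for j in range(cfg.n_race_multimapped):
        read_id = f"multi{j}"
        el = loci[int(rng.integers(0, len(loci)))]
        block = (el.start + 100, el.start + 5000)
        frag = sim.genome.fetch(el.chrom, *block)
        sequences[read_id] = UNIVERSAL_PRIMER + frag + L1_RACE_PRIMER
        alignments.append(Alignment(
            read_id=read_id, chrom=el.chrom, strand=el.strand,
            blocks=[block], score=4900.0, primary=True, n_best=2))
        truth.append((read_id, "", "multimapped", 4900, False))

    truth_df = pd.DataFrame(truth, columns=["read_id", "element_id",
                                            "category", "span", "full_length"])
    return sequences, alignments, truth_df


def write_race_outputs(sequences: dict[str, str],
                       alignments: list[Alignment],
                       reads_fasta: str | Path,
                       blocks_tsv: str | Path) -> None:
    with open(reads_fasta, "w") as fh:
        for read_id, seq in sequences.items():
            fh.write(f">{read_id}\n{seq}\n")
    rows = [(a.read_id, a.chrom, a.strand,
             ",".join(f"{s}-{e}" for s, e in a.blocks), a.score,
             a.primary, a.n_best) for a in alignments]
    pd.DataFrame(rows, columns=["read_id", "chrom", "strand", "blocks",
                                "score", "primary", "n_best"]).to_csv(
        blocks_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bisulfite amplicons


def simulate_bisulfite_reads(
    reference: str,
    seed: int,
    n_reads: int = 300,
    state_mixture: Sequence[tuple[float, float]] = ((1.0, 0.9),),
    conversion_failure_rate: float = 0.005,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Bisulfite-converted amplicon reads from drawn CpG state vectors.

    ``state_mixture`` is (weight, per-CpG methylation probability) pairs;
    each read draws one mixture component, then independent per-CpG states.
    Non-CpG cytosines convert to T with rate 1 - conversion_failure_rate.
    Returns (reads as (id, sequence), per-read truth table).
    """
    from .bisulfite import reference_cpg_positions

    weights = np.array([w for w, _ in state_mixture], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum > 0")
    weights = weights / weights.sum()
    probs = [p for _, p in state_mixture]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    reference = reference.upper()
    cpg_pos = reference_cpg_positions(reference)
    cpg_set = set(cpg_pos)
    reads = []
    truth = []
    for i in range(n_reads):
        comp = int(rng.choice(len(probs), p=weights))
        p = probs[comp]
        states = rng.random(len(cpg_pos)) < p
        chars = list(reference)
        for pos, methylated in zip(cpg_pos, states):
            chars[pos] = "C" if methylated else "T"
        for pos, base in enumerate(reference):
            if base == "C" and pos not in cpg_set:
                if rng.random() >= conversion_failure_rate:
                    chars[pos] = "T"
        read_id = f"bsread{i}"
        reads.append((read_id, "".join(chars)))
        truth.append((read_id, comp, p, int(states.sum()),
                      "".join("M" if s else "u" for s in states)))
    truth_df = pd.DataFrame(truth, columns=["read_id", "component", "p",
                                            "mcpg", "pattern"])
    return reads, truth_df


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            attrs = (f'gene_id "{gene.gene_id}"; '
                     f'transcript_id "{gene.transcript_id}";')
            for s, e in sorted(gene.exons):
                fh.write(f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                         f"{gene.strand}\t.\t{attrs}\n")
            if gene.cds is not None:
                for s, e in _cds_genome_blocks(gene):
                    fh.write(f"{gene.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{gene.strand}\t0\t{attrs}\n")


def _cds_genome_blocks(gene: GeneModel) -> list[tuple[int, int]]:
    c0, c1 = gene.cds
    blocks = []
    offset = 0
    for s, e in gene.exons:  # already 5'->3'
        exon_len = e - s
        lo = max(c0, offset)
        hi = min(c1, offset + exon_len)
        if lo < hi:
            if gene.strand == "+":
                blocks.append((s + (lo - offset), s + (hi - offset)))
            else:
                blocks.append((e - (hi - offset), e - (lo - offset)))
        offset += exon_len
    return sorted(blocks)
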