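"""Targeted bisulfite amplicon analysis of L1 5'UTR monomers.

Per-read CpG methylation calling against a reference amplicon (bisulfite
conversion turns unmethylated C into T; methylated CpG Cs are protected),
conversion-efficiency QC over non-CpG cytosines, nonidentical-sequence
sampling, and the fully (mCpG = 0) / nearly (mCpG < 5) unmethylated
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

DEFAULT_MIN_CONVERSION = 0.95
NEARLY_UNMETHYLATED_MAX_MCPG = 5  # strict '<'

MISSING = "missing"


@dataclass
class AmpliconRead:
    read_id: str
    sequence: str
    cpg_states: list[str]  # per reference CpG: methylated/unmethylated/missing
    conversion_rate: float

    @property
    def mcpg(self) -> int:
        return sum(s == "methylated" for s in self.cpg_states)

    @property
    def scored_cpgs(self) -> int:
        return sum(s != MISSING for s in self.cpg_states)

    @property
    def mcpg_percent(self) -> float:
        n = self.scored_cpgs
        return 100.0 * self.mcpg / n if n else float("nan")


def reference_cpg_positions(reference: str) -> list[int]:
    ref = reference.upper()
    out = []
    idx = ref.find("CG")
    while idx != -1:
        out.append(idx)
        idx = ref.find("CG", idx + 1)
    return out


def _bisulfite_align(reference: str, read: str) -> dict[int, str]:
    """Map reference position -> read base, bisulfite-aware.

    Both sequences are C->T collapsed for alignment so conversion state does
    not penalize the alignment; the returned bases come from the original
    read.
    """
    if len(read) == len(reference):
        return {i: b for i, b in enumerate(read)}
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    ref_ct = reference.upper().replace("C", "T")
    read_ct = read.upper().replace("C", "T")
    aln = aligner.align(ref_ct, read_ct)[0]
    mapping: dict[int, str] = {}
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            mapping[r0 + off] = read[q0 + off]
    return mapping


def call_amplicon(
    read_id: str,
    sequence: str,
    reference: str,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
) -> AmpliconRead | None:
    """Call per-CpG methylation states for one amplicon read.

    At each reference CpG: C -> methylated, T -> unmethylated, anything
    else (or an indel) -> missing.  conversion_rate is the fraction of
    non-CpG reference Cs read as T; reads below ``min_conversion`` are
    rejected (returns None).
    """
    reference = reference.upper()
    sequence = sequence.upper()
    mapping = _bisulfite_align(reference, sequence)
    if not mapping:
        log.warning("read %s unalignable to reference, rejected", read_id)
        return None
    cpg_pos = set(reference_cpg_positions(reference))
    states = []
    for pos in sorted(cpg_pos):
        base = mapping.get(pos)
        if base == "C":
            states.append("methylated")
        elif base == "T":
            states.append("unmethylated")
        else:
            states.append(MISSING)
    converted = total = 0
    for pos, ref_base in enumerate(reference):
        if ref_base != "C" or pos in cpg_pos:
            continue
        base = mapping.get(pos)
        if base in ("C", "T"):
            total += 1
            converted += base == "T"
    rate = converted / total if total else 0.0
    if rate < min_conversion:
        log.info("read %s conversion rate %.3f < %.2f, rejected",
                 read_id, rate, min_conversion)
        return None
    return AmpliconRead(read_id=read_id, sequence=sequence,
                        cpg_states=states, conversion_rate=rate)


def call_amplicons(
    reads: Iterable[tuple[str, str]],
    reference: str,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
) -> list[AmpliconRead]:
    out = []
    for read_id, seq in reads:
        called = call_amplicon(read_id, seq, reference, min_conversion)
        if called is not None:
            out.append(called)
    return out


def sample_nonidentical(
    reads: Sequence[AmpliconRead],
    n: int = 100,
    seed: int = 0,
) -> list[AmpliconRead]:
    """Deduplicate by exact sequence identity, then sample n without
    replacement (seeded).  Returns all unique reads (with a warning) when
    fewer than n exist.
    """
    seen: dict[str, AmpliconRead] = {}
    for read in reads:
        seen.setdefault(read.sequence, read)
    unique = list(seen.values())
    if len(unique) <= n:
        if len(unique) < n:
            log.warning("only %d nonidentical reads available (requested %d)",
                        len(unique), n)
        return unique
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(unique), size=n, replace=False)
    return [unique[i] for i in sorted(idx)]


def classify_amplicons(reads: Sequence[AmpliconRead]) -> dict[str, float]:
    """Mean mCpG% plus fully / nearly unmethylated read counts.

    fully: mCpG = 0; nearly: 0 < mCpG < 5; the combined < 5 class
    (fully + nearly) is also reported.
    """
    n = len(reads)
    fully = sum(r.mcpg == 0 for r in reads)
    nearly = sum(0 < r.mcpg < NEARLY_UNMETHYLATED_MAX_MCPG for r in reads)
    mean_pct = (float(np.mean([r.mcpg_percent for r in reads]))
                if n else float("nan"))
    return {
        "n_reads": n,
        "mean_mcpg_percent": mean_pct,
        "fully_unmethylated": fully,
        "nearly_unmethylated": nearly,
        "under5_mcpg": fully + nearly,
    }


def amplicon_calls_frame(reads: Iterable[AmpliconRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.read_id, r.mcpg, r.scored_cpgs, r.mcpg_percent, r.conversion_rate,
          "".join("M" if s == "methylated" else
                  "u" if s == "unmethylated" else "." for s in r.cpg_states))
         for r in reads],
        columns=["read_id", "mcpg", "scored_cpgs", "mcpg_percent",
                 "conversion_rate", "pattern"])


def lollipop_matrix(reads: Sequence[AmpliconRead]) -> str:
    """Plain-text lollipop matrix: one row per read, filled = methylated."""
    lines = []
    for r in reads:
        lines.append("".join("●" if s == "methylated" else
                             "○" if s == "unmethylated" else "·"
                             for s in r.cpg_states))
    return "\n".join(lines)
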