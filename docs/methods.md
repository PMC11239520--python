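# Methods

This note documents the statistical model behind `retroepi`, the
parameter defaults and the reasons for them, what the synthetic data
generator does and does not emulate, the numerical choices, and known
limitations.

## Model

### Per-CpG calls and segment methylation

The unit observation is a per-read per-CpG methylation call carrying a
log-likelihood ratio (llr) of methylated vs unmethylated signal, as
produced by nanopolish-style callers. Calls are classified by a
symmetric threshold τ:

- llr ≥ τ → methylated
- llr ≤ −τ → unmethylated
- otherwise → ambiguous (excluded from all downstream counts)

Grouped calls covering k > 1 CpG motifs are expanded to k per-CpG calls
at the positions located by scanning the row's sequence context (the
first CG in the context anchors the row's start coordinate). All CpG
positions are strand-collapsed to the forward-strand C of the CG
dinucleotide.

A *segment* (a 10 kbp genome bin, or the 5'UTR interval of a
full-length L1) accumulates the non-ambiguous, primary-alignment calls
whose position falls inside it. Segment methylation is the fraction
methylated / (methylated + unmethylated). Distinct read identifiers are
counted per segment for coverage filtering.

### Differential methylation

For each element passing the coverage filter in both populations, the
2×2 table [methylated, unmethylated] × [population A, population B] is
tested with a two-sided Fisher exact test (point-probability rule: the
p-value is the sum of hypergeometric probabilities, over all tables
with the observed margins, that do not exceed the observed table's
probability, with a 1e-7 relative tolerance for floating-point ties —
the same convention used by standard implementations). P-values are
Bonferroni-corrected by the number of elements actually tested;
significance is corrected P < α. The effect direction is reported from
the sign of fraction(B) − fraction(A): a positive delta means the locus
is hypomethylated in population A.

Under the null (identical methylation probabilities) the Bonferroni
bound makes the familywise probability of any significant locus at most
α, which the acceptance suite verifies empirically over 100 simulated
null cohorts.

### Profiles

- *Composite profile*: position-wise mean methylation over the first
  2 kbp of six-monomer full-length elements, strand-oriented so copies
  align. Because calls sit on the forward-strand C of each CpG, a call
  at position p inside a minus-strand element maps to element-sense
  offset end − 2 − p (the element-sense C of that CpG is the complement
  of the G at p + 1). Positions covered by fewer than 5 calls are
  masked.
- *Locus profile*: for one element ± flank, a genome-space track (at
  each CpG, the call fraction within a centered 28 bp window) and a
  CpG-space track (per-CpG fraction indexed by CpG ordinal).

### 5'RACE TSS classification

A read is retained iff its alignment is primary with a single best
placement and the read carries the L1-specific primer at one terminus
and the 5'RACE universal primer at the other (either orientation, ≤ 2
mismatches, searched within the terminal 40 nt). A retained read is
assigned to the unique full-length L1 whose body contains the
alignment's 3' terminus on the element strand; the 5' terminus is the
putative TSS, categorized as upstream (within 1 kbp 5' of the element),
5'UTR, or body. A transcript is full-length when its aligned length
exceeds 6 kbp (strict). Ties between overlapping candidate elements are
left unassigned rather than guessed.

### Chimeric transcripts and frame check

A chimeric transcript must (i) have ≥ 2 exons, (ii) start inside an L1
5'UTR, (iii) run on the same strand as the partner gene, and (iv) have
a splice acceptor within ±2 bp of an annotated exon start of that gene.
Transcripts antisense to the host element are flagged as antisense-
promoter events (the canonical configuration). The frame check takes
the longest AUG-initiated ORF (≥ 50 codons, stop required) of the
spliced chimeric sequence and asks whether its translation ends with
the canonical protein's sequence from the first codon fully encoded in
the shared exons onward; when it does, the novel N-terminus length is
the chimeric protein length minus that shared suffix.

### Bisulfite amplicons

Reads are mapped to the reference amplicon (directly when lengths
match, otherwise by global alignment of C→T-collapsed sequences so
conversion state cannot bias the alignment). At each reference CpG,
C → methylated, T → unmethylated, anything else → missing. Conversion
efficiency is the fraction of non-CpG reference cytosines read as T;
reads below the cutoff are rejected. After exact-sequence
deduplication, a seeded sample of 100 nonidentical reads is classified:
fully unmethylated (mCpG = 0), nearly unmethylated (0 < mCpG < 5), and
the combined mCpG < 5 class.

## Parameter defaults and rationale

| Parameter | Default | Why |
| --- | --- | --- |
| llr threshold τ | 2.0 | standard nanopolish-style call confidence band; symmetric so neither state is favored |
| coverage filter | ≥ 4 reads and ≥ 20 calls per population | minimum evidence for a per-locus 2×2 test; loci failing in either population are not tested |
| significance | Bonferroni-corrected P < 0.01 | strict familywise control appropriate when a single escapee locus is a discovery |
| Bonferroni m | number of elements actually tested | correcting by untested loci would be anticonservative bookkeeping with no test behind it |
| genome bins | 10 kbp | locus-scale resolution matching L1 element size |
| full-length thresholds | L1 > 6000, B1 > 140, B2 > 185, MT2 > 470, IAP > 320 bp (strict) | full-length elements retain an intact promoter; strict inequality keeps the boundary unambiguous |
| monomer identity | ≥ 75% over a 5'-anchored gap-free walk | tolerant of monomer divergence while rejecting non-monomeric sequence; walk stops at the first sub-threshold window |
| composite profile | six-monomer elements, first 2 kbp, mask < 5 calls | fixed monomer count makes copies positionally comparable; masking suppresses single-read noise |
| locus window | 28 bp | sliding-window smoothing narrow enough to keep single-CpG resolution |
| RACE | terminal 40 nt, ≤ 2 primer mismatches, 1 kbp upstream window, full-length > 6 kbp | primer search window ≳ primer length + anchoring slack; 2 mismatches tolerates long-read error without losing specificity |
| chimera | ±2 bp acceptor tolerance, ≥ 50-codon ORF | tolerance absorbs alignment wobble at splice sites; the ORF floor excludes spurious micro-ORFs |
| bisulfite conversion QC | ≥ 0.95 | standard bisulfite conversion-efficiency cutoff |
| nonidentical sample | n = 100, seeded | deduplication removes PCR duplicates; fixed n makes class counts comparable across amplicons |

Problem sizes used by the acceptance suite (500-locus cohorts, 10
reads/locus over ~33 5'UTR CpGs, 1,000 RACE reads, 100 null cohorts)
are this package's own choices, set so that sampling noise is far
smaller than the stated tolerances.

## Synthetic generator: what it emulates, and what it does not

`simdata` plants, deterministically per seed (one `SeedSequence` with a
spawned child stream per sub-generator):

- Full-length L1 cohorts (default 500) with six tandem ~210 bp toy
  monomers plus a linker (a 1,400 bp 5'UTR holding ~33 CpGs), random
  strand, lengths 7.2–7.4 kbp, on two chromosomes; truncated L1 and
  SINE B1/B2, MT2, IAP decoys on a separate chromosome.
- Two populations with per-call Bernoulli methylation at preset
  per-population probabilities (PV+ 0.839, PV− 0.918), escapee loci at
  0.02, ambiguous calls injected at rate 0.05, llr magnitudes
  ~ N(5, 1) clipped above the call threshold.
- 5'RACE reads whose full-length share is *planted exactly* by
  stratified allocation of read categories (upstream / 5'UTR / body),
  randomized over loci and start positions. This is a deliberate
  design decision made before any acceptance run: planting the share
  exactly isolates pipeline error (filtering, assignment, length
  classification) from multinomial sampling noise, so the recovery
  tolerance measures the pipeline, not the dice. Primerless
  contaminants and multi-mapped decoys are appended to exercise the
  retention filter.
- One gene with an intronic antisense L1 whose 5'UTR drives a spliced
  chimeric transcript into gene exon 3, with a unique N-terminal
  cassette that keeps or (via a 4 bp deletion) breaks frame per config.
- Bisulfite amplicon reads drawn from a mixture of per-CpG methylation
  states with a configurable conversion-failure rate.

The toy monomer, linker, primers and ORF cassette are authored for this
package; they are not database extracts. The generator does **not**
emulate: raw nanopore signal or its error structure, sequence-dependent
call bias, alignment errors or clipped/chimeric mappings, indels in
RACE reads, realistic repeat divergence/phylogeny, PCR bias beyond
exact duplicates, or genome-scale element density.

## Numerical choices

- The two-sided Fisher exact p-value is computed from
  `scipy.stats.hypergeom.pmf` over the table's support, summing
  probabilities ≤ p_obs × (1 + 1e-7). The batch version caches the pmf
  per margin triple, which makes exhaustive sweeps and 500-locus
  cohorts fast; `scipy.stats.fisher_exact`, an exact integer
  enumeration via `math.comb`, and an exhaustive sweep of all 2×2
  tables with margins ≤ 40 all agree with it to well below 1e-9 in the
  test suite.
- Bonferroni is plain multiplication capped at 1, applied over tested
  elements.
- Segment fractions and profile means are exact ratios of integer
  counts; composite/locus profiles accumulate counts, not running
  means, so results are independent of call order.
- All RNG streams are `numpy` `default_rng` seeded from `SeedSequence`
  children; identical seeds give byte-identical outputs.

## Limitations

- Coverage and calls are simulated at uniform depth; the caller's
  behavior under heavily skewed coverage is tested only at the filter
  boundaries.
- The monomer detector is gap-free; monomer arrays with internal
  insertions/deletions will under-count monomers.
- TSS assignment trusts the alignment's terminal coordinates; no
  soft-clip recovery is attempted.
- The frame check compares protein suffixes, so a chimera that
  restores frame downstream of an internal indel is still called
  in-frame if its translation ends with the shared-exon suffix.
- Real-data scale claims (counts of differentially methylated loci in
  actual sorted-cell datasets, subfamily shares, numbers of chimera
  loci genome-wide) require the corresponding sequencing datasets and
  are out of scope for the synthetic acceptance suite; nothing in this
  document asserts them.
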