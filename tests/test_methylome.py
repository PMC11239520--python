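"""Unit tests for call loading, aggregation, Fisher DM and profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from retroepi import methylome, simdata
from retroepi.annotate import GenomeIndex, RetroElement, revcomp
from retroepi.methylome import (MethCall, SegmentMethylation, classify_llr,
                                composite_profile, coverage_filter,
                                differential_methylation, fisher_exact_2x2,
                                fisher_exact_batch, load_meth_calls,
                                locus_profile, segment_methylation)


def _call(pos, state, read="r0", chrom="c", pop="A", primary=True):
    llr = {"methylated": 5.0, "unmethylated": -5.0, "ambiguous": 0.0}[state]
    return MethCall(read_id=read, chrom=chrom, pos=pos, llr=llr, state=state,
                    population=pop, primary=primary)


# --- llr classification and loading ----------------------------------------

@pytest.mark.parametrize("llr,state", [
    (5.1, "methylated"), (2.0, "methylated"), (1.99, "ambiguous"),
    (-0.4, "ambiguous"), (-1.99, "ambiguous"), (-2.0, "unmethylated"),
    (-7.3, "unmethylated"),
])
def test_classify_llr_boundaries(llr, state):
    assert classify_llr(llr) == state


def test_load_simple_dialect(tmp_path):
    path = tmp_path / "calls.tsv"
    pd.DataFrame({"read_id": ["r1", "r2"], "chrom": ["c", "c"],
                  "pos": [10, 20], "llr": [5.1, -0.4],
                  "primary": [True, True]}).to_csv(path, sep="\t", index=False)
    calls = load_meth_calls(path, "A")
    assert [c.state for c in calls] == ["methylated", "ambiguous"]
    assert all(c.population == "A" for c in calls)


def test_load_nanopolish_grouped_calls(tmp_path):
    sequence = "ATCGGACGTTCGA"  # CGs at offsets 2, 6, 10
    naive = [i for i in range(len(sequence) - 1) if sequence[i:i + 2] == "CG"]
    row = {"chromosome": "c", "strand": "+", "start": 1000, "end": 1010,
           "read_name": "r1", "log_lik_ratio": 4.0,
           "log_lik_methylated": 4.0, "log_lik_unmethylated": 0.0,
           "num_calling_strands": 1, "num_motifs": 3, "sequence": sequence}
    path = tmp_path / "np.tsv"
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)
    calls = load_meth_calls(path, "A")
    assert len(calls) == 3
    assert [c.pos for c in calls] == [1000 + off - naive[0] for off in naive]
    assert all(c.state == "methylated" for c in calls)


# --- segment aggregation -----------------------------------------------------

def test_segment_methylation_examples():
    seg = [("s1", "c", 0, 100)]
    calls = [_call(i, "methylated", read=f"r{i}") for i in range(9)]
    calls.append(_call(50, "unmethylated", read="r9"))
    (row,) = segment_methylation(calls, seg)
    assert row.fraction == pytest.approx(0.9)
    assert row.n_reads == 10

    calls = ([_call(1, "methylated")] * 5 + [_call(2, "unmethylated")] * 5
             + [_call(3, "ambiguous")] * 90)
    (row,) = segment_methylation(calls, seg)
    assert (row.n_calls, row.fraction) == (10, 0.5)


def test_segment_methylation_zero_call_segments_and_nonprimary():
    segs = [("s1", "c", 0, 10), ("s2", "c", 50, 60)]
    calls = [_call(5, "methylated"), _call(6, "methylated", primary=False)]
    rows = segment_methylation(calls, segs)
    assert [(r.segment_id, r.n_calls) for r in rows] == [("s1", 1), ("s2", 0)]
    assert math.isnan(rows[1].fraction)


def _random_fixture(rng, n_segments=8, n_calls=200):
    segs = []
    for i in range(n_segments):
        chrom = f"c{rng.integers(0, 2)}"
        start = int(rng.integers(0, 900))
        segs.append((f"s{i}", chrom, start, start + int(rng.integers(5, 120))))
    calls = []
    for i in range(n_calls):
        state = ["methylated", "unmethylated", "ambiguous"][rng.integers(0, 3)]
        calls.append(_call(int(rng.integers(0, 1000)), state,
                           read=f"r{rng.integers(0, 40)}",
                           chrom=f"c{rng.integers(0, 2)}",
                           primary=bool(rng.random() < 0.9)))
    return segs, calls


def _naive_segment_methylation(calls, segs):
    rows = []
    for seg_id, chrom, start, end in segs:
        reads, meth, unmeth = set(), 0, 0
        for c in calls:
            if (c.primary and c.state != "ambiguous" and c.chrom == chrom
                    and start <= c.pos < end):
                reads.add(c.read_id)
                meth += c.state == "methylated"
                unmeth += c.state == "unmethylated"
        rows.append((seg_id, len(reads), meth, unmeth))
    return rows


def test_segment_methylation_matches_naive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        segs, calls = _random_fixture(rng)
        got = [(r.segment_id, r.n_reads, r.n_meth, r.n_unmeth)
               for r in segment_methylation(calls, segs)]
        assert got == _naive_segment_methylation(calls, segs)


def test_bin_conservation(small_sim):
    """Sum of bin call counts equals the number of retained calls."""
    from retroepi.annotate import genome_bins

    df = simdata.simulate_meth_calls(small_sim, "PVpos", seed=5)
    calls = [MethCall(read_id=r.read_id, chrom=r.chrom, pos=int(r.pos),
                      llr=float(r.llr), state=classify_llr(float(r.llr)),
                      population="PVpos", primary=bool(r.primary))
             for r in df.itertuples(index=False)]
    bins = genome_bins(small_sim.genome)
    rows = segment_methylation(calls, bins)
    retained = sum(1 for c in calls if c.primary and c.state != "ambiguous")
    assert sum(r.n_calls for r in rows) == retained


# --- coverage filter ---------------------------------------------------------

def _seg_row(seg, pop, reads, calls):
    return SegmentMethylation(segment_id=seg, population=pop, n_reads=reads,
                              n_calls=calls, n_meth=calls, n_unmeth=0)


def test_coverage_filter_boundaries():
    rows = [_seg_row("e1", "A", 4, 20), _seg_row("e1", "B", 4, 20),
            _seg_row("e2", "A", 10, 19), _seg_row("e2", "B", 10, 50),
            _seg_row("e3", "A", 3, 40), _seg_row("e3", "B", 10, 40),
            _seg_row("e4", "A", 0, 0), _seg_row("e4", "B", 10, 40)]
    assert coverage_filter(rows, ["A", "B"]) == {"e1"}


# --- Fisher exact ------------------------------------------------------------

def _fisher_oracle(a, b, c, d):
    """Exact integer enumeration with the documented 1e-7 tie tolerance."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    nums = [math.comb(n1, i) * math.comb(n2, k - i) for i in range(lo, hi + 1)]
    na = nums[a - lo]
    s = sum(v for v in nums if v * 10**7 <= na * (10**7 + 1))
    return s / math.comb(n1 + n2, k)


def test_fisher_identical_proportions():
    assert fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)


def test_fisher_examples_match_oracle():
    for table in ((90, 10, 60, 40), (0, 20, 20, 0), (5, 0, 0, 5), (1, 0, 0, 0)):
        assert fisher_exact_2x2(*table) == pytest.approx(
            _fisher_oracle(*table), abs=1e-12)


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_exact_batch([-1], [1], [1], [1])


# --- differential methylation ------------------------------------------------

def _dm_row(seg, pop, meth, unmeth, reads=10):
    return SegmentMethylation(segment_id=seg, population=pop, n_reads=reads,
                              n_calls=meth + unmeth, n_meth=meth,
                              n_unmeth=unmeth)


def test_dm_identical_fractions_not_significant():
    a = [_dm_row("e1", "A", 150, 150)]
    b = [_dm_row("e1", "B", 150, 150)]
    (res,) = differential_methylation(a, b)
    assert not res.significant
    assert res.direction == "none"


def test_dm_single_element_padj_equals_p():
    a = [_dm_row("e1", "A", 10, 290)]
    b = [_dm_row("e1", "B", 270, 30)]
    (res,) = differential_methylation(a, b)
    assert res.p_adj == pytest.approx(res.p)
    assert res.significant
    assert res.direction == "hypomethylated_in_A"


def test_dm_planted_escapees_all_recovered():
    a = simdata.simulate_segment_counts(500, 0.839, seed=4, population="A",
                                        escapee_indices=range(20))
    b = simdata.simulate_segment_counts(500, 0.918, seed=5, population="B")
    results = differential_methylation(a, b)
    sig = {r.element_id for r in results if r.significant}
    assert {f"locus{i}" for i in range(20)} <= sig
    assert all(r.direction == "hypomethylated_in_A"
               for r in results if r.significant)
    # output ranked by |delta|: escapees dominate the top of the table
    assert {r.element_id for r in results[:20]} == {f"locus{i}"
                                                    for i in range(20)}


def test_dm_alpha_validation():
    with pytest.raises(ValueError):
        differential_methylation([], [], alpha=0.0)


# --- composite profile -------------------------------------------------------

def _composite_fixture():
    """Three six-monomer elements (one '-') plus one five-monomer decoy."""
    rng = np.random.default_rng(9)
    monomer = simdata.TOY_MONOMER
    sense = monomer * 6 + simdata.TOY_LINKER + simdata._random_seq(rng, 1200)
    seqs, elements = {}, []
    layout = [("c0", "+", 6), ("c1", "-", 6), ("c2", "+", 6), ("c3", "+", 5)]
    for chrom, strand, monomers in layout:
        body = sense if strand == "+" else revcomp(sense)
        pad = simdata._random_seq(rng, 37)
        seqs[chrom] = pad + body + pad
        elements.append(RetroElement(
            element_id=chrom, chrom=chrom, start=len(pad),
            end=len(pad) + len(body), strand=strand, superfamily="L1",
            subfamily="TFI", full_length=True, monomer_count=monomers))
    genome = GenomeIndex(seqs)
    calls = []
    from retroepi.annotate import extract_cpg_sites
    for el in elements:
        for site in extract_cpg_sites(genome, el.chrom, el.start, el.end):
            for ri in range(8):
                state = "methylated" if rng.random() < 0.8 else "unmethylated"
                calls.append(_call(site.pos, state, read=f"{el.chrom}r{ri}",
                                   chrom=el.chrom))
    return genome, elements, calls


def _naive_composite(elements, calls, span=2000, min_calls=5):
    chosen = [el for el in elements if el.monomer_count == 6]
    sums, counts = {}, {}
    for c in calls:
        if c.state == "ambiguous" or not c.primary:
            continue
        for el in chosen:
            if c.chrom == el.chrom and el.start <= c.pos < el.end:
                rel = (c.pos - el.start if el.strand == "+"
                       else el.end - 2 - c.pos)
                if 0 <= rel < span:
                    sums[rel] = sums.get(rel, 0) + (c.state == "methylated")
                    counts[rel] = counts.get(rel, 0) + 1
    return {pos: (sums[pos] / counts[pos] if counts[pos] >= min_calls
                  else float("nan"), counts[pos]) for pos in counts}


def test_composite_profile_matches_naive_oracle_and_excludes_five_monomers():
    _genome, elements, calls = _composite_fixture()
    df = composite_profile(elements, calls)
    oracle = _naive_composite(elements, calls)
    assert set(df["position"]) == set(oracle)
    for row in df.itertuples(index=False):
        mean, n = oracle[row.position]
        assert row.n_calls == n
        if math.isnan(mean):
            assert math.isnan(row.mean_methylation)
        else:
            assert row.mean_methylation == mean  # identical arithmetic
    # strand alignment: identical planted monomers => every covered position
    # draws from all three six-monomer elements, including the '-' one
    assert (df["n_elements"] == 3).all()


def test_composite_profile_all_methylated_constant_one():
    _genome, elements, calls = _composite_fixture()
    forced = [_call(c.pos, "methylated", read=c.read_id, chrom=c.chrom)
              for c in calls]
    df = composite_profile(elements, forced)
    covered = df.dropna(subset=["mean_methylation"])
    assert (covered["mean_methylation"] == 1.0).all()


def test_composite_profile_empty_without_qualifying_elements():
    df = composite_profile([], [])
    assert df.empty


# --- locus profile -----------------------------------------------------------

def _locus_fixture():
    rng = np.random.default_rng(13)
    monomer = simdata.TOY_MONOMER
    seq = simdata._random_seq(rng, 300) + monomer * 4 + simdata._random_seq(
        rng, 300)
    genome = GenomeIndex({"c": seq})
    el = RetroElement(element_id="e", chrom="c", start=300,
                      end=300 + 4 * len(monomer), strand="+",
                      superfamily="L1", full_length=True)
    return genome, el


def test_locus_profile_uniform_half():
    genome, el = _locus_fixture()
    from retroepi.annotate import extract_cpg_sites
    sites = extract_cpg_sites(genome, "c", 0, genome.lengths["c"])
    calls = []
    for s in sites:
        calls.append(_call(s.pos, "methylated", read="r1"))
        calls.append(_call(s.pos, "unmethylated", read="r2"))
    prof = locus_profile(el, calls, genome, flank=100)
    covered = prof["genome_space"].dropna(subset=["smoothed_fraction"])
    assert not covered.empty
    assert (covered["smoothed_fraction"] == 0.5).all()


def test_locus_profile_step_change_and_cpg_space_length():
    genome, el = _locus_fixture()
    from retroepi.annotate import extract_cpg_sites
    flank = 100
    sites = extract_cpg_sites(genome, "c", el.start - flank, el.end + flank)
    breakpoint_pos = el.start + 2 * len(simdata.TOY_MONOMER)
    calls = []
    for s in sites:
        state = "unmethylated" if s.pos < breakpoint_pos else "methylated"
        for ri in range(4):
            calls.append(_call(s.pos, state, read=f"r{ri}"))
    prof = locus_profile(el, calls, genome, flank=flank, window=28)
    assert len(prof["cpg_space"]) == len(sites)
    track = prof["genome_space"].dropna(subset=["smoothed_fraction"])
    before = track[track["pos"] < breakpoint_pos - 28]
    after = track[track["pos"] >= breakpoint_pos + 28]
    assert (before["smoothed_fraction"] == 0.0).all()
    assert (after["smoothed_fraction"] == 1.0).all()


# --- strand invariance -------------------------------------------------------

def test_segment_and_composite_strand_mirror_invariance():
    genome, elements, calls = _composite_fixture()
    segs = [(el.element_id, el.chrom, el.start, el.end) for el in elements]
    base_seg = segment_methylation(calls, segs)
    base_comp = composite_profile(elements, calls)

    lengths = dict(genome.lengths)
    m_elements = []
    for el in elements:
        L = lengths[el.chrom]
        m_elements.append(RetroElement(
            element_id=el.element_id, chrom=el.chrom, start=L - el.end,
            end=L - el.start, strand="-" if el.strand == "+" else "+",
            superfamily=el.superfamily, subfamily=el.subfamily,
            full_length=el.full_length, monomer_count=el.monomer_count))
    m_calls = [MethCall(read_id=c.read_id, chrom=c.chrom,
                        pos=lengths[c.chrom] - c.pos - 2, llr=c.llr,
                        state=c.state, population=c.population,
                        primary=c.primary) for c in calls]
    m_segs = [(el.element_id, el.chrom, el.start, el.end) for el in m_elements]
    mirror_seg = segment_methylation(m_calls, m_segs)
    mirror_comp = composite_profile(m_elements, m_calls)

    for b, m in zip(base_seg, mirror_seg):
        assert (b.segment_id, b.n_meth, b.n_unmeth) == (
            m.segment_id, m.n_meth, m.n_unmeth)
    pd.testing.assert_frame_equal(base_comp, mirror_comp)
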