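"""Read calling, QC filters, residue counts and enrichment."""

import numpy as np
import pandas as pd
import pytest

from actmap.refseq import CodingSequence
from actmap.screen import (
    MutagenesisScreen,
    ResidueCounts,
    accumulate_residue_counts,
    call_read_mutations,
    enrichment,
    evaluate_read,
    qc_filter_read,
    residue_frequency,
    top_enriched_substitution,
)
from actmap.simulate import simulate_reads, simulate_eppcr_library, SimulatedPool
from conftest import make_read

# M  W  A  K  L  *
CDS = CodingSequence("mini", "ATGTGGGCTAAACTTTAA")


def test_reference_identical_read_yields_no_calls():
    read = make_read(CDS, 1, CDS.nt)
    assert call_read_mutations(read, CDS) == []


def test_low_quality_mismatches_are_treated_as_reference():
    # two mismatches: pos1 A->C at quality 10, pos18 A->G at quality 40
    quals = np.full(18, 40)
    quals[0] = 10
    read = make_read(CDS, 1, "CTGTGGGCTAAACTTTAG", quals)
    calls = call_read_mutations(read, CDS, min_base_quality=20)
    assert len(calls) == 1
    assert (calls[0].sub.pos, calls[0].sub.alt) == (18, "G")


def test_direct_diff_against_reference(toy_cds):
    read = make_read(toy_cds, 1, "CTGGCT")
    calls = call_read_mutations(read, toy_cds)
    assert [(c.sub.pos, c.sub.ref, c.sub.alt) for c in calls] == [(1, "A", "C")]


def test_ambiguous_bases_are_skipped(toy_cds):
    read = make_read(toy_cds, 1, "NTGGCT")
    assert call_read_mutations(read, toy_cds) == []


def test_qc_discards_reads_with_too_many_mutations():
    bases = "CTGAGGGTTAAACCTTAA"  # 4 high-quality mismatches, no stop
    read = make_read(CDS, 1, bases)
    calls = call_read_mutations(read, CDS)
    assert len(calls) == 4
    result = qc_filter_read(read, calls, CDS, max_mutations=3)
    assert not result.kept and result.reason == "too_many_mutations"


def test_qc_three_mutations_is_kept_boundary_is_strict():
    bases = "CTGAGGGTTAAACCTTAA".replace("GTT", "GCT")  # back to 3 mismatches
    read = make_read(CDS, 1, bases)
    calls = call_read_mutations(read, CDS)
    assert len(calls) == 3
    result = qc_filter_read(read, calls, CDS, max_mutations=3)
    assert result.kept and result.reason == "ok"


def test_qc_discards_internal_stop_but_not_terminal_stop():
    stop_read = make_read(CDS, 1, "ATGTAGGCTAAACTTTAA")  # W2* via TGG->TAG
    result = evaluate_read(stop_read, CDS)
    assert not result.kept and result.reason == "internal_stop"
    # mutating the reference's own terminal stop codon is read-through, kept
    readthrough = make_read(CDS, 1, "ATGTGGGCTAAACTTCAA")
    result = evaluate_read(readthrough, CDS)
    assert result.kept
    assert result.variants == {6: "Q"}


def test_qc_internal_stop_only_within_covered_codons():
    # the read carries the stop-making call but does not fully cover codon 2
    read = make_read(CDS, 5, "AGGCTAAACTTTAA")  # starts mid-codon-2; pos5 G->A
    result = evaluate_read(read, CDS)
    assert result.kept  # codon 2 not fully spanned, stop not witnessed
    assert result.covered_residues == (3, 6)


def test_indel_and_out_of_range_reasons():
    read = make_read(CDS, 1, CDS.nt, indel=True)
    assert evaluate_read(read, CDS).reason == "indel_or_clip"
    read = make_read(CDS, 10, CDS.nt)  # runs past the reference end
    assert evaluate_read(read, CDS).reason == "out_of_range"


def test_accumulate_bookkeeping():
    ref_reads = [
        evaluate_read(make_read(CDS, 1, CDS.nt, read_id=f"r{i}"), CDS)
        for i in range(100)
    ]
    counts = accumulate_residue_counts(ref_reads, CDS)
    assert counts.covering[0] == 100 and counts.mutant.sum() == 0

    m1l = evaluate_read(make_read(CDS, 1, "CTG" + CDS.nt[3:]), CDS)
    counts = accumulate_residue_counts([m1l], CDS)
    assert counts.covering.tolist() == [1] * 6
    assert counts.mutant.tolist() == [1, 0, 0, 0, 0, 0]
    assert counts.by_alt[1] == {"L": 1}

    syn = evaluate_read(make_read(CDS, 1, CDS.nt[:8] + "A" + CDS.nt[9:]), CDS)
    counts = accumulate_residue_counts([syn], CDS)  # GCT->GCA, still Ala
    assert counts.covering[2] == 1 and counts.mutant[2] == 0


def test_residue_frequency_and_undefined_marker():
    counts = ResidueCounts.empty(3)
    counts.covering[:] = [100, 100, 0]
    counts.mutant[:] = [5, 0, 0]
    assert residue_frequency(counts, 1) == 0.05
    assert residue_frequency(counts, 2) == 0.0
    assert np.isnan(residue_frequency(counts, 3))


def _counts(cds, covering, mutant):
    c = ResidueCounts.empty(cds.n_codons)
    c.covering[:] = covering
    c.mutant[:] = mutant
    return c


def test_enrichment_fold_change_arithmetic(toy_cds):
    pre = _counts(toy_cds, [100, 100], [5, 5])
    post = _counts(toy_cds, [100, 100], [25, 5])
    table = enrichment(pre, post, toy_cds, pseudocount=0.0, threshold=4.0)
    assert table.fold_change[0] == pytest.approx(5.0)
    assert bool(table.is_hit[0]) is True
    assert table.fold_change[1] == pytest.approx(1.0)
    assert bool(table.is_hit[1]) is False


def test_enrichment_pseudocount_keeps_zero_pre_rankable(toy_cds):
    pre = _counts(toy_cds, [100, 100], [0, 0])
    post = _counts(toy_cds, [100, 100], [10, 0])
    table = enrichment(pre, post, toy_cds, pseudocount=0.5)
    assert table.fold_change[0] == pytest.approx((10.5 / 101) / (0.5 / 101))
    assert table.fold_change[0] == pytest.approx(21.0)


def test_enrichment_zero_coverage_excluded_from_hits(toy_cds):
    pre = _counts(toy_cds, [0, 100], [0, 0])
    post = _counts(toy_cds, [100, 100], [50, 0])
    table = enrichment(pre, post, toy_cds)
    assert np.isnan(table.fold_change[0])
    assert bool(table.is_hit[0]) is False


def test_top_enriched_substitution_tie_breaks_alphabetically():
    counts = ResidueCounts.empty(2)
    counts.by_alt[1] = {"P": 12, "R": 3}
    counts.by_alt[2] = {"H": 5, "Y": 5}
    assert top_enriched_substitution(counts, 1) == "P"
    assert top_enriched_substitution(counts, 2) == "H"
    assert top_enriched_substitution(counts, 2) is not None
    counts.by_alt.pop(2)
    assert top_enriched_substitution(counts, 2) is None


def test_wild_type_pools_give_unit_fold_change(ref120):
    """Error-free wild-type reads: zero frequency, fold change exactly 1."""
    library = simulate_eppcr_library(ref120, lam=0.0, n_clones=50, seed=0)
    pool = SimulatedPool(library, np.arange(50))
    reads = simulate_reads(pool, depth=600, error_rate=0.0, seed=1)
    results = MutagenesisScreen(ref120, reads, reads).fit()
    t = results.enrichment
    covered = t[(t.pre_covering > 0) & (t.post_covering > 0)]
    assert (covered.pre_freq == 0).all()
    assert covered.fold_change.to_numpy() == pytest.approx(1.0)
    assert not covered.is_hit.any()


def test_filter_monotonicity(ref120):
    """A stricter mutation cap never keeps more reads; a stricter quality
    cut-off never calls more mutations per read (and, by removing calls,
    can only rescue reads from the count and stop filters)."""
    library = simulate_eppcr_library(ref120, lam=3.0, n_clones=200, seed=3)
    pool = SimulatedPool(library, np.arange(200))
    reads = simulate_reads(pool, depth=500, error_rate=0.005, seed=4)

    def n_kept(min_bq, max_muts):
        return sum(
            evaluate_read(r, ref120, min_bq, max_muts).kept for r in reads
        )

    assert n_kept(20, 2) <= n_kept(20, 3) <= n_kept(20, 4)
    assert n_kept(10, 3) <= n_kept(20, 3) <= n_kept(30, 3)
    from actmap.screen import call_read_mutations

    for read in reads[:100]:
        n10 = len(call_read_mutations(read, ref120, 10))
        n20 = len(call_read_mutations(read, ref120, 20))
        n30 = len(call_read_mutations(read, ref120, 30))
        assert n10 >= n20 >= n30


def test_streaming_accumulator_matches_naive_matrix_oracle(ref120):
    """Frequencies from the streaming path equal a full-matrix recomputation."""
    library = simulate_eppcr_library(
        ref120, lam=1.5, n_clones=300, inactivating_residues={30: 0.0}, seed=8
    )
    pool = SimulatedPool(library, np.arange(300))
    reads = simulate_reads(pool, depth=800, error_rate=0.002, seed=9)
    kept = [r for r in (evaluate_read(x, ref120) for x in reads) if r.kept]
    counts = accumulate_residue_counts(kept, ref120)

    # naive oracle: dense per-read x per-residue matrices
    n = ref120.n_codons
    covering = np.zeros(n, dtype=int)
    mutant = np.zeros(n, dtype=int)
    for r in kept:
        first, last = r.covered_residues
        for res in range(first, last + 1):
            covering[res - 1] += 1
            if res in r.variants:
                mutant[res - 1] += 1
    assert np.array_equal(counts.covering, covering)
    assert np.array_equal(counts.mutant, mutant)
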