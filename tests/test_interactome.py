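"""NSAF normalisation, replicate filtering, fold change and modified Z."""

import numpy as np
import pandas as pd
import pytest

from actmap.interactome import (
    InteractomeComparison,
    MissingBaitError,
    SpectralCountTable,
    combine_isoforms,
    error_estimate,
    fold_change,
    modified_z,
    nsaf,
    rank_interactors,
    relative_nsaf,
    replicate_filter,
)


def make_table(counts: dict, lengths: dict, bait="BAIT", conds=("WT", "MUT")):
    """counts: protein -> list of 6 values (WT r1-3 then MUT r1-3)."""
    cols = pd.MultiIndex.from_product([conds, [1, 2, 3]])
    df = pd.DataFrame.from_dict(counts, orient="index")
    df.columns = cols
    return SpectralCountTable(
        counts=df,
        lengths=pd.Series(lengths, dtype=float),
        bait_id=bait,
        conditions=conds,
    )


def test_combine_isoforms():
    length, counts = combine_isoforms([400, 600], np.array([[3], [1]]))
    assert length == 500 and counts.tolist() == [4]
    length, counts = combine_isoforms([300, 300, 300], np.zeros((3, 2)))
    assert length == 300
    with pytest.raises(ValueError):
        combine_isoforms([0, 100], np.zeros((2, 1)))


@pytest.mark.parametrize(
    "counts,lengths,expected",
    [
        ({"A": 10, "B": 30}, {"A": 100, "B": 300}, {"A": 0.5, "B": 0.5}),
        ({"A": 7}, {"A": 123}, {"A": 1.0}),
        ({"A": 10, "B": 10}, {"A": 100, "B": 400}, {"A": 0.8, "B": 0.2}),
    ],
)
def test_nsaf_length_normalisation(counts, lengths, expected):
    out = nsaf(pd.Series(counts, dtype=float), pd.Series(lengths, dtype=float))
    for protein, value in expected.items():
        assert out[protein] == pytest.approx(value)
    assert out.sum() == pytest.approx(1.0)


def test_nsaf_empty_sample_errors():
    with pytest.raises(ValueError):
        nsaf(pd.Series({"A": 0.0}), pd.Series({"A": 100.0}))


def test_relative_nsaf():
    rel = relative_nsaf(pd.Series({"BAIT": 0.25, "A": 0.05}), "BAIT")
    assert rel["BAIT"] == 1.0 and rel["A"] == pytest.approx(0.2)
    with pytest.raises(MissingBaitError):
        relative_nsaf(pd.Series({"A": 0.05}), "BAIT")
    with pytest.raises(MissingBaitError):
        relative_nsaf(pd.Series({"BAIT": 0.0, "A": 1.0}), "BAIT")


def test_replicate_filter_and_or_semantics():
    table = make_table(
        {
            "BAIT": [9, 9, 9, 9, 9, 9],
            "ALLWT": [2, 1, 3, 0, 0, 0],   # complete in WT only -> kept
            "NEITHER": [2, 0, 3, 1, 0, 2],  # incomplete in both -> dropped
            "BOTH": [1, 1, 1, 1, 1, 1],
        },
        {"BAIT": 500, "ALLWT": 300, "NEITHER": 300, "BOTH": 300},
    )
    kept = set(replicate_filter(table))
    assert kept == {"BAIT", "ALLWT", "BOTH"}


def test_fold_change_is_mean_of_ratios():
    per_rep, avg = fold_change([2, 4, 6], [1, 2, 3])
    assert per_rep.tolist() == [2, 2, 2] and avg == 2.0
    _, avg = fold_change([1, 2, 4], [1, 2, 4])
    assert avg == 1.0
    per_rep, avg = fold_change([1, 2, 4], [1, 1, 1])
    assert per_rep.tolist() == [1, 2, 4]
    assert avg == pytest.approx(7 / 3)  # mean of ratios, not ratio of means
    with pytest.raises(ValueError):
        fold_change([1, 2], [1, 0])


def test_error_estimate_formula():
    assert error_estimate([2, 2, 2]) == 0.0
    expected = (np.log2(7 / 3) + np.log2(7 / 6) + np.log2(12 / 7)) / 3
    assert error_estimate([1, 2, 4]) == pytest.approx(expected, abs=1e-12)
    assert error_estimate([1, 2, 4]) == pytest.approx(0.7408, abs=1e-4)
    assert error_estimate([1, 2, 4], agg="sum") == pytest.approx(3 * expected)
    with pytest.raises(ValueError):
        error_estimate([1, 0, 2])


def test_error_estimate_scale_invariance():
    rng = np.random.default_rng(0)
    values = rng.lognormal(size=3)
    for scale in (1e-6, 1.0, 42.0):
        assert error_estimate(values * scale) == pytest.approx(
            error_estimate(values), rel=1e-12
        )


def test_modified_z():
    z, floored = modified_z(1.0, 0.3, 0.2)
    assert z == 0.0 and not floored
    err = (np.log2(7 / 3) + np.log2(7 / 6) + np.log2(12 / 7)) / 3
    z, _ = modified_z(7 / 3, err, 0.0)
    assert z == pytest.approx(np.log2(7 / 3) / err)
    assert z == pytest.approx(1.650, abs=1e-3)
    z, floored = modified_z(2.0, 0.0, 0.0, epsilon=1e-6)
    assert floored and z == pytest.approx(1e6)
    with pytest.raises(ValueError):
        modified_z(0.0, 0.1, 0.1)


def test_rank_interactors_ordering():
    rows = pd.DataFrame(
        {
            "protein": ["a", "b", "c", "d"],
            "avg_fc": [35.0, 52.0, 2.0, 2.0],
            "modified_z": [1.0, 1.0, 1.0, 4.0],
        }
    )
    ranked = rank_interactors(rows)
    assert ranked.protein.tolist() == ["b", "a", "d", "c"]


def test_model_pipeline_matches_hand_computation():
    """Full fit against arithmetic done longhand on a 3-protein table."""
    table = make_table(
        {
            "BAIT": [50, 50, 50, 50, 50, 50],
            "A": [10, 10, 10, 5, 5, 5],
            "B": [4, 4, 4, 4, 4, 4],
        },
        {"BAIT": 500, "A": 500, "B": 500},
    )
    res = InteractomeComparison(table).fit()
    s = res.scores.set_index("protein")
    # equal lengths: relative NSAF = count ratio to bait; A: 0.2 vs 0.1
    assert s.loc["A", "avg_fc"] == pytest.approx(2.0)
    assert s.loc["A", "error_total"] == pytest.approx(0.0, abs=1e-12)
    assert s.loc["A", "floored"]
    assert s.loc["B", "avg_fc"] == pytest.approx(1.0)
    assert s.loc["BAIT", "avg_fc"] == 1.0
    assert s.loc["BAIT", "modified_z"] == 0.0
    assert res.n_candidates == 3
    assert res.scores.protein.tolist()[0] == "A"  # ranked by avg_fc


def test_swapping_conditions_inverts_per_replicate_fold_changes():
    table = make_table(
        {
            "BAIT": [50, 40, 60, 50, 50, 50],
            "A": [10, 14, 9, 5, 3, 8],
        },
        {"BAIT": 500, "A": 350},
    )
    fwd = InteractomeComparison(table, cond_a="WT", cond_b="MUT").fit()
    rev = InteractomeComparison(table, cond_a="MUT", cond_b="WT").fit()
    f = fwd.scores.set_index("protein").loc["A"]
    r = rev.scores.set_index("protein").loc["A"]
    for rep in (1, 2, 3):
        assert r[f"fc_rep{rep}"] == pytest.approx(1.0 / f[f"fc_rep{rep}"])
    # the mean of reciprocals is NOT the reciprocal of the mean
    assert r["avg_fc"] != pytest.approx(1.0 / f["avg_fc"])


def test_zero_count_imputation_policy():
    """Absent-in-one-condition proteins stay scoreable via 0.5-count imputation."""
    table = make_table(
        {
            "BAIT": [50, 50, 50, 50, 50, 50],
            "ONLYWT": [8, 8, 8, 0, 0, 0],
        },
        {"BAIT": 500, "ONLYWT": 500},
    )
    res = InteractomeComparison(table).fit()
    s = res.scores.set_index("protein")
    # imputed relative NSAF in MUT = (0.5/500)/(50/500) = 0.01; WT = 0.16
    assert s.loc["ONLYWT", "avg_fc"] == pytest.approx(0.16 / 0.01)
    assert s.loc["ONLYWT", "detected_in"] == "WT"
    # reported NSAF columns keep the true zero
    assert s.loc["ONLYWT", "relnsaf_MUT_rep1"] == 0.0


def test_nsaf_sums_to_one_per_sample_in_model():
    rng = np.random.default_rng(3)
    counts = {f"P{i}": rng.integers(0, 30, size=6).tolist() for i in range(20)}
    counts["BAIT"] = [40] * 6
    lengths = {p: float(rng.integers(100, 900)) for p in counts}
    table = make_table(counts, lengths)
    model = InteractomeComparison(table)
    rel, _ = model._relative_nsafs()
    for col in table.counts.columns:
        sample = nsaf(table.counts[col], table.lengths)
        assert sample.sum() == pytest.approx(1.0, abs=1e-9)
        assert rel.loc["BAIT", col] == 1.0
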