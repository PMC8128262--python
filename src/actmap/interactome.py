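"""Comparative AP-MS interactome scoring from spectral counts.

Two pulldown conditions (e.g. wild-type vs an inactive point-mutant
bait), each with matched biological replicates, are compared per protein:

1. spectral counts across a protein group's isoforms are combined and
   normalised to the mean isoform length;
2. each sample's length-normalised counts are converted to normalised
   spectral abundance factors (NSAF: the protein's share of the sample's
   total length-normalised counts);
3. every NSAF is divided by the bait's NSAF in the same sample (relative
   NSAF), absorbing differences in bait expression and purification yield;
4. proteins detected (count > 0) in every replicate of at least one
   condition pass the detection filter;
5. per replicate r, the fold change relNSAF_A[r] / relNSAF_B[r] is formed
   and averaged across replicates;
6. a per-condition dispersion — the mean absolute log2 deviation of each
   replicate's relative NSAF from the replicate mean — is computed for
   both conditions and summed into a total error estimate;
7. the modified Z score is |log2(average fold change)| divided by that
   error estimate. High-Z, high-fold-change proteins bind the two bait
   forms most selectively.

Zeros are imputed as 0.5 spectral counts only when forming ratios and
dispersions; reported NSAF columns keep true zeros. Because the relative
NSAF of protein p in a sample reduces to
``(count_p/len_p) / (count_bait/len_bait)``, the sample-sum term cancels
and the imputation acts directly on that ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCountTable",
    "combine_isoforms",
    "nsaf",
    "relative_nsaf",
    "replicate_filter",
    "fold_change",
    "error_estimate",
    "modified_z",
    "rank_interactors",
    "InteractomeComparison",
    "InteractomeResults",
]


class MissingBaitError(ValueError):
    """The bait protein is absent or undetected in a sample."""


@dataclass
class SpectralCountTable:
    """Protein x (condition, replicate) spectral counts with lengths.

    ``counts`` is indexed by protein group id with a 2-level column
    MultiIndex (condition, replicate); ``lengths`` is the per-protein
    normalising length (mean amino-acid length over isoforms). The bait
    must be detected (count > 0) in every sample.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    bait_id: str
    conditions: tuple

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        conds = self.counts.columns.get_level_values(0).unique()
        if set(conds) != set(self.conditions):
            raise ValueError(
                f"count columns {sorted(conds)} do not match "
                f"conditions {self.conditions}"
            )
        reps = {
            c: sorted(self.counts[c].columns) for c in self.conditions
        }
        if reps[self.conditions[0]] != reps[self.conditions[1]]:
            raise ValueError("conditions must have matching replicate labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every protein needs a positive length")
        if self.bait_id not in self.counts.index:
            raise MissingBaitError(f"bait {self.bait_id!r} not in table")
        if (self.counts.loc[self.bait_id] <= 0).any():
            raise MissingBaitError(
                f"bait {self.bait_id!r} must have count > 0 in every sample"
            )

    @property
    def replicates(self) -> list:
        return sorted(self.counts[self.conditions[0]].columns)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index


def combine_isoforms(isoform_lengths, isoform_counts) -> tuple:
    """Combine a protein group's isoform rows into one row.

    Counts are summed per sample; the normalising length is the
    arithmetic mean of the isoform lengths.
    """
    lengths = np.asarray(list(isoform_lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("at least one isoform is required")
    if (lengths <= 0).any():
        raise ValueError("isoform lengths must be positive")
    counts = np.asarray(isoform_counts, dtype=float)
    combined = counts.sum(axis=0) if counts.ndim == 2 else counts
    return float(lengths.mean()), combined


def nsaf(sample_counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Normalised spectral abundance factors for one pulldown sample.

    NSAF_p = (count_p / length_p) / sum_q (count_q / length_q); the
    resulting factors sum to 1 over the sample.
    """
    lengths = lengths.reindex(sample_counts.index)
    norm = sample_counts / lengths
    total = norm.sum()
    if total <= 0:
        raise ValueError("sample has no spectral counts")
    return norm / total


def relative_nsaf(nsaf_slice: pd.Series, bait_id: str) -> pd.Series:
    """Divide each protein's NSAF by the bait's NSAF in the same sample."""
    if bait_id not in nsaf_slice.index:
        raise MissingBaitError(f"bait {bait_id!r} absent from sample")
    bait = nsaf_slice[bait_id]
    if bait <= 0:
        raise MissingBaitError(f"bait {bait_id!r} has zero NSAF in sample")
    return nsaf_slice / bait


def replicate_filter(table: SpectralCountTable) -> pd.Index:
    """Proteins detected in every replicate of at least one condition."""
    a, b = table.conditions
    all_a = (table.counts[a] > 0).all(axis=1)
    all_b = (table.counts[b] > 0).all(axis=1)
    return table.counts.index[all_a | all_b]


def fold_change(rel_a, rel_b) -> tuple[np.ndarray, float]:
    """Per-replicate and average fold change in relative NSAF.

    Replicate r of condition A is paired with replicate r of condition B;
    the average is the arithmetic mean of the per-replicate ratios (the
    mean of ratios, not the ratio of means). Zeros must have been handled
    upstream (see the module's imputation policy).
    """
    rel_a = np.asarray(rel_a, dtype=float)
    rel_b = np.asarray(rel_b, dtype=float)
    if rel_a.shape != rel_b.shape:
        raise ValueError("replicates are not paired")
    if (rel_b <= 0).any():
        raise ValueError("zero denominators: apply the zero policy first")
    per_rep = rel_a / rel_b
    return per_rep, float(per_rep.mean())


def error_estimate(rel_values, agg: str = "mean") -> float:
    """Replicate dispersion of one protein's relative NSAFs in one condition.

    Each replicate's relative NSAF is normalised to the replicate mean and
    the absolute log2 of those mean-normalised values is aggregated —
    arithmetic mean by default, sum via ``agg="sum"``. Invariant to
    uniform rescaling of the replicate values.
    """
    values = np.asarray(rel_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate value")
    if (values <= 0).any():
        raise ValueError("non-positive values: apply the zero policy first")
    m = values.mean()
    devs = np.abs(np.log2(values / m))
    if agg == "mean":
        return float(devs.mean())
    if agg == "sum":
        return float(devs.sum())
    raise ValueError(f"unknown aggregation {agg!r}")


def modified_z(
    avg_fc: float, error_a: float, error_b: float, epsilon: float = 1e-6
) -> tuple[float, bool]:
    """|log2 average fold change| over the summed per-condition errors.

    Returns ``(z, floored)`` where ``floored`` flags scores whose error
    total fell below ``epsilon`` and was clamped to it (zero-variance
    replicates would otherwise divide by zero).
    """
    if avg_fc <= 0:
        raise ValueError("avg_fc must be positive")
    if error_a < 0 or error_b < 0:
        raise ValueError("errors must be non-negative")
    total = error_a + error_b
    floored = total < epsilon
    return abs(np.log2(avg_fc)) / max(total, epsilon), floored


def rank_interactors(rows: pd.DataFrame) -> pd.DataFrame:
    """Order scored proteins by avg fold change, then modified Z, then id."""
    return rows.sort_values(
        by=["avg_fc", "modified_z", "protein"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


class InteractomeComparison:
    """Model comparing two pulldown interactomes of the same bait.

    Parameters
    ----------
    table : SpectralCountTable
        Combined-isoform spectral counts for both conditions.
    cond_a, cond_b : str, optional
        Numerator and denominator conditions for fold changes (default:
        the table's condition order, A over B — e.g. wild-type over the
        inactive mutant).
    error_agg : {"mean", "sum"}
        How per-replicate absolute log2 deviations aggregate into each
        condition's dispersion term.
    epsilon : float
        Floor on the total error estimate.
    impute_count : float
        Spectral count imputed for a protein undetected in a sample when
        forming ratios and dispersions (never in reported NSAFs).
    """

    def __init__(
        self,
        table: SpectralCountTable,
        cond_a: str | None = None,
        cond_b: str | None = None,
        error_agg: str = "mean",
        epsilon: float = 1e-6,
        impute_count: float = 0.5,
    ) -> None:
        self.table = table
        self.cond_a = cond_a if cond_a is not None else table.conditions[0]
        self.cond_b = cond_b if cond_b is not None else table.conditions[1]
        if {self.cond_a, self.cond_b} != set(table.conditions):
            raise ValueError(
                f"conditions ({self.cond_a}, {self.cond_b}) do not match "
                f"the table's {table.conditions}"
            )
        if error_agg not in ("mean", "sum"):
            raise ValueError("error_agg must be 'mean' or 'sum'")
        self.error_agg = error_agg
        self.epsilon = float(epsilon)
        self.impute_count = float(impute_count)

    @classmethod
    def from_tsv(cls, path, bait_id: str, **kwargs) -> "InteractomeComparison":
        from .io import read_counts_tsv

        cond_a = kwargs.pop("cond_a", None)
        cond_b = kwargs.pop("cond_b", None)
        table = read_counts_tsv(path, bait_id=bait_id)
        return cls(table, cond_a=cond_a, cond_b=cond_b, **kwargs)

    def _relative_nsafs(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """True-zero and imputed relative NSAFs, proteins x samples."""
        t = self.table
        rel = {}
        rel_imputed = {}
        for col in t.counts.columns:
            sample_nsaf = nsaf(t.counts[col], t.lengths)
            rel[col] = relative_nsaf(sample_nsaf, t.bait_id)
            # (count/len)/(bait_count/bait_len): sample sums cancel, so
            # imputing only the missing protein leaves other rows exact.
            bait_rate = (
                t.counts.loc[t.bait_id, col] / t.lengths[t.bait_id]
            )
            imputed = (
                t.counts[col].where(t.counts[col] > 0, self.impute_count)
                / t.lengths
                / bait_rate
            )
            rel_imputed[col] = imputed
        cols = pd.MultiIndex.from_tuples(t.counts.columns)
        return (
            pd.DataFrame(rel, index=t.proteins)[cols],
            pd.DataFrame(rel_imputed, index=t.proteins)[cols],
        )

    def fit(self) -> "InteractomeResults":
        """Score every filter-passing protein; return ranked results."""
        t = self.table
        kept = replicate_filter(t)
        rel, rel_imp = self._relative_nsafs()
        reps = t.replicates
        a, b = self.cond_a, self.cond_b

        records = []
        for protein in kept:
            ra = rel_imp.loc[protein, a].to_numpy(dtype=float)
            rb = rel_imp.loc[protein, b].to_numpy(dtype=float)
            per_rep, avg = fold_change(ra, rb)
            err_a = error_estimate(ra, self.error_agg)
            err_b = error_estimate(rb, self.error_agg)
            z, floored = modified_z(avg, err_a, err_b, self.epsilon)
            detected = []
            if (t.counts.loc[protein, a] > 0).all():
                detected.append(a)
            if (t.counts.loc[protein, b] > 0).all():
                detected.append(b)
            rec = {"protein": protein}
            for cond in (a, b):
                for r in reps:
                    rec[f"relnsaf_{cond}_rep{r}"] = rel.loc[protein, (cond, r)]
            for i, r in enumerate(reps):
                rec[f"fc_rep{r}"] = per_rep[i]
            rec.update(
                avg_fc=avg,
                log2_avg_fc=float(np.log2(avg)),
                error_a=err_a,
                error_b=err_b,
                error_total=err_a + err_b,
                modified_z=z,
                floored=floored,
                detected_in="+".join(detected),
            )
            records.append(rec)
        scores = rank_interactors(pd.DataFrame.from_records(records))
        return InteractomeResults(model=self, scores=scores, n_candidates=len(kept))


@dataclass
class InteractomeResults:
    """Ranked differential-interaction scores for one bait comparison."""

    model: InteractomeComparison
    scores: pd.DataFrame
    n_candidates: int

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.scores.head(n)

    def summary(self, n_top: int = 10) -> str:
        m = self.model
        lines = [
            f"Interactome comparison: {m.cond_a} vs {m.cond_b} "
            f"(bait {m.table.bait_id})",
            f"  {len(m.table.proteins)} proteins in, {self.n_candidates} pass "
            f"the all-replicate detection filter "
            f"({m.table.n_replicates} replicates/condition)",
            f"  error aggregation: {m.error_agg}, epsilon {m.epsilon:g}",
            f"  top {min(n_top, len(self.scores))} by average fold change:",
        ]
        for _, row in self.top(n_top).iterrows():
            lines.append(
                f"    {row.protein:<16s} avg FC {row.avg_fc:8.2f}   "
                f"modified Z {row.modified_z:6.2f}   [{row.detected_in}]"
            )
        return "\n".join(lines)

    def plot_rank(self, ax=None, n_top: int = 25):
        """Ranked bar plot of average fold change for the top interactors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.25 * n_top + 1))
        top = self.top(n_top).iloc[::-1]
        ax.barh(top["protein"], top["avg_fc"], color="0.5")
        ax.set_xlabel(
            f"average fold change ({self.model.cond_a}/{self.model.cond_b})"
        )
        return ax

    def to_tsv(self, path, provenance: dict | None = None) -> None:
        from .io import write_table_tsv

        write_table_tsv(self.scores, path, provenance)
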