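"""Selection-screen enrichment analysis from aligned sequencing reads.

The screen compares two pooled sequencing samples aligned to the same
reference coding sequence: a pre-selection pool (the full mutant library)
and a post-selection pool (cells sorted for loss of reporter activity).
For every residue, the frequency of reads carrying a non-synonymous
change at that codon is computed in each pool; residues whose mutation
frequency rises more than a threshold factor (default 4) from pre to
post are called as required for activity.

Read-level QC mirrors the screen's filtering rules: mismatches are only
trusted at or above a base-quality threshold, reads with more than
``max_mutations`` (default 3) high-quality mismatches are discarded, as
are reads that witness an internal stop codon among the codons they
fully cover. Reads with indels or clipping are discarded with their own
reason code — epPCR libraries are substitution-dominated.

The model object is :class:`MutagenesisScreen`; ``fit()`` returns a
:class:`ScreenResults` carrying the per-residue enrichment table, QC
tallies and plotting/reporting helpers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refseq import CodingSequence, NtSubstitution, translate

__all__ = [
    "AlignedRead",
    "MutationCall",
    "ReadCallResult",
    "ResidueCounts",
    "call_read_mutations",
    "qc_filter_read",
    "evaluate_read",
    "accumulate_residue_counts",
    "residue_frequency",
    "enrichment",
    "top_enriched_substitution",
    "MutagenesisScreen",
    "ScreenResults",
]

_ACGT_BYTES = frozenset(b"ACGT")


@dataclass
class AlignedRead:
    """One sequencing read placed on the coding sequence.

    ``ref_start`` is the 1-based coding-sequence position of the first
    aligned base; ``quals`` are phred-scale integers, one per base.
    Reads whose alignment contained insertions, deletions or clipping
    carry ``indel_or_clip=True`` and are excluded from calling.
    """

    read_id: str
    ref_start: int
    bases: str
    quals: np.ndarray
    indel_or_clip: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MutationCall:
    """A high-quality mismatch call with its supporting base quality."""

    sub: NtSubstitution
    quality: int


@dataclass
class ReadCallResult:
    """Outcome of calling + QC on one read."""

    read_id: str
    kept: bool
    reason: str  # ok | too_many_mutations | internal_stop | indel_or_clip | out_of_range
    calls: list = field(default_factory=list)
    covered_residues: tuple = ()  # (first, last) fully covered codons, or ()
    # residue -> alt_aa for covered codons whose applied calls change them
    variants: dict = field(default_factory=dict)


def call_read_mutations(
    read: AlignedRead, cds: CodingSequence, min_base_quality: int = 20
) -> list[MutationCall]:
    """Call high-quality mismatches of a read against the reference.

    A call is emitted at each position where the read base differs from
    the reference and the read's base quality is at or above
    ``min_base_quality``. Low-quality mismatches and ambiguous (N) bases
    are treated as reference — the read is neither discarded nor credited
    with a mutation there.
    """
    if read.indel_or_clip:
        raise ValueError("cannot call mutations on an indel/clipped alignment")
    start = read.ref_start
    end = start + len(read) - 1
    if start < 1 or end > len(cds.nt):
        raise IndexError(
            f"read {read.read_id} spans {start}..{end}, "
            f"reference is 1..{len(cds.nt)}"
        )
    ref_arr = np.frombuffer(
        cds.nt.encode("ascii"), dtype=np.uint8
    )[start - 1 : end]
    read_arr = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)
    mism = np.nonzero(ref_arr != read_arr)[0]
    calls: list[MutationCall] = []
    for i in mism:
        q = int(read.quals[i])
        if q < min_base_quality:
            continue
        alt = read.bases[i]
        if alt not in "ACGT":
            continue
        calls.append(
            MutationCall(
                sub=NtSubstitution(
                    pos=start + int(i), ref=chr(ref_arr[i]), alt=alt
                ),
                quality=q,
            )
        )
    return calls


def _covered_span(read: AlignedRead, cds: CodingSequence) -> tuple:
    """1-based (first, last) codon fully spanned by the read, or ()."""
    start = read.ref_start
    end = start + len(read) - 1
    first = -(-(start + 2) // 3)  # ceil((start+2)/3): codon r needs 3r-2 >= start
    last = end // 3
    if first > last:
        return ()
    return (first, last)


def qc_filter_read(
    read: AlignedRead,
    calls: list,
    cds: CodingSequence,
    max_mutations: int = 3,
) -> ReadCallResult:
    """Apply the screen's read filters to already-called mutations.

    Discards the read when it carries strictly more than ``max_mutations``
    high-quality mismatches, or when any codon it fully covers — with its
    own calls applied — translates to a stop other than the reference's
    terminal stop codon. All high-quality nucleotide mismatches, including
    synonymous ones, count toward the mutation-load filter.
    """
    if read.indel_or_clip:
        return ReadCallResult(read.read_id, False, "indel_or_clip")
    span = _covered_span(read, cds)
    if len(calls) > max_mutations:
        return ReadCallResult(
            read.read_id, False, "too_many_mutations", calls, span
        )
    variants: dict[int, str] = {}
    if span:
        by_residue: dict[int, list] = {}
        for call in calls:
            r = call.sub.residue
            if span[0] <= r <= span[1]:
                by_residue.setdefault(r, []).append(call.sub)
        terminal = cds.n_codons if cds.has_terminal_stop else None
        for r, subs in by_residue.items():
            codon = list(cds.codon(r))
            for sub in subs:
                codon[(sub.pos - 1) % 3] = sub.alt
            alt_aa = translate("".join(codon))
            if alt_aa == "*" and r != terminal:
                return ReadCallResult(
                    read.read_id, False, "internal_stop", calls, span
                )
            if alt_aa != cds.protein[r - 1]:
                variants[r] = alt_aa
    return ReadCallResult(read.read_id, True, "ok", calls, span, variants)


def evaluate_read(
    read: AlignedRead,
    cds: CodingSequence,
    min_base_quality: int = 20,
    max_mutations: int = 3,
) -> ReadCallResult:
    """Call mutations then QC-filter one read; never raises on bad reads."""
    if read.indel_or_clip:
        return ReadCallResult(read.read_id, False, "indel_or_clip")
    end = read.ref_start + len(read) - 1
    if read.ref_start < 1 or end > len(cds.nt):
        return ReadCallResult(read.read_id, False, "out_of_range")
    calls = call_read_mutations(read, cds, min_base_quality)
    return qc_filter_read(read, calls, cds, max_mutations)


@dataclass
class ResidueCounts:
    """Per-residue coverage and non-synonymous mutation tallies."""

    covering: np.ndarray  # reads fully spanning each codon
    mutant: np.ndarray  # of those, reads with a non-synonymous change
    by_alt: dict  # residue -> Counter(alt_aa -> reads)

    @classmethod
    def empty(cls, n_codons: int) -> "ResidueCounts":
        return cls(
            covering=np.zeros(n_codons, dtype=np.int64),
            mutant=np.zeros(n_codons, dtype=np.int64),
            by_alt={},
        )

    def add(self, result: ReadCallResult) -> None:
        if not result.kept or not result.covered_residues:
            return
        first, last = result.covered_residues
        self.covering[first - 1 : last] += 1
        for r, alt_aa in result.variants.items():
            self.mutant[r - 1] += 1
            self.by_alt.setdefault(r, Counter())[alt_aa] += 1


def accumulate_residue_counts(kept_results, cds: CodingSequence) -> ResidueCounts:
    """Fold a stream of kept read results into per-residue counts."""
    counts = ResidueCounts.empty(cds.n_codons)
    for result in kept_results:
        if not result.kept:
            raise ValueError("accumulate_residue_counts expects kept reads only")
        counts.add(result)
    return counts


def residue_frequency(counts: ResidueCounts, residue: int) -> float:
    """Mutation frequency at one residue; NaN when no read covers it."""
    covering = counts.covering[residue - 1]
    if covering == 0:
        return float("nan")
    return counts.mutant[residue - 1] / covering


def top_enriched_substitution(counts: ResidueCounts, residue: int):
    """Most frequent alternative amino acid at a residue, or None.

    Ties break alphabetically so the report is deterministic.
    """
    tally = counts.by_alt.get(residue)
    if not tally:
        return None
    return min(tally.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def enrichment(
    pre: ResidueCounts,
    post: ResidueCounts,
    cds: CodingSequence,
    pseudocount: float = 0.5,
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Per-residue pre/post mutation frequencies, fold change and hit flag.

    The fold change uses Haldane-smoothed frequencies
    ``(mutant + pseudocount) / (covering + 2*pseudocount)`` so residues
    unmutated in the pre-selection pool remain rankable; ``pseudocount=0``
    recovers the raw ratio. A residue is a hit when its fold change
    strictly exceeds ``threshold``. Residues with zero coverage in either
    pool get NaN frequencies/fold change and are excluded from hit calling.
    """
    if len(pre.covering) != len(post.covering) or len(pre.covering) != cds.n_codons:
        raise ValueError("pre/post counts do not match the reference length")
    pc = float(pseudocount)
    if pc < 0:
        raise ValueError("pseudocount must be non-negative")
    residues = np.arange(1, cds.n_codons + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pre_freq = np.where(pre.covering > 0, pre.mutant / np.maximum(pre.covering, 1), np.nan)
        post_freq = np.where(post.covering > 0, post.mutant / np.maximum(post.covering, 1), np.nan)
        pre_star = (pre.mutant + pc) / (pre.covering + 2 * pc)
        post_star = (post.mutant + pc) / (post.covering + 2 * pc)
        fold = post_star / pre_star
    defined = (pre.covering > 0) & (post.covering > 0)
    fold = np.where(defined, fold, np.nan)
    is_hit = defined & (fold > threshold)
    top = [top_enriched_substitution(post, int(r)) for r in residues]
    return pd.DataFrame(
        {
            "residue": residues,
            "ref_aa": list(cds.protein),
            "pre_mutant": pre.mutant,
            "pre_covering": pre.covering,
            "post_mutant": post.mutant,
            "post_covering": post.covering,
            "pre_freq": pre_freq,
            "post_freq": post_freq,
            "fold_change": fold,
            "is_hit": is_hit,
            "top_substitution": top,
        }
    )


class MutagenesisScreen:
    """Model for a pre/post selection deep-sequencing mutagenesis screen.

    Parameters
    ----------
    cds : CodingSequence
        The wild-type reference coding sequence.
    pre_reads, post_reads : iterable of AlignedRead
        Substitution-only alignments for the pre- and post-selection pools.
    min_base_quality : int
        Phred threshold below which a mismatch is ignored ("high-quality
        mutation" cut-off).
    max_mutations : int
        Reads with strictly more high-quality mismatches are discarded.
    """

    def __init__(
        self,
        cds: CodingSequence,
        pre_reads,
        post_reads,
        min_base_quality: int = 20,
        max_mutations: int = 3,
    ) -> None:
        self.cds = cds
        self.pre_reads = pre_reads
        self.post_reads = post_reads
        self.min_base_quality = int(min_base_quality)
        self.max_mutations = int(max_mutations)

    @classmethod
    def from_files(
        cls,
        fasta_path,
        pre_path,
        post_path,
        ref_id: str | None = None,
        min_base_quality: int = 20,
        max_mutations: int = 3,
    ) -> "MutagenesisScreen":
        """Build a screen from a FASTA reference and two read files.

        Read files may be SAM (``.sam``) or the tab-separated fixture
        format (read_id, ref_start, bases, phred+33 quals).
        """
        from . import io as _io

        cds = _io.read_fasta(fasta_path, ref_id=ref_id)
        pre = _io.read_alignments(pre_path, cds)
        post = _io.read_alignments(post_path, cds)
        return cls(cds, pre, post, min_base_quality, max_mutations)

    def _process_pool(self, reads) -> tuple[ResidueCounts, Counter]:
        counts = ResidueCounts.empty(self.cds.n_codons)
        tally: Counter = Counter()
        for read in reads:
            result = evaluate_read(
                read, self.cds, self.min_base_quality, self.max_mutations
            )
            tally[result.reason] += 1
            if result.kept:
                counts.add(result)
        return counts, tally

    def fit(
        self, pseudocount: float = 0.5, threshold: float = 4.0
    ) -> "ScreenResults":
        """Run calling, QC and enrichment; return the results object."""
        pre_counts, pre_qc = self._process_pool(self.pre_reads)
        post_counts, post_qc = self._process_pool(self.post_reads)
        table = enrichment(pre_counts, post_counts, self.cds, pseudocount, threshold)
        return ScreenResults(
            model=self,
            enrichment=table,
            pre_counts=pre_counts,
            post_counts=post_counts,
            qc={"pre": dict(pre_qc), "post": dict(post_qc)},
            pseudocount=pseudocount,
            threshold=threshold,
        )


@dataclass
class ScreenResults:
    """Fitted screen: per-residue enrichment table plus QC diagnostics."""

    model: MutagenesisScreen
    enrichment: pd.DataFrame
    pre_counts: ResidueCounts
    post_counts: ResidueCounts
    qc: dict
    pseudocount: float
    threshold: float

    @property
    def hits(self) -> pd.DataFrame:
        """Residues whose mutation frequency rose > threshold-fold."""
        return self.enrichment[self.enrichment["is_hit"]]

    def summary(self) -> str:
        lines = [
            f"Mutagenesis screen on {self.model.cds.id} "
            f"({self.model.cds.n_codons} codons)",
            f"  min base quality {self.model.min_base_quality}, "
            f"max mutations/read {self.model.max_mutations}, "
            f"pseudocount {self.pseudocount}, hit threshold "
            f">{self.threshold}-fold",
        ]
        for pool in ("pre", "post"):
            tally = self.qc[pool]
            total = sum(tally.values())
            kept = tally.get("ok", 0)
            drops = ", ".join(
                f"{reason}={n}"
                for reason, n in sorted(tally.items())
                if reason != "ok"
            )
            lines.append(
                f"  {pool}-selection: {total} reads, {kept} kept"
                + (f" ({drops})" if drops else "")
            )
        hits = self.hits
        lines.append(f"  hits: {len(hits)} residue(s)")
        for _, row in hits.iterrows():
            lines.append(
                f"    {row.ref_aa}{row.residue}{row.top_substitution or '?'}"
                f"  fold change {row.fold_change:.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram-style bar plot of per-residue fold change."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = self.enrichment
        ax.bar(t["residue"], t["fold_change"], width=1.0, color="0.6")
        hits = self.hits
        ax.bar(hits["residue"], hits["fold_change"], width=1.0, color="crimson")
        ax.axhline(self.threshold, color="k", lw=0.8, ls="--")
        ax.set_xlabel("residue")
        ax.set_ylabel("fold change in mutation frequency")
        return ax

    def to_tsv(self, path, provenance: dict | None = None) -> None:
        from .io import write_table_tsv

        write_table_tsv(self.enrichment, path, provenance)
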