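"""Mutant-library statistics for error-prone PCR screens.

Three kinds of arithmetic support the design and interpretation of an
epPCR point-mutant library:

* enumeration of the amino-acid variant space reachable by exactly one
  nucleotide substitution of the reference coding sequence;
* coverage arithmetic (how many single-mutant constructs per accessible
  variant);
* the empirical distribution of nucleotide-mutation load over sampled
  clones, used to pick amplification conditions that maximise the
  single-mutation fraction, and a Poisson rate fit for simulator
  calibration.

"Possible variants" is counted as distinct (residue, alternative amino
acid) pairs — missense only by default, since stop-containing reads are
discarded downstream — with nonsense variants includable via a flag and
synonymous changes reported separately as nucleotide events. The
reference's terminal stop codon is excluded from enumeration; changes to
it are read-through events, tallied on their own.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean

from .refseq import CodingSequence, NtSubstitution, classify_substitution

__all__ = [
    "VariantSpace",
    "MutationLoadDistribution",
    "enumerate_snv_variants",
    "coverage_fold",
    "format_fold",
    "single_mutant_count",
    "mutation_load_distribution",
    "select_condition",
    "fit_poisson_lambda",
]

_BASES = "ACGT"


@dataclass
class VariantSpace:
    """Distinct amino-acid variants accessible by one nucleotide change.

    ``missense_by_residue`` and ``nonsense_residues`` dedup on
    (residue, alt amino acid); ``nt_routes`` counts, for each such pair,
    how many distinct nucleotide substitutions reach it.
    """

    missense_by_residue: dict[int, set[str]]
    nonsense_residues: set[int]
    nt_routes: Counter = field(default_factory=Counter)  # (residue, alt_aa) -> n
    n_synonymous_nt_changes: int = 0
    n_readthrough_nt_changes: int = 0
    include_nonsense: bool = False

    @property
    def n_missense_distinct(self) -> int:
        return sum(len(v) for v in self.missense_by_residue.values())

    @property
    def n_nonsense_distinct(self) -> int:
        return len(self.nonsense_residues)

    @property
    def n_variants(self) -> int:
        """Total distinct variants under the configured counting convention."""
        n = self.n_missense_distinct
        if self.include_nonsense:
            n += self.n_nonsense_distinct
        return n

    def summary(self) -> dict:
        return {
            "n_missense_distinct": self.n_missense_distinct,
            "n_nonsense_distinct": self.n_nonsense_distinct,
            "n_synonymous_nt_changes": self.n_synonymous_nt_changes,
            "n_readthrough_nt_changes": self.n_readthrough_nt_changes,
            "include_nonsense": self.include_nonsense,
            "n_variants": self.n_variants,
        }


def enumerate_snv_variants(
    cds: CodingSequence, include_nonsense: bool = False
) -> VariantSpace:
    """Enumerate amino-acid variants reachable by a single substitution.

    Every codon has nine single-base neighbours; each is translated and
    distinct (residue, alt_aa) pairs are collected. Synonymous changes are
    counted as nucleotide events, never as variants. The terminal stop
    codon, if present, is excluded (its changes are read-through events).
    """
    space = VariantSpace(
        missense_by_residue={},
        nonsense_residues=set(),
        include_nonsense=include_nonsense,
    )
    n_coding = cds.n_codons - 1 if cds.has_terminal_stop else cds.n_codons
    for pos in range(1, 3 * cds.n_codons + 1):
        ref = cds.base(pos)
        residue = (pos + 2) // 3
        terminal_stop = residue > n_coding
        for alt in _BASES:
            if alt == ref:
                continue
            var = classify_substitution(
                cds, NtSubstitution(pos=pos, ref=ref, alt=alt)
            )
            if terminal_stop:
                if var.klass != "synonymous":
                    space.n_readthrough_nt_changes += 1
                else:
                    space.n_synonymous_nt_changes += 1
                continue
            if var.klass == "synonymous":
                space.n_synonymous_nt_changes += 1
            elif var.klass == "nonsense":
                space.nonsense_residues.add(residue)
                space.nt_routes[(residue, "*")] += 1
            else:
                space.missense_by_residue.setdefault(residue, set()).add(
                    var.alt_aa
                )
                space.nt_routes[(residue, var.alt_aa)] += 1
    return space


def coverage_fold(n_single_mutant_constructs: int, n_variants: int) -> float:
    """Theoretical library coverage: constructs per accessible variant.

    The exact ratio is returned; :func:`format_fold` renders the
    integer-rounded "N-fold" display string.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if n_single_mutant_constructs < 0:
        raise ValueError("construct count must be non-negative")
    return n_single_mutant_constructs / n_variants


def format_fold(ratio: float) -> str:
    """Render a coverage ratio as the conventional '<n>-fold' string."""
    return f"{round(ratio)}-fold"


def single_mutant_count(library_size: int, single_mutant_fraction: float) -> int:
    """Number of single-mutant constructs in a library of a given size."""
    if not 0.0 <= single_mutant_fraction <= 1.0:
        raise ValueError("single_mutant_fraction must be in [0, 1]")
    if library_size < 0:
        raise ValueError("library_size must be non-negative")
    return round(library_size * single_mutant_fraction)


@dataclass
class MutationLoadDistribution:
    """Empirical pmf of nucleotide mutations per clone."""

    pmf: dict[int, float]
    n_clones: int

    @property
    def fraction_single(self) -> float:
        return self.pmf.get(1, 0.0)


def mutation_load_distribution(clone_mutation_counts) -> MutationLoadDistribution:
    """Empirical distribution of per-clone nucleotide-mutation counts."""
    counts = list(clone_mutation_counts)
    if not counts:
        raise ValueError("clone_mutation_counts must be non-empty")
    if any((not isinstance(c, (int,)) and int(c) != c) or c < 0 for c in counts):
        raise ValueError("mutation counts must be non-negative integers")
    n = len(counts)
    tally = Counter(int(c) for c in counts)
    pmf = {k: v / n for k, v in sorted(tally.items())}
    return MutationLoadDistribution(pmf=pmf, n_clones=n)


def _natural_key(label) -> tuple:
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def select_condition(condition_to_distribution: dict) -> object:
    """Pick the amplification condition maximising the single-mutant fraction.

    Ties break toward the smallest condition label in natural sort order
    (so condition "15" beats "20" at equal fractions).
    """
    if not condition_to_distribution:
        raise ValueError("condition map must be non-empty")

    def frac(dist) -> float:
        if isinstance(dist, MutationLoadDistribution):
            return dist.fraction_single
        return float(dist)

    best = min(
        condition_to_distribution.items(),
        key=lambda kv: (-frac(kv[1]), _natural_key(kv[0])),
    )
    return best[0]


def fit_poisson_lambda(clone_mutation_counts) -> float:
    """Maximum-likelihood Poisson rate for per-clone mutation counts.

    The MLE is the sample mean; used to calibrate the epPCR simulator
    against pilot-clone sequencing.
    """
    counts = list(clone_mutation_counts)
    if not counts:
        raise ValueError("clone_mutation_counts must be non-empty")
    return fmean(counts)
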