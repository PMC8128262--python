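"""Reference coding-sequence model and single-substitution classification.

Everything downstream — variant enumeration, read calling, enrichment —
is anchored on a :class:`CodingSequence`: an in-frame DNA reference whose
codon-by-codon translation defines the residue coordinate system.
Coordinates are 1-based and inclusive for both nucleotides and residues,
matching the convention in which point mutants are quoted (e.g. L317P is
residue 317).

Only the standard nuclear genetic code is supported; ambiguity codes are
rejected rather than silently skipped, so policy for low-confidence bases
lives with the caller (the read layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "NtSubstitution",
    "AminoAcidVariant",
    "FrameError",
    "InvalidAlphabetError",
    "CoordinateError",
    "ReferenceMismatchError",
    "translate",
    "classify_substitution",
    "apply_substitutions",
]

_BASES = frozenset("ACGT")


class FrameError(ValueError):
    """Sequence length is not a positive multiple of three."""


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside A/C/G/T."""


class CoordinateError(IndexError):
    """A 1-based coordinate falls outside the reference."""


class ReferenceMismatchError(ValueError):
    """A substitution's stated reference base disagrees with the reference."""


def translate(nt: str) -> str:
    """Translate an in-frame DNA string under the standard genetic code.

    Returns one single-letter amino acid per codon, with ``'*'`` for the
    stop codons TAA/TAG/TGA. The empty string translates to the empty
    string.

    Raises
    ------
    InvalidAlphabetError
        If ``nt`` contains anything other than A/C/G/T (ambiguity codes
        included — they are rejected, not skipped).
    FrameError
        If ``len(nt)`` is not a multiple of three.
    """
    if not set(nt) <= _BASES:
        bad = sorted(set(nt) - _BASES)
        raise InvalidAlphabetError(f"non-ACGT characters in sequence: {bad}")
    if len(nt) % 3 != 0:
        raise FrameError(f"sequence length {len(nt)} is not a multiple of 3")
    if not nt:
        return ""
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame DNA reference with its protein translation.

    Invariants enforced at construction: the length is a positive multiple
    of three, the alphabet is strict A/C/G/T, and at most one stop codon is
    present — and if present it is the final codon. ``protein`` is always
    the exact translation of ``nt``.
    """

    id: str
    nt: str
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.nt) == 0:
            raise FrameError("coding sequence must be non-empty")
        protein = translate(self.nt)
        internal = protein[:-1]
        if "*" in internal:
            pos = internal.index("*") + 1
            raise ValueError(f"internal stop codon at residue {pos}")
        object.__setattr__(self, "protein", protein)

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    @property
    def has_terminal_stop(self) -> bool:
        return self.protein.endswith("*")

    def codon(self, residue: int) -> str:
        """Return the codon (3 nt) for a 1-based residue index."""
        if not 1 <= residue <= self.n_codons:
            raise CoordinateError(
                f"residue {residue} outside 1..{self.n_codons}"
            )
        return self.nt[3 * (residue - 1) : 3 * residue]

    def base(self, pos: int) -> str:
        """Return the reference base at a 1-based nucleotide position."""
        if not 1 <= pos <= len(self.nt):
            raise CoordinateError(f"position {pos} outside 1..{len(self.nt)}")
        return self.nt[pos - 1]


@dataclass(frozen=True)
class NtSubstitution:
    """A single-nucleotide substitution in 1-based coding coordinates."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise InvalidAlphabetError(
                f"substitution bases must be A/C/G/T, got {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError("substitution alt must differ from ref")

    @property
    def residue(self) -> int:
        """1-based codon index containing this nucleotide."""
        return math.ceil(self.pos / 3)


@dataclass(frozen=True)
class AminoAcidVariant:
    """Amino-acid consequence of a nucleotide change at one residue."""

    residue: int
    ref_aa: str
    alt_aa: str
    klass: str  # "missense" | "nonsense" | "synonymous"


def _klass(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def classify_substitution(
    cds: CodingSequence, sub: NtSubstitution
) -> AminoAcidVariant:
    """Classify one substitution against the reference.

    The affected residue is ``ceil(pos/3)``; the variant amino acid is the
    translation of the mutated codon.

    Raises :class:`CoordinateError` for out-of-range positions and
    :class:`ReferenceMismatchError` when ``sub.ref`` disagrees with the
    reference base at ``sub.pos``.
    """
    if not 1 <= sub.pos <= len(cds.nt):
        raise CoordinateError(
            f"position {sub.pos} outside 1..{len(cds.nt)}"
        )
    ref_base = cds.base(sub.pos)
    if ref_base != sub.ref:
        raise ReferenceMismatchError(
            f"reference base at {sub.pos} is {ref_base}, not {sub.ref}"
        )
    residue = sub.residue
    codon = list(cds.codon(residue))
    offset = (sub.pos - 1) % 3
    codon[offset] = sub.alt
    alt_aa = translate("".join(codon))
    ref_aa = cds.protein[residue - 1]
    return AminoAcidVariant(residue, ref_aa, alt_aa, _klass(ref_aa, alt_aa))


def apply_substitutions(nt: str, subs) -> str:
    """Return ``nt`` with each substitution's alt base applied (1-based)."""
    seq = list(nt)
    for sub in subs:
        if not 1 <= sub.pos <= len(seq):
            raise CoordinateError(f"position {sub.pos} outside 1..{len(seq)}")
        if seq[sub.pos - 1] != sub.ref:
            raise ReferenceMismatchError(
                f"reference base at {sub.pos} is {seq[sub.pos - 1]}, "
                f"not {sub.ref}"
            )
        seq[sub.pos - 1] = sub.alt
    return "".join(seq)
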