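"""Seeded generators emulating the study's two data-generating processes.

Screen side: an error-prone PCR library (Poisson nucleotide-mutation
load per clone, transition/transversion-biased substitutions), a
FACS-style selection collapsed into one weighted resampling step that
enriches clones with low activity, and 150-base substitution-only
sequencing reads with base-quality-annotated errors.

Proteomics side: a two-condition, replicated AP-MS pulldown in which
per-sample spectral counts are Poisson draws around length-scaled
abundances, with a designated bait and a planted set of interactors
whose abundance is multiplied by an effect size in one condition only.

Every generator is deterministic given its seed; regenerating with the
same seed is bit-identical. Planted truth (which residues inactivate,
which proteins are condition-specific) is carried alongside the data so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import SpectralCountTable
from .refseq import CodingSequence, NtSubstitution, classify_substitution
from .screen import AlignedRead

__all__ = [
    "random_coding_sequence",
    "SimulatedClone",
    "SimulatedLibrary",
    "simulate_eppcr_library",
    "SimulatedPool",
    "simulate_selection",
    "simulate_reads",
    "ScreenSim",
    "simulate_screen",
    "SimulatedCountExperiment",
    "design_count_experiment",
    "simulate_spectral_counts",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_coding_sequence(
    n_codons: int, seed=None, id: str = "synthetic_cds"
) -> CodingSequence:
    """A random in-frame CDS: ATG start, ``n_codons`` sense codons, TAA stop.

    Internal stop codons are excluded by rejection so the result is a
    valid reference.
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    rng = _rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return CodingSequence(id=id, nt="".join(codons))


@dataclass(frozen=True)
class SimulatedClone:
    """One library member: its substitutions and ground-truth activity."""

    substitutions: tuple
    activity: float


@dataclass
class SimulatedLibrary:
    """An epPCR clone library with planted inactivating residues."""

    cds: CodingSequence
    clones: list
    lam: float
    ti_tv: float
    truth: dict  # residue -> multiplicative activity effect
    seed: object = None

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def mutation_counts(self) -> list:
        return [len(c.substitutions) for c in self.clones]


def simulate_eppcr_library(
    cds: CodingSequence,
    lam: float = 1.0,
    ti_tv: float = 0.9,
    n_clones: int = 10_000,
    inactivating_residues: dict | None = None,
    seed=None,
) -> SimulatedLibrary:
    """Draw an epPCR library with Poisson mutation load per clone.

    Each clone receives k ~ Poisson(lam) substitutions at positions drawn
    uniformly without replacement; the alternative base is the transition
    partner with probability ``ti_tv / (ti_tv + 2)``, otherwise one of
    the two transversions uniformly. Activity starts at 1 and is
    multiplied, per substitution, by the planted effect for a missense
    change at an inactivating residue; any nonsense change sets it to 0.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    effects = dict(inactivating_residues or {})
    if any(not 0.0 <= e <= 1.0 for e in effects.values()):
        raise ValueError("effects must be in [0, 1]")
    rng = _rng(seed)
    L = len(cds.nt)
    p_transition = ti_tv / (ti_tv + 2.0)
    clones = []
    for _ in range(n_clones):
        k = int(rng.poisson(lam))
        if k == 0:
            clones.append(SimulatedClone((), 1.0))
            continue
        k = min(k, L)
        positions = rng.choice(L, size=k, replace=False) + 1
        subs = []
        activity = 1.0
        for pos in sorted(int(p) for p in positions):
            ref = cds.base(pos)
            if rng.random() < p_transition:
                alt = _TRANSITION[ref]
            else:
                choices = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
                alt = choices[int(rng.integers(2))]
            sub = NtSubstitution(pos=pos, ref=ref, alt=alt)
            subs.append(sub)
            var = classify_substitution(cds, sub)
            if var.klass == "nonsense":
                activity = 0.0
            elif var.klass == "missense" and var.residue in effects:
                activity *= effects[var.residue]
        clones.append(SimulatedClone(tuple(subs), activity))
    return SimulatedLibrary(
        cds=cds, clones=clones, lam=lam, ti_tv=ti_tv, truth=effects, seed=seed
    )


@dataclass
class SimulatedPool:
    """A sampled population of clones (with replacement) from a library."""

    library: SimulatedLibrary
    clone_indices: np.ndarray


def simulate_selection(
    library: SimulatedLibrary,
    pre_size: int,
    post_size: int,
    gate_leak: float = 0.05,
    seed=None,
) -> tuple[SimulatedPool, SimulatedPool]:
    """Sample pre- and post-selection pools from a library.

    The pre pool is a uniform sample of clones; the post pool is drawn
    with per-clone weight ``(1 - activity) + gate_leak``, so inactive
    clones are enriched and ``gate_leak`` models imperfect gating. The
    multi-round sort of a real screen is collapsed into this single
    effective enrichment.
    """
    if pre_size <= 0 or post_size <= 0:
        raise ValueError("pool sizes must be positive")
    if not 0.0 <= gate_leak < 1.0:
        raise ValueError("gate_leak must be in [0, 1)")
    rng = _rng(seed)
    n = library.n_clones
    activities = np.array([c.activity for c in library.clones])
    weights = (1.0 - activities) + gate_leak
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "all clones active with gate_leak 0: post pool is empty"
        )
    pre = rng.integers(0, n, size=pre_size)
    post = rng.choice(n, size=post_size, replace=True, p=weights / total)
    return SimulatedPool(library, pre), SimulatedPool(library, post)


def simulate_reads(
    pool: SimulatedPool,
    depth: int,
    read_len: int = 150,
    error_rate: float = 1e-3,
    base_quality: int = 37,
    error_low_quality: int = 10,
    low_quality_error_fraction: float = 0.5,
    seed=None,
) -> list:
    """Sequence a pool into substitution-only 150-base aligned reads.

    Fragment starts are uniform over the reference; per-base sequencing
    errors occur at ``error_rate``, and a configurable fraction of the
    error bases are flagged with a low quality score (the rest
    masquerade as confident calls). Library mutations always carry the
    baseline quality.
    """
    cds = pool.library.cds
    L = len(cds.nt)
    if read_len > L:
        raise ValueError("read length exceeds the reference")
    rng = _rng(seed)
    ref = np.frombuffer(cds.nt.encode("ascii"), dtype=np.uint8)
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    mutated_cache: dict[int, np.ndarray] = {}

    def mutated(ci: int) -> np.ndarray:
        arr = mutated_cache.get(ci)
        if arr is None:
            arr = ref.copy()
            for sub in pool.library.clones[ci].substitutions:
                arr[sub.pos - 1] = ord(sub.alt)
            mutated_cache[ci] = arr
        return arr

    reads = []
    if depth <= 0:
        return reads
    picks = rng.integers(0, len(pool.clone_indices), size=depth)
    starts = rng.integers(1, L - read_len + 2, size=depth)
    for i in range(depth):
        ci = int(pool.clone_indices[picks[i]])
        start = int(starts[i])
        window = mutated(ci)[start - 1 : start - 1 + read_len].copy()
        quals = np.full(read_len, base_quality, dtype=np.int16)
        n_err = rng.binomial(read_len, error_rate)
        if n_err:
            err_pos = rng.choice(read_len, size=n_err, replace=False)
            for j in err_pos:
                current = window[j]
                alt = current
                while alt == current:
                    alt = base_bytes[int(rng.integers(4))]
                window[j] = alt
                if rng.random() < low_quality_error_fraction:
                    quals[j] = error_low_quality
        reads.append(
            AlignedRead(
                read_id=f"read_{i}",
                ref_start=start,
                bases=window.tobytes().decode("ascii"),
                quals=quals,
            )
        )
    return reads


@dataclass
class ScreenSim:
    """An end-to-end simulated screen dataset with its planted truth."""

    cds: CodingSequence
    library: SimulatedLibrary
    pre_reads: list
    post_reads: list
    truth: dict


def simulate_screen(
    cds: CodingSequence,
    inactivating_residues: dict,
    lam: float = 1.0,
    ti_tv: float = 0.9,
    n_clones: int = 10_000,
    depth: int = 5_000,
    gate_leak: float = 0.05,
    read_len: int = 150,
    error_rate: float = 1e-3,
    seed=None,
) -> ScreenSim:
    """Library -> selection -> sequencing, with one seed for the chain."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_lib, s_sel, s_pre, s_post = [np.random.default_rng(c) for c in ss.spawn(4)]
    library = simulate_eppcr_library(
        cds, lam=lam, ti_tv=ti_tv, n_clones=n_clones,
        inactivating_residues=inactivating_residues, seed=s_lib,
    )
    pre_pool, post_pool = simulate_selection(
        library, pre_size=n_clones, post_size=n_clones,
        gate_leak=gate_leak, seed=s_sel,
    )
    pre_reads = simulate_reads(
        pre_pool, depth=depth, read_len=read_len, error_rate=error_rate, seed=s_pre
    )
    post_reads = simulate_reads(
        post_pool, depth=depth, read_len=read_len, error_rate=error_rate, seed=s_post
    )
    return ScreenSim(cds, library, pre_reads, post_reads, dict(inactivating_residues))


@dataclass
class SimulatedCountExperiment:
    """Design of a two-condition, replicated spectral-count experiment."""

    protein_ids: list
    lengths: np.ndarray  # amino-acid lengths
    abundances: np.ndarray  # baseline relative abundances
    bait_id: str
    planted: dict  # protein_id -> fold effect in condition A
    conditions: tuple = ("WT", "MUT")
    n_replicates: int = 3
    depth: float = 10_000.0  # expected spectra per sample at baseline
    depth_jitter_sigma: float = 0.2  # lognormal sigma of per-sample depth
    seed: object = None


def design_count_experiment(
    n_proteins: int = 500,
    n_planted: int = 20,
    effect: float = 8.0,
    n_replicates: int = 3,
    depth: float = 10_000.0,
    bait_fraction: float = 0.10,
    conditions: tuple = ("WT", "MUT"),
    seed=None,
) -> SimulatedCountExperiment:
    """Draw a realistic pulldown design: lognormal abundances and lengths.

    ``n_planted`` proteins get their abundance multiplied by ``effect``
    in the first condition only; the bait is pinned to ``bait_fraction``
    of the expected sample spectra.
    """
    rng = _rng(seed)
    ids = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    lengths = np.exp(rng.normal(np.log(450.0), 0.5, size=n_proteins))
    lengths = np.clip(lengths, 50, 5000).round()
    abundances = np.exp(rng.normal(0.0, 1.0, size=n_proteins))
    bait_id = "BAIT"
    planted_ids = rng.choice(n_proteins, size=n_planted, replace=False)
    planted = {ids[i]: float(effect) for i in sorted(planted_ids)}
    # bait weight chosen so its expected spectral share is bait_fraction
    w_others = (abundances * lengths).sum()
    bait_len = 550.0
    bait_abundance = (
        bait_fraction / (1.0 - bait_fraction) * w_others / bait_len
    )
    return SimulatedCountExperiment(
        protein_ids=ids + [bait_id],
        lengths=np.append(lengths, bait_len),
        abundances=np.append(abundances, bait_abundance),
        bait_id=bait_id,
        planted=planted,
        conditions=conditions,
        n_replicates=n_replicates,
        depth=depth,
        seed=seed,
    )


def simulate_spectral_counts(
    experiment: SimulatedCountExperiment, seed=None
) -> tuple[SpectralCountTable, dict]:
    """Poisson spectral counts for every (condition, replicate) sample.

    The expected count of protein p in a sample is the sample depth times
    p's share of total length-weighted abundance under the baseline
    composition; planted proteins' rates are multiplied by their effect
    in the first condition. Returns the table and the planted truth map.
    """
    exp = experiment
    if exp.abundances[exp.protein_ids.index(exp.bait_id)] <= 0:
        raise ValueError("bait abundance must be positive")
    rng = _rng(seed if seed is not None else exp.seed)
    ids = exp.protein_ids
    w_base = exp.abundances * exp.lengths
    shares = w_base / w_base.sum()
    effect_vec = np.array([exp.planted.get(p, 1.0) for p in ids])

    cond_a = exp.conditions[0]
    data = {}
    for cond in exp.conditions:
        mult = effect_vec if cond == cond_a else np.ones_like(effect_vec)
        for rep in range(1, exp.n_replicates + 1):
            sample_depth = exp.depth * np.exp(
                rng.normal(0.0, exp.depth_jitter_sigma)
            )
            rates = sample_depth * shares * mult
            counts = rng.poisson(rates)
            data[(cond, rep)] = counts
    df = pd.DataFrame(data, index=ids)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    # the bait is by construction abundant; guard the table invariant
    df.loc[exp.bait_id] = df.loc[exp.bait_id].clip(lower=1)
    table = SpectralCountTable(
        counts=df,
        lengths=pd.Series(exp.lengths, index=ids, dtype=float),
        bait_id=exp.bait_id,
        conditions=tuple(exp.conditions),
    )
    return table, dict(exp.planted)
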