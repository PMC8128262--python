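# Methods

This note documents the models implemented in `actmap`, the defaults
and the reasoning behind them, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout.

## Coordinate model

A `CodingSequence` is an in-frame A/C/G/T string whose length is a
positive multiple of three; its protein is the codon-by-codon standard
genetic-code translation with `*` for stops, and at most one stop codon
is allowed, which must be terminal. All coordinates are 1-based and
inclusive, for nucleotides and residues alike, matching the convention
in which point mutants are named (L317P = residue 317). Ambiguity codes
are rejected at this layer; how to treat uncertain bases is a read-level
policy, decided by the quality filter, not by silent skipping.

## Variant-space enumeration

Every codon has nine single-base neighbours. "Accessible variants" are
counted as distinct (residue, alternative amino acid) pairs: multiple
nucleotide routes to the same amino acid collapse to one variant, with
the route multiplicity reported separately. Missense variants are the
default total because the downstream screen analysis discards
stop-containing reads; nonsense variants (also deduplicated, e.g. the
two routes from TGG to a stop count once) are included only on request.
Synonymous changes are never variants — they are tallied as nucleotide
events so the 9-per-codon accounting closes exactly. The reference's
terminal stop codon is excluded from variant enumeration: changes that
turn it into a sense codon are read-through events and are tallied on
their own, while stop-to-stop changes there count as synonymous
nucleotide events.

Coverage arithmetic is the plain ratio constructs-per-variant; the
"N-fold" display string rounds to the nearest integer (100,000 / 3,370
= 29.67, displayed as "30-fold") while machine output keeps the exact
ratio.

## Screen enrichment model

**Read QC.** A mismatch is only trusted at base quality ≥ 20 (the
`--min-bq` flag); below that the base is treated as reference — the
read is neither discarded nor credited with a mutation. A read is
discarded when it carries strictly more than 3 high-quality mismatches
(synonymous ones included: the filter operates at the nucleotide level),
or when any codon it fully covers — with its own calls applied —
translates to a stop other than the reference's terminal stop. A read
cannot witness stops outside its span, so only fully covered codons are
checked. Reads whose alignments contain insertions, deletions or
clipping are discarded under their own reason code; epPCR libraries are
substitution-dominated and the analysis is defined for substitution-only
alignments. QC tallies are reported per pool; nothing is dropped
silently.

The quality threshold of 20 (1% error probability) is the conventional
"high-quality" cut-off for Illumina data; it is exposed as a parameter
because the boundary is a policy choice, not a derived quantity.

**Frequencies and fold change.** The per-residue denominator is the
number of retained reads that fully span the codon; partial codon
coverage contributes nothing. This is the only denominator that makes
the numerator (reads with a non-synonymous change at the codon) a
well-defined proportion for 150-base fragment data. Synonymous changes
increment coverage but never the mutant count. The fold change uses
Haldane-smoothed frequencies, (m + ½)/(c + 1), so residues unmutated in
the pre-selection pool remain finite and rankable; the pseudocount is
configurable and zero recovers the raw ratio. Residues with zero
coverage in either pool are reported with undefined (NaN) statistics
and excluded from hit calling rather than guessed. A residue is a hit
when its fold change strictly exceeds the threshold (default 4,
exposed), and the reported "top substitution" is the alternative amino
acid with the highest post-pool read count, ties broken alphabetically
for determinism.

A deliberate property of this estimator, visible in simulations:
passenger mutations riding on multi-mutant inactive clones are
co-enriched with the causal mutation ("hitch-hiking"). The read filter
suppresses the dominant vehicle (nonsense clones) only when a read
covers the stop codon itself. At high per-residue counts the effect
stays well below a 4-fold change; at low counts it combines with
sampling noise and can cross the threshold. This is why the simulated
studies below are sized to keep per-residue counts high.

## Interactome scoring model

Spectral counts from each pulldown sample are processed as:

1. **Isoform combining** — counts summed across a protein group's
   isoforms; the normalising length is the arithmetic mean of the
   isoform amino-acid lengths.
2. **NSAF** — length-normalised count divided by the sample total of
   length-normalised counts; NSAFs sum to 1 per sample.
3. **Relative NSAF** — division by the bait's NSAF in the same sample,
   absorbing bait expression and purification-yield variability. The
   bait maps to exactly 1.
4. **Detection filter** — a protein is scored if its raw count is
   positive in *every* replicate of at least one condition (an and/or
   rule: complete detection in one condition suffices).
5. **Fold change** — per replicate r, relNSAF_A[r]/relNSAF_B[r]
   (replicates are paired by index, matching batch-paired acquisition),
   averaged arithmetically. This is a mean of ratios: swapping the
   condition labels inverts each per-replicate ratio exactly but not
   the average, and that asymmetry is asserted in the tests rather than
   "fixed".
6. **Error estimate** — per condition, each replicate's relative NSAF
   is divided by the replicate mean and the |log₂| of those
   mean-normalised values is averaged; the two condition terms are
   summed. The statistic depends only on ratios to the mean, so it is
   invariant to uniform rescaling. Averaging (rather than summing) the
   per-replicate deviations keeps the error on a per-replicate scale
   and makes Z magnitudes comparable across replicate counts;
   `--error-agg sum` exposes the alternative reading.
7. **Modified Z** — |log₂ average fold change| divided by the summed
   error, floored at ε = 1e-6 to keep zero-variance proteins finite;
   floored scores carry an explicit flag.

**Zeros.** A protein undetected in one sample would make ratios and
logs undefined. When (and only when) forming ratios and dispersions, an
undetected protein's count is imputed as 0.5 spectra — the standard
half-count fallback for spectral data. Because relative NSAF reduces to
(count_p/len_p)/(count_bait/len_bait) within a sample (the sample-sum
cancels), the imputation acts directly on that ratio and leaves other
proteins untouched. Reported NSAF columns keep true zeros.

Ranking is by average fold change, then modified Z, then protein id —
a total order, reproducible across runs.

## Synthetic-data generators

The generators emulate the study's data-generating processes so every
stage runs offline; each is deterministic given a seed.

**epPCR library.** Each clone draws k ~ Poisson(λ) substitutions at
uniform distinct positions. The alternative base is the transition
partner with probability ti/tv ÷ (ti/tv + 2); the default ti/tv of 0.9
reflects the roughly balanced transition/transversion spectrum of
mutagenic polymerase blends. λ defaults to 1.0 mutation per clone — the
regime an amplification protocol optimised for single-nucleotide
variants targets — and can be fitted from pilot-clone counts with the
Poisson MLE (the sample mean). Ground-truth activity is multiplicative:
missense changes at planted inactivating residues multiply activity by
their effect (0 = fully inactivating), any nonsense change sets it to
0, everything else is neutral. No per-cycle jackpot structure or
mutational hot-spots are modelled.

**Selection.** The multi-round reporter sort is collapsed into one
weighted resampling: the pre pool samples clones uniformly, the post
pool with weight (1 − activity) + leak. The leak (default 0.05) models
imperfect gating letting active clones through; with it, the effective
enrichment of a fully inactive clone over an active one is about
20-fold before pool-composition normalisation. Only the pre/post
contrast matters to the estimator under test, so this collapse loses
nothing the analysis could see.

**Sequencing.** 150-base substitution-only fragments with uniform
starts over the reference. Per-base errors occur at a configurable rate
(default 1e-3); half of the error bases carry a tell-tale low quality
score (10) and are removed by the quality filter, the other half
masquerade as confident calls (quality 37) — so the residual background
is error_rate/2 per base. Library mutations always carry full quality.
Indels are not simulated, consistently with the screen's
substitution-only policy.

**Spectral counts.** Per sample, counts are Poisson around
depth × (protein's share of length-weighted abundance), with lognormal
protein abundances (σ = 1), lognormal lengths centred near 450 aa,
per-sample depth jitter (lognormal, σ = 0.2) emulating run-to-run
loading differences, a bait pinned at 10% of sample spectra, and
planted interactors whose rate is multiplied by an effect size in one
condition only. Default depth is 10,000 spectra/sample — the scale of a
single-shot affinity-purification run. Peptide-level structure
(retention time, shared peptides, identification FDR) is not modelled:
the simulator starts where protein-level spectral counts exist.

What passing tests on these simulations show — and what they do not:
they validate the estimators' arithmetic, filters and power against
planted ground truth under idealised noise (Poisson counts, uniform
fragmenting, independent errors). They do not certify behaviour under
real-data pathologies such as alignment artefacts, PCR jackpots,
contaminant proteins, shared-peptide inference or batch effects.

## Problem sizes used in simulated studies

The simulated screen study runs 10,000 clones at λ = 1, three planted
null-activity residues, and 5,000 reads per pool, over 20 seeds. The
reference for this study is a synthetic 50-sense-codon sequence
(153 nt). The length is chosen to preserve the *statistical regime* of
a deeply sequenced screen at this read number: per-residue full-span
coverage scales as depth × reads-per-position, and edge codons are
spanned by only a handful of fragment start positions, so a long
reference at 5,000 reads/pool would push edge residues into a
small-count regime (expected mutant counts below ~5) where pseudocount
noise and hitch-hiking dominate — a regime the method is not designed
for and that deep sequencing avoids. At 50 codons every residue keeps
an expected pre-selection mutant count ≥ 15. With these sizes the
planted residues are recovered at fold changes of roughly 7–15 against
a >4-fold threshold, with no false calls across seeds.

The simulated interactome study uses 500 proteins, 20 planted 8-fold
interactors, 3 replicates per condition and the default depth; planted
proteins' median modified Z (≈ 7) sits far above the null 95th
percentile (≈ 1.6).

## Numerical conventions and degenerate inputs

- Ties: most-enriched substitution and condition selection break ties
  deterministically (alphabetical; natural sort order of condition
  labels, so "15" precedes "20").
- Zero coverage → NaN frequency, propagated, never an exception; empty
  inputs (no clones, no counts, empty pools) raise explicit errors.
- The modified-Z error floor ε = 1e-6 bounds the score at |log₂ FC|/ε
  for zero-dispersion proteins; the flag marks these as floor-limited
  rather than meaningfully large.
- All randomness flows through `numpy.random.Generator` seeded
  explicitly; chained stages derive child seeds via `SeedSequence.spawn`
  so stage outputs are independent yet reproducible bit-for-bit.

## Known limitations

- The enrichment analysis is read-level, not clone-level: linked
  mutations on the same clone are only co-observed within one 150-base
  read, so hitch-hiking passengers cannot be deconvolved, and no
  variant-level fitness regression is attempted.
- The spectral-count scorer has no probabilistic interaction model
  (no CompPASS/SAINT-style posterior); the modified Z is a
  signal-to-replicate-dispersion ratio, not a calibrated p-value, and
  with three replicates its error estimate is itself noisy.
- The detection filter admits proteins absent from one whole condition;
  their fold changes depend on the imputation constant and should be
  read as lower bounds on selectivity, not precise ratios.
- SAM ingestion assumes alignments to the coding sequence itself;
  alignments to a genome or to a vector-flanked amplicon must be
  re-projected upstream.
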