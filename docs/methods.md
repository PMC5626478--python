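# Methods

## Model

The cellular tRNA adaptation index treats translation elongation as limited by
the availability of the decoding tRNA and the strength of the codon:anticodon
pair at the wobble position. For codon *i*:

- **Absolute adaptiveness** `W_i = Σ_j (1 − s_ij) · tRC_ij`, summing over the
  anticodon species *j* that decode *i* (per the input table's codon lists),
  where `tRC_ij` is the species' mapped mature read count and `s_ij ∈ [0, 1)`
  penalizes the pairing class of codon base 3 against anticodon base 34.
- **Relative adaptiveness** `w_i = W_i / max(W_max(family), read_cap)`,
  normalized within the synonymous family of *i*'s amino acid. The read cap
  (default 80,000 reads, roughly the third quartile of the measured HEK293
  pool) floors the denominator: without it, the best codon of a scarce family
  (e.g. Gln, family max ≈ 33k reads) would score w = 1 despite being poorly
  supplied. With the cap, w = 1 is reserved for codons whose cognate tRNA is
  genuinely abundant.
- **Per-ORF score** `ctAI = (Π w)^{1/l}`, the geometric mean over the ORF's
  codons, computed as `exp(mean(log w))`. The initial AUG and all internal
  codons are scored; a trailing stop codon is excluded from the length.

The score is a *relative* measure of adaptation to one measured pool, not an
absolute translation rate.

## Pairing classes and penalties

Classes are named codon3:anticodon34. Watson:Crick pairs (A:U, U:A, G:C, C:G)
carry s = 0. Defaults for the wobble classes, fitted upstream against
construct expression data: U:G = 0.6, C:I = 0.3, G:U = 0.8, A:I = 0.5,
A:G = 0.9999 (near-forbidden). Two classes occur in the measured decoding
table but have no published penalty — C:U (e.g. ACC under a U34 Thr
anticodon) and U:U (CCU under U34 Pro) — both default to 0.6 and are
explicitly configurable; this choice only affects codons whose decoding mix
includes those edges, and is the main reason region scores here should be
compared by rank rather than by decimal against other implementations.

Genomic A at position 34 is treated as inosine when classifying (flaggable),
giving the C:I and A:I classes. A U3 against genomic A34 is classified as
Watson:Crick; under the convention that I34 reads U at cognate strength
(s(U:I) = 0) this is numerically identical, so the distinction is immaterial
at defaults.

The decoding table's codon lists are authoritative: no edge is ever added
from pairing geometry alone, and codons absent from every list are reported
as uncovered rather than silently scored.

## Abundance bins

Species are ranked by read count (ties broken by anticodon, lexicographic)
and split into rank-contiguous bins of near-equal size; a remainder goes to
the middle bins first (middle-outward, later bin first on ties), so 45
species in 4 bins gives sizes (11, 11, 12, 11), matching the measured pool's
published grouping. "Bin-1-cognate" codons are, by default, codons all of
whose decoding anticodons are in bin 1 — the strict reading of "must be
decoded by a bin-1 tRNA"; an any-decoder variant is available by flag.

## Windows, regions, design

Window profiles average w over a 10-codon window by default (arithmetic mean;
geometric by flag), stride 1, with the score anchored to the window's first
codon (1-based). The published description of the scan is in nucleotides, but
only a codon-aligned window produces a codon-axis profile, so window length
is counted in codons. Low regions are maximal runs of windows below a
threshold (default 0.4), optionally merged across short gaps; a region spans
the union of its member windows' codons and reports its minimum window score.

Variant design is greedy per codon: because ctAI is a geometric mean of
independent per-codon terms, the per-position argmax/argmin over synonyms is
globally optimal. Ties prefer the source codon (fewest edits), then the
lexicographically smallest codon. The `different-anticodon-only` mode keeps
only synonyms whose decoding anticodon set differs from the source codon's;
the wobble-swap designer performs exclusively NNU→NNC substitutions for which
some anticodon decodes both codons (same tRNA, stronger pair).

## Penalty fitting

Relative expression is regressed on region ctAI by simple OLS (statsmodels);
goodness of fit is R². The default scale is linear (relative expression
against a reference construct), log by flag. Free pairing penalties are fitted
by exhaustive grid search (default grid 0–0.95 step 0.05 plus a 0.9999
sentinel), recomputing the adaptiveness table and all construct scores at
each point; the search is deterministic, capped at 10^6 points, returns the
full trace, and breaks R² ties toward the lexicographically smallest penalty
vector. Grid search was chosen over continuous optimization because the
objective is cheap, low-dimensional, potentially multi-modal, and the
published penalties are themselves coarse — reproducibility beats precision
here. Requirements: at least 3 constructs shared between scores and
expression, non-zero variance on both sides.

## Synthetic data

- **Pools** reuse the measured 45-anticodon decoding repertoire as a fixed
  template and randomize only the counts, i.i.d. log-normal with location
  10.51 and scale 0.93 (the MLE on the measured counts; central mass ≈
  6×10³–3×10⁵ reads). This guarantees 61-codon coverage without inventing
  decoding biology, but discards the rank correlation between amino acid
  usage and tRNA abundance present in real pools.
- **ORFs** draw codons i.i.d. from two w-stratified sets so that a planted
  region and the background hit target mean w (defaults 0.25 inside / 0.8
  outside, tolerance ±0.05, 400 codons with an 80-codon region), resampling
  until realized means are within tolerance. Real ORFs have codon-pair, GC
  and amino-acid-composition structure these lack, so detector results here
  demonstrate correctness of the sliding-window machinery, not real-data
  sensitivity.
- **Expression** is `slope · ctAI + intercept + N(0, sd)` (defaults 3.0, 0.1,
  0.02 — chosen so a construct panel spans a severalfold expression range
  with a few percent measurement noise), kept positive by resampling rather
  than truncation so the noise stays symmetric away from zero.
- The penalty-recovery panel holds 50 constructs of 72 codons drawn from the
  two-codon NNU/NNC families decoded by a single G34 anticodon, with the
  wobble-U fraction spaced over [0, 1]; since
  `log ctAI_c = a_c + f_c · log(1 − s_UG)`, the panel identifies s(U:G)
  sharply, and a 0.05-step grid recovers the generating 0.6 with median
  error 0 over 20 seeded replicates at noise sd 0.02.

Every generator owns a single `numpy.random.Generator` seeded from its
scenario; no global RNG state is used, and identical seeds reproduce outputs
bit-for-bit.

## The packaged construct series

`ctai.data.synthetic_crd` is a **synthetic** 72-codon stand-in for a
destabilizing coding region and its nine codon-swap variants, constructed to
satisfy the published composition constraints (33 distinct codons, 30/72
strictly bin-1-cognate, Tyr 5 UAU + 2 UAC, 5/5 Phe UUU, 5/5 Asn AAU, the
stated pairwise swap relations between variants, and the published ctAI rank
order of the series under default penalties). The underlying protein sequence
and codon order are invented; only those composition statistics are faithful.
Decimal ctAI values of the real constructs are not reproduced — they depend
on the unpublished C:U/U:U penalties and on the exact sequences — so tests
and the acceptance script commit to the rank order and to the composition
statistics, not to decimals.

## Numerical and degenerate-input choices

- ctAI is always computed in log space; agreement with the naive product form
  is asserted to 1e-12 in tests.
- A codon with w = 0 or missing from the table raises by default
  (`zero_policy="error"`); `"skip"` drops it from the mean, for partial pools.
- Bin fractions are exact integer sums divided by the pool total and sum to 1
  within 1e-12.
- `s = 1` on a class is permitted but warned (it zeroes those edges);
  `s = 0.9999` is the sanctioned near-forbidden value.
- Empty regions, reversed spans, out-of-range thresholds, non-integer or
  negative read counts, duplicate anticodons, and codon/amino-acid mismatches
  all raise typed errors naming the offending item.

## Problem sizes

Tests and the acceptance script run the measured 45-species pool, 72-codon
constructs, 400-codon synthetic ORFs, and 20 replicates × 50 constructs × a
20-point grid for recovery — a few seconds end to end on one core; larger
panels and multi-class grids are supported up to the 10^6-point cap.

## Known limitations

- The index ignores codon context (codon-pair effects, mRNA structure, ramp
  effects), initiation, and amino-acid supply; it is a pool-matching score.
- Wobble penalties are treated as global per class, not per anticodon.
- The read cap is a single global floor; families with max W just above vs
  just below 80k reads are treated discontinuously.
- tRNA modification state (beyond the A34→I inference) is not modeled; the
  input table's codon lists carry all modification-dependent decodability.
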