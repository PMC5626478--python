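# ctai — codon optimality against measured cellular tRNA pools

Classic codon-optimality measures such as the tRNA adaptation index (tAI)
weight codons by genomic tRNA gene copy number, which tracks actual tRNA
abundance poorly in human cells. `ctai` implements the *cellular* tRNA
adaptation index: the same adaptiveness framework, but driven by measured
anticodon-level tRNA-seq read counts, so a codon's score reflects the tRNA
pool of the cell type the sequence will actually be expressed in.

The package is aimed at people studying codon-level determinants of mRNA
stability and translation — e.g. mapping destabilizing coding-region
determinants (CRDs), or designing synonymous codon-swap constructs that raise
or lower a region's match to the tRNA pool.

## The statistic

For codon *i* decoded by anticodons *j = 1..n_i* with mapped read counts
tRC_ij and pairing penalties s_ij (0 for Watson:Crick, larger for wobble):

    W_i = Σ_j (1 − s_ij) · tRC_ij
    w_i = W_i / max( max_{family(i)} W , 80 000 reads )
    ctAI_g = ( Π_k w_{i_k g} )^(1/l_g)

Relative adaptiveness w is normalized **within the synonymous family** (not
across all codons), floored by a read cap (~3rd quartile of the pool) so that
families whose best tRNA is itself scarce stay sub-optimal. The per-gene score
is the geometric mean of w over the ORF's codons, computed in the log domain.
Default penalties (codon base 3 : anticodon base 34): U:G = 0.6, C:I = 0.3,
G:U = 0.8, A:I = 0.5, A:G = 0.9999; genomic A34 is treated as inosine.

Around the statistic the package provides: tRNA table loading/validation and
abundance binning; decoding-map construction with pairing-class annotation;
sliding-window profiles and low-optimality region detection; synonymous
variant design (greedy per-codon, or same-anticodon wobble U→C swaps only);
region codon-bias reports; penalty fitting against construct expression data
by exhaustive grid search (`WobbleConstraintModel(...).fit().summary()`);
and seeded synthetic generators for every input.

## Worked example

Score the packaged codon-swap construct series (a synthetic stand-in CRD, see
`ctai.data.synthetic_crd`) against the packaged HEK293 tRNA table:

```python
import ctai
from ctai.data import hek293_pool, crd_constructs, crd_region

pool = hek293_pool()                          # 45 anticodon species, 61 codons covered
table = ctai.adaptiveness_from_map(ctai.build_decoding_map(pool))
region = crd_region()
for name, orf in crd_constructs().items():
    print(name, round(ctai.score_region(orf, region, table), 4))
```

```
WT 0.2897
CS-W 0.2769
CSc 0.3228
CSb 0.3462
CSa 0.3689
CS-I 0.3553
CS-R 0.3882
CS-B 0.4268
CS-Tyr 0.4665
```

The wild-type region scores ~0.29 — deep in the poorly-adapted range — and
purely synonymous swaps move it by ~1.7-fold: 14 same-anticodon wobble U→C
swaps (CSb, 0.3462), 5 further Asn AAU→AAC swaps (CSa, 0.3689), up to a
broadly optimized variant with all 7 Tyr codons at direct-pairing UAC
(CS-Tyr, 0.4665). Scanning the wild-type region with a 10-codon window at
threshold 0.4,

```python
profile = ctai.window_profile(crd_constructs()["WT"], table, window_len=10)
print([(r.start, r.end, round(r.min_score, 3))
       for r in ctai.detect_low_regions(profile, threshold=0.4)])
# [(1, 13, 0.153), (14, 27, 0.224), (28, 44, 0.245), (40, 55, 0.29), (57, 69, 0.308)]
```

shows the clusters of codons cognate to the scarcest (bin-1) tRNAs that make
the region a stability determinant. The same operations are available from the
shell: `ctai bins`, `ctai score`, `ctai scan`, `ctai design`, `ctai bias`,
`ctai fit`, `ctai simulate` (see `ctai --help`).

## Layout

- `ctai.pool` — tRNA table parsing/validation, abundance bins, decoding map
- `ctai.adaptiveness` — penalties (s), W and w tables
- `ctai.scoring` — ctAI, window profiles, region detection, FASTA/BED I/O
- `ctai.design` — synonymous variant design, codon-bias statistics
- `ctai.fit` — expression regression and penalty grid search (model/results)
- `ctai.simulate` — seeded synthetic pools, ORFs, expression tables
- `ctai.data` — packaged HEK293 tRNA counts; synthetic CRD construct series
- `docs/methods.md` — model description, parameter choices, limitations
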