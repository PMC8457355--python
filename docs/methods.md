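# Methods

This note documents the models behind `rhizoepc`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic tests do and do
not establish. Empirical behaviour quoted here is computed by the test suite
or by `scripts/acceptance.py`; nothing below is asserted that the code does
not itself measure.

## 1. The measurement model

A mixed inoculum of *n* rhizobial strains nodulates a host root system; the
nodulated roots are amplified at a barcode locus and sequenced. The package
treats the read pool of a sample as a multinomial draw: conditional on the
assigned total, strain counts are multinomial with probabilities equal to the
strain's share of barcode copies in the root DNA. The EPC index is the
plug-in estimate of that share, in percent, and the per-host value is the
mean over biological replicates.

Two consequences shape the defaults:

* **strict matching is unbiased but lossy** — every substitution error that
  survives merge-correction removes the read from counting; the loss rate is
  the same for all strains at a given error rate, so proportions are
  preserved while effective depth shrinks (at 0.5% per-base error and a
  309-bp allele roughly 40% of pairs survive; the acceptance script prints
  the realised figure);
* **replicate means, not pooled counts** — the per-host EPC is the mean of
  replicate percentages. Under unequal depth this differs from the pooled
  percentage; a `pooled_counts` argument to `summarize_replicates` exposes
  the alternative. CV% uses the n−1 sample standard deviation (the
  convention is not fixed by the definition of the index; either choice is
  scale-free) and is undefined where the mean is zero.

## 2. Read processing chain

The chain is merge → demultiplex → primer clip → expected error →
dereplicate → (optional) chimera flag → exact match.

* **Merging** scans every ungapped offset of R1 against the reverse
  complement of R2, scoring +1 per match and −2 per mismatch. Indels are not
  modelled: a fixed-locus amplicon is indel-free by construction, and this
  keeps the merger a transparent contract rather than a bit-compatible clone
  of any tool. An offset is accepted when the overlap is at least
  `min_overlap` (default 16) and its mismatch fraction at most 0.25; ties
  prefer the larger overlap, then the smaller offset. Staggered overhangs
  (reads extending past the amplicon) are trimmed when `allow_stagger` is
  on. Merged qualities: agreeing positions get Q1+Q2 capped at 41; at
  conflicts the higher-quality base is kept with quality |Q1−Q2| (ties keep
  the forward base at Q0). Note that the conflict rule can locally *raise*
  expected error above the sum of the two reads' EEs (an equal-confidence
  conflict is genuinely uncertain); with the two-state quality model of the
  simulator such positions do not occur, and the EE-subadditivity test is
  run on simulator-model reads.
* **Demultiplexing** requires a full-length exact match of the merged 5'
  prefix against a sample tag (6 bp by default); one mismatch discards the
  read. Merging happens before demultiplexing, matching the stated tool
  order of the protocol the package models.
* **Primer clipping** anchors the forward primer at the 5' end and the
  reverse-complemented reverse primer at the 3' end. A primer may be
  truncated at a read boundary down to ⌈2/3 of its length⌉ (so 14 of 20 bp);
  within a match the mismatch rate may not exceed 0.1. Both primers must be
  found or the read is rejected; primers overlapping each other yield a
  distinct rejection reason. The batched pipeline checks the full-length
  anchored case vectorised and falls back to the scalar routine for short
  (stagger-trimmed) merges where boundary truncation can occur.
* **Expected error** is Σ 10^(−Q/10) over the clipped insert; dereplication
  keeps, per unique sequence, the abundance and the lowest EE.
* **Chimera flagging** is QC only and off by default (the modelled protocol
  found no contamination and used unclustered data): a sequence is flagged
  when two parents, each at least twice as abundant, explain it as a
  single-crossover hybrid with ≥2 fewer mismatches than the best single
  parent. Flags never change counts.
* **Exact matching** assigns a unique sequence to a reference allele iff the
  strings are identical. Alleles shared by several strains (collision
  groups) are counted at group level and labelled by the joined strain ids.

## 3. Synthetic data: the stated world

The generator reproduces the experiment the package models, with full
ground truth:

* 32 strains, 309-bp alleles behind conserved 20-bp primers, one two-strain
  collision group (the real panel could include only one representative of
  its most common nodulation clade);
* 9 host genotypes × 4 biological replicates, ~14,203 read pairs per sample,
  2×250 bp, 6-bp tags;
* substitution errors only, i.i.d. at the requested rate. Qualities follow a
  two-state model: bases are Q38 except a fraction assigned Q7 such that the
  mixture's mean error probability equals the requested rate, and each
  base's error probability is exactly 10^(−Q/10). This is enough to exercise
  expected-error logic without an instrument-specific simulator; indels,
  PCR bias, duplicates and length heterogeneity are out of scope. Below the
  Q38 error rate (1.6·10⁻⁴) the requested rate is applied directly and the
  quality strings are slightly pessimistic.
* host propensities: each strain's propensity on a host is the product of
  the effect sizes of the planted genes it carries; replicate proportions
  are Dirichlet with concentration `c · base` (c = 100 by default — at depth
  10⁴ the replicate noise then dominates counting noise, which is what real
  biological replicates look like). An infinite concentration returns the
  base proportions exactly. Per-sample depth is a parameter, constant by
  default (the modelled study reports only a mean).
* pangenome: planted genes are carried by a contiguous block of about half
  the strains in a randomised order. Null genes default to the extremes of
  the U-shaped gene-frequency spectrum (cloud genes in 1–3 strains,
  near-core genes missing from 1–3). Mid-frequency ("shell") null genes are
  opt-in via `shell_fraction` because in a 32-strain panel a random shell
  gene can, by chance, be present in the whole top-5 and absent from the
  whole bottom-5 — statistically indistinguishable from a true association,
  and exactly the false-positive class the validation step cannot remove.
  With the default spectrum such coincidences are impossible by counting
  (a ≤4-carrier gene cannot cover 5 strains; a ≥28-carrier gene cannot
  avoid 5), so the planted-gene recovery guarantee is structural, not
  statistical. Present genes are written into carrier genomes at 98%
  identity; absent genes leave no homolog; optional decoys plant diverged
  copies below the calling threshold.
* genomes additionally carry a genospecies backbone (per-cluster ancestors
  at 6% divergence, 1% within — between-cluster ANI lands near 88%, within
  near 98%, straddling the 95% threshold) and a repABC cassette per
  replicon; a separate generator emits equal-length concatenated
  nodulation-gene alignments with a nested two-level clade structure whose
  divergences (15% / 2.5% / 0.5%) sit on either side of the default
  classification cuts.

A green synthetic test therefore establishes: correct bookkeeping through
the whole chain, multinomial-level quantitative recovery, and exact recovery
of planted effects under the stated noise model. It does **not** establish
robustness to indels, chimeric amplification, tag hopping, primer-site
variation, or shell-gene confounding — the last is measurable by raising
`shell_fraction`, the others are out of scope.

## 4. Barcode design and core selection

Windows are scanned over a *pre-computed* alignment (alignment itself is out
of scope); allele strings are gap-stripped before comparison and IUPAC
degeneracies compare as literal characters, because downstream matching is
literal. Flanking primer regions are conserved when every sequence is within
`max_primer_mismatch` (default 1) of the column consensus (consensus ties
break to the smaller character). The selected window maximises allele count
among primer-conserved windows, leftmost on ties; note that windows shifted
by a base or two off a physical primer boundary can tie in allele count, so
a reference intended for read matching should come from the inter-primer
window of the actual primers (the simulator writes exactly that reference).
Core-collection selection takes one strain per allele greedily, preferring
in order: a new genospecies/Nod-group combination, a new host of isolation,
a new origin, and nodX balance, with ties to the smallest strain id;
smallest-membership alleles are resolved first so constrained choices come
early.

## 5. Association statistics

* Kruskal–Wallis uses the tie-corrected H; p comes from the χ² approximation
  or, for small samples, from full enumeration of distinct label
  assignments (`method="exact"`). The acceptance suite verifies the exact
  mode against an independent enumeration oracle on all instance shapes up
  to N=8 and the χ² mode's null rejection rate (5% ± 99% binomial CI over
  2,000 simulations at n=13+13).
* The Dunn post hoc uses the rank-variance with tie term
  N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p, Bonferroni over all
  pairs. Compact letters come from the classic insert–absorb construction
  over median-sorted groups: two levels share a letter iff their adjusted p
  is ≥ α.
* Species-level pooling stacks strain × cultivar mean-EPC cells as
  independent observations (13 type-A strains over two cultivars give
  n = 26), deliberately preserving the pseudo-replication convention of the
  design it reproduces.
* The contrast screen ranks strains by mean EPC (ties by total reads, then
  label) and keeps genes present in all top-k and absent from all bottom-k
  or the reverse; k = 5 by default, 4 permitted, and restricted screens
  (e.g. within nodX carriers) are expressed by passing a restricted ranking.
  Validation re-tests each candidate by carrier/non-carrier Kruskal–Wallis
  over all detected strains; genes fixed in the panel are flagged as
  unvalidatable, a single-strain class warns.

## 6. Alignment, ANI and taxonomy

* `local_align` is an ungapped seed-and-extend aligner: exact 11-mer seeds,
  one two-way x-drop extension per diagonal (drop-off 20, +1/−2 scoring).
  It is a contract-level stand-in for BLAST, not score-compatible with it;
  presence calls use strict `>0.70` identity and `>0.70` coverage, where the
  coarse thresholds make heuristic-vs-optimal differences irrelevant (the
  suite still checks exact agreement with an exhaustive best-segment oracle
  on constructed homologies).
* ANI follows the classic fragment recipe: 1020-bp fragments, retained at
  >30% identity over ≥70% of the fragment, averaged, then symmetrised by
  averaging both directions; the self-value is exactly 100. Because
  identity is measured over retained aligned segments, values sit a few
  tenths above 100·(1−d) at divergence d ≳ 5%. Genospecies are connected
  components of the ≥95%-ANI graph (single linkage; a chain of near
  neighbours therefore merges, which is documented behaviour), with strains
  below 92% to everything flagged as outside the species complex.
* The nod phylogeny uses p-distances (gapped sites pairwise-excluded) and
  canonical neighbor joining (delegated to scikit-bio, negative branch
  estimates clamped to zero, labels sorted for deterministic tie-breaking).
  Nod types and groups are nested single-linkage cuts at p-distance 0.10
  and 0.03 — configuration values, since the grouping they reproduce was
  published as a drawn figure without numeric criteria; published labels
  can always be supplied as metadata instead.
* Replicon (Rh) classification: best-scoring repA reference above the
  similarity floor (default identity > 0.70) names the candidate group;
  the group is assigned only when cognate repB and repC are present on the
  same replicon; score ties resolve to the smallest label and are flagged.

## 7. Numerical and API conventions

Coordinates are 0-based half-open. Phred qualities are +33 throughout.
Dereplication sorts by decreasing abundance, then sequence; all
tie-breaking rules (merge offset, ranking, BBH, consensus, replicon labels)
are lexicographic and documented at the function, so every pipeline output
is reproducible bit-for-bit under a fixed seed. Heavy stages (merge,
demultiplex, full-length primer check, error simulation) are vectorised
over equal-length read blocks; the scalar functions define the contract and
the batch paths are tested against them. The full stated-world run
(36 samples × 14,203 pairs) completes in roughly two minutes on one CPU.

## 8. Known limitations

* No indel handling anywhere in the read chain; real data with homopolymer
  errors would lose reads at the strict-match step rather than mis-assign.
* The chimera test is a minimal two-parent crossover check, suitable as a
  negative control, not a replacement for uchime-style scoring.
* BBH and presence calls use the heuristic aligner; parity with BLAST
  outputs on real genomes is a soft expectation, not a guarantee.
* Real-data reproduction of the study this package models requires its
  deposited reads and supplementary tables (sequence archives), which are
  not distributable here; the test suite therefore anchors on
  generator-truth recovery and closed-form oracles.
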