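# Methods

This note records the models, algorithms, parameter choices and known
limitations of `mermine`, in the order the pipeline runs.

## Sequence records and coordinates

All residue positions are 1-based in the numbering of the family
reference sequence, with position 1 the first residue of the deposited
sequence (initiator methionine included). Rule tables (`ResidueRuleTable`)
are ordered, with positions non-decreasing; two rules may share a
position only when their taxon conditions differ, which is how the
merA position 605 dimorphism (tyrosine in bacteria, phenylalanine in
archaea) is encoded as two records over one position. The taxon is a
per-candidate input flag, defaulting to bacteria; it is never inferred
from the sequence.

Rule-table files are YAML with keys `family`, `reference_id` and a
`rules` list of `{ref_pos, allowed, taxon, label}` mappings; the
built-in `merA` and `merB` tables ship in `mermine/data/rules/`.

## Catalog clustering

`build_catalog` is greedy incremental clustering in the cd-hit style:
genes sorted by length descending (ties broken lexicographically by id
for determinism), each gene joins the first-opened representative it
matches at ≥ `t_id` identity and ≥ `t_cov` coverage, else seeds a new
cluster. Defaults: `t_id = 0.95`, `t_cov = 0.90`.

Identity and coverage come from a global affine-gap alignment:
identity = matches / alignment columns between the first and last
column where both sequences carry residues (terminal gaps excluded,
internal gaps counted in the denominator); coverage = residues of the
shorter sequence inside that region / length of the shorter sequence.
The coverage denominator is the shorter sequence — the common cd-hit-est
convention, stated here explicitly because conventions differ. No k-mer
prefiltering is used; the all-vs-representatives scan is quadratic and
intended for catalogs up to ~10⁴ genes, not for million-gene catalogs.

## Pairwise alignment

Global Needleman–Wunsch with affine gaps, via Biopython's
`PairwiseAligner`: BLOSUM62 for proteins with gap open 11 / extend 1
(standard protein defaults), +1/−1 match/mismatch with open 5 / extend 1
for nucleotides. A gap of length L costs `open + L·extend`. Terminal
gaps are penalized (true global) so fragment candidates fail rules whose
positions they do not span — a deliberate strictness choice;
`semiglobal=True` (CLI `--semiglobal`) zeroes terminal gap scores for
users screening known fragments. Co-optimal alignments are resolved by
the aligner's fixed traceback order; the optimal score itself is
tie-break independent and is verified against exhaustive enumeration of
all alignments for short pairs.

## Residue verification

A candidate is aligned to the reference once; each applicable rule's
reference position is mapped through the alignment to a candidate
coordinate (`None` when the column is a candidate gap). The check reads
the candidate residue at the mapped coordinate and compares it with the
rule's allowed set. Decisions on edge cases:

- a rule position mapped to a gap **fails** (the candidate lacks the
  catalytic residue as far as the alignment can tell);
- `X` never satisfies a rule;
- the 628–629 vicinal cysteine pair is two independent rules, both of
  which must pass;
- the verdict is the conjunction over applicable rules only (e.g. the
  archaeal F605 rule is ignored for a bacterial candidate).

## Profile HMMs

One model per family, built from a star alignment: every seed is
globally aligned to the reference, reference residues define the match
columns, seed insertions project into insert states. Topology is
"Plan7-lite": begin → (M/I/D)ⁿ → end with all nine M/I/D transition
types permitted, no local-alignment flanking states — candidates are
full-length predicted genes, so glocal/local modes are unnecessary.
This is deliberately not HMMER-compatible and computes no E-values.

Estimation: match emissions `(count + κ) / (column total + 20κ)` with
pseudocount κ = 0.5 (a Jeffreys-like default); transition probabilities
get the same pseudocount per permitted transition; `X` is skipped when
counting. The background is uniform (1/20) by default and configurable.

Scoring is Viterbi in log₂ space: the bit score is the best path's sum
of log₂ transition probabilities plus per-residue match log-odds against
the background (insert emissions score zero). The implementation is
exact — it agrees with brute-force enumeration over all state paths on
small instances — and deterministic, with M > I > D tie order. No
curated gathering thresholds exist for these models, so the search
threshold is calibrated per model as the midpoint between the lowest
true-family score and the highest decoy score on simulated data.

## Single-copy-gene normalization

`scg_normalize` divides every gene's counts, per sample, by the
arithmetic mean of the *recA*, *rpoB*, *gyrB* counts. The ratio is a
per-cell average copy number; it is exactly invariant to per-sample
count scaling. Samples with a zero SCG mean get missing values (never
infinities) and a logged warning; downstream distance computations drop
such samples rather than zero-fill. metaG and metaT tables are
normalized independently and never mixed.

"Effective counts" are accepted as externally produced tables (the
realistic path). The packaged `assign_reads` is a deliberately small
exact k-mer assigner (unique-best counting, ties discarded, k ≥ 8)
whose only purpose is closing the loop in end-to-end simulations; it is
not a read-mapper replacement and performs no fractional multi-mapper
weighting.

## Ecology statistics

- **Bray–Curtis** `Σ|x−y| / Σ(x+y)` over genes, per sample pair
  (scipy's implementation behind the module surface); an all-zero
  sample is an error because its dissimilarity is undefined.
- **Environmental distances**: covariates standardized to zero mean and
  unit variance, then Euclidean. Missing covariates are handled by
  pairwise-complete deletion: each pair is compared over covariates
  observed in both, squared distance rescaled by (total / shared)
  covariate counts, and the number of dropped comparisons logged.
- **Mantel**: Pearson correlation of upper-triangle vectors; the null
  permutes rows/columns of one matrix simultaneously. One-sided
  ("greater") by default with 999 permutations, p = (b+1)/(n_perm+1).
  When n! is small enough the full permutation group is enumerated and
  the exact p (identity included) is returned instead.
- **PERMANOVA**: Anderson's pseudo-F from squared dissimilarities,
  `SS_total = Σ_{i<j} d²/n`, `SS_within` from within-group pairs; labels
  permuted, 999 by default, exact enumeration of distinct label
  arrangements when few enough. Groups of size 1 are rejected. For
  continuous drivers a distance-regression (McArdle–Anderson) form is
  provided: Gower-centered G, covariate hat matrix, permutation of G.
- **Kruskal–Wallis / pairwise Wilcoxon**: scipy's tie-corrected H and
  rank-sum tests; identical values across groups return H = 0, p = 1.
  Holm correction by default (configurable).
- **nMDS**: nonmetric SMACOF — isotonic regression of configuration
  distances on the input dissimilarities (disparities rescaled to the
  configuration's norm), Guttman transform updates, Kruskal stress-1
  reported. First start is the classical-scaling (PCoA) configuration,
  remaining starts random; best of `n_starts` wins. Stress decreases
  monotonically along the iteration (majorization), and the embedding's
  stress is invariant to sample reordering up to rotation/reflection.

All permutation tests are reproducible under a fixed seed and respect
p ≥ 1/(n_perm + 1).

## Simulators and what they do (not) show

The generators produce: diverged family variants (per-site substitution
rate, geometric-length indels with p = 0.5), single-violation decoys,
random nucleotide genes, uniform-start reads with per-base errors, and
negative-binomial count tables (mean/size parameterization, size = 10
default) in which SCG counts track log-normal library sizes and mer
counts have mean ρ·SCG-mean for a planted per-cell copy number ρ.
Environmental covariates are `strength·PC1 + (1−strength)·noise` of the
log community matrix, so Mantel/PERMANOVA have a controllable signal.

Two deliberate restrictions keep planted ground truth valid:
substitutions never touch rule positions (except the single planted
violation in decoy mode), and indels keep an 8-residue margin around
rule positions — a gap placed immediately next to a rule site makes the
alignment-mapped residue there ambiguous and would silently falsify the
planted pass/fail label in either direction.

What passing these simulations does **not** show: the variants are
i.i.d. mutations of one reference, not a phylogeny, so the profile HMM
and verifier are never challenged with clade-structured divergence or
compositional bias; reads are error-uniform with no duplicates or
strand effects; count overdispersion is a single negative-binomial size
for all genes; and the environmental gradient is one linear axis. Real
catalogs, mappers and ocean metadata are messier in all four respects.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with exact oracles: alignment-oracle pairs ≤ 6 residues
(exhaustive enumeration), Viterbi oracles ≤ 5 columns × ≤ 7 residues,
100 + 100 variant/decoy verification benchmarks at 10% substitution,
20-sample communities, 200-replicate calibration loops at 199
permutations. All dynamic programming is in log space; no scaling
tricks are needed at these sizes. Probability normalizations hold to
1e-9; exact-p assertions are exact rational comparisons.

## Known limitations

- The greedy catalog has no heuristic prefilter; quadratic cost limits
  it to ~10⁴ genes.
- Profile search reports bit scores only; without a null length model
  or E-values, thresholds must be calibrated per model.
- The verifier trusts a single global alignment; a structurally wrong
  alignment (e.g. against a distant paralog that slipped the HMM) can
  mis-map rule positions. Positions are checked independently — no
  joint model of correlated catalytic sites.
- `assign_reads` discards multi-mapping reads, slightly deflating
  counts for near-identical genes; real pipelines should supply mapper
  counts.
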