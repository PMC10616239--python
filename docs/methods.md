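# Methods

## The inference model

The pipeline targets a two-group bulk RNA-seq design: n = 3 + 3 samples
(HIGH vs LOW phenotype), three feature layers (mRNA, lncRNA, miRNA) measured
as gene-level counts. The object of inference is the set of
lncRNA–miRNA–mRNA triplets consistent with ceRNA co-regulation: both the
lncRNA and the mRNA are repressed by the same miRNAs (strong negative rank
correlation), track each other (strong positive correlation), and share more
miRNA regulators than chance given their regulator-set sizes.

### Normalization

- miRNA: tags per million, `TPM = count · 10⁶ / library`, library = column
  sum of the supplied matrix. Every TPM column sums to 10⁶ by construction.
- mRNA/lncRNA: `FPKM = count · 10⁹ / (length_bp · library)`. The effective
  length is the annotated length in bp; no fragment-length correction is
  applied (no fragment model is available at this interface). FPKM is
  invariant under uniform scaling of a sample's counts.

The library size is always the column sum of the supplied matrix rather
than an external mapped-read total, which keeps the transform self-contained
and exactly testable. If the caller's counts were filtered upstream the two
conventions differ by the filtered fraction; that constant cancels from all
downstream correlation and fold-change screens.

### Differential screen

Selection rule: |log2 FC| > log2(1.5) — strictly, so a feature at exactly
1.5-fold fails — and p ≤ 0.05, on log2(x+1) of the normalized values, with
HIGH as the numerator. Two stand-in tests are provided in place of
count-model DE tools (whose dispersion machinery is out of scope here):

- `welch_log` (default): Welch's two-sample t on the log scale.
- `permutation`: the exact two-sided label-permutation test of the group
  mean difference. All C(n, n_HIGH) assignments are enumerated when that
  number is ≤ 50,000 (the observed assignment is one of them), otherwise
  ≥ 1,000 seeded random permutations are drawn. At 3 + 3 the null has 20
  assignments, p-values live on the lattice k/20, and — because the
  two-sided statistic pairs each assignment with its mirror — the smallest
  achievable p is 2/20 = 0.1. The permutation test therefore cannot reject
  at p ≤ 0.05 in a 3 + 3 design; its type-I calibration is demonstrated at
  5 + 5 (252 assignments, finest two-sided level 12/252 ≈ 0.0476).

A pseudo-count of 1 precedes every log. No multiple-testing correction is
applied by default (matching the raw-p selection rule this class of study
uses); Benjamini–Hochberg adjustment is available behind `bh_adjust=True`.

### Target prediction

- **cis**: a gene is a cis target iff it lies on the lncRNA's chromosome
  and the inter-interval gap (0 for overlapping loci; otherwise the number
  of bases strictly between them) is ≤ 10,000 bp, inclusive at the
  boundary, strand-agnostic. Distances are locus-boundary to
  locus-boundary, not TSS-to-TSS. All genomic intervals are 0-based
  half-open internally; GTF/GFF3 coordinates are converted once at the I/O
  boundary.
- **antisense**: candidate iff ≥ 1 bp genomic overlap on opposite strands.
  With transcript sequences supplied, the score is the fraction of
  complementary positions (Watson–Crick plus G·U wobble; wobble is
  switchable) over the overlapping span, and candidates below 0.5 are
  dropped; without sequences the overlap length is the score and all
  candidates pass.
- **trans**: co-expression regardless of location — |Pearson r| ≥ 0.9 with
  correlation-test p ≤ 0.05 across all samples. Free-energy-based pairing
  is out of scope; externally produced relation tables can be merged
  through the predictions TSV interface.
- **miRNA seed match**: a relation iff the reverse complement of the
  miRNA's 7-mer seed (positions 2–8 from the 5' end) occurs in the target
  region; the score counts (overlapping) occurrences; U/T equivalent. The
  two-predictor intersection rule — keep pairs called by both predictors —
  is implemented exactly and is the supported way to combine external
  predictors.

### The ceRNA screen

Thresholds (all configurable, defaults as stated): Spearman ρ ≤ −0.7
(average ranks for ties, all 6 samples pooled), Pearson r > 0.9 (strict),
hypergeometric upper tail p ≤ 0.05 (inclusive tail, P[X ≥ k]; k = 0 gives
exactly 1). Correlations are computed on log2(x+1) of the normalized
values by default (`log_scale=False` for the raw scale; Spearman is
unaffected). Coefficient cutoffs, not correlation p-values, act as the
correlation filters: with n = 6 a correlation p-value adds little beyond
the coefficient itself.

Candidate pairs are differential-lncRNA × differential-mRNA pairs sharing
at least one retained miRNA (`candidate_rule="all_pairs"` removes the
sharing precondition). The hypergeometric universe N defaults to the
miRNAs appearing in the retained (post-Spearman) edge set — self-contained
and reproducible — and can be widened to all expressed miRNAs
(`universe="expressed"`), which can only shrink p (larger N makes any
overlap more surprising).

The assembled network contains ceRNA edges for final pairs only, and
miRNA→target edges only from miRNAs shared by at least one final pair to
the members of those pairs: the network is the union of its interacting
triplets.

**Known limitation — strict screen monotonicity.** Tightening the Pearson
or hypergeometric thresholds can only remove edges. Tightening the DE or
Spearman thresholds shrinks the retained edge set, and because the
hypergeometric p decreases when a *non-shared* regulator leaves K or n
(with k unchanged), a borderline pair can in principle become significant
under a stricter upstream screen. This is inherent to any
regulator-set-size-conditioned test, holds for either universe convention,
and is rare in practice; the end-to-end monotonicity property is verified
on a seeded threshold grid in the test suite, while the stage-level
monotonicity that is guaranteed is tested separately.

### Enrichment and qPCR arithmetic

Over-representation analysis consumes GMT gene sets and shares the
hypergeometric kernel with the ceRNA screen (bit-identical p for identical
(N, K, n, k)); the universe defaults to the union of set members and
should normally be set to all expressed features. The Livak relative
expression is `2^(−ΔΔCt)` with replicates averaged on the Ct scale before
differencing; ΔΔCt = 0 gives 1, condition swap inverts the result, and a
constant Ct shift cancels.

## The synthetic-data generator

The generator emulates the study design every stage assumes — it is the
package's test bed, not a model of any particular tissue.

- **Counts**: negative binomial with gene-specific means (log-uniform in
  [20, 2000]; planted triplet members in [100, 2000] to stay clear of the
  Poisson-noise floor) and a global dispersion, default 0.05 — a typical
  biological-replicate dispersion for homogeneous bulk tissue, and small
  enough that the planted correlation structure survives at n = 6 (see
  calibration below).
- **Planted differential features**: beyond the triplet members, 10 extra
  features per layer (alternating sign) shift the HIGH-group mean by
  2^±1.64, a representative differential fold change for this design.
- **Planted triplets** (default 20 ceRNA pairs × 2 shared miRNAs): each
  pair is driven by a latent per-sample vector z with group means ±1.3 and
  within-group offsets ±0.45 (randomly ordered within groups per triplet),
  scaled to log2 amplitude 2.2. The three members are deterministic
  transforms of z:
  - the lncRNA follows z;
  - the mRNA re-uses z's values re-ordered within groups so that the
    latent Pearson correlation, after the predicted count-noise
    attenuation a²V/(a²V+σ²), lands on the value lattice closest to the
    target r = 0.95;
  - the miRNA follows the negated z re-ordered within groups onto the
    n-sample Spearman lattice value at least as strong as the target
    ρ = −0.85 (count noise only weakens rank correlations, so the planted
    pattern starts at or beyond the target).

  Because all planted structure is deterministic and only count noise
  degrades it, realized correlations concentrate near their targets
  instead of showing the full sampling spread of an n = 6 coefficient —
  this is what makes the stated calibration (realized ρ ≤ −0.7 and
  r > 0.9 for ≥ 90% of planted triplets) achievable at this sample size.
  Measured over 10 seeds at defaults: realized ρ mean −0.85 (99.6% ≤
  −0.7), realized r mean 0.95 (99% > 0.9). Group separation is preserved
  by construction (re-orderings are within-group only), so every triplet
  member is differentially expressed. Orientation alternates per triplet
  (miRNA up in HIGH for half of them) to keep library composition
  balanced. Infeasible targets — anti-correlation weaker than −0.55
  (which cannot coexist with group separation at 3 + 3), a Pearson target
  above the count-noise attenuation ceiling, or nonpositive dispersion —
  are hard errors raised before sampling.
- **Relations**: each triplet's miRNAs target both its ceRNAs; 100
  background relations are drawn uniformly over all miRNA × (lncRNA ∪
  mRNA) pairs, so background mostly touches non-differential features and
  the planted pairs' hypergeometric p stays small while background pairs
  mostly share nothing (p = 1). Two predictor tables are written whose
  intersection is exactly the planted relation set.
- **Sequences**: 22-nt miRNAs and 300-nt target regions with the seed
  sites of planted relations embedded; designated antisense pairs carry
  genome-consistent transcript sequences with controlled complementarity
  (0.98 / 0.80 / 0.40, plus a same-strand control).
- **Genome**: random features on four 3-Mb chromosomes; designated cis
  pairs on a dedicated chromosome at gaps 9,999 / 10,000 / 10,001 bp
  straddling the cis boundary, in blocks 100 kb apart.

Everything is deterministic given the seed (byte-identical re-runs).

What the generator does **not** emulate: isoform structure, batch or
GC/length biases, compositional library effects beyond what the planted
features induce, mapping uncertainty, and count–mean dispersion trends.
Passing tests therefore demonstrate the correctness and calibration of the
screens under a clean planted-signal model, not performance on real
tissue, where upstream pipeline choices dominate.

## Problem sizes used by the tests and the acceptance script

Default cohorts are 300 mRNA + 150 lncRNA + 100 miRNA features × 6
samples; recovery metrics average 10 seeded cohorts, the pure-noise
control uses 20, the null type-I calibration uses one 2,000-feature
5 + 5 cohort with the exact 252-assignment permutation test, the
normalization contracts use 100 random matrices, and the hypergeometric
kernel is checked against exhaustive enumeration for every
(N ≤ 10–12, K, n, k). These sizes make the whole suite run in seconds
while leaving every check statistically meaningful.
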