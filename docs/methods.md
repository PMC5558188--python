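# Methods

This note records the modelling choices behind `prdis`: what each stage
assumes, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical conventions. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Dataset assembly

The pathogenic class is read from a curated table of Disease-annotated
substitutions (Humsavar-style). Proteins contributing fewer than
`thres` pathogenic variants are dropped before anything else;
`thres = 30` is the default, chosen in the original curation to keep the
neutral:pathogenic ratio near 2.8 — larger imbalance becomes hard to
correct even with oversampling. The count is of *pathogenic* variants,
since the filter exists to limit proteins that contribute few pathogenic
but many neutral variants (a `count_all_labels` switch counts everything
instead).

The neutral class uses the homology model: within a family alignment,
every deviation from the human reference seen in a homolog at ≥ 95%
pairwise identity (`identity_min_neutral`) is assumed tolerated, hence
neutral. Homologs below 40% identity (`identity_min_keep`) are removed
first; when the caller supplies an already-pruned alignment this step is
a no-op. Two conventions the upstream description leaves open are fixed
here: pairwise identity is computed within the alignment, over mutually
gap-free columns only; and the same substitution observed in several
homologs is emitted once (variant identity is the tuple protein /
native / position / variant).

`snv_only` keeps substitutions reachable by one nucleotide change in at
least one codon of the native residue (standard genetic code,
enumerated). Protein-level data carry no codon context, so considering
*all* codons of the native amino acid is the most permissive consistent
reading.

## Biological features

All three features come from the family MSA, positions being 1-based in
the ungapped human reference:

- **blosum62** — the canonical NCBI 20×20 integer matrix (via
  Biopython), range [−4, 11], symmetric.
- **entropy** — Shannon entropy of the variant column, gaps excluded
  from the counts; 0 for a conserved column, log 20 ≈ 3.0 nats at the
  uniform composition.
- **pssm_nat** — log(f_nat,i / f_nat,MSA) with f_nat,MSA taken over the
  whole alignment (all columns, gaps excluded, sequences unweighted).

Logarithms are natural by default; a `base` switch rescales both
entropy and pssm_nat monotonically (downstream normalisation makes the
choice immaterial to the classifiers). A pseudocount (default 0.5,
Jeffreys-style, applied as (count + q)/(total + 20 q) to both
frequencies) keeps pssm_nat finite on sparse alignments; q = 0
reproduces the raw formula and raises when the native residue is absent.
Note that on very shallow alignments (a handful of rows) the smoothing
dominates and can push pssm_nat of a conserved column below zero; at
realistic depths (tens of sequences) its effect is negligible.

## Binarization and partitioning

The tools' raw outputs are heterogeneous, and no universal cutoffs
exist, so binarization is an explicit, overridable registry. Defaults
follow each tool's published convention: SIFT < 0.05 deleterious
(score-mode, lower is pathogenic), PolyPhen-2 HDIV ≥ 0.5 damaging, CADD
phred ≥ 15, PON-P2 and MutationTaster2 via categorical maps. Ties at a
threshold are called pathogenic. PON-P2's "unknown" class is treated as
no output rather than as a disagreement (this is a genuine open choice;
treating it as a third call would move those variants from NO-OUTPUT to
PRDIS). A categorical call missing from its map fails loudly instead of
silently becoming MISSING. When a record carries a categorical call for
a score-mode tool, the category map takes precedence.

The rule itself is strictly unanimous — no majority voting — matching
the clinical guideline it formalises. Combinations of ≥ 2 of the five
reference tools give 26 partitions. Two monotonicity properties follow
from unanimity and are tested: adding a tool never shrinks NO-OUTPUT
and never moves a variant from PRDIS to AGREE.

## Specific classifiers

The networks deliberately mirror the classic WEKA MultilayerPerceptron
setup under which this family of predictors was originally built:
sigmoid units throughout, squared-error loss, SGD with momentum,
learning rate 0.3, momentum 0.2, 500 epochs, no validation split (so
the early-stop patience field is inert), per-feature affine input
normalisation to [−1, 1], decision threshold 0.5 with ties pathogenic.
Two architectures: no hidden layer, or one hidden layer with two nodes.
The emulation is not bit-exact with WEKA: weights start at small seeded
uniform values and gradient updates are applied in mini-batches
(default 32, shuffled each epoch; batch size 1 recovers per-instance
updates). With networks this small the estimator is insensitive to the
batching, and all results are replicated cross-validation averages, not
single fits. Everything is deterministic under a fixed seed.

SMOTE is applied to training folds only, oversampling the minority
class to exact parity: each synthetic row is x + u·(x_nn − x), u ~
U[0, 1], with x_nn one of the k = 5 nearest minority neighbours
(Euclidean; k per the original SMOTE recipe, clamped with a warning
when the minority is smaller). A single-point minority degenerates to
replication. Pathogenic is the positive class everywhere.

## Performance assessment

The six measures are derived from pooled confusion counts. A ratio with
a zero denominator is reported as `None` — undefined, never coerced to
0 — and excluded (with a logged count) from cross-replica means, to
keep averages honest. Cross-validation is 10 replicas × stratified
5-fold (replica seeds default 0..9); within a replica the test-fold
confusion counts are pooled (micro-averaged) before computing metrics,
then metrics are averaged across replicas. Whether the original
protocol pooled or fold-averaged is unstated; pooling was chosen
because it is well-defined even when single folds have degenerate
confusion tables.

Coverage denominators: the coincidence rule's coverage is
|AGREE| / initial; a reference tool's is its output count / initial;
the hybrid's is (|AGREE| + |PRDIS|) / initial. Hybrid confusion counts
are the sum of the AGREE-part and PRDIS-part counts (additivity is
tested). The hybrid must be scored on variants disjoint from the
specific model's training data.

## Synthetic panels

The generator exists so every stage is testable without external data.
Each variant has a latent binary label (prevalence 0.265, matching the
15,723 / 59,442 pathogenic fraction of the curated panel); each tool
observes it through an independent Gaussian channel, latent score
s = ±signal + N(0, σ), squashed to the tool's native scale (logistic to
[0, 1], inverted for SIFT; 15 + 5 s phred-like for CADD) and masked at
the tool's no-output rate (defaults mirror observed coverages: SIFT
0.03, PolyPhen-2 0.01, PON-P2 0.30, CADD and MutationTaster2 0.45).
signal/σ = 0.85 puts single-tool accuracy near the ~80% typical of the
field. Because every squashing maps the decision boundary to the
matching registry cutoff, the per-tool error rate is Φ(−signal/σ) and
the partition fractions have closed forms (prod of output
probabilities; unanimity = all-correct + all-wrong), used as 3-SD
statistical oracles.

Alignments are a two-component column mixture: conserved columns
(substitution rate 0.03 in homologs) and variable ones (0.40), half
each. Pathogenic variants are placed on conserved columns — and neutral
ones on variable columns — with probability 0.9, the generative
counterpart of the homology-based neutral model; pathogenic
replacements also lean toward lower-BLOSUM62 residues. This is what
makes the three biological features informative in synthetic panels.

What the generator does **not** emulate: real score distributions and
inter-tool correlations (tools share training data and features, so
real disagreement patterns are not conditionally independent), realistic
family composition, gapped alignments, per-protein variant-count skew,
or label noise in curation. Passing tests therefore demonstrate the
pipeline's correctness and the qualitative structure of the problem
(rule > individual tools on the concordant subset; residual,
feature-improvable signal in the discordant subset), not clinical-grade
performance on real panels.

## Problem sizes

Default test and acceptance panels are 960–3,000 variants with
alignments of 30 sequences — large enough for the 3-SD statistical
oracles and for stable 10 × 5-fold cross-validation of the small
networks, and chosen as the package's standard worked-example scale.

## Known limitations

- Binarization cutoffs for score-mode tools are conventions, not fitted;
  results on real tables depend on them.
- The WEKA emulation reproduces the model class and optimiser family,
  not the exact optimiser trajectory.
- `pssm_nat` with the default pseudocount is biased on very shallow
  alignments (see above).
- The neutral-variant model inherits the usual caveat of homology-based
  labels: a deviation tolerated in a 95%-identical homolog is assumed
  neutral in human.
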