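# Methods

## Model and procedure

`mescreen` screens a gene × sample TPM matrix for genes whose expression
is mutually exclusive (ME) with a chosen source gene. The screen runs on
within-sample percentile ranks rather than raw TPM: ranks are invariant
under any strictly monotone per-sample transform, which removes depth and
scale effects and makes samples from heterogeneous sources comparable.

**Percentile rank.** In each sample, the `N` genes with nonzero TPM are
ranked ascending (ties receive the average ordinal rank) and scored
`P = n/N × 100`; zero-TPM genes get `P = 0`. Ranking among *nonzero*
genes only keeps `P ∈ (0, 100]` for expressed genes and reserves 0 for
absence, so the zero rule and the rank formula never collide. The
tie-average convention makes the transform a deterministic function of
the values, independent of input row order.

**Plasticity.** Per gene across samples, `ARS` is the mean rank and the
gene-plasticity score `GP = q95 − q05` of the rank distribution
(Δ₉₅/₅). Using the 5th/95th percentiles rather than min/max lets at
least 10% of samples support the dynamic range while ignoring outliers.
Quantiles are linearly interpolated between order statistics (the
default "type 7" convention of numpy/R); with fewer than ~20 samples the
5%/95% quantiles are interpolation-dominated and the code warns. A gene
is classed highly plastic when its GP reaches a threshold; the default
threshold is the matrix-wide mean GP, since the meaningful statement is
"more plastic than typical for this compendium" and no absolute cutoff
generalizes across compendia of different heterogeneity.

**Virtual sorting.** Samples are partitioned by the source gene's rank
scores with k-means, k = 2. Because optimal 1-D clusters are contiguous
in sorted order, the global optimum of the within-cluster
sum-of-squares objective is found by an exhaustive scan over the n−1
contiguous split points (prefix sums, O(n log n) with the sort). This
replaces the usual seeded Lloyd iterations with a deterministic exact
solver; a general k-means run from every contiguous initialization
agrees with it (tested). Splits inside a run of tied values are not
representable by a value threshold and are skipped: samples with equal
rank always land on the same side, so labels are a function of the value
alone. Both groups must contain at least `min_group` samples (default
10; below that the group ARS and the rank-sum test are noise-dominated).
A source with a constant rank vector has zero plasticity and is rejected
outright — exclusion around such a gene is unilateral and undetectable.

**δ_ARS and significance.** Per gene, `δ = ARS(high) − ARS(low)`,
bounded in [−100, 100]. Candidate ME genes have `δ ≤ −15`, co-existing
genes `δ ≥ +15`. Group differences are tested with the two-sided
Wilcoxon rank-sum test applied to the percentile ranks (the whole
pipeline's unit of analysis; δ itself is defined on ranks). The exact
null distribution is used when the combined group size is ≤ 25 with no
ties, otherwise the normal approximation with tie and continuity
corrections. p-values are Benjamini–Hochberg corrected across all genes
of one source's screen; when many sources are screened, each source is
its own BH family, matching the per-source interpretation of the
candidate tables. Significance cutoff: `p_adj ≤ 0.01`.

**Cosine filter.** `cos(x, y) = Σxᵢyᵢ / (‖x‖‖y‖)` on the raw TPM
vectors (an option for log1p-TPM exists, off by default). On nonnegative
vectors the cosine lies in [0, 1]; disjoint support gives 0. The
candidate filter is the conjunction `cos ≤ 0.05 ∧ δ ≤ −15 ∧
p_adj ≤ 0.01` with inclusive boundaries. An all-zero gene's cosine is
*undefined* (NaN) and fails the filter: a never-expressed gene carries
no exclusion evidence, and treating it as orthogonal would flood the
screen with spurious hits. The source gene is never its own candidate.

**Reciprocity.** Each candidate is re-used as the source; the check
passes when the original source satisfies the δ and p conditions in the
reversed screen. It is reported as an annotation, not a fourth filter —
it confirms bilaterality but fails for legitimately asymmetric group
structures. Candidates with constant rank vectors (or partitions
violating `min_group`) are recorded as not evaluable rather than failed.

**Pattern classification.** With a GP threshold (same knob as the
plasticity class): both genes plastic and `δ ≤ −15` → bilateral ME; one
side below threshold → unilateral (named for the low side), regardless
of δ, since the δ evidence is not interpretable there; both plastic and
`δ ≥ +15` → co-existing; otherwise none.

## Synthetic data generator

The generator emulates a pooled bulk RNA-seq compendium: 600 samples
drawn uniformly from 8 latent cell phenotypes, 2000 genes, expression
lognormal on the TPM scale (active state median 100 TPM, σ = 1 on the
log scale), and an explicit inactive state that is exactly 0 with
probability 0.85 (dropout) or a lognormal leak with median 0.5 TPM
otherwise. Exact zeros are required by the `P = 0` rule; the lognormal
gives the heavy right tail of real TPM.

Planted structure (defaults; one fixed RNG stream consumed in gene
order, so a fixed spec is bit-reproducible):

* **Hub** — one gene active in phenotypes {0..3} (half the compendium):
  the highly plastic source.
* **20 ME pairs** — gene A active in a subset of the hub's phenotypes,
  gene B in a subset of the complementary ones; subsets have 2–4 of the
  4 phenotypes per side. A gene restricted to a *single* phenotype is
  deliberately excluded from this archetype: it is the low-breadth /
  unilateral confounder, and with ~75 active samples out of 600 its δ
  hovers at the −15 boundary — that regime is represented by the
  phenotype-restricted background class instead. The 20 B-side genes are
  the hub's planted partners.
* **10 co-existing pairs** — both genes share one random 2–4-phenotype
  subset.
* **10 linear negative-correlation pairs** — x uniform mid-level,
  higher (65–95) in hub-active samples and lower (5–35) elsewhere;
  y = 100 − x + N(0, 3), floored at 1. Both strictly positive, strongly
  anti-correlated (Pearson ≈ −1), yet with cosine ≫ 0.05 — the
  confounder the cosine condition must reject. The x side tracks the
  hub's phenotypes so the confounder actually arises in the hub screen;
  a pair independent of the source would be removed by the δ condition
  and would never exercise the cosine filter.
* **20 housekeeping genes** — a fixed per-gene log-mean (drawn once)
  with small per-sample jitter (σ = 0.2). The fixed mean is essential:
  i.i.d. lognormal draws per sample would give a "stable" gene a rank
  that swings across the compendium and a spuriously high GP.
* **50 near-silent genes** — zero in ≥ 95% of samples (detection rate
  0.03), tiny values elsewhere: the noise-orthogonality confounder that
  produces near-zero cosines and must be caught by δ/p.
* **1849 background genes** — a 60/40 mixture. 60% are broadly
  expressed and rank-stable (housekeeping-like, gene-level mean one log
  unit below the active level), 40% are phenotype-restricted with each
  phenotype active independently at probability 0.75. The mixture puts
  the matrix-mean GP mid-scale (≈ 47 at the defaults) rather than near
  100, reproducing the pooled-compendium landscape in which plastic
  genes stand out against a broadly expressed majority. The restricted
  draws are conditioned to keep ≥ 2 active phenotypes on *each* side of
  the hub's split: an unconditioned subset occasionally lands disjoint
  from the hub, which makes the gene a bona fide ME partner — the screen
  then flags it correctly, but the "background" ground-truth label would
  be false. The conditioning keeps the labels sound by construction.

What the generator does **not** model: library-size or batch effects,
gene–gene correlation beyond the planted pairs, single-cell sparsity
beyond the dropout parameter, compositional coupling between genes, or
read-level noise. Passing tests on this data therefore demonstrates that
the statistics behave as designed under phenotype-driven on/off
expression with dropout — not that the screen is robust to batch
structure or to confounders absent from the model.

## Problem sizes and numerical choices

The default study (600 × 2000, the full screen plus 20-fold reciprocal
re-screens) runs in a few seconds on one core; the test suite exercises
smaller matrices (100–150 samples, 200–400 genes) where per-gene
behaviour is checked against independent oracles (counting-based ranks,
direct interpolation quantiles, brute-force WCSS splits, enumeration
Wilcoxon, step-up BH). Note that at 150 samples a narrow two-phenotype
partner can show δ ≈ −18 yet miss `p_adj ≤ 0.01`: with heavy
zero-inflation the rank-sum test keys on detection proportions, and its
power for such genes needs the full 600-sample design — the reason the
pooled-compendium scale matters for screening sensitivity.

Other numerics: result TSVs serialize floats at 6 significant digits;
constant-across-both-groups genes receive p = 1 by definition (the
normal approximation would be 0/0); BH output is clipped at 1;
equal-cost splits in the partition resolve to the smallest high-group
boundary (first minimum in the scan), which is reachable only on exact
float ties.

## Known limitations

* The screen detects *expression-level* exclusion only; it cannot
  distinguish direct negative regulation from mutually exclusive
  lineage identity.
* Sensitivity depends on the source gene's plasticity in the assembled
  compendium; genes silent in most pooled phenotypes yield unilateral
  exclusion and are skipped (multi-source mode) or rejected
  (single-source mode) rather than analyzed badly.
* The ±15 δ cutoff, 0.05 cosine ceiling and 0.01 significance level are
  conventions inherited from the screening design, exposed as
  configuration; nothing in the package calibrates them to a particular
  dataset.
* The reciprocal check reruns a full per-source screen per candidate;
  for very large candidate sets this dominates runtime (it is linear in
  candidates × genes × samples).
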