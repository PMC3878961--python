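# Methods

This note documents the statistical models, the numerical conventions
and the genuinely open design choices behind fermstage. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Expression quantification (NPKM)

Expression is quantified as NPKM — nucleotides per kilobase of gene
model per million mapped reads:

    NPKM(g, s) = N_g / ((L_g / 1e3) · (R_s / 1e6))

`N_g` sums the per-base alignment depth over the gene's 1-based
inclusive interval; bedGraph input (0-based half-open) is converted at
the reader boundary, and all internal coordinates are 1-based
inclusive. The computation is run-length aware: depth sums are
independent of how coverage runs are encoded. A gene with zero
coverage has NPKM exactly 0; NPKM is invariant under joint scaling of
depth and sequencing depth.

Choices made where a convention had to be fixed:

* The denominator is the per-sample **total mapped reads** taken
  verbatim from the design table (the acronym read literally); an
  alternative `denominator="nucleotides"` divides by total mapped
  nucleotides × 1e-9 for comparability with read-length-scaled
  variants.
* Gene models are single intervals — for a bacterial annotation the
  "exon model" degenerates to the gene interval; no exon chaining.
* Overlapping genes are counted independently from the same
  unstranded track (double-counting accepted). Strand-specific
  coverage is supported only as an explicit input, never inferred.

## Differential expression

Two statistics are computed per gene on the untransformed NPKM scale
and combined by union:

**One-way fixed-effects ANOVA** across the five stages,
F = (SSB/(g−1)) / (SSW/(N−g)) with p from F(g−1, N−g). Degenerate
conventions keep downstream set logic total: all 15 values identical →
F = 0, p = 1; zero within-group variance with unequal group means →
p = 0 plus a degeneracy flag. Sums of squares are declared exactly
zero below a 1e-12 relative floor so that floating-point dust cannot
flip a degenerate case. ANOVA is deliberately run untransformed (no
log), with a config hook available for a log offset; on multiplicative
data this costs power for weak effects, which is one reason the union
with the EB criterion matters.

**Empirical-Bayes negative-binomial two-model posterior.** Each gene
is scored under M0 (one shared mean) versus M_DE (an independent mean
per stage), both with NB observation noise, variance = μ + φμ² — the
same parameterization the synthetic generator uses, stated once so
simulator and model cannot silently disagree. NPKM values are rounded
to pseudo-counts with size factors 1 (NPKM is already
depth-normalized); raw counts can be supplied instead. Marginal
likelihoods are approximated by averaging the NB likelihood over an
empirical prior of particles, each combining

* a dispersion drawn from the pooled method-of-moments estimates
  across genes (clipped to [1e-4, 5]),
* a log-normal scale jitter (σ = 0.25) around the gene's own overall
  mean, and
* for M_DE, a relative stage profile drawn from the observed per-gene
  profiles.

Mixture proportions π(M_DE) are estimated by EM over all genes, and
the EM extends to the profile prior: after a first pass the profile
pool is resampled with weights proportional to the posterior DE
probability, so the M_DE prior concentrates on genuinely
stage-dependent shapes rather than being diluted by the flat majority.
Two rounds with 128 particles are the default; the posterior is
invariant under relabeling of replicates within a stage by
construction. Genes with all-zero pseudo-counts or non-finite
likelihood are flagged, excluded from the EM and reported with
likelihood 0.

This two-model posterior is a deliberately compact stand-in for a full
model-averaging framework over arbitrary stage partitions: it
preserves the decision rule (posterior likelihood thresholds of 0.9
for calling and 0.99 for cluster seeding) at a desk-scale cost.

**Decision rule.** DE by ANOVA ⇔ p < 0.01 (strict); DE by EB ⇔
likelihood > 0.9 (strict); DE = union. BH-adjusted q-values and the
estimated FDR at the ANOVA threshold, FDR(t) = m·t / #{p ≤ t} capped
at 1, are reported alongside.

**Replicate reliability.** Per stage, a two-sided one-sample t-test of
the replicate NPKMs against zero (t = mean/(sd/√n), df = n−1) measures
signal-to-noise; sd = 0 gives p = 0 for nonzero means and p = 1
otherwise. A gene is reliable when ≥ 3 of 5 stages have p < 0.15.
This is the only test computable from replicates of a single condition
without a reference and is used purely as a filter for clustering.

## Profile clustering

Stage means are z-scored per gene with the sample sd (n−1 divisor; the
convention is recorded in the output metadata so the population-sd
variant can be compared). Constant rows become all-zero and are
flagged; they are excluded from clustering.

**Cluster number.** Leave-one-stage-out figure of merit: for held-out
stage e, k-means on the remaining four stages, then
FOM(e,k) = √(mean over genes of (x_ge − μ_{c(g),e})²), summed over the
five stages and multiplied by the adjustment factor 1/√((n−k)/n).
The estimate is the elbow: the largest k whose step still improves the
adjusted curve by at least `elbow_tol` (default 5%) of the curve's
value at the smallest scanned k. Normalizing steps by that fixed
scale keeps the estimate stable both against plateau wiggles at large
k and against curves whose true elbow sits at the scan's lower edge —
a local-improvement rule fails on non-convex curves whose drop pauses
just before the true k.

**Seeding and assignment.** Genes that are reliable with EB likelihood
> 0.99 seed k-means (Euclidean Lloyd, best of 20 restarts, fixed
seed); clusters are labeled A, B, … by decreasing size at formation
time. Remaining reliable genes are attached by scaled distance:
d_scaled = d / d_max with d_max the maximum of the full gene × cluster
Euclidean distance matrix (stored for reproducibility). A gene joins
the nearest cluster whose threshold it strictly beats (default 0.3;
per-cluster overrides are a config map, mirroring published analyses
that relaxed two clusters to 0.6); ties break to the earliest label.
"Scaled distance" is not a standardized quantity — division by the
matrix maximum is the simplest scaling that brings an unbounded metric
into [0,1] consistently with thresholds of that magnitude.

**Leftovers.** Unassigned profiles (at least 2× the minimum cluster
size of them) are clustered on their own (FOM + k-means) and the
resulting clusters appended with fresh labels; the leftovers are then
re-assigned against all old and new means, and new clusters that end
up empty under the threshold are dropped. Manual cluster curation is
replaced by two deterministic utilities: merging clusters whose mean
profiles are closer than `merge_tol`, and dropping clusters below
`min_cluster_size` (members return to the assignment pool).

## GO enrichment

Annotations are propagated up the is_a/part_of closure (true-path
rule) before testing. Per cluster, every term with ≥ 3 annotated
universe genes is tested with a two-tailed Fisher exact test in the
point-probability convention (sum of all same-margin tables whose
probability does not exceed the observed one — recorded because the
tail-doubling alternative differs). The universe defaults to genes
with at least one annotation (whole-genome optional). BH adjustment
is applied within each cluster (not jointly across clusters, matching
per-cluster reporting); direction is "over" when the cluster's term
fraction exceeds the background's. When an ancestor and a descendant
are significant in the same cluster with the same direction, the
ancestor is flagged pruned so the most specific term is reported.
GO-slim analysis is a separate pass over slim-mapped annotations (each
direct term maps to its minimal slim ancestors), never mixed with
full-ontology tests.

## Synthetic data

The generator emulates a five-stage fed-batch fermentation
transcriptome: 4172 genes, 5 stages × 3 replicate fermentations,
log-normal NPKM baselines (meanlog 4, sdlog 2 in natural log — median
≈ 55, upper tail into the tens of thousands), library sizes 2×10⁷ ±
20%, gene lengths 200–6000 bp, NB nucleotide counts with dispersion
0.1. A fraction `frac_de` (default 0.33) of genes receives one of
`k_true` planted shapes — unit-norm, zero-mean 5-vectors with pairwise
separation ≥ `min_shape_separation`, drawn by rejection with restarts
— applied in log2 space: stage mean = baseline · 2^(amplitude·shape).
Amplitudes follow effect_scale · LogNormal(0, `amplitude_spread`)
(defaults 1.5 and 0.25): median log2 amplitude 1.5, typical min–max
stage swings of 3–5 fold, the magnitude real stage-dependent operons
(glycolysis, overflow metabolism, sporulation regulons) show across
such fermentations. Amplitudes are positive so a planted cluster is a
coherent shape rather than a shape ± its mirror image.

Coverage materialization spreads each gene's nucleotide count
uniformly over its bases (remainder on the leading positions), which
reproduces the count exactly — NPKM depends only on the depth sum, so
uniformity loses nothing the pipeline can test. Annotations come from
a three-level random DAG (1 root, 12 mid-level terms that double as
the slim set, leaf terms with 1–2 parents); one leaf term per planted
cluster appears in members at probability 0.5 against a 0.05
background, other leaves at uniform 1–10% background rates.

What the generator does **not** emulate: operon structure and
correlated neighboring genes, antisense/ncRNA overlap, rRNA depletion
artifacts, batch effects between fermentations, annotation bias toward
well-studied pathways, or GO term co-occurrence structure. Passing
recovery tests therefore demonstrates correctness of the machinery
under the stated noise model, not performance on any real fermentation
dataset.

## Problem sizes used by the tests and the acceptance script

The statistical contract checks run at the sizes the analysis was
designed around: calibration and DE recovery at 4000–4172 genes
(20 generator seeds for DE recovery in the test suite, 10 in the
acceptance script), and the end-to-end determinism check on the
full-scale 4172-gene fixture. Cluster-recovery checks use a
well-separated configuration (800 genes, frac_de 0.5, effect_scale
2.5, amplitude_spread 0.2, dispersion 0.05, shape separation ≥ 1.2)
chosen so that between-shape distance exceeds three times the
within-shape noise sd on the z-profile scale — the regime in which
figure-of-merit k-selection is well-posed; the tests verify that
separation condition on every generated dataset rather than assuming
it. Enrichment recovery uses 3000 genes with six planted
(cluster, term) pairs and 10–20 annotation permutations for the
type-I side.

## Determinism and numerics

One global seed fans out to per-stage seeds (stage-name CRC mixed with
the base seed, kept below 2³¹) so a single stage can be re-run with
identical randomness. All stochastic operations (k-means restarts,
FOM, EB particle draws, the generator) take explicit seeds; reruns of
`fermstage run` with identical config and inputs are byte-identical
across all result artifacts. `run.log` carries wall-clock timestamps
and is the one deliberately non-reproducible file. Likelihood
aggregation uses log-sum-exp throughout; EM iterates to a 1e-10
fixed-point tolerance with proportions clamped to (1e-6, 1−1e-6).

## Known limitations

* The EB posterior distinguishes only "flat" versus "fully stage
  dependent"; partial patterns (e.g. equal in stages I–III, shifted in
  IV–V) are detected but not identified as such.
* ANOVA on untransformed NPKM is heteroskedastic across expression
  levels; the union criterion compensates but a variance-stabilized
  variant would change individual calls.
* The scaled-distance threshold depends on d_max and hence on the
  composition of the assignment pool; d_max is stored with the model
  so assignments can be audited.
* Genes whose NPKM rounds to zero in every sample cannot be scored by
  the EB model and are reported with likelihood 0.
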