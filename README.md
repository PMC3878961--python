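# fermstage

Stage-resolved transcriptome analysis for bacterial fed-batch
fermentations. The package re-implements, as one tested and fully
deterministic pipeline, the analysis pattern used for industrial
*Bacillus* enzyme-production processes sampled at five fermentation
stages (I–V: glucose excess, early and late glucose starvation, and two
glucose-fed productive stages) in triplicate fermentations (R, M, L):

1. **NPKM quantification** — expression of gene *g* in sample *s* as
   the normalized amount of sequenced nucleotides,

   `NPKM(g,s) = N_g / ((L_g / 10^3) · (R_s / 10^6))`

   where `N_g` is the summed per-base alignment depth over the gene
   interval, `L_g` the gene length in bp and `R_s` the sample's total
   mapped reads (a close kin of RPKM, computed at single-base
   resolution from bedGraph coverage and GFF3 gene models).
2. **Dual-criterion differential expression** — a gene is stage
   dependent if its empirical-Bayes negative-binomial posterior
   likelihood of the stage-dependent model exceeds 0.9 **or** its
   one-way ANOVA p-value across the five stages falls below 0.01
   (estimated FDR is reported alongside).
3. **Profile clustering** — replicate-reliability filtering
   (one-sample t-test per stage, ≥3 of 5 stages with p < 0.15),
   z-scoring of stage-mean profiles, k-means seeding on
   high-confidence genes (EB likelihood > 0.99) with the cluster
   number chosen by leave-one-stage-out figure-of-merit analysis,
   scaled-distance attachment of the remaining reliable genes
   (Euclidean distance / matrix maximum, strictly < 0.3 with
   per-cluster overrides), and formation of new clusters from
   unassignable leftovers.
4. **GO enrichment** — per-cluster two-tailed Fisher exact tests
   (point-probability convention) over true-path-propagated
   annotations with Benjamini–Hochberg control at FDR 0.05,
   parent/child pruning of redundant significant terms, and a generic
   GO-slim rollup.
5. **Heat-map matrices** — z-scored stage means with the standard
   masking rules (whole row masked when NPKM stays below an abundance
   threshold at every stage; single stages masked when the replicate
   measurements are not statistically reliable).

Because real fermentation RNA-Seq datasets of this design are rarely
public, the package ships a first-class synthetic generator
(`fermstage.synthetic`) that emulates the study design — 4172
protein-coding genes, 5 stages × 3 replicates, log-normal baselines
spanning 0 to tens of thousands of NPKM units, negative-binomial noise
(variance = μ + φμ²), planted profile-shape clusters and planted
GO-term enrichments — so every stage of the pipeline is testable
against known ground truth.

## Worked example

Generate a synthetic fermentation fixture under the default study
conditions and run the full pipeline:

```sh
fermstage simulate --out fixture --seed 17
cat > config.yaml <<EOF
design: fixture/design.tsv
npkm: fixture/npkm.tsv
obo: fixture/go.obo
annotations: fixture/ann.tsv
slim: fixture/slim.txt
out_dir: results
seed: 17
EOF
fermstage run --config config.yaml
```

`results/summary.json` then contains (excerpt, exactly as printed by
this command sequence):

```json
"de": {
 "de_by_anova": 869,
 "de_by_eb": 1087,
 "de_union": 1186,
 "estimated_fdr_at_anova_alpha": 0.048,
 "n_genes": 4172,
 "reliable": 4170
},
"cluster": {
 "k_seed": 6,
 "n_clusters": 7,
 "n_seed_members": 796,
 "n_assigned": 2210,
 "n_unassigned": 1960
},
"enrichment": {"n_significant": 6, "n_over": 6, "slim_significant": 8}
```

Reading: of 4172 genes, 869 are called stage dependent by ANOVA
(p < 0.01), 1087 by the EB posterior (likelihood > 0.9), 1186 by at
least one criterion. The figure-of-merit analysis selects k = 6 seed
clusters (the generator planted six latent profile shapes); 796
high-confidence genes seed them, scaled-distance assignment and
leftover clustering attach 2210 genes in total to 7 final clusters,
and each planted cluster recovers its planted GO term as
over-represented (6 significant terms after parent/child pruning;
8 at GO-slim level). Re-running the same config and seed reproduces
every output byte for byte.

The individual stages are also available as subcommands
(`fermstage quantify|de|cluster|enrich|simulate|heatmap`) and as plain
library functions (`fermstage.quantify`, `.diffexpr`, `.cluster`,
`.enrichment`, `.pipeline`).

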