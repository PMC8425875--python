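# mpinet

Analysis toolkit for directed metabolite–protein interaction (MPI) networks:

- **network** — bipartite MPI network model with TSV/GMT I/O, multi-source
  integration (role conflicts merge to reversible), common-metabolite degree
  filtering, core-protein extraction, producer/consumer neighborhoods,
  hypergeometric node-set enrichment, and PPI community detection.
- **stats** — expression-cohort screens: paired/unpaired Wilcoxon
  differential expression with BH/Bonferroni correction, log2 fold change,
  univariate Cox screening (Efron ties), k-group log-rank, one-sided Fisher
  enrichment, z-score normalization.
- **subtyping** — two-subtype discovery: PCA of core-protein expression,
  PAM-based consensus clustering, marker-gene orientation (the cluster with
  lower marker expression is C1), PC1−PC2 discriminant diagnostics,
  random-forest gene ranking, elastic-net classifiers (GL1 for C1/C2, GL2
  for S1/S2), TME-based sub-clustering of C1.
- **enrichment** — ranked-list set enrichment (weighted KS running sum,
  size-matched random-set permutation null, NES/p/FDR), immune gene-list
  construction, and ssGSEA-style per-sample signature scoring.
- **deltam** — per-metabolite accumulation score
  `deltaM = sum(log2FC over producers) − sum(log2FC over consumers)` and
  metabolite-set enrichment on the deltaM ranking.
- **mpi_predict** — bipartite link prediction from six network topology
  features (preferential attachment, 3-path count, two neighborhood-Jaccard
  variants, inverse shortest path, resource allocation) with a seeded
  random forest, out-of-fold ROC/AUROC, and a protein × pathway
  enrichment map of high-confidence predictions.
- **synth** — seeded generators for every pipeline input: heavy-tailed
  bipartite networks with filterable hubs, cohorts with planted subtypes and
  exponential survival, accumulation scenarios with known ground truth, and
  planted-block link-prediction instances.
- **pipeline / cli** — end-to-end orchestration with a provenance manifest.

## CLI

```sh
mpinet simulate  --seed 1 --out data/                     # synthetic inputs
mpinet build-net --edges KEGG:kegg.tsv,BRENDA:brenda.tsv --out net.tsv
mpinet subtype   --expr expr.tsv --net net.tsv --clinical clin.tsv \
                 --markers markers.txt --out subtypes/
mpinet predict   --model subtypes/gl1.json --expr other_cohort.tsv
mpinet deltam    --net net.tsv --fc fold_changes.tsv --sets compounds.gmt --out dm/
mpinet gsea      --ranked ranked.tsv --gmt sets.gmt --nperm 1000 --seed 7 --out gsea.tsv
mpinet immup     --expr expr.tsv --labels labels.tsv --gmt immune.gmt --out immup.tsv
mpinet predict-mpi --net net.tsv --seed 7 --threshold 0.9 --out links/
mpinet run-all   --seed 1 --out run/                      # full synthetic pipeline
```

Edge lists are TSV with columns `metabolite_id`, `protein_id`, `role`
(`substrate` / `product` / `both`) and optionally `source`. Expression
matrices are TSV with genes as rows and samples as columns (log2 scale);
clinical tables carry `group`, `pair_id`, `time`, `event`. Gene/metabolite
sets use standard GMT.

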