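# vepmeta

Gene-level benchmarking and meta-prediction of variant effect predictor
(VEP) performance.

Computational predictors of missense-variant pathogenicity perform very
unevenly across human protein-coding genes: the same tool can separate
pathogenic from benign variants almost perfectly in one gene and barely
better than chance in another.  `vepmeta` is a toolkit for quantifying,
predicting and explaining that heterogeneity.  It is aimed at researchers
who evaluate VEPs against ClinVar-style pathogenic and gnomAD-style
putatively benign variant sets and want per-gene — rather than global —
performance estimates, together with an understanding of which gene
properties drive them.

The package provides:

* **Per-gene discrimination metrics.**  AUROC via the rank-sum
  (Mann–Whitney) statistic with midrank ties,
  `AUROC = (#{p > b} + ½·#{p = b}) / (n_p · n_b)`, whose null value is 0.5
  for every gene regardless of class balance; average-precision AUPRC,
  whose null value is the pathogenic fraction; and full TPR/FPR/TNR
  threshold curves.
* **The variant-set construction rules** used in this style of analysis:
  gnomAD quality filters on the putatively benign set (inbreeding
  coefficient ≥ −0.3, depth ≥ 10, genotype quality ≥ 20, allele balance
  > 0.2, no allele-frequency filter), removal of benign records that occur
  in the pathogenic set, a ≥ 10-variants-per-class gene rule, and a ≥ 75%
  score-coverage rule per VEP.
* **Gene-level features** that predict AUROC: mean FoldX-style ΔΔG over
  benign variants (`ddg_fold`), mean VEP score over benign variants
  (`vep_gnomad_mean`), mean nearest-benign-variant Cα distance
  (`gnomad_distance`), the ESM/ΔΔG ratio median (`efx_raw`), nonsense
  constraint (`n_lof`, `exac_oe_lof`), intrinsic-disorder content from
  AlphaFold pLDDT (`plddt_disorder`, `mean_plddt`), and GO-term binaries
  selected by a Fisher-exact / Benjamini–Hochberg over-representation test
  on better- vs worse-predicted genes.
* **Random-forest meta-models** (one per VEP) that regress per-gene AUROC
  on those features, with Sobol quasi-Monte-Carlo hyperparameter search,
  repeated 80/20 hold-out cross-validation with t-distribution confidence
  intervals, and final refitting on all genes — exposed statsmodels-style
  as `AurocMetaModel` / `AurocMetaModelResults`.
* **Exact interventional Tree SHAP** attribution of the trained forests
  (implemented in this package, numba-accelerated, verified against a
  subset-enumeration oracle), plus cross-VEP average-rank aggregation.
* **The disorder-inflation diagnostic**: AUROC recomputed with variants at
  intrinsically disordered residues (pLDDT < 50) excluded, and a High/Low
  disorder-content group comparison — quantifying how easy benign variants
  in disordered regions inflate apparent VEP performance.
* **A synthetic-data generator** with known ground truth (per-gene score
  noise σ and the exact asymptotic AUROC it implies) that emulates the
  ClinVar/gnomAD/VEP-score structure, so every stage of the pipeline can
  be tested end to end without downloads.

## Worked example

```python
import pandas as pd
from vepmeta import synthetic as syn, metrics as met
from vepmeta.variant_io import apply_quality_filters, build_gene_dataset
from vepmeta.meta_model import AurocMetaModel, HyperparamSpec

ds = syn.generate_dataset(syn.SyntheticConfig(n_genes=120, length_range=(150, 400), seed=42))
path = ds.variants[ds.variants.class_label == "pathogenic"]
ben = ds.variants[ds.variants.class_label == "benign"]
ben_mis = apply_quality_filters(ben[ben.consequence == "missense"])
dataset = build_gene_dataset(path, pd.concat([ben_mis, ben[ben.consequence == "nonsense"]]),
                             ds.scores, ds.orientation)
perf = met.per_gene_performance(dataset, ds.scores, ds.genes)
print(perf.head(3)[["gene_id", "vep", "auroc", "auprc", "auroc_no_disorder"]].to_string(index=False))

feats = ds.features.loc[ds.features.index.isin(dataset.genes)]
model = AurocMetaModel.from_performance(feats, perf, "VEP01",
                                        spec=HyperparamSpec(n_trials=20, seed=7))
print(model.fit(n_repeats=20).summary())
```

```
gene_id   vep    auroc    auprc  auroc_no_disorder
   G001 VEP01 0.857143 0.940126           0.698529
   G001 VEP02 0.815873 0.912145           0.862903
   G001 VEP03 0.862934 0.910748           0.945312

AUROC meta-model: VEP01
==============================================
genes (with target):     119
features:                31
CV repeats:              20

hyperparameters:
  n_estimators       310
  max_depth          26
  max_features       0.761943934392184
  min_samples_leaf   4
  min_samples_split  5

metric         mean                  95% CI
spearman     0.6964        [0.6261, 0.7668]
r2           0.4703        [0.3964, 0.5442]
rmse         0.0572        [0.0545, 0.0599]
```

The first table gives, per (gene, VEP), the discrimination between
pathogenic and putatively benign variants over all variants (`auroc`,
`auprc`) and with disordered-residue variants excluded
(`auroc_no_disorder`) — for gene G001 and VEP01, excluding disorder drops
the AUROC from 0.86 to 0.70, i.e. much of that VEP's apparent performance
on this gene comes from easily-classified benign variants in disordered
regions.  The summary shows that a random forest on 31 gene features
predicts VEP01's per-gene AUROC with a mean held-out Spearman ρ of about
0.70 (95% CI from 20 hold-out repeats).

The full pipeline — generation/ingestion, filtering, metrics, feature
assembly with GO selection, non-redundant subset, per-VEP tuning + CV +
final fit, SHAP, disorder analyses — runs as one call:

```bash
vepmeta run --out run_dir --seed 7       # or: vepmeta.pipeline.run_all(RunConfig(...))
```

and writes TSV artefacts plus a `manifest.json` with the configuration,
seed and SHA-256 of every output (bit-for-bit reproducible for a fixed
seed).

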