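# Methods

## Problem setting

A variant effect predictor (VEP) assigns each missense variant a score;
given a gene's known pathogenic variants and the putatively benign missense
variants observed in the population, the per-gene AUROC is the probability
that a randomly chosen pathogenic variant outscores a randomly chosen
benign one.  The package quantifies this per (gene, VEP), models it as a
function of gene-level properties, and diagnoses a specific artefact:
benign variants in intrinsically disordered regions are easy negatives and
inflate the per-gene AUROC.

## Metrics

**AUROC** is computed by the rank-sum (Mann–Whitney) formulation with
midrank tie handling: `U / (n_p · n_b)` with `U = R_p − n_p(n_p+1)/2`,
where `R_p` is the pathogenic rank sum over the pooled scores.  Midranks
are the convention consistent with the Mann–Whitney statistic; the choice
matters only for tied scores.  The implementation is invariant under
strictly increasing score transforms and satisfies the label-swap
complement `AUROC + AUROC_swapped = 1`; both are asserted as property
tests, and equality with an exhaustive pairwise-counting oracle is checked
to 1e−12.

**AUPRC** is average precision (no interpolation): the sum over positives
of precision at each recall step.  Tied scores are processed as blocks at
a single threshold, so the value does not depend on the ordering of equal
scores.  Its null value is the pathogenic fraction, which is why it is
reported but not used for cross-gene comparison.

**Threshold curves** contain one operating point per distinct score (rule:
call pathogenic when score ≥ t) plus a +∞ sentinel for the (0, 0) corner;
the minimum score already yields (1, 1), so a −∞ sentinel would duplicate
a point.  The trapezoidal area under (FPR, TPR) equals the rank-sum AUROC
exactly, which is asserted on random instances.

**Undefined metrics** (an empty class after pairwise score deletion or
disorder exclusion) propagate as missing values, never as zeros, so group
means are not silently biased.

**Disorder definitions.**  A residue is disordered when its pLDDT is below
50 on the 0–100 scale; this single constant is shared by every module.
The disorder-excluded AUROC simply drops variants at disordered residues.
The High/Low group split assigns a gene to High when its percentage of
disordered residues strictly exceeds the median over the analysed gene
set; ties go to Low.

## Dataset construction rules

Benign-set quality filters (applied only to the putatively benign class):
retain iff inbreeding coefficient ≥ −0.3 AND maximum sample depth ≥ 10 AND
genotype quality ≥ 20 AND allele balance > 0.2.  A record missing a QC
field fails that filter (conservative choice; the alternative of passing
missing values through would silently admit unfiltered data).  Allele
frequency is carried but never filtered on.  Benign records whose
protein-level key (gene, residue, ref, alt) appears in the pathogenic set
are removed.  Genes need ≥ 10 missense variants in each class; VEPs need
scores for ≥ 75% of the retained genes' missense variants.  All three
thresholds are configuration values with those defaults.

## Gene features

* `ddg_fold` — arithmetic mean ΔΔG (kcal/mol) over the gene's benign
  missense variants; `vep_gnomad_mean` — same aggregation over the target
  VEP's raw scores (computed per meta-model target).
* `gnomad_distance` — mean over all residues of the minimum Cα–Cα distance
  to any benign-variant-bearing residue (variant residues contribute 0).
  This concretises a variant-density numerator: the exact published form
  of the clustering metric it derives from is not restated here, and the
  kernel is deliberately isolated so it can be swapped.  It is
  non-increasing under variant addition (property-tested).
* `efx_raw` — median of VEP-score/ΔΔG over the full length × 19
  substitution matrix, excluding |ΔΔG| < 1e−6 (a division guard; the
  quantity is otherwise unstable at the near-zero ΔΔG values typical of
  disordered residues).
* `n_lof` — distinct nonsense variants per residue; `exac_oe_lof` —
  observed/expected nonsense count with the expected count supplied by the
  caller (it is an external constraint estimate, never recomputed).
* `plddt_disorder` (percentage of residues with pLDDT < 50) and
  `mean_plddt`.
* `s_het`, `p_lof` and similar constraint/mechanism scores are passthrough
  inputs; their defining models live elsewhere.

**GO selection.**  Genes are split at the median of per-gene mean AUROC
across VEPs (strictly greater = better-predicted; ties to worse, since
"greater than the median" defines the better group and the complement
takes the rest).  Each GO term is tested with a two-sided Fisher exact
test on the better/worse × has/lacks 2×2 table; p-values are adjusted by
Benjamini–Hochberg (the standard step-up FDR procedure), and a term is
converted to a 0/1 column iff adjusted p < 0.05 *and* the term is more
frequent among better-predicted genes (over-representation, not mere
association).  Fisher p-values are verified against hypergeometric
enumeration for all tables with margins ≤ 12; BH against a hand step-up
oracle.

**Assembly.**  Components are joined on gene id; missing numeric values
are imputed by the column median with an explicit imputation mask emitted;
binary columns are never imputed (absent annotation = 0).

## Non-redundant gene set

To prevent a model being evaluated on homologues of its training genes,
the gene set is reduced so no retained pair exceeds 30% sequence identity
(strictly greater is redundant).  Removal is greedy hub removal — drop the
gene with the most above-threshold neighbours, ties broken by shorter
protein then lexicographic id — followed by a re-add pass that restores
any removed gene with no remaining conflict, making the result maximal.
Greedy was chosen over exact maximum-independent-set because it is
deterministic, near-optimal (within 2 of the exhaustive optimum on random
12-gene fixtures, tested), and the threshold itself is heuristic.  Percent
identity for small sets is matches/alignment-length from global alignment
(match 1, mismatch 0, gap open −2, extend −0.5); for large sets an
ungapped positional screen is provided, or a precomputed matrix can be
supplied.

## Meta-models

One random-forest regression per VEP: response = per-gene AUROC on the
non-redundant set, design = the gene feature table.  Genes with an
undefined AUROC for a VEP are excluded from that VEP's model only, but
still receive final predictions.

* **Tuning**: Sobol (scrambled) quasi-Monte-Carlo sampling of
  (n_estimators ∈ [100, 500], max_depth ∈ [2, 32], max_features ∈
  [0.1, 1.0], min_samples_leaf ∈ [1, 20], min_samples_split ∈ [2, 20]),
  300 trials by default; each trial is scored by 5-fold cross-validated
  RMSE on the training genes and the minimiser wins.  The 5-fold inner
  estimate was chosen because a single validation split is too noisy at a
  few hundred genes.  The n_estimators ceiling of 500 is the package
  default for desk-scale gene sets; forests of this size are already
  variance-saturated at n ≤ 1000 genes.
* **Evaluation**: repeated hold-out cross-validation — n_repeats (default
  100) independent 80/20 shuffle splits, reporting Spearman ρ, R²
  (1 − SSE/SST) and RMSE on each held-out fifth, with mean and 95%
  t-distribution confidence intervals (mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n).  A
  repeat with constant held-out targets has undefined ρ, recorded as
  missing.  Repeated hold-out (rather than one k-fold pass) gives a
  smoother estimate at small n and is what the CI formula assumes.
* **Final fit**: refit on all genes with targets; predictions clipped to
  [0, 1] and emitted for every gene in the feature table.
* **Seeding**: a single master seed fans out via `numpy.random.SeedSequence`
  (per stage, per trial, per repeat); the whole tune → CV → fit pipeline is
  bit-for-bit reproducible, which is asserted in the tests.

## SHAP attribution

Attributions use exact interventional Tree SHAP, implemented in this
package.  For one background sample z, the payoff of a coalition S is the
model output with features in S taken from the explained gene and the rest
from z.  Restricted to one tree leaf this payoff is a conjunction of
literals (the leaf is reached iff each diverging path feature lies on the
required side), and the Shapley value of a conjunction has the closed form
φᵢ = ±v·a!b!/(a+b)!-type weights with a = |x-side features| and
b = |z-side features|.  Summing over leaves and averaging over a
background set (default: the training table, subsampled to 200 rows,
seeded) and trees gives the exact interventional values; additivity
(Σφᵢ + E_z f(z) = f(x)) holds to float precision and is asserted, as is
agreement with a brute-force subset-enumeration Shapley oracle on small
forests.  Per-VEP features are ranked by mean |SHAP|; cross-VEP importance
is the average rank; a feature's direction is the sign of the correlation
between its value and its signed attribution, and the cross-VEP direction
consensus is the sign of the mean per-VEP direction.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with ground
truth for recovery tests.  Defaults (the package's study conditions): 300
genes of 200–800 residues; disorder fraction uniform in [0.02, 0.45] laid
out as 1–4 contiguous tracts; pLDDT bimodal (ordered mode N(90, 5),
disordered N(35, 8), clipped to respect the pLDDT-50 boundary so the
generated disorder fraction is exact); conservation N(0.8, 0.1) in ordered
and N(0.2, 0.1) in disordered tracts; Cα positions a 3.8 Å-stepped random
walk with excluded volume (sufficient for distance features; no folded
topology is attempted).  Per gene, 10–100 pathogenic and 10–100 benign
missense variants: pathogenic sites fall in ordered residues with
probability 0.9, benign in disordered residues with probability 0.7
(placement falls back to the other tract type when the requested one is
absent, except that a probability of exactly 0 or 1 is a hard constraint
and raises).  A pathogenic site inside a disordered tract is treated as a
conserved functional motif: its conservation is redrawn from the ordered
mode.  This reflects how disease mutations in disordered regions
concentrate in conserved motifs and gives the observed phenomenology that
excluding disordered variants leaves the true-positive rate essentially
unchanged while lowering the true-negative rate — i.e. inflation is driven
by easy benign negatives.  5% of benign variants fail one random QC filter
to exercise the filtering stage.

Pseudo-VEP scores: `a_v·conservation + b_v·1[pathogenic] + ε`,
ε ~ N(0, σ_gene), with a = 2.0 and b = 1.0 (±10% per-VEP jitter) so that
the conservation and label signals are comparable and all VEPs share the
conservation signal (making their per-gene AUROC vectors positively
correlated).  Every third VEP is emitted negated with a higher-is-benign
flag; 8% of scores per VEP are missing.  The per-gene noise scale is
σ_gene = clip(softplus(β₀ + Σ cⱼ zⱼ), 0.15, 1.2) over standardized causal
feature values — by default s_het (−0.9), plddt_disorder (−0.7),
exac_oe_lof (+0.9) and expression_level (−0.6), signs chosen so that
constrained, high-disorder, highly-expressed genes are better predicted.
The asymptotic per-gene AUROC implied by σ_gene is computed analytically
as a placement-weighted mixture of Gaussian comparisons
Φ((a·Δμ + b)/√(a²(v_p+v_b) + 2σ²)) and stored as ground truth; it matches
the empirical AUROC within ±0.05 at 200 variants per class.  The truth is
exact in the sparse-variant regime; at very high variant density
(hundreds of variants on short genes) benign variants start colliding with
redrawn motif residues and the approximation degrades slightly.

ΔΔG substitution matrices are Gamma(2, ~1.2)-distributed in ordered tracts
and N(0, 0.1) in disordered ones (disordered residues lack contacts, so
mutations barely destabilise).  Nonsense counts are Poisson with mean
0.02·length·mutability·oe, where the per-gene mutability (uniform
[0.6, 1.4]) decouples `n_lof` from `exac_oe_lof`.  GO annotations include
two terms whose membership probability rises as σ_gene falls, so the
over-representation selection has true signal, plus random terms.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mutational spectra and codon structure, allele
frequencies, realistic fold topology, correlated features beyond the
designed causal structure, inheritance-mode differences, and any form of
training-set circularity between VEP scores and the pathogenic labels.
Results on synthetic data validate the machinery (estimators, filters,
protocol), not biological conclusions.

## Problem sizes in the test suite

The acceptance-level tests run the package at: 500 simulated genes for the
metric null; 300 default-condition genes for the disorder-inflation
checks; 600 genes, 50 tuning trials and 25 hold-out repeats for the
meta-model recovery check (hyperparameters are tuned once on the first
pseudo-VEP and shared across the per-VEP models whose SHAP ranks are
aggregated — tuning precedes evaluation, and per-VEP retuning adds nothing
to a recovery check).  These sizes make the whole suite a desk-scale run
while keeping every estimate comfortably inside its assertion band.

## Known limitations

* The identity screen for large gene sets is ungapped and underestimates
  identity for shifted homologues; supply a precomputed matrix from a real
  aligner for serious use.
* The interventional SHAP cost scales with foreground × background ×
  total leaves; the default 200-row background subsample is a bias-free
  estimator of the full-background value but adds sampling noise for very
  small attribution magnitudes.
* `efx_raw`'s division guard (1e−6 kcal/mol) is arbitrary below the scale
  of any meaningful ΔΔG; values between the guard and ~0.1 still produce
  heavy-tailed ratios, which is why the median (not the mean) is used.
* Real-data mode expects inputs already reduced to protein-level TSVs (or
  VCF with protein-level INFO keys); no transcript mapping or liftover is
  performed.
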