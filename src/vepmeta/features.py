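"""Gene-level features used to explain and predict per-gene VEP performance.

Each feature summarises one gene, most of them from the putatively benign
(population) variants observed in it:

``ddg_fold``
    mean predicted stability change (ΔΔG, kcal/mol) over benign missense
    variants — genes whose population variants are structurally mild tend to
    be easier to score.
``vep_gnomad_mean``
    mean raw score of the target VEP over the same benign variants.
``gnomad_distance``
    mean over all residues of the minimum Cα-Cα distance to any
    benign-variant-bearing residue (Å); high values mean a sparse variant
    coverage of the structure (the numerator of the extent-of-disease-
    clustering statistic, applied to population variants).
``efx_raw``
    median ratio of an ESM-like VEP score to ΔΔG over the full
    length × 19 substitution matrix.
``n_lof`` / ``exac_oe_lof``
    distinct nonsense variants per residue, and observed/expected
    loss-of-function ratio (expected counts are supplied, never recomputed).
``plddt_disorder`` / ``mean_plddt``
    percentage of residues with pLDDT < 50 and the mean pLDDT.

GO terms are reduced to binary columns by a local over-representation test:
genes are split at the median of their mean AUROC across VEPs, each term is
tested with a two-sided Fisher exact test on the better/worse × has/lacks
table, p-values are Benjamini-Hochberg adjusted, and a term is kept when the
adjusted p is below the FDR threshold *and* the term is more frequent among
better-predicted genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: Features computed here for every gene (plus passthrough columns).
NAMED_FEATURES = (
    "ddg_fold",
    "vep_gnomad_mean",
    "gnomad_distance",
    "efx_raw",
    "n_lof",
    "exac_oe_lof",
    "plddt_disorder",
    "mean_plddt",
)

#: Guard against near-zero ΔΔG denominators in efx_raw.
DDG_RATIO_GUARD = 1e-6


def ddg_fold(benign_ddg) -> float:
    """Mean ΔΔG (kcal/mol) over a gene's benign missense variants.

    ``benign_ddg`` is the sequence of ΔΔG values looked up for each benign
    variant; entries that could not be looked up should be NaN and are
    skipped (logged).  Returns NaN when no value is available.
    """
    vals = np.asarray(list(benign_ddg), dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.debug("ddg_fold: skipping %d variants without ΔΔG", n_missing)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def vep_gnomad_mean(benign_scores) -> float:
    """Mean raw VEP score over a gene's benign missense variants (NaN-safe)."""
    return ddg_fold(benign_scores)  # same aggregation kernel


def gnomad_distance(ca_coords, benign_residues) -> float:
    """Mean nearest benign-variant Cα distance over all residues (Å).

    Residues carrying a benign variant contribute 0; sparse variant coverage
    yields large values.  Returns NaN when no coordinates or no variant
    residues are available.
    """
    coords = np.asarray(ca_coords, dtype=float)
    residues = np.unique(np.asarray(list(benign_residues), dtype=int))
    if coords.size == 0 or residues.size == 0:
        return float("nan")
    variant_xyz = coords[residues - 1]
    tree = cKDTree(variant_xyz)
    dmin, _ = tree.query(coords, k=1)
    return float(np.mean(dmin))


def efx_raw(vep_matrix, ddg_matrix, guard: float = DDG_RATIO_GUARD) -> float:
    """Median score/ΔΔG ratio over the full substitution matrix.

    Substitutions with ``|ΔΔG| < guard`` are excluded to avoid unstable
    ratios; NaN entries in either matrix are skipped.  Returns NaN when
    everything is excluded.
    """
    v = np.asarray(vep_matrix, dtype=float)
    d = np.asarray(ddg_matrix, dtype=float)
    if v.shape != d.shape:
        raise SchemaError(f"substitution matrices differ in shape: {v.shape} vs {d.shape}")
    mask = (np.abs(d) >= guard) & ~np.isnan(v) & ~np.isnan(d)
    if not mask.any():
        return float("nan")
    return float(np.median(v[mask] / d[mask]))


def lof_features(nonsense_residues, expected_lof: float, length: int) -> tuple[float, float]:
    """``(n_lof, exac_oe_lof)`` from observed nonsense variants.

    ``n_lof`` is the number of *distinct* nonsense variants divided by the
    protein length; ``exac_oe_lof`` is observed/expected with the expected
    count supplied by the caller (it is an external constraint estimate and
    is never recomputed here).
    """
    if length < 1:
        raise SchemaError("protein length must be >= 1")
    observed = len(set(nonsense_residues))
    n_lof = observed / length
    if expected_lof is None or expected_lof <= 0:
        return float(n_lof), float("nan")
    return float(n_lof), float(observed / expected_lof)


def plddt_features(plddt, cutoff: float = 50.0) -> tuple[float, float]:
    """``(plddt_disorder, mean_plddt)`` from a per-residue pLDDT array.

    ``plddt_disorder`` is the percentage (0-100) of residues with pLDDT
    below the cutoff.
    """
    arr = np.asarray(plddt, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(100.0 * (arr < cutoff).mean()), float(arr.mean())


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's 2x2 over-representation test.

    ``a``/``b`` count better-predicted genes with/without the term,
    ``c``/``d`` the worse-predicted genes with/without it.
    """

    go_term: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    fdr_adjusted_p: float
    selected: bool

    @property
    def better_proportion(self) -> float:
        return self.a / (self.a + self.b) if (self.a + self.b) else float("nan")

    @property
    def worse_proportion(self) -> float:
        return self.c / (self.c + self.d) if (self.c + self.d) else float("nan")


def go_feature_selection(
    mean_auroc: pd.Series,
    go_annotations: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Select GO terms over-represented in better-predicted genes.

    Parameters
    ----------
    mean_auroc
        Per-gene mean AUROC across all VEPs (index: gene_id).
    go_annotations
        Long table with columns ``gene_id`` and ``go_term``.
    fdr
        Benjamini-Hochberg threshold on the adjusted p-values.

    Genes with mean AUROC strictly above the median are "better-predicted";
    ties go to the worse group.  Terms annotated to none of the genes are
    skipped.  Returns the per-term results and a gene × selected-term 0/1
    frame (absent annotation = 0, never imputed).
    """
    genes = mean_auroc.index
    median = float(mean_auroc.median())
    better = mean_auroc > median
    ann = go_annotations[go_annotations["gene_id"].isin(genes)]
    term_genes = {t: set(g) for t, g in ann.groupby("go_term")["gene_id"]}

    records = []
    for term, members in sorted(term_genes.items()):
        if not members:
            continue
        has = genes.isin(members)
        a = int((better & has).sum())
        b = int((better & ~has).sum())
        c = int((~better & has).sum())
        d = int((~better & ~has).sum())
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        records.append((term, a, b, c, d, float(p)))
    if not records:
        return [], pd.DataFrame(index=genes)

    pvals = np.array([r[5] for r in records])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (term, a, b, c, d, p), q in zip(records, p_adj):
        prop_better = a / (a + b) if (a + b) else 0.0
        prop_worse = c / (c + d) if (c + d) else 0.0
        selected = bool(q < fdr and prop_better > prop_worse)
        results.append(EnrichmentResult(term, a, b, c, d, p, float(q), selected))

    columns = {}
    for res in results:
        if res.selected:
            columns[f"GO_{res.go_term}"] = genes.isin(term_genes[res.go_term]).astype(int)
    binary = pd.DataFrame(columns, index=genes)
    return results, binary


def assemble_feature_table(
    components: dict[str, pd.Series | pd.DataFrame],
    imputation_policy: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-gene feature components into a single table.

    ``components`` maps a component name to a Series (one feature) or a
    DataFrame (several), all indexed by gene.  Missing numeric values are
    imputed with the column median (the default policy); binary 0/1 columns
    are never imputed — an absent annotation simply stays 0.  The returned
    mask frame marks exactly the cells that were imputed.

    Raises
    ------
    SchemaError
        On duplicate feature names across components, or conflicting values.
    """
    if imputation_policy not in ("median", "none"):
        raise SchemaError(f"unknown imputation policy {imputation_policy!r}")
    frames = []
    seen: set[str] = set()
    for name, comp in components.items():
        frame = comp.to_frame() if isinstance(comp, pd.Series) else comp.copy()
        dup = seen.intersection(frame.columns)
        if dup:
            raise SchemaError(f"duplicate feature name(s) {sorted(dup)} in component {name!r}")
        seen.update(frame.columns)
        frames.append(frame)
    table = pd.concat(frames, axis=1, join="outer").sort_index()
    table.index.name = "gene_id"

    is_binary = {
        c: set(pd.unique(table[c].dropna())).issubset({0, 1, 0.0, 1.0, True, False})
        and table[c].dropna().size > 0
        for c in table.columns
    }
    mask = table.isna()
    if imputation_policy == "median":
        for col in table.columns:
            if is_binary[col]:
                table[col] = table[col].fillna(0).astype(int)
                mask[col] = False  # absent binary annotation is a true 0
            elif table[col].isna().any():
                med = table[col].median()
                table[col] = table[col].fillna(med)
    return table, mask
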