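"""Per-gene discrimination metrics for variant effect predictors.

The central quantity is the per-gene AUROC: the probability that a randomly
chosen pathogenic variant receives a higher predictor score than a randomly
chosen putatively benign variant.  It is computed with the rank-sum
(Mann-Whitney) formulation with midrank tie handling, which makes it
invariant under any strictly increasing transform of the scores and gives a
null value of exactly 0.5 for label-independent scores regardless of class
balance.  AUPRC (average precision) is reported alongside; its null value is
the pathogenic fraction, which is why it is not comparable across genes.

The module also implements the two disorder-stratified diagnostics: AUROC
recomputed with variants at intrinsically disordered residues (pLDDT below
50) excluded, and the High/Low disorder-content group comparison over genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import PLDDT_DISORDER_CUTOFF
from .errors import ConfigurationError, UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "auroc",
    "auprc",
    "threshold_curves",
    "ThresholdCurve",
    "DisorderSplit",
    "per_gene_performance",
    "disorder_group_comparison",
    "auroc_correlation_matrix",
]


def _as_scores(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise UndefinedMetricError(f"{name} score set is empty; metric undefined")
    if np.isnan(arr).any():
        raise UndefinedMetricError(f"{name} score set contains NaN")
    return arr


def auroc(pathogenic_scores, benign_scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank-sum statistic.

    Equals ``(#{(p, b): p > b} + 0.5 * #{(p, b): p == b}) / (n_p * n_b)``
    over all pathogenic/benign score pairs; ties contribute half via
    midranks.  Scores must be oriented so that higher means more pathogenic.

    Raises
    ------
    UndefinedMetricError
        If either class is empty (the metric has no value; callers that
        tabulate many genes convert this to an explicit missing value).
    """
    p = _as_scores(pathogenic_scores, "pathogenic")
    b = _as_scores(benign_scores, "benign")
    ranks = rankdata(np.concatenate([p, b]), method="average")
    rank_sum_p = ranks[: p.size].sum()
    u = rank_sum_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def auprc(pathogenic_scores, benign_scores) -> float:
    """Area under the precision-recall curve as average precision.

    Sum over the pathogenic (positive) class of precision at each recall
    step, with no interpolation between points.  Tied scores are treated as
    a single threshold block, so the result does not depend on the ordering
    of equal scores.
    """
    p = _as_scores(pathogenic_scores, "pathogenic")
    b = _as_scores(benign_scores, "benign")
    scores = np.concatenate([p, b])
    labels = np.concatenate([np.ones(p.size, dtype=int), np.zeros(b.size, dtype=int)])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    # block boundaries: one threshold per distinct score value
    _, starts = np.unique(-scores, return_index=True)
    block_ends = np.append(starts[1:], scores.size)
    tp = fp = 0
    ap = 0.0
    n_pos = p.size
    for s, e in zip(starts, block_ends):
        block_tp = int(labels[s:e].sum())
        block_fp = (e - s) - block_tp
        if block_tp:
            # average precision over the block: precision varies linearly in
            # the expected ranking of tied positives; use the block-level
            # step convention (precision at the end of the block).
            tp += block_tp
            fp += block_fp
            ap += block_tp * tp / (tp + fp)
        else:
            fp += block_fp
    return float(ap / n_pos)


@dataclass(frozen=True)
class ThresholdCurve:
    """ROC operating points: one per distinct score plus a +inf sentinel.

    ``tpr`` is sensitivity, ``fpr`` the false-positive rate and
    ``tnr = 1 - fpr`` the specificity, each evaluated with the decision rule
    "call pathogenic when score >= threshold" (higher is pathogenic).  The
    +inf sentinel gives the (0, 0) corner; the minimum score itself already
    gives (1, 1), so no second sentinel is needed.  Points are ordered by
    descending threshold, i.e. from (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tnr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tnr", 1.0 - self.fpr)

    def area(self) -> float:
        """Trapezoidal area under (fpr, tpr); equals :func:`auroc`."""
        return float(np.trapezoid(self.tpr, self.fpr))


def threshold_curves(pathogenic_scores, benign_scores) -> ThresholdCurve:
    """Full TPR/FPR/TNR trade-off across all classification thresholds."""
    p = _as_scores(pathogenic_scores, "pathogenic")
    b = _as_scores(benign_scores, "benign")
    cuts = np.unique(np.concatenate([p, b]))  # ascending
    thresholds = np.concatenate([cuts, [np.inf]])[::-1]  # descending
    # at threshold t: predicted pathogenic iff score >= t
    tpr = np.array([(p >= t).mean() for t in thresholds])
    fpr = np.array([(b >= t).mean() for t in thresholds])
    return ThresholdCurve(thresholds, tpr, fpr)


@dataclass(frozen=True)
class DisorderSplit:
    """High/Low split of genes by intrinsically disordered content.

    A gene is "High" when its percentage of residues with pLDDT below the
    cutoff strictly exceeds the median over the gene set; ties go to "Low".
    """

    cutoff_plddt: float
    median_disorder_pct: float
    groups: pd.Series  # gene_id -> "High" | "Low"


def _oriented(scores: np.ndarray, higher_is_pathogenic: bool) -> np.ndarray:
    return scores if higher_is_pathogenic else -scores


def per_gene_performance(
    dataset,
    scores: pd.DataFrame,
    annotations: dict,
    orientation: dict[str, bool] | None = None,
    plddt_cutoff: float = PLDDT_DISORDER_CUTOFF,
) -> pd.DataFrame:
    """Per (gene, VEP) AUROC/AUPRC table, with disorder-excluded AUROC.

    Parameters
    ----------
    dataset
        A :class:`~vepmeta.variant_io.GeneDataset` (or anything exposing
        ``variants`` — a missense-variant frame with columns ``gene_id``,
        ``residue_index``, ``alt_aa``, ``class_label`` — plus ``genes`` and
        ``veps`` lists).
    scores
        Long-format score table with columns
        ``gene_id, residue_index, alt_aa, vep, score``.
    annotations
        Mapping ``gene_id ->`` object with a ``plddt`` array (1-based
        residue indexing maps to position 0 of the array).
    orientation
        ``vep -> higher_is_pathogenic``.  Defaults to ``dataset.orientation``.

    Variants lacking a VEP's score are dropped pairwise for that VEP.  A
    metric with an empty class is reported as missing (NaN), never zero.
    """
    if orientation is None:
        orientation = getattr(dataset, "orientation", None)
    if orientation is None:
        raise ConfigurationError("orientation metadata is required")
    for vep in dataset.veps:
        if vep not in orientation:
            raise ConfigurationError(f"no orientation declared for VEP {vep!r}")

    variants = dataset.variants
    variants = variants[variants["consequence"] == "missense"]
    merged = variants.merge(
        scores[scores["vep"].isin(dataset.veps)],
        on=["gene_id", "residue_index", "alt_aa"],
        how="inner",
    )
    rows = []
    n_undefined = 0
    for (gene, vep), grp in merged.groupby(["gene_id", "vep"], sort=True):
        s = _oriented(grp["score"].to_numpy(float), orientation[vep])
        is_path = (grp["class_label"] == "pathogenic").to_numpy()
        p, b = s[is_path], s[~is_path]
        ann = annotations.get(gene)
        if ann is not None:
            plddt = np.asarray(ann.plddt, dtype=float)
            disordered = plddt[grp["residue_index"].to_numpy(int) - 1] < plddt_cutoff
        else:
            disordered = np.zeros(len(grp), dtype=bool)
        row = {
            "gene_id": gene,
            "vep": vep,
            "n_pathogenic": int(is_path.sum()),
            "n_benign": int((~is_path).sum()),
            "n_excluded_disordered": int(disordered.sum()),
        }
        try:
            row["auroc"] = auroc(p, b)
            row["auprc"] = auprc(p, b)
        except UndefinedMetricError:
            row["auroc"] = np.nan
            row["auprc"] = np.nan
            n_undefined += 1
        keep = ~disordered
        p2, b2 = s[is_path & keep], s[~is_path & keep]
        row["n_pathogenic_no_disorder"] = int(p2.size)
        row["n_benign_no_disorder"] = int(b2.size)
        try:
            row["auroc_no_disorder"] = auroc(p2, b2)
        except UndefinedMetricError:
            row["auroc_no_disorder"] = np.nan
        rows.append(row)
    if n_undefined:
        logger.info("per_gene_performance: %d undefined (gene, VEP) metrics", n_undefined)
    cols = [
        "gene_id", "vep", "auroc", "auprc", "n_pathogenic", "n_benign",
        "auroc_no_disorder", "n_pathogenic_no_disorder",
        "n_benign_no_disorder", "n_excluded_disordered",
    ]
    return pd.DataFrame(rows, columns=cols)


def disorder_percentage(annotations: dict, plddt_cutoff: float = PLDDT_DISORDER_CUTOFF) -> pd.Series:
    """Percentage (0-100) of residues with pLDDT below the cutoff, per gene."""
    out = {
        g: 100.0 * float((np.asarray(a.plddt, dtype=float) < plddt_cutoff).mean())
        for g, a in annotations.items()
    }
    return pd.Series(out, name="disorder_pct").sort_index()


def disorder_group_comparison(
    performances: pd.DataFrame,
    annotations: dict,
    plddt_cutoff: float = PLDDT_DISORDER_CUTOFF,
) -> tuple[pd.DataFrame, DisorderSplit]:
    """Compare per-VEP AUROC between High- and Low-disorder gene groups.

    Genes are split at the median disorder percentage over the analysed gene
    set (strictly greater -> High).  Returns a per-VEP summary with group
    means/medians and the High - Low mean difference, sorted by that
    difference in descending order, together with the split itself.
    """
    genes = performances["gene_id"].unique()
    if len(genes) < 2:
        raise ConfigurationError("need at least 2 genes for a disorder split")
    pct = disorder_percentage({g: annotations[g] for g in genes}, plddt_cutoff)
    median = float(pct.median())
    groups = pd.Series(np.where(pct > median, "High", "Low"), index=pct.index, name="group")
    if (groups == "High").sum() == 0:
        logger.warning("disorder_group_comparison: High group is empty (all genes at/below median)")
    split = DisorderSplit(cutoff_plddt=plddt_cutoff, median_disorder_pct=median, groups=groups)

    perf = performances.merge(groups.rename("group"), left_on="gene_id", right_index=True)
    summary = (
        perf.groupby(["vep", "group"])["auroc"]
        .agg(["mean", "median", "count"])
        .unstack("group")
    )
    for grp in ("High", "Low"):
        if ("mean", grp) not in summary.columns:
            summary[("mean", grp)] = np.nan
            summary[("median", grp)] = np.nan
            summary[("count", grp)] = 0
    out = pd.DataFrame(
        {
            "mean_auroc_high": summary[("mean", "High")],
            "mean_auroc_low": summary[("mean", "Low")],
            "median_auroc_high": summary[("median", "High")],
            "median_auroc_low": summary[("median", "Low")],
            "n_high": summary[("count", "High")].astype(int),
            "n_low": summary[("count", "Low")].astype(int),
        }
    )
    out["mean_difference"] = out["mean_auroc_high"] - out["mean_auroc_low"]
    out["median_difference"] = out["median_auroc_high"] - out["median_auroc_low"]
    out = out.sort_values("mean_difference", ascending=False)
    return out, split


def auroc_correlation_matrix(performances: pd.DataFrame, min_genes: int = 3) -> pd.DataFrame:
    """Pearson correlation of per-gene AUROC vectors between VEP pairs.

    Computed over pairwise-complete genes; the diagonal is exactly 1.  A VEP
    whose AUROC vector has zero variance yields NaN off-diagonal entries,
    which are left in place (flagged via log) rather than filled.
    """
    wide = performances.pivot(index="gene_id", columns="vep", values="auroc")
    corr = wide.corr(method="pearson", min_periods=min_genes)
    np.fill_diagonal(corr.values, 1.0)
    degenerate = wide.std(ddof=0) == 0
    if degenerate.any():
        logger.warning(
            "auroc_correlation_matrix: zero-variance AUROC for %s",
            list(wide.columns[degenerate]),
        )
        for vep in wide.columns[degenerate]:
            corr.loc[vep, corr.columns != vep] = np.nan
            corr.loc[corr.index != vep, vep] = np.nan
    return corr
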