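"""Reading, quality-filtering and assembling the per-gene variant dataset.

Variants are identified at the protein level by the key
``(gene_id, residue_index, ref_aa, alt_aa)``, which makes overlap removal
between the pathogenic (ClinVar-style) and putatively benign (gnomAD-style)
sets unambiguous across transcripts.  TSV is the canonical interchange
format; VCF ingestion maps INFO fields through a user-supplied key map.

The gnomAD-style quality filters apply only to the putatively benign set:
a record is retained iff inbreeding coefficient >= -0.3, at least one
sample with depth >= 10, genotype quality >= 20 and minor allele balance
> 0.2.  A record missing a QC field is treated as failing that filter.  No
allele-frequency filter is ever applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneDataset",
    "REQUIRED_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "write_vcf",
    "read_scores",
    "apply_quality_filters",
    "build_gene_dataset",
]

REQUIRED_COLUMNS = ("gene_id", "residue_index", "ref_aa", "alt_aa", "consequence", "class_label")
QC_COLUMNS = ("inbreeding_coeff", "max_sample_depth", "genotype_quality", "allele_balance")
OPTIONAL_COLUMNS = QC_COLUMNS + ("allele_frequency",)
KNOWN_CONSEQUENCES = ("missense", "nonsense")

#: Default VCF INFO key -> column mapping.
DEFAULT_VCF_INFO_MAP = {
    "GENE": "gene_id",
    "AA_POS": "residue_index",
    "REF_AA": "ref_aa",
    "ALT_AA": "alt_aa",
    "CSQ_TYPE": "consequence",
    "CLASS": "class_label",
    "IC": "inbreeding_coeff",
    "DP_MAX": "max_sample_depth",
    "GQ": "genotype_quality",
    "AB": "allele_balance",
    "AF": "allele_frequency",
}


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level missense or nonsense variant."""

    gene_id: str
    residue_index: int
    ref_aa: str
    alt_aa: str
    consequence: str  # "missense" | "nonsense"
    class_label: str  # "pathogenic" | "benign"
    inbreeding_coeff: float | None = None
    max_sample_depth: float | None = None
    genotype_quality: float | None = None
    allele_balance: float | None = None
    allele_frequency: float | None = None  # informational; never filtered on

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValidationError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.consequence == "missense" and self.ref_aa == self.alt_aa:
            raise ValidationError("missense variant with ref_aa == alt_aa")
        if self.consequence == "nonsense" and self.alt_aa != "*":
            raise ValidationError("nonsense variant must have alt_aa '*'")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.residue_index, self.ref_aa, self.alt_aa)


def _validate_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing mandatory column(s) {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    unknown = ~df["consequence"].isin(KNOWN_CONSEQUENCES)
    if unknown.any():
        logger.info("%s: skipping %d rows with unknown consequence", source, int(unknown.sum()))
        df = df[~unknown]
    df = df.copy()
    try:
        df["residue_index"] = df["residue_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{source}: non-integer residue_index ({exc})") from exc
    if (df["residue_index"] < 1).any():
        bad = df.index[df["residue_index"] < 1][0]
        raise ParseError(f"{source}: residue_index < 1 at row {bad}")
    return df.reset_index(drop=True)


def read_variant_table(path: str | Path, format: str = "tsv",
                       info_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a variant table from TSV or VCF into the canonical frame.

    Rows with consequences other than missense/nonsense are skipped with a
    logged count; a malformed row raises :class:`ParseError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        except pd.errors.ParserError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        return _validate_frame(df, str(path))
    if format == "vcf":
        return _read_vcf(path, info_map or DEFAULT_VCF_INFO_MAP)
    raise SchemaError(f"unknown format {format!r}; expected 'tsv' or 'vcf'")


def _read_vcf(path: Path, info_map: dict[str, str]) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    for i, rec in enumerate(VCF(str(path))):
        row = {}
        for key, col in info_map.items():
            val = rec.INFO.get(key)
            row[col] = val
        for col in REQUIRED_COLUMNS:
            if row.get(col) is None:
                raise ParseError(f"{path}: record {i + 1} missing INFO field for {col!r}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(info_map.values()))
    if df.empty:
        df = pd.DataFrame(columns=list(info_map.values()))
    return _validate_frame(df, str(path))


def write_variant_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")
    return path


def write_vcf(df: pd.DataFrame, path: str | Path) -> Path:
    """Write variants as a minimal VCF 4.2 with protein-level INFO fields.

    Genomic coordinates are placeholders (a synthetic contig with the
    residue index as position); the protein-level key lives in INFO.
    """
    path = Path(path)
    inv = {v: k for k, v in DEFAULT_VCF_INFO_MAP.items()}
    float_keys = {"inbreeding_coeff", "genotype_quality", "allele_balance", "allele_frequency"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=synthetic>\n')
        for col, key in inv.items():
            if col in ("residue_index", "max_sample_depth"):
                typ, num = "Integer", "1"
            elif col in float_keys:
                typ, num = "Float", "1"
            else:
                typ, num = "String", "1"
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{col}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in df.iterrows():
            info = []
            for col, key in inv.items():
                val = row.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    continue
                if col in ("residue_index", "max_sample_depth"):
                    info.append(f"{key}={int(val)}")
                elif col in float_keys:
                    info.append(f"{key}={float(val):.10g}")
                else:
                    info.append(f"{key}={val}")
            fh.write(
                f"synthetic\t{int(row['residue_index'])}\t.\tN\tA\t.\tPASS\t{';'.join(info)}\n"
            )
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long-format score table (gene_id, residue_index, alt_aa, vep, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "vep": str})
    required = ("gene_id", "residue_index", "alt_aa", "vep", "score")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing score column(s) {missing}")
    return df


def apply_quality_filters(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the gnomAD-style QC filters to putatively benign records.

    Retained iff ``inbreeding_coeff >= -0.3`` and ``max_sample_depth >= 10``
    and ``genotype_quality >= 20`` and ``allele_balance > 0.2``.  Missing
    values fail their filter.  Idempotent.  Raises if any pathogenic-class
    record is passed in — the filters are defined for the benign set only.
    """
    if (records["class_label"] == "pathogenic").any():
        raise ValidationError("quality filters apply only to the putatively benign set")
    ic = pd.to_numeric(records["inbreeding_coeff"], errors="coerce")
    dp = pd.to_numeric(records["max_sample_depth"], errors="coerce")
    gq = pd.to_numeric(records["genotype_quality"], errors="coerce")
    ab = pd.to_numeric(records["allele_balance"], errors="coerce")
    keep = (ic >= -0.3) & (dp >= 10) & (gq >= 20) & (ab > 0.2)
    keep = keep.fillna(False)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("apply_quality_filters: removed %d / %d records", n_drop, len(records))
    return records[keep].reset_index(drop=True)


@dataclass
class GeneDataset:
    """Eligible genes with their labelled variants and retained VEPs."""

    variants: pd.DataFrame  # both classes, retained genes only
    genes: list[str]
    veps: list[str]
    orientation: dict[str, bool]
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    min_per_class: int = 10
    coverage_threshold: float = 0.75

    def class_counts(self) -> pd.DataFrame:
        mis = self.variants[self.variants["consequence"] == "missense"]
        return mis.groupby(["gene_id", "class_label"]).size().unstack(fill_value=0)


def build_gene_dataset(
    pathogenic: pd.DataFrame,
    benign: pd.DataFrame,
    scores: pd.DataFrame,
    orientation: dict[str, bool],
    min_per_class: int = 10,
    coverage_threshold: float = 0.75,
) -> GeneDataset:
    """Assemble the analysis dataset with the gene and VEP eligibility rules.

    * benign records whose protein-level key appears in the pathogenic set
      are removed;
    * genes are retained when they have at least ``min_per_class`` missense
      variants in each class;
    * VEPs are retained when they score at least ``coverage_threshold`` of
      all missense variants of the retained genes.

    An empty result is legal and logged, never an error.
    """
    if pathogenic.empty or benign.empty:
        raise ValidationError("both variant collections must be non-empty")
    key_cols = ["gene_id", "residue_index", "ref_aa", "alt_aa"]
    path_keys = set(map(tuple, pathogenic[key_cols].itertuples(index=False, name=None)))
    ben_keys = list(map(tuple, benign[key_cols].itertuples(index=False, name=None)))
    overlap = np.array([k in path_keys for k in ben_keys])
    if overlap.any():
        logger.info("build_gene_dataset: removed %d benign records present in the pathogenic set",
                    int(overlap.sum()))
    benign = benign[~overlap]

    both = pd.concat([pathogenic, benign], ignore_index=True)
    mis = both[both["consequence"] == "missense"]
    counts = mis.groupby(["gene_id", "class_label"]).size().unstack(fill_value=0)
    for cls in ("pathogenic", "benign"):
        if cls not in counts.columns:
            counts[cls] = 0
    eligible = counts[(counts["pathogenic"] >= min_per_class) & (counts["benign"] >= min_per_class)]
    genes = sorted(eligible.index)
    if not genes:
        logger.warning("build_gene_dataset: no gene meets the %d-per-class threshold", min_per_class)
    variants = both[both["gene_id"].isin(genes)].reset_index(drop=True)

    mis_kept = variants[variants["consequence"] == "missense"]
    n_total = len(mis_kept)
    keys = pd.MultiIndex.from_frame(mis_kept[["gene_id", "residue_index", "alt_aa"]])
    coverage = {}
    veps = []
    for vep, grp in scores.groupby("vep"):
        if vep not in orientation:
            continue
        scored = pd.MultiIndex.from_frame(grp[["gene_id", "residue_index", "alt_aa"]])
        cov = float(keys.isin(scored).mean()) if n_total else 0.0
        coverage[vep] = cov
        if cov >= coverage_threshold:
            veps.append(vep)
        else:
            logger.info("build_gene_dataset: dropping %s (coverage %.3f < %.2f)",
                        vep, cov, coverage_threshold)
    return GeneDataset(
        variants=variants,
        genes=genes,
        veps=sorted(veps),
        orientation={v: orientation[v] for v in veps},
        coverage=pd.Series(coverage, name="coverage").sort_index(),
        min_per_class=min_per_class,
        coverage_threshold=coverage_threshold,
    )
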