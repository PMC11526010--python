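"""End-to-end orchestration: generate/ingest → metrics → features → models.

A run executes, in order: data generation (synthetic mode) or file ingestion
(real mode); benign-set quality filtering; gene/VEP eligibility; per-gene
metrics; GO feature selection and feature-table assembly; non-redundant
subset construction; per-VEP hyperparameter tuning, repeated hold-out CV and
final fitting; SHAP attribution and cross-VEP rank aggregation; and the
disorder-stratified analyses.  Every artefact is written as TSV under the
output directory together with a ``manifest.json`` recording the
configuration, the master seed and the SHA-256 of each output, so two runs
with the same config and seed produce identical manifests.

A single master seed fans out to per-stage seeds through
:func:`vepmeta._util.spawn_rng`; no stage shares a raw generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import homology, metrics, synthetic, variant_io
from ._util import derive_int_seed
from .errors import VepmetaError
from .explain import aggregate_feature_ranks, compute_shap, summarize_shap
from .meta_model import AurocMetaModel, HyperparamSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all"]

_FLOAT_FMT = "%.10g"


class PipelineError(VepmetaError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of a full run; round-trips losslessly through YAML."""

    mode: str = "synthetic"  # "synthetic" | "real"
    output_dir: str = "vepmeta_run"
    seed: int = 0
    # eligibility and analysis thresholds
    min_per_class: int = 10
    coverage_threshold: float = 0.75
    plddt_cutoff: float = 50.0
    identity_threshold: float = 30.0
    fdr: float = 0.05
    # model protocol
    n_repeats: int = 100
    hyperparams: HyperparamSpec = field(default_factory=HyperparamSpec)
    shap_background: int = 200
    # synthetic mode
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    # real mode input paths (TSV, as written by write_dataset)
    paths: dict = field(default_factory=dict)
    # optional precomputed identity matrix TSV; otherwise computed from sequences
    identity_path: str | None = None
    exact_identity_limit: int = 80

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if not 0 < self.coverage_threshold <= 1:
            raise PipelineError("coverage_threshold must be in (0, 1]")
        if isinstance(self.hyperparams, dict):
            fixed = {
                k: tuple(v) if isinstance(v, list) else v for k, v in self.hyperparams.items()
            }
            self.hyperparams = HyperparamSpec(**fixed)
        if isinstance(self.synthetic, dict):
            fixed = {
                k: tuple(v) if isinstance(v, list) else v for k, v in self.synthetic.items()
            }
            self.synthetic = synthetic.SyntheticConfig(**fixed)

    def to_yaml(self, path: str | Path) -> Path:
        payload = dataclasses.asdict(self)
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vepmeta")
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    root.setLevel(logging.INFO)
    return handler


def _ingest_real(config: RunConfig):
    paths = config.paths
    for key in ("variants", "scores", "residues", "orientation"):
        if key not in paths:
            raise FileNotFoundError(f"real mode requires a {key!r} path")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {paths[key]}")
    variants = variant_io.read_variant_table(paths["variants"], format="tsv")
    scores = variant_io.read_scores(paths["scores"])
    annotations = synthetic.read_annotations(paths["residues"])
    orient_df = pd.read_csv(paths["orientation"], sep="\t")
    orientation = dict(zip(orient_df["vep"], orient_df["higher_is_pathogenic"].astype(bool)))
    features_table = (
        pd.read_csv(paths["features"], sep="\t", index_col="gene_id")
        if "features" in paths and Path(paths["features"]).exists()
        else None
    )
    go = (
        pd.read_csv(paths["go_annotations"], sep="\t")
        if "go_annotations" in paths and Path(paths["go_annotations"]).exists()
        else pd.DataFrame(columns=["gene_id", "go_term"])
    )
    return variants, scores, annotations, orientation, features_table, go


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report (the manifest)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    t_start = time.time()
    stage = "init"

    def _record(name: str, n_in: int | None = None, n_out: int | None = None, **extra) -> None:
        # timings go to the log only, so manifests are reproducible bit-for-bit
        manifest["stages"][name] = {
            **({"n_in": n_in} if n_in is not None else {}),
            **({"n_out": n_out} if n_out is not None else {}),
            **extra,
        }
        logger.info("stage %s done in %.1fs (%s)", name, time.time() - t_start,
                    manifest["stages"][name])

    def _emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # 1. generate / ingest -------------------------------------------------
        stage = "ingest"
        if config.mode == "synthetic":
            syn_cfg = dataclasses.replace(config.synthetic, seed=derive_int_seed(config.seed, 1))
            ds = synthetic.generate_dataset(syn_cfg)
            variants = ds.variants
            scores = ds.scores
            annotations = ds.genes
            orientation = ds.orientation
            base_features = ds.features
            go = ds.go_annotations
            sequences = {g: a.sequence for g, a in ds.genes.items()}
            truth_path = outdir / "truth.json"
            truth_path.write_text(
                json.dumps(
                    json.loads(ds.truth.table.to_json(orient="index", double_precision=10)),
                    indent=1, sort_keys=True,
                )
            )
            _emit("truth", truth_path)
        else:
            variants, scores, annotations, orientation, base_features, go = _ingest_real(config)
            sequences = {g: a.sequence for g, a in annotations.items()}
            if base_features is None:
                raise FileNotFoundError("real mode requires a 'features' path")
        _record(stage, n_out=len(variants))

        # 2. quality filtering -------------------------------------------------
        stage = "filter"
        pathogenic = variants[variants["class_label"] == "pathogenic"].reset_index(drop=True)
        benign_raw = variants[variants["class_label"] == "benign"].reset_index(drop=True)
        benign_mis = benign_raw[benign_raw["consequence"] == "missense"]
        benign_kept = variant_io.apply_quality_filters(benign_mis)
        nonsense = benign_raw[benign_raw["consequence"] == "nonsense"]
        benign = pd.concat([benign_kept, nonsense], ignore_index=True)
        _record(stage, n_in=len(benign_raw), n_out=len(benign))

        # 3. gene/VEP eligibility ---------------------------------------------
        stage = "dataset"
        dataset = variant_io.build_gene_dataset(
            pathogenic, benign, scores, orientation,
            min_per_class=config.min_per_class,
            coverage_threshold=config.coverage_threshold,
        )
        _emit("eligible_variants", _write(dataset.variants, outdir / "eligible_variants.tsv"))
        _record(stage, n_in=len(variants), n_out=len(dataset.genes),
                veps=len(dataset.veps))

        # 4. per-gene metrics --------------------------------------------------
        stage = "metrics"
        perf = metrics.per_gene_performance(
            dataset, scores, annotations, plddt_cutoff=config.plddt_cutoff
        )
        _emit("gene_performance", _write(perf, outdir / "gene_performance.tsv"))
        corr = metrics.auroc_correlation_matrix(perf)
        _emit("auroc_correlation", _write(corr, outdir / "auroc_correlation.tsv", index=True))
        _record(stage, n_out=len(perf))

        # 5. features + GO selection ------------------------------------------
        stage = "features"
        mean_auroc = perf.groupby("gene_id")["auroc"].mean()
        enrichment, go_binary = feat.go_feature_selection(mean_auroc, go, fdr=config.fdr)
        enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enrichment])
        _emit("go_enrichment", _write(enr_df, outdir / "go_enrichment.tsv"))
        components: dict[str, pd.DataFrame] = {
            "base": base_features.loc[base_features.index.isin(dataset.genes)]
        }
        if not go_binary.empty:
            components["go"] = go_binary.loc[go_binary.index.isin(dataset.genes)]
        feature_table, imputed_mask = feat.assemble_feature_table(components)
        _emit("feature_table", _write(feature_table, outdir / "feature_table.tsv", index=True))
        _emit("imputation_mask", _write(imputed_mask, outdir / "imputation_mask.tsv", index=True))
        _record(stage, n_out=feature_table.shape[1], go_selected=int(go_binary.shape[1]))

        # 6. non-redundant subset ---------------------------------------------
        stage = "nonredundant"
        if config.identity_path:
            identity = pd.read_csv(config.identity_path, sep="\t", index_col=0)
        elif len(dataset.genes) <= config.exact_identity_limit:
            identity = homology.pairwise_identity(
                {g: sequences[g] for g in dataset.genes}
            )
        else:
            identity = homology.approximate_identity(
                {g: sequences[g] for g in dataset.genes}
            )
        lengths = {g: len(sequences[g]) for g in dataset.genes}
        nonredundant = homology.nonredundant_subset(
            identity, threshold_pct=config.identity_threshold, lengths=lengths
        )
        nr_path = outdir / "nonredundant_genes.tsv"
        pd.Series(nonredundant, name="gene_id").to_csv(nr_path, sep="\t", index=False)
        _emit("nonredundant_genes", nr_path)
        _record(stage, n_in=len(dataset.genes), n_out=len(nonredundant))

        # 7. per-VEP meta-models ----------------------------------------------
        stage = "meta_model"
        train_features = feature_table.loc[feature_table.index.isin(nonredundant)]
        cv_rows, agg_rows, pred_frames, results_by_vep = [], [], [], {}
        for i, vep in enumerate(dataset.veps):
            spec = dataclasses.replace(
                config.hyperparams, seed=derive_int_seed(config.seed, 70, i)
            )
            model = AurocMetaModel.from_performance(train_features, perf, vep, spec=spec)
            res = model.fit(n_repeats=config.n_repeats)
            results_by_vep[vep] = res
            rep = res.cv_repeats.copy()
            rep.insert(0, "vep", vep)
            cv_rows.append(rep)
            agg = res.cv_aggregate.copy()
            agg.insert(0, "vep", vep)
            agg_rows.append(agg.reset_index(names="metric"))
            full_pred = res.predict(feature_table)
            pred_frames.append(
                pd.DataFrame(
                    {"gene_id": feature_table.index, "vep": vep, "predicted_auroc": full_pred}
                )
            )
        _emit("cv_report", _write(pd.concat(cv_rows, ignore_index=True), outdir / "cv_report.tsv"))
        _emit("cv_aggregate", _write(pd.concat(agg_rows, ignore_index=True),
                                     outdir / "cv_aggregate.tsv"))
        _emit("predictions", _write(pd.concat(pred_frames, ignore_index=True),
                                    outdir / "predictions.tsv"))
        configs_path = outdir / "model_configs.json"
        configs_path.write_text(
            json.dumps({v: r.params for v, r in results_by_vep.items()}, indent=1, sort_keys=True)
        )
        _emit("model_configs", configs_path)
        _record(stage, n_out=len(results_by_vep))

        # 8. SHAP --------------------------------------------------------------
        stage = "explain"
        summaries = []
        shap_frames = []
        for vep, res in results_by_vep.items():
            attr = compute_shap(
                res.estimator, res.model.features,
                max_background=config.shap_background,
                seed=derive_int_seed(config.seed, 80),
            )
            shap_long = attr.reset_index(names="gene_id").melt(
                id_vars="gene_id", var_name="feature", value_name="shap"
            )
            shap_long.insert(1, "vep", vep)
            shap_frames.append(shap_long)
            summaries.append(summarize_shap(attr, res.model.features, vep_name=vep))
        ranked = aggregate_feature_ranks(summaries)
        _emit("shap_values", _write(pd.concat(shap_frames, ignore_index=True),
                                    outdir / "shap_values.tsv"))
        _emit("shap_summary", _write(pd.concat(summaries).reset_index(),
                                     outdir / "shap_summary.tsv"))
        _emit("feature_ranks", _write(ranked, outdir / "feature_ranks.tsv", index=True))
        _record(stage, n_out=len(ranked))

        # 9. disorder analyses -------------------------------------------------
        stage = "disorder"
        comparison, split = metrics.disorder_group_comparison(
            perf, annotations, plddt_cutoff=config.plddt_cutoff
        )
        _emit("disorder_groups", _write(comparison.reset_index(), outdir / "disorder_groups.tsv"))
        inflation = perf[["gene_id", "vep", "auroc", "auroc_no_disorder"]].copy()
        inflation["inflation"] = inflation["auroc"] - inflation["auroc_no_disorder"]
        _emit("disorder_inflation", _write(inflation, outdir / "disorder_inflation.tsv"))
        _record(stage, median_disorder_pct=split.median_disorder_pct)

        manifest["status"] = "ok"
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logging.getLogger("vepmeta").removeHandler(handler)
        handler.close()
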