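"""Synthetic gene/variant/score generator with known ground truth.

The generator emulates the statistical structure of a ClinVar/gnomAD/VEP
benchmarking dataset at the protein level:

* genes are chains of residues with contiguous ordered and intrinsically
  disordered tracts; pLDDT is bimodal (ordered mode near 90, disordered near
  35) and per-residue conservation is high in ordered tracts and low in
  disordered ones;
* pathogenic variants fall preferentially in ordered (conserved) residues,
  putatively benign population variants preferentially in disordered ones;
* pseudo-VEP scores are driven by residue conservation plus a pathogenicity
  shift and gene-specific Gaussian noise; the per-gene noise scale σ_gene is
  a linear function of a designated *causal* subset of gene features passed
  through a softplus link, so the true (asymptotic) per-gene AUROC is known
  analytically and recoverable;
* a full length × 19 substitution matrix of ΔΔG values (near zero in
  disordered tracts, Gamma-distributed in ordered ones) and ESM-like scores
  supports the stability-derived features.

Fixing the seed fixes every emitted array and file byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import features as feat
from ._util import AMINO_ACIDS, PLDDT_DISORDER_CUTOFF, inv_softplus, softplus, spawn_rng
from .errors import ConfigurationError, GenerationError

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ResidueAnnotation",
    "SubstitutionMatrix",
    "SyntheticDataset",
    "generate_genes",
    "generate_truth",
    "generate_variants",
    "generate_scores",
    "generate_feature_table",
    "generate_go_annotations",
    "generate_dataset",
    "write_dataset",
]

#: Latent gene traits that may serve as causal features.
_LATENT_TRAITS = ("s_het", "p_lof", "exac_oe_lof", "expression_level")

#: Expected nonsense variants per residue, used for observed/expected ratios.
LOF_EXPECTED_RATE = 0.02

#: Conservation modes for ordered and disordered tracts (mean, sd).
CONS_ORDERED = (0.8, 0.1)
CONS_DISORDERED = (0.2, 0.1)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the package's study conditions.

    The defaults are deliberately opinionated: 300 genes of 200-800
    residues, a benign-variant disorder enrichment of 0.7 and a pathogenic
    ordered-placement probability of 0.9, matching the qualitative picture
    of population variants concentrating in disordered tracts and disease
    variants in folded domains.
    """

    n_genes: int = 300
    length_range: tuple[int, int] = (200, 800)
    disorder_fraction_range: tuple[float, float] = (0.02, 0.45)
    n_pathogenic_range: tuple[int, int] = (10, 100)
    n_benign_range: tuple[int, int] = (10, 100)
    benign_disorder_enrichment: float = 0.7
    pathogenic_ordered_prob: float = 0.9
    n_veps: int = 5
    conservation_weight: float = 2.0
    pathogenic_shift: float = 1.0
    vep_param_jitter: float = 0.1
    vep_missingness: float | tuple[float, ...] = 0.08
    flip_orientation_every: int = 3
    causal_feature_names: tuple[str, ...] = (
        "s_het",
        "plddt_disorder",
        "exac_oe_lof",
        "expression_level",
    )
    causal_coefficients: tuple[float, ...] = (-0.9, -0.7, 0.9, -0.6)
    n_distractor_features: int = 20
    noise_scale_range: tuple[float, float] = (0.15, 1.2)
    qc_fail_rate: float = 0.05
    n_go_terms: int = 25
    n_go_causal_terms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        for name in ("benign_disorder_enrichment", "pathogenic_ordered_prob", "qc_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "length_range",
            "disorder_fraction_range",
            "n_pathogenic_range",
            "n_benign_range",
            "noise_scale_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name} is empty: {lo} > {hi}")
        if self.noise_scale_range[0] <= 0:
            raise ConfigurationError("noise scales must be positive")
        if not 0.0 <= self.disorder_fraction_range[0] <= 1.0 or self.disorder_fraction_range[1] > 1.0:
            raise ConfigurationError("disorder_fraction_range must lie within [0, 1]")
        if len(self.causal_feature_names) != len(self.causal_coefficients):
            raise ConfigurationError("causal_feature_names and causal_coefficients differ in length")
        allowed = set(_LATENT_TRAITS) | set(feat.NAMED_FEATURES)
        unknown = set(self.causal_feature_names) - allowed
        if unknown:
            raise ConfigurationError(
                f"causal feature(s) {sorted(unknown)} not in the feature schema {sorted(allowed)}"
            )
        if self.n_veps < 1:
            raise ConfigurationError("n_veps must be >= 1")

    def missingness(self) -> np.ndarray:
        m = self.vep_missingness
        if np.isscalar(m):
            return np.full(self.n_veps, float(m))
        arr = np.asarray(m, dtype=float)
        if arr.size != self.n_veps:
            raise ConfigurationError("vep_missingness length must equal n_veps")
        return arr


@dataclass
class ResidueAnnotation:
    """Per-gene residue-level arrays: sequence, pLDDT, Cα coordinates, conservation."""

    gene_id: str
    sequence: str
    plddt: np.ndarray  # (L,), 0-100
    coords: np.ndarray  # (L, 3), Å
    conservation: np.ndarray  # (L,)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def disordered(self) -> np.ndarray:
        return self.plddt < PLDDT_DISORDER_CUTOFF


@dataclass
class SubstitutionMatrix:
    """Full per-substitution ΔΔG and ESM-like score matrices for one gene.

    Row ``r`` (0-based; residue ``r + 1``) holds the 19 alternates to the
    reference amino acid at that residue, ordered by the canonical alphabet
    with the reference removed.
    """

    gene_id: str
    sequence: str
    ddg: np.ndarray  # (L, 19) kcal/mol
    vep_scores: np.ndarray  # (L, 19)

    def alt_column(self, residue_index: int, alt_aa: str) -> int:
        ref = self.sequence[residue_index - 1]
        alts = [aa for aa in AMINO_ACIDS if aa != ref]
        return alts.index(alt_aa)

    def lookup_ddg(self, residue_index: int, alt_aa: str) -> float:
        return float(self.ddg[residue_index - 1, self.alt_column(residue_index, alt_aa)])


@dataclass
class SyntheticTruth:
    """Latent ground truth: per-gene noise scale and asymptotic AUROC.

    ``table`` is indexed by gene_id with columns ``sigma``, ``true_auroc``,
    the latent traits, and the causal feature values actually used.
    """

    table: pd.DataFrame
    causal_feature_names: tuple[str, ...]
    causal_coefficients: tuple[float, ...]

    @property
    def sigma(self) -> pd.Series:
        return self.table["sigma"]

    @property
    def true_auroc(self) -> pd.Series:
        return self.table["true_auroc"]


def _self_avoiding_chain(rng: np.random.Generator, length: int, spacing: float = 3.8,
                         min_sep: float = 3.0, max_tries: int = 30) -> np.ndarray:
    """A spacing-Å-stepped random walk with (soft) excluded volume."""
    coords = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(max_tries):
            step = rng.normal(size=3)
            step *= spacing / np.linalg.norm(step)
            cand = coords[i - 1] + step
            d2 = np.sum((coords[: i - 1] - cand) ** 2, axis=1) if i > 1 else np.array([np.inf])
            if d2.size == 0 or d2.min() >= min_sep ** 2:
                break
        coords[i] = cand
    return coords


def _disorder_layout(rng: np.random.Generator, length: int, fraction: float) -> np.ndarray:
    """Boolean disorder mask with contiguous disordered tracts of total size round(f*L)."""
    k = int(round(fraction * length))
    mask = np.zeros(length, dtype=bool)
    if k == 0:
        return mask
    if k == length:
        return ~mask
    m = 1 + min(int(rng.poisson(0.8)), 3)  # number of disordered tracts
    m = min(m, k)
    chunks = rng.multinomial(k - m, np.full(m, 1.0 / m)) + 1
    gaps = rng.multinomial(length - k, np.full(m + 1, 1.0 / (m + 1)))
    pos = 0
    for gap, chunk in zip(gaps[:-1], chunks):
        pos += gap
        mask[pos : pos + chunk] = True
        pos += chunk
    return mask


def generate_genes(config: SyntheticConfig) -> dict[str, ResidueAnnotation]:
    """Generate gene residue annotations (sequence, pLDDT, Cα chain, conservation).

    Ordered residues draw pLDDT from a high mode centred near 90 and
    disordered residues from a low mode centred near 35; both modes respect
    the pLDDT < 50 disorder definition so the generated disorder fraction is
    exact.  Conservation is high in ordered tracts and low in disordered
    ones.  Cα coordinates form a 3.8 Å-spaced self-avoiding chain.
    """
    rng = spawn_rng(config.seed, 1)
    width = len(str(config.n_genes))
    genes: dict[str, ResidueAnnotation] = {}
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        fraction = float(rng.uniform(*config.disorder_fraction_range))
        dis = _disorder_layout(rng, length, fraction)
        plddt = np.where(
            dis,
            np.clip(rng.normal(35.0, 8.0, length), 0.0, 49.5),
            np.clip(rng.normal(90.0, 5.0, length), 50.5, 100.0),
        )
        conservation = np.where(
            dis,
            rng.normal(*CONS_DISORDERED, length),
            rng.normal(*CONS_ORDERED, length),
        )
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        coords = _self_avoiding_chain(rng, length)
        genes[gene_id] = ResidueAnnotation(gene_id, sequence, plddt, coords, conservation)
    return genes


def _effective_placement(n_ordered: int, n_disordered: int, prob_primary: float,
                         primary_is_ordered: bool) -> float:
    """Probability of landing in the primary class after empty-pool fallback."""
    n_primary = n_ordered if primary_is_ordered else n_disordered
    n_other = n_disordered if primary_is_ordered else n_ordered
    if n_primary == 0:
        return 0.0
    if n_other == 0:
        return 1.0
    return prob_primary


def _analytic_auroc(ann: ResidueAnnotation, sigma: float, config: SyntheticConfig) -> float:
    """Asymptotic AUROC for one gene under the generative score model.

    Mixture over the (pathogenic placement, benign placement) combinations
    of normal comparisons: within each combination the score difference is
    Gaussian with mean a·Δμ_conservation + b and variance
    a²(var_p + var_b) + 2σ², so P(s_p > s_b) = Φ(mean / sd).  Pathogenic
    sites inside disordered tracts carry ordered-mode conservation
    (conserved functional motifs), so the pathogenic side always draws from
    a high-conservation distribution.
    """
    a, b = config.conservation_weight, config.pathogenic_shift
    dis = ann.disordered
    n_dis, n_ord = int(dis.sum()), int((~dis).sum())
    p_ord = _effective_placement(n_ord, n_dis, config.pathogenic_ordered_prob, True)
    b_dis = _effective_placement(n_ord, n_dis, config.benign_disorder_enrichment, False)
    moments = {}
    if n_ord:
        moments["ord"] = (float(ann.conservation[~dis].mean()), float(ann.conservation[~dis].var()))
    if n_dis:
        moments["dis"] = (float(ann.conservation[dis].mean()), float(ann.conservation[dis].var()))
    # pathogenic-in-disorder sites have conservation redrawn from the ordered mode
    moments["motif"] = (CONS_ORDERED[0], CONS_ORDERED[1] ** 2)
    total = 0.0
    for p_cls, wp in (("ord", p_ord), ("motif", 1.0 - p_ord)):
        for b_cls, wb in (("dis", b_dis), ("ord", 1.0 - b_dis)):
            w = wp * wb
            if w == 0.0:
                continue
            mu_p, var_p = moments[p_cls]
            mu_b, var_b = moments[b_cls]
            delta = a * (mu_p - mu_b) + b
            sd = np.sqrt(a * a * (var_p + var_b) + 2.0 * sigma * sigma)
            total += w * float(norm.cdf(delta / sd))
    return total


def generate_truth(genes: dict[str, ResidueAnnotation], config: SyntheticConfig) -> SyntheticTruth:
    """Draw latent gene traits and derive σ_gene and the true AUROC per gene.

    σ_gene = clip(softplus(β₀ + Σ cⱼ·zⱼ), noise_scale_range) where the zⱼ are
    the standardized causal feature values and β₀ centres the link at the
    midpoint of the noise range.  Larger σ_gene always means lower true AUROC.
    """
    rng = spawn_rng(config.seed, 2)
    gene_ids = list(genes)
    n = len(gene_ids)
    traits = pd.DataFrame(
        {
            "s_het": rng.beta(1.5, 8.0, n),
            "p_lof": rng.uniform(0.0, 1.0, n),
            "exac_oe_lof": rng.uniform(0.05, 1.5, n),
            "expression_level": rng.normal(0.0, 1.0, n),
            # per-gene mutational opportunity for nonsense variants, so the
            # expected LoF count is not simply proportional to length
            "lof_mutability": rng.uniform(0.6, 1.4, n),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    traits["plddt_disorder"] = [
        100.0 * float(genes[g].disordered.mean()) for g in gene_ids
    ]
    lo, hi = config.noise_scale_range
    beta0 = inv_softplus((lo + hi) / 2.0)
    eta = np.full(n, beta0)
    for name, coef in zip(config.causal_feature_names, config.causal_coefficients):
        vals = traits[name].to_numpy(float)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
        eta = eta + coef * z
    sigma = np.clip(softplus(eta), lo, hi)
    traits["sigma"] = sigma
    traits["true_auroc"] = [
        _analytic_auroc(genes[g], s, config) for g, s in zip(gene_ids, sigma)
    ]
    return SyntheticTruth(traits, config.causal_feature_names, config.causal_coefficients)


def _pick_alt(rng: np.random.Generator, ref: str) -> str:
    alts = [aa for aa in AMINO_ACIDS if aa != ref]
    return alts[int(rng.integers(len(alts)))]


def _place_variants(rng, ann: ResidueAnnotation, n: int, prob_primary: float,
                    primary_is_ordered: bool, used: set) -> list[tuple[int, str]]:
    """(residue_index, alt_aa) pairs for n variants, unique at (residue, alt) level."""
    dis = ann.disordered
    pools = {
        True: np.flatnonzero(~dis) + 1,  # ordered
        False: np.flatnonzero(dis) + 1,  # disordered
    }
    out = []
    max_tries = 200 * max(n, 1)
    tries = 0
    placed = 0
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"{ann.gene_id}: could not place {n} unique variants (gene too short)"
            )
        in_primary = rng.random() < prob_primary
        want_ordered = in_primary if primary_is_ordered else not in_primary
        pool = pools[want_ordered]
        if pool.size == 0:
            if prob_primary in (0.0, 1.0):
                side = "ordered" if want_ordered else "disordered"
                raise GenerationError(
                    f"{ann.gene_id}: no {side} residues available for forced placement"
                )
            pool = pools[not want_ordered]
        res = int(pool[int(rng.integers(pool.size))])
        alt = _pick_alt(rng, ann.sequence[res - 1])
        if (res, alt) in used:
            continue
        used.add((res, alt))
        out.append((res, alt))
        placed += 1
    return out


def generate_variants(
    genes: dict[str, ResidueAnnotation],
    config: SyntheticConfig,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Generate labelled missense variants plus nonsense variants per gene.

    Pathogenic variants land in ordered residues with probability
    ``pathogenic_ordered_prob`` and benign variants in disordered residues
    with probability ``benign_disorder_enrichment`` (falling back to the
    other tract type when the requested one is absent, unless the
    probability is exactly 0 or 1, which is treated as a hard constraint and
    raises).  A pathogenic site that falls inside a disordered tract is
    treated as a conserved functional motif residue: its conservation is
    redrawn from the ordered mode (disease mutations in disordered regions
    cluster in conserved motifs, so predictors score them like ordered
    pathogenic variants).  Variants are unique at (gene, residue, alt)
    granularity and no variant appears in both classes.  Benign variants carry gnomAD-style QC
    fields, a configurable fraction of which fail one filter.  Nonsense
    variant counts follow the gene's latent observed/expected LoF ratio when
    ``truth`` is given.
    """
    if not genes:
        raise GenerationError("no genes supplied")
    rng = spawn_rng(config.seed, 3)
    rows: list[dict] = []
    for gene_id, ann in genes.items():
        n_p = int(rng.integers(config.n_pathogenic_range[0], config.n_pathogenic_range[1] + 1))
        n_b = int(rng.integers(config.n_benign_range[0], config.n_benign_range[1] + 1))
        if n_p + n_b > ann.length * 19:
            raise GenerationError(
                f"{gene_id}: requested {n_p + n_b} variants exceeds {ann.length * 19} possible"
            )
        used: set = set()
        path_vars = _place_variants(rng, ann, n_p, config.pathogenic_ordered_prob, True, used)
        ben_vars = _place_variants(rng, ann, n_b, config.benign_disorder_enrichment, False, used)
        for res, _alt in path_vars:
            if ann.disordered[res - 1]:  # conserved motif within the disordered tract
                ann.conservation[res - 1] = rng.normal(*CONS_ORDERED)
        for res, alt in path_vars:
            rows.append(
                {
                    "gene_id": gene_id,
                    "residue_index": res,
                    "ref_aa": ann.sequence[res - 1],
                    "alt_aa": alt,
                    "consequence": "missense",
                    "class_label": "pathogenic",
                    "inbreeding_coeff": np.nan,
                    "max_sample_depth": np.nan,
                    "genotype_quality": np.nan,
                    "allele_balance": np.nan,
                    "allele_frequency": np.nan,
                }
            )
        for res, alt in ben_vars:
            qc = {
                "inbreeding_coeff": float(np.clip(rng.normal(0.0, 0.08), -0.299, 1.0)),
                "max_sample_depth": int(rng.integers(10, 120)),
                "genotype_quality": float(rng.uniform(20.0, 99.0)),
                "allele_balance": float(rng.uniform(0.201, 0.5)),
            }
            if rng.random() < config.qc_fail_rate:
                which = int(rng.integers(4))
                if which == 0:
                    qc["inbreeding_coeff"] = float(rng.uniform(-0.9, -0.301))
                elif which == 1:
                    qc["max_sample_depth"] = int(rng.integers(0, 10))
                elif which == 2:
                    qc["genotype_quality"] = float(rng.uniform(0.0, 19.99))
                else:
                    qc["allele_balance"] = float(rng.uniform(0.0, 0.2))
            rows.append(
                {
                    "gene_id": gene_id,
                    "residue_index": res,
                    "ref_aa": ann.sequence[res - 1],
                    "alt_aa": alt,
                    "consequence": "missense",
                    "class_label": "benign",
                    **qc,
                    "allele_frequency": float(10.0 ** rng.uniform(-6.0, -2.0)),
                }
            )
        # nonsense variants (gnomAD-observed premature stops) for n_lof
        mut = float(truth.table.loc[gene_id, "lof_mutability"]) if truth is not None else 1.0
        expected = LOF_EXPECTED_RATE * ann.length * mut
        oe = float(truth.table.loc[gene_id, "exac_oe_lof"]) if truth is not None else 1.0
        n_nonsense = int(rng.poisson(expected * oe))
        n_nonsense = min(n_nonsense, ann.length)
        if n_nonsense:
            stops = rng.choice(ann.length, size=n_nonsense, replace=False) + 1
            for res in np.sort(stops):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "residue_index": int(res),
                        "ref_aa": ann.sequence[res - 1],
                        "alt_aa": "*",
                        "consequence": "nonsense",
                        "class_label": "benign",
                        "inbreeding_coeff": np.nan,
                        "max_sample_depth": np.nan,
                        "genotype_quality": np.nan,
                        "allele_balance": np.nan,
                        "allele_frequency": float(10.0 ** rng.uniform(-6.0, -3.0)),
                    }
                )
    return pd.DataFrame(rows)


def generate_scores(
    genes: dict[str, ResidueAnnotation],
    variants: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, bool], dict[str, SubstitutionMatrix]]:
    """Pseudo-VEP scores for variants plus full substitution matrices.

    Each pseudo-VEP v scores a missense variant as
    ``a_v·conservation(residue) + b_v·1[pathogenic] + ε`` with
    ``ε ~ N(0, σ_gene)``; a_v and b_v are mildly jittered per VEP around the
    configured values, so all VEPs share the conservation signal and their
    per-gene AUROC vectors are positively correlated.  Every
    ``flip_orientation_every``-th VEP is emitted negated with a
    higher-is-benign orientation flag to exercise orientation handling.
    Per-VEP missingness removes a configurable fraction of scores.

    Also emits, per gene, the (length × 19) ΔΔG matrix (Gamma-distributed in
    ordered tracts, near zero in disordered ones) and the designated
    ESM-like VEP's substitution score matrix.
    """
    missing = [v for v in variants["gene_id"].unique() if v not in genes]
    if missing:
        raise GenerationError(f"variants reference unknown genes: {missing[:5]}")
    rng = spawn_rng(config.seed, 4)
    veps = [f"VEP{i + 1:02d}" for i in range(config.n_veps)]
    jit = config.vep_param_jitter
    a_v = config.conservation_weight * (1.0 + jit * rng.uniform(-1, 1, config.n_veps))
    b_v = config.pathogenic_shift * (1.0 + jit * rng.uniform(-1, 1, config.n_veps))
    k = config.flip_orientation_every
    orientation = {
        vep: not (k > 0 and (i + 1) % k == 0) for i, vep in enumerate(veps)
    }
    miss = config.missingness()

    mis = variants[variants["consequence"] == "missense"].reset_index(drop=True)
    cons = np.array(
        [genes[g].conservation[r - 1] for g, r in zip(mis["gene_id"], mis["residue_index"])]
    )
    sigma = truth.sigma.reindex(mis["gene_id"]).to_numpy(float)
    is_path = (mis["class_label"] == "pathogenic").to_numpy()

    frames = []
    for i, vep in enumerate(veps):
        eps = rng.normal(0.0, 1.0, len(mis)) * sigma
        score = a_v[i] * cons + b_v[i] * is_path + eps
        if not orientation[vep]:
            score = -score
        keep = rng.random(len(mis)) >= miss[i]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": mis["gene_id"],
                    "residue_index": mis["residue_index"],
                    "alt_aa": mis["alt_aa"],
                    "vep": vep,
                    "score": score,
                }
            )[keep]
        )
    scores = pd.concat(frames, ignore_index=True)

    substitutions: dict[str, SubstitutionMatrix] = {}
    for gene_id, ann in genes.items():
        L = ann.length
        dis = ann.disordered
        ddg_scale = rng.uniform(0.8, 1.5)
        ddg = np.where(
            dis[:, None],
            rng.normal(0.0, 0.1, (L, 19)),
            rng.gamma(2.0, ddg_scale, (L, 19)),
        )
        sig = float(truth.sigma.loc[gene_id])
        vmat = a_v[0] * ann.conservation[:, None] + rng.normal(0.0, sig, (L, 19))
        if not orientation[veps[0]]:
            vmat = -vmat
        substitutions[gene_id] = SubstitutionMatrix(gene_id, ann.sequence, ddg, vmat)
    return scores, orientation, substitutions


def generate_feature_table(
    genes: dict[str, ResidueAnnotation],
    variants: pd.DataFrame,
    scores: pd.DataFrame,
    substitutions: dict[str, SubstitutionMatrix],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    target_vep: str | None = None,
) -> pd.DataFrame:
    """Gene × feature table: all named features plus distractor columns.

    The named features are computed from the generated data with the same
    functions the real-data path uses (:mod:`vepmeta.features`); latent
    traits (``s_het``, ``p_lof``, ``expression_level``) pass through
    unchanged, while ``exac_oe_lof`` is the *observed*/expected ratio and
    therefore a noisy measurement of its latent counterpart.  Distractor
    columns are i.i.d. standard normal.
    """
    rng = spawn_rng(config.seed, 5)
    if target_vep is None:
        target_vep = sorted(scores["vep"].unique())[0]
    tv = scores[scores["vep"] == target_vep]
    tv_lookup = {
        (g, r, a): s
        for g, r, a, s in zip(tv["gene_id"], tv["residue_index"], tv["alt_aa"], tv["score"])
    }
    rows = {}
    for gene_id, ann in genes.items():
        gv = variants[variants["gene_id"] == gene_id]
        benign = gv[(gv["class_label"] == "benign") & (gv["consequence"] == "missense")]
        nonsense = gv[gv["consequence"] == "nonsense"]
        sub = substitutions[gene_id]
        ddg_vals = [sub.lookup_ddg(r, a) for r, a in zip(benign["residue_index"], benign["alt_aa"])]
        vep_vals = [
            tv_lookup.get((gene_id, r, a), np.nan)
            for r, a in zip(benign["residue_index"], benign["alt_aa"])
        ]
        mut = float(truth.table.loc[gene_id, "lof_mutability"])
        n_lof, oe = feat.lof_features(
            nonsense["residue_index"], LOF_EXPECTED_RATE * ann.length * mut, ann.length
        )
        pd_disorder, mean_plddt = feat.plddt_features(ann.plddt)
        rows[gene_id] = {
            "ddg_fold": feat.ddg_fold(ddg_vals),
            "vep_gnomad_mean": feat.vep_gnomad_mean(vep_vals),
            "gnomad_distance": feat.gnomad_distance(ann.coords, benign["residue_index"]),
            "efx_raw": feat.efx_raw(sub.vep_scores, sub.ddg),
            "n_lof": n_lof,
            "exac_oe_lof": oe,
            "plddt_disorder": pd_disorder,
            "mean_plddt": mean_plddt,
            "s_het": float(truth.table.loc[gene_id, "s_het"]),
            "p_lof": float(truth.table.loc[gene_id, "p_lof"]),
            "expression_level": float(truth.table.loc[gene_id, "expression_level"]),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "gene_id"
    for j in range(config.n_distractor_features):
        table[f"distractor_{j + 1:02d}"] = rng.normal(0.0, 1.0, len(table))
    if table.columns.duplicated().any():
        raise ConfigurationError("duplicate feature names in generated table")
    return table


def generate_go_annotations(
    genes: dict[str, ResidueAnnotation],
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Synthetic GO annotations: random terms plus a few σ-linked ones.

    The first ``n_go_causal_terms`` terms have membership probability that
    increases as σ_gene decreases (i.e. they mark better-predicted genes),
    so the over-representation selection has something real to find.
    """
    rng = spawn_rng(config.seed, 6)
    gene_ids = list(genes)
    sigma = truth.sigma.loc[gene_ids].to_numpy(float)
    z = (sigma - sigma.mean()) / (sigma.std() or 1.0)
    rows = []
    for t in range(config.n_go_terms):
        term = f"GO:SYN{t + 1:04d}"
        base = rng.uniform(0.08, 0.4)
        if t < config.n_go_causal_terms:
            logit = np.log(base / (1 - base)) - 1.8 * z
            probs = 1.0 / (1.0 + np.exp(-logit))
        else:
            probs = np.full(len(gene_ids), base)
        member = rng.random(len(gene_ids)) < probs
        rows.extend({"gene_id": g, "go_term": term} for g, m in zip(gene_ids, member) if m)
    return pd.DataFrame(rows, columns=["gene_id", "go_term"])


@dataclass
class SyntheticDataset:
    """Bundle of everything one generator run produces."""

    config: SyntheticConfig
    genes: dict[str, ResidueAnnotation]
    truth: SyntheticTruth
    variants: pd.DataFrame
    scores: pd.DataFrame
    orientation: dict[str, bool]
    substitutions: dict[str, SubstitutionMatrix]
    features: pd.DataFrame
    go_annotations: pd.DataFrame

    @property
    def veps(self) -> list[str]:
        return sorted(self.orientation)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run the full generator: genes → truth → variants → scores → features."""
    genes = generate_genes(config)
    truth = generate_truth(genes, config)
    variants = generate_variants(genes, config, truth)
    scores, orientation, substitutions = generate_scores(genes, variants, truth, config)
    features = generate_feature_table(genes, variants, scores, substitutions, truth, config)
    go = generate_go_annotations(genes, truth, config)
    return SyntheticDataset(
        config, genes, truth, variants, scores, orientation, substitutions, features, go
    )


_FLOAT_FMT = "%.10g"


def write_dataset(ds: SyntheticDataset, outdir: str | Path, write_substitutions: bool = False) -> dict[str, Path]:
    """Write the dataset as TSV/JSON files; byte-stable under a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index, float_format=_FLOAT_FMT)
        paths[name] = p

    _tsv("variants", ds.variants)
    _tsv("scores", ds.scores)
    residues = pd.concat(
        [
            pd.DataFrame(
                {
                    "gene_id": g.gene_id,
                    "residue_index": np.arange(1, g.length + 1),
                    "ref_aa": list(g.sequence),
                    "plddt": g.plddt,
                    "conservation": g.conservation,
                    "ca_x": g.coords[:, 0],
                    "ca_y": g.coords[:, 1],
                    "ca_z": g.coords[:, 2],
                }
            )
            for g in ds.genes.values()
        ],
        ignore_index=True,
    )
    _tsv("residues", residues)
    _tsv("features", ds.features, index=True)
    _tsv("go_annotations", ds.go_annotations)
    orient = pd.DataFrame(
        {"vep": ds.veps, "higher_is_pathogenic": [ds.orientation[v] for v in ds.veps]}
    )
    _tsv("orientation", orient)
    truth_payload = {
        "causal_feature_names": list(ds.truth.causal_feature_names),
        "causal_coefficients": list(ds.truth.causal_coefficients),
        "genes": json.loads(ds.truth.table.to_json(orient="index", double_precision=10)),
    }
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    paths["truth"] = tp
    if write_substitutions:
        frames = []
        for g, sub in ds.substitutions.items():
            L = len(sub.sequence)
            res = np.repeat(np.arange(1, L + 1), 19)
            alts = np.concatenate(
                [[aa for aa in AMINO_ACIDS if aa != sub.sequence[r]] for r in range(L)]
            )
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": g,
                        "residue_index": res,
                        "alt_aa": alts,
                        "ddg": sub.ddg.ravel(),
                        "vep_score": sub.vep_scores.ravel(),
                    }
                )
            )
        _tsv("substitutions", pd.concat(frames, ignore_index=True))
    return paths


def read_annotations(path: str | Path) -> dict[str, ResidueAnnotation]:
    """Read back a ``residues.tsv`` written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, ResidueAnnotation] = {}
    for gene_id, grp in df.groupby("gene_id", sort=True):
        grp = grp.sort_values("residue_index")
        out[str(gene_id)] = ResidueAnnotation(
            str(gene_id),
            "".join(grp["ref_aa"]),
            grp["plddt"].to_numpy(float),
            grp[["ca_x", "ca_y", "ca_z"]].to_numpy(float),
            grp["conservation"].to_numpy(float),
        )
    return out


def write_mmcif(ann: ResidueAnnotation, path: str | Path) -> Path:
    """Write a minimal mmCIF with Cα atoms and pLDDT in the B-factor column.

    Mirrors how AlphaFold structures carry pLDDT, for parser testing.
    Requires :mod:`gemmi`.
    """
    import gemmi

    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    structure = gemmi.Structure()
    structure.name = ann.gene_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (aa, xyz, plddt) in enumerate(zip(ann.sequence, ann.coords, ann.plddt), start=1):
        residue = gemmi.Residue()
        residue.name = three[aa]
        residue.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.b_iso = float(plddt)
        atom.occ = 1.0
        residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.make_mmcif_document().write_file(str(path))
    return path
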