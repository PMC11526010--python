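"""Random-forest meta-models that predict per-gene AUROC from gene features.

One model is trained per VEP: the response is that VEP's per-gene AUROC
over the non-redundant gene set, the design matrix is the gene feature
table.  The workflow mirrors a careful small-n regression protocol:

1. hyperparameters are chosen by low-discrepancy (Sobol/quasi-Monte-Carlo)
   search over the space, scoring each trial by 5-fold cross-validated RMSE
   and keeping the minimiser;
2. generalisation is estimated by repeated hold-out cross-validation —
   many independent 80/20 shuffle splits — reporting Spearman ρ, R² and
   RMSE per repeat with t-distribution 95% confidence intervals;
3. the final model is refit on all genes with a defined target, and
   predictions (clipped to [0, 1]) are emitted for every gene in the
   feature table, including target-less genes.

The public surface follows the Model/Results idiom: build an
:class:`AurocMetaModel`, call :meth:`~AurocMetaModel.fit`, inspect the
returned :class:`AurocMetaModelResults` (``summary()``, ``cv_repeats``,
``predict``, ``shap_values``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold, train_test_split

from ._util import derive_int_seed
from .errors import ConfigurationError, SchemaError, TuningError

__all__ = [
    "HyperparamSpec",
    "CVResult",
    "tune_hyperparameters",
    "repeated_holdout_cv",
    "t_confidence_interval",
    "fit_final_and_predict",
    "AurocMetaModel",
    "AurocMetaModelResults",
]


@dataclass(frozen=True)
class HyperparamSpec:
    """Search space for the random-forest hyperparameters.

    Ranges are inclusive; integer dimensions are rounded after Sobol
    sampling.  ``n_trials`` defaults to 300 configurations.
    """

    n_estimators: tuple[int, int] = (100, 500)
    max_depth: tuple[int, int] = (2, 32)
    max_features: tuple[float, float] = (0.1, 1.0)
    min_samples_leaf: tuple[int, int] = (1, 20)
    min_samples_split: tuple[int, int] = (2, 20)
    n_trials: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        for name in ("n_estimators", "max_depth", "max_features",
                     "min_samples_leaf", "min_samples_split"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"degenerate range for {name}: ({lo}, {hi})")

    def sample(self) -> list[dict]:
        """Draw ``n_trials`` configurations by Sobol low-discrepancy sampling."""
        import warnings

        sampler = qmc.Sobol(d=5, scramble=True, seed=self.seed)
        with warnings.catch_warnings():
            # non-power-of-two trial counts are fine for a hyperparameter sweep
            warnings.simplefilter("ignore", UserWarning)
            u = sampler.random(self.n_trials)
        configs = []
        for row in u:
            configs.append(
                {
                    "n_estimators": _scale_int(row[0], self.n_estimators),
                    "max_depth": _scale_int(row[1], self.max_depth),
                    "max_features": float(
                        self.max_features[0]
                        + row[2] * (self.max_features[1] - self.max_features[0])
                    ),
                    "min_samples_leaf": _scale_int(row[3], self.min_samples_leaf),
                    "min_samples_split": _scale_int(row[4], self.min_samples_split),
                }
            )
        return configs


def _scale_int(u: float, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(min(hi, lo + int(u * (hi - lo + 1))))


def _make_rf(config: dict, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=int(config["n_estimators"]),
        max_depth=int(config["max_depth"]),
        max_features=float(config["max_features"]),
        min_samples_leaf=int(config["min_samples_leaf"]),
        min_samples_split=int(config["min_samples_split"]),
        random_state=seed,
        n_jobs=1,
    )


def tune_hyperparameters(
    features: pd.DataFrame,
    targets: pd.Series,
    spec: HyperparamSpec,
    cv_folds: int = 5,
) -> tuple[dict, pd.DataFrame]:
    """Pick the configuration minimising k-fold CV RMSE over a Sobol sweep.

    Returns the winning configuration and the full trial table (one row per
    configuration with its CV RMSE), deterministic under ``spec.seed``.
    """
    X = features.to_numpy(float)
    y = targets.to_numpy(float)
    if len(y) < cv_folds:
        raise TuningError(f"need at least {cv_folds} genes for {cv_folds}-fold tuning")
    configs = spec.sample()
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=derive_int_seed(spec.seed, 11))
    splits = list(kf.split(X))
    records = []
    for t, config in enumerate(configs):
        errs = []
        for train, test in splits:
            rf = _make_rf(config, derive_int_seed(spec.seed, 12, t))
            rf.fit(X[train], y[train])
            pred = rf.predict(X[test])
            errs.append(np.sqrt(mean_squared_error(y[test], pred)))
        records.append({**config, "cv_rmse": float(np.mean(errs)), "trial": t})
    trials = pd.DataFrame(records)
    if trials["cv_rmse"].isna().all():
        raise TuningError("all tuning trials failed")
    best = trials.loc[trials["cv_rmse"].idxmin()]
    config = {
        k: (int(best[k]) if k != "max_features" else float(best[k]))
        for k in ("n_estimators", "max_depth", "max_features",
                  "min_samples_leaf", "min_samples_split")
    }
    return config, trials


def t_confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Mean ± t-critical · SE confidence interval for a sample mean.

    Uses the t distribution with n-1 degrees of freedom; requires n >= 2.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ConfigurationError("confidence interval needs at least 2 values")
    mean = arr.mean()
    se = arr.std(ddof=1) / np.sqrt(arr.size)
    tcrit = stats.t.ppf((1.0 + level) / 2.0, df=arr.size - 1)
    return float(mean - tcrit * se), float(mean + tcrit * se)


@dataclass
class CVResult:
    """Repeated hold-out cross-validation outcomes for one model."""

    repeats: pd.DataFrame  # columns: repeat, spearman, r2, rmse
    level: float = 0.95
    aggregate: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = {}
        for metric in ("spearman", "r2", "rmse"):
            vals = self.repeats[metric]
            if vals.notna().sum() >= 2:
                lo, hi = t_confidence_interval(vals, self.level)
            else:
                lo = hi = np.nan
            rows[metric] = {
                "mean": float(vals.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n_repeats": int(vals.notna().sum()),
            }
        self.aggregate = pd.DataFrame(rows).T


def repeated_holdout_cv(
    features: pd.DataFrame,
    targets: pd.Series,
    config: dict,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> CVResult:
    """Repeated 80/20 shuffle-split evaluation of a configuration.

    Each repeat reshuffles, fits on the training fraction and scores the
    held-out fraction with Spearman ρ, R² and RMSE.  Per-repeat seeds derive
    deterministically from the master seed.  A repeat whose held-out targets
    are constant has an undefined Spearman ρ, recorded as NaN (never zero).
    """
    X = features.to_numpy(float)
    y = targets.to_numpy(float)
    if len(y) < 10:
        raise ConfigurationError("repeated hold-out CV needs at least 10 genes")
    rows = []
    for r in range(n_repeats):
        rs = derive_int_seed(seed, 100, r)
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_fraction, random_state=rs)
        rf = _make_rf(config, derive_int_seed(seed, 101, r))
        rf.fit(X_tr, y_tr)
        pred = rf.predict(X_te)
        if np.ptp(y_te) == 0 or np.ptp(pred) == 0:
            rho = np.nan
        else:
            rho = float(stats.spearmanr(y_te, pred).statistic)
        rows.append(
            {
                "repeat": r,
                "spearman": rho,
                "r2": float(r2_score(y_te, pred)),
                "rmse": float(np.sqrt(mean_squared_error(y_te, pred))),
            }
        )
    return CVResult(pd.DataFrame(rows))


def fit_final_and_predict(
    features: pd.DataFrame,
    targets: pd.Series,
    config: dict,
    predict_features: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[RandomForestRegressor, pd.Series]:
    """Fit on all genes with targets; predict for every gene in the table.

    Predictions are clipped to [0, 1] (the AUROC domain).
    """
    if predict_features is None:
        predict_features = features
    if list(predict_features.columns) != list(features.columns):
        raise SchemaError("feature schema mismatch between fit and predict tables")
    rf = _make_rf(config, derive_int_seed(seed, 7))
    rf.fit(features.to_numpy(float), targets.to_numpy(float))
    pred = np.clip(rf.predict(predict_features.to_numpy(float)), 0.0, 1.0)
    return rf, pd.Series(pred, index=predict_features.index, name="predicted_auroc")


class AurocMetaModel:
    """Per-VEP AUROC regression model (Model half of the Model/Results pair).

    Parameters
    ----------
    features
        Gene × feature table (numeric; impute upstream).
    target
        Per-gene AUROC for one VEP.  Genes with an undefined (NaN) target
        are excluded from fitting but still receive final predictions.
    vep_name
        Label carried through reports.
    spec
        Hyperparameter search space; ``spec.seed`` is the master seed for
        the whole tune → CV → fit pipeline.
    """

    def __init__(self, features: pd.DataFrame, target: pd.Series,
                 vep_name: str = "VEP", spec: HyperparamSpec | None = None) -> None:
        self.features = features
        self.vep_name = vep_name
        self.spec = spec or HyperparamSpec()
        target = target.reindex(features.index)
        self.target = target[target.notna()]
        self.train_features = features.loc[self.target.index]

    @classmethod
    def from_performance(cls, features: pd.DataFrame, performances: pd.DataFrame,
                         vep: str, spec: HyperparamSpec | None = None) -> "AurocMetaModel":
        """Build from a per-gene performance table (one row per gene × VEP)."""
        target = (
            performances[performances["vep"] == vep]
            .set_index("gene_id")["auroc"]
        )
        return cls(features, target, vep_name=vep, spec=spec)

    def fit(self, n_repeats: int = 100, test_fraction: float = 0.2,
            tune: bool = True, config: dict | None = None) -> "AurocMetaModelResults":
        """Tune (optional), cross-validate, and fit the final model."""
        if config is None:
            if tune:
                config, trials = tune_hyperparameters(self.train_features, self.target, self.spec)
            else:
                config = {
                    "n_estimators": 300, "max_depth": 16, "max_features": 0.5,
                    "min_samples_leaf": 2, "min_samples_split": 4,
                }
                trials = pd.DataFrame()
        else:
            trials = pd.DataFrame()
        cv = repeated_holdout_cv(
            self.train_features, self.target, config,
            n_repeats=n_repeats, test_fraction=test_fraction, seed=self.spec.seed,
        )
        estimator, predictions = fit_final_and_predict(
            self.train_features, self.target, config,
            predict_features=self.features, seed=self.spec.seed,
        )
        return AurocMetaModelResults(self, config, trials, cv, estimator, predictions)


class AurocMetaModelResults:
    """Estimates, uncertainties and diagnostics of a fitted meta-model."""

    def __init__(self, model: AurocMetaModel, config: dict, trials: pd.DataFrame,
                 cv: CVResult, estimator: RandomForestRegressor,
                 predictions: pd.Series) -> None:
        self.model = model
        self.params = config
        self.trials = trials
        self.cv = cv
        self.estimator = estimator
        self.predictions = predictions

    @property
    def cv_repeats(self) -> pd.DataFrame:
        return self.cv.repeats

    @property
    def cv_aggregate(self) -> pd.DataFrame:
        return self.cv.aggregate

    def predict(self, features: pd.DataFrame) -> pd.Series:
        if list(features.columns) != list(self.model.features.columns):
            raise SchemaError("feature schema mismatch between fit and predict tables")
        pred = np.clip(self.estimator.predict(features.to_numpy(float)), 0.0, 1.0)
        return pd.Series(pred, index=features.index, name="predicted_auroc")

    def shap_values(self, background: pd.DataFrame | None = None,
                    max_background: int = 200) -> pd.DataFrame:
        """Interventional Tree SHAP attributions for every gene in the table."""
        from .explain import compute_shap

        return compute_shap(
            self.estimator, self.model.features,
            background=background, max_background=max_background,
            seed=self.model.spec.seed,
        )

    def summary(self) -> str:
        agg = self.cv.aggregate
        lines = [
            f"AUROC meta-model: {self.model.vep_name}",
            "=" * 46,
            f"genes (with target):     {len(self.model.target)}",
            f"features:                {self.model.features.shape[1]}",
            f"CV repeats:              {agg.loc['spearman', 'n_repeats']:.0f}",
            "",
            "hyperparameters:",
        ]
        lines += [f"  {k:<18} {v}" for k, v in self.params.items()]
        lines += ["", f"{'metric':<10}{'mean':>9}{'95% CI':>24}"]
        for metric in ("spearman", "r2", "rmse"):
            row = agg.loc[metric]
            lines.append(
                f"{metric:<10}{row['mean']:>9.4f}"
                f"{'[' + format(row['ci_low'], '.4f') + ', ' + format(row['ci_high'], '.4f') + ']':>24}"
            )
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """Error-bar plot of the CV aggregate (mean with 95% t-CI)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        agg = self.cv.aggregate.loc[["spearman", "r2"]]
        x = np.arange(len(agg))
        err = np.vstack([agg["mean"] - agg["ci_low"], agg["ci_high"] - agg["mean"]])
        ax.errorbar(x, agg["mean"], yerr=err, fmt="o", capsize=4)
        ax.set_xticks(x, agg.index)
        ax.set_ylabel("held-out value")
        ax.set_title(self.model.vep_name)
        return ax
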