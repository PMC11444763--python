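"""Binding-affinity regression and thermodynamic label conversion.

Experimental inhibition constants (Ki or IC50) are converted to binding free
energies with dG = R*T*ln(K), K in mol/l, R = 1.987e-3 kcal/(mol*K).  A
regression model (linear, random forest, or gradient boosting) maps molecular
descriptor vectors to dG; performance is reported as RMSE plus Pearson and
Spearman correlations, with uncertainties from a paired nonparametric
bootstrap.
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .chem_library import CompoundRecord, Library

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ki_to_dg",
    "ic50_to_dg",
    "ModelSpec",
    "SplitSpec",
    "MetricsReport",
    "AffinityModel",
    "train",
    "predict",
    "evaluate",
    "select_top",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3


def ki_to_dg(ki: float, T: float = 300.0) -> float:
    """Binding free energy R*T*ln(Ki) in kcal/mol from Ki in mol/l.

    Negative for sub-molar constants; strictly increasing in ``ki``.
    """
    if not ki > 0:
        raise ValueError(f"Ki must be positive (molar), got {ki}")
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return GAS_CONSTANT_KCAL * T * math.log(ki)


def ic50_to_dg(ic50: float, T: float = 300.0) -> float:
    """Binding free energy R*T*ln(IC50) in kcal/mol from IC50 in mol/l.

    Same functional form as :func:`ki_to_dg`; kept separate so call sites
    document which constant they hold.
    """
    return ki_to_dg(ic50, T)


@dataclass(frozen=True)
class ModelSpec:
    """Regression family, hyperparameters, and the mandatory RNG seed."""

    family: str = "gradient-boosting"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    _FAMILIES = ("linear", "random-forest", "gradient-boosting")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {self._FAMILIES}"
            )


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: ``n_train`` records train, the rest test."""

    n_train: int
    seed: int = 0


@dataclass(frozen=True)
class MetricsReport:
    """Point metrics with bootstrap standard deviations on a held-out set."""

    rmse: float
    pearson_r: float | None
    spearman_rho: float | None
    n: int
    rmse_sd: float | None = None
    pearson_sd: float | None = None
    spearman_sd: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "rmse_sd": self.rmse_sd,
            "pearson_r": self.pearson_r,
            "pearson_sd": self.pearson_sd,
            "spearman_rho": self.spearman_rho,
            "spearman_sd": self.spearman_sd,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


class AffinityModel:
    """A fitted descriptor->dG regressor with its expected feature length."""

    def __init__(self, estimator, feature_dim: int, spec: ModelSpec):
        self.estimator = estimator
        self.feature_dim = int(feature_dim)
        self.spec = spec

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature matrix has dimension {X.shape}, "
                f"model expects (*, {self.feature_dim})"
            )
        return np.asarray(self.estimator.predict(X), dtype=float)

    def save(self, path: str | Path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "AffinityModel":
        with Path(path).open("rb") as fh:
            return pickle.load(fh)


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression(**hp)
    if spec.family == "random-forest":
        from sklearn.ensemble import RandomForestRegressor

        hp.setdefault("n_estimators", 300)
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    # gradient boosting
    from xgboost import XGBRegressor

    hp.setdefault("n_estimators", 300)
    hp.setdefault("max_depth", 5)
    hp.setdefault("learning_rate", 0.1)
    return XGBRegressor(
        random_state=spec.seed, n_jobs=1, tree_method="hist", verbosity=0, **hp
    )


def train(
    spec: ModelSpec,
    library: Library,
    split: SplitSpec,
    n_boot: int = 1000,
) -> tuple[AffinityModel, MetricsReport]:
    """Fit a regressor on a random split and score it on the held-out records.

    Deterministic given ``spec.seed`` and ``split.seed``.  Every training
    record must carry both features and an experimental dG label.
    """
    n_total = len(library)
    if not 0 < split.n_train < n_total:
        raise ValueError(
            f"n_train must be in (0, {n_total}), got {split.n_train}"
        )
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(n_total)
    train_idx, test_idx = order[: split.n_train], order[split.n_train :]

    records = library.records
    missing = [
        records[i].id
        for i in train_idx
        if records[i].dg_exp is None or records[i].features is None
    ]
    if missing:
        raise ValueError(
            f"training records lacking dg_exp or features: {sorted(missing)}"
        )
    X = library.feature_matrix()
    y = np.array(
        [r.dg_exp if r.dg_exp is not None else np.nan for r in records], dtype=float
    )
    est = _make_estimator(spec)
    est.fit(X[train_idx], y[train_idx])
    model = AffinityModel(est, X.shape[1], spec)

    test_ok = np.array([i for i in test_idx if np.isfinite(y[i])], dtype=int)
    pred = model.predict_features(X[test_ok])
    report = evaluate(pred, y[test_ok], n_boot=n_boot, seed=spec.seed)
    return model, report


def predict(model: AffinityModel, library: Library) -> Library:
    """Return a copy of the library with ``dg_pred`` filled for every record."""
    X = library.feature_matrix()
    return library.with_predictions(model.predict_features(X))


def _point_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    if np.std(pred) == 0 or np.std(truth) == 0:
        return rmse, np.nan, np.nan
    pearson = float(stats.pearsonr(pred, truth)[0])
    spearman = float(stats.spearmanr(pred, truth)[0])
    return rmse, pearson, spearman


def evaluate(
    pred: Sequence[float],
    truth: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """RMSE, Pearson R and Spearman rho with paired-bootstrap uncertainties.

    The point metrics are computed on the full vectors; each uncertainty is
    the standard deviation of the metric over ``n_boot`` paired resamples
    drawn with the given seed.  If either vector has zero variance the
    correlations are reported as None (RMSE is still valid); fewer than
    three pairs is an error.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    n = pred.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs for evaluation, got {n}")
    rmse, pearson, spearman = _point_metrics(pred, truth)
    degenerate = not np.isfinite(pearson)
    if degenerate:
        warnings.warn(
            "zero variance in predictions or truth: correlations undefined",
            stacklevel=2,
        )

    rmse_sd = pearson_sd = spearman_sd = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, 3))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot[b] = _point_metrics(pred[idx], truth[idx])
        rmse_sd = float(np.std(boot[:, 0], ddof=1))
        if not degenerate:
            pearson_sd = float(np.nanstd(boot[:, 1], ddof=1))
            spearman_sd = float(np.nanstd(boot[:, 2], ddof=1))
    return MetricsReport(
        rmse=rmse,
        pearson_r=None if degenerate else pearson,
        spearman_rho=None if degenerate else spearman,
        n=int(n),
        rmse_sd=rmse_sd,
        pearson_sd=pearson_sd,
        spearman_sd=spearman_sd,
        n_boot=n_boot,
        seed=seed,
    )


def select_top(
    library: Library | Sequence[CompoundRecord],
    mode: str,
    value: float,
) -> list[CompoundRecord]:
    """Select the strongest-binding predicted compounds.

    ``threshold`` mode keeps records with ``dg_pred`` strictly below
    ``value``; ``top_k`` keeps the ``value`` records with the smallest
    ``dg_pred``.  Both return the selection sorted ascending by ``dg_pred``
    with ties broken lexicographically by id.
    """
    records = list(library.records if isinstance(library, Library) else library)
    missing = [r.id for r in records if r.dg_pred is None]
    if missing:
        raise ValueError(f"records lacking dg_pred: {sorted(missing)}")
    ranked = sorted(records, key=lambda r: (r.dg_pred, r.id))
    if mode == "threshold":
        return [r for r in ranked if r.dg_pred < value]
    if mode == "top_k":
        k = int(value)
        if k < 0 or k > len(ranked):
            raise ValueError(f"top_k k={k} out of range for {len(ranked)} records")
        return ranked[:k]
    raise ValueError(f"unknown selection mode {mode!r}")
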