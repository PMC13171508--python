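"""Morgan-fingerprint QSAR: a ten-regressor suite with hold-out + CV.

Molecules are featurized as folded binary Morgan (circular) fingerprints.
Ten regressors — ridge, lasso, elastic net, random forest, gradient
boosting, extra trees, AdaBoost, SVR, k-NN and XGBoost — are trained on a
common random 80:20 split; 5-fold cross-validation R^2 is computed on the
training partition only, so the held-out rows never leak into model
selection.  Grid-search tuning of the boosted-tree model scores candidate
settings by mean CV R^2 on the training partition and evaluates the winner
once on the untouched test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .dataset import CompoundRecord
from .errors import ConfigurationError, StructureError

#: names in the fixed reporting order
MODEL_NAMES = (
    "Ridge regression",
    "Lasso regression",
    "ElasticNet",
    "Random forest",
    "Gradient boosting",
    "Extra trees",
    "AdaBoost",
    "SVR",
    "KNN regressor",
    "XGBoost regressor",
)

TREE_ENSEMBLES = ("Random forest", "Gradient boosting", "Extra trees",
                  "XGBoost regressor")

#: default grid for boosted-tree tuning
DEFAULT_GRID: Mapping[str, Sequence] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, 7],
    "learning_rate": [0.01, 0.05, 0.1],
    "subsample": [0.8, 1.0],
}


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out and cross-validation layout shared by every model."""

    test_fraction: float = 0.20
    n_folds: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")


@dataclass
class FingerprintMatrix:
    compound_ids: list[str]
    bits: np.ndarray  # n x n_bits, uint8 in {0, 1}
    radius: int
    n_bits: int


@dataclass
class ModelReport:
    model_name: str
    r2_train: float
    r2_test: float
    rmse_test: float
    cv_r2_mean: float
    cv_r2_sd: float
    hyperparameters: dict = field(default_factory=dict)


def featurize(
    records: Sequence[CompoundRecord] | Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
) -> FingerprintMatrix:
    """Folded binary Morgan fingerprints for curated records or SMILES."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ids, rows, bad = [], [], []
    for i, rec in enumerate(records):
        smiles = rec if isinstance(rec, str) else rec.smiles
        cid = f"SMI-{i:05d}" if isinstance(rec, str) else rec.compound_id
        mol = Chem.MolFromSmiles("".join(str(smiles).split()))
        if mol is None:
            bad.append(cid)
            continue
        ids.append(cid)
        rows.append(gen.GetFingerprintAsNumPy(mol))
    if bad:
        raise StructureError(",".join(bad), detail="unparseable SMILES in featurize")
    bits = np.asarray(rows, dtype=np.uint8) if rows else np.zeros((0, n_bits), np.uint8)
    return FingerprintMatrix(compound_ids=ids, bits=bits, radius=radius, n_bits=n_bits)


def build_models(seed: int) -> dict[str, object]:
    """Fresh instances of the ten regressors, single-threaded/deterministic."""
    return {
        "Ridge regression": Ridge(alpha=1.0),
        "Lasso regression": Lasso(alpha=0.01, max_iter=10000),
        "ElasticNet": ElasticNet(alpha=0.01, max_iter=10000),
        "Random forest": RandomForestRegressor(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "Gradient boosting": GradientBoostingRegressor(random_state=seed),
        "Extra trees": ExtraTreesRegressor(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "AdaBoost": AdaBoostRegressor(random_state=seed),
        "SVR": SVR(),
        "KNN regressor": KNeighborsRegressor(n_jobs=1),
        "XGBoost regressor": XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist"
        ),
    }


def make_split(n: int, split: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test index split shared across all models."""
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=split.test_fraction, random_state=split.seed, shuffle=True
    )
    return train_idx, test_idx


def _evaluate(model, X_train, y_train, X_test, y_test, split: SplitSpec,
              name: str, hyperparameters: dict | None = None) -> ModelReport:
    cv = KFold(n_splits=split.n_folds, shuffle=True, random_state=split.seed)
    scores = cross_val_score(clone(model), X_train, y_train, cv=cv,
                             scoring="r2", n_jobs=1)
    model.fit(X_train, y_train)
    pred_train = model.predict(X_train)
    pred_test = model.predict(X_test)
    return ModelReport(
        model_name=name,
        r2_train=float(r2_score(y_train, pred_train)),
        r2_test=float(r2_score(y_test, pred_test)),
        rmse_test=float(np.sqrt(mean_squared_error(y_test, pred_test))),
        cv_r2_mean=float(scores.mean()),
        cv_r2_sd=float(scores.std()),
        hyperparameters=hyperparameters or {},
    )


def train_suite(
    X: FingerprintMatrix,
    y: Sequence[float],
    split: SplitSpec = SplitSpec(),
) -> list[ModelReport]:
    """Train and evaluate all ten regressors on one shared split."""
    y = np.asarray(y, dtype=float)
    n = X.bits.shape[0]
    if n != y.size:
        raise ConfigurationError("X and y lengths differ")
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("y contains non-finite values")
    if n < 20:
        raise ConfigurationError(f"need at least 20 molecules, got {n}")
    train_idx, test_idx = make_split(n, split)
    if train_idx.size < split.n_folds:
        raise ConfigurationError("training partition smaller than fold count")
    Xb = X.bits.astype(np.float64)
    reports = []
    models = build_models(split.seed)
    for name in MODEL_NAMES:
        reports.append(
            _evaluate(models[name], Xb[train_idx], y[train_idx],
                      Xb[test_idx], y[test_idx], split, name)
        )
    return reports


def reports_to_frame(reports: Sequence[ModelReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = r.__dict__.copy()
        d["hyperparameters"] = repr(d["hyperparameters"])
        rows.append(d)
    return pd.DataFrame(rows)


def tune_boosted(
    X: FingerprintMatrix,
    y: Sequence[float],
    split: SplitSpec = SplitSpec(),
    grid: Mapping[str, Sequence] | None = None,
) -> ModelReport:
    """Exhaustive grid search of the boosted-tree model.

    Scored by mean CV R^2 on the training partition; the winning setting is
    refit on the full training partition and evaluated once on the test set.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if not grid:
        raise ConfigurationError("tuning grid must be non-empty")
    base = XGBRegressor(random_state=split.seed, n_jobs=1, verbosity=0,
                        tree_method="hist")
    valid = base.get_params()
    for key in grid:
        if key not in valid:
            raise ConfigurationError(f"unknown XGBoost parameter {key!r} in grid")
    y = np.asarray(y, dtype=float)
    train_idx, test_idx = make_split(X.bits.shape[0], split)
    Xb = X.bits.astype(np.float64)
    cv = KFold(n_splits=split.n_folds, shuffle=True, random_state=split.seed)
    search = GridSearchCV(base, param_grid=grid, cv=cv, scoring="r2", n_jobs=1)
    search.fit(Xb[train_idx], y[train_idx])
    best = search.best_estimator_
    i = int(search.best_index_)
    pred_train = best.predict(Xb[train_idx])
    pred_test = best.predict(Xb[test_idx])
    return ModelReport(
        model_name="XGBoost regressor (tuned)",
        r2_train=float(r2_score(y[train_idx], pred_train)),
        r2_test=float(r2_score(y[test_idx], pred_test)),
        rmse_test=float(np.sqrt(mean_squared_error(y[test_idx], pred_test))),
        cv_r2_mean=float(search.cv_results_["mean_test_score"][i]),
        cv_r2_sd=float(search.cv_results_["std_test_score"][i]),
        hyperparameters=dict(search.best_params_),
    )


def save_model(path: str | Path, model, X: FingerprintMatrix,
               model_name: str = "") -> None:
    """Persist a fitted model with its fingerprint parameters embedded."""
    joblib.dump(
        {"model": model, "radius": X.radius, "n_bits": X.n_bits,
         "model_name": model_name},
        path,
    )


def load_model(path: str | Path) -> dict:
    bundle = joblib.load(path)
    for key in ("model", "radius", "n_bits"):
        if key not in bundle:
            raise ConfigurationError(f"model bundle missing {key!r}")
    return bundle


def predict_smiles(bundle: dict, smiles_list: Sequence[str]) -> np.ndarray:
    """Apply a saved model bundle to new SMILES strings."""
    fp = featurize(list(smiles_list), radius=bundle["radius"],
                   n_bits=bundle["n_bits"])
    return np.asarray(bundle["model"].predict(fp.bits.astype(np.float64)),
                      dtype=float)
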