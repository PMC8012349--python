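"""Nested cross-validation benchmark of regression algorithms against a
sugars+acids baseline.

Each iteration draws one random 90/10 train/test split (shared by every
algorithm, so comparisons are paired), tunes hyperparameters by 5-fold CV
inside the 90%, refits on the full training split and scores R^2 both on the
pooled inner-CV predictions and on the held-out 10%.  The baseline is an
ordinary least-squares fit restricted to sucrose, glucose, fructose, malic
and citric acid under the identical split scheme.  R^2 is 1 - SS_res/SS_tot
with SS_tot centered on the evaluation fold's own mean (a config switch
allows training-mean centering instead).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import BayesianRidge, Lasso, LinearRegression
from sklearn.model_selection import KFold, cross_val_predict

log = logging.getLogger(__name__)

BASELINE_FEATURES = ("sucrose", "glucose", "fructose", "malic_acid", "citric_acid")

ALGORITHM_NAMES = (
    "random_forest",
    "bayes_glm",
    "glm",
    "componentwise_boosting",
    "lasso",
    "pls",
)


class ComponentwiseBoosting(BaseEstimator, RegressorMixin):
    """L2 boosting with componentwise linear base learners.

    Each step fits every single predictor to the current residual by least
    squares, takes the one with the largest SSE reduction, and adds a
    shrunken (``learning_rate``) copy of that fit to the ensemble.  The
    result is a sparse linear model akin to slow forward stagewise
    regression.
    """

    def __init__(self, n_steps: int = 100, learning_rate: float = 0.1):
        self.n_steps = n_steps
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.intercept_ = y.mean()
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        ss = (Xc**2).sum(axis=0)
        ss[ss == 0] = np.inf  # constant columns can never be picked
        coef = np.zeros(X.shape[1])
        r = y - self.intercept_
        for _ in range(self.n_steps):
            b = Xc.T @ r / ss
            gain = b**2 * ss
            j = int(np.argmax(gain))
            if gain[j] <= 0:
                break
            step = self.learning_rate * b[j]
            coef[j] += step
            r -= step * Xc[:, j]
        self.coef_ = coef
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + (X - self.x_mean_) @ self.coef_


def default_grids() -> dict:
    return {
        "random_forest": {"max_features": ["sqrt", 0.33]},
        "bayes_glm": {},
        "glm": {},
        "componentwise_boosting": {"n_steps": [100, 300]},
        "lasso": {"alpha": [0.01, 0.03, 0.1, 0.3]},
        "pls": {"n_components": [2, 3, 5]},
    }


def _make_estimator(name: str, params: dict, seed: int):
    if name == "random_forest":
        return RandomForestRegressor(
            n_estimators=200, random_state=seed, n_jobs=1, **params
        )
    if name == "bayes_glm":
        return BayesianRidge(**params)
    if name == "glm":
        return LinearRegression(**params)
    if name == "componentwise_boosting":
        return ComponentwiseBoosting(**params)
    if name == "lasso":
        return Lasso(max_iter=20_000, **params)
    if name == "pls":
        return PLSRegression(scale=False, **params)
    raise ValueError(f"unknown algorithm {name!r}")


def _param_grid(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    combos = [{}]
    for k in keys:
        combos = [c | {k: v} for c in combos for v in grid[k]]
    return combos


@dataclass
class BenchmarkConfig:
    """Benchmark settings; iteration splits derive from ``seed`` substreams."""

    algorithms: tuple = ALGORITHM_NAMES
    test_fraction: float = 0.10
    inner_folds: int = 5
    iterations: int = 100
    grids: dict = field(default_factory=default_grids)
    seed: int = 0
    r2_centering: str = "test"  # or "train"

    def validate(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHM_NAMES)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.r2_centering not in ("test", "train"):
            raise ValueError("r2_centering must be 'test' or 'train'")


@dataclass
class BenchmarkResult:
    """Mean/SD of nested-CV and test R^2 per algorithm (baseline included)."""

    table: pd.DataFrame            # index algorithm; mean/sd columns
    per_iteration: pd.DataFrame    # long: iteration, algorithm, cv_r2, test_r2
    split_hashes: list             # one hash per iteration (paired design)
    config: BenchmarkConfig
    response: str = ""

    def summary(self) -> str:
        lines = [f"Nested-CV benchmark ({self.response or 'response'}), "
                 f"{self.config.iterations} iterations"]
        lines.append(self.table.round(4).to_string())
        return "\n".join(lines)


def _r2(y_true, y_pred, train_mean=None, centering="test") -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    center = y_true.mean() if centering == "test" or train_mean is None else train_mean
    ss_tot = ((y_true - center) ** 2).sum()
    if ss_tot == 0:
        return np.nan
    return 1.0 - ((y_true - y_pred) ** 2).sum() / ss_tot


class NestedCVBenchmark:
    """Model object: algorithms x iterations nested-CV evaluation of
    predicting ``y`` from ``X``, with the sugars+acids baseline."""

    def __init__(self, X: pd.DataFrame, y: pd.Series, config: BenchmarkConfig | None = None,
                 response: str = "", include_baseline: bool = True):
        config = config or BenchmarkConfig()
        config.validate()
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("X must be fully numeric/complete post-harmonization")
        if len(X) < 20:
            raise ValueError("need n >= 20 samples")
        self.X = X
        self.y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        self.config = config
        self.response = response
        self.include_baseline = include_baseline
        if include_baseline:
            missing = [c for c in BASELINE_FEATURES if c not in X.columns]
            if missing:
                raise ValueError(f"baseline columns missing from X: {missing}")

    def _iteration_split(self, it: int):
        rng = np.random.default_rng([self.config.seed, it])
        n = len(self.X)
        perm = rng.permutation(n)
        n_test = max(1, int(round(self.config.test_fraction * n)))
        return perm[n_test:], perm[:n_test], rng

    def _evaluate(self, name, train_idx, test_idx, inner_seed):
        Xtr = self.X.iloc[train_idx].to_numpy()
        ytr = self.y.iloc[train_idx].to_numpy()
        Xte = self.X.iloc[test_idx].to_numpy()
        yte = self.y.iloc[test_idx].to_numpy()
        kf = KFold(self.config.inner_folds, shuffle=True, random_state=inner_seed)
        best, best_score = None, -np.inf
        for params in _param_grid(self.config.grids.get(name, {})):
            est = _make_estimator(name, params, inner_seed)
            preds = cross_val_predict(clone(est), Xtr, ytr, cv=kf).ravel()
            score = _r2(ytr, preds, centering="test")
            if score > best_score:
                best, best_score = est, score
        cv_r2 = best_score
        fitted = clone(best).fit(Xtr, ytr)
        test_pred = np.asarray(fitted.predict(Xte)).ravel()
        test_r2 = _r2(yte, test_pred, train_mean=ytr.mean(),
                      centering=self.config.r2_centering)
        return cv_r2, test_r2

    def fit(self) -> BenchmarkResult:
        cfg = self.config
        rows, hashes = [], []
        for it in range(cfg.iterations):
            train_idx, test_idx, rng = self._iteration_split(it)
            inner_seed = int(rng.integers(2**31 - 1))
            h = hashlib.sha1(np.sort(test_idx).tobytes()).hexdigest()[:12]
            hashes.append(h)
            if self.y.iloc[test_idx].nunique() <= 1:
                log.warning("iteration %d: constant test response; skipped", it)
                continue
            for name in cfg.algorithms:
                cv_r2, test_r2 = self._evaluate(name, train_idx, test_idx, inner_seed)
                rows.append((it, name, cv_r2, test_r2))
            if self.include_baseline:
                cv_r2, test_r2 = self._baseline_eval(train_idx, test_idx, inner_seed)
                rows.append((it, "baseline_sugars_acids", cv_r2, test_r2))
        per_it = pd.DataFrame(
            rows, columns=["iteration", "algorithm", "cv_r2", "test_r2"]
        )
        agg = per_it.groupby("algorithm").agg(
            cv_r2_mean=("cv_r2", "mean"), cv_r2_sd=("cv_r2", "std"),
            test_r2_mean=("test_r2", "mean"), test_r2_sd=("test_r2", "std"),
            n_iterations=("iteration", "count"),
        )
        order = [a for a in ("baseline_sugars_acids",) + tuple(cfg.algorithms)
                 if a in agg.index]
        return BenchmarkResult(
            table=agg.loc[order], per_iteration=per_it,
            split_hashes=hashes, config=cfg, response=self.response,
        )

    def _baseline_eval(self, train_idx, test_idx, inner_seed):
        Xb = self.X[list(BASELINE_FEATURES)]
        Xtr, Xte = Xb.iloc[train_idx].to_numpy(), Xb.iloc[test_idx].to_numpy()
        ytr = self.y.iloc[train_idx].to_numpy()
        yte = self.y.iloc[test_idx].to_numpy()
        kf = KFold(self.config.inner_folds, shuffle=True, random_state=inner_seed)
        preds = cross_val_predict(LinearRegression(), Xtr, ytr, cv=kf)
        cv_r2 = _r2(ytr, preds, centering="test")
        fitted = LinearRegression().fit(Xtr, ytr)
        test_r2 = _r2(yte, fitted.predict(Xte), train_mean=ytr.mean(),
                      centering=self.config.r2_centering)
        return cv_r2, test_r2


def baseline_sugars_acids(
    X: pd.DataFrame, y: pd.Series, config: BenchmarkConfig | None = None,
    features: tuple = BASELINE_FEATURES,
) -> pd.Series:
    """Sugars+acids OLS baseline row under the shared split scheme.

    ``features`` must be exactly the five named sugar/acid columns; passing
    anything else (e.g. appended volatile columns) is rejected.
    """
    if tuple(features) != BASELINE_FEATURES:
        raise ValueError(
            "the baseline is restricted to sucrose/glucose/fructose/"
            "malic_acid/citric_acid; extra features are not allowed"
        )
    bench = NestedCVBenchmark(
        X, y, config=config, include_baseline=True
    )
    cfg = bench.config
    rows = []
    for it in range(cfg.iterations):
        train_idx, test_idx, rng = bench._iteration_split(it)
        inner_seed = int(rng.integers(2**31 - 1))
        if bench.y.iloc[test_idx].nunique() <= 1:
            continue
        rows.append(bench._baseline_eval(train_idx, test_idx, inner_seed))
    arr = np.array(rows)
    return pd.Series(
        {
            "cv_r2_mean": arr[:, 0].mean(), "cv_r2_sd": arr[:, 0].std(ddof=1),
            "test_r2_mean": arr[:, 1].mean(), "test_r2_sd": arr[:, 1].std(ddof=1),
            "n_iterations": len(arr),
        },
        name="baseline_sugars_acids",
    )
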