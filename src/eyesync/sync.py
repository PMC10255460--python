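"""Synchronization scoring: regression of EEG band ratios on eye band ratios.

For each (eye feature, EEG channel, band, session) triple, a regression
model is fit on the first 70% of aligned windows and evaluated on the held
out 30%; the test-set R² is the synchronization score (MAE and MSE are
reported alongside).  Five model families are supported with fixed
hyperparameters: Bayesian ridge, ordinary least squares, elastic net, RBF
support-vector regression and gradient boosting.

A chronological split is the default: with 180 s windows sliding by 1 s,
adjacent windows share ~99% of their samples, so a random split would place
near-duplicates of training windows in the test set and inflate R².  The
random mode is retained (``split_mode="random"``) for comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import BayesianRidge, ElasticNet, LinearRegression
from sklearn.metrics import explained_variance_score
from sklearn.svm import SVR

from .spectral import BandRatioSeries, align_ratio_series

MODEL_ORDER = ("bayesian_ridge", "linear", "elastic_net", "svr", "gbr")

#: Fixed hyperparameters per model family.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "bayesian_ridge": dict(alpha_1=1e-6, alpha_2=1e-6, lambda_1=1e-6,
                           lambda_2=1e-6, max_iter=300, tol=1e-3,
                           fit_intercept=True),
    "linear": dict(fit_intercept=True),
    "elastic_net": dict(alpha=1.0, l1_ratio=0.5, max_iter=1000, tol=1e-4,
                        fit_intercept=True, selection="cyclic"),
    "svr": dict(kernel="rbf", C=1.0, epsilon=0.1, gamma="auto", degree=3,
                coef0=0.0, tol=1e-3, shrinking=True, cache_size=200),
    "gbr": dict(n_estimators=100, learning_rate=0.1, max_depth=3,
                loss="squared_error", subsample=1.0, alpha=0.9,
                min_samples_split=2, min_samples_leaf=1),
}


# ---------------------------------------------------------------------------
# evaluation metrics (the three formulas scored on the test set)
# ---------------------------------------------------------------------------

def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error: (1/m) sum |h(x_i) - y_i|."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.abs(y_pred - y_true).sum() / len(y_true))

def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error: (1/n) sum (y_i - yhat_i)^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(((y_true - y_pred) ** 2).sum() / len(y_true))

def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot.

    Negative values are reported as-is (the model did worse than the mean
    predictor).  Raises when ``y_true`` has zero variance (R² undefined).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ZeroDivisionError("R^2 undefined: zero-variance target")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class RegressionSpec:
    """One model family with fixed hyperparameters and split policy."""

    model: str = "gbr"
    hyperparameters: dict = field(default_factory=dict)
    split_fraction: float = 0.7
    split_mode: str = "chronological"  # chronological | random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_ORDER:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.split_mode not in ("chronological", "random"):
            raise ValueError(f"unknown split mode {self.split_mode!r}")
        params = dict(DEFAULT_HYPERPARAMETERS[self.model])
        params.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", params)

    def make_estimator(self):
        p = self.hyperparameters
        if self.model == "bayesian_ridge":
            return BayesianRidge(**p)
        if self.model == "linear":
            return LinearRegression(**p)
        if self.model == "elastic_net":
            return ElasticNet(random_state=self.seed, **p)
        if self.model == "svr":
            return SVR(**p)
        return GradientBoostingRegressor(random_state=self.seed, **p)


def default_specs(seed: int = 0, **kwargs) -> dict[str, RegressionSpec]:
    """The five model specs with their fixed hyperparameters."""
    return {m: RegressionSpec(model=m, seed=seed, **kwargs)
            for m in MODEL_ORDER}


@dataclass
class SyncResult:
    """Held-out regression evaluation of one feature/channel/band triple."""

    eye_feature: str
    channel: str
    band: str
    subject_id: int
    video_id: int
    condition: str
    quadrant: str
    model: str
    r2: float
    mae: float
    mse: float
    n_train: int
    n_test: int
    undefined: bool = False


def split_windows(n_windows: int, fraction: float = 0.7,
                  mode: str = "chronological", seed: int = 0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive 7:3 train/test split of window indices.

    ``chronological`` puts the first ``floor(n * fraction)`` windows in the
    training set; ``random`` shuffles with the given seed first.
    """
    if n_windows < 10:
        raise ValueError(f"need >= 10 paired windows, got {n_windows}")
    n_train = int(np.floor(n_windows * fraction))
    idx = np.arange(n_windows)
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(idx)
    elif mode != "chronological":
        raise ValueError(f"unknown split mode {mode!r}")
    return idx[:n_train], idx[n_train:]


def fit_sync(x: np.ndarray, y: np.ndarray, spec: RegressionSpec,
             **meta) -> SyncResult:
    """Fit ``y = f(x)`` on the training windows and score the held-out set.

    ``x`` and ``y`` are aligned single-band ratio columns (eye feature and
    EEG channel respectively).  A zero-variance test target leaves R²
    undefined; the result is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be aligned (equal length)")
    train, test = split_windows(len(x), spec.split_fraction, spec.split_mode,
                                spec.seed)
    est = spec.make_estimator()
    est.fit(x[train, None], y[train])
    pred = est.predict(x[test, None])
    defaults = dict(eye_feature="", channel="", band="", subject_id=0,
                    video_id=0, condition="", quadrant="", model=spec.model)
    defaults.update(meta)
    try:
        r2 = r2_score(y[test], pred)
        undefined = False
    except ZeroDivisionError:
        r2 = np.nan
        undefined = True
    return SyncResult(r2=r2, mae=mae(y[test], pred), mse=mse(y[test], pred),
                      n_train=len(train), n_test=len(test),
                      undefined=undefined, **defaults)


def evaluate_models(x: np.ndarray, y: np.ndarray,
                    specs: dict[str, RegressionSpec] | None = None,
                    n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Compare model families over repeated random 7:3 splits.

    Returns one row per model with the mean explained variance, MAE, MSE
    and R² score across repeats (distinct split seeds), the comparison the
    model-selection step consumes.
    """
    if specs is None:
        specs = default_specs(seed=seed)
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    rows = []
    for name, spec in specs.items():
        evs, maes, mses, r2s = [], [], [], []
        for r in range(n_repeats):
            rspec = replace(spec, split_mode="random", seed=seed + r)
            x_arr = np.asarray(x, dtype=float)
            y_arr = np.asarray(y, dtype=float)
            train, test = split_windows(len(x_arr), rspec.split_fraction,
                                        "random", rspec.seed)
            est = rspec.make_estimator()
            est.fit(x_arr[train, None], y_arr[train])
            pred = est.predict(x_arr[test, None])
            evs.append(explained_variance_score(y_arr[test], pred))
            maes.append(mae(y_arr[test], pred))
            mses.append(mse(y_arr[test], pred))
            r2s.append(r2_score(y_arr[test], pred))
        rows.append((name, float(np.mean(evs)), float(np.mean(maes)),
                     float(np.mean(mses)), float(np.mean(r2s))))
    return pd.DataFrame(rows, columns=["model", "ev", "mae", "mse",
                                       "r2_score"])


def select_best_model(table: pd.DataFrame) -> str:
    """Model with the highest R² score; ties break on lower MSE, then on
    the fixed model-name order."""
    if table.empty:
        raise ValueError("empty model comparison table")
    t = table.dropna(subset=["r2_score"])
    if t.empty:
        raise ValueError("all models have undefined metrics")
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    t = t.assign(_order=t["model"].map(order))
    t = t.sort_values(by=["r2_score", "mse", "_order"],
                      ascending=[False, True, True], kind="stable")
    return str(t.iloc[0]["model"])


def run_sync_matrix(eye_ratios: dict[str, BandRatioSeries],
                    eeg_ratios: dict[str, BandRatioSeries],
                    spec: RegressionSpec,
                    label=None) -> list[SyncResult]:
    """Score every (eye feature x channel x band) triple of one session.

    4 features x 18 channels x 4 bands = 288 results for the full montage;
    triples with an undefined R² (zero-variance target) are flagged, not
    dropped.
    """
    meta = {}
    if label is not None:
        meta = dict(subject_id=label.subject_id, video_id=label.video_id,
                    condition=label.condition, quadrant=label.quadrant)
    results = []
    for feature, ers in eye_ratios.items():
        for channel, crs in eeg_ratios.items():
            _, xr, yr = align_ratio_series(ers, crs)
            for j, band in enumerate(ers.scheme.names):
                results.append(fit_sync(
                    xr[:, j], yr[:, j], spec, eye_feature=feature,
                    channel=channel, band=band, **meta))
    return results


def results_to_frame(results: list[SyncResult]) -> pd.DataFrame:
    cols = ["subject_id", "video_id", "condition", "quadrant", "eye_feature",
            "channel", "band", "model", "r2", "mae", "mse", "n_train",
            "n_test", "undefined"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results],
                        columns=cols)
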