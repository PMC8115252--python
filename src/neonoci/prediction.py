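"""Prediction of noxious-evoked response amplitudes from non-noxious features.

The estimator is a linear support vector regression (epsilon-insensitive
loss, ridge penalty) evaluated by leave-one-out cross-validation (LOO-CV).
Nuisance structure is removed by *cross-validated confound regression*:
within every training fold, each feature column and the response are
residualised on their confound sets by OLS fit on training rows only, and
the held-out subject is residualised with those training coefficients —
no held-out information ever reaches the fit.  Features are z-scored on
training statistics inside each fold so the ridge penalty is
scale-comparable across features.  The regularisation strength C is chosen
per fold by an inner LOO grid search minimising mean squared error, with
ties broken toward the smallest C (the stronger penalty).

Out-of-fold performance is summarised by the sums-of-squares coefficient of
determination R^2 = 1 - SS_res/SS_tot (reported as-is, possibly negative),
the root mean squared error, and Spearman's rank correlation.  Significance
is assessed by one-tailed permutation tests that shuffle the *raw* response
before any adjustment and rerun the entire pipeline — confound regression,
standardisation and grid search included — so the null preserves the
confound structure.

The statsmodels-style surface is :class:`AmplitudePredictionModel` /
:class:`PredictionResults`; the module-level functions expose the same
computations for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVR

from .permutation import PermResult, mc_p

__all__ = [
    "PredictionConfig",
    "PredictionResults",
    "AmplitudePredictionModel",
    "cv_confound_regress",
    "loocv_svr",
    "prediction_metrics",
    "perm_prediction_test",
    "univariate_screens",
    "apply_model",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Hyperparameters of the LOO-CV linear SVR pipeline."""

    epsilon: float = 0.1
    c_grid: tuple = (0.001, 0.01, 0.1, 1.0)
    standardize_features: bool = True
    max_iter: int = 200000
    tol: float = 1e-6
    permute_raw_response: bool = True   # shuffle y before confound adjustment

    def __post_init__(self):
        if len(self.c_grid) == 0:
            raise ValueError("c_grid must be nonempty")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid entries must be positive")
        if list(self.c_grid) != sorted(self.c_grid):
            raise ValueError("c_grid must be ascending")


# ---------------------------------------------------------------------------
# Cross-validated confound regression
# ---------------------------------------------------------------------------

def _with_intercept(Z: Optional[np.ndarray], n: int) -> np.ndarray:
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        return np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([Z, np.ones(n)])


def _residualize_fold(A: np.ndarray, Z: Optional[np.ndarray],
                      train: np.ndarray) -> np.ndarray:
    """Residualise columns of A on [Z, 1] using training-row coefficients."""
    A = np.asarray(A, dtype=float)
    squeeze = A.ndim == 1
    if squeeze:
        A = A[:, None]
    Z1 = _with_intercept(Z, A.shape[0])
    Ztr = Z1[train]
    if np.linalg.matrix_rank(Ztr) < Z1.shape[1]:
        raise ValueError("confound matrix rank deficient on training fold")
    beta, _, _, _ = np.linalg.lstsq(Ztr, A[train], rcond=None)
    resid = A - Z1 @ beta
    return resid[:, 0] if squeeze else resid


def cv_confound_regress(X: np.ndarray, y: np.ndarray,
                        conf_X: Optional[np.ndarray],
                        conf_y: Optional[np.ndarray],
                        folds: Sequence[tuple]) -> list:
    """Fold-wise confound adjustment of features and response.

    For every (train, test) fold, each column of X (and y) is regressed by
    OLS on its confounds plus intercept using *training rows only*, and
    residuals for both train and test rows are formed with those training
    coefficients.  With no confounds this reduces to train-mean centring.

    Returns a list of dicts with keys ``train``, ``test``, ``X_train``,
    ``X_test``, ``y_train``, ``y_test``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    for train, test in folds:
        train = np.asarray(train, dtype=int)
        test = np.asarray(test, dtype=int)
        Xr = _residualize_fold(X, conf_X, train)
        yr = _residualize_fold(y, conf_y, train)
        out.append({
            "train": train, "test": test,
            "X_train": Xr[train], "X_test": Xr[test],
            "y_train": yr[train], "y_test": yr[test],
        })
    return out


# ---------------------------------------------------------------------------
# LOO-CV SVR
# ---------------------------------------------------------------------------

def _svr(C: float, config: PredictionConfig) -> LinearSVR:
    return LinearSVR(C=C, epsilon=config.epsilon, loss="epsilon_insensitive",
                     fit_intercept=True, tol=config.tol,
                     max_iter=config.max_iter, random_state=0)


def _standardizer(Xtr: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _select_c(Xtr: np.ndarray, ytr: np.ndarray, config: PredictionConfig) -> float:
    """Inner LOO grid search over C minimising MSE; ties -> smallest C.

    The search operates on the outer fold's already-adjusted, standardized
    training data (the adjustment is not re-fit per inner split).
    """
    if len(config.c_grid) == 1:
        return float(config.c_grid[0])
    m = Xtr.shape[0]
    best_c, best_mse = None, np.inf
    idx = np.arange(m)
    for C in config.c_grid:
        err = np.empty(m)
        for j in range(m):
            tr = idx != j
            model = _svr(C, config).fit(Xtr[tr], ytr[tr])
            err[j] = model.predict(Xtr[j][None, :])[0] - ytr[j]
        mse = float(np.mean(err ** 2))
        if mse < best_mse - 1e-15:      # strict improvement; ties keep smaller C
            best_mse, best_c = mse, float(C)
    return best_c


def _loocv(X: np.ndarray, y: np.ndarray, conf_X, conf_y,
           config: PredictionConfig):
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOO-CV")
    folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    adjusted = cv_confound_regress(X, y, conf_X, conf_y, folds)
    y_pred = np.empty(n)
    y_adj = np.empty(n)
    chosen = np.empty(n)
    for fold in adjusted:
        i = int(fold["test"][0])
        Xtr, ytr = fold["X_train"], fold["y_train"]
        if ytr.std() == 0:
            raise ValueError("constant adjusted response in a training fold")
        if config.standardize_features:
            mu, sd = _standardizer(Xtr)
        else:
            mu, sd = 0.0, 1.0
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (fold["X_test"] - mu) / sd
        C = _select_c(Xtr_s, ytr, config)
        model = _svr(C, config).fit(Xtr_s, ytr)
        y_pred[i] = model.predict(Xte_s)[0]
        y_adj[i] = fold["y_test"][0]
        chosen[i] = C
    return y_pred, y_adj, chosen


def prediction_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> dict:
    """Sums-of-squares R^2 (possibly negative), RMSE, and Spearman rho."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("length mismatch")
    ss_tot = np.sum((y_obs - y_obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant observed response")
    ss_res = np.sum((y_obs - y_pred) ** 2)
    if np.ptp(y_pred) == 0:
        rho = 0.0          # constant prediction carries no rank information
    else:
        rho = stats.spearmanr(y_obs, y_pred).statistic
    return {
        "r2": float(1.0 - ss_res / ss_tot),
        "rmse": float(np.sqrt(np.mean((y_obs - y_pred) ** 2))),
        "spearman": float(rho),
    }


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class AmplitudePredictionModel:
    """LOO-CV linear SVR prediction of response amplitudes.

    Parameters
    ----------
    X : (n, k) feature matrix (e.g. resting-state network amplitudes).
    y : (n,) response (e.g. overall noxious-evoked response amplitudes).
    conf_X, conf_y : optional confound matrices for the features and the
        response; adjustment is cross-validated (see module docstring).
    config : :class:`PredictionConfig`.
    """

    def __init__(self, X, y, conf_X=None, conf_y=None,
                 config: Optional[PredictionConfig] = None,
                 feature_names: Optional[Sequence[str]] = None,
                 subject_ids: Optional[Sequence[str]] = None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        self.conf_X = None if conf_X is None else np.asarray(conf_X, dtype=float)
        self.conf_y = None if conf_y is None else np.asarray(conf_y, dtype=float)
        self.config = config or PredictionConfig()
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{j}" for j in range(self.X.shape[1])])
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"sub-{i:03d}" for i in range(self.y.size)])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       features: Sequence[str],
                       feature_confounds: Sequence[str] = (),
                       response_confounds: Sequence[str] = (),
                       config: Optional[PredictionConfig] = None,
                       subject_col: str = "subject_id") -> "AmplitudePredictionModel":
        ids = df[subject_col].astype(str).tolist() if subject_col in df else None
        return cls(
            df[list(features)].to_numpy(float),
            df[response].to_numpy(float),
            conf_X=df[list(feature_confounds)].to_numpy(float) if feature_confounds else None,
            conf_y=df[list(response_confounds)].to_numpy(float) if response_confounds else None,
            config=config, feature_names=list(features), subject_ids=ids,
        )

    def fit(self) -> "PredictionResults":
        y_pred, y_adj, chosen = _loocv(self.X, self.y, self.conf_X,
                                       self.conf_y, self.config)
        return PredictionResults(self, y_pred, y_adj, chosen)


class PredictionResults:
    """Out-of-fold predictions, adjusted responses and performance metrics."""

    def __init__(self, model: AmplitudePredictionModel, y_pred, y_adj, chosen_c):
        self.model = model
        self.y_pred = np.asarray(y_pred, dtype=float)
        self.y_adj = np.asarray(y_adj, dtype=float)
        self.chosen_c = np.asarray(chosen_c, dtype=float)
        self.metrics = prediction_metrics(self.y_adj, self.y_pred)
        self.perm_results: dict = {}

    @property
    def r2(self) -> float:
        return self.metrics["r2"]

    @property
    def rmse(self) -> float:
        return self.metrics["rmse"]

    @property
    def spearman(self) -> float:
        return self.metrics["spearman"]

    def permutation_test(self, n_perm: int = 10000, seed: int = 0) -> dict:
        """Full-pipeline permutation test; see :func:`perm_prediction_test`."""
        self.perm_results = perm_prediction_test(
            self.model.X, self.model.y, self.model.conf_X, self.model.conf_y,
            self.model.config, n_perm=n_perm, seed=seed, observed=self.metrics)
        return self.perm_results

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.model.subject_ids,
            "y_adj": self.y_adj,
            "y_pred": self.y_pred,
            "fold_C": self.chosen_c,
        })

    def summary(self) -> str:
        lines = [
            "LOO-CV linear SVR prediction",
            "=" * 44,
            f"subjects: {self.y_adj.size}   features: {self.model.X.shape[1]}",
            f"epsilon: {self.model.config.epsilon}   "
            f"C grid: {list(self.model.config.c_grid)}",
            f"R^2 (sums of squares): {self.r2: .4f}",
            f"RMSE:                  {self.rmse: .4f}",
            f"Spearman rho:          {self.spearman: .4f}",
        ]
        for name, pr in self.perm_results.items():
            lines.append(f"perm p ({name}): {pr.p:.4f}  [{pr.convention}, B={pr.n_perm}]")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed (adjusted) vs predicted amplitudes with the y = x line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(self.y_adj, self.y_pred, s=25)
        lo = min(self.y_adj.min(), self.y_pred.min())
        hi = max(self.y_adj.max(), self.y_pred.max())
        ax.plot([lo, hi], [lo, hi], "--", color="grey")
        ax.set_xlabel("observed amplitude (confound-adjusted)")
        ax.set_ylabel("predicted amplitude")
        ax.set_title(f"$R^2$ = {self.r2:.2f}")
        return ax


def loocv_svr(X, y, conf_X=None, conf_y=None,
              config: Optional[PredictionConfig] = None,
              seed: int = 0) -> PredictionResults:
    """Functional form of :meth:`AmplitudePredictionModel.fit`."""
    return AmplitudePredictionModel(X, y, conf_X, conf_y, config).fit()


def perm_prediction_test(X, y, conf_X=None, conf_y=None,
                         config: Optional[PredictionConfig] = None,
                         n_perm: int = 10000, seed: int = 0,
                         observed: Optional[dict] = None) -> dict:
    """One-tailed full-pipeline permutation tests for R^2, RMSE and Spearman.

    Each permutation shuffles the raw response before any adjustment and
    reruns the entire pipeline (confound regression, standardisation, grid
    search, SVR).  p = (1 + c)/(1 + B) with c counting permutations at least
    as good as observed (>= for R^2/Spearman, <= for RMSE).
    """
    config = config or PredictionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if observed is None:
        y_pred, y_adj, _ = _loocv(X, y, conf_X, conf_y, config)
        observed = prediction_metrics(y_adj, y_pred)
    rng = np.random.default_rng(seed)
    null = {k: np.empty(n_perm) for k in ("r2", "rmse", "spearman")}
    for b in range(n_perm):
        y_b = rng.permutation(y)
        y_pred, y_adj, _ = _loocv(X, y_b, conf_X, conf_y, config)
        m = prediction_metrics(y_adj, y_pred)
        for k in null:
            null[k][b] = m[k]
    out = {}
    for k in null:
        if k == "rmse":
            c = int(np.sum(null[k] <= observed[k] + 1e-12))
        else:
            c = int(np.sum(null[k] >= observed[k] - 1e-12))
        out[k] = PermResult(observed[k], null[k], mc_p(c, n_perm),
                            "one", "monte_carlo", n_perm, seed)
    return out


def univariate_screens(X, y, conf_X=None, conf_y=None,
                       config: Optional[PredictionConfig] = None,
                       feature_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-feature confound-adjusted correlation and single-feature LOO-CV R^2."""
    config = config or PredictionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    full = np.arange(n)
    Xr = _residualize_fold(X, conf_X, full)
    yr = _residualize_fold(y, conf_y, full)
    rows = []
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    for j in range(X.shape[1]):
        xc = Xr[:, j] - Xr[:, j].mean()
        yc = yr - yr.mean()
        r = float(np.dot(xc, yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))
        res = loocv_svr(X[:, [j]], y, conf_X, conf_y, config)
        rows.append({"feature": names[j], "pearson_r": r,
                     "single_feature_r2": res.r2})
    return pd.DataFrame(rows)


def apply_model(train: dict, new_X, new_conf_X=None,
                config: Optional[PredictionConfig] = None,
                adjust_mode: str = "within_target") -> np.ndarray:
    """Train once on a full cohort and score a new cohort.

    ``train`` holds keys ``X``, ``y`` and optionally ``conf_X``, ``conf_y``.
    The model is fit on the full training set (confound-adjusted on the full
    sample, standardized, C chosen by LOO grid search).  Target features are
    adjusted per ``adjust_mode``:

    * ``within_target`` (default): residualise the target features on the
      *target sample's own* confound regression — appropriate when the new
      cohort's features and confounds were extracted in the same way but on
      a different scanner/population;
    * ``train_coefs``: apply the training-sample confound coefficients.
    """
    config = config or PredictionConfig()
    X = np.asarray(train["X"], dtype=float)
    y = np.asarray(train["y"], dtype=float)
    conf_X = train.get("conf_X")
    conf_y = train.get("conf_y")
    new_X = np.asarray(new_X, dtype=float)
    if new_X.ndim == 1:
        new_X = new_X[:, None]
    if new_X.shape[1] != X.shape[1]:
        raise ValueError("feature column mismatch between train and target")

    n = y.size
    full = np.arange(n)
    Z1 = _with_intercept(conf_X, n)
    beta_X, _, _, _ = np.linalg.lstsq(Z1, X, rcond=None)
    Xr = X - Z1 @ beta_X
    yr = _residualize_fold(y, conf_y, full)
    if config.standardize_features:
        mu, sd = _standardizer(Xr)
    else:
        mu, sd = 0.0, 1.0
    Xr_s = (Xr - mu) / sd
    C = _select_c(Xr_s, yr, config)
    model = _svr(C, config).fit(Xr_s, yr)

    if adjust_mode == "within_target":
        new_Xr = _residualize_fold(new_X, new_conf_X, np.arange(new_X.shape[0]))
    elif adjust_mode == "train_coefs":
        Z1n = _with_intercept(new_conf_X, new_X.shape[0])
        if Z1n.shape[1] != Z1.shape[1]:
            raise ValueError("confound column mismatch between train and target")
        new_Xr = new_X - Z1n @ beta_X
    else:
        raise ValueError(f"unknown adjust_mode {adjust_mode!r}")
    return model.predict((new_Xr - mu) / sd)
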