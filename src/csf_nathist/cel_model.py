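"""Elastic-net model of contrast-enhancing lesion counts and the lesion
"destructiveness" residual score.

The model predicts CEL# from adjusted CSF analytes while deliberately
excluding the neurofilament aptamers (NEFL, NEFH), so that the axonal-injury
marker can later be contrasted against the predicted lesion activity.  The
mixing parameter (Lasso <-> Ridge balance) is chosen from a 20-point grid on
[0, 1] and the penalty from a log-spaced path, jointly minimizing 10-fold
cross-validated MSE; folds are stratified by disease subtype when labels
are supplied.  Evaluation reports Spearman rho, R² and Lin's concordance
correlation coefficient (CCC).  Samples whose predicted CEL# exceeds the
upper 95% prediction interval of the healthy-control predicted-CEL#-vs-age
regression define the cohort on which NEFL is regressed on predicted CEL#;
the signed residual is the per-sample destructiveness score (NEFL in excess
of lesion load).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from ._linmod import simple_slope


@dataclass
class ElasticNetModel:
    mixing: float                      # Lasso/Ridge balance in [0, 1]
    penalty: float                     # regularization strength
    coefficients: dict[str, float]     # nonzero terms only
    intercept: float
    excluded: list[str]
    cv_table: pd.DataFrame             # mixing grid x best CV MSE
    features: list[str]
    feature_mean: pd.Series
    feature_sd: pd.Series
    seed: int

    def predict(self, adjusted: pd.DataFrame) -> pd.Series:
        X = adjusted[self.features]
        Z = (X - self.feature_mean) / self.feature_sd
        beta = pd.Series(0.0, index=self.features)
        for k, v in self.coefficients.items():
            beta[k] = v
        return (Z @ beta + self.intercept).rename("predicted_cel")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mixing": self.mixing, "penalty": self.penalty,
            "coefficients": self.coefficients, "intercept": self.intercept,
            "excluded": self.excluded,
            "cv_table": self.cv_table.to_dict(orient="list"),
            "features": self.features,
            "feature_mean": self.feature_mean.to_dict(),
            "feature_sd": self.feature_sd.to_dict(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class ModelEvaluation:
    spearman_rho: float
    r_squared: float
    ccc: float
    n: int


def lin_ccc(measured: np.ndarray, predicted: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2); equals
    the Pearson correlation only when the two series share mean and
    variance, and is attenuated toward 0 by any location or scale shift.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    cov = np.cov(x, y, ddof=1)[0, 1]
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return 1.0
    return float(2.0 * cov / denom)


def _stratified_folds(n: int, folds: int, rng: np.random.Generator,
                      strata: np.ndarray | None) -> np.ndarray:
    """Deterministic fold labels, balanced within each stratum."""
    labels = np.empty(n, dtype=int)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        labels[idx] = np.arange(len(idx)) % folds
    return labels


def train_cel_model(adjusted: pd.DataFrame, cel: pd.Series,
                    exclude: tuple[str, ...] = (),
                    n_mixing: int = 20, folds: int = 10,
                    seed: int = 0, subtype: pd.Series | None = None,
                    n_penalty: int = 30) -> ElasticNetModel:
    """Grid-search elastic net for CEL# over (mixing, penalty) by CV MSE.

    ``exclude`` lists feature IDs that must never enter the model (the
    neurofilament aptamers in the standard analysis); their absence from
    the coefficient map is asserted.
    """
    common = adjusted.index.intersection(cel.dropna().index)
    if len(common) < folds:
        raise ValueError("training cohort smaller than fold count")
    features = [c for c in adjusted.columns if c not in set(exclude)]
    X_raw = adjusted.loc[common, features]
    mean, sd = X_raw.mean(), X_raw.std(ddof=1).replace(0.0, 1.0)
    X = ((X_raw - mean) / sd).to_numpy(dtype=float)
    y = cel.loc[common].to_numpy(dtype=float)
    n = len(y)

    rng = np.random.default_rng(seed)
    strata = subtype.loc[common].to_numpy() if subtype is not None else None
    fold_of = _stratified_folds(n, folds, rng, strata)

    mixing_grid = np.linspace(0.0, 1.0, n_mixing)
    # penalty path anchored at the smallest penalty that zeroes all
    # coefficients at the current mixing (floored for the ridge end),
    # spanning two decades below it
    alpha_max0 = np.max(np.abs(X.T @ (y - y.mean()))) / n
    cv_mse = np.full((n_mixing, n_penalty), np.nan)
    paths = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, l1 in enumerate(mixing_grid):
            a_max = alpha_max0 / max(l1, 0.05)
            path = np.logspace(np.log10(a_max), np.log10(a_max * 1e-2),
                               n_penalty)
            paths.append(path)
            sq_err = np.zeros(n_penalty)
            for f in range(folds):
                te = fold_of == f
                tr = ~te
                Xtr, ytr = X[tr], y[tr]
                xm, ym = Xtr.mean(axis=0), ytr.mean()
                _, coefs, _ = enet_path(Xtr - xm, ytr - ym, l1_ratio=l1,
                                        alphas=path, tol=1e-3)
                preds = (X[te] - xm) @ coefs + ym       # (n_te, n_penalty)
                sq_err += ((preds - y[te][:, None]) ** 2).sum(axis=0)
            cv_mse[i] = sq_err / n

    best_i, best_j = np.unravel_index(np.nanargmin(cv_mse), cv_mse.shape)
    best_mix = float(mixing_grid[best_i])
    best_pen = float(paths[best_i][best_j])
    final = ElasticNet(alpha=best_pen, l1_ratio=best_mix, max_iter=50000)
    final.fit(X, y)
    coef = {f: float(c) for f, c in zip(features, final.coef_) if c != 0.0}
    assert not set(coef) & set(exclude), \
        "excluded features leaked into the coefficient map"
    cv_table = pd.DataFrame({"mixing": mixing_grid,
                             "cv_mse": np.nanmin(cv_mse, axis=1)})
    return ElasticNetModel(
        mixing=best_mix, penalty=best_pen, coefficients=coef,
        intercept=float(final.intercept_), excluded=list(exclude),
        cv_table=cv_table, features=features, feature_mean=mean,
        feature_sd=sd, seed=seed)


def evaluate_model(model: ElasticNetModel, adjusted: pd.DataFrame,
                   cel: pd.Series,
                   training_ids: set[str] | None = None) -> ModelEvaluation:
    """Spearman rho, R² (squared Pearson) and Lin's CCC on a holdout set."""
    common = adjusted.index.intersection(cel.dropna().index)
    if training_ids is not None:
        overlap = set(common) & set(training_ids)
        if overlap:
            raise ValueError(f"holdout overlaps training "
                             f"({len(overlap)} samples)")
    if len(common) < 3:
        raise ValueError("need >= 3 holdout samples")
    pred = model.predict(adjusted.loc[common]).to_numpy()
    meas = cel.loc[common].to_numpy(dtype=float)
    rho = float(stats.spearmanr(meas, pred).statistic)
    r = float(np.corrcoef(meas, pred)[0, 1])
    return ModelEvaluation(spearman_rho=rho, r_squared=r * r,
                           ccc=lin_ccc(meas, pred), n=len(common))


def hc_prediction_gate(predicted: pd.Series, ages: pd.Series,
                       hc_ids: list[str], level: float = 0.95) -> pd.Series:
    """Flag samples above the HC predicted-CEL#-vs-age prediction interval.

    An OLS of predicted CEL# on age is fit over the healthy controls; every
    sample is flagged when its predicted value exceeds the upper bound of
    the ``level`` prediction interval at its own age.
    """
    hc_ids = [s for s in hc_ids if s in predicted.index]
    if len(hc_ids) < 5:
        raise ValueError("need >= 5 HC samples for the prediction interval")
    x = ages.loc[hc_ids].to_numpy(dtype=float)
    y = predicted.loc[hc_ids].to_numpy(dtype=float)
    slope, intercept = simple_slope(x, y)
    n = len(x)
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid ** 2) / (n - 2))
    if s2 == 0:
        raise ValueError("degenerate HC regression (zero residual variance)")
    sxx = float(np.sum((x - x.mean()) ** 2))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    all_age = ages.loc[predicted.index].to_numpy(dtype=float)
    half_width = tcrit * np.sqrt(s2 * (1.0 + 1.0 / n
                                       + (all_age - x.mean()) ** 2 / sxx))
    upper = intercept + slope * all_age + half_width
    return pd.Series(predicted.to_numpy() > upper, index=predicted.index,
                     name="above_pi")


def nefl_cel_residuals(nefl: pd.Series, predicted: pd.Series,
                       above_pi: pd.Series) -> pd.DataFrame:
    """Destructiveness table: NEFL regressed on predicted CEL# above the PI.

    Residuals are defined only for above-PI samples; a higher residual
    means more axonal injury per unit of predicted lesion activity.
    """
    subset = above_pi.index[above_pi.astype(bool)]
    subset = subset.intersection(nefl.dropna().index) \
                   .intersection(predicted.dropna().index)
    if len(subset) < 3:
        raise ValueError("need >= 3 above-PI samples with NEFL")
    x = predicted.loc[subset].to_numpy(dtype=float)
    y = nefl.loc[subset].to_numpy(dtype=float)
    slope, intercept = simple_slope(x, y)
    resid = y - (intercept + slope * x)
    out = pd.DataFrame({
        "predicted_cel": predicted,
        "above_pi": above_pi.astype(bool),
        "nefl": nefl,
        "nefl_cel_residual": np.nan,
    })
    out.loc[subset, "nefl_cel_residual"] = resid
    return out
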