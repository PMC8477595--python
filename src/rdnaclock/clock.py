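"""Penalized-regression age clocks.

Fits ridge / elastic-net / lasso age models on percent-methylation matrices
under the glmnet-style objective

    (1/2n) * sum (y - yhat)^2  +  lambda * [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ]

with predictors standardized inside each training set, a 100-value
log-spaced lambda grid on [1e-3, 1e3], k-fold tuning on median MAE, a fully
nested leave-one-out validation protocol, a reduced unpenalized model, and
cohort/sex diagnostics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold
from statsmodels.formula.api import ols as smf_ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .methylation import MethylationMatrix
from .screen import holm_adjust

LAMBDA_MIN = 1e-3
LAMBDA_MAX = 1e3
N_LAMBDAS = 100


def make_lambda_grid() -> np.ndarray:
    """100 log-uniformly spaced penalty strengths from 1e-3 to 1e3 inclusive."""
    return np.logspace(math.log10(LAMBDA_MIN), math.log10(LAMBDA_MAX), N_LAMBDAS)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero mean / unit (population) SD; constant columns get sd 1."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _coef_paths(
    Xs: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray, tol: float = 1e-4
) -> np.ndarray:
    """Coefficients for every lambda on standardized X / centered y.

    Returns an (n_features, n_lambdas) array aligned with ``lambdas``.
    Ridge (alpha=0) is solved in closed form through the SVD; lambda=0 falls
    back to least squares for any alpha.
    """
    n, p = Xs.shape
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.empty((p, lambdas.size))
    zero_mask = lambdas == 0.0
    if zero_mask.any():
        beta_ols, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        coefs[:, zero_mask] = beta_ols[:, None]
    pos = ~zero_mask
    if pos.any():
        lam_pos = lambdas[pos]
        if alpha == 0.0:
            U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
            uty = U.T @ yc
            # beta(lam) = V diag(s / (s^2 + n*lam)) U^T y
            shrink = s[:, None] / (s[:, None] ** 2 + n * lam_pos[None, :])
            coefs[:, pos] = Vt.T @ (shrink * uty[:, None])
        else:
            order = np.argsort(lam_pos)[::-1]  # enet_path wants decreasing
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, path_coefs, _ = enet_path(
                    Xs, yc, l1_ratio=alpha, alphas=lam_pos[order], max_iter=10000, tol=tol
                )
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            coefs[:, pos] = path_coefs[:, inv]
    return coefs


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    """(MAE, RMSE, R^2 as squared Pearson r, R^2 as 1 - SSE/SST)."""
    resid = y_true - y_pred
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2_sse = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else math.nan
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        r2_pearson = 0.0
    else:
        r2_pearson = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    return mae, rmse, r2_pearson, r2_sse


@dataclass
class TuneResult:
    alpha: float
    lambda_best: float
    cv_table: pd.DataFrame  # per-lambda medians and means across folds
    folds: int
    seed: int


def tune(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    alpha: float,
    lambdas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
) -> TuneResult:
    """k-fold cross-validated penalty selection.

    Predictors are standardized inside each training fold (held-out data is
    transformed with the training statistics). The winning lambda minimises
    the median across folds of the validation MAE; fold assignment is
    deterministic given ``seed``.
    """
    X, y, _ = _as_arrays(matrix, ages)
    if lambdas is None:
        lambdas = make_lambda_grid()
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant ages: cannot tune an age model")

    mae = np.empty((folds, lambdas.size))
    rmse = np.empty((folds, lambdas.size))
    r2 = np.empty((folds, lambdas.size))
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (tr, va) in enumerate(splitter.split(X)):
        Xs, mean, sd = _standardize(X[tr])
        ybar = y[tr].mean()
        coefs = _coef_paths(Xs, y[tr] - ybar, alpha, lambdas, tol=tol)
        Xva = (X[va] - mean) / sd
        preds = ybar + Xva @ coefs  # (n_va, n_lambdas)
        for j in range(lambdas.size):
            mae[k, j], rmse[k, j], r2[k, j], _ = _metrics(y[va], preds[:, j])
    cv_table = pd.DataFrame(
        {
            "lambda": lambdas,
            "median_mae": np.median(mae, axis=0),
            "mean_mae": mae.mean(axis=0),
            "median_rmse": np.median(rmse, axis=0),
            "mean_rmse": rmse.mean(axis=0),
            "median_r2": np.median(r2, axis=0),
            "mean_r2": r2.mean(axis=0),
        }
    )
    best = int(np.argmin(cv_table["median_mae"].to_numpy()))
    return TuneResult(
        alpha=alpha,
        lambda_best=float(lambdas[best]),
        cv_table=cv_table,
        folds=folds,
        seed=seed,
    )


@dataclass
class ClockModel:
    """Serializable penalized (or OLS) age model.

    Coefficients live on the standardized-predictor scale; each stored locus
    carries the training mean/SD needed to reproduce predictions exactly
    from the serialized form. Ridge stores every locus; lasso/elastic-net
    store only nonzero coefficients.
    """

    alpha: float
    lambda_: float
    intercept: float  # months
    coefficients: dict[str, float]  # locus_id -> months per standardized percent
    standardization: dict[str, tuple[float, float]]  # locus_id -> (mean, sd)
    training_metrics: dict[str, float] = field(default_factory=dict)
    n_training_samples: int = 0
    version: str = __version__

    @property
    def n_loci_selected(self) -> int:
        return len(self.coefficients)

    @property
    def loci(self) -> list[str]:
        return list(self.coefficients)

    def raw_scale_coefficients(self) -> dict[str, float]:
        """Coefficients per raw percent methylation (coef / training sd)."""
        return {l: c / self.standardization[l][1] for l, c in self.coefficients.items()}

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standardization": {l: list(ms) for l, ms in self.standardization.items()},
            "training_metrics": self.training_metrics,
            "n_training_samples": self.n_training_samples,
            "version": self.version,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "ClockModel":
        return cls(
            alpha=data["alpha"],
            lambda_=data["lambda"],
            intercept=data["intercept"],
            coefficients=dict(data["coefficients"]),
            standardization={l: tuple(ms) for l, ms in data["standardization"].items()},
            training_metrics=dict(data.get("training_metrics", {})),
            n_training_samples=int(data.get("n_training_samples", 0)),
            version=data.get("version", ""),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_arrays(
    matrix: MethylationMatrix | pd.DataFrame, ages: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(ages, pd.Series):
        ages = ages.loc[values.index]
    y = np.asarray(ages, dtype=float)
    X = values.to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("ages and matrix rows do not align")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run QC first")
    if np.isnan(y).any():
        raise ValueError("ages contain missing values")
    return X, y, list(values.columns)


def fit_final(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    tol: float = 1e-4,
) -> ClockModel:
    """Refit on all samples at the tuned penalty (tuning runs internally when
    no lambda is supplied)."""
    X, y, locus_ids = _as_arrays(matrix, ages)
    if X.shape[1] == 0 or X.shape[0] == 0:
        raise ValueError("empty matrix")
    if lambda_ is None:
        lambda_ = tune(
            matrix, ages, alpha, lambdas=lambdas, folds=folds, seed=seed, tol=tol
        ).lambda_best
    Xs, mean, sd = _standardize(X)
    ybar = float(y.mean())
    if alpha > 0.0 and lambda_ > 0.0:
        # warm-started descent from heavier penalties: coordinate descent at a
        # single small lambda from a cold start can stop far from the optimum
        path = np.concatenate([make_lambda_grid()[make_lambda_grid() > lambda_], [lambda_]])
        beta = _coef_paths(Xs, y - ybar, alpha, path, tol=tol)[:, -1]
    else:
        beta = _coef_paths(Xs, y - ybar, alpha, np.array([lambda_]), tol=tol)[:, 0]
    if alpha == 0.0:
        keep = np.ones(len(beta), dtype=bool)  # ridge keeps every locus
    else:
        keep = beta != 0.0
    coefficients = {locus_ids[i]: float(beta[i]) for i in range(len(beta)) if keep[i]}
    standardization = {
        locus_ids[i]: (float(mean[i]), float(sd[i])) for i in range(len(beta)) if keep[i]
    }
    preds = ybar + Xs @ beta
    mae, rmse, r2p, r2s = _metrics(y, preds)
    return ClockModel(
        alpha=alpha,
        lambda_=float(lambda_),
        intercept=ybar,
        coefficients=coefficients,
        standardization=standardization,
        training_metrics={
            "mae": mae,
            "rmse": rmse,
            "r2_pearson": r2p,
            "r2_sse": r2s,
        },
        n_training_samples=len(y),
    )


def predict_age(model: ClockModel, matrix: MethylationMatrix | pd.DataFrame) -> pd.Series:
    """yhat = intercept + sum coef_l * (x_l - mean_l) / sd_l, per sample.

    Negative predictions are returned as-is (flagged by the caller, never
    clamped). Raises when any model locus is absent from the matrix — no
    silent imputation.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    missing = [l for l in model.loci if l not in values.columns]
    if missing:
        raise KeyError(f"matrix is missing model loci: {missing}")
    preds = np.full(len(values), model.intercept)
    for locus, coef in model.coefficients.items():
        m, s = model.standardization[locus]
        preds = preds + coef * (values[locus].to_numpy(dtype=float) - m) / s
    return pd.Series(preds, index=values.index, name="predicted_age_months")


@dataclass
class ModelComparison:
    table: pd.DataFrame  # one row per alpha
    chosen_alpha: float
    rel_tolerance: float


def compare_models(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    alphas: tuple[float, ...] = (0.0, 0.5, 1.0),
    lambdas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    rel_tolerance: float = 0.01,
    tol: float = 1e-4,
) -> ModelComparison:
    """Tune each penalty family and compare at its best lambda.

    Selection: lowest median cross-validated MAE; alphas whose MAE is within
    ``rel_tolerance`` (relative) of the minimum are tied and the tie goes to
    the model with fewer selected loci.
    """
    rows = []
    for alpha in alphas:
        tuned = tune(matrix, ages, alpha, lambdas=lambdas, folds=folds, seed=seed, tol=tol)
        at_best = tuned.cv_table.loc[
            (tuned.cv_table["lambda"] - tuned.lambda_best).abs().idxmin()
        ]
        model = fit_final(matrix, ages, alpha=alpha, lambda_=tuned.lambda_best, tol=tol)
        rows.append(
            {
                "alpha": alpha,
                "lambda_best": tuned.lambda_best,
                "median_mae": float(at_best["median_mae"]),
                "mean_rmse": float(at_best["mean_rmse"]),
                "median_rmse": float(at_best["median_rmse"]),
                "mean_r2": float(at_best["mean_r2"]),
                "median_r2": float(at_best["median_r2"]),
                "n_loci": model.n_loci_selected,
            }
        )
    table = pd.DataFrame(rows)
    best_mae = table["median_mae"].min()
    tied = table[table["median_mae"] <= best_mae * (1.0 + rel_tolerance)]
    chosen = tied.sort_values(["n_loci", "median_mae"]).iloc[0]
    return ModelComparison(table=table, chosen_alpha=float(chosen["alpha"]), rel_tolerance=rel_tolerance)


def precision_sd(known, predicted) -> float:
    """Sample SD (n-1 denominator) of known - predicted; bias-blind by design."""
    known = np.asarray(known, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if known.shape != predicted.shape:
        raise ValueError("known and predicted must have equal length")
    if known.size < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.std(known - predicted, ddof=1))


@dataclass
class PrecisionReport:
    table: pd.DataFrame  # sample_id, known, predicted, difference[, cohort]
    precision_sd: float
    per_cohort_mean_difference: pd.Series | None
    anova: dict | None  # F, df_between, df_within, p
    tukey: pd.DataFrame | None
    training_ids: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def r2_pearson(self) -> float:
        known = self.table["known"].to_numpy()
        pred = self.table["predicted"].to_numpy()
        if np.std(pred) == 0:
            return 0.0
        return float(np.corrcoef(known, pred)[0, 1] ** 2)

    @property
    def mae(self) -> float:
        return float(self.table["difference"].abs().mean())


def _cohort_anova(diffs: pd.Series, cohorts: pd.Series) -> tuple[dict | None, pd.DataFrame | None]:
    groups = [g.to_numpy() for _, g in diffs.groupby(cohorts)]
    usable = [g for g in groups if len(g) >= 2]
    if len(usable) < 2:
        return None, None
    f_stat, p = stats.f_oneway(*groups)
    anova = {
        "F": float(f_stat),
        "df_between": len(groups) - 1,
        "df_within": int(len(diffs) - len(groups)),
        "p": float(p),
    }
    tukey = None
    try:
        res = pairwise_tukeyhsd(diffs.to_numpy(), cohorts.to_numpy())
        tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    except Exception:  # pragma: no cover - tukey needs >=2 per group
        pass
    return anova, tukey


def loocv(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    alpha: float = 0.5,
    lambdas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    cohorts: pd.Series | None = None,
    tol: float = 1e-4,
) -> PrecisionReport:
    """Fully nested leave-one-out validation.

    For each sample the entire tuning + fitting pipeline runs on the other
    n-1 samples before predicting the held-out one, so locus selection is
    free to differ fold to fold. ``training_ids`` records each fold's
    training set for protocol verification.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(ages, pd.Series):
        ages = ages.loc[values.index]
    y = pd.Series(np.asarray(ages, dtype=float), index=values.index)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    preds = {}
    training_ids = []
    for sample in values.index:
        train = values.drop(index=sample).sort_index()  # canonical fold order
        model = fit_final(
            train, y.drop(index=sample).loc[train.index], alpha=alpha, lambdas=lambdas,
            folds=min(folds, len(train)), seed=seed, tol=tol,
        )
        preds[sample] = float(predict_age(model, values.loc[[sample]]).iloc[0])
        training_ids.append(tuple(train.index))
    table = pd.DataFrame(
        {
            "known": y,
            "predicted": pd.Series(preds).loc[values.index],
        }
    )
    table["difference"] = table["known"] - table["predicted"]
    table.index.name = "sample_id"
    per_cohort = anova = tukey = None
    if cohorts is not None:
        cohorts = cohorts.loc[values.index]
        table["cohort"] = cohorts
        per_cohort = table.groupby("cohort")["difference"].mean()
        anova, tukey = _cohort_anova(table["difference"], cohorts)
    return PrecisionReport(
        table=table,
        precision_sd=precision_sd(table["known"], table["predicted"]),
        per_cohort_mean_difference=per_cohort,
        anova=anova,
        tukey=tukey,
        training_ids=training_ids,
    )


def _ols_model(values: pd.DataFrame, y: pd.Series, loci: list[str]) -> ClockModel:
    X = values[loci].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
    preds = design @ beta
    mae, rmse, r2p, r2s = _metrics(y.to_numpy(dtype=float), preds)
    return ClockModel(
        alpha=math.nan,
        lambda_=0.0,
        intercept=float(beta[0]),
        coefficients={l: float(b) for l, b in zip(loci, beta[1:])},
        standardization={l: (0.0, 1.0) for l in loci},
        training_metrics={"mae": mae, "rmse": rmse, "r2_pearson": r2p, "r2_sse": r2s},
        n_training_samples=len(y),
    )


def reduced_model(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    screen_results: pd.DataFrame,
    selected_loci: list[str],
    k: int = 15,
) -> ClockModel:
    """Unpenalized model on the k best clock loci.

    Ranks the penalized model's selected loci by single-locus R^2 (ties
    broken by lower genomic position) and fits ordinary multiple least
    squares on the top k.
    """
    if k > len(selected_loci):
        raise ValueError(f"k={k} exceeds the {len(selected_loci)} selected loci")
    sub = screen_results.set_index("locus_id")
    missing = [l for l in selected_loci if l not in sub.index]
    if missing:
        raise ValueError(f"screen results missing selected loci: {missing}")
    ranked = sorted(
        selected_loci,
        key=lambda l: (-sub.at[l, "r_squared"], sub.at[l, "position"]),
    )
    top = ranked[:k]
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(ages, pd.Series):
        y = ages.loc[values.index].astype(float)
    else:
        y = pd.Series(np.asarray(ages, dtype=float), index=values.index)
    return _ols_model(values, y, top)


def loocv_ols(
    matrix: MethylationMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    loci: list[str],
    cohorts: pd.Series | None = None,
) -> PrecisionReport:
    """Leave-one-out validation of a fixed-locus OLS model (no tuning step)."""
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(ages, pd.Series):
        ages = ages.loc[values.index]
    y = pd.Series(np.asarray(ages, dtype=float), index=values.index)
    preds = {}
    training_ids = []
    for sample in values.index:
        train = values.drop(index=sample).sort_index()
        model = _ols_model(train, y.drop(index=sample).loc[train.index], loci)
        preds[sample] = float(predict_age(model, values.loc[[sample]]).iloc[0])
        training_ids.append(tuple(train.index))
    table = pd.DataFrame({"known": y, "predicted": pd.Series(preds).loc[values.index]})
    table["difference"] = table["known"] - table["predicted"]
    table.index.name = "sample_id"
    per_cohort = anova = tukey = None
    if cohorts is not None:
        cohorts = cohorts.loc[values.index]
        table["cohort"] = cohorts
        per_cohort = table.groupby("cohort")["difference"].mean()
        anova, tukey = _cohort_anova(table["difference"], cohorts)
    return PrecisionReport(
        table=table,
        precision_sd=precision_sd(table["known"], table["predicted"]),
        per_cohort_mean_difference=per_cohort,
        anova=anova,
        tukey=tukey,
        training_ids=training_ids,
    )


@dataclass
class SexEffectReport:
    per_locus: pd.DataFrame  # cohort, locus_id, mean_f, mean_m, sign, test, p_raw, p_holm
    sign_counts: dict[str, tuple[int, int]]  # cohort -> (n female-higher, n loci tested)
    anova: dict | None  # type-II two-way ANOVA of predicted age: sex term
    skipped_cohorts: list[str] = field(default_factory=list)


def sex_effects(
    matrix: MethylationMatrix | pd.DataFrame,
    samplesheet: pd.DataFrame,
    model: ClockModel,
    cohorts: list[str],
    levene_alpha: float = 0.05,
) -> SexEffectReport:
    """Per-locus sex comparisons within cohorts plus an overall ANOVA.

    Each model locus is tested per cohort with a two-sided two-sample t test
    (equal variances when Levene's test passes at ``levene_alpha``, Welch
    otherwise); p-values are Holm-adjusted within each cohort. The sign is
    positive when females exceed males. Predicted age is then tested for a
    sex effect controlling for cohort with a type-II two-way ANOVA.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    rows = []
    sign_counts: dict[str, tuple[int, int]] = {}
    skipped = []
    for cohort in cohorts:
        members = samplesheet.index[samplesheet["cohort"] == cohort]
        members = [m for m in members if m in values.index]
        sexes = samplesheet.loc[members, "sex"]
        f_ids = [m for m in members if sexes[m] == "F"]
        m_ids = [m for m in members if sexes[m] == "M"]
        if len(f_ids) < 2 or len(m_ids) < 2:
            warnings.warn(f"cohort {cohort}: fewer than 2 samples of each sex; skipped", stacklevel=2)
            skipped.append(cohort)
            continue
        cohort_rows = []
        for locus in model.loci:
            f_vals = values.loc[f_ids, locus].to_numpy(dtype=float)
            m_vals = values.loc[m_ids, locus].to_numpy(dtype=float)
            diff = float(f_vals.mean() - m_vals.mean())
            if np.ptp(np.concatenate([f_vals, m_vals])) == 0.0:
                # saturated/constant locus: no evidence either way
                cohort_rows.append(
                    {
                        "cohort": cohort,
                        "locus_id": locus,
                        "mean_f": float(f_vals.mean()),
                        "mean_m": float(m_vals.mean()),
                        "mean_difference": 0.0,
                        "sign": 0,
                        "test": "degenerate",
                        "p_raw": 1.0,
                    }
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lev_p = stats.levene(f_vals, m_vals).pvalue
                equal_var = bool(lev_p >= levene_alpha) if math.isfinite(lev_p) else True
                t_res = stats.ttest_ind(f_vals, m_vals, equal_var=equal_var)
            p_raw = float(t_res.pvalue) if math.isfinite(t_res.pvalue) else 1.0
            cohort_rows.append(
                {
                    "cohort": cohort,
                    "locus_id": locus,
                    "mean_f": float(f_vals.mean()),
                    "mean_m": float(m_vals.mean()),
                    "mean_difference": diff,
                    "sign": int(np.sign(diff)),
                    "test": "student" if equal_var else "welch",
                    "p_raw": p_raw,
                }
            )
        p_holm = holm_adjust([r["p_raw"] for r in cohort_rows])
        for r, p in zip(cohort_rows, p_holm):
            r["p_holm"] = float(p)
        rows.extend(cohort_rows)
        sign_counts[cohort] = (
            sum(1 for r in cohort_rows if r["sign"] > 0),
            len(cohort_rows),
        )
    per_locus = pd.DataFrame(rows)

    anova = None
    tested = [c for c in cohorts if c not in skipped]
    if tested:
        members = samplesheet.index[samplesheet["cohort"].isin(tested)]
        members = [m for m in members if m in values.index]
        preds = predict_age(model, values.loc[members])
        frame = pd.DataFrame(
            {
                "predicted": preds,
                "sex": samplesheet.loc[members, "sex"],
                "cohort": samplesheet.loc[members, "cohort"],
            }
        )
        formula = (
            "predicted ~ C(sex) + C(cohort)"
            if frame["cohort"].nunique() > 1
            else "predicted ~ C(sex)"
        )
        fit = smf_ols(formula, data=frame).fit()
        aov = anova_lm(fit, typ=2)
        anova = {
            "F": float(aov.loc["C(sex)", "F"]),
            "df_sex": float(aov.loc["C(sex)", "df"]),
            "df_resid": float(aov.loc["Residual", "df"]),
            "p": float(aov.loc["C(sex)", "PR(>F)"]),
        }
    return SexEffectReport(
        per_locus=per_locus, sign_counts=sign_counts, anova=anova, skipped_cohorts=skipped
    )
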