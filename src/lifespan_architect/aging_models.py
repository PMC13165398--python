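"""Behavioral clocks, lifespan forecasting, and survival comparison.

Each animal-day is summarized by its vector of age-factor weights from the
behaviorome tensor decomposition.  From these this module builds:

* **aging trajectories**: PCA of z-scored age factors, with per-animal
  smoothing and a trajectory fan-out measure (across-animal variance by
  age);
* a **behavioral clock**: a random-forest regressor estimating
  chronological age from one day's age factors, evaluated with
  leave-one-fish-out cross-validation (all days of an animal held out
  together, so no within-animal leakage);
* a per-animal **aging rate**: the least-squares slope of clock-estimated
  versus true age;
* **lifespan forecasting**: age-fixed random-forest classifiers predicting
  whether an animal will live past 200 days from its mean behavior over
  the 5 days before the prediction age, with extreme agers (> 300 days)
  excluded;
* **survival comparison** of the predicted groups (Kaplan-Meier curves,
  log-rank test) and per-age **differential usage** between true groups
  (Mann-Whitney U, Bonferroni-corrected per age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress, mannwhitneyu, pearsonr
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .behaviorome_tca import CPModel, UsageTensor

__all__ = [
    "ClockResult",
    "LifespanForecast",
    "age_factor_table",
    "trajectory_pca",
    "fit_behavior_clock",
    "aging_rate",
    "forecast_lifespan",
    "survival_compare",
    "differential_usage",
]

LONG_LIVED_THRESHOLD = 200.0   # days; lifespan >= threshold is long-lived
EXTREME_AGER_CUTOFF = 300.0    # days; longer-lived animals are excluded


def age_factor_table(model: CPModel, tensor: UsageTensor) -> pd.DataFrame:
    """Tidy table of age factors: one row per animal-day.

    Columns: ``animal``, ``age`` and ``tc0..tc{R-1}``.
    """
    R = model.rank
    df = pd.DataFrame(model.age_factors, columns=[f"tc{r}" for r in range(R)])
    df.insert(0, "age", tensor.ages)
    df.insert(0, "animal", tensor.animal_ids)
    return df


def _factor_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("tc")]


@dataclass
class ClockResult:
    """Leave-one-fish-out behavioral-clock predictions and summaries."""

    predictions: pd.DataFrame = field(repr=False)  # animal, age, estimated_age
    pearson_r: float = float("nan")
    mae_by_age: pd.DataFrame = field(default=None, repr=False)
    feature_importances: np.ndarray | None = None
    training_animals: dict[str, list[str]] = field(default_factory=dict, repr=False)


@dataclass
class LifespanForecast:
    """Age-fixed lifespan classification at one prediction age."""

    prediction_age: float
    window: float
    predictions: pd.DataFrame = field(repr=False)  # animal, label, predicted, score
    accuracy: float = float("nan")
    roc_auc: float = float("nan")
    training_animals: dict[str, list[str]] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def trajectory_pca(
    factors: pd.DataFrame,
    n_pcs: int = 3,
    smoothing_sd: float | None = None,
) -> dict:
    """PCA of z-scored age factors with per-animal smoothed trajectories.

    Also reports the across-animal variance of the z-scored factors at each
    age, summed over factors — the fan-out of aging trajectories.
    """
    cols = _factor_columns(factors)
    X = factors[cols].to_numpy(dtype=float)
    if len(X) < n_pcs:
        raise ValueError("fewer animal-days than requested components")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    pca = PCA(n_components=min(n_pcs, Z.shape[1]), svd_solver="full")
    scores = pca.fit_transform(Z)
    out = factors[["animal", "age"]].copy()
    for i in range(scores.shape[1]):
        out[f"pc{i + 1}"] = scores[:, i]
    if smoothing_sd:
        pcs = [f"pc{i + 1}" for i in range(scores.shape[1])]
        for animal, grp in out.groupby("animal", sort=False):
            idx = grp.sort_values("age").index
            out.loc[idx, pcs] = gaussian_filter1d(
                out.loc[idx, pcs].to_numpy(), sigma=smoothing_sd, axis=0
            )
    zdf = pd.DataFrame(Z, columns=cols)
    zdf["age"] = factors["age"].to_numpy()
    var_by_age = (
        zdf.groupby("age")[cols].var(ddof=0).sum(axis=1).rename("summed_variance")
        .reset_index()
    )
    return {
        "trajectories": out,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "loadings": pca.components_.T,
        "variance_by_age": var_by_age,
    }


# ---------------------------------------------------------------------------
# behavioral clock
# ---------------------------------------------------------------------------

def fit_behavior_clock(
    factors: pd.DataFrame,
    n_estimators: int = 100,
    seed: int = 0,
) -> ClockResult:
    """Leave-one-fish-out random-forest clock of age from age factors.

    For each animal, a regressor is trained on all other animals'
    (age-factor, age) pairs and predicts the held-out animal's days.
    Reported: pooled Pearson R over all held-out predictions, per-age median
    absolute error, and impurity-based feature importances from a model
    trained on all animals (importances are non-negative and sum to 1).
    """
    cols = _factor_columns(factors)
    animals = pd.unique(factors["animal"])
    if len(animals) < 3:
        raise ValueError("leave-one-fish-out needs at least 3 animals")
    preds = []
    training: dict[str, list[str]] = {}
    for animal in animals:
        held = factors["animal"] == animal
        if held.sum() < 1:
            warnings.warn(f"animal {animal} has no recorded days; skipped")
            continue
        train = factors[~held]
        training[str(animal)] = sorted(map(str, pd.unique(train["animal"])))
        rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
        rf.fit(train[cols], train["age"])
        est = rf.predict(factors.loc[held, cols])
        preds.append(pd.DataFrame({
            "animal": animal,
            "age": factors.loc[held, "age"].to_numpy(),
            "estimated_age": est,
        }))
    predictions = pd.concat(preds, ignore_index=True)
    r = float(pearsonr(predictions["age"], predictions["estimated_age"])[0])
    err = (predictions["estimated_age"] - predictions["age"]).abs()
    mae = (
        predictions.assign(abs_error=err)
        .groupby("age")["abs_error"].median().rename("median_abs_error").reset_index()
    )
    full = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    full.fit(factors[cols], factors["age"])
    return ClockResult(
        predictions=predictions,
        pearson_r=r,
        mae_by_age=mae,
        feature_importances=full.feature_importances_,
        training_animals=training,
    )


def aging_rate(clock: ClockResult) -> pd.DataFrame:
    """Per-animal least-squares slope of estimated versus true age.

    A slope of 1 is calibrated aging; below 1, the behavioral clock runs
    slow for that animal.  Animals with a single predicted day get NaN.
    """
    rows = []
    for animal, grp in clock.predictions.groupby("animal", sort=False):
        if len(grp) < 2 or grp["age"].nunique() < 2:
            rows.append({"animal": animal, "slope": np.nan, "intercept": np.nan})
            continue
        fit = linregress(grp["age"], grp["estimated_age"])
        rows.append({"animal": animal, "slope": fit.slope, "intercept": fit.intercept})
    return pd.DataFrame(rows)


def compare_aging_rates(rates: pd.DataFrame, groups: dict[str, str]) -> dict:
    """Mann-Whitney U comparison of per-animal aging-rate slopes by group."""
    rates = rates.dropna(subset=["slope"]).copy()
    rates["group"] = rates["animal"].map(groups)
    names = sorted(rates["group"].dropna().unique())
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = rates.loc[rates["group"] == names[0], "slope"]
    b = rates.loc[rates["group"] == names[1], "slope"]
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {"groups": names, "medians": (float(a.median()), float(b.median())),
            "U": float(stat), "p": float(p)}


# ---------------------------------------------------------------------------
# lifespan forecasting
# ---------------------------------------------------------------------------

def forecast_lifespan(
    factors: pd.DataFrame,
    lifespans: dict[str, float],
    prediction_age: float,
    window: float = 5.0,
    threshold: float = LONG_LIVED_THRESHOLD,
    exclude_above: float = EXTREME_AGER_CUTOFF,
    n_estimators: int = 100,
    seed: int = 0,
) -> LifespanForecast:
    """Age-fixed long/short lifespan classifier at one prediction age.

    Features are the mean age factors over days in
    ``(prediction_age - window, prediction_age]`` (days with missing
    recordings are simply absent from the mean), z-scored by training-fold
    statistics.  Animals are long-lived if lifespan >= ``threshold`` (200 d);
    extreme agers (> ``exclude_above``) are excluded, as are animals dead
    before the prediction age or with no recorded day in the window.
    Leave-one-fish-out accuracy and ROC AUC are pooled over folds.
    """
    cols = _factor_columns(factors)
    rows = []
    for animal, grp in factors.groupby("animal", sort=False):
        lifespan = lifespans.get(str(animal), lifespans.get(animal))
        if lifespan is None or lifespan < prediction_age or lifespan > exclude_above:
            continue
        sel = grp[(grp["age"] > prediction_age - window) & (grp["age"] <= prediction_age)]
        if sel.empty:
            continue
        rows.append(
            {"animal": animal, "label": int(lifespan >= threshold),
             **{c: sel[c].mean() for c in cols}}
        )
    table = pd.DataFrame(rows)
    if table.empty or table["label"].nunique() < 2:
        raise ValueError("need both long- and short-lived animals at this age")
    preds = []
    training: dict[str, list[str]] = {}
    for i, row in table.iterrows():
        train = table.drop(index=i)
        if train["label"].nunique() < 2:
            warnings.warn(f"single-class training fold for {row['animal']}; skipped")
            continue
        mu = train[cols].mean()
        sd = train[cols].std(ddof=0).replace(0, 1.0)
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        rf.fit((train[cols] - mu) / sd, train["label"])
        x = ((row[cols] - mu) / sd).to_frame().T.astype(float)
        score = float(rf.predict_proba(x)[0, list(rf.classes_).index(1)])
        preds.append({
            "animal": row["animal"], "label": int(row["label"]),
            "predicted": int(score >= 0.5), "score": score,
        })
        training[str(row["animal"])] = sorted(map(str, train["animal"]))
    predictions = pd.DataFrame(preds)
    acc = float(accuracy_score(predictions["label"], predictions["predicted"]))
    auc = float(roc_auc_score(predictions["label"], predictions["score"]))
    return LifespanForecast(
        prediction_age=prediction_age,
        window=window,
        predictions=predictions,
        accuracy=acc,
        roc_auc=auc,
        training_animals=training,
    )


# ---------------------------------------------------------------------------
# survival analysis
# ---------------------------------------------------------------------------

def survival_compare(
    lifespans: np.ndarray,
    groups: np.ndarray,
    censored: np.ndarray | None = None,
) -> dict:
    """Kaplan-Meier curves and log-rank test between two groups.

    Removal before natural death is right-censoring.  If every animal is
    censored the log-rank test is undefined and reported as NaN.
    """
    lifespans = np.asarray(lifespans, dtype=float)
    groups = np.asarray(groups)
    observed = (
        np.ones(len(lifespans), dtype=bool)
        if censored is None else ~np.asarray(censored, dtype=bool)
    )
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    fitters = {}
    for name in names:
        sel = groups == name
        km = KaplanMeierFitter(label=str(name))
        km.fit(lifespans[sel], event_observed=observed[sel])
        fitters[str(name)] = km
    if not observed.any():
        warnings.warn("all lifespans censored; log-rank test undefined")
        return {"km": fitters, "statistic": float("nan"), "p": float("nan")}
    a = groups == names[0]
    res = logrank_test(
        lifespans[a], lifespans[~a],
        event_observed_A=observed[a], event_observed_B=observed[~a],
    )
    return {"km": fitters, "statistic": float(res.test_statistic),
            "p": float(res.p_value)}


def differential_usage(
    factors: pd.DataFrame,
    groups: dict[str, str],
    ages: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-age, per-factor group differences in age-factor weights.

    At each age, every factor is compared between the two groups with a
    two-sided Mann-Whitney U test; p-values are Bonferroni-corrected within
    the age (m = number of factors tested at that age).
    """
    cols = _factor_columns(factors)
    df = factors.copy()
    df["group"] = df["animal"].map(lambda a: groups.get(str(a), groups.get(a)))
    names = sorted(df["group"].dropna().unique())
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    out = []
    for age in np.asarray(ages):
        at = df[df["age"] == age]
        a = at[at["group"] == names[0]]
        b = at[at["group"] == names[1]]
        if a.empty or b.empty:
            continue
        recs = []
        for col in cols:
            stat, p = mannwhitneyu(a[col], b[col], alternative="two-sided")
            recs.append({
                "age": age, "factor": col,
                "mean_diff": float(a[col].mean() - b[col].mean()),
                "U": float(stat), "p_raw": float(p),
            })
        block = pd.DataFrame(recs)
        reject, p_adj, _, _ = multipletests(
            block["p_raw"], alpha=alpha, method="bonferroni"
        )
        block["p_adj"] = p_adj
        block["significant"] = reject
        out.append(block)
    if not out:
        raise ValueError("no age with both groups present")
    return pd.concat(out, ignore_index=True)
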