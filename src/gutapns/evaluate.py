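"""Longitudinal train/test evaluation of MERF models with permutation importance.

The protocol: train on the week-2 and week-8 outcome observations, hold
out every week-12 observation, and repeat the whole fit over ten forest
seeds. Per seed we record test RMSE, Pearson correlation of true versus
predicted week-12 values, and permuted variable importance (mean
increase in test MSE when one feature column is shuffled, the fitted
cluster intercepts held fixed). Importances are averaged across seeds,
ranked, filtered to positive contributions and capped at the top 15;
each ranked feature also gets a direction — the Spearman correlation of
its values with the outcome across all observation rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, SpeciesAbundanceTable
from .merf import MERF, MERFResults

__all__ = [
    "time_split",
    "build_feature_matrix",
    "rows_to_xy",
    "SeedRunResult",
    "run_seeds",
    "permutation_importance",
    "aggregate_importance",
    "feature_direction",
]

logger = logging.getLogger(__name__)

TRAIN_WEEKS = (2, 8)
TEST_WEEK = 12


def time_split(panel: pd.DataFrame,
               train_weeks: Sequence[int] = TRAIN_WEEKS,
               test_week: int = TEST_WEEK) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition outcome rows into early-week training and week-12 test sets."""
    train = panel[panel["week"].isin(train_weeks)]
    test = panel[panel["week"] == test_week]
    if test.empty:
        raise ValueError(f"no week-{test_week} rows available for testing")
    if train.empty:
        raise ValueError(f"no rows in training weeks {tuple(train_weeks)}")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def build_feature_matrix(species: SpeciesAbundanceTable, cohort: CohortTable) -> pd.DataFrame:
    """Per-subject features: species proportions plus encoded covariates.

    Each subject's single microbiome sample supplies the abundance
    features for all of that subject's outcome rows.
    """
    props = species.to_proportions()
    by_subject = props.loc[cohort.data["sample_id"].to_numpy()]
    by_subject.index = cohort.data.index
    cov = pd.DataFrame(index=cohort.data.index)
    cov["age"] = cohort.data["age"].astype(float)
    cov["bmi"] = cohort.data["bmi"].astype(float)
    cov["sex_male"] = (cohort.data["sex"] == "male").astype(float)
    race = pd.get_dummies(cohort.data["race_ethnicity"], prefix="race", drop_first=True)
    cov = pd.concat([cov, race.astype(float)], axis=1)
    cov["days_since_trauma"] = cohort.data["days_since_trauma"].astype(float)
    return pd.concat([by_subject, cov], axis=1)


@dataclass
class SeedRunResult:
    seed: int
    rmse_test: float = np.nan
    corr_test: float = np.nan
    importance: pd.Series | None = field(default=None, repr=False)
    error: str | None = None
    results: MERFResults | None = field(default=None, repr=False)


def rows_to_xy(rows: pd.DataFrame, features: pd.DataFrame, outcome: str):
    X = features.loc[rows["subject_id"].to_numpy()]
    X.index = pd.RangeIndex(len(X))
    y = rows[outcome].to_numpy(dtype=float)
    groups = rows["subject_id"].to_numpy()
    return X, y, groups


def run_seeds(panel: pd.DataFrame, features: pd.DataFrame, outcome: str,
              seeds: Sequence[int] = tuple(range(10)), n_repeats: int = 5,
              keep_models: bool = False, **merf_kwargs) -> list[SeedRunResult]:
    """Fit/evaluate the MERF once per forest seed; failures are recorded, not raised."""
    train, test = time_split(panel)
    X_tr, y_tr, g_tr = rows_to_xy(train, features, outcome)
    X_te, y_te, g_te = rows_to_xy(test, features, outcome)
    out: list[SeedRunResult] = []
    for seed in seeds:
        try:
            res = MERF(y_tr, X_tr, g_tr, random_state=seed, **merf_kwargs).fit()
            pred = res.predict(X_te, g_te)
            rmse = float(np.sqrt(np.mean((y_te - pred) ** 2)))
            corr = float(stats.pearsonr(y_te, pred).statistic) if np.std(pred) > 0 else np.nan
            imp = permutation_importance(
                res, X_te, g_te, y_te, n_repeats=n_repeats,
                rng=np.random.default_rng(seed),
            )
            out.append(SeedRunResult(seed=seed, rmse_test=rmse, corr_test=corr,
                                     importance=imp,
                                     results=res if keep_models else None))
        except Exception as exc:  # per-seed failures must not kill the sweep
            logger.warning("seed %d failed: %s", seed, exc)
            out.append(SeedRunResult(seed=seed, error=str(exc)))
    return out


def permutation_importance(results: MERFResults, X: pd.DataFrame, groups, y,
                           n_repeats: int = 5,
                           rng: np.random.Generator | None = None) -> pd.Series:
    """Mean increase in test MSE when one feature column is permuted.

    The fitted cluster intercepts stay fixed, so the importance
    reflects the forest's use of the feature, not the random effects.
    Constant features permute to themselves and score exactly 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y, dtype=float)
    base_pred = results.predict(X, groups)
    base_mse = float(np.mean((y - base_pred) ** 2))
    scores = {}
    n = len(X)
    groups_rep = np.tile(np.asarray(groups), n_repeats)
    y_rep = np.tile(y, n_repeats)
    stacked = pd.concat([X] * n_repeats, ignore_index=True)
    for col in X.columns:
        # one batched predict over all repeats of this feature's permutations
        col_vals = X[col].to_numpy()
        perm = np.concatenate([col_vals[rng.permutation(n)] for _ in range(n_repeats)])
        stacked[col] = perm
        pred = results.predict(stacked, groups_rep)
        mse = ((y_rep - pred) ** 2).reshape(n_repeats, n).mean(axis=1)
        scores[col] = float(np.mean(mse - base_mse))
        stacked[col] = np.tile(col_vals, n_repeats)
    return pd.Series(scores, name="importance")


def feature_direction(x, y) -> float:
    """Spearman correlation giving an importance's sign; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def aggregate_importance(results: list[SeedRunResult], top_k: int = 15,
                         directions: pd.Series | None = None) -> pd.DataFrame:
    """Cross-seed importance table: mean score, rank, top-15 membership count.

    Features with non-positive mean importance are dropped, so the table
    can be shorter than ``top_k`` (few genuinely informative features is
    a legitimate outcome). Ties rank lexicographically by feature name.
    """
    with_imp = [r for r in results if r.importance is not None]
    if not with_imp:
        raise ValueError("no successful seed runs to aggregate")
    imp = pd.DataFrame({r.seed: r.importance for r in with_imp})
    mean_imp = imp.mean(axis=1, skipna=True)
    n_seeds_present = imp.notna().sum(axis=1)
    top_counts = pd.Series(0, index=imp.index)
    for seed in imp.columns:
        col = imp[seed].dropna().sort_values(ascending=False)
        top_counts[col.index[:top_k]] += 1
    table = pd.DataFrame(
        {
            "mean_importance": mean_imp,
            "n_seeds": n_seeds_present,
            f"times_in_top{top_k}": top_counts,
        }
    )
    table = table[table["mean_importance"] > 0]
    # deterministic order: descending importance, ties by feature name
    table = table.loc[
        sorted(table.index, key=lambda f: (-table.at[f, "mean_importance"], f))
    ]
    table = table.head(top_k)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if directions is not None:
        table["direction_rho"] = directions.reindex(table.index)
    table.index.name = "feature"
    return table


def compute_directions(panel: pd.DataFrame, features: pd.DataFrame,
                       outcome: str) -> pd.Series:
    """Spearman rho of every feature with the outcome across all rows."""
    merged = features.loc[panel["subject_id"].to_numpy()]
    y = panel[outcome].to_numpy(dtype=float)
    out = {}
    for col in features.columns:
        x = merged[col].to_numpy(dtype=float)
        out[col] = feature_direction(x, y) if np.std(x) > 0 and np.std(y) > 0 else np.nan
    return pd.Series(out, name="direction_rho")
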