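"""Per-species mixed-model screening and variance partitioning.

The two-tier scheme: (1) for every species, fit a linear mixed model of
the outcome on clinical covariates, days since trauma, the categorical
follow-up week and the arcsine-square-root transformed abundance of
that species alone, with a subject random intercept (REML); keep
species whose abundance term survives Benjamini-Hochberg FDR control at
q <= 0.05. (2) Combine the survivors in one global mixed model and
partition outcome variation by sequential (Type I) ANOVA sums of
squares, covariates entered first, species last, so the species share
is conservative. Ratios are reported against total variation (fixed SS
plus residual SS) by default; fixed-effects-only ratios are also
computed since published pie-chart shares are ambiguous between the two
normalizations.

statsmodels' MixedLM provides the REML machinery; the screening logic,
selection bookkeeping and SS decomposition live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import CohortTable, SpeciesAbundanceTable

__all__ = [
    "arcsine_sqrt",
    "ScreenResult",
    "screen_features",
    "GlobalLMM",
    "GlobalLMMResults",
    "VariancePartition",
    "fit_global_lmm",
]

logger = logging.getLogger(__name__)

_COVARIATE_TERMS = ("age", "C(sex)", "bmi", "C(race_ethnicity)", "days_since_trauma")
_ABUND_PREFIX = "abund_"


def arcsine_sqrt(p):
    """Variance-stabilizing asin(sqrt(p)) for proportions in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


@dataclass
class ScreenResult:
    feature: str
    coefficient: float
    p_value: float
    q_value: float
    selected: bool
    flagged: bool = False  # singular / non-converged fit, assigned p = 1


def _long_frame(panel: pd.DataFrame, cohort: CohortTable, outcome: str) -> pd.DataFrame:
    df = panel.merge(cohort.data.reset_index(), on="subject_id", how="left")
    if df[["age", "sex", "bmi", "race_ethnicity", "days_since_trauma"]].isna().any().any():
        raise ValueError("covariates incomplete after merging cohort metadata")
    if outcome not in df.columns:
        raise ValueError(f"outcome {outcome!r} not in panel")
    return df


def _formula(outcome: str, extra_terms: list[str]) -> str:
    rhs = list(_COVARIATE_TERMS) + ["C(week)"] + extra_terms
    return f"{outcome} ~ " + " + ".join(rhs)


def _fit_mixed(formula: str, df: pd.DataFrame):
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(reml=True)


def screen_features(
    panel: pd.DataFrame,
    species: SpeciesAbundanceTable,
    cohort: CohortTable,
    outcome: str,
    fdr_level: float = 0.05,
) -> list[ScreenResult]:
    """Independent mixed-model screen of every species against ``outcome``.

    Each fit adjusts for covariates, days since trauma and week; the
    abundance term's Wald p-value enters a single Benjamini-Hochberg
    correction across all species. Singular or failed fits are flagged
    and assigned p = 1 (kept, so the BH family size is stable).
    """
    df = _long_frame(panel, cohort, outcome)
    props = species.to_proportions()
    sample_of = cohort.data["sample_id"]
    # each subject's single microbiome sample, repeated across weeks
    trans = pd.DataFrame(
        arcsine_sqrt(props.to_numpy()), index=props.index, columns=props.columns
    )
    trans_by_subject = trans.loc[sample_of.to_numpy()]
    trans_by_subject.index = sample_of.index

    names, coefs, pvals, flags = [], [], [], []
    for sp in species.species_names:
        x = trans_by_subject[sp]
        df["abund"] = x.reindex(df["subject_id"]).to_numpy()
        names.append(sp)
        if np.ptp(df["abund"].to_numpy()) == 0.0:
            coefs.append(0.0)
            pvals.append(1.0)
            flags.append(True)
            logger.info("screen: %s has zero variance; assigned p = 1", sp)
            continue
        try:
            fit = _fit_mixed(_formula(outcome, ["abund"]), df)
            coef = float(fit.params["abund"])
            p = float(fit.pvalues["abund"])
            bad = not np.isfinite(p)
            coefs.append(coef if np.isfinite(coef) else 0.0)
            pvals.append(p if not bad else 1.0)
            flags.append(bad)
            if bad:
                logger.warning("screen: %s produced a non-finite p-value; assigned p = 1", sp)
        except (np.linalg.LinAlgError, ValueError) as exc:
            coefs.append(0.0)
            pvals.append(1.0)
            flags.append(True)
            logger.warning("screen: %s failed to fit (%s); assigned p = 1", sp, exc)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    return [
        ScreenResult(feature=n, coefficient=c, p_value=p, q_value=float(q),
                     selected=bool(r), flagged=f)
        for n, c, p, q, r, f in zip(names, coefs, pvals, qvals, reject, flags)
    ]


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# global model and variance partition
# ---------------------------------------------------------------------------


@dataclass
class VariancePartition:
    """Sequential-SS shares of outcome variation by model term."""

    sum_squares: pd.Series  # per fixed term, intercept excluded
    residual_ss: float
    ratios: pd.Series  # residual-inclusive, sums (with residual share) to 1
    fixed_only_ratios: pd.Series  # normalized over fixed SS alone
    species_terms: list[str]

    @property
    def residual_ratio(self) -> float:
        total = float(self.sum_squares.sum()) + self.residual_ss
        return self.residual_ss / total

    @property
    def microbiome_share(self) -> float:
        """Share of total outcome variation attributed to species terms."""
        return float(self.ratios[self.species_terms].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sum_squares": self.sum_squares, "ratio": self.ratios,
             "fixed_only_ratio": self.fixed_only_ratios}
        )
        df.loc["Residual"] = [self.residual_ss, self.residual_ratio, np.nan]
        df.index.name = "term"
        return df


class GlobalLMM:
    """Global mixed model over the FDR-selected species set.

    statsmodels-style: construct from the long outcome frame plus the
    selected species, then :meth:`fit` returns :class:`GlobalLMMResults`.
    """

    def __init__(self, panel: pd.DataFrame, species: SpeciesAbundanceTable,
                 cohort: CohortTable, outcome: str, selected: list[str]) -> None:
        self.outcome = outcome
        self.selected = list(selected)
        df = _long_frame(panel, cohort, outcome)
        props = species.to_proportions()
        sample_of = cohort.data["sample_id"]
        self.term_of: dict[str, str] = {}
        dropped: list[str] = []
        cols = {}
        for j, sp in enumerate(self.selected):
            col = f"{_ABUND_PREFIX}{j}"
            x = arcsine_sqrt(props[sp].loc[sample_of.to_numpy()].to_numpy())
            cols[col] = pd.Series(x, index=sample_of.index).reindex(df["subject_id"]).to_numpy()
            self.term_of[col] = sp
        X = pd.DataFrame(cols, index=df.index)
        # drop aliased (collinear) species columns, keeping first occurrences
        if len(X.columns) > 1:
            keep: list[str] = []
            for col in X.columns:
                trial = X[keep + [col]].to_numpy()
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(col)
                else:
                    dropped.append(self.term_of[col])
            if dropped:
                warnings.warn(
                    f"dropping aliased species terms: {dropped}", UserWarning, stacklevel=2
                )
            X = X[keep]
        self.design = pd.concat([df, X], axis=1)
        self.feature_cols = list(X.columns)
        self.dropped = dropped

    def fit(self) -> "GlobalLMMResults":
        if not self.feature_cols:
            return GlobalLMMResults(model=self, fit=None)
        formula = _formula(self.outcome, self.feature_cols)
        return GlobalLMMResults(model=self, fit=_fit_mixed(formula, self.design))


@dataclass
class GlobalLMMResults:
    model: GlobalLMM
    fit: object | None = field(repr=False, default=None)

    @property
    def empty(self) -> bool:
        """True when no species survived selection — an explicit no-model result."""
        return self.fit is None

    @property
    def species_coefficients(self) -> pd.Series:
        if self.empty:
            return pd.Series(dtype=float)
        params = self.fit.params
        return pd.Series(
            {self.model.term_of[c]: params[c] for c in self.model.feature_cols}
        )

    def summary(self):
        if self.empty:
            return "GlobalLMMResults: no species selected; no model was fit."
        return self.fit.summary()

    def variance_partition(self) -> VariancePartition:
        """Sequential Type I decomposition of the outcome's total SS.

        Terms enter in model order (covariates, week, then species);
        each term's SS is the drop in OLS residual SS when its columns
        join the design, so the shares — including the residual share —
        sum to one by construction.
        """
        if self.empty:
            raise ValueError("no model was fit (zero selected features)")
        df = self.model.design
        y = df[self.model.outcome].to_numpy(dtype=float)
        term_blocks: list[tuple[str, np.ndarray]] = []
        term_blocks.append(("age", df[["age"]].to_numpy(dtype=float)))
        term_blocks.append(("sex", pd.get_dummies(df["sex"], drop_first=True).to_numpy(dtype=float)))
        term_blocks.append(("bmi", df[["bmi"]].to_numpy(dtype=float)))
        term_blocks.append((
            "race_ethnicity",
            pd.get_dummies(df["race_ethnicity"], drop_first=True).to_numpy(dtype=float),
        ))
        term_blocks.append(("days_since_trauma", df[["days_since_trauma"]].to_numpy(dtype=float)))
        term_blocks.append(("week", pd.get_dummies(df["week"].astype("category"),
                                                   drop_first=True).to_numpy(dtype=float)))
        species_terms = []
        for col in self.model.feature_cols:
            name = self.model.term_of[col]
            species_terms.append(name)
            term_blocks.append((name, df[[col]].to_numpy(dtype=float)))

        n = len(y)
        design = np.ones((n, 1))
        rss_prev = _ols_rss(design, y)
        ss = {}
        for name, block in term_blocks:
            design = np.hstack([design, block])
            rss = _ols_rss(design, y)
            ss[name] = max(rss_prev - rss, 0.0)
            rss_prev = rss
        residual_ss = rss_prev
        ss_series = pd.Series(ss)
        total = float(ss_series.sum()) + residual_ss
        ratios = ss_series / total
        fixed_total = float(ss_series.sum())
        fixed_only = ss_series / fixed_total if fixed_total > 0 else ss_series * 0.0
        return VariancePartition(
            sum_squares=ss_series,
            residual_ss=residual_ss,
            ratios=ratios,
            fixed_only_ratios=fixed_only,
            species_terms=species_terms,
        )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_global_lmm(panel: pd.DataFrame, species: SpeciesAbundanceTable,
                   cohort: CohortTable, outcome: str,
                   selected: list[str]) -> GlobalLMMResults:
    """Convenience wrapper: build and fit the global model in one call."""
    return GlobalLMM(panel, species, cohort, outcome, selected).fit()
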