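"""Survey-weighted estimation with replicate-weight variance.

The estimation core is a statsmodels-style pair: :class:`SurveyWLS` is built
from an outcome, a design matrix and a :class:`SurveyDesign` (person weight
plus R sets of replicate weights); ``fit()`` returns a
:class:`SurveyWLSResults` carrying coefficients, replicate-based standard
errors, normal-reference 95% CIs and p-values, and a ``summary()`` table.

Variance convention: a generic delete-a-group jackknife,

    Var(beta) = variance_scale * sum_r (beta_r - beta)^2,

with ``variance_scale`` defaulting to (R-1)/R.  Inference uses the standard
normal reference, the usual large-sample convention in complex-survey
analysis where jackknife degrees of freedom are ambiguous.

Higher-level routines build the published table shapes: descriptives by
index quintile with trend tests, index-on-UPF regression models (crude /
sociodemographic-adjusted / + energy misreporting), per-component
associations, and moderation (interaction) models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reference import GroupScheme
from .scoring import INDEX_TYPES, assign_quintile, weighted_quantile

log = logging.getLogger(__name__)

#: Categorical covariates with their level order; the first level is the
#: regression reference category.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "education": ["low", "medium", "high"],
    "country_of_birth": ["australia", "english_speaking", "other"],
    "rurality": ["major_city", "inner_regional", "other"],
    "area_disadvantage": ["q1", "q2", "q3", "q4", "q5"],
}

MODEL1_COVARIATES = ["age", "sex", "education", "country_of_birth", "rurality", "area_disadvantage"]
MODEL2_COVARIATES = MODEL1_COVARIATES + ["ei_bmr_ratio"]


class RankDeficientError(ValueError):
    """The weighted design matrix is rank deficient."""


@dataclass
class SurveyDesign:
    """Person weights plus replicate weights for variance estimation.

    Parameters
    ----------
    person_weight
        Positive full-sample weight per participant.
    replicate_weights
        DataFrame aligned with ``person_weight`` holding R >= 2 non-negative
        replicate weight columns.
    variance_scale
        Multiplier for the sum of squared replicate deviations; defaults to
        (R-1)/R (delete-a-group jackknife).
    """

    person_weight: pd.Series
    replicate_weights: pd.DataFrame
    variance_scale: float | None = None

    def __post_init__(self) -> None:
        if (self.person_weight <= 0).any():
            raise ValueError("person weights must be strictly positive")
        if self.replicate_weights.shape[1] < 2:
            raise ValueError("at least 2 replicate weight columns are required")
        if (self.replicate_weights.to_numpy() < 0).any():
            raise ValueError("replicate weights must be non-negative")
        if not self.person_weight.index.equals(self.replicate_weights.index):
            self.replicate_weights = self.replicate_weights.reindex(self.person_weight.index)
            if self.replicate_weights.isna().any().any():
                raise ValueError("replicate weights not aligned with person weights")
        if self.variance_scale is None:
            r = self.n_replicates
            self.variance_scale = (r - 1) / r

    @property
    def n_replicates(self) -> int:
        return self.replicate_weights.shape[1]

    def subset(self, index: pd.Index) -> "SurveyDesign":
        return SurveyDesign(
            self.person_weight.loc[index],
            self.replicate_weights.loc[index],
            self.variance_scale,
        )


def build_design_matrix(df: pd.DataFrame, terms: list[str], add_const: bool = True) -> pd.DataFrame:
    """Design matrix with treatment-coded categoricals at fixed levels."""
    cols: list[pd.Series | pd.DataFrame] = []
    for term in terms:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            observed = set(df[term].dropna().unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unknown level(s) for {term}: {sorted(unknown)}")
            for level in levels[1:]:
                cols.append((df[term] == level).astype(float).rename(f"{term}[{level}]"))
        else:
            cols.append(df[term].astype(float))
    X = pd.concat(cols, axis=1)
    if add_const:
        # zero-variance columns are absorbed by the intercept (e.g., a
        # constant covariate, or a category level absent from a subgroup)
        keep = [c for c in X.columns if X[c].nunique(dropna=False) > 1]
        dropped = [c for c in X.columns if c not in keep]
        if dropped:
            log.debug("dropping constant design columns: %s", dropped)
        X = X[keep]
        X.insert(0, "const", 1.0)
    return X


def _wls_params(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return sm.WLS(y, X, weights=w).fit(method="pinv").params


class SurveyWLS:
    """Weighted least squares with replicate-weight variance estimation.

    Parameters
    ----------
    endog
        Outcome series aligned with ``exog``.
    exog
        Design matrix (include a constant; see :func:`build_design_matrix`).
    design
        :class:`SurveyDesign` aligned with the data.
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame, design: SurveyDesign):
        if not endog.index.equals(exog.index):
            raise ValueError("endog and exog must share an index")
        self.endog = endog
        self.exog = exog
        self.design = design.subset(endog.index)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, response: str, terms: list[str], design: SurveyDesign
    ) -> "SurveyWLS":
        X = build_design_matrix(df, terms)
        return cls(df[response].astype(float), X, design)

    def _check_rank(self, Xw: np.ndarray) -> None:
        rank = np.linalg.matrix_rank(Xw)
        if rank < Xw.shape[1]:
            # name the collinear columns via QR pivoting on correlations
            _, r = np.linalg.qr(Xw)
            small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
            names = [c for c, s in zip(self.exog.columns, small) if s]
            raise RankDeficientError(
                f"design matrix is rank deficient (rank {rank} < {Xw.shape[1]}); "
                f"suspect columns: {names or list(self.exog.columns)}"
            )

    def fit(self) -> "SurveyWLSResults":
        y = self.endog.to_numpy(dtype=float)
        X = self.exog.to_numpy(dtype=float)
        w = self.design.person_weight.to_numpy(dtype=float)
        self._check_rank(X * np.sqrt(w)[:, None])
        beta = _wls_params(y, X, w)
        reps = self.design.replicate_weights.to_numpy(dtype=float)
        deviations = np.empty((reps.shape[1], X.shape[1]))
        for r in range(reps.shape[1]):
            deviations[r] = _wls_params(y, X, reps[:, r]) - beta
        cov = self.design.variance_scale * deviations.T @ deviations
        return SurveyWLSResults(
            params=pd.Series(beta, index=self.exog.columns),
            cov_params_=pd.DataFrame(cov, index=self.exog.columns, columns=self.exog.columns),
            nobs=len(y),
            n_replicates=reps.shape[1],
            model=self,
        )


@dataclass
class SurveyWLSResults:
    """Fit results: coefficients, replicate-based uncertainty, diagnostics."""

    params: pd.Series
    cov_params_: pd.DataFrame
    nobs: int
    n_replicates: int
    model: SurveyWLS = field(repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.tvalues.to_numpy()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_

    @property
    def fittedvalues(self) -> pd.Series:
        return pd.Series(
            self.model.exog.to_numpy() @ self.params.to_numpy(), index=self.model.endog.index
        )

    @property
    def resid(self) -> pd.Series:
        return self.model.endog - self.fittedvalues

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Survey-weighted least squares (replicate-weight variance)",
            f"  n obs: {self.nobs}    replicates: {self.n_replicates}    "
            f"variance scale: {self.model.design.variance_scale:.4f}",
            "",
            f"{'term':<28}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>9}{'[0.025':>10}{'0.975]':>10}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:<28}{self.params[term]:>10.4f}{self.bse[term]:>10.4f}"
                f"{self.tvalues[term]:>8.2f}{self.pvalues[term]:>9.3g}"
                f"{ci.loc[term, 'ci_low']:>10.4f}{ci.loc[term, 'ci_high']:>10.4f}"
            )
        return "\n".join(lines)

    def term_row(self, term: str) -> dict:
        ci = self.conf_int()
        return {
            "term": term,
            "beta": float(self.params[term]),
            "se": float(self.bse[term]),
            "ci_low": float(ci.loc[term, "ci_low"]),
            "ci_high": float(ci.loc[term, "ci_high"]),
            "p_value": float(self.pvalues[term]),
        }


# ---------------------------------------------------------------------------
# cohort filter and descriptive machinery


def filter_cohort(participants: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequential exclusions: under 19 y, pregnant, breastfeeding, missing UPF.

    Returns the analysis set and an exclusion ledger with counts in that
    order plus the number retained.
    """
    ledger: dict[str, int] = {"initial": len(participants)}
    df = participants
    steps = [
        ("under19", df["age"] < 19),
        ("pregnant", None),
        ("breastfeeding", None),
        ("missing_upf", None),
    ]
    for name, _ in steps:
        if name == "under19":
            mask = df["age"] < 19
        else:
            mask = df[name].astype(bool) if name in df.columns else pd.Series(False, index=df.index)
        ledger[name] = int(mask.sum())
        df = df.loc[~mask]
    ledger["included"] = len(df)
    log.info("cohort filter: %s", ledger)
    return df, ledger


def weighted_estimate(
    values: pd.Series, design: SurveyDesign, statistic: str = "mean"
) -> tuple[float, float]:
    """Survey-weighted mean or proportion with replicate-based SE."""
    design = design.subset(values.index)
    v = values.astype(float).to_numpy()
    w = design.person_weight.to_numpy(dtype=float)
    if statistic == "proportion":
        v = v.astype(bool).astype(float)
    elif statistic != "mean":
        raise ValueError("statistic must be 'mean' or 'proportion'")
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    theta = float(np.average(v, weights=w))
    reps = design.replicate_weights.to_numpy(dtype=float)
    rep_tot = reps.sum(axis=0)
    if (rep_tot <= 0).any():
        raise ValueError("a replicate has zero total weight")
    thetas = (v[:, None] * reps).sum(axis=0) / rep_tot
    se = float(np.sqrt(design.variance_scale * ((thetas - theta) ** 2).sum()))
    return theta, se


def weighted_chi2(
    a: pd.Series, b: pd.Series, design: SurveyDesign, rao_scott: bool = False
) -> tuple[float, int, float]:
    """Weighted Pearson chi-square test of homogeneity between two categoricals.

    The statistic is Pearson's chi-square computed on the survey-weighted
    contingency table (so with unit weights it reduces to the classic
    count-based statistic).  ``rao_scott=True`` applies a first-order
    design-effect correction estimated from the replicate weights.
    """
    design = design.subset(a.index)
    w = design.person_weight

    def table(weights: pd.Series) -> pd.DataFrame:
        return pd.crosstab(a, b, values=weights, aggfunc="sum").fillna(0.0)

    obs = table(w)
    n = obs.to_numpy().sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected <= 0).any():
        # drop empty rows/cols
        obs = obs.loc[obs.sum(axis=1) > 0, obs.sum(axis=0) > 0]
        n = obs.to_numpy().sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = float((((obs.to_numpy() - expected) ** 2) / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if df <= 0:
        return 0.0, 0, 1.0
    if rao_scott:
        # first-order correction: mean design effect of the cell proportions
        p_full = obs.to_numpy().ravel() / n
        reps = design.replicate_weights
        rep_p = np.stack(
            [
                table(reps.iloc[:, r]).reindex_like(obs).fillna(0.0).to_numpy().ravel()
                / max(table(reps.iloc[:, r]).to_numpy().sum(), 1e-300)
                for r in range(design.n_replicates)
            ]
        )
        var_rep = design.variance_scale * ((rep_p - p_full) ** 2).sum(axis=0)
        n_eff = w.sum() ** 2 / (w**2).sum()
        var_srs = p_full * (1 - p_full) / n_eff
        ok = var_srs > 0
        deff = float(np.mean(var_rep[ok] / var_srs[ok])) if ok.any() else 1.0
        deff = max(deff, 1e-12)
        stat = stat / deff
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# published table shapes


def fit_index_models(
    table: pd.DataFrame,
    design: SurveyDesign,
    transpose: bool = False,
) -> pd.DataFrame:
    """Crude / model-1 / model-2 regressions of UPF energy share on each index.

    The outcome is the percent of daily energy from UPFs and the exposure is
    the index score (per the analysis plan); ``transpose=True`` swaps them
    as a sensitivity analysis.  Model 1 adds the sociodemographic
    covariates; model 2 adds the EI:BMR misreporting ratio.  The reported
    row is the index (or UPF) term.
    """
    rows = []
    model_terms = {"crude": [], "model1": MODEL1_COVARIATES, "model2": MODEL2_COVARIATES}
    for index_type in INDEX_TYPES:
        for tag, covs in model_terms.items():
            if transpose:
                response, exposure = index_type, "pct_energy_upf"
            else:
                response, exposure = "pct_energy_upf", index_type
            res = SurveyWLS.from_dataframe(table, response, [exposure] + covs, design).fit()
            row = res.term_row(exposure)
            row.update({"index": index_type, "model": tag, "n": res.nobs})
            rows.append(row)
    return pd.DataFrame(rows)[
        ["index", "model", "term", "beta", "se", "ci_low", "ci_high", "p_value", "n"]
    ]


def component_associations(
    table: pd.DataFrame, design: SurveyDesign, scheme: GroupScheme
) -> pd.DataFrame:
    """Model-2-adjusted association of each component score with UPF share.

    One fit per component per index, UPF % energy as the outcome, the
    component score as exposure plus the model-2 covariates.  The six
    animal groups enter as a single combined score (sum of the six animal
    component scores), which is identical under all three indices because
    animal groups are reverse-scored throughout.
    """
    rows = []
    plant_groups = [g for g in scheme.analysis_groups if scheme.health_class[g] != "animal"]
    animal_groups = scheme.groups_of_class("animal")
    work = table.copy()
    for index_type in INDEX_TYPES:
        work[f"{index_type}_animal_combined"] = work[
            [f"{index_type}_{g}" for g in animal_groups]
        ].sum(axis=1)
    for index_type in INDEX_TYPES:
        for group in list(plant_groups) + ["animal_combined"]:
            col = f"{index_type}_{group}"
            res = SurveyWLS.from_dataframe(
                work, "pct_energy_upf", [col] + MODEL2_COVARIATES, design
            ).fit()
            row = res.term_row(col)
            row.update(
                {
                    "index": index_type,
                    "group": group,
                    "health_class": scheme.health_class.get(group, "animal"),
                    "n": res.nobs,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)[
        ["index", "group", "health_class", "beta", "se", "ci_low", "ci_high", "p_value", "n"]
    ]


CONTINUOUS_ROWS = ["pct_energy_upf", "energy_kcal", "age"]
CATEGORICAL_ROWS = ["sex", "education", "country_of_birth", "rurality", "area_disadvantage"]


def quintile_table(
    table: pd.DataFrame,
    design: SurveyDesign,
    index_type: str,
    rao_scott: bool = False,
) -> pd.DataFrame:
    """Descriptives by weighted quintile of one diet index, with trend tests.

    Continuous rows report the weighted mean (SE) per quintile and a trend
    p-value from a survey-weighted regression of the row variable on the
    quintile number (1-5); categorical rows report weighted percentages and
    a weighted Pearson chi-square across quintiles.
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index type {index_type!r}")
    design = design.subset(table.index)
    scores = table[index_type].astype(float)
    cuts = weighted_quantile(
        scores.to_numpy(), design.person_weight.to_numpy(), [0.2, 0.4, 0.6, 0.8]
    )
    q = pd.Series(assign_quintile(scores.to_numpy(), cuts), index=table.index, name="quintile")
    work = table.copy()
    work["quintile"] = q.astype(float)

    total_w = design.person_weight.sum()
    out_rows: list[dict] = []

    def quintile_cells(fn) -> dict:
        cells = {}
        for k in range(1, 6):
            idx = q.index[q == k]
            est, se = fn(idx)
            cells[f"q{k}"] = est
            cells[f"q{k}_se"] = se
        return cells

    # unweighted n and weight-adjusted share
    cells = {}
    for k in range(1, 6):
        idx = q.index[q == k]
        cells[f"q{k}"] = float(len(idx))
        cells[f"q{k}_se"] = float(100 * design.person_weight.loc[idx].sum() / total_w)
    out_rows.append({"row": "n_pct_weighted", "level": "", **cells, "p_trend": np.nan, "test": ""})

    cont = [index_type] + [r for r in CONTINUOUS_ROWS if r in work.columns]
    for var in cont:
        cells = quintile_cells(
            lambda idx, v=var: weighted_estimate(work.loc[idx, v], design, "mean")
        )
        trend = SurveyWLS.from_dataframe(work, var, ["quintile"], design).fit()
        out_rows.append(
            {
                "row": var,
                "level": "",
                **cells,
                "p_trend": float(trend.pvalues["quintile"]),
                "test": "linear",
            }
        )
    for var in [r for r in CATEGORICAL_ROWS if r in work.columns]:
        _, _, p = weighted_chi2(work[var], q, design, rao_scott=rao_scott)
        for level in CATEGORICAL_LEVELS.get(var, sorted(work[var].unique())):
            cells = quintile_cells(
                lambda idx, v=var, lv=level: tuple(
                    100 * x for x in weighted_estimate(work.loc[idx, v] == lv, design, "proportion")
                )
            )
            out_rows.append(
                {"row": var, "level": level, **cells, "p_trend": p, "test": "chi2"}
            )
    return pd.DataFrame(out_rows)


def moderation_models(
    table: pd.DataFrame,
    design: SurveyDesign,
    moderators: tuple[str, ...] = ("age", "sex", "education"),
) -> pd.DataFrame:
    """Model 2 augmented with index x moderator interaction terms.

    For each index and moderator the model-2 fit gains product term(s)
    between the index score and the moderator (its dummy columns when
    categorical); the interaction coefficients are reported, and subgroup
    model-2 fits by moderator level (median split for age) are emitted
    alongside with ``model='subgroup'``.
    """
    rows = []
    for index_type in INDEX_TYPES:
        for mod in moderators:
            work = table.copy()
            if mod in CATEGORICAL_LEVELS:
                inter_cols = []
                for level in CATEGORICAL_LEVELS[mod][1:]:
                    col = f"{index_type}:{mod}[{level}]"
                    work[col] = work[index_type].astype(float) * (work[mod] == level).astype(float)
                    inter_cols.append(col)
            else:
                col = f"{index_type}:{mod}"
                work[col] = work[index_type].astype(float) * work[mod].astype(float)
                inter_cols = [col]
            terms = [index_type] + MODEL2_COVARIATES + inter_cols
            res = SurveyWLS.from_dataframe(work, "pct_energy_upf", terms, design).fit()
            for col in inter_cols:
                row = res.term_row(col)
                row.update(
                    {"index": index_type, "moderator": mod, "model": "interaction", "n": res.nobs}
                )
                rows.append(row)
            # subgroup fits
            if mod in CATEGORICAL_LEVELS:
                levels = {lv: table.index[table[mod] == lv] for lv in CATEGORICAL_LEVELS[mod]}
            else:
                med = weighted_quantile(
                    table[mod].to_numpy(),
                    design.subset(table.index).person_weight.to_numpy(),
                    [0.5],
                )[0]
                levels = {
                    f"{mod}<= {med:g}": table.index[table[mod] <= med],
                    f"{mod}> {med:g}": table.index[table[mod] > med],
                }
            for label, idx in levels.items():
                if len(idx) < 20:
                    continue
                sub = table.loc[idx]
                covs = [c for c in MODEL2_COVARIATES if c != mod]
                res_s = SurveyWLS.from_dataframe(
                    sub, "pct_energy_upf", [index_type] + covs, design.subset(idx)
                ).fit()
                row = res_s.term_row(index_type)
                row.update(
                    {
                        "index": index_type,
                        "moderator": f"{mod}={label}",
                        "model": "subgroup",
                        "n": res_s.nobs,
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)[
        ["index", "moderator", "model", "term", "beta", "se", "ci_low", "ci_high", "p_value", "n"]
    ]
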