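"""Association stages: standardized linear regression, ANOVA with Bonferroni
post hoc comparisons, and age/sex-adjusted logistic regression.

These are the three analyses run on a cohort once the GRS is computed:

* multiple linear regression of maximum IOP (or mean VCDR) on age, sex and
  either the nine individual variant dosages or the GRS, reporting
  *standardized* coefficients (beta * sd(x)/sd(y)) alongside raw-scale
  coefficients and standard errors;
* one-way ANOVA of the GRS across control/NTG/HTG with pairwise post hoc
  t-tests at the Bonferroni threshold alpha = 0.05/3;
* logistic regression of case status (NTG or HTG vs control) on age, male
  sex and the GRS, with per-unit odds ratios and Wald 95% CIs.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from pydantic import BaseModel
from scipy import stats

from .errors import (
    CollinearityError,
    ContractError,
    DegenerateLabelsError,
    InsufficientDataError,
)
from .panel import VariantPanel
from .scoring import ScoreVector, _fit_logit

POSTHOC_ALPHA = 0.05 / 3  # Bonferroni threshold for 3 pairwise comparisons


# ---------------------------------------------------------------------------
# result models
# ---------------------------------------------------------------------------


class PredictorEffect(BaseModel):
    name: str
    beta_standardized: float
    beta_raw: float
    se_raw: float
    p_value: float


class LinearStageResult(BaseModel):
    outcome: str
    predictors: List[PredictorEffect]
    f_statistic: float
    f_pvalue: float
    r_squared: float
    n_used: int

    def predictor(self, name: str) -> PredictorEffect:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


class GroupStat(BaseModel):
    n: int
    mean: float
    sd: float


class PairwiseComparison(BaseModel):
    pair: Tuple[str, str]
    t_statistic: float
    p_value: float  # unadjusted two-sided
    p_bonferroni: float  # 3*p capped at 1
    significant_at_bonferroni: bool  # p_value < 0.05/3


class AnovaStageResult(BaseModel):
    groups: Dict[str, GroupStat]
    f_statistic: float
    p_value: float
    comparisons: List[PairwiseComparison]
    posthoc_alpha: float = POSTHOC_ALPHA
    posthoc_method: Literal["pooled", "welch"] = "pooled"

    def comparison(self, a: str, b: str) -> PairwiseComparison:
        want = frozenset((a, b))
        for c in self.comparisons:
            if frozenset(c.pair) == want:
                return c
        raise KeyError((a, b))


class LogisticPredictor(BaseModel):
    name: str
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None


class LogisticStageResult(BaseModel):
    contrast: str  # "NTG-vs-control" | "HTG-vs-control" | free-form
    n_cases: int
    n_controls: int
    separated: bool = False
    predictors: List[LogisticPredictor] = []

    def predictor(self, name: str) -> LogisticPredictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


# ---------------------------------------------------------------------------
# linear stage
# ---------------------------------------------------------------------------


def standardized_linear_regression(
    outcome: Sequence[float],
    predictors: pd.DataFrame,
    outcome_name: str = "outcome",
) -> LinearStageResult:
    """OLS with intercept, reporting standardized and raw coefficients.

    Standardization: ``beta_std_j = beta_raw_j * sd(x_j) / sd(y)`` (sample
    SDs), so a single-predictor standardized beta equals the Pearson
    correlation.  Rows with a missing outcome or predictor are dropped and
    reflected in ``n_used``.  Constant or linearly dependent predictor
    columns raise :class:`CollinearityError`.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    X = predictors.reset_index(drop=True).astype(float)
    if len(y) != len(X):
        raise ContractError("outcome and predictors differ in length")
    ok = np.isfinite(y.to_numpy()) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[ok], X[ok]
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} too small for {p} predictors")
    sds = X.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise CollinearityError(constant)
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(_dependent_columns(X))
    res = sm.OLS(y, design).fit()
    sy = y.std(ddof=1)
    effects = [
        PredictorEffect(
            name=col,
            beta_raw=float(res.params[col]),
            beta_standardized=float(res.params[col] * sds[col] / sy),
            se_raw=float(res.bse[col]),
            p_value=float(res.pvalues[col]),
        )
        for col in X.columns
    ]
    return LinearStageResult(
        outcome=outcome_name,
        predictors=effects,
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        n_used=int(n),
    )


def _dependent_columns(X: pd.DataFrame) -> List[str]:
    """Columns whose removal restores full rank (greedy QR-based scan)."""
    cols = list(X.columns)
    deps = []
    kept: List[str] = []
    for c in cols:
        trial = kept + [c]
        m = np.column_stack([np.ones(len(X))] + [X[k].to_numpy() for k in trial])
        if np.linalg.matrix_rank(m) < m.shape[1]:
            deps.append(c)
        else:
            kept.append(c)
    return deps


def _male_indicator(phenotypes: pd.DataFrame) -> np.ndarray:
    sex = phenotypes["sex"].astype(str).str.upper()
    bad = ~sex.isin(("M", "F"))
    if bad.any():
        raise ContractError(f"unrecognised sex codes: {sorted(sex[bad].unique())}")
    return (sex == "M").to_numpy(dtype=float)


def _merge_scores(phenotypes: pd.DataFrame, scores: ScoreVector) -> pd.DataFrame:
    s = scores.to_frame().rename(columns={"grs": "_grs"})
    merged = phenotypes.merge(s[["participant_id", "_grs"]], on="participant_id", how="inner")
    return merged


# convenience wrappers over the same contract ---------------------------------


def iop_on_variants(
    genotypes: pd.DataFrame, phenotypes: pd.DataFrame, panel: VariantPanel
) -> LinearStageResult:
    """Maximum IOP on age, male sex, and the nine variant dosages jointly."""
    geno = genotypes.loc[phenotypes["participant_id"]]
    X = pd.DataFrame(
        {"age": phenotypes["age_years"].to_numpy(), "male": _male_indicator(phenotypes)}
    )
    for rsid in panel.rsids:
        X[rsid] = geno[rsid].to_numpy(dtype=float)
    return standardized_linear_regression(
        phenotypes["max_iop_mmhg"], X, outcome_name="max_iop_mmhg"
    )


def iop_on_grs(phenotypes: pd.DataFrame, scores: ScoreVector) -> LinearStageResult:
    """Maximum IOP on age, male sex and the GRS."""
    m = _merge_scores(phenotypes, scores)
    X = pd.DataFrame(
        {"age": m["age_years"].to_numpy(), "male": _male_indicator(m), "grs": m["_grs"]}
    )
    return standardized_linear_regression(m["max_iop_mmhg"], X, outcome_name="max_iop_mmhg")


def vcdr_on_grs(phenotypes: pd.DataFrame, scores: ScoreVector) -> LinearStageResult:
    """Mean VCDR on age, male sex and the GRS."""
    m = _merge_scores(phenotypes, scores)
    X = pd.DataFrame(
        {"age": m["age_years"].to_numpy(), "male": _male_indicator(m), "grs": m["_grs"]}
    )
    return standardized_linear_regression(m["mean_vcdr"], X, outcome_name="mean_vcdr")


def iop_vcdr_correlation(phenotypes: pd.DataFrame) -> LinearStageResult:
    """Mean VCDR on maximum IOP alone; the standardized beta is Pearson's r."""
    X = pd.DataFrame({"max_iop_mmhg": phenotypes["max_iop_mmhg"].to_numpy()})
    return standardized_linear_regression(phenotypes["mean_vcdr"], X, outcome_name="mean_vcdr")


# ---------------------------------------------------------------------------
# ANOVA stage
# ---------------------------------------------------------------------------


def pairwise_t(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> Tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance unless ``welch``."""
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def anova_bonferroni(
    scores: Sequence[float],
    groups: Sequence[str],
    welch: bool = False,
) -> AnovaStageResult:
    """One-way ANOVA over three groups plus Bonferroni post hoc t-tests.

    All three pairwise p-values are reported unadjusted alongside the fixed
    threshold 0.05/3 (the classical Bonferroni decision) and as 3*p adjusted
    values capped at 1.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups, dtype=object)
    ok = np.isfinite(s)
    s, g = s[ok], g[ok]
    labels = sorted(set(g), key=lambda x: str(x))
    if len(labels) < 3:
        raise ContractError(f"need 3 groups, found {labels}")
    samples = {lab: s[g == lab] for lab in labels}
    if not any(len(v) >= 2 and np.std(v) > 0 for v in samples.values()):
        raise ContractError("no group with >=2 observations and nonzero variance")
    f_stat, p = stats.f_oneway(*samples.values())
    comparisons = []
    for a, b in itertools.combinations(labels, 2):
        t, pv = pairwise_t(samples[a], samples[b], welch=welch)
        comparisons.append(
            PairwiseComparison(
                pair=(a, b),
                t_statistic=t,
                p_value=pv,
                p_bonferroni=min(1.0, 3.0 * pv),
                significant_at_bonferroni=bool(pv < POSTHOC_ALPHA),
            )
        )
    return AnovaStageResult(
        groups={
            lab: GroupStat(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))
            for lab, v in samples.items()
        },
        f_statistic=float(f_stat),
        p_value=float(p),
        comparisons=comparisons,
        posthoc_method="welch" if welch else "pooled",
    )


# ---------------------------------------------------------------------------
# logistic stage
# ---------------------------------------------------------------------------


def logistic_case_control(
    case: Sequence[bool],
    predictors: pd.DataFrame,
    contrast: str = "case-vs-control",
) -> LogisticStageResult:
    """Logistic regression of case status; Wald per-unit ORs and 95% CIs.

    Quasi/complete separation is reported as a flagged result with no numeric
    odds ratios rather than divergent estimates.
    """
    y = np.asarray(case, dtype=float)
    X = predictors.reset_index(drop=True).astype(float)
    if len(y) != len(X):
        raise ContractError("labels and predictors differ in length")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise DegenerateLabelsError("one class is empty")
    res = _fit_logit(y, sm.add_constant(X))
    if res is None:
        return LogisticStageResult(
            contrast=contrast, n_cases=n_cases, n_controls=n_controls, separated=True
        )
    ci = res.conf_int()
    preds = [
        LogisticPredictor(
            name=col,
            odds_ratio=float(np.exp(res.params[col])),
            ci_low=float(np.exp(ci.loc[col, 0])),
            ci_high=float(np.exp(ci.loc[col, 1])),
            p_value=float(res.pvalues[col]),
        )
        for col in X.columns
    ]
    return LogisticStageResult(
        contrast=contrast, n_cases=n_cases, n_controls=n_controls, predictors=preds
    )


def logistic_group_on_grs(
    phenotypes: pd.DataFrame,
    scores: ScoreVector,
    contrast: Literal["NTG", "HTG"],
) -> LogisticStageResult:
    """Case (NTG or HTG) vs control on age, male sex and the unweighted GRS."""
    if contrast not in ("NTG", "HTG"):
        raise ContractError(f"contrast must be NTG or HTG, got {contrast!r}")
    m = _merge_scores(phenotypes, scores)
    m = m[m["group"].isin((contrast, "control"))]
    if (m["group"] == contrast).sum() == 0 or (m["group"] == "control").sum() == 0:
        raise ContractError(f"empty {contrast} or control group")
    X = pd.DataFrame(
        {"age": m["age_years"].to_numpy(), "male": _male_indicator(m), "grs": m["_grs"].to_numpy()}
    )
    return logistic_case_control(
        (m["group"] == contrast).to_numpy(), X, contrast=f"{contrast}-vs-control"
    )
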