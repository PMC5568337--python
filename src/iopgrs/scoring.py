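"""Genetic risk score construction.

Two scores over a risk-allele dosage matrix:

* **unweighted GRS** — the total risk-allele count across the panel
  (0..18 for the nine-variant default panel);
* **weighted GRS** — the dosage-weighted sum of per-variant natural-log odds
  ratios, ``score_i = sum_v dosage_iv * ln(OR_v)``, with per-allele ORs
  estimated by single-predictor logistic regression of case status on dosage.

Missing dosages are handled by an explicit policy: ``exclude`` drops the
participant (the default), ``mean_impute`` substitutes the variant's observed
mean dosage (the score may then be non-integer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ContractError, DegenerateLabelsError, SchemaError
from .panel import VariantPanel

log = logging.getLogger(__name__)

MISSING_POLICIES = ("exclude", "mean_impute")


@dataclass
class ScoreVector:
    """Per-participant GRS plus provenance of how it was computed."""

    participant_ids: np.ndarray
    scores: np.ndarray
    kind: str  # "unweighted" | "weighted"
    weights_used: Optional[Dict[str, float]] = None
    n_missing_handled: int = 0
    imputed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": self.participant_ids, "grs": self.scores, "kind": self.kind}
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.participant_ids, name="grs")


@dataclass
class AlleleOR:
    rsid: str
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    separated: bool = False


@dataclass
class AlleleORTable:
    """Per-variant odds ratios for case status, additive (per-allele) coding."""

    entries: Sequence[AlleleOR]
    n_cases: int = 0
    n_controls: int = 0

    def __getitem__(self, rsid: str) -> AlleleOR:
        for e in self.entries:
            if e.rsid == rsid:
                return e
        raise KeyError(rsid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries]).set_index("rsid")

    def weights(self) -> Dict[str, float]:
        """Natural-log OR weights, dropping variants flagged for separation."""
        out = {}
        for e in self.entries:
            if e.separated or not np.isfinite(e.odds_ratio):
                log.warning("excluding %s from weighted GRS (separation/unestimable)", e.rsid)
                continue
            out[e.rsid] = float(np.log(e.odds_ratio))
        return out


def _panel_dosages(genotypes: pd.DataFrame, rsids: Sequence[str]) -> pd.DataFrame:
    missing_cols = [r for r in rsids if r not in genotypes.columns]
    if missing_cols:
        raise SchemaError(f"genotype table lacks panel rsID column(s): {missing_cols}")
    return genotypes[list(rsids)]


def _apply_missing_policy(dosages: pd.DataFrame, policy: str):
    if policy not in MISSING_POLICIES:
        raise ContractError(f"missing_policy must be one of {MISSING_POLICIES}: {policy!r}")
    values = dosages.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    any_bad_row = bad.any(axis=1)
    n_affected = int(any_bad_row.sum())
    if n_affected == 0:
        return values, np.ones(len(dosages), dtype=bool), 0, False
    if policy == "exclude":
        return values, ~any_bad_row, n_affected, False
    col_means = np.nanmean(values, axis=0)
    if not np.all(np.isfinite(col_means)):
        dead = [c for c, m in zip(dosages.columns, col_means) if not np.isfinite(m)]
        raise SchemaError(f"cannot mean-impute: no observed dosages at {dead}")
    values = np.where(bad, col_means[None, :], values)
    return values, np.ones(len(dosages), dtype=bool), n_affected, True


def unweighted_grs(
    genotypes: pd.DataFrame,
    panel: VariantPanel,
    missing_policy: str = "exclude",
) -> ScoreVector:
    """Total risk-allele count per participant over the panel variants.

    Scores lie in [0, 2*len(panel)]; with ``mean_impute`` an imputed score may
    be non-integer but the vector is still of kind "unweighted" with the
    ``imputed`` flag set.
    """
    dosages = _panel_dosages(genotypes, panel.rsids)
    values, keep, n_handled, imputed = _apply_missing_policy(dosages, missing_policy)
    scores = values[keep].sum(axis=1)
    ids = genotypes.index.to_numpy()[keep]
    return ScoreVector(
        participant_ids=ids,
        scores=scores,
        kind="unweighted",
        n_missing_handled=n_handled,
        imputed=imputed,
    )


def weighted_grs(
    genotypes: pd.DataFrame,
    weights: Mapping[str, float],
    missing_policy: str = "exclude",
    panel: Optional[VariantPanel] = None,
) -> ScoreVector:
    """Dosage-weighted sum of per-variant log-OR weights.

    ``weights`` maps rsID -> natural-log odds ratio. When ``panel`` is given,
    a weight must exist for every panel variant (schema error otherwise);
    scoring then follows panel order.
    """
    if panel is not None:
        missing_w = [r for r in panel.rsids if r not in weights]
        if missing_w:
            raise SchemaError(f"missing weight for panel variant(s): {missing_w}")
        rsids = panel.rsids
    else:
        rsids = list(weights)
    w = np.array([float(weights[r]) for r in rsids])
    if not np.all(np.isfinite(w)):
        raise SchemaError("non-finite weight(s) supplied")
    dosages = _panel_dosages(genotypes, rsids)
    values, keep, n_handled, imputed = _apply_missing_policy(dosages, missing_policy)
    scores = values[keep] @ w
    return ScoreVector(
        participant_ids=genotypes.index.to_numpy()[keep],
        scores=scores,
        kind="weighted",
        weights_used=dict(zip(rsids, w.tolist())),
        n_missing_handled=n_handled,
        imputed=imputed,
    )


def estimate_allele_ors(genotypes: pd.DataFrame, labels: Sequence[bool]) -> AlleleORTable:
    """Per-allele odds ratios by single-predictor logistic regression.

    For each variant independently, case status is regressed on dosage
    (additive coding, no covariates); OR = exp(coefficient) with Wald 95% CI.
    Variants showing quasi/complete separation are flagged rather than
    reported with divergent estimates.
    """
    y = np.asarray(labels, dtype=float)
    if len(y) != len(genotypes):
        raise ContractError("labels not aligned to genotype rows")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    if n_cases < 2 or n_controls < 2:
        raise DegenerateLabelsError(
            f"need >=2 cases and >=2 controls, got {n_cases}/{n_controls}"
        )
    entries = []
    for rsid in genotypes.columns:
        x = genotypes[rsid].to_numpy(dtype=float)
        ok = np.isfinite(x)
        res = _fit_logit(y[ok], sm.add_constant(x[ok]))
        if res is None:
            entries.append(AlleleOR(rsid=rsid, separated=True))
            continue
        coef = res.params[1]
        lo, hi = res.conf_int()[1]
        entries.append(
            AlleleOR(
                rsid=rsid,
                odds_ratio=float(np.exp(coef)),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)),
                p_value=float(res.pvalues[1]),
            )
        )
    return AlleleORTable(entries=entries, n_cases=n_cases, n_controls=n_controls)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Fit a logistic model; return None on separation or non-convergence."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.abs(res.params).max() > 15:  # quasi-separation: runaway coefficient
        return None
    return res
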