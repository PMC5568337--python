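"""Synthetic cohort generator for the IOP-related GRS analyses.

The study design being emulated is a clinic-based case-control collection of
Japanese participants in three diagnostic groups:

* **control** — no glaucoma, maximum IOP <= 21 mmHg, mean VCDR <= 0.4;
* **NTG** (normal tension glaucoma) — glaucoma with maximum IOP <= 21 mmHg;
* **HTG** (high tension glaucoma) — glaucoma with at least one IOP
  measurement >= 22 mmHg.

The generative model is a two-liability scheme:

1. *Latent maximum IOP* is additive in risk-allele dosage over the variant
   panel, with age and sex covariate effects, a latent shift for
   glaucoma-vulnerable subjects, and Gaussian noise.  Subjects whose latent
   IOP crosses the 22 mmHg threshold receive an extra log-normal "tail"
   inflation, reflecting that the observed *maximum* of many pressure
   readings in ocular-hypertensive eyes is strongly right-skewed.
2. *Glaucoma vulnerability* (a stand-in for the aggregate burden of
   non-IOP-related susceptibility variants) is an independent Bernoulli
   latent; vulnerable subjects develop glaucoma and are classified NTG or HTG
   purely by their maximum IOP.

Mean VCDR is linear in the (observed) maximum IOP with an additive glaucoma
offset and Gaussian noise, clamped to [0, 1].

Maximum IOP is rounded to 1 decimal (tonometry granularity) and VCDR to two
decimals *before* group assignment, so writing a cohort to CSV and reading it
back is lossless.  All draws are vectorised and reproducible from a single
integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError, ContractError, GenerationInfeasibleError
from .panel import VariantPanel

GROUPS = ("control", "NTG", "HTG")

#: phenotype columns of a finished cohort, in canonical order
PHENOTYPE_COLUMNS = (
    "participant_id",
    "age_years",
    "sex",
    "max_iop_mmhg",
    "mean_vcdr",
    "group",
)

HTG_IOP_THRESHOLD = 22.0  # mmHg, inclusive
NORMAL_IOP_CEILING = 21.0  # mmHg, inclusive
CONTROL_VCDR_CEILING = 0.4


# ---------------------------------------------------------------------------
# parameter models
# ---------------------------------------------------------------------------


class NoiseSpec(BaseModel):
    """Additive noise distribution. Only the Gaussian family is implemented."""

    family: Literal["normal"] = "normal"
    sd: float = Field(ge=0.0)


class TailSpec(BaseModel):
    """Right-tail inflation added to latent IOP above the HTG threshold.

    ``lognormal`` draws exp(N(mu, sigma^2)); the draw is added to the latent
    IOP only when the latent value is already >= 22 mmHg.
    """

    family: Literal["lognormal"] = "lognormal"
    mu: float = 0.0
    sigma: float = Field(default=1.0, ge=0.0)


class VcdrModel(BaseModel):
    """mean_vcdr = intercept + iop_slope*max_iop + glaucoma_offset*glaucoma + N(0, sd)."""

    intercept: float
    iop_slope: float
    glaucoma_offset: float
    noise_sd: float = Field(ge=0.0)


class GroupProfile(BaseModel):
    """Age/sex sampling distribution used when drawing candidates for a group."""

    age_mean: float
    age_sd: float = Field(ge=0.0)
    male_fraction: float = Field(ge=0.0, le=1.0)


class Quotas(BaseModel):
    control: int = Field(gt=0)
    ntg: int = Field(gt=0)
    htg: int = Field(gt=0)

    @property
    def total(self) -> int:
        return self.control + self.ntg + self.htg

    def for_group(self, group: str) -> int:
        return {"control": self.control, "NTG": self.ntg, "HTG": self.htg}[group]


class GeneratorParams(BaseModel):
    """Full parameterisation of the synthetic cohort generator."""

    panel: VariantPanel
    baseline_iop_mmhg: float
    age_effect_per_year: float
    male_effect_mmhg: float
    age_reference_years: float = 65.0
    iop_noise: NoiseSpec
    htg_tail: TailSpec
    #: latent IOP shift (mmHg) for glaucoma-vulnerable subjects; lets the NTG
    #: maximum-IOP distribution sit above the control distribution below the
    #: shared 21 mmHg ceiling
    glaucoma_iop_shift_mmhg: float = 0.0
    vulnerability_prevalence: float = Field(gt=0.0, lt=1.0)
    vcdr_model: VcdrModel
    #: candidate age/sex profiles keyed by "control", "NTG", "HTG" and
    #: "population" (the profile used when no target group is specified)
    group_profiles: Dict[str, GroupProfile]
    quotas: Quotas
    seed: int = 0
    #: rejection-sampling budget, multiples of the total quota
    attempt_cap_multiple: int = Field(default=1000, gt=0)

    @model_validator(mode="after")
    def _check_profiles(self) -> "GeneratorParams":
        missing = [g for g in (*GROUPS, "population") if g not in self.group_profiles]
        if missing:
            raise ValueError(f"group_profiles missing entries for {missing}")
        return self

    @classmethod
    def from_profile(cls, name: str = "paper_calibrated", **overrides) -> "GeneratorParams":
        """Load a packaged profile; keyword overrides replace top-level fields."""
        data = load_profile(name)["params"]
        data.update(overrides)
        return cls.model_validate(data)

    def with_updates(self, **updates) -> "GeneratorParams":
        """Validated copy with top-level fields replaced (accepts plain dicts
        for nested models, unlike ``model_copy``)."""
        data = self.model_dump()
        data.update(updates)
        return GeneratorParams.model_validate(data)

    @classmethod
    def from_json(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            data = json.load(fh)
        if "params" in data:  # full profile file
            data = data["params"]
        return cls.model_validate(data)


def load_profile(name: str) -> dict:
    """Return a packaged generator profile as a dict (with calibration record)."""
    try:
        text = resources.files("iopgrs.data").joinpath(f"{name}.json").read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown packaged profile: {name}") from exc
    return json.loads(text)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Genotypes (participants x rsIDs dosage matrix) plus phenotype table."""

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    params_used: Optional[GeneratorParams] = None

    def __post_init__(self):
        if list(self.genotypes.index) != list(self.phenotypes["participant_id"]):
            raise ContractError("genotype rows and phenotype rows are not aligned")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def group_counts(self) -> pd.Series:
        return self.phenotypes["group"].value_counts()

    def validate_invariants(self) -> None:
        """Assert the diagnostic-group IOP/VCDR constraints on every row."""
        ph = self.phenotypes
        htg = ph[ph["group"] == "HTG"]
        ntg = ph[ph["group"] == "NTG"]
        ctl = ph[ph["group"] == "control"]
        if not (htg["max_iop_mmhg"] >= HTG_IOP_THRESHOLD).all():
            raise ContractError("HTG row with max IOP below 22 mmHg")
        if not (ntg["max_iop_mmhg"] <= NORMAL_IOP_CEILING).all():
            raise ContractError("NTG row with max IOP above 21 mmHg")
        if not (ctl["max_iop_mmhg"] <= NORMAL_IOP_CEILING).all():
            raise ContractError("control row with max IOP above 21 mmHg")
        if not (ctl["mean_vcdr"] <= CONTROL_VCDR_CEILING).all():
            raise ContractError("control row with mean VCDR above 0.4")

    def write_csv(self, prefix) -> tuple[str, str]:
        """Write `<prefix>_genotypes.csv` and `<prefix>_phenotypes.csv`."""
        gpath = f"{prefix}_genotypes.csv"
        ppath = f"{prefix}_phenotypes.csv"
        geno = self.genotypes.copy()
        geno.insert(0, "participant_id", geno.index)
        geno.to_csv(gpath, index=False)
        self.phenotypes.to_csv(ppath, index=False)
        return gpath, ppath


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(panel: VariantPanel, n: int, seed) -> pd.DataFrame:
    """Draw an n x len(panel) risk-allele dosage matrix under Hardy-Weinberg.

    Each dosage is Binomial(2, f_v): the sum of two independent allele draws
    at the variant's risk-allele frequency.  Returns a DataFrame with rsID
    columns and a default integer index (participant ids are assigned when a
    cohort is assembled).
    """
    if n < 1:
        raise ContractError(f"n must be >= 1, got {n}")
    freqs = panel.frequencies
    if not np.all(np.isfinite(freqs)) or freqs.min() < 0 or freqs.max() > 1:
        raise ConfigError(f"risk-allele frequencies out of range: {freqs}")
    rng = _as_rng(seed)
    dosages = rng.binomial(2, freqs[None, :], size=(n, len(panel)))
    return pd.DataFrame(dosages.astype(np.int8), columns=panel.rsids)


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    params: GeneratorParams,
    seed,
    profile: str = "population",
) -> pd.DataFrame:
    """Draw phenotypes for each genotype row under the two-liability model.

    ``profile`` selects the candidate age/sex distribution ("population" or a
    diagnostic group name; quota sampling uses the group-specific profiles so
    the realised covariate structure matches the emulated study groups).

    Returns a DataFrame with columns age_years, sex ("M"/"F"), latent_iop_mmhg
    (pre-rounding, pre-inflation; useful for model checking), max_iop_mmhg,
    mean_vcdr, vulnerable, and the assigned ``group`` (one of control/NTG/HTG
    or "ineligible" for draws fitting no group definition).
    """
    panel = params.panel
    if list(genotypes.columns) != panel.rsids:
        raise ContractError(
            "genotype columns do not match params.panel "
            f"({list(genotypes.columns)} vs {panel.rsids})"
        )
    if profile not in params.group_profiles:
        raise ConfigError(f"no group profile named {profile!r}")
    prof = params.group_profiles[profile]
    n = len(genotypes)
    rng = _as_rng(seed)

    # fixed draw order => deterministic given seed
    age = rng.normal(prof.age_mean, prof.age_sd, n)
    male = rng.random(n) < prof.male_fraction
    iop_noise = rng.normal(0.0, params.iop_noise.sd, n)
    vulnerable = rng.random(n) < params.vulnerability_prevalence
    tail = rng.lognormal(params.htg_tail.mu, params.htg_tail.sigma, n)
    vcdr_noise = rng.normal(0.0, params.vcdr_model.noise_sd, n)

    dosage = genotypes.to_numpy(dtype=float)
    latent = (
        params.baseline_iop_mmhg
        + dosage @ panel.effects
        + params.age_effect_per_year * (age - params.age_reference_years)
        + params.male_effect_mmhg * male
        + params.glaucoma_iop_shift_mmhg * vulnerable
        + iop_noise
    )
    max_iop = np.round(np.where(latent >= HTG_IOP_THRESHOLD, latent + tail, latent), 1)

    vm = params.vcdr_model
    vcdr = vm.intercept + vm.iop_slope * max_iop + vm.glaucoma_offset * vulnerable + vcdr_noise
    vcdr = np.round(np.clip(vcdr, 0.0, 1.0), 2)

    group = np.full(n, "ineligible", dtype=object)
    high = max_iop >= HTG_IOP_THRESHOLD
    normal = max_iop <= NORMAL_IOP_CEILING
    group[vulnerable & high] = "HTG"
    group[vulnerable & normal] = "NTG"
    group[~vulnerable & normal & (vcdr <= CONTROL_VCDR_CEILING)] = "control"

    return pd.DataFrame(
        {
            "age_years": np.round(age, 1),
            "sex": np.where(male, "M", "F"),
            "latent_iop_mmhg": latent,
            "max_iop_mmhg": max_iop,
            "mean_vcdr": vcdr,
            "vulnerable": vulnerable,
            "group": group,
        },
        index=genotypes.index,
    )


def simulate_eligible(
    params: GeneratorParams,
    group: str,
    n: int,
    seed,
    max_attempts: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rejection-sample ``n`` participants eligible for one diagnostic group.

    Candidates are drawn with the group's age/sex profile and kept when the
    generative model assigns them to ``group``.  Returns (genotypes,
    phenotypes) with a fresh RangeIndex, phenotypes restricted to eligible
    rows (internal columns retained).  Raises
    :class:`GenerationInfeasibleError` when the attempt budget is exhausted.
    """
    if group not in GROUPS:
        raise ContractError(f"unknown group {group!r}")
    rng = _as_rng(seed)
    cap = max_attempts if max_attempts is not None else params.attempt_cap_multiple * n
    geno_parts, pheno_parts = [], []
    got = 0
    attempts = 0
    while got < n:
        if attempts >= cap:
            raise GenerationInfeasibleError(group, attempts, got, n)
        chunk = int(min(max(4096, 2 * (n - got)), cap - attempts))
        g = simulate_genotypes(params.panel, chunk, rng)
        p = simulate_phenotypes(g, params, rng, profile=group)
        attempts += chunk
        keep = p["group"] == group
        if keep.any():
            geno_parts.append(g.loc[keep])
            pheno_parts.append(p.loc[keep])
            got += int(keep.sum())
    geno = pd.concat(geno_parts, ignore_index=True).head(n)
    pheno = pd.concat(pheno_parts, ignore_index=True).head(n)
    return geno, pheno


def simulate_case_control_logistic(
    panel: VariantPanel,
    or_per_allele: float,
    n_cases: int,
    n_controls: int,
    seed,
    age_mean: float = 65.0,
    age_sd: float = 13.0,
    male_fraction: float = 0.5,
    age_or_per_year: float = 0.98,
    male_or: float = 2.63,
    intercept: float = -1.0,
    max_attempts: int = 2_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-control cohort with an exactly specified per-allele odds ratio.

    Disease status follows a prospective logistic model on the unweighted
    risk-allele count G, age and sex::

        logit P(case) = intercept + ln(or_per_allele) * G
                        + ln(age_or_per_year) * (age - 65) + ln(male_or) * male

    and cases/controls are then quota-sampled from the simulated population.
    Under retrospective (case-control) sampling the logistic slope
    coefficients remain consistent for the prospective ones, so fitting the
    age/sex-adjusted logistic model to the output recovers ``or_per_allele``
    up to sampling error — the construction used for odds-ratio recovery
    experiments, where the liability-threshold cohort model cannot pin the
    per-allele OR analytically.

    Returns (genotypes, phenotypes) where phenotypes has columns
    participant_id, age_years, sex, case (bool).
    """
    if not (or_per_allele > 0 and np.isfinite(or_per_allele)):
        raise ConfigError(f"or_per_allele must be finite and positive: {or_per_allele}")
    rng = _as_rng(seed)
    beta_g = np.log(or_per_allele)
    beta_age = np.log(age_or_per_year)
    beta_male = np.log(male_or)

    geno_cases, geno_ctls = [], []
    cov_cases, cov_ctls = [], []
    nc = nk = 0
    attempts = 0
    while nc < n_cases or nk < n_controls:
        if attempts >= max_attempts:
            starved = "cases" if nc < n_cases else "controls"
            raise GenerationInfeasibleError(
                starved, attempts, nc if starved == "cases" else nk,
                n_cases if starved == "cases" else n_controls,
            )
        chunk = 8192
        g = simulate_genotypes(panel, chunk, rng)
        age = rng.normal(age_mean, age_sd, chunk)
        male = rng.random(chunk) < male_fraction
        eta = (
            intercept
            + beta_g * g.to_numpy(dtype=float).sum(axis=1)
            + beta_age * (age - 65.0)
            + beta_male * male
        )
        case = rng.random(chunk) < 1.0 / (1.0 + np.exp(-eta))
        attempts += chunk
        cov = pd.DataFrame(
            {"age_years": np.round(age, 1), "sex": np.where(male, "M", "F"), "case": case}
        )
        if nc < n_cases and case.any():
            geno_cases.append(g.loc[case])
            cov_cases.append(cov.loc[case])
            nc += int(case.sum())
        if nk < n_controls and (~case).any():
            geno_ctls.append(g.loc[~case])
            cov_ctls.append(cov.loc[~case])
            nk += int((~case).sum())
    geno = pd.concat(
        [pd.concat(geno_cases, ignore_index=True).head(n_cases),
         pd.concat(geno_ctls, ignore_index=True).head(n_controls)],
        ignore_index=True,
    )
    pheno = pd.concat(
        [pd.concat(cov_cases, ignore_index=True).head(n_cases),
         pd.concat(cov_ctls, ignore_index=True).head(n_controls)],
        ignore_index=True,
    )
    ids = [f"P{i + 1:06d}" for i in range(len(pheno))]
    geno.index = pd.Index(ids, name="participant_id")
    pheno.insert(0, "participant_id", ids)
    return geno, pheno


def sample_cohort(params: GeneratorParams, seed: Optional[int] = None) -> Cohort:
    """Quota-sample a full cohort: exact group sizes from ``params.quotas``.

    Deterministic given (params, seed); ``seed`` defaults to ``params.seed``.
    Participants are ordered control, NTG, HTG and assigned ids P000001...
    """
    base_seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(GROUPS))
    cap = params.attempt_cap_multiple * params.quotas.total
    geno_parts, pheno_parts = [], []
    for group, child in zip(GROUPS, children):
        quota = params.quotas.for_group(group)
        g, p = simulate_eligible(
            params, group, quota, np.random.default_rng(child), max_attempts=cap
        )
        geno_parts.append(g)
        pheno_parts.append(p)
    genotypes = pd.concat(geno_parts, ignore_index=True)
    phenotypes = pd.concat(pheno_parts, ignore_index=True)
    ids = [f"P{i + 1:06d}" for i in range(len(phenotypes))]
    genotypes.index = pd.Index(ids, name="participant_id")
    phenotypes.insert(0, "participant_id", ids)
    phenotypes = phenotypes[list(PHENOTYPE_COLUMNS)]
    cohort = Cohort(genotypes=genotypes, phenotypes=phenotypes, params_used=params)
    cohort.validate_invariants()
    return cohort
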