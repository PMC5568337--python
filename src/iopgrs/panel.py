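"""Variant panel for IOP-related genetic risk scoring.

The default panel is the nine biallelic variants reported as associated with
intraocular pressure (IOP) in GWAS of Japanese and other populations, each
identified by rsID, risk allele (the allele associated with IOP elevation) and
nearby gene label.  Risk-allele frequencies and per-allele IOP effects are not
part of the published panel; the packaged defaults are the frozen output of the
generator calibration (see :mod:`iopgrs.calibrate` and the
``paper_calibrated`` profile) and every value is configurable per variant.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import List

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError

#: (rsID, risk allele, nearby-gene label) of the nine IOP-associated variants.
PANEL_DEFINITION = (
    ("rs1052990", "T", "CAV2"),
    ("rs11656696", "C", "GAS7"),
    ("rs59072263", "G", "GLCCI1/ICA1"),
    ("rs2472493", "C", "ABCA1"),
    ("rs58073046", "G", "ARHGEF12"),
    ("rs2286885", "T", "FAM125B"),
    ("rs6445055", "G", "FNDC3B"),
    ("rs8176743", "A", "ABO"),
    ("rs747782", "G", "PTPRJ"),
)


class Variant(BaseModel):
    """One biallelic variant of the risk panel."""

    rsid: str
    risk_allele: str = Field(pattern=r"^[ACGT]$")
    locus_label: str
    risk_allele_frequency: float = Field(ge=0.0, le=1.0)
    #: additive latent-IOP effect per risk-allele copy, mmHg
    iop_effect_mmhg: float = Field(ge=0.0)

    @field_validator("risk_allele_frequency", "iop_effect_mmhg")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not np.isfinite(v):
            raise ValueError("must be finite")
        return v


class VariantPanel(BaseModel):
    """Ordered collection of risk variants.

    Frequencies must lie strictly inside (0, 1) for simulation; boundary
    (monomorphic) frequencies are permitted only with
    ``allow_monomorphic=True``, which some degenerate tests use.
    """

    variants: List[Variant]
    allow_monomorphic: bool = False

    @model_validator(mode="after")
    def _check(self) -> "VariantPanel":
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValueError(f"duplicate rsIDs in panel: {dupes}")
        if not self.allow_monomorphic:
            for v in self.variants:
                if not (0.0 < v.risk_allele_frequency < 1.0):
                    raise ValueError(
                        f"{v.rsid}: risk_allele_frequency must be in (0,1) for "
                        f"simulation (got {v.risk_allele_frequency}); set "
                        "allow_monomorphic=True to override"
                    )
        return self

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> List[str]:
        return [v.rsid for v in self.variants]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([v.risk_allele_frequency for v in self.variants])

    @property
    def effects(self) -> np.ndarray:
        return np.array([v.iop_effect_mmhg for v in self.variants])

    @property
    def max_score(self) -> int:
        """Upper bound of the unweighted GRS (two alleles per variant)."""
        return 2 * len(self.variants)

    def variant(self, rsid: str) -> Variant:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)

    # -- constructors ----------------------------------------------------------

    @classmethod
    def default(
        cls,
        frequency: float | None = None,
        iop_effect_mmhg: float | None = None,
    ) -> "VariantPanel":
        """The nine-variant panel.

        With no arguments, frequencies and effects come from the packaged
        ``paper_calibrated`` profile.  Passing scalars applies the same value
        to every variant (useful for controlled simulations).
        """
        if frequency is None and iop_effect_mmhg is None:
            profile = _load_profile_dict("paper_calibrated")
            return cls.model_validate(profile["params"]["panel"])
        freq = 0.5 if frequency is None else frequency
        eff = 0.0 if iop_effect_mmhg is None else iop_effect_mmhg
        return cls.uniform(frequency=freq, iop_effect_mmhg=eff)

    @classmethod
    def uniform(cls, frequency: float, iop_effect_mmhg: float = 0.0,
                allow_monomorphic: bool = False) -> "VariantPanel":
        """Panel with the published rsIDs and one shared frequency/effect."""
        variants = [
            Variant(
                rsid=r,
                risk_allele=a,
                locus_label=g,
                risk_allele_frequency=frequency,
                iop_effect_mmhg=iop_effect_mmhg,
            )
            for r, a, g in PANEL_DEFINITION
        ]
        return cls(variants=variants, allow_monomorphic=allow_monomorphic)

    @classmethod
    def from_json(cls, path) -> "VariantPanel":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))


def _load_profile_dict(name: str) -> dict:
    """Load a packaged generator profile (JSON) by name."""
    try:
        text = resources.files("iopgrs.data").joinpath(f"{name}.json").read_text()
    except FileNotFoundError as exc:  # pragma: no cover
        raise ConfigError(f"unknown packaged profile: {name}") from exc
    return json.loads(text)
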