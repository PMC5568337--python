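"""Reading and writing the package's tabular formats.

Genotype tables are CSV with a ``participant_id`` column followed by one
column per rsID holding integer dosages 0/1/2 (empty cell = missing).
Phenotype tables are CSV with columns participant_id, age_years, sex (M/F),
max_iop_mmhg, mean_vcdr, group.  An optional VCF ingestion path converts
genotype calls to risk-allele dosages against a variant panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .errors import AlleleMismatchError, SchemaError
from .panel import VariantPanel

log = logging.getLogger(__name__)

PHENOTYPE_REQUIRED = ("participant_id", "age_years", "sex", "max_iop_mmhg", "mean_vcdr", "group")


def read_genotypes_csv(path) -> pd.DataFrame:
    """Genotype dosage matrix indexed by participant_id; missing cells -> NaN."""
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise SchemaError(f"{path}: genotype CSV lacks a participant_id column")
    df = df.set_index("participant_id")
    values = df.to_numpy(dtype=float)
    present = np.isfinite(values)
    bad = present & ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        raise SchemaError(f"{path}: dosages must be 0/1/2 (or empty for missing)")
    return df.astype(float)


def write_genotypes_csv(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    # integer cells where present, empty where missing
    out = out.astype("Int64") if out.isna().any().any() else out.astype(int)
    out.insert(0, "participant_id", out.index)
    out.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: phenotype CSV lacks column(s) {missing}")
    return df


@dataclass
class VcfIngestionReport:
    """Which panel variants were found in (or absent from) a VCF."""

    found: List[str] = field(default_factory=list)
    missing: List[str] = field(default_factory=list)


def read_genotypes_vcf(path, panel: VariantPanel) -> tuple[pd.DataFrame, VcfIngestionReport]:
    """Risk-allele dosage matrix from a VCF, matched by the ID field.

    The risk allele must equal REF or ALT of its record (anything else is a
    hard :class:`AlleleMismatchError`: no silent strand flips on a nine-variant
    panel).  Missing calls (``./.``) become missing dosages.  Panel rsIDs
    absent from the VCF are reported and returned as all-missing columns.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    records = {}
    for rec in vf.fetch() if vf.index is not None else vf:
        if rec.id:
            records[rec.id] = rec
    report = VcfIngestionReport()
    data = {}
    for v in panel.variants:
        rec = records.get(v.rsid)
        if rec is None:
            report.missing.append(v.rsid)
            data[v.rsid] = np.full(len(samples), np.nan)
            continue
        alts = rec.alts or ()
        if len(alts) != 1:
            raise SchemaError(f"{v.rsid}: expected a biallelic record, got ALT={alts}")
        if v.risk_allele == rec.ref:
            risk_index = 0
        elif v.risk_allele == alts[0]:
            risk_index = 1
        else:
            raise AlleleMismatchError(
                f"{v.rsid}: risk allele {v.risk_allele} matches neither "
                f"REF={rec.ref} nor ALT={alts[0]}"
            )
        col = np.full(len(samples), np.nan)
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(al is None for al in gt):
                continue
            col[i] = sum(1 for al in gt if al == risk_index)
        report.found.append(v.rsid)
        data[v.rsid] = col
    if report.missing:
        log.warning("panel rsIDs absent from VCF: %s", report.missing)
    df = pd.DataFrame(data, index=pd.Index(samples, name="participant_id"))
    return df[panel.rsids], report
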