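"""Patient cohort: CSV I/O, inclusion filters, state and age assignment.

A cohort is a diagnosis-time table with one row per patient: tumor diameter
in millimetres, binary metastasis status at four sites (bone, lung, liver,
brain) and hormone-receptor / HER2 status.  The canonical CSV schema is

    patient_id, diameter_mm, met_bone, met_lung, met_liver, met_brain,
    er, pr, her2 [, subtype]

with metastasis flags 0/1 and receptor statuses "pos"/"neg" (a ``subtype``
column, when present, overrides derivation from the receptors).  A tumor
positive for either ER or PR is hormone-receptor (HR) positive, giving the
four molecular subtypes HR-/HER2+, HR+/HER2+, HR+/HER2- and HR-/HER2-.

Preparation assigns each patient a network state index (from the site
flags) and a tumor age in years (from the diameter via the Gompertz model);
those two derived quantities are all the likelihood needs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import GompertzParams, diameter_to_age
from .states import state_index_from_flags

logger = logging.getLogger(__name__)

SITES = ("bone", "lung", "liver", "brain")
MET_COLUMNS = tuple(f"met_{s}" for s in SITES)
REQUIRED_COLUMNS = ("patient_id", "diameter_mm") + MET_COLUMNS + ("er", "pr", "her2")
SUBTYPES = ("HR-/HER2+", "HR+/HER2+", "HR+/HER2-", "HR-/HER2-")

_POS = {"pos", "positive", "+", "1"}
_NEG = {"neg", "negative", "-", "0"}


def _receptor(value) -> str:
    if pd.isna(value):
        return "unknown"
    v = str(value).strip().lower()
    if v in _POS:
        return "positive"
    if v in _NEG:
        return "negative"
    return "unknown"


def derive_subtype(er: str, pr: str, her2: str) -> str | None:
    """Molecular subtype from receptor statuses; None when not assignable."""
    if her2 not in ("positive", "negative"):
        return None
    if "positive" in (er, pr):
        hr = "HR+"
    elif er == "negative" and pr == "negative":
        hr = "HR-"
    else:
        return None
    return f"{hr}/HER2{'+' if her2 == 'positive' else '-'}"


@dataclass
class PatientRecord:
    """One diagnosis-time record (convenience view; bulk work uses the frame)."""

    patient_id: str
    diameter_mm: float
    bone: int
    lung: int
    liver: int
    brain: int
    er: str = "unknown"
    pr: str = "unknown"
    her2: str = "unknown"
    subtype: str | None = None
    state_index: int | None = None
    tumor_age_years: float | None = None


@dataclass
class Cohort:
    """A patient table plus provenance (source, filters, seed if synthetic)."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def prepared(self) -> bool:
        return {"state_index", "tumor_age_years"}.issubset(self.df.columns)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    diameter_mm=float(row.diameter_mm),
                    bone=int(row.met_bone),
                    lung=int(row.met_lung),
                    liver=int(row.met_liver),
                    brain=int(row.met_brain),
                    er=getattr(row, "er", "unknown"),
                    pr=getattr(row, "pr", "unknown"),
                    her2=getattr(row, "her2", "unknown"),
                    subtype=getattr(row, "subtype", None),
                    state_index=int(row.state_index) if hasattr(row, "state_index") else None,
                    tumor_age_years=float(row.tumor_age_years)
                    if hasattr(row, "tumor_age_years")
                    else None,
                )
            )
        return out

    def state_counts(self) -> pd.Series:
        """Patient counts per network state (index 1..16)."""
        if not self.prepared:
            raise ValueError("cohort not prepared: call prepare_cohort first")
        counts = self.df["state_index"].value_counts()
        return counts.reindex(range(1, 17), fill_value=0).sort_index()

    def subset(self, mask_or_index) -> "Cohort":
        sub = self.df.loc[mask_or_index].reset_index(drop=True)
        return Cohort(df=sub, provenance=dict(self.provenance))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded as printed in tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def read_cohort(path, column_map: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV, validating and reporting rejected rows.

    ``column_map`` renames source columns to the canonical schema
    (``{"source_name": "canonical_name"}``).  Rows with an unparseable
    diameter or metastasis flag are dropped with a counted reason; missing
    required columns raise.
    """
    raw = pd.read_csv(path, dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file missing required column(s): {missing}")

    rejected: dict[str, int] = {}

    def _reject(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            rejected[reason] = rejected.get(reason, 0) + n
        return ~mask

    df = raw.copy()
    diam = pd.to_numeric(df["diameter_mm"], errors="coerce")
    keep = _reject(diam.isna(), "missing diameter")
    df = df[keep].copy()
    df["diameter_mm"] = diam[keep]

    for col in MET_COLUMNS:
        flags = pd.to_numeric(df[col], errors="coerce")
        ok = flags.isin([0, 1])
        keep = _reject(~ok, f"invalid {col}")
        df = df[keep].copy()
        df[col] = flags[keep].astype(int)

    for col in ("er", "pr", "her2"):
        df[col] = df[col].map(_receptor)

    if rejected:
        logger.warning("read_cohort: rejected rows %s", rejected)
    df = df.reset_index(drop=True)
    return Cohort(
        df=df,
        provenance={
            "source": str(path),
            "rows_read": len(raw),
            "rows_rejected": rejected,
        },
    )


def write_cohort(cohort: Cohort, path) -> None:
    cohort.df.to_csv(path, index=False)


def apply_inclusion_filters(cohort: Cohort, d_max: float = 100.0) -> Cohort:
    """Apply the diagnosis-time inclusion criteria, reporting removals.

    Retains records with a known diameter in (0, d_max], all four
    metastasis statuses known (guaranteed 0/1 after parsing) and an
    assignable molecular subtype.  Registry-extraction criteria (sex, age,
    histology confirmation, site/year coding) are assumed applied upstream
    of the CSV.  The per-criterion removal counts are stored in
    ``provenance["filter_report"]``.
    """
    df = cohort.df.copy()
    report: dict[str, int] = {}

    mask = df["diameter_mm"] > 0
    report["diameter <= 0"] = int((~mask).sum())
    df = df[mask]

    mask = df["diameter_mm"] <= d_max
    report[f"diameter > {d_max:g} mm"] = int((~mask).sum())
    df = df[mask]

    if "subtype" in df.columns:
        subtype = df["subtype"].where(df["subtype"].isin(SUBTYPES))
    else:
        subtype = pd.Series(index=df.index, dtype=object)
    derived = [
        derive_subtype(e, p, h) for e, p, h in zip(df["er"], df["pr"], df["her2"])
    ]
    subtype = subtype.fillna(pd.Series(derived, index=df.index))
    mask = subtype.notna()
    report["subtype not assignable"] = int((~mask).sum())
    df = df[mask].copy()
    df["subtype"] = subtype[mask]

    prov = dict(cohort.provenance)
    prov["filter_report"] = report
    prov["d_max_mm"] = d_max
    return Cohort(df=df.reset_index(drop=True), provenance=prov)


def write_filter_report(cohort: Cohort, path) -> None:
    report = cohort.provenance.get("filter_report", {})
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def prepare_cohort(cohort: Cohort, growth: GompertzParams = GompertzParams()) -> Cohort:
    """Assign every record its network state index and tumor age (years)."""
    df = cohort.df.copy()
    df["state_index"] = [
        state_index_from_flags(b, l, li, br)
        for b, l, li, br in zip(
            df["met_bone"], df["met_lung"], df["met_liver"], df["met_brain"]
        )
    ]
    df["tumor_age_years"] = diameter_to_age(df["diameter_mm"].to_numpy(float), growth)
    prov = dict(cohort.provenance)
    prov["growth"] = {
        "alpha_per_day": growth.alpha_per_day,
        "beta_per_day": growth.beta_per_day,
        "d0_um": growth.d0_um,
        "d_lethal_mm": growth.d_lethal_mm,
    }
    return Cohort(df=df, provenance=prov)


def stratify_by_subtype(cohort: Cohort) -> dict[str, Cohort]:
    """Partition a cohort into the four molecular-subtype strata."""
    if "subtype" not in cohort.df.columns:
        raise ValueError("cohort has no subtype column; apply inclusion filters first")
    known = cohort.df["subtype"].isin(SUBTYPES)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("stratify_by_subtype: %d record(s) with unknown subtype excluded", n_unknown)
    out = {}
    for st in SUBTYPES:
        sub = cohort.df[cohort.df["subtype"] == st].reset_index(drop=True)
        prov = dict(cohort.provenance)
        prov["subtype"] = st
        out[st] = Cohort(df=sub, provenance=prov)
    return out
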