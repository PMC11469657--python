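"""Cohort table I/O, eligibility filtering and group summaries.

The cohort lives in two CSV files: ``patients.csv`` (one row per patient:
demographics, mechanism, arrival vitals, AVPU, outcome flags) and
``injuries.csv`` (one row per injury: patient_id, AIS body region, AIS
code).  Missing vitals are empty cells — distinct from a recorded zero,
which is a valid RTS input.

Eligibility mirrors the usual trauma-registry screening: only blunt or
penetrating mechanisms are analysable (MGAP and TRISS are undefined
otherwise), and every score input (GCS, SBP, RR, AVPU, injury data) must be
present.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scores import (
    AVPU_LEVELS,
    MECHANISMS,
    REGIONS,
    InjuryRecord,
    PatientRecord,
    PhysiologyAtArrival,
)

__all__ = [
    "CohortTable",
    "EligibilityReport",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "summarize_groups",
]

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "mechanism", "gcs", "sbp", "rr", "avpu",
    "injuries_unknown", "death7", "death30",
]
INJURY_COLUMNS = ["patient_id", "region", "ais"]


class CohortParseError(ValueError):
    """A cohort CSV row failed validation; the message names the row."""


@dataclass
class CohortTable:
    patients: list[PatientRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


@dataclass
class EligibilityReport:
    """Screening accounting: input = eligible + mechanism + missing."""

    n_input: int
    n_excluded_mechanism: int
    n_excluded_missing: int
    n_eligible: int
    reasons: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        assert self.n_input == (self.n_eligible + self.n_excluded_mechanism
                                + self.n_excluded_missing)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_mechanism": self.n_excluded_mechanism,
            "n_excluded_missing": self.n_excluded_missing,
            "n_eligible": self.n_eligible,
            "reasons": dict(self.reasons),
        }


def _opt_float(value, row: str, col: str):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortParseError(f"{row}: column {col!r} has non-numeric value {value!r}")


def read_cohort(patients_path, injuries_path) -> CohortTable:
    """Parse the two cohort CSVs into typed records.

    Missing vitals come back as None.  Raises :class:`CohortParseError` on
    malformed rows, unknown labels, duplicate patient ids, or injury rows
    referencing an unknown patient.
    """
    pdf = pd.read_csv(patients_path, dtype={"patient_id": str, "avpu": str,
                                            "sex": str, "mechanism": str})
    idf = pd.read_csv(injuries_path, dtype={"patient_id": str, "region": str})

    for col in PATIENT_COLUMNS:
        if col not in pdf.columns:
            raise CohortParseError(f"patients file lacks column {col!r}")
    for col in INJURY_COLUMNS:
        if col not in idf.columns:
            raise CohortParseError(f"injuries file lacks column {col!r}")

    dupes = pdf["patient_id"][pdf["patient_id"].duplicated()]
    if len(dupes):
        raise CohortParseError(f"duplicate patient_id {dupes.iloc[0]!r}")

    injuries_by_pid: dict[str, list[InjuryRecord]] = {}
    known = set(pdf["patient_id"])
    for i, row in enumerate(idf.itertuples(index=False)):
        where = f"injuries row {i}"
        if row.patient_id not in known:
            raise CohortParseError(f"{where}: unknown patient_id {row.patient_id!r}")
        if row.region not in REGIONS:
            raise CohortParseError(f"{where}: unknown region {row.region!r}")
        ais = row.ais
        if not (isinstance(ais, (int, np.integer)) or float(ais).is_integer()):
            raise CohortParseError(f"{where}: AIS must be an integer, got {ais!r}")
        if int(ais) not in (1, 2, 3, 4, 5, 6):
            raise CohortParseError(f"{where}: AIS must be 1-6, got {ais!r}")
        injuries_by_pid.setdefault(row.patient_id, []).append(
            InjuryRecord(region=row.region, ais=int(ais)))

    patients = []
    for i, row in enumerate(pdf.itertuples(index=False)):
        where = f"patients row {i} (id {row.patient_id!r})"
        if row.mechanism not in MECHANISMS:
            raise CohortParseError(f"{where}: unknown mechanism {row.mechanism!r}")
        avpu = row.avpu
        if avpu is not None and (not isinstance(avpu, str) or avpu == ""):
            avpu = None
        if isinstance(avpu, float) and math.isnan(avpu):
            avpu = None
        if avpu is not None and avpu not in AVPU_LEVELS:
            raise CohortParseError(f"{where}: unknown AVPU {avpu!r}")
        gcs = _opt_float(row.gcs, where, "gcs")
        try:
            phys = PhysiologyAtArrival(
                gcs=None if gcs is None else int(gcs),
                sbp=_opt_float(row.sbp, where, "sbp"),
                rr=_opt_float(row.rr, where, "rr"),
                avpu=avpu,
            )
            patients.append(PatientRecord(
                patient_id=row.patient_id,
                age=float(row.age),
                sex=row.sex,
                mechanism=row.mechanism,
                physiology=phys,
                injuries=injuries_by_pid.get(row.patient_id, []),
                injuries_unknown=bool(int(row.injuries_unknown)),
                death7=int(row.death7),
                death30=int(row.death30),
            ))
        except ValueError as exc:
            raise CohortParseError(f"{where}: {exc}") from exc
    return CohortTable(patients=patients, provenance=str(patients_path))


def write_cohort(cohort: CohortTable, patients_path, injuries_path) -> None:
    """Write the two CSVs; round-trips through :func:`read_cohort`."""
    prow = []
    irow = []
    for p in cohort:
        phys = p.physiology
        prow.append({
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "mechanism": p.mechanism,
            "gcs": "" if phys.gcs is None else phys.gcs,
            "sbp": "" if phys.sbp is None else phys.sbp,
            "rr": "" if phys.rr is None else phys.rr,
            "avpu": "" if phys.avpu is None else phys.avpu,
            "injuries_unknown": int(p.injuries_unknown),
            "death7": p.death7,
            "death30": p.death30,
        })
        for inj in p.injuries:
            irow.append({"patient_id": p.patient_id, "region": inj.region,
                         "ais": inj.ais})
    pd.DataFrame(prow, columns=PATIENT_COLUMNS).to_csv(patients_path, index=False)
    pd.DataFrame(irow, columns=INJURY_COLUMNS).to_csv(injuries_path, index=False)


def _score_inputs_complete(p: PatientRecord) -> bool:
    phys = p.physiology
    if phys.gcs is None or phys.sbp is None or phys.rr is None or phys.avpu is None:
        return False
    # ISS is "missing" only when injuries are explicitly unknown; an empty
    # injury list without the flag is a valid ISS of 0.
    if p.injuries_unknown:
        return False
    return True


def apply_eligibility(cohort: CohortTable) -> tuple[CohortTable, EligibilityReport]:
    """Screen the cohort: keep blunt/penetrating patients with complete
    score inputs.  Mechanism exclusion takes precedence over missingness in
    the accounting, so each patient is counted once."""
    eligible = []
    reasons: Counter = Counter()
    n_mech = 0
    n_miss = 0
    for p in cohort:
        if p.mechanism not in ("blunt", "penetrating"):
            n_mech += 1
            reasons[f"mechanism:{p.mechanism}"] += 1
            continue
        if not _score_inputs_complete(p):
            n_miss += 1
            phys = p.physiology
            for name, val in (("gcs", phys.gcs), ("sbp", phys.sbp),
                              ("rr", phys.rr), ("avpu", phys.avpu)):
                if val is None:
                    reasons[f"missing:{name}"] += 1
            if p.injuries_unknown:
                reasons["missing:injuries"] += 1
            continue
        eligible.append(p)
    report = EligibilityReport(
        n_input=len(cohort),
        n_excluded_mechanism=n_mech,
        n_excluded_missing=n_miss,
        n_eligible=len(eligible),
        reasons=reasons,
    )
    return CohortTable(patients=eligible, provenance=cohort.provenance), report


def _ranksum_p(x: np.ndarray, y: np.ndarray):
    """Two-sample rank-sum p (normal approximation, tie-corrected, no
    continuity correction); None when degenerate."""
    if len(x) == 0 or len(y) == 0:
        return None
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return None
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.pvalue)


def _chi2_p(table: np.ndarray):
    """Chi-squared p without continuity correction; None when degenerate."""
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def summarize_groups(cohort: CohortTable, outcome: str = "death7",
                     scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Survivor vs non-survivor summary table.

    Continuous variables (age, vitals, and any columns of ``scores``) are
    summarised as median (IQR) with a rank-sum p-value; categorical
    variables (sex, mechanism, per-region injury indicators) as n (%) with a
    chi-squared p-value.  Degenerate variables get an absent p-value.
    """
    if outcome not in ("death7", "death30"):
        raise ValueError(f"outcome must be death7/death30, got {outcome!r}")
    died = np.array([getattr(p, outcome) for p in cohort], dtype=bool)
    rows = []

    def fmt_median(vals):
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return "-"
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return f"{med:.2f} ({q1:.2f}, {q3:.2f})"

    def add_continuous(name, values):
        values = np.asarray(values, dtype=float)
        surv, nons = values[~died], values[died]
        p = _ranksum_p(surv[~np.isnan(surv)], nons[~np.isnan(nons)])
        rows.append({
            "variable": name, "type": "continuous",
            "survivors": fmt_median(surv), "non_survivors": fmt_median(nons),
            "p_value": p,
            "degenerate": p is None,
        })

    def add_binary(name, flags):
        flags = np.asarray(flags, dtype=bool)
        surv, nons = flags[~died], flags[died]
        table = np.array([[surv.sum(), (~surv).sum()],
                          [nons.sum(), (~nons).sum()]])
        p = _chi2_p(table)

        def fmt(group):
            n = len(group)
            k = int(group.sum())
            return f"{k} ({100 * k / n:.1f})" if n else "-"

        rows.append({
            "variable": name, "type": "categorical",
            "survivors": fmt(surv), "non_survivors": fmt(nons),
            "p_value": p,
            "degenerate": p is None,
        })

    n = len(cohort)
    rows.append({
        "variable": "population", "type": "count",
        "survivors": f"{int((~died).sum())} ({100 * (~died).sum() / n:.1f})" if n else "-",
        "non_survivors": f"{int(died.sum())} ({100 * died.sum() / n:.1f})" if n else "-",
        "p_value": None, "degenerate": n == 0,
    })
    add_binary("sex_male", [p.sex == "male" for p in cohort])
    add_continuous("age", [p.age for p in cohort])
    add_continuous("sbp", [np.nan if p.physiology.sbp is None else p.physiology.sbp
                           for p in cohort])
    add_continuous("rr", [np.nan if p.physiology.rr is None else p.physiology.rr
                          for p in cohort])
    add_continuous("gcs", [np.nan if p.physiology.gcs is None else p.physiology.gcs
                           for p in cohort])
    add_binary("mechanism_penetrating", [p.mechanism == "penetrating" for p in cohort])
    for region in REGIONS:
        add_binary(f"region_{region}",
                   [any(i.region == region for i in p.injuries) for p in cohort])
    if scores is not None:
        for col in scores.columns:
            add_continuous(col, scores[col].to_numpy())
    return pd.DataFrame(rows)
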