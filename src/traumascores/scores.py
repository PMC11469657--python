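"""Trauma severity scores: ISS, NISS, RTS, MGAP, KTS and TRISS.

Six scoring systems commonly used to summarise injury severity in trauma
cohorts.  ISS and NISS are anatomical (built from per-injury Abbreviated
Injury Scale codes), RTS is physiological (coded GCS, systolic blood
pressure and respiratory rate), MGAP and KTS are additive hybrid triage
scores, and TRISS is a logistic probability-of-survival model with separate
coefficient sets for blunt and penetrating mechanisms.

Orientation matters downstream: higher ISS/NISS means worse injury, while
lower RTS/MGAP/KTS/TRISS means worse injury.  :func:`to_risk` maps any score
onto a "larger = worse" axis for ROC analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "REGIONS",
    "MECHANISMS",
    "AVPU_LEVELS",
    "ORIENTATION",
    "HIGHER_WORSE",
    "LOWER_WORSE",
    "InvalidInputError",
    "NotComputableError",
    "MissingValueError",
    "InjuryRecord",
    "PhysiologyAtArrival",
    "PatientRecord",
    "ScoreCoefficients",
    "ScorePanel",
    "code_rts_components",
    "rts_from_codes",
    "compute_rts",
    "compute_iss",
    "compute_niss",
    "compute_mgap",
    "compute_kts",
    "count_serious_injuries",
    "triss_age_index",
    "compute_triss",
    "score_panel",
    "to_risk",
]

# The six AIS body regions, in the vocabulary used by the cohort CSV schema.
REGIONS = ("head_neck", "face", "chest", "abdomen", "extremities", "external")

MECHANISMS = ("blunt", "penetrating", "burn", "mixed", "unknown")

AVPU_LEVELS = ("A", "V", "P", "U")

HIGHER_WORSE = "higher_worse"
LOWER_WORSE = "lower_worse"

#: Severity orientation of each score (direction of "worse").
ORIENTATION = {
    "iss": HIGHER_WORSE,
    "niss": HIGHER_WORSE,
    "rts": LOWER_WORSE,
    "mgap": LOWER_WORSE,
    "kts": LOWER_WORSE,
    "triss": LOWER_WORSE,
}

SCORE_NAMES = tuple(ORIENTATION)


class InvalidInputError(ValueError):
    """An input value is outside its admissible domain."""


class NotComputableError(ValueError):
    """The score is undefined for this patient (e.g. TRISS for burns)."""


class MissingValueError(ValueError):
    """A required input is missing; the patient should have been excluded."""


@dataclass(frozen=True)
class InjuryRecord:
    """A single injury: AIS body region plus AIS severity code 1-6."""

    region: str
    ais: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidInputError(f"unknown AIS body region {self.region!r}")
        if self.ais not in (1, 2, 3, 4, 5, 6):
            raise InvalidInputError(f"AIS code must be 1-6, got {self.ais!r}")


@dataclass
class PhysiologyAtArrival:
    """Arrival vitals; any field may be None when not recorded."""

    gcs: Optional[int] = None
    sbp: Optional[float] = None
    rr: Optional[float] = None
    avpu: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise InvalidInputError(f"GCS must be in [3, 15], got {self.gcs}")
        if self.sbp is not None and self.sbp < 0:
            raise InvalidInputError(f"SBP must be >= 0, got {self.sbp}")
        if self.rr is not None and self.rr < 0:
            raise InvalidInputError(f"RR must be >= 0, got {self.rr}")
        if self.avpu is not None and self.avpu not in AVPU_LEVELS:
            raise InvalidInputError(f"AVPU must be one of {AVPU_LEVELS}, got {self.avpu!r}")


@dataclass
class PatientRecord:
    """One patient: demographics, mechanism, vitals, injuries, outcomes."""

    patient_id: str
    age: float
    sex: str
    mechanism: str
    physiology: PhysiologyAtArrival = field(default_factory=PhysiologyAtArrival)
    injuries: list[InjuryRecord] = field(default_factory=list)
    injuries_unknown: bool = False
    death7: int = 0
    death30: int = 0

    def __post_init__(self) -> None:
        if self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be male/female, got {self.sex!r}")
        if self.mechanism not in MECHANISMS:
            raise InvalidInputError(f"unknown mechanism {self.mechanism!r}")
        if self.death7 not in (0, 1) or self.death30 not in (0, 1):
            raise InvalidInputError("death7/death30 must be 0 or 1")
        if self.death7 == 1 and self.death30 != 1:
            raise InvalidInputError("death7=1 implies death30=1")


@dataclass(frozen=True)
class ScoreCoefficients:
    """Fixed published constants for RTS and TRISS."""

    rts_weights: tuple[float, float, float] = (0.7326, 0.2908, 0.9368)  # SBP, RR, GCS
    triss_blunt: tuple[float, float, float, float] = (0.4499, 0.8085, -0.0835, -1.7430)
    triss_penetrating: tuple[float, float, float, float] = (2.5355, 0.9934, -0.0651, -1.1360)


COEFFS = ScoreCoefficients()

#: Maximum attainable RTS: all three coded variables at code 4.
RTS_MAX = 4 * sum(COEFFS.rts_weights)  # 7.8408


@dataclass
class ScorePanel:
    """The six scores for one patient, with severity orientations."""

    iss: int
    niss: int
    rts: float
    mgap: int
    kts: int
    triss: float
    orientation: dict = field(default_factory=lambda: dict(ORIENTATION))

    def as_dict(self) -> dict:
        return {
            "iss": self.iss,
            "niss": self.niss,
            "rts": self.rts,
            "mgap": self.mgap,
            "kts": self.kts,
            "triss": self.triss,
        }

    def risks(self) -> dict:
        """Scores mapped onto the larger-is-worse axis."""
        return {k: to_risk(v, self.orientation[k]) for k, v in self.as_dict().items()}


# ---------------------------------------------------------------------------
# RTS — coded Champion bands, weighted sum
# ---------------------------------------------------------------------------

def code_rts_components(gcs: int, sbp: float, rr: float) -> tuple[int, int, int]:
    """Code GCS, SBP and RR into the 0-4 RTS bands.

    Bands (Champion revision): GCS 13-15 -> 4, 9-12 -> 3, 6-8 -> 2, 4-5 -> 1,
    3 -> 0; SBP >89 -> 4, 76-89 -> 3, 50-75 -> 2, 1-49 -> 1, 0 -> 0;
    RR 10-29 -> 4, >29 -> 3, 6-9 -> 2, 1-5 -> 1, 0 -> 0.
    """
    if gcs is None or sbp is None or rr is None:
        raise MissingValueError("RTS needs GCS, SBP and RR")
    if not 3 <= gcs <= 15:
        raise InvalidInputError(f"GCS must be in [3, 15], got {gcs}")
    if sbp < 0 or rr < 0:
        raise InvalidInputError("SBP and RR must be >= 0")

    if gcs >= 13:
        gcs_c = 4
    elif gcs >= 9:
        gcs_c = 3
    elif gcs >= 6:
        gcs_c = 2
    elif gcs >= 4:
        gcs_c = 1
    else:
        gcs_c = 0

    if sbp > 89:
        sbp_c = 4
    elif sbp >= 76:
        sbp_c = 3
    elif sbp >= 50:
        sbp_c = 2
    elif sbp > 0:
        sbp_c = 1
    else:
        sbp_c = 0

    if 10 <= rr <= 29:
        rr_c = 4
    elif rr > 29:
        rr_c = 3
    elif rr >= 6:
        rr_c = 2
    elif rr > 0:
        rr_c = 1
    else:
        rr_c = 0

    return gcs_c, sbp_c, rr_c


def rts_from_codes(gcs_code: int, sbp_code: int, rr_code: int) -> float:
    """RTS = 0.7326*SBPc + 0.2908*RRc + 0.9368*GCSc for coded values in 0-4."""
    for c in (gcs_code, sbp_code, rr_code):
        if c not in (0, 1, 2, 3, 4):
            raise InvalidInputError(f"RTS codes must be in 0-4, got {c}")
    w_sbp, w_rr, w_gcs = COEFFS.rts_weights
    return w_sbp * sbp_code + w_rr * rr_code + w_gcs * gcs_code


def compute_rts(gcs: int, sbp: float, rr: float) -> float:
    """Revised Trauma Score in [0, 7.8408]; lower is worse."""
    return rts_from_codes(*code_rts_components(gcs, sbp, rr))


# ---------------------------------------------------------------------------
# ISS / NISS — sums of squared AIS codes
# ---------------------------------------------------------------------------

def _validate_injuries(injuries: Sequence[InjuryRecord]) -> None:
    for inj in injuries:
        if not isinstance(inj, InjuryRecord):
            # revalidates plain tuples etc. through the dataclass checks
            raise InvalidInputError(f"expected InjuryRecord, got {inj!r}")


def compute_iss(injuries: Sequence[InjuryRecord]) -> int:
    """Injury Severity Score: sum of squares of the three highest per-region
    AIS maxima, each body region counted at most once.

    Any AIS 6 (unsurvivable) forces ISS = 75, the conventional maximum.
    Fewer than three injured regions contribute zero for the absent terms;
    an empty injury list yields 0.
    """
    _validate_injuries(injuries)
    if any(inj.ais == 6 for inj in injuries):
        return 75
    region_max: dict[str, int] = {}
    for inj in injuries:
        region_max[inj.region] = max(region_max.get(inj.region, 0), inj.ais)
    top3 = sorted(region_max.values(), reverse=True)[:3]
    return sum(a * a for a in top3)


def compute_niss(injuries: Sequence[InjuryRecord]) -> int:
    """New ISS: squares of the three highest AIS codes regardless of region.

    Always >= ISS on the same injury list; AIS 6 forces 75.
    """
    _validate_injuries(injuries)
    if any(inj.ais == 6 for inj in injuries):
        return 75
    top3 = sorted((inj.ais for inj in injuries), reverse=True)[:3]
    return sum(a * a for a in top3)


# ---------------------------------------------------------------------------
# MGAP — mechanism, GCS, age, pressure
# ---------------------------------------------------------------------------

def compute_mgap(mechanism: str, gcs: int, age: float, sbp: float) -> int:
    """MGAP in [3, 29]; lower is worse.

    Raw GCS (3-15) plus mechanism points (blunt +4, penetrating +0), age
    points (<60 years +5, else 0) and SBP points (>120 +5, 60-120 +3,
    <60 +0).
    """
    if mechanism not in ("blunt", "penetrating"):
        raise NotComputableError(f"MGAP is undefined for mechanism {mechanism!r}")
    if gcs is None or sbp is None or age is None:
        raise MissingValueError("MGAP needs GCS, age and SBP")
    if not 3 <= gcs <= 15:
        raise InvalidInputError(f"GCS must be in [3, 15], got {gcs}")
    score = int(gcs)
    if mechanism == "blunt":
        score += 4
    if age < 60:
        score += 5
    if sbp > 120:
        score += 5
    elif sbp >= 60:
        score += 3
    return score


# ---------------------------------------------------------------------------
# KTS — Kampala Trauma Score
# ---------------------------------------------------------------------------

def count_serious_injuries(injuries: Sequence[InjuryRecord]) -> int:
    """Number of injuries with AIS >= 3 (the conventional 'serious' band)."""
    _validate_injuries(injuries)
    return sum(1 for inj in injuries if inj.ais >= 3)


def compute_kts(age: float, sbp: float, rr: float, avpu: str,
                n_serious_injuries: int) -> int:
    """Kampala Trauma Score in [0, 10]; lower is worse.

    Components: age (<55 -> 1, >=55 -> 0), SBP (>=89 -> 2, 50-88 -> 1,
    <50 -> 0), RR (10-29 -> 2, >=30 -> 1, <10 -> 0), AVPU (A -> 3, V -> 2,
    P -> 1, U -> 0) and serious-injury count (0 -> 2, 1 -> 1, >=2 -> 0).
    """
    if avpu not in AVPU_LEVELS:
        raise InvalidInputError(f"AVPU must be one of {AVPU_LEVELS}, got {avpu!r}")
    if age is None or sbp is None or rr is None:
        raise MissingValueError("KTS needs age, SBP, RR and AVPU")
    if n_serious_injuries < 0:
        raise InvalidInputError("serious-injury count must be >= 0")

    score = 1 if age < 55 else 0

    if sbp >= 89:
        score += 2
    elif sbp >= 50:
        score += 1

    if 10 <= rr <= 29:
        score += 2
    elif rr >= 30:
        score += 1

    score += {"A": 3, "V": 2, "P": 1, "U": 0}[avpu]

    if n_serious_injuries == 0:
        score += 2
    elif n_serious_injuries == 1:
        score += 1

    return score


# ---------------------------------------------------------------------------
# TRISS — probability of survival
# ---------------------------------------------------------------------------

def triss_age_index(age: float) -> int:
    """TRISS age index: 0 for 15-54 years, 1 for >= 55."""
    if age < 15:
        raise InvalidInputError(f"TRISS age index requires age >= 15, got {age}")
    return 0 if age <= 54 else 1


def compute_triss(mechanism: str, rts: float, iss: float, age: float) -> float:
    """TRISS probability of survival, Ps = 1/(1 + e^-b).

    b uses the mechanism-specific coefficients:
    blunt        b = 0.4499 + 0.8085*RTS - 0.0835*ISS - 1.7430*AgeIndex
    penetrating  b = 2.5355 + 0.9934*RTS - 0.0651*ISS - 1.1360*AgeIndex
    """
    if mechanism == "blunt":
        b0, b_rts, b_iss, b_age = COEFFS.triss_blunt
    elif mechanism == "penetrating":
        b0, b_rts, b_iss, b_age = COEFFS.triss_penetrating
    else:
        raise NotComputableError(f"TRISS is undefined for mechanism {mechanism!r}")
    if not 0 <= rts <= RTS_MAX + 1e-9:
        raise InvalidInputError(f"RTS must be in [0, {RTS_MAX}], got {rts}")
    if not 0 <= iss <= 75:
        raise InvalidInputError(f"ISS must be in [0, 75], got {iss}")
    b = b0 + b_rts * rts + b_iss * iss + b_age * triss_age_index(age)
    return 1.0 / (1.0 + math.exp(-b))


# ---------------------------------------------------------------------------
# Panel assembly and orientation
# ---------------------------------------------------------------------------

def score_panel(patient: PatientRecord) -> ScorePanel:
    """Compute all six scores for an eligible patient.

    Raises :class:`MissingValueError` naming every score whose inputs are
    absent, and :class:`NotComputableError` for mechanisms other than
    blunt/penetrating (MGAP and TRISS are undefined there).
    """
    phys = patient.physiology
    missing = []
    if phys.gcs is None or phys.sbp is None or phys.rr is None:
        missing.extend(["rts", "triss"])
    if phys.gcs is None or phys.sbp is None:
        missing.append("mgap")
    if phys.sbp is None or phys.rr is None or phys.avpu is None:
        missing.append("kts")
    if patient.injuries_unknown:
        missing.extend(["iss", "niss", "kts", "triss"])
    if missing:
        raise MissingValueError(
            f"patient {patient.patient_id}: missing inputs for "
            + ", ".join(sorted(set(missing)))
        )
    if patient.mechanism not in ("blunt", "penetrating"):
        raise NotComputableError(
            f"patient {patient.patient_id}: MGAP/TRISS undefined for "
            f"mechanism {patient.mechanism!r}"
        )

    iss = compute_iss(patient.injuries)
    niss = compute_niss(patient.injuries)
    rts = compute_rts(phys.gcs, phys.sbp, phys.rr)
    mgap = compute_mgap(patient.mechanism, phys.gcs, patient.age, phys.sbp)
    kts = compute_kts(patient.age, phys.sbp, phys.rr, phys.avpu,
                      count_serious_injuries(patient.injuries))
    triss = compute_triss(patient.mechanism, rts, iss, patient.age)
    return ScorePanel(iss=iss, niss=niss, rts=rts, mgap=mgap, kts=kts, triss=triss)


def to_risk(score_value: float, orientation: str) -> float:
    """Map a score onto the larger-is-worse axis used for ROC analysis."""
    if orientation == HIGHER_WORSE:
        return score_value
    if orientation == LOWER_WORSE:
        return -score_value
    raise InvalidInputError(f"unknown orientation {orientation!r}")
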