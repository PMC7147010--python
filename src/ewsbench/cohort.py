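"""Cohort construction: eligibility filters, first-contact deduplication,
first complete vital set within a time window, 7-day mortality outcome,
and full exclusion accounting.

Rules applied, in order, each record counted once under its first reason:

1. age < 16 years
2. elective admission
3. registered healthy companion
4. no national identity number
5. repeat contact (only the earliest arrival per patient is kept)
6. no complete vital set within ``window_hours`` of arrival, where complete
   means all six score parameters (five numerics plus consciousness via GCS
   or AVPU) *and* a documented oxygen-supplement status; encounters that
   failed completeness solely for lack of oxygen documentation are
   sub-counted separately.

Two equivalent implementations are provided: an object-level path built
from the individual operations, and a vectorised DataFrame path
(:func:`build_cohort_frame`) for large simulated cohorts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .scoring import (
    AvpuLevel,
    ScoreSystem,
    VitalSet,
    ValidationError,
    VITAL_PARAMETERS,
    gcs_to_avpu,
    load_bundled_systems,
    score,
    score_frame,
)

__all__ = [
    "VitalRecord",
    "PatientEncounter",
    "EligibleCase",
    "ExclusionFlow",
    "DataIntegrityError",
    "apply_eligibility",
    "select_index_contact",
    "first_complete_vitals",
    "derive_outcome",
    "build_cohort",
    "build_cohort_frame",
    "read_encounters_csv",
    "frame_to_encounters",
    "ENCOUNTER_COLUMNS",
]

logger = logging.getLogger(__name__)

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "patient_id",
    "arrival",
    "age_years",
    "sex",
    "elective",
    "companion",
    "has_national_id",
    "hospital",
    "death_date",
    "measured_at",
    "sbp",
    "hr",
    "temp",
    "rr",
    "spo2",
    "gcs",
    "avpu",
    "agitated",
    "on_oxygen",
]


class DataIntegrityError(ValueError):
    """Raised for impossible raw data, e.g. death recorded before arrival."""


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return v is pd.NaT or (isinstance(v, str) and v == "")


@dataclass
class VitalRecord:
    """One possibly-incomplete vital-sign measurement row (all fields nullable)."""

    measured_at: datetime
    sbp: float | None = None
    hr: float | None = None
    temp: float | None = None
    rr: float | None = None
    spo2: float | None = None
    gcs: int | None = None
    avpu: AvpuLevel | str | None = None
    agitated: bool | None = None
    on_oxygen: bool | None = None

    def loc_documented(self) -> bool:
        return not (_is_missing(self.gcs) and _is_missing(self.avpu))

    def numerics_documented(self) -> bool:
        return all(not _is_missing(getattr(self, p)) for p in VITAL_PARAMETERS)

    def is_complete(self) -> bool:
        return (
            self.numerics_documented()
            and self.loc_documented()
            and not _is_missing(self.on_oxygen)
        )

    def missing_oxygen_only(self) -> bool:
        """Complete except for the oxygen-supplement documentation."""
        return (
            self.numerics_documented()
            and self.loc_documented()
            and _is_missing(self.on_oxygen)
        )

    def to_vital_set(self, honor_gcs_agitation: bool = False) -> VitalSet:
        """Promote to a complete :class:`VitalSet`.

        Consciousness comes from AVPU when documented, otherwise from GCS.
        When LOC was derived from GCS the agitation flag is suppressed
        (triage GCS does not record agitation) unless ``honor_gcs_agitation``.
        """
        if not self.is_complete():
            raise ValidationError("cannot promote an incomplete vital record")
        if not _is_missing(self.avpu):
            loc = AvpuLevel.parse(self.avpu)
            agitated = bool(self.agitated) if not _is_missing(self.agitated) else False
        else:
            loc = gcs_to_avpu(int(self.gcs))
            agitated = (
                bool(self.agitated)
                if honor_gcs_agitation and not _is_missing(self.agitated)
                else False
            )
        return VitalSet(
            sbp=float(self.sbp),
            hr=float(self.hr),
            temp=float(self.temp),
            rr=float(self.rr),
            spo2=float(self.spo2),
            loc=loc,
            agitated=agitated,
            on_oxygen=bool(self.on_oxygen),
            measured_at=self.measured_at,
        )


@dataclass
class PatientEncounter:
    """One hospital course: identity, arrival, vital records, outcome fields."""

    encounter_id: str
    patient_id: str
    arrival: datetime
    age_years: int
    sex: str
    elective: bool = False
    companion: bool = False
    has_national_id: bool = True
    hospital: str = ""
    vitals: list[VitalRecord] = field(default_factory=list)
    death_date: date | None = None

    def __post_init__(self):
        if self.age_years < 0:
            raise DataIntegrityError(f"negative age for {self.encounter_id}")


@dataclass
class EligibleCase:
    """An included encounter with its index vital set, scores, and outcome."""

    encounter: PatientEncounter
    index_vitals: VitalSet
    scores: dict[str, int]
    died_7d: bool


@dataclass
class ExclusionFlow:
    """Sequential exclusion accounting; every input counted exactly once.

    ``oxygen_only_missing`` is a sub-count of ``no_complete_vitals``.
    """

    raw_total: int = 0
    under_16: int = 0
    elective: int = 0
    companion: int = 0
    no_national_id: int = 0
    repeat_contact: int = 0
    no_complete_vitals: int = 0
    oxygen_only_missing: int = 0
    included: int = 0

    EXCLUSION_FIELDS = (
        "under_16",
        "elective",
        "companion",
        "no_national_id",
        "repeat_contact",
        "no_complete_vitals",
    )

    def total_accounted(self) -> int:
        return sum(getattr(self, f) for f in self.EXCLUSION_FIELDS) + self.included

    def check_conservation(self) -> None:
        if self.total_accounted() != self.raw_total:
            raise DataIntegrityError(
                f"exclusion flow does not conserve counts: "
                f"{self.total_accounted()} accounted vs {self.raw_total} input"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_eligibility(
    encounters: list[PatientEncounter],
) -> tuple[list[PatientEncounter], ExclusionFlow]:
    """Drop ineligible encounters (age, elective, companion, national id, in order)."""
    flow = ExclusionFlow(raw_total=len(encounters))
    kept = []
    for enc in encounters:
        if enc.age_years < 16:
            flow.under_16 += 1
        elif enc.elective:
            flow.elective += 1
        elif enc.companion:
            flow.companion += 1
        elif not enc.has_national_id:
            flow.no_national_id += 1
        else:
            kept.append(enc)
    return kept, flow


def select_index_contact(encounters: list[PatientEncounter]) -> list[PatientEncounter]:
    """Keep each patient's earliest-arrival encounter; ties go to the first record."""
    best: dict[str, PatientEncounter] = {}
    for enc in encounters:
        prev = best.get(enc.patient_id)
        if prev is None:
            best[enc.patient_id] = enc
        elif enc.arrival < prev.arrival:
            best[enc.patient_id] = enc
        elif enc.arrival == prev.arrival:
            logger.warning(
                "tied arrival times for patient %s; keeping first record %s",
                enc.patient_id,
                prev.encounter_id,
            )
    index_ids = {id(e) for e in best.values()}
    return [e for e in encounters if id(e) in index_ids]


def first_complete_vitals(
    encounter: PatientEncounter,
    window_hours: float = 4.0,
    honor_gcs_agitation: bool = False,
) -> tuple[VitalSet | None, bool]:
    """Earliest complete vital set within ``window_hours`` of arrival.

    Returns ``(vital_set, oxygen_only)``: the promoted set or None, and a
    flag that is True when no record was complete but at least one in-window
    record was missing only the oxygen-supplement documentation.
    """
    deadline = encounter.arrival + timedelta(hours=window_hours)
    records = sorted(encounter.vitals, key=lambda r: r.measured_at)
    oxygen_only = False
    for rec in records:
        if rec.measured_at < encounter.arrival:
            raise DataIntegrityError(
                f"vital record before arrival in encounter {encounter.encounter_id}"
            )
        if rec.measured_at > deadline:
            break
        if rec.is_complete():
            return rec.to_vital_set(honor_gcs_agitation=honor_gcs_agitation), False
        if rec.missing_oxygen_only():
            oxygen_only = True
    return None, oxygen_only


def derive_outcome(encounter: PatientEncounter, followup_days: int = 7) -> bool:
    """Death within ``followup_days`` calendar days, day zero = arrival day."""
    if encounter.death_date is None or _is_missing(encounter.death_date):
        return False
    death = encounter.death_date
    if isinstance(death, datetime):
        death = death.date()
    arrival_day = encounter.arrival.date()
    offset = (death - arrival_day).days
    if offset < 0:
        raise DataIntegrityError(
            f"death date {death} precedes arrival {arrival_day} "
            f"for encounter {encounter.encounter_id}"
        )
    return offset <= followup_days


def build_cohort(
    encounters: list[PatientEncounter],
    window_hours: float = 4.0,
    followup_days: int = 7,
    systems: dict[str, ScoreSystem] | None = None,
    honor_gcs_agitation: bool = False,
) -> tuple[list[EligibleCase], ExclusionFlow]:
    """Full pipeline: eligibility -> index contact -> index vitals -> scores + outcome."""
    if systems is None:
        systems = load_bundled_systems()
    eligible, flow = apply_eligibility(encounters)
    index = select_index_contact(eligible)
    flow.repeat_contact = len(eligible) - len(index)
    cases = []
    for enc in index:
        vitals, oxygen_only = first_complete_vitals(
            enc, window_hours=window_hours, honor_gcs_agitation=honor_gcs_agitation
        )
        if vitals is None:
            flow.no_complete_vitals += 1
            if oxygen_only:
                flow.oxygen_only_missing += 1
            continue
        scores = {name: score(sys_, vitals) for name, sys_ in systems.items()}
        cases.append(
            EligibleCase(
                encounter=enc,
                index_vitals=vitals,
                scores=scores,
                died_7d=derive_outcome(enc, followup_days=followup_days),
            )
        )
    flow.included = len(cases)
    flow.check_conservation()
    return cases, flow


# ---------------------------------------------------------------------------
# vectorised DataFrame path
# ---------------------------------------------------------------------------

_META_COLS = [
    "patient_id",
    "arrival",
    "age_years",
    "sex",
    "elective",
    "companion",
    "has_national_id",
    "hospital",
    "death_date",
]


def _gcs_to_avpu_codes(gcs: np.ndarray) -> np.ndarray:
    return np.select([gcs == 15, gcs == 14, gcs >= 9], [0, 1, 2], default=3)


def build_cohort_frame(
    records: pd.DataFrame,
    window_hours: float = 4.0,
    followup_days: int = 7,
    systems: dict[str, ScoreSystem] | None = None,
    honor_gcs_agitation: bool = False,
) -> tuple[pd.DataFrame, ExclusionFlow]:
    """Vectorised :func:`build_cohort` over the one-row-per-vital-record table.

    Returns one row per included encounter with the effective index vitals,
    one integer score column per system, and ``died_7d``.
    """
    if systems is None:
        systems = load_bundled_systems()
    df = records.reset_index(drop=True)
    df["arrival"] = pd.to_datetime(df["arrival"])
    df["measured_at"] = pd.to_datetime(df["measured_at"])
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")

    enc = df.drop_duplicates("encounter_id")[["encounter_id"] + _META_COLS].copy()
    flow = ExclusionFlow(raw_total=len(enc))

    reason = pd.Series(pd.NA, index=enc.index, dtype="object")
    checks = [
        ("under_16", enc["age_years"] < 16),
        ("elective", enc["elective"].astype(bool)),
        ("companion", enc["companion"].astype(bool)),
        ("no_national_id", ~enc["has_national_id"].astype(bool)),
    ]
    for name, mask in checks:
        hit = mask & reason.isna()
        reason[hit] = name
        setattr(flow, name, int(hit.sum()))

    eligible = enc[reason.isna()]
    # index contact: earliest arrival per patient, stable first-record tiebreak
    idx = eligible.sort_values(["patient_id", "arrival"], kind="stable").drop_duplicates(
        "patient_id"
    )
    flow.repeat_contact = len(eligible) - len(idx)

    rows = df[df["encounter_id"].isin(idx["encounter_id"])].copy()
    if (rows["measured_at"] < rows["arrival"]).any():
        raise DataIntegrityError("vital record timestamp precedes arrival")
    in_window = rows["measured_at"] <= rows["arrival"] + pd.to_timedelta(window_hours, unit="h")
    numerics_ok = rows[list(VITAL_PARAMETERS)].notna().all(axis=1)
    loc_ok = rows["gcs"].notna() | rows["avpu"].notna()
    complete = numerics_ok & loc_ok & rows["on_oxygen"].notna()
    ox_only = numerics_ok & loc_ok & rows["on_oxygen"].isna()

    cand = rows[in_window & complete].sort_values("measured_at", kind="stable")
    picked = cand.drop_duplicates("encounter_id")
    ox_only_enc = set(rows.loc[in_window & ox_only, "encounter_id"]) - set(
        picked["encounter_id"]
    )
    flow.no_complete_vitals = len(idx) - len(picked)
    flow.oxygen_only_missing = len(ox_only_enc)
    flow.included = len(picked)
    flow.check_conservation()
    if len(picked) == 0:
        return pd.DataFrame(), flow

    out = picked.copy()
    have_avpu = out["avpu"].notna()
    avpu_codes = np.empty(len(out), dtype=np.int64)
    if have_avpu.any():
        avpu_codes[have_avpu.to_numpy()] = [
            int(AvpuLevel.parse(a)) for a in out.loc[have_avpu, "avpu"]
        ]
    from_gcs = ~have_avpu
    if from_gcs.any():
        avpu_codes[from_gcs.to_numpy()] = _gcs_to_avpu_codes(
            out.loc[from_gcs, "gcs"].to_numpy(dtype=float)
        )
    agitated = np.where(out["agitated"].isna(), False, out["agitated"]).astype(bool)
    if not honor_gcs_agitation:
        agitated = np.where(from_gcs.to_numpy(), False, agitated)
    out["avpu_code"] = avpu_codes
    out["agitated_effective"] = agitated
    out["on_oxygen"] = out["on_oxygen"].astype(bool)

    for name, sys_ in systems.items():
        out[name] = score_frame(
            sys_,
            out["sbp"],
            out["hr"],
            out["temp"],
            out["rr"],
            out["spo2"],
            avpu_codes,
            agitated,
            out["on_oxygen"],
        )

    death_ok = out["death_date"].notna()
    if (
        death_ok.any()
        and (out.loc[death_ok, "death_date"].dt.normalize()
             < out.loc[death_ok, "arrival"].dt.normalize()).any()
    ):
        raise DataIntegrityError("death date precedes arrival date")
    offset = (out["death_date"].dt.normalize() - out["arrival"].dt.normalize()).dt.days
    out["died_7d"] = death_ok & (offset <= followup_days)

    keep = (
        ["encounter_id"]
        + _META_COLS
        + ["measured_at"]
        + list(VITAL_PARAMETERS)
        + ["avpu_code", "agitated_effective", "on_oxygen"]
        + list(systems)
        + ["died_7d"]
    )
    return out[keep].reset_index(drop=True), flow


def frame_to_encounters(df: pd.DataFrame) -> list[PatientEncounter]:
    """Group the one-row-per-vital-record table into encounter objects."""
    df = df.copy()
    df["arrival"] = pd.to_datetime(df["arrival"])
    df["measured_at"] = pd.to_datetime(df["measured_at"])
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    encounters = []
    for enc_id, grp in df.groupby("encounter_id", sort=False):
        meta = grp.iloc[0]
        death = None if pd.isna(meta["death_date"]) else meta["death_date"].date()
        vitals = [
            VitalRecord(
                measured_at=row["measured_at"].to_pydatetime(),
                sbp=None if pd.isna(row["sbp"]) else float(row["sbp"]),
                hr=None if pd.isna(row["hr"]) else float(row["hr"]),
                temp=None if pd.isna(row["temp"]) else float(row["temp"]),
                rr=None if pd.isna(row["rr"]) else float(row["rr"]),
                spo2=None if pd.isna(row["spo2"]) else float(row["spo2"]),
                gcs=None if pd.isna(row["gcs"]) else int(row["gcs"]),
                avpu=None if pd.isna(row["avpu"]) else row["avpu"],
                agitated=None if pd.isna(row["agitated"]) else bool(row["agitated"]),
                on_oxygen=None if pd.isna(row["on_oxygen"]) else bool(row["on_oxygen"]),
            )
            for _, row in grp.iterrows()
            if not pd.isna(row["measured_at"])
        ]
        encounters.append(
            PatientEncounter(
                encounter_id=str(enc_id),
                patient_id=str(meta["patient_id"]),
                arrival=meta["arrival"].to_pydatetime(),
                age_years=int(meta["age_years"]),
                sex=str(meta["sex"]),
                elective=bool(meta["elective"]),
                companion=bool(meta["companion"]),
                has_national_id=bool(meta["has_national_id"]),
                hospital=str(meta["hospital"]),
                vitals=vitals,
                death_date=death,
            )
        )
    return encounters


def read_encounters_csv(path) -> pd.DataFrame:
    """Read the encounters CSV dialect (one row per vital record)."""
    df = pd.read_csv(path)
    missing = set(ENCOUNTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"encounters CSV missing columns: {sorted(missing)}")
    df["arrival"] = pd.to_datetime(df["arrival"])
    df["measured_at"] = pd.to_datetime(df["measured_at"])
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")
    for col in ("elective", "companion", "has_national_id"):
        df[col] = df[col].astype(bool)
    return df
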