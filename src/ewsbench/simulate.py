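"""Synthetic emergency-department cohort generator.

A single latent severity per encounter drives correlated vital-sign
derangement, oxygen administration, consciousness level, and 7-day
mortality through logistic links.  Low-acuity encounters (minor injuries)
mostly skip vital-sign measurement, so excluded encounters are younger and
healthier than included ones.  Oxygen therapy partially corrects saturation
and respiratory rate toward normal (configurable shrinkage), which makes
the oxygen flag carry prognostic signal beyond the measured vitals.

Default parameters target the reference cohort margins: ~52% female,
median adult age 61 (IQR 41-76) among included encounters, ~2% 7-day
mortality among included, and ~37% of eligible contacts lacking a complete
vital set within 4 hours.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import ENCOUNTER_COLUMNS, frame_to_encounters

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_frame",
    "generate_cohort",
    "make_fixture",
    "write_encounters_csv",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SimulationConfig:
    """All parameters of the synthetic cohort generator."""

    n_encounters: int = 20000
    seed: int = 0

    # demographics
    female_frac: float = 0.52
    #: inverse-CDF knots for eligible acute adults at quantiles 0/.25/.5/.75/1
    acute_age_knots: tuple = (16, 44, 64, 78, 97)
    #: younger, healthier minor-injury population
    low_acuity_age_knots: tuple = (16, 25, 41, 60, 92)
    under16_rate: float = 0.03
    elective_rate: float = 0.02
    companion_rate: float = 0.01
    no_id_rate: float = 0.005
    repeat_rate: float = 0.05
    hospitals: tuple = ("Aarhus", "Horsens", "Viborg", "Randers", "Vest")
    hospital_probs: tuple = (0.30, 0.16, 0.17, 0.20, 0.17)
    period_start: str = "2015-03-01"
    period_days: int = 92

    # latent severity: |N(0, sigma)| plus a deranged gamma-distributed bump
    low_acuity_frac: float = 0.40
    deranged_frac: float = 0.18
    base_sigma: float = 0.40
    low_acuity_sigma: float = 0.15
    deranged_shape: float = 2.0
    deranged_scale: float = 0.70

    # per-vital response curves: value = baseline + slope * severity + noise
    sbp_base: float = 125.0
    sbp_slope: float = -9.0
    sbp_sd: float = 15.0
    hr_base: float = 82.0
    hr_slope: float = 10.0
    hr_sd: float = 12.0
    rr_base: float = 16.0
    rr_slope: float = 2.8
    rr_sd: float = 2.5
    temp_base: float = 37.0
    temp_slope: float = 0.55  # magnitude; direction drawn per encounter
    temp_fever_frac: float = 0.8  # share of derangement that runs febrile
    temp_sd: float = 0.45
    spo2_base: float = 97.0
    spo2_slope: float = -1.8
    spo2_sd: float = 1.5

    # consciousness thresholds on (severity + noise)
    loc_noise_sd: float = 0.3
    loc_v_threshold: float = 2.2
    loc_p_threshold: float = 2.8
    loc_u_threshold: float = 3.4
    agitation_intercept: float = -4.0
    agitation_slope: float = 0.8

    # oxygen administration and its masking of spo2 / rr
    oxygen_intercept: float = -3.8
    oxygen_slope: float = 2.4
    oxygen_spontaneous: float = 0.02
    oxygen_mask_shrink: float = 0.75

    # mortality link (7-day), logistic in severity
    mortality_intercept: float = -6.85
    mortality_slope: float = 2.1
    late_death_rate: float = 0.01  # deaths on day 8-60, beyond the outcome window

    # missingness of the vital panel
    missing_given_low_acuity: float = 0.82
    missing_given_acute: float = 0.05
    no_vitals_given_missing: float = 0.6
    oxygen_only_share: float = 0.06  # share of partial rows missing only on_oxygen
    late_vitals_rate: float = 0.015  # complete set recorded only after the window
    prerecord_rate: float = 0.15  # extra earlier incomplete row before the full set

    def validate(self) -> None:
        if self.n_encounters <= 0:
            raise ConfigError("n_encounters must be positive")
        probs = {
            "female_frac": self.female_frac,
            "under16_rate": self.under16_rate,
            "elective_rate": self.elective_rate,
            "companion_rate": self.companion_rate,
            "no_id_rate": self.no_id_rate,
            "repeat_rate": self.repeat_rate,
            "low_acuity_frac": self.low_acuity_frac,
            "deranged_frac": self.deranged_frac,
            "oxygen_spontaneous": self.oxygen_spontaneous,
            "oxygen_mask_shrink": self.oxygen_mask_shrink,
            "missing_given_low_acuity": self.missing_given_low_acuity,
            "missing_given_acute": self.missing_given_acute,
            "no_vitals_given_missing": self.no_vitals_given_missing,
            "oxygen_only_share": self.oxygen_only_share,
            "late_vitals_rate": self.late_vitals_rate,
            "prerecord_rate": self.prerecord_rate,
            "late_death_rate": self.late_death_rate,
        }
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")
        if abs(sum(self.hospital_probs) - 1) > 1e-9:
            raise ConfigError("hospital_probs must sum to 1")
        for name in ("base_sigma", "low_acuity_sigma", "deranged_shape", "deranged_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent state of each generated encounter (aligned with encounter order)."""

    encounter_ids: np.ndarray
    severity: np.ndarray
    mortality_prob: np.ndarray


def _piecewise_ages(rng, knots, size):
    u = rng.uniform(0, 1, size)
    q = np.linspace(0, 1, len(knots))
    return np.floor(np.interp(u, q, knots)).astype(int)


def generate_frame(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the one-row-per-vital-record encounters table.

    Deterministic for a given (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_encounters

    # --- encounter-level attributes -------------------------------------
    under16 = rng.random(n) < cfg.under16_rate
    elective = rng.random(n) < cfg.elective_rate
    companion = rng.random(n) < cfg.companion_rate
    no_id = rng.random(n) < cfg.no_id_rate
    low_acuity = rng.random(n) < cfg.low_acuity_frac

    female = rng.random(n) < cfg.female_frac
    ages = np.where(
        low_acuity,
        _piecewise_ages(rng, cfg.low_acuity_age_knots, n),
        _piecewise_ages(rng, cfg.acute_age_knots, n),
    )
    ages = np.where(under16, rng.integers(0, 16, n), ages)
    hospital = rng.choice(np.array(cfg.hospitals), size=n, p=np.array(cfg.hospital_probs))

    start = pd.Timestamp(cfg.period_start)
    arrival_offset_min = rng.uniform(0, cfg.period_days * 24 * 60, n)
    arrival = start + pd.to_timedelta(np.round(arrival_offset_min), unit="m")

    # --- latent severity -------------------------------------------------
    sigma = np.where(low_acuity, cfg.low_acuity_sigma, cfg.base_sigma)
    severity = np.abs(rng.normal(0, 1, n)) * sigma
    deranged = (~low_acuity) & (rng.random(n) < cfg.deranged_frac)
    severity = severity + np.where(
        deranged, rng.gamma(cfg.deranged_shape, cfg.deranged_scale, n), 0.0
    )

    # --- oxygen, vitals, consciousness ----------------------------------
    p_oxygen = np.clip(
        expit(cfg.oxygen_intercept + cfg.oxygen_slope * severity) + cfg.oxygen_spontaneous,
        0,
        1,
    )
    on_oxygen = rng.random(n) < p_oxygen

    sbp = rng.normal(cfg.sbp_base + cfg.sbp_slope * severity, cfg.sbp_sd)
    sbp = np.clip(sbp, 40, 260)
    hr = np.clip(rng.normal(cfg.hr_base + cfg.hr_slope * severity, cfg.hr_sd), 25, 220)
    rr = rng.normal(cfg.rr_base + cfg.rr_slope * severity, cfg.rr_sd)
    temp_dir = np.where(rng.random(n) < cfg.temp_fever_frac, 1.0, -1.0)
    temp = rng.normal(cfg.temp_base + temp_dir * cfg.temp_slope * severity, cfg.temp_sd)
    temp = np.clip(temp, 27, 43.5)
    spo2 = rng.normal(cfg.spo2_base + cfg.spo2_slope * severity, cfg.spo2_sd)

    # oxygen therapy partially corrects saturation and respiratory rate
    shrink = np.where(on_oxygen, cfg.oxygen_mask_shrink, 0.0)
    spo2 = spo2 + shrink * (cfg.spo2_base - spo2)
    rr = rr + shrink * (cfg.rr_base - rr)
    spo2 = np.clip(spo2, 50, 100)
    rr = np.clip(rr, 4, 60)

    loc_latent = severity + rng.normal(0, cfg.loc_noise_sd, n)
    gcs = np.select(
        [
            loc_latent >= cfg.loc_u_threshold,
            loc_latent >= cfg.loc_p_threshold,
            loc_latent >= cfg.loc_v_threshold,
        ],
        [rng.integers(3, 9, n), rng.integers(9, 14, n), np.full(n, 14)],
        default=15,
    )
    agitated = rng.random(n) < expit(cfg.agitation_intercept + cfg.agitation_slope * severity)

    # --- mortality -------------------------------------------------------
    p_death = expit(cfg.mortality_intercept + cfg.mortality_slope * severity)
    died_7d = rng.random(n) < p_death
    death_offset = np.where(died_7d, rng.integers(0, 8, n), -1)
    late = (~died_7d) & (rng.random(n) < cfg.late_death_rate)
    death_offset = np.where(late, rng.integers(8, 61, n), death_offset)
    dd_all = (
        arrival.normalize() + pd.to_timedelta(np.clip(death_offset, 0, None), unit="D")
    ).date
    death_date = pd.Series(np.where(death_offset >= 0, dd_all, None), dtype="object")

    # --- repeat visits ---------------------------------------------------
    patient_idx = np.arange(n)
    repeat = rng.random(n) < cfg.repeat_rate
    repeat[0] = False
    # a repeat copies patient identity from an earlier non-dying encounter
    for i in np.nonzero(repeat)[0]:
        src = int(rng.integers(0, i))
        if death_offset[src] >= 0:  # keep death dates patient-consistent
            repeat[i] = False
            continue
        patient_idx[i] = patient_idx[src]
        ages[i] = ages[src]
        female[i] = female[src]
        under16[i] = under16[src]
        no_id[i] = no_id[src]
        death_date.iloc[i] = None
        death_offset[i] = -1
        died_7d[i] = False

    # --- missingness of the vital panel ---------------------------------
    p_missing = np.where(low_acuity, cfg.missing_given_low_acuity, cfg.missing_given_acute)
    incomplete = rng.random(n) < p_missing
    no_vitals = incomplete & (rng.random(n) < cfg.no_vitals_given_missing)
    ox_only = incomplete & ~no_vitals & (rng.random(n) < cfg.oxygen_only_share)
    partial = incomplete & ~no_vitals & ~ox_only

    delay_min = np.round(rng.gamma(1.5, 0.6, n) * 60)
    late_vitals = (~incomplete) & (rng.random(n) < cfg.late_vitals_rate)
    delay_min = np.where(late_vitals, np.round((4 + rng.exponential(2.0, n)) * 60), delay_min)
    measured_at = arrival + pd.to_timedelta(delay_min, unit="m")

    enc_ids = np.array([f"E{i:06d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "patient_id": np.array([f"P{j:06d}" for j in patient_idx]),
            "arrival": arrival,
            "age_years": ages,
            "sex": np.where(female, "female", "male"),
            "elective": elective,
            "companion": companion,
            "has_national_id": ~no_id,
            "hospital": hospital,
            "death_date": death_date,
            "measured_at": measured_at,
            "sbp": np.round(sbp, 0),
            "hr": np.round(hr, 0),
            "temp": np.round(temp, 1),
            "rr": np.round(rr, 0),
            "spo2": np.round(spo2, 0),
            "gcs": gcs.astype(float),
            "avpu": pd.Series([None] * n, dtype="object"),
            "agitated": agitated.astype(object),
            "on_oxygen": on_oxygen.astype(object),
        }
    )

    vital_cols = ["sbp", "hr", "temp", "rr", "spo2", "gcs", "agitated", "on_oxygen"]
    df.loc[no_vitals, vital_cols] = None
    df.loc[no_vitals, "measured_at"] = pd.NaT
    df.loc[ox_only, "on_oxygen"] = None
    # partial rows: drop one guaranteed core field plus a random scatter
    p_idx = np.nonzero(partial)[0]
    core = ["sbp", "hr", "temp", "rr", "spo2", "gcs"]
    if len(p_idx):
        forced = rng.integers(0, len(core), len(p_idx))
        dropmask = rng.random((len(p_idx), len(core))) < 0.3
        dropmask[np.arange(len(p_idx)), forced] = True
        for j, col in enumerate(core):
            df.loc[p_idx[dropmask[:, j]], col] = None

    # extra earlier incomplete row before some complete panels
    pre = (~incomplete) & (~late_vitals) & (rng.random(n) < cfg.prerecord_rate)
    pre &= delay_min >= 10
    pre_rows = df.loc[pre].copy()
    pre_rows["measured_at"] = df.loc[pre, "arrival"] + pd.to_timedelta(
        np.round(delay_min[pre] / 2), unit="m"
    )
    drop_col = rng.choice(core, size=len(pre_rows))
    for col in core:
        pre_rows.loc[drop_col == col, col] = None
    frame = pd.concat([df, pre_rows], ignore_index=True)
    frame = frame.sort_values(
        ["encounter_id", "measured_at"], kind="stable", na_position="last"
    ).reset_index(drop=True)

    truth = GroundTruth(encounter_ids=enc_ids, severity=severity, mortality_prob=p_death)
    return frame[ENCOUNTER_COLUMNS], truth


def generate_cohort(config: SimulationConfig | None = None, seed: int | None = None):
    """Like :func:`generate_frame` but returns encounter objects.

    Returns ``(encounters, truth)`` where ``encounters`` is a list of
    :class:`~ewsbench.cohort.PatientEncounter`.
    """
    frame, truth = generate_frame(config, seed=seed)
    return frame_to_encounters(frame), truth


def write_encounters_csv(frame: pd.DataFrame, path) -> None:
    """Write the encounters table with a stable, byte-reproducible format."""
    out = frame.copy()
    for col in ("arrival", "measured_at"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False, float_format="%.1f")


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("eligibility_toy", "roc_worked", "flow100", "tie_arrivals")

_BASE_ROW = {
    "arrival": "2015-03-01 08:00:00",
    "age_years": 50,
    "sex": "female",
    "elective": False,
    "companion": False,
    "has_national_id": True,
    "hospital": "Aarhus",
    "death_date": None,
    "measured_at": "2015-03-01 08:30:00",
    "sbp": 120.0,
    "hr": 70.0,
    "temp": 37.0,
    "rr": 16.0,
    "spo2": 98.0,
    "gcs": 15.0,
    "avpu": None,
    "agitated": False,
    "on_oxygen": False,
}


def _rows(*overrides):
    rows = []
    for i, ov in enumerate(overrides):
        row = dict(_BASE_ROW)
        row["encounter_id"] = f"E{i:03d}"
        row["patient_id"] = f"P{i:03d}"
        row.update(ov)
        rows.append(row)
    return pd.DataFrame(rows)[ENCOUNTER_COLUMNS]


def make_fixture(name: str) -> pd.DataFrame:
    """Small deterministic encounter tables used across the test suite.

    ``eligibility_toy``: six encounters, one per ineligibility reason plus
    two eligible.  ``roc_worked``: six scored subjects with one tie for the
    pairwise AUROC oracle.  ``flow100``: 100 encounters with a hand-counted
    exclusion flow (4 under-16, 3 elective, 2 companion, 1 no-id, 5 repeat,
    20 without complete vitals of which 3 oxygen-only, 65 included, 2 deaths).
    ``tie_arrivals``: one patient with two identical arrival timestamps.
    """
    if name == "eligibility_toy":
        return _rows(
            {"age_years": 15},
            {"elective": True},
            {"companion": True},
            {"has_national_id": False},
            {},
            {"age_years": 80, "sex": "male"},
        )
    if name == "roc_worked":
        return pd.DataFrame(
            {"score": [1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
             "died": [False, False, True, False, True, True]}
        )
    if name == "flow100":
        overrides = []
        overrides += [{"age_years": a} for a in (0, 5, 10, 15)]  # 4 under-16
        overrides += [{"elective": True}] * 3
        overrides += [{"companion": True}] * 2
        overrides += [{"has_national_id": False}]
        # 5 repeat contacts: patients R0-R4 each get a later second visit
        for j in range(5):
            overrides.append(
                {"patient_id": f"R{j}", "arrival": "2015-03-02 08:00:00",
                 "measured_at": "2015-03-02 08:30:00"}
            )
            overrides.append(
                {"patient_id": f"R{j}", "arrival": "2015-03-10 08:00:00",
                 "measured_at": "2015-03-10 08:30:00"}
            )
        # 20 encounters without a complete set in the window
        overrides += [{"sbp": None, "measured_at": None}] * 10  # no vitals at all
        overrides += [{"rr": None}] * 4  # partial panel
        overrides += [{"gcs": None}] * 3  # no consciousness
        overrides += [{"on_oxygen": None}] * 3  # oxygen-documentation-only
        # 60 clean included encounters (the 5 repeat index visits make 65)
        overrides += [{} for _ in range(58)]
        overrides += [
            {"death_date": "2015-03-03", "sbp": 85.0, "spo2": 88.0, "on_oxygen": True},
            {"death_date": "2015-03-20", "hr": 120.0},  # beyond the 7-day window
        ]
        df = _rows(*overrides)
        # give non-repeat rows unique patients (the _rows default already does)
        return df
    if name == "tie_arrivals":
        return _rows(
            {"patient_id": "T0"},
            {"patient_id": "T0"},
        )
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
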