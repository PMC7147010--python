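"""Data-driven early-warning-score engines.

A score system is a named collection of per-parameter threshold scales
(ordered half-open bands, each worth 0-3 points), a level-of-consciousness
rule (AVPU points combined with an agitation point), and an additive
oxygen-supplement modifier.  The three bundled systems — TOKS, mTOKS and
NEWS — are shipped as YAML files under ``ewsbench/data`` and validated
against their published maximum attainable scores, so any transcription
error in the band tables is caught as data, not silently scored.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AvpuLevel",
    "VitalSet",
    "ScoreBand",
    "ParameterScale",
    "LocRule",
    "ScoreSystem",
    "ValidationError",
    "VITAL_PARAMETERS",
    "gcs_to_avpu",
    "validate_score_system",
    "score_parameter",
    "score_loc",
    "score",
    "score_all_systems",
    "score_frame",
    "load_system",
    "load_bundled_systems",
    "BUNDLED_SYSTEMS",
]

#: the five numeric vital parameters every system must cover
VITAL_PARAMETERS = ("sbp", "hr", "temp", "rr", "spo2")

BUNDLED_SYSTEMS = ("TOKS", "mTOKS", "NEWS")


class ValidationError(ValueError):
    """Raised when an input value or structure violates a documented contract."""


class AvpuLevel(enum.IntEnum):
    """Four-level consciousness scale, ordered A < V < P < U."""

    A = 0
    V = 1
    P = 2
    U = 3

    @classmethod
    def parse(cls, value) -> "AvpuLevel":
        if isinstance(value, AvpuLevel):
            return value
        if isinstance(value, str):
            try:
                return cls[value.strip().upper()]
            except KeyError:
                raise ValidationError(f"unknown AVPU level {value!r}") from None
        raise ValidationError(f"cannot interpret {value!r} as an AVPU level")


def gcs_to_avpu(gcs: int) -> AvpuLevel:
    """Map a Glasgow Coma Scale total (3-15) onto the AVPU scale.

    15 -> A, 14 -> V, 9-13 -> P, 3-8 -> U.

    Raises
    ------
    ValidationError
        If ``gcs`` is outside 3-15 or not an integer value.
    """
    if not float(gcs).is_integer():
        raise ValidationError(f"GCS must be an integer, got {gcs!r}")
    gcs = int(gcs)
    if not 3 <= gcs <= 15:
        raise ValidationError(f"GCS total out of range 3-15: {gcs}")
    if gcs == 15:
        return AvpuLevel.A
    if gcs == 14:
        return AvpuLevel.V
    if gcs >= 9:
        return AvpuLevel.P
    return AvpuLevel.U


@dataclass(frozen=True)
class VitalSet:
    """One complete panel of vital signs sharing a single timestamp."""

    sbp: float
    hr: float
    temp: float
    rr: float
    spo2: float
    loc: AvpuLevel
    agitated: bool = False
    on_oxygen: bool = False
    measured_at: datetime | None = None

    def missing_fields(self) -> list[str]:
        """Names of vital fields that are absent or non-finite."""
        missing = []
        for name in VITAL_PARAMETERS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                missing.append(name)
        if self.loc is None:
            missing.append("loc")
        if self.on_oxygen is None:
            missing.append("on_oxygen")
        return missing

    def validate(self) -> None:
        missing = self.missing_fields()
        if missing:
            raise ValidationError(f"incomplete vital set, missing: {', '.join(missing)}")
        if not 0 <= self.spo2 <= 100:
            raise ValidationError(f"spo2 out of [0, 100]: {self.spo2}")


@dataclass(frozen=True)
class ScoreBand:
    """Half-open interval [lower, upper) worth a fixed number of points."""

    lower: float  # -inf allowed
    upper: float  # +inf allowed
    points: int

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValidationError(f"band requires lower < upper, got [{self.lower}, {self.upper})")
        if self.points not in (0, 1, 2, 3):
            raise ValidationError(f"band points must be in 0-3, got {self.points}")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass(frozen=True)
class ParameterScale:
    """Ordered bands partitioning the real line for one vital parameter."""

    parameter: str
    bands: tuple[ScoreBand, ...]

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(sorted(self.bands, key=lambda b: b.lower)))

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bands)

    def violations(self) -> list[str]:
        """Partition defects: gaps, overlaps, open ends, zero-band count."""
        out = []
        bands = self.bands
        if bands[0].lower != -math.inf:
            out.append(f"{self.parameter}: gap below {bands[0].lower} (no band covers -inf)")
        if bands[-1].upper != math.inf:
            out.append(f"{self.parameter}: gap above {bands[-1].upper} (no band covers +inf)")
        for a, b in zip(bands, bands[1:]):
            if a.upper < b.lower:
                out.append(f"{self.parameter}: gap over [{a.upper}, {b.lower})")
            elif a.upper > b.lower:
                out.append(f"{self.parameter}: overlap over [{b.lower}, {min(a.upper, b.upper)})")
        n_zero = sum(1 for b in bands if b.points == 0)
        if n_zero != 1:
            out.append(f"{self.parameter}: expected exactly one zero band, found {n_zero}")
        return out

    def score(self, value: float) -> int:
        return score_parameter(self, value)

    # edge arrays for the vectorised path, cached lazily
    def _edges(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.array([b.lower for b in self.bands[1:]])
        points = np.array([b.points for b in self.bands], dtype=np.int64)
        return edges, points


@dataclass(frozen=True)
class LocRule:
    """How AVPU points and the agitation point combine into the LOC component."""

    avpu_points: Mapping[AvpuLevel, int]
    agitation_points: int = 1
    combination: str = "max"  # or "sum"

    def __post_init__(self):
        pts = {AvpuLevel.parse(k): int(v) for k, v in self.avpu_points.items()}
        object.__setattr__(self, "avpu_points", pts)
        if set(pts) != set(AvpuLevel):
            raise ValidationError("loc rule must map all four AVPU levels")
        if pts[AvpuLevel.A] != 0:
            raise ValidationError("AVPU level A must score 0 points")
        ordered = [pts[l] for l in sorted(AvpuLevel)]
        if ordered != sorted(ordered):
            raise ValidationError("AVPU points must be non-decreasing in A < V < P < U")
        if self.combination not in ("max", "sum"):
            raise ValidationError(f"unknown loc combination {self.combination!r}")

    @property
    def max_points(self) -> int:
        worst_avpu = max(self.avpu_points.values())
        if self.combination == "max":
            return max(worst_avpu, self.agitation_points)
        return worst_avpu + self.agitation_points


@dataclass(frozen=True)
class ScoreSystem:
    """A named, validated early-warning-score definition."""

    name: str
    scales: Mapping[str, ParameterScale]
    loc_rule: LocRule
    oxygen_points: int
    declared_max: int

    @property
    def computed_max(self) -> int:
        return (
            sum(s.max_points for s in self.scales.values())
            + self.loc_rule.max_points
            + self.oxygen_points
        )

    def validate(self) -> list[str]:
        return validate_score_system(self)

    def score(self, vitals: VitalSet) -> int:
        return score(self, vitals)


def _band_from_cfg(d: Mapping) -> ScoreBand:
    lower = -math.inf if d.get("lower") is None else float(d["lower"])
    upper = math.inf if d.get("upper") is None else float(d["upper"])
    return ScoreBand(lower=lower, upper=upper, points=int(d["points"]))


def _system_from_cfg(cfg: Mapping) -> ScoreSystem:
    for key in ("name", "declared_max", "oxygen_points", "loc_rule", "scales"):
        if key not in cfg:
            raise ValidationError(f"score-system config missing field {key!r}")
    scales = {}
    for sc in cfg["scales"]:
        p = sc["parameter"]
        if p not in VITAL_PARAMETERS:
            raise ValidationError(f"unknown parameter {p!r} in score-system config")
        if p in scales:
            raise ValidationError(f"duplicate scale for parameter {p!r}")
        scales[p] = ParameterScale(parameter=p, bands=tuple(_band_from_cfg(b) for b in sc["bands"]))
    missing = set(VITAL_PARAMETERS) - set(scales)
    if missing:
        raise ValidationError(f"score-system config missing scales for: {sorted(missing)}")
    lr = cfg["loc_rule"]
    rule = LocRule(
        avpu_points=lr["avpu_points"],
        agitation_points=int(lr.get("agitation_points", 0)),
        combination=lr.get("combination", "max"),
    )
    return ScoreSystem(
        name=str(cfg["name"]),
        scales=scales,
        loc_rule=rule,
        oxygen_points=int(cfg["oxygen_points"]),
        declared_max=int(cfg["declared_max"]),
    )


def load_system(source) -> ScoreSystem:
    """Load a score system from a YAML path, file object, or parsed mapping."""
    if isinstance(source, Mapping):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    system = _system_from_cfg(cfg)
    problems = validate_score_system(system)
    if problems:
        raise ValidationError(f"invalid score system {system.name!r}: " + "; ".join(problems))
    return system


def load_bundled_systems(names: Iterable[str] = BUNDLED_SYSTEMS) -> dict[str, ScoreSystem]:
    """Load the bundled TOKS/mTOKS/NEWS definitions shipped with the package."""
    out = {}
    for name in names:
        text = resources.files("ewsbench.data").joinpath(f"{name.lower()}.yaml").read_text()
        out[name] = load_system(yaml.safe_load(text))
    return out


def validate_score_system(system: ScoreSystem) -> list[str]:
    """Return all structural violations (empty list means valid).

    Checks that every scale partitions the real line with half-open bands,
    has exactly one zero band, and that the computed maximum attainable
    score matches the declared maximum — the transcription checksum.
    """
    out = []
    for scale in system.scales.values():
        out.extend(scale.violations())
    if system.computed_max != system.declared_max:
        out.append(
            f"{system.name}: computed max {system.computed_max} != declared max {system.declared_max}"
        )
    return out


def score_parameter(scale: ParameterScale, value: float) -> int:
    """Points for one vital value: the unique band with lower <= value < upper."""
    if value is None or not math.isfinite(value):
        raise ValidationError(f"non-finite value for {scale.parameter}: {value!r}")
    lowers = [b.lower for b in scale.bands]
    i = bisect_right(lowers, value) - 1
    band = scale.bands[i]
    if not band.contains(value):  # only possible on a gapped (invalid) scale
        raise ValidationError(f"no band of {scale.parameter} contains {value}")
    return band.points


def score_loc(rule: LocRule, loc: AvpuLevel, agitated: bool) -> int:
    """LOC component: AVPU points combined with the agitation point."""
    avpu = rule.avpu_points[AvpuLevel.parse(loc)]
    agit = rule.agitation_points if agitated else 0
    if rule.combination == "max":
        return max(avpu, agit)
    return avpu + agit


def score(system: ScoreSystem, vitals: VitalSet) -> int:
    """Aggregate score: sum of the five parameter points + LOC + oxygen modifier."""
    vitals.validate()
    total = sum(score_parameter(system.scales[p], getattr(vitals, p)) for p in VITAL_PARAMETERS)
    total += score_loc(system.loc_rule, vitals.loc, vitals.agitated)
    if vitals.on_oxygen:
        total += system.oxygen_points
    return total


def score_all_systems(
    vitals: VitalSet, systems: Mapping[str, ScoreSystem] | None = None
) -> dict[str, int]:
    """Score the same vital set under every system (bundled three by default)."""
    if systems is None:
        systems = load_bundled_systems()
    return {name: score(sys_, vitals) for name, sys_ in systems.items()}


def score_frame(
    system: ScoreSystem,
    sbp: Sequence[float],
    hr: Sequence[float],
    temp: Sequence[float],
    rr: Sequence[float],
    spo2: Sequence[float],
    avpu: Sequence[int],
    agitated: Sequence[bool],
    on_oxygen: Sequence[bool],
) -> np.ndarray:
    """Vectorised aggregate scores for column arrays of complete vital sets.

    ``avpu`` is integer-coded (A=0 .. U=3).  Equivalent to calling
    :func:`score` row by row; used for bulk cohort scoring.
    """
    total = np.zeros(len(np.asarray(sbp)), dtype=np.int64)
    cols = {"sbp": sbp, "hr": hr, "temp": temp, "rr": rr, "spo2": spo2}
    for p, values in cols.items():
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError(f"non-finite values in column {p}")
        edges, points = system.scales[p]._edges()
        total += points[np.searchsorted(edges, values, side="right")]
    avpu = np.asarray(avpu, dtype=np.int64)
    avpu_pts = np.array([system.loc_rule.avpu_points[l] for l in sorted(AvpuLevel)])
    agit_pts = np.where(np.asarray(agitated, dtype=bool), system.loc_rule.agitation_points, 0)
    if system.loc_rule.combination == "max":
        total += np.maximum(avpu_pts[avpu], agit_pts)
    else:
        total += avpu_pts[avpu] + agit_pts
    total += np.where(np.asarray(on_oxygen, dtype=bool), system.oxygen_points, 0)
    return total
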