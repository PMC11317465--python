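"""Domain model for a longitudinally followed GCA cohort.

Giant cell arteritis (GCA) is monitored here at the level of *visits*: each
encounter records the clinician's relapse/remission call, a CRP measurement,
treatment, and a protocol vascular ultrasound exam covering 18 bilateral
arterial segments (4 cranial vessels and 5 supraaortic large vessels per
side). Cranial arteries and the vertebral artery are read as a binary halo
sign; the remaining large vessels are read as a maximum intima-media
thickness (IMT) in millimetres.

This module defines the segment taxonomy, the visit/patient/cohort
containers, CSV input/output with validation, the analysis configuration,
and the single involvement predicate every scoring rule quantifies over.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import NoExamError, SchemaError

# Tolerance for IMT threshold comparisons: values are physical measurements
# carried as binary floats, and the relapse rule treats exact ties as hits.
IMT_EPS = 1e-9


class Vessel(str, enum.Enum):
    """The nine vessels assessed per side."""

    TEMPORAL_COMMON = "temporal_common"
    TEMPORAL_FRONTAL = "temporal_frontal"
    TEMPORAL_PARIETAL = "temporal_parietal"
    FACIAL = "facial"
    VERTEBRAL = "vertebral"
    CAROTID = "carotid"
    SUBCLAVIAN = "subclavian"
    AXILLARY_PROXIMAL = "axillary_proximal"
    AXILLARY_DISTAL = "axillary_distal"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


#: Cranial arteries: the temporal tree plus the facial artery.
CRANIAL_VESSELS = frozenset(
    {
        Vessel.TEMPORAL_COMMON,
        Vessel.TEMPORAL_FRONTAL,
        Vessel.TEMPORAL_PARIETAL,
        Vessel.FACIAL,
    }
)

#: Large vessels (LV). The vertebral artery is assessed by halo sign but
#: belongs to the large-vessel class for subtype and counting purposes.
LV_VESSELS = frozenset(
    {
        Vessel.VERTEBRAL,
        Vessel.CAROTID,
        Vessel.SUBCLAVIAN,
        Vessel.AXILLARY_PROXIMAL,
        Vessel.AXILLARY_DISTAL,
    }
)

#: Vessels recorded as a binary halo sign.
HALO_VESSELS = CRANIAL_VESSELS | {Vessel.VERTEBRAL}

#: Vessels recorded as a maximum IMT in millimetres.
IMT_VESSELS = LV_VESSELS - {Vessel.VERTEBRAL}

#: Branches of the temporal artery tree, counted once per side in the
#: simple halo count.
TEMPORAL_TREE = frozenset(
    {Vessel.TEMPORAL_COMMON, Vessel.TEMPORAL_FRONTAL, Vessel.TEMPORAL_PARIETAL}
)


@dataclass(frozen=True, order=True)
class SegmentID:
    """One of the 18 bilateral arterial segments."""

    vessel: Vessel
    side: Side

    @property
    def is_cranial(self) -> bool:
        return self.vessel in CRANIAL_VESSELS

    @property
    def is_lv(self) -> bool:
        return self.vessel in LV_VESSELS

    @property
    def carries_halo(self) -> bool:
        return self.vessel in HALO_VESSELS

    @property
    def carries_imt(self) -> bool:
        return self.vessel in IMT_VESSELS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.side.value} {self.vessel.value}"


#: All 18 segments in a fixed deterministic order (vessel enum order, left
#: before right).
ALL_SEGMENTS: tuple[SegmentID, ...] = tuple(
    SegmentID(vessel, side) for vessel in Vessel for side in (Side.LEFT, Side.RIGHT)
)


@dataclass(frozen=True)
class SegmentFinding:
    """One segment's reading at one exam.

    Halo vessels (cranial + vertebral) carry a boolean halo and no IMT;
    the non-vertebral large vessels carry an IMT in (0, 5) mm and no halo.
    """

    segment: SegmentID
    halo: Optional[bool] = None
    imt_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.segment.carries_halo:
            if self.halo is None or self.imt_mm is not None:
                raise SchemaError(
                    f"segment {self.segment} is halo-assessed: requires a halo "
                    f"flag and must not carry an IMT value"
                )
        else:
            if self.imt_mm is None or self.halo is not None:
                raise SchemaError(
                    f"segment {self.segment} is IMT-assessed: requires an IMT "
                    f"value and must not carry a halo flag"
                )
            if not (0.0 < self.imt_mm < 5.0):
                raise SchemaError(
                    f"segment {self.segment}: imt_mm={self.imt_mm} outside (0, 5) mm"
                )


@dataclass(frozen=True)
class UltrasoundExam:
    """All segment findings of one visit; the unit compared across visits."""

    findings: Mapping[SegmentID, SegmentFinding] = field(default_factory=dict)
    performed: bool = True

    def __post_init__(self) -> None:
        if not self.performed and self.findings:
            raise SchemaError("an exam that was not performed cannot carry findings")
        for seg, finding in self.findings.items():
            if finding.segment != seg:
                raise SchemaError(f"finding for {finding.segment} keyed as {seg}")

    @classmethod
    def not_performed(cls) -> "UltrasoundExam":
        return cls(findings={}, performed=False)

    @classmethod
    def from_findings(cls, findings: Iterable[SegmentFinding]) -> "UltrasoundExam":
        mapping: dict[SegmentID, SegmentFinding] = {}
        for f in findings:
            if f.segment in mapping:
                raise SchemaError(f"duplicate finding for segment {f.segment}")
            mapping[f.segment] = f
        return cls(findings=mapping, performed=True)


@dataclass(frozen=True)
class Visit:
    """One encounter: clinical call, labs, treatment, and the exam."""

    patient_id: str
    month: float
    clinical_relapse: bool
    exam: UltrasoundExam
    crp_mg_l: Optional[float] = None
    prednisolone_mg: Optional[float] = None
    dmard: Optional[str] = None

    def __post_init__(self) -> None:
        if self.month < 0:
            raise SchemaError(f"visit month must be >= 0, got {self.month}")
        if self.month == 0 and self.clinical_relapse:
            raise SchemaError(
                "clinical relapse is undefined at the diagnosis visit "
                "(relapse requires a prior remission period)"
            )
        if self.crp_mg_l is not None and self.crp_mg_l < 0:
            raise SchemaError(f"crp_mg_l must be >= 0, got {self.crp_mg_l}")

    @property
    def is_diagnosis(self) -> bool:
        return self.month == 0


@dataclass(frozen=True)
class Patient:
    """A patient and their visits, ordered by month since diagnosis.

    Demographics are optional: the visit-level CSV schema does not carry
    them, so cohorts read from disk leave them unset.
    """

    patient_id: str
    visits: tuple[Visit, ...]
    sex: Optional[str] = None
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        months = [v.month for v in self.visits]
        if not months:
            raise SchemaError(f"patient {self.patient_id} has no visits")
        if months[0] != 0:
            raise SchemaError(
                f"patient {self.patient_id}: first visit must be month 0"
            )
        if any(b <= a for a, b in zip(months, months[1:])):
            raise SchemaError(
                f"patient {self.patient_id}: visit months must be strictly increasing"
            )
        for v in self.visits:
            if v.patient_id != self.patient_id:
                raise SchemaError(
                    f"visit patient_id {v.patient_id} != patient {self.patient_id}"
                )

    @property
    def diagnosis_visit(self) -> Visit:
        return self.visits[0]

    @property
    def followup_visits(self) -> tuple[Visit, ...]:
        return self.visits[1:]


@dataclass(frozen=True)
class Cohort:
    patients: tuple[Patient, ...]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def _default_lv_cutoffs() -> dict[Vessel, float]:
    # Convention, not a published fact: a 1.0 mm IMT cutoff for every
    # compression-incapable large vessel. Configurable per vessel.
    return {
        Vessel.CAROTID: 1.0,
        Vessel.SUBCLAVIAN: 1.0,
        Vessel.AXILLARY_PROXIMAL: 1.0,
        Vessel.AXILLARY_DISTAL: 1.0,
    }


@dataclass
class AnalysisConfig:
    """Thresholds governing every rule in the pipeline.

    imt_delta_cutoff_mm
        Minimum IMT increase (mm) in an already-involved large vessel, versus
        the previous performed exam, that counts as ultrasound relapse.
    crp_threshold_mg_l
        CRP is "elevated" when strictly above this value (mg/L).
    lv_involvement_cutoff_mm
        Per-vessel IMT cutoff (mm) at or above which an IMT-assessed large
        vessel counts as involved.
    gcas_active_threshold
        Number of positive GCAS components (of 3) defining active disease.
    """

    imt_delta_cutoff_mm: float = 0.2
    crp_threshold_mg_l: float = 5.0
    lv_involvement_cutoff_mm: dict[Vessel, float] = field(
        default_factory=_default_lv_cutoffs
    )
    gcas_active_threshold: int = 2

    def __post_init__(self) -> None:
        self.lv_involvement_cutoff_mm = {
            Vessel(k): float(v) for k, v in self.lv_involvement_cutoff_mm.items()
        }
        self.validate()

    def validate(self) -> None:
        if not self.imt_delta_cutoff_mm > 0:
            raise SchemaError("imt_delta_cutoff_mm must be > 0")
        if not self.crp_threshold_mg_l > 0:
            raise SchemaError("crp_threshold_mg_l must be > 0")
        for vessel in IMT_VESSELS:
            cut = self.lv_involvement_cutoff_mm.get(vessel)
            if cut is None or not cut > 0:
                raise SchemaError(
                    f"lv_involvement_cutoff_mm must give a positive cutoff "
                    f"for {vessel.value}"
                )
        if self.gcas_active_threshold not in (1, 2, 3):
            raise SchemaError("gcas_active_threshold must be 1, 2 or 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return {
            "imt_delta_cutoff_mm": self.imt_delta_cutoff_mm,
            "crp_threshold_mg_l": self.crp_threshold_mg_l,
            "lv_involvement_cutoff_mm": {
                v.value: c for v, c in sorted(self.lv_involvement_cutoff_mm.items())
            },
            "gcas_active_threshold": self.gcas_active_threshold,
        }


def involved_segments(exam: UltrasoundExam, config: AnalysisConfig) -> set[SegmentID]:
    """Segments with ultrasound findings consistent with vasculitis.

    A halo-assessed segment (cranial or vertebral) is involved iff its halo
    sign is positive; an IMT-assessed large vessel is involved iff its IMT is
    at or above the configured cutoff for that vessel. Segments absent from
    the exam were not assessed and are never involved.

    Raises
    ------
    NoExamError
        If the exam was not performed; "no information" is deliberately
        distinct from "no involvement".
    """
    if not exam.performed:
        raise NoExamError("ultrasound was not performed at this visit")
    involved: set[SegmentID] = set()
    for seg, finding in exam.findings.items():
        if seg.carries_halo:
            if finding.halo:
                involved.add(seg)
        else:
            cutoff = config.lv_involvement_cutoff_mm[seg.vessel]
            if finding.imt_mm is not None and finding.imt_mm >= cutoff - IMT_EPS:
                involved.add(seg)
    return involved


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

VISITS_COLUMNS = [
    "patient_id",
    "month",
    "clinical_relapse",
    "crp_mg_l",
    "prednisolone_mg",
    "dmard",
    "ultrasound_performed",
]

VESSELS_COLUMNS = ["patient_id", "month", "vessel", "side", "halo", "imt_mm"]


def _require_columns(df: pd.DataFrame, expected: list[str], path: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_flag(value: str, path: str, row: int, col: str) -> bool:
    if value not in ("0", "1"):
        raise SchemaError(f"{path} row {row}: {col} must be 0 or 1, got {value!r}")
    return value == "1"


def _parse_float(value: str, path: str, row: int, col: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise SchemaError(
            f"{path} row {row}: {col} must be numeric, got {value!r}"
        ) from None
    if math.isnan(out) or math.isinf(out):
        raise SchemaError(f"{path} row {row}: {col} must be finite, got {value!r}")
    return out


def read_cohort(visits_path: str | Path, vessels_path: str | Path) -> Cohort:
    """Read and validate a cohort from its two CSV tables.

    ``visits.csv`` holds one row per encounter; ``vessels.csv`` holds one row
    per assessed segment per encounter. Blank CRP cells become absent values;
    visits without vessel rows and with ``ultrasound_performed=0`` get a
    skipped exam. Row numbers in error messages are 1-based data rows
    (header excluded).
    """
    visits_path, vessels_path = str(visits_path), str(vessels_path)
    visits_df = pd.read_csv(visits_path, dtype=str, keep_default_na=False)
    vessels_df = pd.read_csv(vessels_path, dtype=str, keep_default_na=False)
    _require_columns(visits_df, VISITS_COLUMNS, visits_path)
    _require_columns(vessels_df, VESSELS_COLUMNS, vessels_path)

    # Parse segment rows, grouped per (patient, month).
    findings_by_visit: dict[tuple[str, float], list[SegmentFinding]] = {}
    seen_segments: set[tuple[str, float, Vessel, Side]] = set()
    for i, row in enumerate(vessels_df.itertuples(index=False), start=1):
        pid = row.patient_id
        month = _parse_float(row.month, vessels_path, i, "month")
        try:
            vessel = Vessel(row.vessel)
        except ValueError:
            raise SchemaError(
                f"{vessels_path} row {i}: unknown vessel {row.vessel!r}"
            ) from None
        try:
            side = Side(row.side)
        except ValueError:
            raise SchemaError(
                f"{vessels_path} row {i}: side must be left or right, got {row.side!r}"
            ) from None
        key = (pid, month, vessel, side)
        if key in seen_segments:
            raise SchemaError(
                f"{vessels_path} row {i}: duplicate segment for patient {pid} "
                f"month {month:g}: {side.value} {vessel.value}"
            )
        seen_segments.add(key)
        segment = SegmentID(vessel, side)
        halo = None if row.halo == "" else _parse_flag(row.halo, vessels_path, i, "halo")
        imt = None if row.imt_mm == "" else _parse_float(row.imt_mm, vessels_path, i, "imt_mm")
        try:
            finding = SegmentFinding(segment=segment, halo=halo, imt_mm=imt)
        except SchemaError as exc:
            raise SchemaError(f"{vessels_path} row {i}: {exc}") from None
        findings_by_visit.setdefault((pid, month), []).append(finding)

    # Parse visit rows.
    visits_by_patient: dict[str, list[Visit]] = {}
    patient_order: list[str] = []
    seen_visits: set[tuple[str, float]] = set()
    for i, row in enumerate(visits_df.itertuples(index=False), start=1):
        pid = row.patient_id
        if pid == "":
            raise SchemaError(f"{visits_path} row {i}: empty patient_id")
        month = _parse_float(row.month, visits_path, i, "month")
        if (pid, month) in seen_visits:
            raise SchemaError(
                f"{visits_path} row {i}: duplicate visit for patient {pid} "
                f"month {month:g}"
            )
        seen_visits.add((pid, month))
        performed = _parse_flag(
            row.ultrasound_performed, visits_path, i, "ultrasound_performed"
        )
        visit_findings = findings_by_visit.pop((pid, month), [])
        if performed:
            exam = UltrasoundExam.from_findings(visit_findings)
        else:
            if visit_findings:
                raise SchemaError(
                    f"{visits_path} row {i}: patient {pid} month {month:g} has "
                    f"ultrasound_performed=0 but vessel rows exist"
                )
            exam = UltrasoundExam.not_performed()
        try:
            visit = Visit(
                patient_id=pid,
                month=month,
                clinical_relapse=_parse_flag(
                    row.clinical_relapse, visits_path, i, "clinical_relapse"
                ),
                crp_mg_l=None
                if row.crp_mg_l == ""
                else _parse_float(row.crp_mg_l, visits_path, i, "crp_mg_l"),
                prednisolone_mg=None
                if row.prednisolone_mg == ""
                else _parse_float(row.prednisolone_mg, visits_path, i, "prednisolone_mg"),
                dmard=None if row.dmard == "" else row.dmard,
                exam=exam,
            )
        except SchemaError as exc:
            raise SchemaError(f"{visits_path} row {i}: {exc}") from None
        if pid not in visits_by_patient:
            visits_by_patient[pid] = []
            patient_order.append(pid)
        visits_by_patient[pid].append(visit)

    if findings_by_visit:
        (pid, month), _ = next(iter(findings_by_visit.items()))
        raise SchemaError(
            f"{vessels_path}: vessel rows for patient {pid} month {month:g} "
            f"have no matching visit row"
        )

    patients = tuple(
        Patient(
            patient_id=pid,
            visits=tuple(sorted(visits_by_patient[pid], key=lambda v: v.month)),
        )
        for pid in patient_order
    )
    return Cohort(patients=patients)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return str(value)


def write_cohort(
    cohort: Cohort, visits_path: str | Path, vessels_path: str | Path
) -> None:
    """Write a cohort to the two CSV tables; inverse of :func:`read_cohort`."""
    visit_rows = []
    vessel_rows = []
    for patient in cohort:
        for visit in patient.visits:
            visit_rows.append(
                {
                    "patient_id": visit.patient_id,
                    "month": str(visit.month),
                    "clinical_relapse": int(visit.clinical_relapse),
                    "crp_mg_l": _fmt(visit.crp_mg_l),
                    "prednisolone_mg": _fmt(visit.prednisolone_mg),
                    "dmard": visit.dmard or "",
                    "ultrasound_performed": int(visit.exam.performed),
                }
            )
            for seg in sorted(visit.exam.findings):
                finding = visit.exam.findings[seg]
                vessel_rows.append(
                    {
                        "patient_id": visit.patient_id,
                        "month": str(visit.month),
                        "vessel": seg.vessel.value,
                        "side": seg.side.value,
                        "halo": "" if finding.halo is None else int(finding.halo),
                        "imt_mm": _fmt(finding.imt_mm),
                    }
                )
    pd.DataFrame(visit_rows, columns=VISITS_COLUMNS).to_csv(visits_path, index=False)
    pd.DataFrame(vessel_rows, columns=VESSELS_COLUMNS).to_csv(vessels_path, index=False)
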