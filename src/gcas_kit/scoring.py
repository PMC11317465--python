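"""Per-visit GCA scoring rules.

Four rule families operate on the involvement predicate of
:mod:`gcas_kit.cohort_model`:

* subtype classification at diagnosis (cranial-only, large-vessel-only, or
  mixed involvement);
* the three halo counts measuring extent of disease (simple, extended, and
  modified extended, the last weighting large vessels double);
* the ultrasound relapse rule — a new involved segment, or an IMT increase of
  at least the configured delta (default 0.2 mm) in an already-involved
  large vessel, versus the previous performed exam;
* the GCAS composite activity score: clinical symptoms, elevated CRP
  (> 5 mg/L), positive imaging; active disease at >= 2 of 3 components.

Missing inputs propagate as "not assessed"/undefined rather than being
imputed; the accuracy analytics decide per index test which visits to drop.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort_model import (
    CRANIAL_VESSELS,
    IMT_EPS,
    IMT_VESSELS,
    TEMPORAL_TREE,
    AnalysisConfig,
    Cohort,
    Patient,
    SegmentID,
    Side,
    UltrasoundExam,
    Visit,
    involved_segments,
)
from .errors import NoExamError, NotClassifiableError


class Subtype(str, enum.Enum):
    """GCA subtype from the diagnosis exam's involvement pattern."""

    C_GCA = "c_gca"
    LV_GCA = "lv_gca"
    MIXED_GCA = "mixed_gca"


class UsState(str, enum.Enum):
    RELAPSE = "relapse"
    REMISSION = "remission"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class RelapseReason:
    """Why a visit is ultrasound relapse: a new segment or an IMT increase."""

    kind: str  # "new_segment" | "imt_increase"
    segment: SegmentID
    delta_mm: Optional[float] = None


@dataclass(frozen=True)
class UltrasoundStatus:
    status: UsState
    reasons: tuple[RelapseReason, ...] = ()

    def __post_init__(self) -> None:
        if (self.status is UsState.RELAPSE) != bool(self.reasons):
            raise ValueError("status is relapse iff reasons are non-empty")


NOT_ASSESSED = UltrasoundStatus(status=UsState.NOT_ASSESSED)


@dataclass(frozen=True)
class GcasResult:
    """GCAS components and score; undefined pieces stay None.

    The score is only defined when all three components are defined (the
    clinical component always is; CRP and imaging may be missing).
    """

    clinical_component: bool
    crp_component: Optional[bool]
    imaging_component: Optional[bool]

    @property
    def score(self) -> Optional[int]:
        if self.crp_component is None or self.imaging_component is None:
            return None
        return int(self.clinical_component) + int(self.crp_component) + int(
            self.imaging_component
        )

    def active(self, threshold: int = 2) -> Optional[bool]:
        score = self.score
        return None if score is None else score >= threshold


def classify_subtype(diagnosis_exam: UltrasoundExam, config: AnalysisConfig) -> Subtype:
    """Assign the GCA subtype from involvement at diagnosis.

    Cranial-only involvement -> c-GCA, large-vessel-only -> LV-GCA (the
    vertebral artery counts as a large vessel), both -> mixed-GCA.
    """
    involved = involved_segments(diagnosis_exam, config)
    if not involved:
        raise NotClassifiableError(
            "diagnosis exam has no involved segments; GCA diagnosis in this "
            "cohort requires positive imaging"
        )
    any_cranial = any(s.is_cranial for s in involved)
    any_lv = any(s.is_lv for s in involved)
    if any_cranial and any_lv:
        return Subtype.MIXED_GCA
    return Subtype.C_GCA if any_cranial else Subtype.LV_GCA


def simple_halo_count(exam: UltrasoundExam, config: AnalysisConfig) -> int:
    """1 point per side with an involved temporal branch, per involved facial
    artery, and per involved large-vessel segment. Range 0-14."""
    involved = involved_segments(exam, config)
    temporal_sides = {s.side for s in involved if s.vessel in TEMPORAL_TREE}
    facial = sum(1 for s in involved if s.vessel.value == "facial")
    lv = sum(1 for s in involved if s.is_lv)
    return len(temporal_sides) + facial + lv


def extended_halo_count(exam: UltrasoundExam, config: AnalysisConfig) -> int:
    """1 point per involved cranial branch (facial included) and per involved
    large-vessel segment. Range 0-18."""
    involved = involved_segments(exam, config)
    return len(involved)


def modified_extended_halo_count(exam: UltrasoundExam, config: AnalysisConfig) -> int:
    """Like the extended count but large vessels score 2 points. Range 0-28."""
    involved = involved_segments(exam, config)
    lv = sum(1 for s in involved if s.is_lv)
    return len(involved) + lv


def ultrasound_relapse(
    current: UltrasoundExam, reference: UltrasoundExam, config: AnalysisConfig
) -> UltrasoundStatus:
    """Classify a visit as ultrasound relapse or remission.

    Relapse iff (a) some segment is involved now but was not involved at the
    reference exam, or (b) some non-vertebral large vessel involved at the
    reference exam shows an IMT increase of at least
    ``config.imt_delta_cutoff_mm`` (ties count). "Already involved" is read
    against the reference exam only, not cumulative history. A segment absent
    from the current exam was not assessed and contributes nothing.
    """
    if not current.performed or not reference.performed:
        return NOT_ASSESSED
    cur_involved = involved_segments(current, config)
    ref_involved = involved_segments(reference, config)

    reasons: list[RelapseReason] = []
    for seg in sorted(cur_involved - ref_involved):
        reasons.append(RelapseReason(kind="new_segment", segment=seg))
    for seg in sorted(ref_involved):
        if seg.vessel not in IMT_VESSELS or seg not in current.findings:
            continue
        cur_imt = current.findings[seg].imt_mm
        ref_imt = reference.findings[seg].imt_mm
        if cur_imt is None or ref_imt is None:
            continue
        delta = cur_imt - ref_imt
        if delta >= config.imt_delta_cutoff_mm - IMT_EPS:
            reasons.append(
                RelapseReason(kind="imt_increase", segment=seg, delta_mm=delta)
            )
    if reasons:
        return UltrasoundStatus(status=UsState.RELAPSE, reasons=tuple(reasons))
    return UltrasoundStatus(status=UsState.REMISSION)


def reference_exam_for(visit: Visit, patient: Patient) -> Optional[UltrasoundExam]:
    """The exam of the latest earlier visit that was actually performed.

    Resolves "the previous visit" when exams are sporadically missing: a
    skipped exam is bridged back to the last performed one (the diagnosis
    exam included). None at the diagnosis visit or when no earlier exam was
    performed.
    """
    best: Optional[UltrasoundExam] = None
    for other in patient.visits:
        if other.month >= visit.month:
            break
        if other.exam.performed:
            best = other.exam
    return best


def gcas(
    visit: Visit, ultrasound_status: UltrasoundStatus, config: AnalysisConfig
) -> GcasResult:
    """GCAS components for one visit.

    Missing CRP or an unassessed ultrasound status leaves the corresponding
    component (and hence the score) undefined; nothing is raised.
    """
    crp: Optional[bool]
    if visit.crp_mg_l is None:
        crp = None
    else:
        crp = visit.crp_mg_l > config.crp_threshold_mg_l
    imaging: Optional[bool]
    if ultrasound_status.status is UsState.NOT_ASSESSED:
        imaging = None
    else:
        imaging = ultrasound_status.status is UsState.RELAPSE
    return GcasResult(
        clinical_component=visit.clinical_relapse,
        crp_component=crp,
        imaging_component=imaging,
    )


# ---------------------------------------------------------------------------
# Whole-cohort scoring table
# ---------------------------------------------------------------------------

SCORED_COLUMNS = [
    "patient_id",
    "month",
    "clinical_relapse",
    "crp_mg_l",
    "prednisolone_mg",
    "dmard",
    "subtype",
    "ultrasound_performed",
    "simple_halo_count",
    "extended_halo_count",
    "modified_extended_halo_count",
    "ultrasound_status",
    "gcas_clinical",
    "gcas_crp",
    "gcas_imaging",
    "gcas_score",
    "gcas_active",
]


def _score_visit_row(
    visit: Visit, patient: Patient, subtype: Optional[Subtype], config: AnalysisConfig
) -> dict:
    if visit.exam.performed:
        simple = simple_halo_count(visit.exam, config)
        extended = extended_halo_count(visit.exam, config)
        modified = modified_extended_halo_count(visit.exam, config)
    else:
        simple = extended = modified = None

    # The diagnosis visit has no prior exam; its imaging status is reported
    # as not assessed rather than inventing a baseline-positivity rule.
    if visit.is_diagnosis:
        status = NOT_ASSESSED
    else:
        reference = reference_exam_for(visit, patient)
        if reference is None:
            status = NOT_ASSESSED
        else:
            status = ultrasound_relapse(visit.exam, reference, config)

    result = gcas(visit, status, config)
    return {
        "patient_id": visit.patient_id,
        "month": visit.month,
        "clinical_relapse": visit.clinical_relapse,
        "crp_mg_l": visit.crp_mg_l,
        "prednisolone_mg": visit.prednisolone_mg,
        "dmard": visit.dmard,
        "subtype": subtype.value if subtype is not None else None,
        "ultrasound_performed": visit.exam.performed,
        "simple_halo_count": simple,
        "extended_halo_count": extended,
        "modified_extended_halo_count": modified,
        "ultrasound_status": status.status.value,
        "gcas_clinical": result.clinical_component,
        "gcas_crp": result.crp_component,
        "gcas_imaging": result.imaging_component,
        "gcas_score": result.score,
        "gcas_active": result.active(config.gcas_active_threshold),
    }


def score_cohort(cohort: Cohort, config: AnalysisConfig) -> pd.DataFrame:
    """Score every visit of a cohort; one row per visit.

    Subtype is assigned once per patient from the diagnosis exam and repeated
    on every row; patients whose diagnosis exam was skipped or shows no
    involvement get a null subtype rather than an error (real registries
    contain such records; subtype-stratified analytics simply exclude them).
    """
    rows = []
    for patient in cohort:
        try:
            subtype = classify_subtype(patient.diagnosis_visit.exam, config)
        except (NotClassifiableError, NoExamError):
            subtype = None
        for visit in patient.visits:
            rows.append(_score_visit_row(visit, patient, subtype, config))
    df = pd.DataFrame(rows, columns=SCORED_COLUMNS)
    # Nullable dtypes keep missing scores distinct from zero in CSV output.
    for col in ("simple_halo_count", "extended_halo_count",
                "modified_extended_halo_count", "gcas_score"):
        df[col] = df[col].astype("Int64")
    for col in ("clinical_relapse", "ultrasound_performed", "gcas_clinical",
                "gcas_crp", "gcas_imaging", "gcas_active"):
        df[col] = df[col].astype("boolean")
    return df


def write_scored_visits(df: pd.DataFrame, path) -> None:
    """Write a scored-visit table as CSV with blanks for undefined values."""
    out = df.copy()
    for col in out.columns:
        if str(out[col].dtype) == "boolean":
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else int(x))
    out.to_csv(path, index=False)


def read_scored_visits(path) -> pd.DataFrame:
    """Read a scored-visit CSV back into the dtypes score_cohort emits."""
    df = pd.read_csv(path, dtype={"patient_id": str, "dmard": str})
    for col in ("simple_halo_count", "extended_halo_count",
                "modified_extended_halo_count", "gcas_score"):
        df[col] = df[col].astype("Int64")
    for col in ("clinical_relapse", "ultrasound_performed", "gcas_clinical",
                "gcas_crp", "gcas_imaging", "gcas_active"):
        df[col] = df[col].map(
            lambda x: pd.NA if pd.isna(x) else bool(int(x))
        ).astype("boolean")
    return df
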