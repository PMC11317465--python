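import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from gcas_kit import (
    ALL_SEGMENTS,
    AnalysisConfig,
    SegmentFinding,
    SegmentID,
    Side,
    UltrasoundExam,
    Vessel,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # the shared AnalysisConfig fixture is read-only inside @given tests
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def seg(vessel: str, side: str = "left") -> SegmentID:
    return SegmentID(Vessel(vessel), Side(side))


def build_exam(halos=None, imts=None) -> UltrasoundExam:
    """Exam with only the given segments assessed."""
    findings = []
    for s, h in (halos or {}).items():
        findings.append(SegmentFinding(segment=s, halo=h))
    for s, v in (imts or {}).items():
        findings.append(SegmentFinding(segment=s, imt_mm=v))
    return UltrasoundExam.from_findings(findings)


def full_exam(involved=(), imt_involved=1.3, imt_normal=0.7,
              imt_overrides=None) -> UltrasoundExam:
    """Exam assessing all 18 segments, involvement per the given set."""
    involved = set(involved)
    overrides = imt_overrides or {}
    findings = []
    for s in ALL_SEGMENTS:
        if s.carries_halo:
            findings.append(SegmentFinding(segment=s, halo=s in involved))
        else:
            value = overrides.get(s, imt_involved if s in involved else imt_normal)
            findings.append(SegmentFinding(segment=s, imt_mm=value))
    return UltrasoundExam.from_findings(findings)


def random_exam_strategy():
    """Hypothesis strategy over partial exams with plausible findings."""

    @st.composite
    def _exam(draw):
        findings = []
        for s in ALL_SEGMENTS:
            if not draw(st.booleans()):
                continue  # segment not assessed
            if s.carries_halo:
                findings.append(SegmentFinding(segment=s, halo=draw(st.booleans())))
            else:
                value = draw(
                    st.floats(min_value=0.3, max_value=3.0,
                              allow_nan=False, allow_infinity=False)
                )
                findings.append(SegmentFinding(segment=s, imt_mm=value))
        return UltrasoundExam.from_findings(findings)

    return _exam()
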