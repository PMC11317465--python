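"""Diagnostic-accuracy analytics for visit-level index tests.

Every analysis here compares an index test (ultrasound relapse, elevated
CRP, their AND/OR combinations, or the GCAS composite) against the
clinician's relapse call — the gold standard — across follow-up visits.
Visits lacking the data an index test needs are excluded from that test's
table, so each result carries its own denominator; the diagnosis visit is
always excluded (relapse presupposes a prior remission period).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import AnalysisConfig, Cohort
from .errors import EmptyTableError, UndefinedStatisticError
from .scoring import score_cohort

INDEX_TESTS = ("ultrasound", "crp", "crp_and_ultrasound", "crp_or_ultrasound", "gcas")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as clinical tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """A percentage printed to ``ndigits`` decimals, ties rounding up."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class ConfusionTable:
    """Visit-level 2x2 of an index test against clinical relapse."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_relapse(self) -> int:
        return self.tp + self.fn

    @property
    def n_remission(self) -> int:
        return self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class AccuracyResult:
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    phi: Optional[float] = None
    chi_square: Optional[float] = None
    p_value: Optional[float] = None
    n_visits: int = 0


def sensitivity_specificity(table: ConfusionTable) -> AccuracyResult:
    """Sensitivity tp/(tp+fn) and specificity tn/(fp+tn) as exact ratios."""
    if table.n_relapse == 0 or table.n_remission == 0:
        raise UndefinedStatisticError(
            "sensitivity/specificity undefined on an empty relapse or "
            "remission margin"
        )
    return AccuracyResult(
        sensitivity=table.tp / table.n_relapse,
        specificity=table.tn / table.n_remission,
        n_visits=table.n,
    )


def phi_coefficient(table: ConfusionTable) -> float:
    """Pearson correlation of two binary variables on a 2x2 table."""
    margins = (
        table.tp + table.fn,
        table.fp + table.tn,
        table.tp + table.fp,
        table.fn + table.tn,
    )
    if any(m == 0 for m in margins):
        raise UndefinedStatisticError("phi undefined with a zero margin")
    num = table.tp * table.tn - table.fn * table.fp
    return num / math.sqrt(math.prod(margins))


def chi_square_independence(
    counts: Sequence[Sequence[int]] | np.ndarray, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square of independence on an r x c contingency table.

    Yates' continuity correction is applied only on request (and only
    affects 2x2 tables). Returns ``(statistic, p_value)``.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.size == 0 or arr.sum() <= 0:
        raise UndefinedStatisticError("chi-square needs a non-empty 2-d table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise UndefinedStatisticError("chi-square undefined with a zero margin")
    result = stats.chi2_contingency(arr, correction=yates)
    return float(result.statistic), float(result.pvalue)


def evaluate_table(table: ConfusionTable, yates: bool = False) -> AccuracyResult:
    """Sensitivity, specificity, phi and chi-square for one 2x2 table."""
    base = sensitivity_specificity(table)
    phi = phi_coefficient(table)
    chi2, p = chi_square_independence(table.as_array(), yates=yates)
    return replace(base, phi=phi, chi_square=chi2, p_value=p)


# ---------------------------------------------------------------------------
# Building tables from scored visits
# ---------------------------------------------------------------------------


def _eligibility_and_positivity(
    df: pd.DataFrame, index_test: str, config: AnalysisConfig
) -> tuple[pd.Series, pd.Series]:
    assessed = df["ultrasound_status"].isin(["relapse", "remission"])
    has_crp = df["crp_mg_l"].notna()
    us_pos = df["ultrasound_status"].eq("relapse")
    crp_pos = df["gcas_crp"].fillna(False).astype(bool)

    # CRP, combination and GCAS tests all use the visit set with BOTH a CRP
    # value and an assessed ultrasound status, mirroring the mixed
    # denominators of the source analyses (720- vs 615-visit analogues).
    both = assessed & has_crp
    if index_test == "ultrasound":
        return assessed, us_pos
    if index_test == "crp":
        return both, crp_pos
    if index_test == "crp_and_ultrasound":
        return both, crp_pos & us_pos
    if index_test == "crp_or_ultrasound":
        return both, crp_pos | us_pos
    if index_test == "gcas":
        return both, df["gcas_active"].fillna(False).astype(bool)
    raise ValueError(f"unknown index test {index_test!r}; one of {INDEX_TESTS}")


def build_confusion(
    scored_visits: pd.DataFrame, index_test: str, config: AnalysisConfig
) -> tuple[ConfusionTable, int]:
    """2x2 of one index test against clinical relapse over follow-up visits.

    Returns the table and the number of follow-up visits excluded because
    the index test's inputs were missing there.
    """
    followup = scored_visits[scored_visits["month"] > 0]
    eligible, positive = _eligibility_and_positivity(followup, index_test, config)
    n_excluded = int((~eligible).sum())
    sub = followup[eligible]
    if sub.empty:
        raise EmptyTableError(
            f"no eligible follow-up visits for index test {index_test!r}"
        )
    truth = sub["clinical_relapse"].astype(bool)
    pos = positive[eligible].astype(bool)
    table = ConfusionTable(
        tp=int((truth & pos).sum()),
        fn=int((truth & ~pos).sum()),
        fp=int((~truth & pos).sum()),
        tn=int((~truth & ~pos).sum()),
    )
    return table, n_excluded


def cutoff_sweep(
    cohort: Cohort, cutoffs: Sequence[float], config: AnalysisConfig
) -> pd.DataFrame:
    """Rescore ultrasound status at each IMT-delta cutoff and re-evaluate.

    Raising the cutoff can only remove IMT-increase triggers (new-segment
    triggers are cutoff-independent), so sensitivity is non-increasing and
    specificity non-decreasing in the cutoff. Undefined statistics (an empty
    relapse margin in a tiny cohort) are reported as NaN.
    """
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be sorted strictly ascending")
    rows = []
    for cutoff in cutoffs:
        cfg = dataclasses.replace(
            config,
            imt_delta_cutoff_mm=float(cutoff),
            lv_involvement_cutoff_mm=dict(config.lv_involvement_cutoff_mm),
        )
        scored = score_cohort(cohort, cfg)
        table, _ = build_confusion(scored, "ultrasound", cfg)
        try:
            acc = sensitivity_specificity(table)
            sens, spec = acc.sensitivity, acc.specificity
        except UndefinedStatisticError:
            sens = spec = float("nan")
        try:
            phi = phi_coefficient(table)
        except UndefinedStatisticError:
            phi = float("nan")
        rows.append(
            {
                "cutoff_mm": float(cutoff),
                "n_visits": table.n,
                "tp": table.tp,
                "fn": table.fn,
                "fp": table.fp,
                "tn": table.tn,
                "sensitivity": sens,
                "specificity": spec,
                "phi": phi,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GcasCrossTable:
    """Clinical relapse x GCAS-active cross-table with margins.

    The two discordance percentages are the clinically interesting corners:
    relapse visits the composite missed (score below threshold) as a
    fraction of relapse visits, and remission visits the composite flagged
    as a fraction of remission visits.
    """

    relapse_active: int
    relapse_inactive: int
    remission_active: int
    remission_inactive: int

    @property
    def n_relapse(self) -> int:
        return self.relapse_active + self.relapse_inactive

    @property
    def n_remission(self) -> int:
        return self.remission_active + self.remission_inactive

    @property
    def n_active(self) -> int:
        return self.relapse_active + self.remission_active

    @property
    def n_inactive(self) -> int:
        return self.relapse_inactive + self.remission_inactive

    @property
    def n(self) -> int:
        return self.n_relapse + self.n_remission

    @property
    def discordant_relapse_pct(self) -> float:
        """% of clinical-relapse visits with GCAS below threshold."""
        return percent(self.relapse_inactive, self.n_relapse)

    @property
    def discordant_remission_pct(self) -> float:
        """% of clinical-remission visits with GCAS at/above threshold."""
        return percent(self.remission_active, self.n_remission)

    def to_dict(self) -> dict:
        return {
            "relapse_active": self.relapse_active,
            "relapse_inactive": self.relapse_inactive,
            "remission_active": self.remission_active,
            "remission_inactive": self.remission_inactive,
            "n_relapse": self.n_relapse,
            "n_remission": self.n_remission,
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n": self.n,
            "discordant_relapse_pct": self.discordant_relapse_pct,
            "discordant_remission_pct": self.discordant_remission_pct,
        }


def gcas_cross_table(
    scored_visits: pd.DataFrame, config: AnalysisConfig
) -> GcasCrossTable:
    """Cross-tabulate clinical relapse against GCAS activity.

    Only follow-up visits with a computable score (CRP present and an
    assessed ultrasound status) enter.
    """
    followup = scored_visits[scored_visits["month"] > 0]
    sub = followup[followup["gcas_score"].notna()]
    if sub.empty:
        raise EmptyTableError("no follow-up visits with a computable GCAS")
    truth = sub["clinical_relapse"].astype(bool)
    active = sub["gcas_active"].astype(bool)
    return GcasCrossTable(
        relapse_active=int((truth & active).sum()),
        relapse_inactive=int((truth & ~active).sum()),
        remission_active=int((~truth & active).sum()),
        remission_inactive=int((~truth & ~active).sum()),
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def _median_iqr(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return float(med), float(q3 - q1)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_relapsed: int
    relapse_rate: float
    relapse_rate_by_subtype: dict[str, float]
    n_by_subtype: dict[str, int]
    median_followup_months: float
    iqr_followup_months: float
    median_followup_by_relapse: dict[str, float]
    iqr_followup_by_relapse: dict[str, float]
    dmard_proportion: float
    n_followup_visits: int
    n_visits_with_ultrasound: int
    n_visits_with_crp: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cohort_summary(cohort: Cohort, scored_visits: pd.DataFrame) -> CohortSummary:
    """Patient-level characteristics of a cohort.

    A patient counts as relapsed if any follow-up visit carries a clinical
    relapse; patients with no follow-up visits (drop-outs after diagnosis)
    are excluded from relapse-rate denominators. Medians and IQRs use linear
    interpolation between order statistics.
    """
    if len(cohort) == 0:
        raise ValueError("cohort_summary requires at least one patient")

    subtype_by_patient = (
        scored_visits.groupby("patient_id")["subtype"].first().to_dict()
    )

    followed = [p for p in cohort if p.followup_visits]
    relapsed = {
        p.patient_id
        for p in followed
        if any(v.clinical_relapse for v in p.followup_visits)
    }
    followup_months = {p.patient_id: p.visits[-1].month for p in followed}

    n_by_subtype: dict[str, int] = {}
    relapsed_by_subtype: dict[str, int] = {}
    for p in followed:
        subtype = subtype_by_patient.get(p.patient_id)
        if subtype is None or pd.isna(subtype):
            continue
        n_by_subtype[subtype] = n_by_subtype.get(subtype, 0) + 1
        if p.patient_id in relapsed:
            relapsed_by_subtype[subtype] = relapsed_by_subtype.get(subtype, 0) + 1
    relapse_rate_by_subtype = {
        st: relapsed_by_subtype.get(st, 0) / n for st, n in sorted(n_by_subtype.items())
    }

    med_all, iqr_all = _median_iqr(list(followup_months.values()))
    med_rel, iqr_rel = _median_iqr(
        [m for pid, m in followup_months.items() if pid in relapsed]
    )
    med_rem, iqr_rem = _median_iqr(
        [m for pid, m in followup_months.items() if pid not in relapsed]
    )

    dmard_users = sum(
        1 for p in followed if any(v.dmard is not None for v in p.visits)
    )

    followup = scored_visits[scored_visits["month"] > 0]
    return CohortSummary(
        n_patients=len(followed),
        n_relapsed=len(relapsed),
        relapse_rate=len(relapsed) / len(followed) if followed else float("nan"),
        relapse_rate_by_subtype=relapse_rate_by_subtype,
        n_by_subtype=dict(sorted(n_by_subtype.items())),
        median_followup_months=med_all,
        iqr_followup_months=iqr_all,
        median_followup_by_relapse={"relapse": med_rel, "no_relapse": med_rem},
        iqr_followup_by_relapse={"relapse": iqr_rel, "no_relapse": iqr_rem},
        dmard_proportion=dmard_users / len(followed) if followed else float("nan"),
        n_followup_visits=int(len(followup)),
        n_visits_with_ultrasound=int(followup["ultrasound_performed"].sum()),
        n_visits_with_crp=int(followup["crp_mg_l"].notna().sum()),
    )
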