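"""Confusion tables, accuracy statistics, sweeps, and the cohort summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcas_kit import (
    Cohort,
    ConfusionTable,
    EmptyTableError,
    Patient,
    UltrasoundExam,
    UndefinedStatisticError,
    Visit,
    build_confusion,
    chi_square_independence,
    cohort_summary,
    cutoff_sweep,
    default_params,
    gcas_cross_table,
    generate_cohort,
    percent,
    phi_coefficient,
    round_half_up,
    score_cohort,
    sensitivity_specificity,
)
from gcas_kit.accuracy import GcasCrossTable


def scored_frame(rows):
    """Minimal scored-visit frame from (month, clinical, us-status, crp)."""
    records = []
    for month, clinical, us, crp in rows:
        crp_pos = None if crp is None else crp > 5.0
        imaging = None if us == "not_assessed" else (us == "relapse")
        score = (
            None
            if crp_pos is None or imaging is None
            else int(clinical) + int(crp_pos) + int(imaging)
        )
        records.append(
            {
                "month": month,
                "clinical_relapse": clinical,
                "ultrasound_status": us,
                "crp_mg_l": crp,
                "gcas_crp": crp_pos,
                "gcas_imaging": imaging,
                "gcas_score": score,
                "gcas_active": None if score is None else score >= 2,
            }
        )
    df = pd.DataFrame(records)
    df["gcas_score"] = df["gcas_score"].astype("Int64")
    for col in ("clinical_relapse", "gcas_crp", "gcas_imaging", "gcas_active"):
        df[col] = df[col].astype("boolean")
    return df


class TestBuildConfusion:
    def test_one_visit_per_cell(self, config):
        df = scored_frame(
            [
                (3, True, "relapse", 8.0),
                (6, True, "remission", 8.0),
                (9, False, "relapse", 8.0),
                (12, False, "remission", 8.0),
            ]
        )
        table, excluded = build_confusion(df, "ultrasound", config)
        assert (table.tp, table.fn, table.fp, table.tn) == (1, 1, 1, 1)
        assert excluded == 0

    def test_diagnosis_visit_always_excluded(self, config):
        df = scored_frame(
            [(0, False, "not_assessed", 30.0), (3, True, "relapse", 8.0)]
        )
        table, _ = build_confusion(df, "ultrasound", config)
        assert table.n == 1

    def test_missingness_policy_per_index_test(self, config):
        df = scored_frame(
            [
                (3, True, "relapse", None),  # CRP missing: ultrasound only
                (6, False, "not_assessed", 8.0),  # US missing: excluded everywhere
                (9, False, "remission", 3.0),  # complete
            ]
        )
        us_table, us_excluded = build_confusion(df, "ultrasound", config)
        assert us_table.n == 2 and us_excluded == 1
        crp_table, crp_excluded = build_confusion(df, "crp", config)
        assert crp_table.n == 1 and crp_excluded == 2
        gcas_table, _ = build_confusion(df, "gcas", config)
        assert gcas_table.n == 1

    def test_empty_table_is_an_error(self, config):
        df = scored_frame([(3, True, "not_assessed", None)])
        with pytest.raises(EmptyTableError):
            build_confusion(df, "crp", config)

    def test_combination_bounds(self, config):
        """AND positives never exceed either component; OR never fall below."""
        rng = np.random.default_rng(3)
        rows = [
            (float(m + 1), bool(rng.random() < 0.3),
             "relapse" if rng.random() < 0.4 else "remission",
             float(rng.lognormal(1.5, 1.0)))
            for m in range(120)
        ]
        df = scored_frame(rows)
        tables = {
            t: build_confusion(df, t, config)[0]
            for t in ("crp", "ultrasound", "crp_and_ultrasound", "crp_or_ultrasound")
        }
        # restrict components to the shared denominator for comparability
        assert tables["crp_and_ultrasound"].tp <= min(
            tables["crp"].tp, tables["crp_or_ultrasound"].tp
        )
        assert tables["crp_or_ultrasound"].tp >= max(
            tables["crp"].tp, tables["crp_and_ultrasound"].tp
        )
        sens = {
            t: sensitivity_specificity(tab).sensitivity for t, tab in tables.items()
        }
        spec = {
            t: sensitivity_specificity(tab).specificity for t, tab in tables.items()
        }
        assert sens["crp_or_ultrasound"] >= max(sens["crp"], sens["ultrasound"])
        assert spec["crp_and_ultrasound"] >= max(spec["crp"], spec["ultrasound"])


class TestStatistics:
    @pytest.mark.parametrize(
        "cells,sens,spec",
        [
            ((85, 54, 161, 420), 61.2, 72.3),
            ((92, 38, 189, 296), 70.8, 61.0),
            ((10, 0, 0, 10), 100.0, 100.0),
        ],
    )
    def test_sensitivity_specificity_printed_to_one_decimal(self, cells, sens, spec):
        table = ConfusionTable(*cells)
        result = sensitivity_specificity(table)
        assert percent(result.sensitivity * table.n_relapse, table.n_relapse) == sens
        assert round_half_up(100 * result.specificity) == spec

    def test_empty_margin_is_undefined_not_zero(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity_specificity(ConfusionTable(0, 0, 5, 5))

    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((85, 54, 161, 420), 0.28),
            ((10, 0, 0, 10), 1.0),
            ((5, 5, 5, 5), 0.0),
        ],
    )
    def test_phi_examples(self, cells, expected):
        assert round_half_up(phi_coefficient(ConfusionTable(*cells)), 2) == expected

    def test_phi_zero_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(ConfusionTable(5, 5, 0, 0))

    def test_identical_row_distributions_give_zero_statistic(self):
        stat, p = chi_square_independence([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_yates_correction_shrinks_the_statistic(self):
        plain, _ = chi_square_independence([[12, 5], [6, 14]], yates=False)
        corrected, _ = chi_square_independence([[12, 5], [6, 14]], yates=True)
        assert corrected < plain

    @given(
        cells=st.tuples(*(st.integers(min_value=1, max_value=500) for _ in range(4)))
    )
    def test_phi_squared_times_n_is_chi_square(self, cells):
        table = ConfusionTable(*cells)
        phi = phi_coefficient(table)
        stat, _ = chi_square_independence(table.as_array(), yates=False)
        assert phi * phi * table.n == pytest.approx(stat, abs=1e-9)

    def test_round_half_up_ties_away_from_zero(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(60.55, 1) == 60.6


class TestCutoffSweep:
    def test_single_cutoff_matches_direct_evaluation(self, config):
        cohort = generate_cohort(default_params(seed=21, n_patients=15))
        scored = score_cohort(cohort, config)
        direct, _ = build_confusion(scored, "ultrasound", config)
        sweep = cutoff_sweep(cohort, [config.imt_delta_cutoff_mm], config)
        row = sweep.iloc[0]
        assert (row.tp, row.fn, row.fp, row.tn) == (
            direct.tp, direct.fn, direct.fp, direct.tn
        )

    def test_all_imt_deltas_between_cutoffs_vanish(self, config):
        """A cohort whose only changes are 0.25 mm IMT rises is positive at
        0.2 and fully negative at 0.3."""
        from conftest import full_exam, seg

        target = seg("axillary_distal")
        visits = (
            Visit(patient_id="P1", month=0.0, clinical_relapse=False,
                  exam=full_exam(involved={target}, imt_overrides={target: 1.3})),
            Visit(patient_id="P1", month=3.0, clinical_relapse=True,
                  exam=full_exam(involved={target}, imt_overrides={target: 1.55})),
        )
        cohort = Cohort(patients=(Patient(patient_id="P1", visits=visits),))
        sweep = cutoff_sweep(cohort, [0.2, 0.3], config)
        assert sweep.iloc[0].tp == 1
        assert sweep.iloc[1].tp == 0

    def test_unsorted_cutoffs_rejected(self, config):
        cohort = generate_cohort(default_params(seed=4, n_patients=3))
        with pytest.raises(ValueError):
            cutoff_sweep(cohort, [0.3, 0.2], config)


class TestGcasCrossTable:
    def test_discordance_percentages(self):
        table = GcasCrossTable(
            relapse_active=120, relapse_inactive=10,
            remission_active=50, remission_inactive=435,
        )
        assert table.n == 615
        assert table.discordant_relapse_pct == 7.7
        assert table.discordant_remission_pct == 10.3

    def test_concordant_data_has_empty_off_diagonal(self, config):
        from test_accuracy import scored_frame  # self-import for clarity

        df = scored_frame(
            [(3, True, "relapse", 20.0), (6, False, "remission", 2.0)] * 3
        )
        cross = gcas_cross_table(df, config)
        assert cross.relapse_inactive == 0
        assert cross.remission_active == 0

    def test_matches_confusion_table_counts(self, config):
        cohort = generate_cohort(default_params(seed=31, n_patients=25))
        scored = score_cohort(cohort, config)
        cross = gcas_cross_table(scored, config)
        table, _ = build_confusion(scored, "gcas", config)
        assert (cross.relapse_active, cross.relapse_inactive) == (table.tp, table.fn)
        assert (cross.remission_active, cross.remission_inactive) == (
            table.fp, table.tn
        )


def single_patient(months_relapse):
    exam = UltrasoundExam.not_performed
    from conftest import full_exam, seg

    visits = [
        Visit(patient_id="P1", month=0.0, clinical_relapse=False,
              exam=full_exam(involved={seg("facial")}))
    ]
    for month, relapse in months_relapse:
        visits.append(
            Visit(patient_id="P1", month=month, clinical_relapse=relapse,
                  exam=full_exam(involved={seg("facial")}))
        )
    return Patient(patient_id="P1", visits=tuple(visits))


class TestCohortSummary:
    def test_single_relapsing_patient(self, config):
        cohort = Cohort(patients=(single_patient([(6.0, True)]),))
        summary = cohort_summary(cohort, score_cohort(cohort, config))
        assert summary.relapse_rate == 1.0
        assert summary.n_patients == 1
        assert summary.median_followup_months == 6.0

    def test_patient_without_followup_excluded_from_denominator(self, config):
        from conftest import full_exam, seg

        dropout = Patient(
            patient_id="P2",
            visits=(
                Visit(patient_id="P2", month=0.0, clinical_relapse=False,
                      exam=full_exam(involved={seg("carotid")}, imt_involved=1.4)),
            ),
        )
        cohort = Cohort(patients=(single_patient([(6.0, False)]), dropout))
        summary = cohort_summary(cohort, score_cohort(cohort, config))
        assert summary.n_patients == 1
        assert summary.relapse_rate == 0.0

    def test_subtype_counts_sum_to_total(self, config):
        cohort = generate_cohort(default_params(seed=17, n_patients=60))
        summary = cohort_summary(cohort, score_cohort(cohort, config))
        assert sum(summary.n_by_subtype.values()) == summary.n_patients
        for rate in summary.relapse_rate_by_subtype.values():
            assert 0.0 <= rate <= 1.0

    def test_subtype_mixture_recovered_at_scale(self, config):
        """Monte Carlo: empirical subtype proportions track the generator's
        mixture within 3 binomial SE."""
        n = 1000
        cohort = generate_cohort(default_params(seed=99, n_patients=n))
        summary = cohort_summary(cohort, score_cohort(cohort, config))
        probs = {"c_gca": 0.311, "lv_gca": 0.152, "mixed_gca": 0.538}
        total = sum(probs.values())
        for subtype, p in probs.items():
            p = p / total
            se = (p * (1 - p) / n) ** 0.5
            observed = summary.n_by_subtype[subtype] / summary.n_patients
            assert abs(observed - p) <= 3 * se
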