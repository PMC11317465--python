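"""Brute-force recount of confusion tables straight from the raw CSVs.

Deliberately independent of gcas_kit: plain csv + dict code re-derives
involvement, ultrasound status, CRP positivity and GCAS per visit, then
recounts each index test's 2x2 against the clinical relapse flag. Used as
the oracle that the pipeline's tables must equal on small cohorts.
"""

import csv

CRANIAL = {"temporal_common", "temporal_frontal", "temporal_parietal", "facial"}
HALO = CRANIAL | {"vertebral"}
IMT = {"carotid", "subclavian", "axillary_proximal", "axillary_distal"}
EPS = 1e-9


def _read_rows(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def brute_force_tables(
    visits_csv,
    vessels_csv,
    imt_delta=0.2,
    crp_threshold=5.0,
    lv_cutoff=1.0,
    gcas_threshold=2,
):
    """Return {index_test: (tp, fn, fp, tn)} recounted from the raw files."""
    vessel_rows = {}
    for row in _read_rows(vessels_csv):
        key = (row["patient_id"], float(row["month"]))
        vessel_rows.setdefault(key, []).append(row)

    visits_by_patient = {}
    for row in _read_rows(visits_csv):
        visits_by_patient.setdefault(row["patient_id"], []).append(row)

    def involvement(pid, month):
        involved = {}
        for row in vessel_rows.get((pid, month), []):
            segment = (row["vessel"], row["side"])
            if row["vessel"] in HALO:
                involved[segment] = (row["halo"] == "1", None)
            else:
                value = float(row["imt_mm"])
                involved[segment] = (value >= lv_cutoff - EPS, value)
        return involved

    counts = {
        t: [0, 0, 0, 0]
        for t in ("ultrasound", "crp", "crp_and_ultrasound",
                  "crp_or_ultrasound", "gcas")
    }
    for pid, rows in visits_by_patient.items():
        rows = sorted(rows, key=lambda r: float(r["month"]))
        for i, row in enumerate(rows):
            month = float(row["month"])
            if month == 0:
                continue
            clinical = row["clinical_relapse"] == "1"

            us_state = None  # None = not assessed
            if row["ultrasound_performed"] == "1":
                ref_month = None
                for prev in rows[:i]:
                    if prev["ultrasound_performed"] == "1":
                        ref_month = float(prev["month"])
                if ref_month is not None:
                    cur = involvement(pid, month)
                    ref = involvement(pid, ref_month)
                    relapse = False
                    for segment, (inv, value) in cur.items():
                        ref_inv = ref.get(segment, (False, None))[0]
                        if inv and not ref_inv:
                            relapse = True
                    for segment, (inv, ref_value) in ref.items():
                        if not inv or segment[0] not in IMT:
                            continue
                        cur_value = cur.get(segment, (False, None))[1]
                        if cur_value is not None and (
                            cur_value - ref_value >= imt_delta - EPS
                        ):
                            relapse = True
                    us_state = relapse

            crp_state = None
            if row["crp_mg_l"] != "":
                crp_state = float(row["crp_mg_l"]) > crp_threshold

            def tally(test, positive):
                idx = (0 if positive else 1) if clinical else (2 if positive else 3)
                counts[test][idx] += 1

            if us_state is not None:
                tally("ultrasound", us_state)
            if us_state is not None and crp_state is not None:
                tally("crp", crp_state)
                tally("crp_and_ultrasound", crp_state and us_state)
                tally("crp_or_ultrasound", crp_state or us_state)
                score = int(clinical) + int(crp_state) + int(us_state)
                tally("gcas", score >= gcas_threshold)
    return {t: tuple(v) for t, v in counts.items()}
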