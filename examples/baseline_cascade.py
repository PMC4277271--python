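"""The three routes to a baseline creatinine.

When the admission creatinine is normal it (or a lower pre-admission value)
serves as baseline; when it is elevated, a pre-admission value is preferred,
and failing that a baseline is imputed by inverting the MDRD equation at a
presumed GFR of 75 ml/min/1.73 m².
"""

from cardiorenal import (
    CreatinineMeasurement,
    PatientRecord,
    backcalc_baseline,
    estimate_baseline,
    mdrd_egfr,
)


def patient(scr_pairs, sex="male", age=60.0):
    return PatientRecord(
        patient_id="x",
        age_years=age,
        sex=sex,
        measurements=[CreatinineMeasurement(t, v) for t, v in scr_pairs],
        outcome_time_hours=240.0,
    )


cases = {
    "normal admission, lower prior": patient([(-200.0, 80.0), (0.0, 90.0)]),
    "normal admission, no prior": patient([(0.0, 90.0)]),
    "elevated admission, prior available": patient([(-300.0, 150.0), (0.0, 210.0)]),
    "elevated admission, no prior": patient([(0.0, 210.0)]),
}

for label, p in cases.items():
    est = estimate_baseline(p)
    print(f"{label:38s} -> {est.value_umol:6.1f} µmol/L via {est.source}")

# the imputed value is exactly the creatinine whose MDRD eGFR is 75:
b = backcalc_baseline(60.0, "male")
print(f"\nback-calculated baseline (male, 60 y): {b:.1f} µmol/L")
print(f"check: MDRD eGFR at that creatinine  = {mdrd_egfr(b, 60.0, 'male'):.6f}")
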