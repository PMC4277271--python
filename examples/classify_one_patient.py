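"""Classify a single creatinine trajectory under RIFLE, AKIN and KDIGO.

The patient below rises by 28 µmol/L inside 36 hours but never reaches
1.5x baseline: AKIN and KDIGO detect the episode (via the absolute 48-h
clause), RIFLE misses it — the archetypal K(+)R(-) patient.
"""

from cardiorenal import (
    CreatinineMeasurement,
    PatientRecord,
    classify_patient,
    estimate_baseline,
)

patient = PatientRecord(
    patient_id="example",
    age_years=67.0,
    sex="male",
    measurements=[
        CreatinineMeasurement(0.0, 100.0),   # admission
        CreatinineMeasurement(36.0, 128.0),  # +28 µmol/L in 36 h
        CreatinineMeasurement(72.0, 120.0),
    ],
    outcome_time_hours=240.0,
)

baseline = estimate_baseline(patient)
print(f"baseline: {baseline.value_umol:.1f} µmol/L (source: {baseline.source})")

row = classify_patient(patient, baseline)
for name, cls in (("RIFLE", row.rifle), ("AKIN", row.akin), ("KDIGO", row.kdigo)):
    if cls.detected:
        print(
            f"{name:5s}: AKI stage {cls.stage}, onset {cls.onset_hours:.0f} h, "
            f"trigger {cls.trigger}"
        )
    else:
        print(f"{name:5s}: no AKI")
# A detected episode means that criterion's creatinine clause fired within
# the first 7 days; the stage reflects the peak-to-baseline ratio.
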