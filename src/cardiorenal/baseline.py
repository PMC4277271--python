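"""Baseline serum-creatinine estimation.

Relative AKI criteria need a reference ("baseline") creatinine. For an acute
admission this is rarely observed directly, so it is estimated by a cascade:

1. If the admission creatinine is within the sex-specific normal range, the
   baseline is the lowest of the admission value and any pre-admission value
   from the previous 90 days.
2. If the admission value is elevated but a pre-admission value exists, the
   lowest pre-admission value is used.
3. If the admission value is elevated and no prior value exists, a baseline
   is imputed by inverting the 4-variable MDRD equation at a presumed
   "standard" GFR of 75 ml/min/1.73 m² — such patients are AKI by
   construction whenever their admission value exceeds the imputed baseline
   by the criteria's margins.

The MDRD form used is the IDMS-traceable re-expression,
``eGFR = 175 × SCr[mg/dL]^-1.154 × age^-0.203 × (0.742 if female)``,
with the race factor fixed at 1. The coefficient and the normal-range upper
limits are configurable because laboratories differ.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import MGDL_TO_UMOL, PRIOR_LOOKBACK_HOURS, PatientRecord

__all__ = [
    "MDRD_COEFFICIENT",
    "MDRD_SCR_EXPONENT",
    "MDRD_AGE_EXPONENT",
    "MDRD_FEMALE_FACTOR",
    "PRESUMED_GFR",
    "NormalRange",
    "BaselineEstimate",
    "umol_from_mgdl",
    "mgdl_from_umol",
    "mdrd_egfr",
    "backcalc_baseline",
    "estimate_baseline",
]

MDRD_COEFFICIENT = 175.0
MDRD_SCR_EXPONENT = -1.154
MDRD_AGE_EXPONENT = -0.203
MDRD_FEMALE_FACTOR = 0.742

#: Presumed GFR (ml/min/1.73 m²) for back-calculated baselines.
PRESUMED_GFR = 75.0


def umol_from_mgdl(x: float) -> float:
    """Convert creatinine from mg/dL to µmol/L (factor 88.4)."""
    if x < 0:
        raise ValueError(f"creatinine cannot be negative, got {x}")
    return x * MGDL_TO_UMOL


def mgdl_from_umol(x: float) -> float:
    """Convert creatinine from µmol/L to mg/dL (factor 1/88.4)."""
    if x < 0:
        raise ValueError(f"creatinine cannot be negative, got {x}")
    return x / MGDL_TO_UMOL


def _sex_factor(sex: str) -> float:
    if sex == "male":
        return 1.0
    if sex == "female":
        return MDRD_FEMALE_FACTOR
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def mdrd_egfr(
    scr_umol: float,
    age_years: float,
    sex: str,
    coefficient: float = MDRD_COEFFICIENT,
) -> float:
    """Estimated GFR (ml/min/1.73 m²) by the 4-variable MDRD equation.

    Strictly decreasing in both creatinine and age; the race factor is 1.
    """
    if scr_umol <= 0:
        raise ValueError(f"scr_umol must be positive, got {scr_umol}")
    if age_years < 18:
        raise ValueError(f"age_years must be >= 18, got {age_years}")
    scr_mgdl = mgdl_from_umol(scr_umol)
    return (
        coefficient
        * scr_mgdl**MDRD_SCR_EXPONENT
        * age_years**MDRD_AGE_EXPONENT
        * _sex_factor(sex)
    )


def backcalc_baseline(
    age_years: float,
    sex: str,
    presumed_gfr: float = PRESUMED_GFR,
    coefficient: float = MDRD_COEFFICIENT,
) -> float:
    """Creatinine (µmol/L) whose MDRD eGFR equals ``presumed_gfr``.

    Closed-form inversion of :func:`mdrd_egfr`:
    ``SCr[mg/dL] = (coef × age^-0.203 × sex_factor / GFR)^(1/1.154)``.
    """
    if age_years < 18:
        raise ValueError(f"age_years must be >= 18, got {age_years}")
    if presumed_gfr <= 0:
        raise ValueError(f"presumed_gfr must be positive, got {presumed_gfr}")
    scr_mgdl = (
        coefficient * age_years**MDRD_AGE_EXPONENT * _sex_factor(sex) / presumed_gfr
    ) ** (1.0 / -MDRD_SCR_EXPONENT)
    return umol_from_mgdl(scr_mgdl)


@dataclass(frozen=True)
class NormalRange:
    """Sex-specific upper limits of the laboratory normal range (µmol/L)."""

    upper_male_umol: float = 104.0
    upper_female_umol: float = 84.0

    def upper(self, sex: str) -> float:
        if sex == "male":
            return self.upper_male_umol
        if sex == "female":
            return self.upper_female_umol
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


@dataclass(frozen=True)
class BaselineEstimate:
    """Estimated baseline creatinine and which cascade rule produced it."""

    value_umol: float
    source: str  # "admission" | "prior_minimum" | "mdrd_backcalc"

    def __post_init__(self) -> None:
        if self.value_umol <= 0:
            raise ValueError("baseline must be positive")
        if self.source not in ("admission", "prior_minimum", "mdrd_backcalc"):
            raise ValueError(f"unknown baseline source {self.source!r}")


def estimate_baseline(
    record: PatientRecord,
    normal: NormalRange = NormalRange(),
    presumed_gfr: float = PRESUMED_GFR,
    coefficient: float = MDRD_COEFFICIENT,
    lookback_hours: float = PRIOR_LOOKBACK_HOURS,
) -> BaselineEstimate:
    """Apply the baseline cascade to one patient.

    Ties in rule 1 (admission equal to the lowest prior value) resolve to
    ``source="admission"`` so the source labels are deterministic.
    """
    admission = record.admission_scr()
    if admission is None:
        raise ValueError(
            f"patient {record.patient_id}: no post-admission measurement; "
            "baseline is undefined"
        )
    priors = [m.scr_umol for m in record.prior_measurements(lookback_hours)]
    a = admission.scr_umol
    if a <= normal.upper(record.sex):
        lowest_prior = min(priors) if priors else None
        if lowest_prior is not None and lowest_prior < a:
            return BaselineEstimate(lowest_prior, "prior_minimum")
        return BaselineEstimate(a, "admission")
    if priors:
        return BaselineEstimate(min(priors), "prior_minimum")
    value = backcalc_baseline(record.age_years, record.sex, presumed_gfr, coefficient)
    return BaselineEstimate(value, "mdrd_backcalc")
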