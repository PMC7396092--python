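"""Reference paired-t rows used as validation hooks for p_from_t.

Reported antipsychotic-trial analyses print, for each outcome and patient
class, the paired t statistic, its degrees of freedom and the two-sided
p-value at a fixed table precision.  Recomputing p from the printed t and
df and rounding to the same precision must reproduce the printed value;
rows whose printed numbers are internally consistent at that precision
are collected here and frozen as regression anchors.

Each row: (label, t, df, printed_p_string).  Labels encode
table family (symptom / cognitive / lab), outcome and class.
"""

from __future__ import annotations

from .outcomes import p_from_t

#: rows that reproduce exactly at printed precision from (t, df)
EXACT_ROWS: list[tuple[str, float, int, str]] = [
    ("total_symptom_class1", 3.98, 171, "1.02E-04"),
    ("total_symptom_class5", 1.82, 79, "0.0725"),
    ("negative_symptom_class4", 2.65, 44, "0.0111"),
    ("processing_speed_all", -6.45, 224, "6.8E-10"),
    ("processing_speed_class1", -3.56, 87, "0.0006"),
    ("processing_speed_class5", -3.23, 42, "0.0024"),
    ("working_memory_class1", -3.14, 87, "0.0023"),
    ("reasoning_class1", -3.27, 87, "0.0015"),
    ("reasoning_class4", -2.78, 26, "0.0100"),
    ("hdl_class1", -3.04, 168, "0.0027"),
    ("calcium_all", 3.61, 419, "0.0003"),
    ("phosphorus_class3", 2.26, 50, "0.0282"),
    ("lymphocytes_class4", -2.86, 43, "0.0065"),
]

#: additional rows consistent with (t, df) once the +-0.005 rounding of the
#: printed t is accounted for (the tables print t to two decimals)
INTERVAL_ROWS: list[tuple[str, float, int, str]] = [
    ("total_symptom_all", 5.17, 435, "3.50E-07"),
    ("total_symptom_class2", 2.48, 81, "0.0151"),
    ("total_symptom_class4", 1.97, 44, "0.0557"),
    ("positive_symptom_all", 4.24, 435, "2.78E-05"),
    ("positive_symptom_class1", 2.61, 171, "9.90E-03"),
    ("positive_symptom_class2", 2.00, 81, "0.0492"),
    ("positive_symptom_class3", 1.09, 56, "0.2801"),
    ("positive_symptom_class4", 1.77, 44, "0.0839"),
    ("positive_symptom_class5", 1.83, 79, "0.0707"),
    ("negative_symptom_all", 3.38, 435, "7.94E-04"),
    ("negative_symptom_class1", 3.03, 171, "2.81E-03"),
    ("negative_symptom_class2", 1.08, 81, "0.2817"),
    ("negative_symptom_class3", -0.75, 56, "0.4556"),
    ("negative_symptom_class5", 1.19, 79, "0.2382"),
    ("vigilance_class1", -2.64, 79, "0.0099"),
    ("vigilance_class2", -1.45, 33, "0.1578"),
    ("vigilance_class3", -2.97, 24, "0.0066"),
    ("vigilance_class4", -2.41, 23, "0.0242"),
    ("vigilance_class5", -3.03, 37, "0.0045"),
    ("processing_speed_class2", -2.85, 38, "0.0071"),
    ("processing_speed_class3", -2.41, 27, "0.0229"),
    ("processing_speed_class4", -2.17, 26, "0.0395"),
    ("working_memory_class2", -1.36, 38, "0.1819"),
    ("working_memory_class3", -0.57, 27, "0.5740"),
    ("working_memory_class4", -2.12, 26, "0.0433"),
    ("working_memory_class5", -2.32, 42, "0.0252"),
    ("reasoning_all", -5.15, 224, "5.8E-07"),
    ("reasoning_class2", -1.95, 38, "0.0585"),
    ("reasoning_class3", -1.67, 27, "0.1056"),
    ("reasoning_class5", -1.66, 42, "0.1053"),
    ("hdl_all", -0.15, 419, "0.8833"),
    ("hdl_class3", 1.98, 49, "0.0537"),
    ("hdl_class5", 2.30, 77, "0.0239"),
    ("calcium_class5", 2.71, 77, "0.0084"),
    ("phosphorus_class5", 2.25, 77, "0.0276"),
    ("neutrophils_class4", 2.39, 43, "0.0214"),
]


def format_at_precision(p: float, template: str) -> str:
    """Render p with the same notation and precision as ``template``."""
    if "E" in template.upper():
        mant = template.upper().split("E")[0]
        dec = len(mant.split(".")[1]) if "." in mant else 0
        return ("%." + str(dec) + "E") % p
    dec = len(template.split(".")[1])
    return ("%." + str(dec) + "f") % p


def recompute(t: float, df: int) -> float:
    return p_from_t(t, df)


def matches_at_printed_precision(t: float, df: int, printed: str) -> bool:
    return float(format_at_precision(recompute(t, df), printed)) == float(printed)


def consistent_within_t_rounding(t: float, df: int, printed: str) -> bool:
    """Is the printed p achievable for some t' that rounds to the printed t?"""
    at = abs(t)
    lo = recompute(at + 0.005, df)
    hi = recompute(max(at - 0.005, 0.0), df)
    return lo - 1e-15 <= float(printed) <= hi + 1e-15
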