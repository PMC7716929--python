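"""Published summary counts from a large two-arm screening RCT.

A 4500-participant randomised evaluation of individualised, risk-based,
variable-interval diabetic-retinopathy screening against annual recall
reported its safety and efficiency outcomes as count tables.  Those
aggregate counts are reproduced here as worked-example inputs and
calibration targets for this package: no individual-level data are
involved, only arm-level and risk-group-level numerators and denominators,
appointment totals and programme cost totals.

Tuples are ``(events, denominator)``.  ``"individualised"`` /
``"control"`` index the variable-interval and annual-recall arms.
"""

from __future__ import annotations

__all__ = [
    "ATTENDANCE_FIRST_FOLLOWUP",
    "STDR_24M",
    "EFFICIENCY",
    "PROGRAMME_COSTS",
    "ALLOCATION",
    "UNIT_COSTS",
]

#: Attendance at the first follow-up invitation (primary safety outcome).
ATTENDANCE_FIRST_FOLLOWUP = {
    "per_protocol": {
        "overall": {"control": (1883, 2224), "individualised": (1754, 2097)},
        "high": {"control": (157, 203), "individualised": (141, 195)},
        "medium": {"control": (138, 169), "individualised": (171, 208)},
        "low": {"control": (1588, 1852), "individualised": (1442, 1694)},
    },
    "multiple_imputation": {
        "overall": {"control": (1910, 2269), "individualised": (1870, 2234)},
    },
    "itt": {
        "overall": {"control": (1883, 2224), "individualised": (1798, 2143)},
    },
    "itt_multiple_imputation": {
        "overall": {"control": (1913, 2269), "individualised": (1903, 2265)},
    },
}

#: Confirmed sight-threatening retinopathy within 24 months (+ window).
STDR_24M = {
    "per_protocol": {
        "overall": {"control": (35, 2042), "individualised": (28, 1956)},
        "high": {"control": (20, 176), "individualised": (17, 127)},
        "medium": {"control": (5, 157), "individualised": (7, 179)},
        "low": {"control": (10, 1709), "individualised": (4, 1650)},
    },
    "multiple_imputation": {
        "overall": {"control": (39, 2269), "individualised": (36, 2234)},
    },
    "itt": {
        "overall": {"control": (35, 2042), "individualised": (32, 2056)},
    },
}

#: Attended-appointment totals and screen-positive episodes over 24 months.
EFFICIENCY = {
    "attended_appointments": {"control": 3536, "individualised": 2008},
    "screen_positive": {"control": (160, 3536), "individualised": (102, 2008)},
    "screen_positive_by_group": {
        "high": (34, 317),
        "medium": (15, 249),
        "low": (53, 1442),
    },
}

#: Total programme costs over the two-year horizon, GBP.
PROGRAMME_COSTS = {
    "nhs": {"control": 193983.0, "individualised": 154386.0},
    "societal": {"control": 248114.0, "individualised": 195348.0},
}

#: Baseline risk-group allocation in the individualised arm.
ALLOCATION = {"high": 198, "medium": 211, "low": 1856}

#: Unit costs (GBP) per screening episode.
UNIT_COSTS = {
    "nhs_per_attendance": 28.73,
    "nhs_per_nonattendance": 12.73,
    "societal_addon_per_attendance": 9.00,
}

#: Baseline two-eye retinopathy state distribution (fractions of cohort).
BASELINE_STATE_FRACTIONS = {"R0R0": 0.812, "R1R0": 0.124, "R1R1": 0.063}
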