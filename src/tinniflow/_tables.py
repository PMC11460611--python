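"""Published cohort parameters used as generator defaults.

Per-cell (mean, SD) values for the two residual-inhibition groups across
the four follow-up timepoints, plus group hearing thresholds, ages and
tinnitus characteristics, exactly as printed in the source study's
descriptive tables.
"""

GROUP_POS = "RI+"
GROUP_NEG = "RI-"
GROUPS = (GROUP_POS, GROUP_NEG)

TIMEPOINTS = ("pre", "month1", "month3", "month6")

OUTCOMES = (
    "TLL",
    "MML",
    "THI",
    "VAS_severity",
    "VAS_discomfort",
    "VAS_attention",
    "VAS_sleep",
)

#: group -> outcome -> tuple of (mean, sd) at (pre, 1, 3, 6 months).
OUTCOME_PARAMS: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    GROUP_POS: {
        "TLL": ((64.5, 4.9), (55.1, 8.9), (49.7, 11.3), (37.8, 5.8)),
        "MML": ((57.3, 3.1), (42.4, 6.8), (40.8, 6.9), (36.1, 3.7)),
        "THI": ((52.32, 21.39), (34.08, 16.49), (24.87, 12.18), (18.32, 3.01)),
        "VAS_severity": ((7.3, 1.9), (6.4, 2.2), (6.1, 1.6), (4.3, 0.7)),
        "VAS_discomfort": ((7.3, 1.6), (6.5, 2.1), (5.9, 1.7), (5.1, 0.7)),
        "VAS_attention": ((4.5, 1.8), (3.8, 2.9), (3.5, 1.1), (2.7, 0.3)),
        "VAS_sleep": ((6.2, 2.4), (5.9, 1.6), (5.3, 1.8), (4.2, 0.8)),
    },
    GROUP_NEG: {
        "TLL": ((65.7, 7.3), (61.2, 5.1), (60.1, 5.8), (59.2, 6.2)),
        "MML": ((57.5, 5.8), (54.3, 4.1), (50.9, 5.2), (49.8, 4.2)),
        "THI": ((52.58, 16.93), (50.32, 15.51), (48.24, 14.01), (47.47, 12.21)),
        "VAS_severity": ((7.8, 1.2), (7.1, 1.9), (6.7, 1.4), (6.4, 1.1)),
        "VAS_discomfort": ((7.8, 1.5), (7.4, 1.7), (7.1, 1.2), (6.8, 0.9)),
        "VAS_attention": ((4.9, 1.7), (4.7, 1.6), (4.2, 1.5), (4.0, 1.3)),
        "VAS_sleep": ((6.5, 2.5), (6.1, 1.9), (5.7, 2.4), (5.6, 1.9)),
    },
}

#: group -> frequency (Hz) -> (mean, sd) hearing threshold in dB HL.
HEARING_THRESHOLD_PARAMS: dict[str, dict[int, tuple[float, float]]] = {
    GROUP_POS: {
        125: (13.05, 8.76),
        250: (16.94, 12.14),
        500: (20.0, 12.48),
        1000: (29.72, 13.87),
        2000: (35.27, 8.48),
        4000: (44.72, 11.56),
        8000: (46.94, 19.71),
        10000: (50.0, 30.72),
        12000: (60.45, 17.38),
        16000: (64.54, 15.4),
        20000: (70.0, 10.95),
    },
    GROUP_NEG: {
        125: (15.8, 10.57),
        250: (15.92, 10.73),
        500: (19.2, 12.88),
        1000: (27.12, 11.72),
        2000: (36.4, 10.55),
        4000: (42.0, 13.14),
        8000: (41.25, 17.12),
        10000: (54.37, 24.99),
        12000: (63.0, 19.74),
        16000: (68.5, 12.48),
        20000: (71.5, 9.44),
    },
}

#: group -> (mean, sd, (min, max)) age in years.
AGE_PARAMS = {
    GROUP_POS: (31.18, 6.75, (23, 45)),
    GROUP_NEG: (33.41, 7.37, (21, 42)),
}

#: group -> (mean, sd, (min, max)) tinnitus frequency in kHz.  The printed
#: mean/SD and range are mutually inconsistent; draws use the mean/SD and
#: are clipped to the printed range.
TINNITUS_FREQ_KHZ_PARAMS = {
    GROUP_POS: (7.2, 0.7, (1.0, 8.0)),
    GROUP_NEG: (7.32, 0.6, (1.0, 8.0)),
}

N_POS = 38
N_NEG = 29
N_RESOLVED_POS = 11
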