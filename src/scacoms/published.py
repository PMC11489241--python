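"""Published reference values for the SCACOMS composite models.

The SCACOMS derivation study reported, for four natural-history derivation
cohorts (CRC-SCA and EUROSCA registries, all-genotype and SCA3-only
analytic samples), the retained items' PLS weights and composite MSDRs, the
final-visit LS means of the troriluzole phase-3 SCA3 subgroup under each
model, and a sample-size table over slowing x power.  Those printed values
are inputs here: the package's arithmetic (percent contributions,
progression avoided, noncentral-t sample sizes) can be driven directly from
them, while the underlying patient-level registry and trial data remain
restricted.
"""

from __future__ import annotations

# PLS regression weights of the retained items, by derivation cohort.
WEIGHTS: dict[str, dict[str, float]] = {
    "crc_all": {
        "fsara_gait": 5.0057,
        "fars_func": 8.7293,
        "fsara_stance": 4.7659,
        "fsara_speech": 3.8264,
        "cgi": 11.4228,
    },
    "euro_all": {
        "fsara_gait": 6.1773,
        "fsara_stance": 8.3214,
        "fsara_speech": 5.2110,
        "fsara_sitting": 3.9369,
        "cgi": 26.7503,
    },
    "crc_sca3": {
        "fsara_gait": 4.5390,
        "fars_func": 10.8056,
        "fsara_stance": 9.9743,
        "fsara_speech": 4.2284,
        "cgi": 13.9060,
    },
    "euro_sca3": {
        "fsara_gait": 2.5315,
        "fsara_stance": 13.5141,
        "fsara_speech": 10.7757,
        "fsara_sitting": 2.0793,
        "cgi": 23.5624,
    },
}

# Published percent contributions for the same models (2 dp).
PERCENT_CONTRIBUTIONS: dict[str, dict[str, float]] = {
    "crc_all": {
        "fsara_gait": 14.83,
        "fars_func": 25.86,
        "fsara_stance": 14.12,
        "fsara_speech": 11.34,
        "cgi": 33.85,
    },
    "euro_all": {
        "fsara_gait": 12.26,
        "fsara_stance": 16.51,
        "fsara_speech": 10.34,
        "fsara_sitting": 7.81,
        "cgi": 53.08,
    },
    "crc_sca3": {
        "fsara_gait": 10.45,
        "fars_func": 24.87,
        "fsara_stance": 22.95,
        "fsara_speech": 9.73,
        "cgi": 32.00,
    },
    "euro_sca3": {
        "fsara_gait": 4.83,
        "fsara_stance": 25.76,
        "fsara_speech": 20.54,
        "fsara_sitting": 3.96,
        "cgi": 44.91,
    },
}

# Composite and f-SARA total-score MSDRs, by derivation cohort.
MSDR: dict[str, dict[str, float]] = {
    "crc_all": {"scacoms": 0.8276, "fsara": 0.4826},
    "crc_sca3": {"scacoms": 0.9171, "fsara": 0.5582},
    "euro_all": {"scacoms": 1.1206, "fsara": 0.5117},
    "euro_sca3": {"scacoms": 1.1157, "fsara": 0.5893},
}

# Final-visit (week 48) LS-mean composite CFB in the phase-3 SCA3 subgroup,
# by the natural-history model used to score it: (placebo, treated).
TRIAL_LSM: dict[str, tuple[float, float]] = {
    "crc_all": (3.6254, 0.9001),
    "euro_all": (6.8458, 1.2550),
    "crc_sca3": (4.4884, 0.8833),
    "euro_sca3": (6.3255, 0.8086),
}

# Published per-arm sample sizes: (power, slowing) -> (f-SARA n, composite n).
SAMPLE_SIZES: dict[str, dict[tuple[float, float], tuple[int, int]]] = {
    "crc_all": {
        (0.80, 0.3): (750, 256),
        (0.80, 0.5): (271, 93),
        (0.90, 0.3): (1004, 342),
        (0.90, 0.5): (362, 124),
    },
    "crc_sca3": {
        (0.80, 0.3): (561, 209),
        (0.80, 0.5): (203, 76),
        (0.90, 0.3): (751, 279),
        (0.90, 0.5): (271, 101),
    },
    "euro_all": {
        (0.80, 0.3): (668, 140),
        (0.80, 0.5): (241, 51),
        (0.90, 0.3): (893, 187),
        (0.90, 0.5): (323, 68),
    },
    "euro_sca3": {
        (0.80, 0.3): (504, 142),
        (0.80, 0.5): (182, 52),
        (0.90, 0.3): (674, 189),
        (0.90, 0.5): (244, 69),
    },
}
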