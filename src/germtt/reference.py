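"""Published reference values for the Gentiana lutea germination study.

Printed summary values from the field study this package's methods were
designed around (two Gennargentu localities, IS and TM): final germination
percentages by stratification duration and incubation temperature, the
resulting base-temperature and thermal-time estimates, and the cold-day
counts of the soil-logger analysis under RCP warming increments. They serve
as sanity anchors for the pipeline and as realistic targets for the
synthetic-data generator; the underlying raw time-courses and logger
readings are not redistributed here.
"""

from __future__ import annotations

import pandas as pd

PRETREATMENTS = (0, 15, 30, 60, 90)
TEMPERATURES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: (site, pretreatment_days, temperature_c) -> (mean %, SD %) of final
#: germination on filled seeds, four dishes per condition.
FINAL_GERMINATION: dict[tuple[str, int, float], tuple[float, float]] = {
    # IS, by temperature within pretreatment
    ("IS", 0, 5.0): (2.00, 4.00), ("IS", 0, 10.0): (0.00, 0.00),
    ("IS", 0, 15.0): (0.00, 0.00), ("IS", 0, 20.0): (2.27, 4.55),
    ("IS", 0, 25.0): (2.22, 2.57), ("IS", 0, 30.0): (0.00, 0.00),
    ("IS", 15, 5.0): (17.21, 6.16), ("IS", 15, 10.0): (1.00, 2.00),
    ("IS", 15, 15.0): (0.00, 0.00), ("IS", 15, 20.0): (1.00, 2.00),
    ("IS", 15, 25.0): (0.00, 0.00), ("IS", 15, 30.0): (1.19, 2.38),
    ("IS", 30, 5.0): (26.20, 8.75), ("IS", 30, 10.0): (15.62, 9.01),
    ("IS", 30, 15.0): (34.63, 8.74), ("IS", 30, 20.0): (31.71, 14.24),
    ("IS", 30, 25.0): (10.20, 4.34), ("IS", 30, 30.0): (0.00, 0.00),
    ("IS", 60, 5.0): (27.01, 6.60), ("IS", 60, 10.0): (55.70, 17.52),
    ("IS", 60, 15.0): (65.08, 5.32), ("IS", 60, 20.0): (58.25, 6.52),
    ("IS", 60, 25.0): (29.17, 6.18), ("IS", 60, 30.0): (2.27, 4.55),
    ("IS", 90, 5.0): (82.67, 1.81), ("IS", 90, 10.0): (90.00, 4.00),
    ("IS", 90, 15.0): (92.83, 7.13), ("IS", 90, 20.0): (93.96, 3.97),
    ("IS", 90, 25.0): (15.00, 3.83), ("IS", 90, 30.0): (2.27, 4.55),
    # TM
    ("TM", 0, 5.0): (1.14, 2.27), ("TM", 0, 10.0): (0.00, 0.00),
    ("TM", 0, 15.0): (0.00, 0.00), ("TM", 0, 20.0): (0.00, 0.00),
    ("TM", 0, 25.0): (0.00, 0.00), ("TM", 0, 30.0): (1.09, 2.17),
    ("TM", 15, 5.0): (8.46, 7.06), ("TM", 15, 10.0): (0.00, 0.00),
    ("TM", 15, 15.0): (0.00, 0.00), ("TM", 15, 20.0): (0.00, 0.00),
    ("TM", 15, 25.0): (1.19, 2.38), ("TM", 15, 30.0): (0.00, 0.00),
    ("TM", 30, 5.0): (29.67, 10.75), ("TM", 30, 10.0): (26.47, 11.77),
    ("TM", 30, 15.0): (34.21, 3.29), ("TM", 30, 20.0): (22.86, 6.75),
    ("TM", 30, 25.0): (1.25, 2.50), ("TM", 30, 30.0): (0.00, 0.00),
    ("TM", 60, 5.0): (28.01, 17.79), ("TM", 60, 10.0): (46.20, 12.25),
    ("TM", 60, 15.0): (60.33, 11.13), ("TM", 60, 20.0): (38.20, 14.10),
    ("TM", 60, 25.0): (3.31, 4.18), ("TM", 60, 30.0): (0.00, 0.00),
    ("TM", 90, 5.0): (82.67, 1.81), ("TM", 90, 10.0): (90.00, 4.00),
    ("TM", 90, 15.0): (92.83, 7.13), ("TM", 90, 20.0): (93.96, 3.97),
    ("TM", 90, 25.0): (15.00, 3.83), ("TM", 90, 30.0): (0.00, 0.00),
}

#: (site, pretreatment_days) -> (T_b mean degC, T_b SD, theta50 degC d).
#: Only the two longest stratifications released enough dormancy to fit.
THERMAL_PARAMS: dict[tuple[str, int], tuple[float, float, int]] = {
    ("IS", 60): (3.34, 1.03, 115),
    ("IS", 90): (-1.96, 1.23, 130),
    ("TM", 60): (2.15, 0.86, 112),
    ("TM", 90): (-1.58, 3.74, 108),
}

#: (site, scenario) -> (mean cold days <= 1 +/- 1 degC, SD over 3 winters).
COLD_DAYS: dict[tuple[str, str], tuple[float, float]] = {
    ("IS", "Current"): (76.33, 14.36),
    ("IS", "RCP2.6-OP"): (68.33, 24.00), ("IS", "RCP2.6-LOP"): (18.00, 14.56),
    ("IS", "RCP4.5-OP"): (33.66, 23.86), ("IS", "RCP4.5-LOP"): (4.33, 4.51),
    ("IS", "RCP6.0-OP"): (24.00, 15.72), ("IS", "RCP6.0-LOP"): (0.66, 1.15),
    ("IS", "RCP8.5-OP"): (4.33, 4.51), ("IS", "RCP8.5-LOP"): (0.00, 0.00),
    ("TM", "Current"): (78.33, 12.66),
    ("TM", "RCP2.6-OP"): (73.33, 15.31), ("TM", "RCP2.6-LOP"): (20.00, 11.00),
    ("TM", "RCP4.5-OP"): (39.00, 15.52), ("TM", "RCP4.5-LOP"): (7.66, 10.02),
    ("TM", "RCP6.0-OP"): (28.00, 8.71), ("TM", "RCP6.0-LOP"): (1.00, 1.73),
    ("TM", "RCP8.5-OP"): (7.66, 10.02), ("TM", "RCP8.5-LOP"): (0.00, 0.00),
}


def reported_summary_table() -> pd.DataFrame:
    """The published final-germination table in :func:`summary_table` shape."""
    rows = [
        {
            "site": site,
            "pretreatment_days": pre,
            "temperature_c": temp,
            "mean_pct": mean,
            "sd_pct": sd,
            "n_dishes": 4,
        }
        for (site, pre, temp), (mean, sd) in sorted(FINAL_GERMINATION.items())
    ]
    return pd.DataFrame(rows)
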