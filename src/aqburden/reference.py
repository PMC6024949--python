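"""Published national summary tables used as consistency-check inputs.

These are the national-scale results of a published 190-city assessment
of PM2.5-attributable health burden in China, 2014-2016: attributable
cases per endpoint-year, and economic losses per endpoint-year under the
lower (AHC) and upper (VSL) bounds in hundred-million USD. They are
*inputs* to internal-consistency checks (the affected-population row must
equal the sum of the five non-overlapping endpoint rows; the total
economic loss row must equal all-cause mortality plus the four morbidity
rows) and to worked examples of the summary statistics; the pipeline does
not reproduce them, since the underlying city data and pooled
coefficients are unpublished.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "national_health_impacts",
    "national_losses",
    "AFFECTED_ROW",
    "TEL_ROW",
]

AFFECTED_ROW = "affected_population"
TEL_ROW = "total_economic_loss"

# Attributable cases per endpoint-year (national totals, persons).
_HEALTH_IMPACTS = {
    "endpoint": [
        "all_cause_mortality",
        "cardiovascular_mortality",
        "respiratory_mortality",
        "lung_cancer_mortality",
        "cardiovascular_hospitalization",
        "chronic_bronchitis",
        "acute_bronchitis",
        "asthma_attack",
        AFFECTED_ROW,
    ],
    2014: [278_444, 71_058, 42_590, 92_512, 1_001_233, 185_798, 1_034_080, 19_197_994, 21_697_549],
    2015: [238_622, 60_991, 36_431, 78_444, 851_497, 159_366, 881_692, 15_935_983, 18_067_160],
    2016: [216_164, 55_321, 32_959, 70_557, 767_387, 144_459, 795_978, 14_130_036, 16_054_024],
}

# Economic losses per endpoint-year-bound, hundred-million USD.
_LOSSES = {
    "endpoint": [
        "all_cause_mortality",
        "cardiovascular_mortality",
        "respiratory_mortality",
        "lung_cancer_mortality",
        "cardiovascular_hospitalization",
        "chronic_bronchitis",
        "acute_bronchitis",
        "asthma_attack",
        TEL_ROW,
    ],
    (2014, "lower_AHC"): [256.32, 65.46, 39.19, 84.84, 12.2, 42.48, 0.35, 6.57, 317.93],
    (2014, "upper_VSL"): [1157.59, 295.48, 177.0, 383.9, 12.2, 42.48, 0.35, 6.57, 1219.19],
    (2015, "lower_AHC"): [230.89, 59.03, 35.23, 75.7, 10.95, 39.0, 0.31, 5.8, 286.97],
    (2015, "upper_VSL"): [1061.69, 271.44, 162.02, 348.39, 10.95, 39.0, 0.31, 5.8, 1117.76],
    (2016, "lower_AHC"): [214.16, 54.84, 32.63, 69.68, 10.28, 37.44, 0.29, 5.4, 267.38],
    (2016, "upper_VSL"): [1018.62, 260.75, 155.24, 331.86, 10.28, 37.44, 0.29, 5.4, 1072.02],
}

# TEL as a share of total GDP, by year and bound.
TEL_GDP_RATIO = {
    (2014, "lower_AHC"): 0.0036,
    (2014, "upper_VSL"): 0.0136,
    (2015, "lower_AHC"): 0.0030,
    (2015, "upper_VSL"): 0.0118,
    (2016, "lower_AHC"): 0.0026,
    (2016, "upper_VSL"): 0.0106,
}

#: National mean PM2.5 concentration (µg/m³) per year, from the annual
#: environmental-status bulletins.
NATIONAL_MEAN_CONCENTRATION = {2014: 62.0, 2015: 50.0, 2016: 47.0}

#: Share of cities with annual concentration in 35-75 µg/m³ (final year).
BAND_35_75_SHARE_2016 = 0.71


def national_health_impacts() -> pd.DataFrame:
    """Endpoint-by-year attributable cases, indexed by endpoint name."""
    df = pd.DataFrame(_HEALTH_IMPACTS).set_index("endpoint")
    df.columns = [int(c) for c in df.columns]
    return df


def national_losses() -> pd.DataFrame:
    """Endpoint-by-(year, bound) losses in hundred-million USD."""
    data = {k: v for k, v in _LOSSES.items() if k != "endpoint"}
    df = pd.DataFrame(data, index=_LOSSES["endpoint"])
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["year", "bound"])
    df.index.name = "endpoint"
    return df
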