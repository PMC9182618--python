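"""Bundled worked-example data.

``load_maize_yield_means`` returns the published genotype x location mean
grain yields (t/ha) of a 45-hybrid maize multi-environment trial grown at
three Bangladeshi research stations (Barishal, Ishwardi, Jashore). The
table carries location means only — the plot-level raw data were never
deposited — so it exercises the means-based operations (phenotypic and
locational indices, top-performer ranking) exactly as published reports
tabulate them.

``GENETIC_PARAMETER_EXAMPLES`` holds a handful of published per-location
ANOVA summaries (trait mean, genotypic/phenotypic/error variances) from the
same trial, used as worked-example inputs for the variance-component and
coefficient-of-variation arithmetic.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_maize_yield_means", "GENETIC_PARAMETER_EXAMPLES"]

_YIELD_MEANS_CSV = """\
genotype,Barishal,Ishwardi,Jashore
G1,11.12,11.35,11.43
G2,10.82,12.53,11.00
G3,9.78,12.05,10.10
G4,10.38,11.54,8.53
G5,11.68,13.58,11.53
G6,11.46,11.51,9.61
G7,11.51,13.91,9.90
G8,13.04,12.51,11.39
G9,12.13,12.91,10.88
G10,9.81,10.56,8.27
G11,9.79,11.53,10.32
G12,9.35,10.10,9.92
G13,10.83,13.86,10.12
G14,9.80,11.38,10.88
G15,11.21,11.62,11.39
G16,9.51,10.02,9.60
G17,10.62,10.63,11.22
G18,10.33,10.68,9.76
G19,9.75,5.68,9.97
G20,10.56,10.83,10.92
G21,11.83,10.57,11.05
G22,12.24,12.38,10.26
G23,11.17,11.71,11.10
G24,10.54,10.17,10.61
G25,10.20,11.88,9.57
G26,11.86,13.19,9.94
G27,12.18,13.62,10.44
G28,10.58,11.92,12.07
G29,13.00,11.84,12.89
G30,13.19,10.37,12.15
G31,8.63,13.09,9.14
G32,11.57,11.31,10.73
G33,10.59,13.05,11.24
G34,9.22,11.32,10.18
G35,9.73,12.65,11.04
G36,10.48,11.99,11.40
G37,9.70,14.51,10.65
G38,8.78,12.52,10.97
G39,10.62,11.14,10.75
G40,9.53,11.39,11.19
G41,11.80,11.99,12.11
G42,13.79,12.35,11.97
G43,7.80,9.48,9.67
G44,9.12,10.83,10.13
G45,12.31,10.32,11.79
"""


def load_maize_yield_means() -> pd.DataFrame:
    """Genotype x location mean grain yield (t/ha) of the 45-hybrid trial."""
    return pd.read_csv(io.StringIO(_YIELD_MEANS_CSV), index_col="genotype")


#: Published per-location genetic-parameter rows (trait mean and the
#: genotypic / phenotypic / error variance estimates) used as worked-example
#: inputs. Units: days (AD), g (TKW), t/ha (GY), days (ASI).
GENETIC_PARAMETER_EXAMPLES = {
    ("Jashore", "TKW"): {"mean": 351.33, "sigma2_g": 1758.71,
                         "sigma2_p": 2476.29, "sigma2_e": 717.57},
    ("Ishwardi", "AD"): {"mean": 97.40, "sigma2_g": 11.25,
                         "sigma2_p": 11.89, "sigma2_e": 0.64},
    ("Ishwardi", "GY"): {"mean": 11.65, "sigma2_g": 1.84,
                         "sigma2_p": 2.47, "sigma2_e": 0.63},
    ("Barishal", "ASI"): {"mean": 1.20, "sigma2_g": 0.00,
                          "sigma2_p": 0.39, "sigma2_e": 0.39},
    ("Barishal", "AD"): {"mean": 88.03, "sigma2_g": 4.10,
                         "sigma2_p": 8.44, "sigma2_e": 4.34},
}

#: Published combined genotype x location ANOVA sums of squares for grain
#: yield in the same trial (Location, Genotype, Genotype x Location,
#: Residual), with degrees of freedom.
COMBINED_ANOVA_EXAMPLE = {
    "SS": {"location": 53.901, "genotype": 219.712,
           "genotype_x_location": 203.979, "residual": 139.081},
    "df": {"location": 2, "genotype": 44, "genotype_x_location": 88},
}
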