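"""Published summary tables from the crayfish feeding trial.

These are the desk-side inputs of the re-analysis: the diet formulations and
the per-group phenotype summaries (mean ± SEM of three cage replicates) for
a control diet (CK) and four kelp-extract supplementation levels
(LJP0.5–LJP2.0, i.e. 500–2000 mg/kg). Raw per-animal data and the sequencing
reads are not distributed; all sequencing-derived quantities are exercised on
synthetic data instead (:mod:`micronet.simulate`).
"""

from __future__ import annotations

import pandas as pd

from micronet.core import DEFAULT_GROUPS, DoseDesign

GROUPS = DEFAULT_GROUPS
DESIGN = DoseDesign()

#: Diet formulation, % of dried mass per ingredient and diet. Each column sums
#: to exactly 100.00; the kelp extract displaces wheat bran gram for gram.
DIET_FORMULATION = pd.DataFrame(
    {
        "CK": [25.00, 22.00, 15.00, 24.00, 3.53, 5.23, 2.00, 2.00, 1.00, 0.01, 0.03, 0.20, 0.00],
        "LJP0.5": [25.00, 22.00, 15.00, 24.00, 3.53, 5.18, 2.00, 2.00, 1.00, 0.01, 0.03, 0.20, 0.05],
        "LJP1.0": [25.00, 22.00, 15.00, 24.00, 3.53, 5.13, 2.00, 2.00, 1.00, 0.01, 0.03, 0.20, 0.10],
        "LJP1.5": [25.00, 22.00, 15.00, 24.00, 3.53, 5.08, 2.00, 2.00, 1.00, 0.01, 0.03, 0.20, 0.15],
        "LJP2.0": [25.00, 22.00, 15.00, 24.00, 3.53, 5.03, 2.00, 2.00, 1.00, 0.01, 0.03, 0.20, 0.20],
    },
    index=[
        "soybean_meal",
        "rapeseed_meal",
        "poultry_byproduct_meal",
        "wheat_flour",
        "soybean_oil",
        "wheat_bran",
        "alpha_starch",
        "monocalcium_phosphate",
        "premix",
        "antioxidant",
        "anti_mildew_agent",
        "choline_chloride",
        "kelp_extract",
    ],
)


def _summary(means, sems, n=3) -> pd.DataFrame:
    return pd.DataFrame(
        {"group": GROUPS, "mean": means, "sem": sems, "n": [n] * len(GROUPS)}
    )


#: Growth performance, mean ± SEM of three cage replicates per group.
GROWTH_SUMMARIES: dict[str, pd.DataFrame] = {
    "IAW": _summary([4.04, 4.01, 4.03, 4.01, 4.04], [0.02, 0.01, 0.02, 0.00, 0.01]),
    "FAW": _summary([9.99, 9.97, 10.43, 10.78, 10.38], [0.15, 0.15, 0.09, 0.09, 0.12]),
    "WGR": _summary([147.31, 148.70, 159.00, 168.60, 156.88], [3.02, 4.42, 3.32, 2.36, 3.43]),
    "SGR": _summary([2.16, 2.17, 2.27, 2.35, 2.25], [0.03, 0.04, 0.03, 0.02, 0.03]),
    "FCR": _summary([1.68, 1.65, 1.52, 1.46, 1.53], [0.05, 0.05, 0.04, 0.03, 0.05]),
    "SR": _summary([76.00, 79.33, 80.67, 78.67, 81.33], [2.31, 4.67, 1.33, 1.76, 2.40]),
    "HSI": _summary([12.35, 10.62, 10.06, 10.24, 9.90], [0.43, 0.28, 0.35, 0.39, 0.20]),
    "CF": _summary([4.57, 4.68, 4.68, 4.69, 4.52], [0.11, 0.13, 0.09, 0.07, 0.17]),
}

#: Hemolymph biochemistry (MDA nmol/mL, GOT U/L, LZM ug/mL, ACP king's unit/L).
HEMOLYMPH_SUMMARIES: dict[str, pd.DataFrame] = {
    "MDA": _summary([7.64, 6.92, 5.78, 4.96, 5.02], [0.15, 0.14, 0.22, 0.25, 0.25]),
    "GOT": _summary([38.27, 35.17, 34.09, 31.57, 28.63], [1.28, 1.00, 1.02, 2.86, 3.49]),
    "LZM": _summary([6.84, 7.07, 7.33, 8.04, 7.39], [0.28, 0.32, 0.27, 0.19, 0.11]),
    "ACP": _summary([3.16, 3.39, 3.64, 3.80, 3.33], [0.07, 0.09, 0.17, 0.19, 0.03]),
}

#: Hepatopancreas MDA and antioxidant panel (per mg protein except GSH umol/g).
HEPATOPANCREAS_SUMMARIES: dict[str, pd.DataFrame] = {
    "MDA": _summary([0.91, 0.83, 0.75, 0.66, 0.68], [0.01, 0.02, 0.03, 0.03, 0.04]),
    "GSH": _summary([41.48, 43.18, 46.50, 53.65, 57.66], [2.40, 1.66, 1.67, 2.53, 1.58]),
    "SOD": _summary([26.01, 30.94, 32.73, 35.57, 36.60], [1.02, 0.95, 1.27, 1.61, 0.64]),
    "CAT": _summary([11.81, 12.18, 14.16, 16.31, 14.83], [0.47, 0.43, 0.38, 1.07, 0.43]),
    "GPx": _summary([28.41, 32.85, 36.64, 37.84, 33.90], [1.51, 1.20, 0.82, 1.30, 1.36]),
    "GST": _summary([5.57, 6.12, 7.51, 8.49, 8.78], [0.33, 0.17, 0.23, 0.51, 0.46]),
    "GR": _summary([3.50, 3.69, 4.41, 5.22, 5.20], [0.06, 0.12, 0.38, 0.55, 0.23]),
}

#: Responses whose quadratic fits define the reported optimal dose window.
OPTIMUM_RESPONSES = ("WGR", "SGR", "FCR")

#: Objective per response when searching for an interior optimum: growth rates
#: are maximized, feed conversion ratio minimized.
RESPONSE_OBJECTIVES = {"WGR": "max", "SGR": "max", "FCR": "min"}


def group_means(variable: str) -> pd.Series:
    """Published group means of a growth variable, indexed by group."""
    df = GROWTH_SUMMARIES[variable]
    return pd.Series(df["mean"].to_numpy(), index=df["group"].to_numpy())
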