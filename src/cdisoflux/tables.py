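"""Packaged per-treatment reference dataset from the cacao Cd hydroponics study.

Eight treatments of cacao seedlings were grown for 14 days in 3 L of
half-strength Hoagland solution carrying 2.25 mg/L Cd (20 umol/L CdCl2),
with hydroponic Fe and/or Zn included or excluded and optional foliar Fe- or
Zn-EDTA sprays. The published replicate-averaged values — per-organ Cd
concentrations, total plant Cd, delta114Cd compositions and the derived
fractionation pairs — are reproduced here verbatim (including their
Mean/sd/Min/Max summary rows where printed) so that the analysis pipeline
can be exercised and checked against them without any external data.

Concentration/mass uncertainties are 1sd, isotope uncertainties 2sd, both
across the two (T6: three) biological replicates.
"""

from __future__ import annotations

import pandas as pd

from .isotope_metrics import DeltaValue

__all__ = [
    "DELTA_SOLUTION",
    "SOLUTION_VOLUME_L",
    "SOLUTION_CD_MG_PER_L",
    "RESERVOIR_CD_UG",
    "MEAN_UPTAKE_FRACTION",
    "treatment_design",
    "treatment_concentrations",
    "treatment_fractionation",
    "published_means",
]

#: Isotope composition of the CdCl2 added to every hydroponic solution.
DELTA_SOLUTION = DeltaValue(-0.36, 0.04, n=6)

SOLUTION_VOLUME_L = 3.0
SOLUTION_CD_MG_PER_L = 2.25
#: Initial Cd inventory of one container (ug).
RESERVOIR_CD_UG = SOLUTION_VOLUME_L * SOLUTION_CD_MG_PER_L * 1000.0
#: Mean fraction of reservoir Cd taken up by the three plants of a treatment.
MEAN_UPTAKE_FRACTION = 0.05

# treatment id -> (hydro_fe, hydro_zn, foliar_fe, foliar_zn)
_DESIGN = {
    "T1": (True, True, False, False),
    "T2": (True, True, True, False),
    "T3": (True, True, False, True),
    "T4": (False, True, False, False),
    "T5": (False, True, True, False),
    "T6": (True, False, False, False),
    "T7": (True, False, False, True),
    "T8": (False, False, False, False),
}

# Per-organ [Cd] (mg/kg +- 1sd), total plant Cd (ug +- 1sd) and delta114Cd
# (permil +- 2sd) per treatment; replicate averages, isotope values
# inverse-variance weighted.
_CONCENTRATIONS = [
    # tid, conc_root, sd, conc_stem, sd, conc_leaf, sd, cd_total, sd,
    #      d_root, 2sd, d_stem, 2sd, d_leaf, 2sd, d_total, 2sd
    ("T1", 322, 67, 284, 12, 115, 33, 142, 9, -0.74, 0.08, -0.74, 0.04, -0.48, 0.08, -0.64, 0.04),
    ("T2", 348, 1, 282, 73, 159, 62, 187, 38, -0.73, 0.08, -0.80, 0.02, -0.58, 0.07, -0.67, 0.04),
    ("T3", 352, 34, 253, 17, 109, 2, 141, 24, -0.61, 0.08, -0.76, 0.09, -0.59, 0.08, -0.66, 0.05),
    ("T4", 482, 14, 160, 23, 37, 6, 82, 14, -0.70, 0.07, -0.61, 0.06, -0.38, 0.08, -0.62, 0.05),
    ("T5", 486, 6, 207, 31, 47, 19, 101, 0, -0.74, 0.07, -0.65, 0.04, -0.50, 0.09, -0.67, 0.04),
    ("T6", 377, 32, 240, 106, 69, 42, 118, 68, -0.61, 0.05, -0.77, 0.05, -0.45, 0.09, -0.63, 0.04),
    ("T7", 316, 61, 308, 93, 90, 33, 122, 27, -0.65, 0.07, -0.80, 0.09, -0.49, 0.10, -0.64, 0.05),
    ("T8", 374, 47, 93, 61, 27, 28, 59, 15, -0.68, 0.13, -0.64, 0.09, -0.43, 0.05, -0.61, 0.10),
]

# Fractionation pairs (permil) and the per-treatment sequestration-
# mobilisation epsilon (leaf sink, total plant source; mean of the two
# per-plant values).
_FRACTIONATION = [
    # tid, d_leaf_stem, d_stem_root, d_leaf_root, d_tot_sol, d_leaf_tot, d_shoot_tot, eps_seq_mob
    ("T1", 0.28, 0.00, 0.25, -0.29, 0.17, 0.03, -0.15),
    ("T2", 0.22, -0.07, 0.14, -0.31, 0.09, 0.02, -0.12),
    ("T3", 0.16, -0.16, 0.01, -0.28, 0.04, -0.02, -0.10),
    ("T4", 0.23, 0.07, 0.31, -0.25, 0.23, 0.09, -0.15),
    ("T5", 0.14, 0.09, 0.24, -0.31, 0.17, 0.07, -0.10),
    ("T6", 0.27, -0.09, 0.19, -0.26, 0.16, 0.03, -0.15),
    ("T7", 0.27, -0.15, 0.14, -0.29, 0.13, 0.00, -0.11),
    ("T8", 0.27, 0.09, 0.23, -0.21, 0.13, 0.07, -0.11),
]

#: Printed Mean-row values of the replicate-averaged dataset, for checks.
published_means = {
    "conc_root": 382.0,
    "conc_stem": 228.0,
    "conc_leaf": 82.0,
    "cd_total_ug": 119.0,
    "delta_root": -0.68,
    "delta_stem": -0.72,
    "delta_leaf": -0.49,
    "delta_total": -0.64,
    "d_leaf_stem": 0.23,
    "d_stem_root": -0.03,
    "d_leaf_root": 0.19,
    "d_tot_sol": -0.27,
    "d_leaf_tot": 0.14,
    "d_shoot_tot": 0.04,
    "eps_seq_mob": -0.12,
}


def _with_design(df: pd.DataFrame) -> pd.DataFrame:
    design = treatment_design()
    return design.merge(df, on="treatment_id")


def treatment_design() -> pd.DataFrame:
    """Design flags of the eight treatments."""
    return pd.DataFrame(
        [(tid, *flags) for tid, flags in _DESIGN.items()],
        columns=["treatment_id", "hydro_fe", "hydro_zn", "foliar_fe", "foliar_zn"],
    )


def treatment_concentrations() -> pd.DataFrame:
    """Replicate-averaged concentrations, total Cd and delta values per treatment."""
    cols = [
        "treatment_id",
        "conc_root", "conc_root_sd",
        "conc_stem", "conc_stem_sd",
        "conc_leaf", "conc_leaf_sd",
        "cd_total_ug", "cd_total_sd",
        "delta_root", "delta_root_2sd",
        "delta_stem", "delta_stem_2sd",
        "delta_leaf", "delta_leaf_2sd",
        "delta_total", "delta_total_2sd",
    ]
    return _with_design(pd.DataFrame(_CONCENTRATIONS, columns=cols))


def treatment_fractionation() -> pd.DataFrame:
    """Replicate-averaged fractionation pairs and epsilon per treatment."""
    cols = [
        "treatment_id",
        "d_leaf_stem", "d_stem_root", "d_leaf_root",
        "d_tot_sol", "d_leaf_tot", "d_shoot_tot",
        "eps_seq_mob",
    ]
    return _with_design(pd.DataFrame(_FRACTIONATION, columns=cols))
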