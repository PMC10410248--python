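"""Post hoc associations of hit species (and their combined abundance) with
blood pressure and HbA1c.

Each feature is tested against SBP, DBP and HbA1c with partial Spearman
correlation adjusted for age, sex, alcohol intake, smoking, fiber intake,
total energy intake, physical activity, birth country, all three OSA
parameters and DNA extraction plate (season is not part of this covariate
set, and BMI enters only in the second pass).  Antihypertensive users are
excluded from the BP models and antidiabetic users from the HbA1c model.
BH is applied across features within each (outcome, BMI-adjustment) family,
combined abundance and individual species in one family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .association import bh_adjust, combined_abundance, design_matrix, partial_spearman_many

OUTCOME_COVARIATES = [
    "age",
    "sex",
    "alcohol",
    "smoking",
    "fiber",
    "energy",
    "physical_activity",
    "birth_country",
    "ahi",
    "odi",
    "t90",
    "plate",
]


@dataclass(frozen=True)
class OutcomeModelSpec:
    outcome: str
    covariates: tuple[str, ...]
    exclusion_flag: str          # boolean column in the outcome table
    bmi_adjusted: bool = False


def default_outcome_models(bmi_adjusted: bool = False) -> list[OutcomeModelSpec]:
    cov = tuple(OUTCOME_COVARIATES) + (("bmi",) if bmi_adjusted else ())
    return [
        OutcomeModelSpec("sbp", cov, "antihypertensive_med", bmi_adjusted),
        OutcomeModelSpec("dbp", cov, "antihypertensive_med", bmi_adjusted),
        OutcomeModelSpec("hba1c", cov, "antidiabetic_med", bmi_adjusted),
    ]


def outcome_associations(
    hit_species: Sequence[str],
    abundance: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    exposures: pd.DataFrame,
    include_combined: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hit species and combined abundance vs SBP/DBP/HbA1c, with and without
    BMI adjustment.  Returns a tidy table (outcome, feature, bmi_adjusted,
    rho, p, q, n, n_excluded)."""
    if not len(hit_species):
        raise ValueError("hit set is empty")
    feats = abundance[list(hit_species)].copy()
    if include_combined:
        feats["combined_abundance"] = combined_abundance(abundance, list(hit_species))
    cov_all = pd.concat([covariates, exposures[["ahi", "odi", "t90"]]], axis=1)
    tables = []
    for bmi_adjusted in (False, True):
        for spec in default_outcome_models(bmi_adjusted):
            y = outcomes[spec.outcome]
            excluded = outcomes[spec.exclusion_flag].astype(bool)
            mask = (
                ~excluded
                & y.notna()
                & cov_all[list(spec.covariates)].notna().all(axis=1)
            )
            if mask.sum() == 0:
                raise ValueError(f"no participants left for outcome {spec.outcome!r}")
            d = design_matrix(cov_all.loc[mask, list(spec.covariates)])
            rho, p = partial_spearman_many(
                y[mask].to_numpy(float), feats.loc[mask].to_numpy(float), d
            )
            t = pd.DataFrame(
                {
                    "outcome": spec.outcome,
                    "feature": feats.columns,
                    "bmi_adjusted": bmi_adjusted,
                    "rho": rho,
                    "p": p,
                    "q": bh_adjust(p),
                    "n": int(mask.sum()),
                    "n_excluded": int((excluded & y.notna()).sum()),
                }
            )
            tables.append(t)
    return pd.concat(tables, ignore_index=True)
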