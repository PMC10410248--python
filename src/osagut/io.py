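"""Readers/writers for the pipeline's interchange formats.

Everything tabular is TSV (tab-separated, header row, UTF-8) with the
participant or species identifier as the first column; nested results and
manifests are JSON; GMM definitions use the flat text format documented in
:mod:`osagut.gmm`.  Readers validate identifier uniqueness and basic schema
constraints and raise with row/column context.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("osagut")

FLOAT_FORMAT = "%.10g"

FILENAMES = {
    "exposures": "exposures.tsv",
    "covariates": "covariates.tsv",
    "abundance": "abundance.tsv",
    "ko": "ko_profiles.tsv",
    "gmm_definitions": "gmm_definitions.txt",
    "recordings": "recordings.tsv",
    "events": "events.tsv",
    "outcomes": "outcomes.tsv",
    "truth": "truth.json",
}

_CATEGORICAL_COVARIATES = [
    "sex", "smoking", "physical_activity", "education",
    "birth_country", "season", "plate",
]
_BOOL_COVARIATES = [
    "metformin", "ppi", "antihypertensive_med", "lipid_med",
    "antibiotic_6mo", "lung_disease",
]


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label)


def _read_indexed(path, index_label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_label not in df.columns:
        raise ValueError(f"{path}: missing required column {index_label!r}")
    if df[index_label].duplicated().any():
        dup = df.loc[df[index_label].duplicated(), index_label].iloc[0]
        raise ValueError(f"{path}: duplicated id {dup!r}")
    return df.set_index(index_label)


def write_abundance(abundance: pd.DataFrame, path) -> None:
    write_table(abundance, path, index_label="participant_id")


def read_abundance(path, tolerance: float = 1e-6) -> pd.DataFrame:
    df = _read_indexed(path, "participant_id").astype(float)
    rowsums = df.sum(axis=1)
    bad = np.abs(rowsums - 1.0) > tolerance
    if bad.any():
        pid = rowsums.index[bad][0]
        raise ValueError(
            f"{path}: abundance row {pid!r} sums to {rowsums[bad].iloc[0]:.6f}, not 1"
        )
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundances")
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    write_table(cov, path, index_label="participant_id")


def read_covariates(path) -> pd.DataFrame:
    df = _read_indexed(path, "participant_id")
    for col in _CATEGORICAL_COVARIATES:
        if col in df:
            df[col] = pd.Categorical(df[col].astype("string"))
    for col in _BOOL_COVARIATES:
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_exposures(exp: pd.DataFrame, path) -> None:
    write_table(exp, path, index_label="participant_id")


def read_exposures(path) -> pd.DataFrame:
    return _read_indexed(path, "participant_id").astype(float)


def write_ko(ko: pd.DataFrame, path) -> None:
    write_table(ko, path)


def read_ko(path, known_species: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("species_id", "ko_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if known_species is not None:
        unknown = set(df["species_id"]) - set(known_species)
        if unknown:
            warnings.warn(f"{path}: {len(unknown)} unknown species in KO table; excluded")
            df = df[~df["species_id"].isin(unknown)]
    return df.reset_index(drop=True)


def write_results(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort, out_dir) -> dict[str, str]:
    """Write a generated cohort to ``out_dir``; returns file checksums."""
    from .gmm import write_gmm_file

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_exposures(cohort.exposures, out / FILENAMES["exposures"])
    write_covariates(cohort.covariates, out / FILENAMES["covariates"])
    write_abundance(cohort.abundance, out / FILENAMES["abundance"])
    write_ko(cohort.ko_profiles, out / FILENAMES["ko"])
    write_gmm_file(cohort.gmm_definitions, out / FILENAMES["gmm_definitions"])
    write_table(cohort.recordings, out / FILENAMES["recordings"], index_label="participant_id")
    write_table(cohort.events, out / FILENAMES["events"])
    write_table(cohort.outcomes, out / FILENAMES["outcomes"], index_label="participant_id")
    write_json(cohort.truth.to_dict(), out / FILENAMES["truth"])
    return {name: sha256_file(out / fname) for name, fname in FILENAMES.items()}
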