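"""Effect modification by hemoglobin: stratified partial Spearman
correlations with bootstrap standard errors and a two-group coefficient
comparison.

Participants are split at the sex-specific hemoglobin median (ties go to the
low stratum).  Within each stratum the partial Spearman correlation is
recomputed, its standard error estimated by a full-pipeline bootstrap
(participants resampled with replacement; ranks and covariate
residualization recomputed in every resample), and the pair of coefficients
compared with z = (rho_low - rho_high) / sqrt(se_low^2 + se_high^2) against a
standard normal.  The comparison is on the raw rho difference by default; a
Fisher-z variant is available behind a flag.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelSpec, bh_adjust, default_models, design_matrix, partial_spearman


def split_by_hemoglobin(covariates: pd.DataFrame) -> pd.Series:
    """Low/high stratum labels at the sex-specific hemoglobin median.

    Participants at or below their sex's median go to "low".  Missing
    hemoglobin or sex yields a missing label; an empty stratum in either sex
    is an error.
    """
    hb = covariates["hemoglobin"]
    sex = covariates["sex"].astype(str)
    labels = pd.Series(pd.NA, index=covariates.index, dtype="object")
    for s in sex.dropna().unique():
        mask = (sex == s) & hb.notna()
        if mask.sum() == 0:
            raise ValueError(f"no hemoglobin values for sex level {s!r}")
        med = hb[mask].median()
        labels[mask] = np.where(hb[mask] <= med, "low", "high")
    for s in sex.dropna().unique():
        sub = labels[sex == s].dropna()
        if len(sub) and (sub == "low").all() and len(sub) > 1:
            # degenerate only if *all* values tie at the median in one sex;
            # allowed (ties go low), but an empty "low" stratum cannot occur
            pass
    return labels


def bootstrap_se(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    b: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE: sample SD of the statistic over ``b`` resamples of rows
    with replacement.  Errors if the statistic is undefined (NaN or raising)
    in more than 10% of resamples."""
    if b < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    rng = np.random.default_rng(seed)
    n = len(data)
    values = np.empty(b)
    bad = 0
    for i in range(b):
        idx = rng.integers(0, n, size=n)
        try:
            values[i] = statistic(data.iloc[idx])
        except Exception:
            values[i] = np.nan
        if np.isnan(values[i]):
            bad += 1
    if bad > 0.1 * b:
        raise ValueError(f"statistic undefined in {bad}/{b} resamples")
    return float(np.nanstd(values, ddof=1))


def _bootstrap_partial_spearman_se(
    x: np.ndarray,
    y: np.ndarray,
    design: np.ndarray,
    b: int,
    rng: np.random.Generator,
    chunk: int = 100,
) -> float:
    """Vectorized full-pipeline bootstrap SE of the partial Spearman rho.

    Resamples participants, re-ranks and re-residualizes per resample; the
    normal equations are solved batched with a small ridge for resamples in
    which a one-hot column degenerates.
    """
    n, k = design.shape
    rhos = np.empty(b)
    pos = 0
    ridge = 1e-8 * np.eye(k)
    while pos < b:
        size = min(chunk, b - pos)
        idx = rng.integers(0, n, size=(size, n))
        rx = stats.rankdata(x[idx], axis=1)
        ry = stats.rankdata(y[idx], axis=1)
        d = design[idx]                                   # (size, n, k)
        dtd = np.einsum("bij,bik->bjk", d, d) + ridge
        m = np.stack([rx, ry], axis=2)                    # (size, n, 2)
        dtm = np.einsum("bij,bik->bjk", d, m)
        beta = np.linalg.solve(dtd, dtm)
        res = m - d @ beta
        ex, ey = res[..., 0], res[..., 1]
        num = (ex * ey).sum(axis=1)
        den = np.sqrt((ex**2).sum(axis=1) * (ey**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            rhos[pos : pos + size] = num / den
        pos += size
    bad = int(np.isnan(rhos).sum())
    if bad > 0.1 * b:
        raise ValueError(f"correlation undefined in {bad}/{b} bootstrap resamples")
    return float(np.nanstd(rhos, ddof=1))


def compare_correlations(
    rho_low: float,
    se_low: float,
    rho_high: float,
    se_high: float,
    fisher: bool = False,
    n_low: int | None = None,
    n_high: int | None = None,
) -> tuple[float, float]:
    """Two-group coefficient comparison: z on the raw rho difference with
    bootstrap SEs, two-sided normal p.  ``fisher=True`` compares atanh(rho)
    values with analytic 1/(n-3) variances instead."""
    if se_low <= 0 or se_high <= 0:
        raise ValueError("standard errors must be positive")
    if fisher:
        if n_low is None or n_high is None:
            raise ValueError("fisher variant needs stratum sizes")
        z = (np.arctanh(rho_low) - np.arctanh(rho_high)) / np.sqrt(
            1.0 / (n_low - 3) + 1.0 / (n_high - 3)
        )
    else:
        z = (rho_low - rho_high) / np.sqrt(se_low**2 + se_high**2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def heterogeneity_screen(
    hit_species: list[str],
    exposures: pd.DataFrame,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: pd.Series,
    model: ModelSpec | None = None,
    exposure_names: tuple[str, ...] = ("t90", "odi"),
    b: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stratified correlations and heterogeneity tests for the hit species.

    One row per (species, exposure); q-values are BH across species within
    each exposure.  Strata too small for the covariate set are skipped with a
    warning.
    """
    if model is None:
        model = default_models()["extended"]
    rng = np.random.default_rng(seed)
    rows = []
    for exp_name in exposure_names:
        prepared = {}
        skip_exposure = False
        for level in ("low", "high"):
            mask = (
                (strata == level).fillna(False)
                & exposures[exp_name].notna()
                & covariates[list(model.covariates)].notna().all(axis=1)
            )
            x = exposures.loc[mask, exp_name].to_numpy(float)
            d = design_matrix(covariates.loc[mask, list(model.covariates)])
            if len(x) <= d.shape[1] + 2:
                warnings.warn(f"stratum {level!r} too small for exposure {exp_name}; rows skipped")
                skip_exposure = True
            prepared[level] = (mask, x, d)
        if skip_exposure:
            continue
        for sp in hit_species:
            est = {}
            for level in ("low", "high"):
                mask, x, d = prepared[level]
                y = abundance.loc[mask, sp].to_numpy(float)
                rho, _, n = partial_spearman(
                    x, y, covariates.loc[mask, list(model.covariates)].reset_index(drop=True)
                )
                se = _bootstrap_partial_spearman_se(x, y, d, b, rng)
                est[level] = (rho, se, n)
            z, p = compare_correlations(est["low"][0], est["low"][1], est["high"][0], est["high"][1])
            rows.append(
                (
                    sp,
                    exp_name,
                    est["low"][0],
                    est["low"][1],
                    est["low"][2],
                    est["high"][0],
                    est["high"][1],
                    est["high"][2],
                    z,
                    p,
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature",
            "exposure",
            "rho_low",
            "se_low",
            "n_low",
            "rho_high",
            "se_high",
            "n_high",
            "z",
            "p_het",
        ],
    )
    if len(out):
        out["q_het"] = np.nan
        for exp_name in out["exposure"].unique():
            sel = out["exposure"] == exp_name
            out.loc[sel, "q_het"] = bh_adjust(out.loc[sel, "p_het"].to_numpy())
    return out
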