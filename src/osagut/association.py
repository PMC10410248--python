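"""Covariate-adjusted partial Spearman correlation and the model cascade.

The inference engine of the pipeline.  A partial Spearman correlation
rank-transforms the two variables (average ranks for ties), residualizes both
ranks on the covariate design matrix by least squares, and takes the Pearson
correlation of the residuals; the p-value uses t = rho sqrt((n-2-k)/(1-rho^2))
on n-2-k degrees of freedom, with k the number of non-intercept design
columns.

Species-level inference runs through a three-stage cascade: a screening model
(main-model covariates without BMI) over all prevalence-filtered species,
then the main model (with BMI) and the extended model over the screening
hits, with Benjamini-Hochberg adjustment within each (exposure, stage)
family.  The final hit set per exposure is the extended-model q < 0.05 set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FDR_DEFAULT = 0.05

SCREENING_COVARIATES = ["age", "sex", "smoking", "alcohol", "plate"]
MAIN_COVARIATES = SCREENING_COVARIATES + ["bmi"]
EXTENDED_COVARIATES = MAIN_COVARIATES + [
    "fiber",
    "energy",
    "physical_activity",
    "education",
    "birth_country",
    "season",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate set with optional participant exclusions."""

    name: str
    covariates: tuple[str, ...]
    exclusions: Callable[[pd.DataFrame], pd.Series] | None = None


def default_models() -> dict[str, ModelSpec]:
    return {
        "screening": ModelSpec("screening", tuple(SCREENING_COVARIATES)),
        "main": ModelSpec("main", tuple(MAIN_COVARIATES)),
        "extended": ModelSpec("extended", tuple(EXTENDED_COVARIATES)),
    }


# ---------------------------------------------------------------------------
# Design matrices and the correlation primitive
# ---------------------------------------------------------------------------

def design_matrix(covariates: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
    """Intercept + numeric columns as-is + one-hot (drop-first) categoricals.

    Categorical levels that are degenerate after subsetting (a single level)
    are dropped with a warning.
    """
    if covariates is None or covariates.shape[1] == 0:
        if n is None:
            raise ValueError("need n when no covariates are given")
        return np.ones((n, 1))
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "fiu" and not isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(col.to_numpy(float))
        elif col.dtype.kind == "b":
            cols.append(col.to_numpy(float))
        else:
            values = col.astype(str).to_numpy()
            levels = pd.unique(values)
            if len(levels) < 2:
                warnings.warn(f"covariate {name!r} has a single level after subsetting; dropped")
                continue
            for lv in levels[1:]:
                cols.append((values == lv).astype(float))
    return np.column_stack(cols)


def _residualize(m: np.ndarray, d: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(d, m, rcond=None)
    return m - d @ beta


def partial_spearman(
    x,
    y,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates.

    Complete cases only; returns (rho, p, n).  Raises on too-few
    observations (n <= k + 3) or zero-variance rank residuals.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float), index=x.index)
    mask = x.notna() & y.notna()
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= covariates.notna().all(axis=1)
    xs, ys = x[mask].to_numpy(), y[mask].to_numpy()
    cov = covariates[mask.to_numpy()] if covariates is not None else None
    if cov is not None:
        for name in cov.columns:
            col = cov[name]
            if col.dtype.kind in "fiu" and (
                np.array_equal(col.to_numpy(float), xs) or np.array_equal(col.to_numpy(float), ys)
            ):
                raise ValueError(f"covariate {name!r} is identical to a correlated variable")
    n = len(xs)
    d = design_matrix(cov, n=n)
    k = d.shape[1] - 1
    if n <= k + 3:
        raise ValueError(f"too few complete cases (n={n}) for {k} covariate columns")
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    res = _residualize(np.column_stack([rx, ry]), d)
    sx = np.sqrt((res[:, 0] ** 2).sum())
    sy = np.sqrt((res[:, 1] ** 2).sum())
    scale = np.sqrt(n) * max(rx.max(), 1.0)
    if sx <= 1e-12 * scale or sy <= 1e-12 * scale:
        raise ValueError("zero-variance rank residuals; correlation undefined")
    rho = float(res[:, 0] @ res[:, 1] / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p, n


def partial_spearman_many(
    x: np.ndarray,
    features: np.ndarray,
    design: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial Spearman of one exposure against many features.

    All inputs must already be complete cases; ``design`` includes the
    intercept.  Features with zero residual variance get NaN.  Returns
    (rho, p) arrays of length features.shape[1].
    """
    n, m = features.shape
    k = design.shape[1] - 1
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough observations for the covariate set")
    rx = stats.rankdata(x)
    rf = stats.rankdata(features, axis=0)
    res = _residualize(np.column_stack([rx, rf]), design)
    ex, ef = res[:, 0], res[:, 1:]
    sx = np.sqrt((ex**2).sum())
    sf = np.sqrt((ef**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ex @ ef) / (sx * sf)
    scale = np.sqrt(n) * n
    rho[sf <= 1e-12 * scale] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


# ---------------------------------------------------------------------------
# Multiple testing and filters
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[valid]
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[valid] = out
    return q


def prevalence_filter(abundance: pd.DataFrame, threshold: float = 0.01) -> list[str]:
    """Species present (abundance > 0) in more than ``threshold`` of
    participants; species at or below the threshold are removed."""
    prevalence = (abundance.to_numpy() > 0).mean(axis=0)
    return [s for s, pr in zip(abundance.columns, prevalence) if pr > threshold]


def combined_abundance(abundance: pd.DataFrame, species: Sequence[str]) -> pd.Series:
    """Row-wise summed relative abundance over a species set, in percent."""
    species = list(species)
    unknown = [s for s in species if s not in abundance.columns]
    if unknown:
        raise KeyError(f"unknown species ids: {unknown[:5]}")
    total = abundance[species].sum(axis=1) * 100.0 if species else pd.Series(0.0, index=abundance.index)
    total.name = "combined_abundance_pct"
    return total


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    table: pd.DataFrame                    # exposure, feature, model, stage, rho, p, q, n
    hits: dict[str, list[str]]             # final (extended-model) hits per exposure
    stage1_hits: dict[str, list[str]]
    retained_species: list[str]

    def hits_union(self, exposures: Sequence[str] = ("t90", "odi")) -> list[str]:
        out: list[str] = []
        for e in exposures:
            for s in self.hits.get(e, []):
                if s not in out:
                    out.append(s)
        return out


def _complete_case_mask(
    exposure: pd.Series, covariates: pd.DataFrame, model: ModelSpec
) -> pd.Series:
    mask = exposure.notna() & covariates[list(model.covariates)].notna().all(axis=1)
    if model.exclusions is not None:
        mask &= ~model.exclusions(covariates)
    return mask


def run_model(
    exposure: pd.Series,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    model: ModelSpec,
) -> pd.DataFrame:
    """All features against one exposure under one model (no FDR yet)."""
    mask = _complete_case_mask(exposure, covariates, model)
    sub_x = exposure[mask].to_numpy(float)
    sub_f = features.loc[mask].to_numpy(float)
    d = design_matrix(covariates.loc[mask, list(model.covariates)])
    rho, p = partial_spearman_many(sub_x, sub_f, d)
    return pd.DataFrame(
        {
            "feature": features.columns,
            "model": model.name,
            "rho": rho,
            "p": p,
            "n": int(mask.sum()),
        }
    )


def run_cascade(
    exposures: pd.DataFrame,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    models: dict[str, ModelSpec] | None = None,
    fdr: float = FDR_DEFAULT,
    screening_threshold: float | None = None,
    prevalence_threshold: float = 0.01,
    exposure_names: Sequence[str] = ("ahi", "t90", "odi"),
) -> CascadeResult:
    """Screening -> main -> extended cascade over all exposures.

    Stage 1 (screening model, no BMI) tests every retained species; stages 2
    (main model) and 3 (extended model) retest the stage-1 hits.  BH is
    applied within each (exposure, stage) family; complete-case samples are
    recomputed per exposure and model.  An empty stage-1 hit set simply
    yields empty downstream tables.
    """
    if models is None:
        models = default_models()
    if screening_threshold is None:
        screening_threshold = fdr
    retained = prevalence_filter(abundance, prevalence_threshold)
    feats = abundance[retained]
    tables: list[pd.DataFrame] = []
    hits: dict[str, list[str]] = {}
    stage1_hits: dict[str, list[str]] = {}
    for exp_name in exposure_names:
        exp = exposures[exp_name]
        t1 = run_model(exp, feats, covariates, models["screening"])
        t1["q"] = bh_adjust(t1["p"].to_numpy())
        t1.insert(0, "exposure", exp_name)
        t1["stage"] = 1
        tables.append(t1)
        s1 = t1.loc[t1["q"] < screening_threshold, "feature"].tolist()
        stage1_hits[exp_name] = s1
        if not s1:
            hits[exp_name] = []
            continue
        sub = feats[s1]
        for stage, key in ((2, "main"), (3, "extended")):
            t = run_model(exp, sub, covariates, models[key])
            t["q"] = bh_adjust(t["p"].to_numpy())
            t.insert(0, "exposure", exp_name)
            t["stage"] = stage
            tables.append(t)
            if stage == 3:
                hits[exp_name] = t.loc[t["q"] < fdr, "feature"].tolist()
    table = pd.concat(tables, ignore_index=True)
    return CascadeResult(table=table, hits=hits, stage1_hits=stage1_hits, retained_species=retained)


def diversity_associations(
    shannon: pd.Series,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    models: dict[str, ModelSpec] | None = None,
    exposure_names: Sequence[str] = ("ahi", "t90", "odi"),
) -> pd.DataFrame:
    """Shannon index vs each exposure under the main and extended models."""
    if models is None:
        models = default_models()
    feats = shannon.to_frame(name="shannon")
    rows = []
    for exp_name in exposure_names:
        for key in ("main", "extended"):
            t = run_model(exposures[exp_name], feats, covariates, models[key])
            t.insert(0, "exposure", exp_name)
            rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def sensitivity_suite(
    hits: dict[str, list[str]],
    exposures: pd.DataFrame,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr: float = FDR_DEFAULT,
    base_model: ModelSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-run the extended-model hits under four sensitivity variants.

    (1) medication covariates added; (2) waist-to-hip ratio added;
    (3) recent antibiotic users excluded; (4) lung-disease participants
    excluded.  Each variant reports which hits retain q < fdr.
    """
    if base_model is None:
        base_model = default_models()["extended"]
    med_cols = tuple(
        c for c in ("metformin", "ppi", "antihypertensive_med", "lipid_med") if c in covariates
    )
    variants = {
        "medications": ModelSpec("medications", base_model.covariates + med_cols),
        "whr": ModelSpec("whr", base_model.covariates + ("whr",)),
        "no_antibiotics": ModelSpec(
            "no_antibiotics", base_model.covariates,
            exclusions=lambda cov: cov["antibiotic_6mo"].astype(bool),
        ),
        "no_lung_disease": ModelSpec(
            "no_lung_disease", base_model.covariates,
            exclusions=lambda cov: cov["lung_disease"].astype(bool),
        ),
    }
    out: dict[str, pd.DataFrame] = {}
    for vname, model in variants.items():
        tables = []
        for exp_name, species in hits.items():
            if not species:
                continue
            mask = _complete_case_mask(exposures[exp_name], covariates, model)
            if mask.sum() == 0:
                raise ValueError(f"sensitivity variant {vname!r} empties the sample")
            t = run_model(exposures[exp_name], abundance[species], covariates, model)
            t["q"] = bh_adjust(t["p"].to_numpy())
            t["retained"] = t["q"] < fdr
            t.insert(0, "exposure", exp_name)
            tables.append(t)
        out[vname] = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["exposure", "feature", "model", "rho", "p", "n", "q", "retained"])
        )
    return out
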