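"""Multiple imputation of missing AHI by predictive mean matching (PMM),
with Rubin pooling of partial Spearman estimates.

PMM (type-1 matching): per imputation, the regression of the target on the
predictors is fit on the observed rows and the coefficients perturbed by a
draw from their approximate posterior (sigma^2 from a scaled inverse
chi-square draw, beta from the corresponding normal); each missing row's
perturbed prediction is matched to the k observed rows with the nearest
(unperturbed) predictions and one donor's observed value is drawn uniformly.
Observed values are never altered, and every imputed value is a member of
the observed donor pool.

Pooling follows Rubin's rules on the Fisher-z scale: z = atanh(rho) with
within-imputation variance 1/(n - 3 - k), between-imputation variance the
sample variance of the z's, total variance W + (1 + 1/m) B, and
small-sample degrees of freedom (m - 1)(1 + W / ((1 + 1/m) B))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelSpec, bh_adjust, default_models, design_matrix, partial_spearman


@dataclass(frozen=True)
class ImputationSpec:
    target: str
    predictors: tuple[str, ...]
    k_neighbors: int = 5
    m_imputations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be >= 2")


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float          # pooled mean on the input scale
    within_var: float
    between_var: float
    total_var: float
    df: float
    p: float


def pmm_impute(data: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of ``data`` with the target imputed.

    Predictors must be complete (categoricals are one-hot encoded).  With no
    missing targets the result is ``m`` identical copies of the input.
    """
    target = data[spec.target]
    pred = data[list(spec.predictors)]
    if pred.isna().any().any():
        raise ValueError("predictors must be complete (or previously completed)")
    d = design_matrix(pred)
    obs = target.notna().to_numpy()
    mis = ~obs
    n_obs, p_cols = int(obs.sum()), d.shape[1]
    if mis.sum() == 0:
        return [data.copy() for _ in range(spec.m_imputations)]
    if n_obs < p_cols + spec.k_neighbors:
        raise ValueError("fewer observed rows than predictors + k_neighbors")

    rng = np.random.default_rng(spec.seed)
    x_obs, y_obs = d[obs], target.to_numpy(float)[obs]
    x_mis = d[mis]
    xtx = x_obs.T @ x_obs + 1e-10 * np.eye(p_cols)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (x_obs.T @ y_obs)
    resid = y_obs - x_obs @ beta_hat
    dof = max(n_obs - p_cols, 1)
    sse = float(resid @ resid)
    yhat_obs = x_obs @ beta_hat
    chol = np.linalg.cholesky(xtx_inv)

    completed = []
    mis_idx = np.flatnonzero(mis)
    for _ in range(spec.m_imputations):
        sigma2 = sse / rng.chisquare(dof)
        beta_star = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p_cols))
        yhat_mis = x_mis @ beta_star
        dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
        donors = np.argpartition(dist, spec.k_neighbors - 1, axis=1)[:, : spec.k_neighbors]
        pick = donors[np.arange(len(mis_idx)), rng.integers(0, spec.k_neighbors, size=len(mis_idx))]
        filled = data.copy()
        col = filled[spec.target].to_numpy(float)
        col[mis_idx] = y_obs[pick]
        filled[spec.target] = col
        completed.append(filled)
    return completed


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine per-imputation (estimate, variance) pairs on a common scale.

    The pooled estimate is the mean; total variance = W + (1 + 1/m) B;
    p-value from a t reference with the standard small-sample df.  Zero
    within- and between-variance together is an error (no uncertainty to
    pool).  For correlations, pool Fisher-z values and back-transform the
    pooled estimate (as :func:`imputed_cascade` does).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2:
        raise ValueError("need at least two imputations to pool")
    z_bar = est.mean()
    w = var.mean()
    b = est.var(ddof=1)
    total = w + (1.0 + 1.0 / m) * b
    if total <= 0:
        raise ValueError("zero within- and between-imputation variance")
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = np.inf
    t = z_bar / np.sqrt(total)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PooledEstimate(
        estimate=float(z_bar),
        within_var=float(w),
        between_var=float(b),
        total_var=float(total),
        df=float(df),
        p=p,
    )


def _fisher_z_variance(n: int, k: int) -> float:
    d = n - 3 - k
    if d <= 0:
        raise ValueError("not enough observations for the Fisher-z variance")
    return 1.0 / d


def imputed_cascade(
    exposures: pd.DataFrame,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    species: list[str],
    shannon: pd.Series | None = None,
    model: ModelSpec | None = None,
    m_imputations: int = 10,
    k_neighbors: int = 5,
    seed: int = 0,
    rank_abundance: bool = True,
) -> pd.DataFrame:
    """Pooled AHI associations for each species after multiple imputation.

    A separate imputation round is run per species (its own abundance among
    the predictors, rank-transformed by default, alongside the extended-model
    covariates, Shannon index, T90, ODI and waist-to-hip ratio).  Rows with
    missing predictors are dropped before imputation; per completed dataset
    the partial Spearman of imputed AHI vs the species is computed, Fisher-z
    transformed, pooled with Rubin's rules, and BH-adjusted across species.
    """
    if model is None:
        model = default_models()["extended"]
    if shannon is None:
        from .diversity import shannon_table

        shannon = shannon_table(abundance)
    rows = []
    base = covariates[list(model.covariates)].copy()
    extra = pd.DataFrame(
        {
            "shannon": shannon,
            "t90": exposures["t90"],
            "odi": exposures["odi"],
        },
        index=covariates.index,
    )
    if "whr" in covariates:
        extra["whr"] = covariates["whr"]
    rng = np.random.default_rng(seed)
    for sp in species:
        ab = abundance[sp]
        if rank_abundance:
            ab = pd.Series(stats.rankdata(ab), index=ab.index)
        frame = pd.concat(
            [exposures[["ahi"]], base, extra, ab.rename("species_abundance")], axis=1
        )
        complete_pred = frame.drop(columns=["ahi"]).notna().all(axis=1)
        frame = frame.loc[complete_pred].reset_index(drop=True)
        spec = ImputationSpec(
            target="ahi",
            predictors=tuple(c for c in frame.columns if c != "ahi"),
            k_neighbors=k_neighbors,
            m_imputations=m_imputations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        completed = pmm_impute(frame, spec)
        zs, vs, n_used = [], [], 0
        for filled in completed:
            rho, _, n = partial_spearman(
                filled["ahi"],
                filled["species_abundance"],
                filled[list(model.covariates)],
            )
            k_cols = design_matrix(filled[list(model.covariates)]).shape[1] - 1
            zs.append(np.arctanh(np.clip(rho, -0.999999, 0.999999)))
            vs.append(_fisher_z_variance(n, k_cols))
            n_used = n
        pooled = rubin_pool(zs, vs)
        rho_pooled = float(np.tanh(pooled.estimate))
        rows.append((sp, rho_pooled, pooled.p, pooled.within_var, pooled.between_var, pooled.total_var, pooled.df, n_used))
    out = pd.DataFrame(
        rows,
        columns=["feature", "rho", "p", "within_var", "between_var", "total_var", "df", "n"],
    )
    out.insert(0, "exposure", "ahi")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out
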