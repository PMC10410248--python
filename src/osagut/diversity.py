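"""Alpha/beta diversity, ordination and permutation-based group testing.

Implements Shannon entropy, Bray-Curtis dissimilarity, classical principal
coordinate analysis (metric multidimensional scaling on the double-centered
Gower matrix) and a covariate-adjusted PERMANOVA with sequential
(covariates-first) sums of squares, all from first principles on numpy.

PERMANOVA follows the trace identities of the distance-based linear model:
with the Gower-centered matrix G = -1/2 J D^2 J and symmetric idempotent hat
matrices H, sums of squares are traces tr(H G), and the pseudo-F for the
group term entered after the covariates is

    F = [tr((H_full - H_cov) G) / df1] / [tr((I - H_full) G) / df2].

The permutation null permutes raw rows (rows/columns of G jointly); a
Freedman-Lane residual permutation is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.isfinite(d).all():
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.d = d


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray        # participants x axes
    eigenvalues: np.ndarray        # full spectrum, descending (may be negative)
    explained_variance: np.ndarray  # per returned axis, eigenvalue / sum(positive)


def shannon_index(abundances, base: str = "e") -> float:
    """Shannon entropy H = -sum p_i log p_i of one composition.

    Abundances are renormalized; zero entries contribute nothing.  Natural
    log by default, ``base="2"`` for bits.
    """
    p = np.asarray(abundances, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single abundance row")
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance row")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return h


def shannon_table(abundance: pd.DataFrame, base: str = "e") -> pd.Series:
    """Shannon index per participant row."""
    x = abundance.to_numpy(float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero abundance row")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if base == "2":
        h = h / np.log(2.0)
    return pd.Series(h, index=abundance.index, name="shannon")


def bray_curtis(abundance: pd.DataFrame, chunk: int = 64) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    x = abundance.to_numpy(float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    rowsums = x.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("each row needs at least one positive entry")
    n = x.shape[0]
    d = np.zeros((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = x[start:stop]
        num = np.abs(block[:, None, :] - x[None, :, :]).sum(axis=2)
        den = rowsums[start:stop, None] + rowsums[None, :]
        d[start:stop] = num / den
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against fp noise
    return DistanceMatrix(ids=list(abundance.index.astype(str)), d=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Eigendecomposition of the double-centered Gower matrix; axes ordered by
    eigenvalue.  Negative eigenvalues are retained in the spectrum but
    excluded from the explained-variance denominator, and no corrective
    constant is added.  Requesting more axes than there are positive
    eigenvalues truncates with a warning.
    """
    g = _gower_center(dm.d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if eigvals.size else 0.0
    n_pos = int((eigvals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating")
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[eigvals > tol].sum()
    explained = eigvals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return OrdinationResult(ids=list(dm.ids), coordinates=coords, eigenvalues=eigvals, explained_variance=explained)


def group_centroids(ordination: OrdinationResult, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean and standard error (SD/sqrt(m)) on each axis.

    Singleton groups get missing SEs.
    """
    coords = pd.DataFrame(
        ordination.coordinates,
        index=pd.Index(ordination.ids),
        columns=[f"axis{i + 1}" for i in range(ordination.coordinates.shape[1])],
    )
    g = pd.Series(np.asarray(groups), index=coords.index) if len(groups) == len(coords) else groups
    rows = []
    for level, sub in coords.groupby(g.astype(str), observed=True):
        m = len(sub)
        mean = sub.mean()
        se = sub.std(ddof=1) / np.sqrt(m) if m > 1 else pd.Series(np.nan, index=sub.columns)
        row = {"group": level, "n": m}
        row.update({f"mean_{c}": mean[c] for c in sub.columns})
        row.update({f"se_{c}": se[c] for c in sub.columns})
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _group_design(groups: np.ndarray) -> np.ndarray:
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two group levels")
    return np.column_stack([(groups == lv).astype(float) for lv in levels[1:]])


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept + standardized numeric columns + one-hot categoricals."""
    cols = [np.ones(n)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "fiu" and not isinstance(col.dtype, pd.CategoricalDtype):
                v = col.to_numpy(float)
                sd = v.std()
                cols.append((v - v.mean()) / sd if sd > 0 else np.zeros(n))
            else:
                values = col.astype(str).to_numpy()
                for lv in pd.unique(values)[1:]:
                    cols.append((values == lv).astype(float))
    return np.column_stack(cols)


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    df_group: int
    df_resid: int
    n: int
    n_permutations: int


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "raw",
) -> PermanovaResult:
    """Covariate-adjusted PERMANOVA for a single group term.

    Covariates enter before the group term (sequential sums of squares); the
    permutation p-value is (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    ``method="raw"`` permutes raw rows; ``method="freedman-lane"`` permutes
    the covariate-residualized Gower matrix.  R^2 is SS_group / SS_total.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    g_arr = np.asarray(groups)
    mask = ~pd.isna(g_arr)
    if covariates is not None:
        mask &= covariates.notna().all(axis=1).to_numpy()
    idx = np.flatnonzero(mask)
    n = len(idx)
    g_arr = g_arr[idx].astype(str)
    d = dm.d[np.ix_(idx, idx)]
    cov = covariates.iloc[idx] if covariates is not None else None

    z = _covariate_design(cov, n)
    x = _group_design(g_arr)
    h_cov, rank_cov = _hat(z)
    h_full, rank_full = _hat(np.column_stack([z, x]))
    df1 = rank_full - rank_cov
    if df1 == 0:
        raise ValueError("group term is collinear with the covariates")
    df2 = n - rank_full
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")

    g_mat = _gower_center(d)
    m_group = h_full - h_cov
    m_resid = np.eye(n) - h_full

    def f_stat(gm: np.ndarray) -> tuple[float, float]:
        ss_g = float((m_group * gm).sum())
        ss_r = float((m_resid * gm).sum())
        return ss_g, ss_r

    ss_group, ss_resid = f_stat(g_mat)
    ss_total = float(np.trace(g_mat))
    f_obs = (ss_group / df1) / (ss_resid / df2)

    rng = np.random.default_rng(seed)
    if method == "freedman-lane":
        r_mat = (np.eye(n) - h_cov) @ g_mat @ (np.eye(n) - h_cov)
        base = g_mat - r_mat
    elif method != "raw":
        raise ValueError("method must be 'raw' or 'freedman-lane'")
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if method == "raw":
            gp = g_mat[np.ix_(p, p)]
        else:
            gp = base + r_mat[np.ix_(p, p)]
        ss_g, ss_r = f_stat(gp)
        fp = (ss_g / df1) / (ss_r / df2) if ss_r > 0 else np.inf
        if fp >= f_obs:
            count += 1
    p_value = (1.0 + count) / (1.0 + n_permutations)
    return PermanovaResult(
        r2=ss_group / ss_total,
        pseudo_f=f_obs,
        p=p_value,
        df_group=df1,
        df_resid=df2,
        n=n,
        n_permutations=n_permutations,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """The same contract applied to every pair of group levels."""
    g_arr = pd.Series(np.asarray(groups).astype(object))
    levels = [lv for lv in pd.unique(g_arr.dropna()) if lv is not None]
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            sel = g_arr.isin([a, b]).to_numpy()
            sub_ids = [dm.ids[k] for k in np.flatnonzero(sel)]
            sub = DistanceMatrix(ids=sub_ids, d=dm.d[np.ix_(sel, sel)])
            sub_groups = pd.Series(g_arr[sel].astype(str).to_numpy())
            sub_cov = covariates.iloc[np.flatnonzero(sel)] if covariates is not None else None
            res = permanova(
                sub, sub_groups, sub_cov, n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append((str(a), str(b), res.r2, res.pseudo_f, res.p, res.n))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "r2", "pseudo_f", "p", "n"])
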