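"""Probabilistic pairwise species co-occurrence.

Under random, independent placement of two species across n sites, the
number of shared sites follows a hypergeometric law; the probability of
observing at least (p_gt) or at most (p_lt) the observed co-occurrence count
classifies the pair as positively associated, negatively associated, or
random at a significance level alpha.  Pairs whose prevalences make any
detectable deviation impossible at alpha are flagged untestable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CooccurrencePair:
    species_a: str
    species_b: str
    n_sites: int
    prevalence_a: int
    prevalence_b: int
    obs_cooccur: int
    exp_cooccur: float
    p_lt: float
    p_gt: float
    classification: str  # positive | negative | random
    testable: bool


def presence_matrix(abundance: pd.DataFrame, species: list[str] | None = None) -> pd.DataFrame:
    """Boolean participants x species matrix; presence = abundance > 0."""
    cols = list(species) if species is not None else list(abundance.columns)
    missing = [s for s in cols if s not in abundance.columns]
    if missing:
        raise KeyError(f"species not in abundance matrix: {missing[:5]}")
    return abundance[cols] > 0


def pair_probability(n_sites: int, prev_a: int, prev_b: int, obs: int) -> tuple[float, float, float]:
    """(p_lt, p_gt, expected) for an observed co-occurrence count.

    p_gt = P(X >= obs), p_lt = P(X <= obs) under X ~ Hypergeometric
    (n_sites, prev_a, prev_b); both include the observed point mass.
    """
    if prev_a > n_sites or prev_b > n_sites:
        raise ValueError("prevalence cannot exceed the number of sites")
    lo = max(0, prev_a + prev_b - n_sites)
    hi = min(prev_a, prev_b)
    if not lo <= obs <= hi:
        raise ValueError(f"observed count {obs} outside the support [{lo}, {hi}]")
    dist = stats.hypergeom(n_sites, prev_a, prev_b)
    p_gt = float(dist.sf(obs - 1))
    p_lt = float(dist.cdf(obs))
    exp = prev_a * prev_b / n_sites
    return p_lt, p_gt, exp


def _classify(p_lt: float, p_gt: float, alpha: float) -> str:
    if p_gt < alpha:
        return "positive"
    if p_lt < alpha:
        return "negative"
    return "random"


def build_network(presence: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Evaluate all species pairs; returns the tidy pair table.

    A pair is untestable when even the most extreme attainable co-occurrence
    count (either end of the hypergeometric support) could not reach alpha.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least two species")
    n_sites = presence.shape[0]
    pres = presence.to_numpy(bool)
    prev = pres.sum(axis=0)
    co = pres.T.astype(int) @ pres.astype(int)
    rows = []
    cols = list(presence.columns)
    for i, j in combinations(range(len(cols)), 2):
        obs = int(co[i, j])
        p_lt, p_gt, exp = pair_probability(n_sites, int(prev[i]), int(prev[j]), obs)
        dist = stats.hypergeom(n_sites, int(prev[i]), int(prev[j]))
        lo = max(0, int(prev[i]) + int(prev[j]) - n_sites)
        hi = min(int(prev[i]), int(prev[j]))
        min_p_gt = float(dist.sf(hi - 1))    # smallest attainable upper tail
        min_p_lt = float(dist.cdf(lo))       # smallest attainable lower tail
        testable = (min_p_gt < alpha) or (min_p_lt < alpha)
        rows.append(
            CooccurrencePair(
                species_a=cols[i],
                species_b=cols[j],
                n_sites=n_sites,
                prevalence_a=int(prev[i]),
                prevalence_b=int(prev[j]),
                obs_cooccur=obs,
                exp_cooccur=exp,
                p_lt=p_lt,
                p_gt=p_gt,
                classification=_classify(p_lt, p_gt, alpha),
                testable=testable,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def edge_list(network: pd.DataFrame) -> pd.DataFrame:
    """Non-random, testable pairs only (the drawn network edges)."""
    sel = (network["classification"] != "random") & network["testable"]
    return network.loc[sel].reset_index(drop=True)
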