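"""Synthetic cohort generator for OSA-microbiota association studies.

Generates cohorts with the statistical structure the downstream analysis
assumes -- right-skewed, mutually correlated OSA exposures (AHI, ODI, T90)
driven by a latent hypoxia-severity factor; BMI confounding; a compositional,
zero-inflated species abundance matrix with planted exposure effects; KO
profiles and gut metabolic module (GMM) definitions with planted functional
enrichment; nocturnal event records that reproduce the tabulated parameters;
and blood-pressure/HbA1c outcomes with planted species effects.

Every generated quantity is accompanied by a ground-truth ledger
(:class:`SyntheticTruth`) so that recovery of planted structure can be scored.
All randomness flows from ``CohortConfig.seed`` through independent
``numpy.random.Generator`` streams; identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gmm import GMMDefinition, required_steps

EXPOSURES = ("ahi", "t90", "odi")

# Marginal parameters of the exposure distributions.  AHI and ODI are
# log-normal in the latent normal score; T90 is a shifted log-normal hurdle
# (values below the shift are the "T90 = 0" group).  Location/scale chosen so
# the medians and interquartile ranges sit near typical population-screening
# values (AHI median ~3.8 events/h, ODI ~4.1 events/h, T90 ~2%).
_AHI_MU, _AHI_SIGMA = 1.335, 1.296
_ODI_MU, _ODI_SIGMA = 1.411, 1.251
_T90_MU, _T90_SIGMA = 1.072, 2.2

# Stream offsets: one independent child generator per generation stage.
_S_EXPOSURE, _S_COVARIATE, _S_ABUNDANCE, _S_KO, _S_EVENTS, _S_OUTCOMES = range(6)


def _rng(config: "CohortConfig", stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Effect sizes are latent-scale slopes: a species planted with
    ``effect_size`` beta has latent log-abundance ``beta * latent_severity``
    plus unit noise.  ``confounding_strength`` is the correlation between BMI
    and the latent severity factor (the BMI->exposure / BMI->abundance
    backdoor path weight).
    """

    n_participants: int = 2000
    n_species: int = 300
    n_ko: int = 1500
    n_gmm: int = 20
    n_true_pos: int = 15
    n_true_neg: int = 15
    n_confounded: int = 10
    n_planted_gmm: int = 3
    n_outcome_species: int = 3
    effect_size: float = 0.5
    bp_effect: float = 2.5
    hba1c_effect: float = 0.0
    confounding_strength: float = 0.3
    missing_ahi_fraction: float = 0.10
    missing_mechanism: str = "MCAR"  # "MCAR" or "MAR" (on BMI)
    covariate_missing_fraction: float = 0.03
    zero_inflation: float = 0.30
    t90_zero_fraction: float = 0.30
    rho_ahi_odi: float = 0.92
    rho_ahi_t90: float = 0.56
    rho_t90_odi: float = 0.63
    antihypertensive_prevalence: float = 0.18
    antidiabetic_prevalence: float = 0.04
    metformin_prevalence: float = 0.03
    ppi_prevalence: float = 0.03
    lipid_med_prevalence: float = 0.07
    antibiotic_prevalence: float = 0.10
    lung_disease_prevalence: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_species <= 0 or self.n_ko <= 0 or self.n_gmm <= 0:
            raise ValueError("n_species, n_ko and n_gmm must be positive")
        if self.n_true_pos + self.n_true_neg > self.n_species:
            raise ValueError("n_true_pos + n_true_neg exceeds n_species")
        for name in (
            "missing_ahi_fraction",
            "covariate_missing_fraction",
            "zero_inflation",
            "t90_zero_fraction",
            "antihypertensive_prevalence",
            "antidiabetic_prevalence",
            "metformin_prevalence",
            "ppi_prevalence",
            "lipid_med_prevalence",
            "antibiotic_prevalence",
            "lung_disease_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rho_ahi_odi", "rho_ahi_t90", "rho_t90_odi"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a correlation in [-1, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted-effect ledger: which features truly respond, and how."""

    positive_species: frozenset[str]
    negative_species: frozenset[str]
    null_species: frozenset[str]
    confounded_species: frozenset[str]
    planted_gmms: frozenset[str]
    outcome_species: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_species & self.negative_species:
            raise ValueError("positive and negative species sets overlap")
        if (self.positive_species | self.negative_species) & self.null_species:
            raise ValueError("null species overlap planted species")

    def to_dict(self) -> dict:
        return {k: sorted(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**{k: frozenset(v) for k, v in d.items()})


def species_ids(config: CohortConfig) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(config.n_species)]


def participant_ids(config: CohortConfig) -> list[str]:
    return [f"P{i + 1:05d}" for i in range(config.n_participants)]


def plant_truth(config: CohortConfig) -> SyntheticTruth:
    """Assign planted roles to species ids (deterministic given the config)."""
    ids = species_ids(config)
    pos = ids[: config.n_true_pos]
    neg = ids[config.n_true_pos : config.n_true_pos + config.n_true_neg]
    null = ids[config.n_true_pos + config.n_true_neg :]
    confounded = null[: min(config.n_confounded, len(null))]
    outcome = pos[: min(config.n_outcome_species, len(pos))]
    planted_gmms = [f"MF{i + 1:04d}" for i in range(min(config.n_planted_gmm, config.n_gmm))]
    return SyntheticTruth(
        positive_species=frozenset(pos),
        negative_species=frozenset(neg),
        null_species=frozenset(null),
        confounded_species=frozenset(confounded),
        planted_gmms=frozenset(planted_gmms),
        outcome_species=frozenset(outcome),
    )


# ---------------------------------------------------------------------------
# Exposures
# ---------------------------------------------------------------------------

def _latent_exposure_normals(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw (z_ahi, z_odi, z_t90) from the target correlation matrix.

    Uses an eigen-factorization so degenerate (perfectly correlated) targets
    are representable: with all correlations 1 the three columns coincide.
    """
    r = np.array(
        [
            [1.0, config.rho_ahi_odi, config.rho_ahi_t90],
            [config.rho_ahi_odi, 1.0, config.rho_t90_odi],
            [config.rho_ahi_t90, config.rho_t90_odi, 1.0],
        ]
    )
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError("exposure correlation targets do not form a valid correlation matrix")
    root = v * np.sqrt(np.clip(w, 0.0, None))
    e = rng.standard_normal((config.n_participants, 3))
    return e @ root.T


def generate_exposures(config: CohortConfig) -> pd.DataFrame:
    """Per-participant latent severity and the three OSA parameters.

    The latent severity factor is the ODI latent normal (ODI being the purest
    intermittent-hypoxia measure); AHI and T90 latents correlate with it per
    the configured targets.  Marginals: AHI and ODI are log-normal; T90 is a
    shifted log-normal with a point mass at zero sized by
    ``t90_zero_fraction``, capped at 100%.
    """
    rng = _rng(config, _S_EXPOSURE)
    z = _latent_exposure_normals(config, rng)
    z_ahi, z_odi, z_t90 = z[:, 0], z[:, 1], z[:, 2]
    ahi = np.exp(_AHI_MU + _AHI_SIGMA * z_ahi)
    odi = np.exp(_ODI_MU + _ODI_SIGMA * z_odi)
    if config.t90_zero_fraction > 0:
        shift = np.exp(_T90_MU + _T90_SIGMA * stats.norm.ppf(config.t90_zero_fraction))
    else:
        shift = 0.0
    t90 = np.clip(np.exp(_T90_MU + _T90_SIGMA * z_t90) - shift, 0.0, 100.0)
    return pd.DataFrame(
        {"latent_severity": z_odi, "ahi": ahi, "odi": odi, "t90": t90},
        index=pd.Index(participant_ids(config), name="participant_id"),
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

_SMOKING = ("never", "former", "current")
_EDUCATION = ("incomplete_compulsory", "compulsory", "upper_secondary", "university")
_PHYSACT = ("sedentary", "moderate", "regular_moderate", "regular_exercise")
_BIRTH = ("scandinavia", "europe", "asia", "other")
_SEASONS = tuple(f"season_{i + 1:02d}" for i in range(11))


def _categorical(rng, n, levels, probs) -> pd.Categorical:
    draws = rng.choice(len(levels), size=n, p=probs)
    return pd.Categorical.from_codes(draws, categories=list(levels))


def generate_covariates(config: CohortConfig, exposures: pd.DataFrame) -> pd.DataFrame:
    """Questionnaire/anthropometric covariate table.

    BMI carries the confounding path: it correlates with latent severity by
    ``confounding_strength``.  Hemoglobin has a sex-specific location shift.
    Fiber/energy get a small MCAR missing fraction so the extended model's
    complete-case sample is smaller than the main model's, as in a real
    questionnaire-based cohort.
    """
    rng = _rng(config, _S_COVARIATE)
    n = config.n_participants
    sev = exposures["latent_severity"].to_numpy()

    w = config.confounding_strength
    bmi_latent = w * sev + np.sqrt(max(0.0, 1.0 - w**2)) * rng.standard_normal(n)
    bmi = 26.5 + 3.5 * bmi_latent
    whr = np.clip(0.93 + 0.05 * bmi_latent + 0.04 * rng.standard_normal(n), 0.6, 1.4)

    sex = _categorical(rng, n, ("female", "male"), (0.53, 0.47))
    male = (np.asarray(sex) == "male").astype(float)
    hemoglobin = 134.0 + 13.0 * male + 9.0 * rng.standard_normal(n)

    age = rng.uniform(50.0, 64.0, size=n)
    alcohol = np.exp(rng.normal(1.6, 0.9, size=n))
    fiber = np.exp(rng.normal(2.9, 0.45, size=n))
    energy = np.exp(rng.normal(np.log(1611.0), 0.35, size=n))

    n_plates = max(8, int(np.ceil(n / 96)))
    plate = pd.Categorical.from_codes(
        rng.integers(0, n_plates, size=n), categories=[f"plate_{i + 1:02d}" for i in range(n_plates)]
    )

    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "whr": whr,
            "smoking": _categorical(rng, n, _SMOKING, (0.55, 0.37, 0.08)),
            "alcohol": alcohol,
            "fiber": fiber,
            "energy": energy,
            "physical_activity": _categorical(rng, n, _PHYSACT, (0.10, 0.46, 0.32, 0.12)),
            "education": _categorical(rng, n, _EDUCATION, (0.02, 0.06, 0.40, 0.52)),
            "birth_country": _categorical(rng, n, _BIRTH, (0.90, 0.04, 0.04, 0.02)),
            "season": _categorical(rng, n, _SEASONS, np.full(11, 1 / 11)),
            "plate": plate,
            "hemoglobin": hemoglobin,
            "metformin": rng.random(n) < config.metformin_prevalence,
            "ppi": rng.random(n) < config.ppi_prevalence,
            "antihypertensive_med": rng.random(n) < config.antihypertensive_prevalence,
            "lipid_med": rng.random(n) < config.lipid_med_prevalence,
            "antibiotic_6mo": rng.random(n) < config.antibiotic_prevalence,
            "lung_disease": rng.random(n) < config.lung_disease_prevalence,
        },
        index=exposures.index,
    )
    if config.covariate_missing_fraction > 0:
        for col in ("fiber", "energy"):
            mask = rng.random(n) < config.covariate_missing_fraction
            cov.loc[mask, col] = np.nan
    return cov


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

def generate_abundances(
    config: CohortConfig,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Participants x species relative abundance matrix (rows sum to 1).

    Latent model: per-species log-abundance is a Gaussian with a planted
    severity slope (``+effect_size`` for positive species, ``-`` for negative),
    a BMI loading for the confounded species, and unit noise; abundances are
    left-censored at a per-species detection quantile to create zero inflation
    whose prevalence spectrum includes species rare enough to hit the
    prevalence filter.  Rows are closed to sum 1.
    """
    rng = _rng(config, _S_ABUNDANCE)
    n, m = config.n_participants, config.n_species
    ids = species_ids(config)
    sev = exposures["latent_severity"].to_numpy()
    bmi = covariates["bmi"].to_numpy()
    bmi_z = (bmi - bmi.mean()) / bmi.std()

    beta = np.zeros(m)
    gamma = np.zeros(m)
    pos = np.array([s in truth.positive_species for s in ids])
    neg = np.array([s in truth.negative_species for s in ids])
    conf = np.array([s in truth.confounded_species for s in ids])
    beta[pos] = config.effect_size
    beta[neg] = -config.effect_size
    gamma[conf] = 0.35

    base_mu = rng.normal(-1.0, 2.0, size=m)       # heterogeneous mean log-abundance
    sigma = rng.uniform(0.5, 1.5, size=m)          # per-species dispersion
    # pair positive/negative planted species on size and dispersion so their
    # opposite severity effects cancel in the row totals to first order;
    # otherwise the closure operation would push a severity signal into every
    # null species' relative abundance
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(neg)
    n_pair = min(len(pos_idx), len(neg_idx))
    base_mu[neg_idx[:n_pair]] = base_mu[pos_idx[:n_pair]]
    sigma[neg_idx[:n_pair]] = sigma[pos_idx[:n_pair]]

    # Zero-inflation: per-species censoring probability.  Planted species are
    # kept prevalent; a small tail of null species is made rare (<1% prevalence)
    # to exercise the prevalence filter.
    zi = config.zero_inflation
    if zi > 0:
        a = max(zi * 4.0, 1e-6)
        b = max((1.0 - zi) * 4.0, 1e-6)
        pi = rng.beta(a, b, size=m)
    else:
        pi = np.zeros(m)
    pi[pos | neg] = np.minimum(pi[pos | neg], 0.4)
    n_rare = max(3, m // 30)
    rare_candidates = np.flatnonzero(~(pos | neg | conf))
    rare = rare_candidates[-n_rare:]
    pi[rare] = rng.uniform(0.992, 0.999, size=len(rare))

    g = beta[None, :] * sev[:, None] + gamma[None, :] * bmi_z[:, None]
    g = g + rng.standard_normal((n, m))
    with np.errstate(over="ignore"):
        raw = np.exp(base_mu[None, :] + sigma[None, :] * g)
    # left-censor: zero where the latent score is below the species' detection
    # quantile (couples rarity with low abundance, like a detection limit)
    thresh = stats.norm.ppf(np.clip(pi, 1e-12, 1 - 1e-12))
    g_std = (g - (beta * sev.mean())[None, :]) / np.sqrt(beta**2 * sev.var() + gamma**2 + 1.0)[None, :]
    raw[g_std < thresh[None, :]] = 0.0

    rowsum = raw.sum(axis=1)
    if np.any(rowsum <= 0):
        # pathological configs (extreme zero inflation): give empty rows the
        # single most prevalent species so closure is defined
        j = int(np.argmin(pi))
        raw[rowsum <= 0, j] = 1.0
        rowsum = raw.sum(axis=1)
    rel = raw / rowsum[:, None]
    return pd.DataFrame(rel, index=exposures.index, columns=ids)


# ---------------------------------------------------------------------------
# KO profiles and GMM definitions
# ---------------------------------------------------------------------------

def generate_gmm_definitions(config: CohortConfig, rng: np.random.Generator | None = None) -> list[GMMDefinition]:
    """Synthetic gut metabolic module definitions (2-8 steps, some with
    alternative paths) over a synthetic KO universe, exercising all three
    detection-rule branches (all-steps, two-thirds, alternative paths)."""
    if rng is None:
        rng = _rng(config, _S_KO)
    universe = [f"K{i + 1:05d}" for i in range(config.n_ko)]
    perm = rng.permutation(config.n_ko)
    cursor = 0
    defs: list[GMMDefinition] = []
    for i in range(config.n_gmm):
        paths = []
        n_paths = 2 if rng.random() < 0.2 else 1
        for _ in range(n_paths):
            n_steps = int(rng.integers(2, 9))
            steps = []
            for _ in range(n_steps):
                k = int(rng.integers(1, 4))
                if cursor + k > config.n_ko:
                    cursor = 0  # wrap (tiny KO universes in tests)
                steps.append(frozenset(universe[perm[j]] for j in range(cursor, cursor + k)))
                cursor += k
            paths.append(tuple(steps))
        defs.append(GMMDefinition(id=f"MF{i + 1:04d}", name=f"synthetic pathway {i + 1}", paths=tuple(paths)))
    return defs


def generate_ko_profiles(
    config: CohortConfig,
    truth: SyntheticTruth,
    gmms: Sequence[GMMDefinition],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format (species_id, ko_id) annotation table.

    Planted GMMs are carried (one full path) by positive species with high
    probability and by other species rarely; non-planted GMMs are carried at a
    uniform background rate.  A share of carriers receive only the minimal
    step coverage required by the detection rule, and some non-carriers a
    near-miss coverage one step short, so both sides of the rule boundary
    occur in the data.
    """
    if rng is None:
        rng = _rng(config, _S_KO)
        generate_gmm_definitions(config, rng)  # advance stream identically
    ids = species_ids(config)
    universe = [f"K{i + 1:05d}" for i in range(config.n_ko)]
    module_kos = {g.id: sorted(set().union(*[set().union(*p) for p in g.paths])) for g in gmms}
    rows: list[tuple[str, str]] = []
    for sp in ids:
        kos: set[str] = set(rng.choice(universe, size=min(60, config.n_ko), replace=False))
        # strip accidental background coverage of module KOs to keep carriage deliberate
        for g in gmms:
            kos -= set(module_kos[g.id])
        is_pos = sp in truth.positive_species
        for g in gmms:
            planted = g.id in truth.planted_gmms
            p_carry = (0.9 if is_pos else 0.08) if planted else 0.30
            path = g.paths[int(rng.integers(0, len(g.paths)))]
            need = required_steps(len(path))
            if rng.random() < p_carry:
                if rng.random() < 0.3 and need < len(path):
                    chosen = rng.choice(len(path), size=need, replace=False)
                else:
                    chosen = range(len(path))
                for j in chosen:
                    kos |= set(path[j])
            elif rng.random() < 0.2 and need >= 2:
                for j in rng.choice(len(path), size=need - 1, replace=False):
                    kos |= set(path[j])
        rows.extend((sp, k) for k in sorted(kos))
    return pd.DataFrame(rows, columns=["species_id", "ko_id"])


# ---------------------------------------------------------------------------
# Event records
# ---------------------------------------------------------------------------

def generate_event_records(
    config: CohortConfig,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nocturnal recording summaries and event lists.

    Returns ``(recordings, events)``.  ``recordings`` has one row per
    participant (flow/SpO2 recording minutes and minutes below 90%
    saturation); ``events`` one row per respiratory event with a duration.
    Event counts are chosen so that recomputing AHI/ODI/T90 from the records
    reproduces the exposure table within count rounding.  A configured
    fraction of participants receives a flow recording under the 4-h validity
    threshold (AHI missing) while the SpO2 channel stays valid, under MCAR or
    a BMI-dependent MAR mechanism.
    """
    rng = _rng(config, _S_EVENTS)
    n = config.n_participants
    frac = config.missing_ahi_fraction
    if config.missing_mechanism == "MAR":
        if covariates is None:
            raise ValueError("MAR missingness requires the covariate table")
        bmi = covariates["bmi"].to_numpy()
        z = (bmi - bmi.mean()) / bmi.std()
        w = np.exp(0.7 * z)
        p_invalid = np.clip(frac * w / w.mean(), 0.0, 0.95)
    else:
        p_invalid = np.full(n, frac)
    invalid = rng.random(n) < p_invalid

    flow_minutes = np.clip(rng.normal(420.0, 40.0, size=n), 250.0, 560.0)
    flow_minutes[invalid] = rng.uniform(120.0, 235.0, size=int(invalid.sum()))
    spo2_minutes = np.clip(rng.normal(430.0, 40.0, size=n), 250.0, 560.0)

    ahi = exposures["ahi"].to_numpy()
    odi = exposures["odi"].to_numpy()
    t90 = exposures["t90"].to_numpy()
    n_ah = np.rint(ahi * flow_minutes / 60.0).astype(int)
    n_desat = np.rint(odi * spo2_minutes / 60.0).astype(int)
    minutes_below_90 = t90 / 100.0 * spo2_minutes

    recordings = pd.DataFrame(
        {
            "flow_recording_minutes": flow_minutes,
            "spo2_recording_minutes": spo2_minutes,
            "minutes_below_90": minutes_below_90,
        },
        index=exposures.index,
    )

    pid = np.asarray(exposures.index)
    ev_pid: list[np.ndarray] = []
    ev_type: list[np.ndarray] = []
    ev_dur: list[np.ndarray] = []
    for arr, kinds in ((n_ah, ("apnea", "hypopnea")), (n_desat, ("desaturation",))):
        total = int(arr.sum())
        ids = np.repeat(pid, arr)
        if len(kinds) == 2:
            is_apnea = rng.random(total) < 0.4
            types = np.where(is_apnea, kinds[0], kinds[1])
            dur = rng.uniform(10.0, 60.0, size=total)
        else:
            types = np.full(total, kinds[0], dtype=object)
            dur = rng.uniform(10.0, 90.0, size=total)
        ev_pid.append(ids)
        ev_type.append(types)
        ev_dur.append(dur)
    events = pd.DataFrame(
        {
            "participant_id": np.concatenate(ev_pid),
            "event_type": np.concatenate(ev_type),
            "duration_s": np.concatenate(ev_dur),
        }
    )
    return recordings, events


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def generate_outcomes(
    config: CohortConfig,
    covariates: pd.DataFrame,
    abundances: pd.DataFrame,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Systolic/diastolic BP and HbA1c with planted species effects.

    ``truth.outcome_species`` each add ``bp_effect`` mm Hg per SD of their
    rank-normalized abundance to both BP outcomes.  Medication indicators are
    copied/derived from the covariate table so the outcome table is
    self-contained for the post hoc exclusion rules.
    """
    rng = _rng(config, _S_OUTCOMES)
    n = len(covariates)
    age_c = covariates["age"].to_numpy() - 57.0
    male = (covariates["sex"].astype(str) == "male").astype(float).to_numpy()
    bmi_c = covariates["bmi"].to_numpy() - 26.5

    micro = np.zeros(n)
    for sp in sorted(truth.outcome_species):
        a = abundances[sp].to_numpy()
        r = stats.rankdata(a)
        micro += stats.norm.ppf((r - 0.5) / n)
    sbp = 118.0 + 0.35 * age_c + 6.0 * male + 0.8 * bmi_c + config.bp_effect * micro
    sbp = sbp + 10.0 * rng.standard_normal(n)
    dbp = 72.0 + 0.18 * age_c + 3.0 * male + 0.5 * bmi_c + 0.6 * config.bp_effect * micro
    dbp = dbp + 7.0 * rng.standard_normal(n)
    hba1c = 35.0 + 0.10 * age_c + 0.25 * bmi_c + config.hba1c_effect * micro
    hba1c = hba1c + 4.0 * rng.standard_normal(n)

    antidiabetic = covariates["metformin"].to_numpy() | (
        rng.random(n) < max(0.0, config.antidiabetic_prevalence - config.metformin_prevalence)
    )
    return pd.DataFrame(
        {
            "sbp": sbp,
            "dbp": dbp,
            "hba1c": hba1c,
            "antihypertensive_med": covariates["antihypertensive_med"].to_numpy(),
            "antidiabetic_med": antidiabetic,
        },
        index=covariates.index,
    )


# ---------------------------------------------------------------------------
# Bundled cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    truth: SyntheticTruth
    exposures: pd.DataFrame
    covariates: pd.DataFrame
    abundance: pd.DataFrame
    ko_profiles: pd.DataFrame
    gmm_definitions: list[GMMDefinition]
    recordings: pd.DataFrame
    events: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def analysis_exposures(self) -> pd.DataFrame:
        """Exposures as observed: AHI masked where the flow channel is invalid."""
        obs = self.exposures[["ahi", "t90", "odi"]].copy()
        invalid = self.recordings["flow_recording_minutes"] < 240.0
        obs.loc[invalid, "ahi"] = np.nan
        return obs


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: exposures, covariates, abundances, KO/GMM
    annotations, event records and outcomes, plus the truth ledger."""
    truth = plant_truth(config)
    exposures = generate_exposures(config)
    covariates = generate_covariates(config, exposures)
    abundance = generate_abundances(config, exposures, covariates, truth)
    rng = _rng(config, _S_KO)
    gmms = generate_gmm_definitions(config, rng)
    ko = generate_ko_profiles(config, truth, gmms, rng)
    recordings, events = generate_event_records(config, exposures, covariates)
    outcomes = generate_outcomes(config, covariates, abundance, truth)
    return Cohort(config, truth, exposures, covariates, abundance, ko, gmms, recordings, events, outcomes)
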