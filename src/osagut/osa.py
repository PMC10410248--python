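"""OSA parameter construction: AHI, ODI, T90, validity rules and groupings.

AHI (apnea-hypopnea index) is the number of apnea + hypopnea events per hour
of air-flow recording; ODI (oxygen desaturation index) the number of >=4%
desaturation events per hour of SpO2 recording; T90 the percentage of SpO2
recording time spent below 90% saturation.  A parameter is valid only with at
least 4 h of the relevant channel; because the hypopnea definition requires a
concurrent desaturation, AHI additionally requires a valid SpO2 channel.

Channel-specific denominators are used (flow time for AHI, SpO2 time for
ODI/T90) because validity is assessed per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_VALID_MINUTES = 240.0  # the 4-hour validity rule

AHI_SEVERITY_LEVELS = ("no_osa", "mild", "moderate", "severe")
T90_GROUP_LEVELS = ("t90_0", "t1", "t2", "t3")
ODI_GROUP_LEVELS = ("q1", "q2", "q3", "q4")


@dataclass(frozen=True)
class OSARecord:
    """One participant's nocturnal recording summary."""

    n_apnea_hypopnea: int
    n_desaturation: int
    minutes_below_90: float
    flow_recording_minutes: float
    spo2_recording_minutes: float

    def __post_init__(self) -> None:
        for name in (
            "n_apnea_hypopnea",
            "n_desaturation",
            "minutes_below_90",
            "flow_recording_minutes",
            "spo2_recording_minutes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.minutes_below_90 > self.spo2_recording_minutes + 1e-9:
            raise ValueError("minutes_below_90 exceeds SpO2 recording time")


@dataclass(frozen=True)
class OSAParameters:
    ahi: float
    odi: float
    t90: float
    ahi_valid: bool
    sat_valid: bool


def compute_parameters(record: OSARecord) -> OSAParameters:
    """AHI/ODI/T90 with the 4-h validity rule applied.

    Zero recording time with events present is an error; zero recording time
    with zero events yields all-missing parameters with validity flags False.
    """
    flow_ok = record.flow_recording_minutes >= MIN_VALID_MINUTES
    sat_ok = record.spo2_recording_minutes >= MIN_VALID_MINUTES
    if record.flow_recording_minutes == 0 and record.n_apnea_hypopnea > 0:
        raise ValueError("events recorded with zero flow recording time")
    if record.spo2_recording_minutes == 0 and (record.n_desaturation > 0 or record.minutes_below_90 > 0):
        raise ValueError("desaturation data with zero SpO2 recording time")
    ahi_valid = flow_ok and sat_ok
    ahi = record.n_apnea_hypopnea / (record.flow_recording_minutes / 60.0) if ahi_valid else np.nan
    odi = record.n_desaturation / (record.spo2_recording_minutes / 60.0) if sat_ok else np.nan
    t90 = 100.0 * record.minutes_below_90 / record.spo2_recording_minutes if sat_ok else np.nan
    return OSAParameters(ahi=ahi, odi=odi, t90=t90, ahi_valid=ahi_valid, sat_valid=sat_ok)


def compute_parameters_table(recordings: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Vectorized parameter computation from a recordings table plus an event
    list (``participant_id``, ``event_type`` in {apnea, hypopnea,
    desaturation}).  Returns ahi/odi/t90 with validity flags, indexed like
    ``recordings``."""
    counts = (
        events.assign(
            is_ah=events["event_type"].isin(["apnea", "hypopnea"]),
            is_desat=events["event_type"] == "desaturation",
        )
        .groupby("participant_id", observed=True)[["is_ah", "is_desat"]]
        .sum()
        .reindex(recordings.index, fill_value=0)
    )
    flow = recordings["flow_recording_minutes"].to_numpy(float)
    spo2 = recordings["spo2_recording_minutes"].to_numpy(float)
    below = recordings["minutes_below_90"].to_numpy(float)
    n_ah = counts["is_ah"].to_numpy(float)
    n_ds = counts["is_desat"].to_numpy(float)
    if np.any((flow == 0) & (n_ah > 0)) or np.any((spo2 == 0) & ((n_ds > 0) | (below > 0))):
        raise ValueError("events recorded with zero recording time")
    flow_ok = flow >= MIN_VALID_MINUTES
    sat_ok = spo2 >= MIN_VALID_MINUTES
    ahi_ok = flow_ok & sat_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        ahi = np.where(ahi_ok, n_ah / (flow / 60.0), np.nan)
        odi = np.where(sat_ok, n_ds / (spo2 / 60.0), np.nan)
        t90 = np.where(sat_ok, 100.0 * below / spo2, np.nan)
    return pd.DataFrame(
        {"ahi": ahi, "odi": odi, "t90": t90, "ahi_valid": ahi_ok, "sat_valid": sat_ok},
        index=recordings.index,
    )


def _cut_left_closed(values: np.ndarray, breaks: list[float], labels: tuple[str, ...]) -> pd.Categorical:
    # intervals closed on the left: [b0, b1), [b1, b2), ..., last closed at left only
    codes = np.searchsorted(np.asarray(breaks), values, side="right")
    codes = np.where(np.isnan(values), -1, codes)
    return pd.Categorical.from_codes(codes.astype(int), categories=list(labels))


def _quantile_groups(values: np.ndarray, probs: list[float], labels: tuple[str, ...]) -> pd.Categorical:
    # empirical quantile breaks with linear interpolation; ties at a break go low
    finite = values[~np.isnan(values)]
    breaks = np.quantile(finite, probs)
    codes = np.searchsorted(breaks, values, side="left")
    codes = np.where(np.isnan(values), -1, codes)
    return pd.Categorical.from_codes(codes.astype(int), categories=list(labels))


def assign_severity_groups(params: pd.DataFrame) -> pd.DataFrame:
    """Severity/grouping labels for each parameter.

    AHI: no OSA < 5, mild [5, 15), moderate [15, 30), severe >= 30.
    T90: one group for T90 = 0, the positive values split at empirical
    tertiles.  ODI: empirical quartiles.  Missing parameters yield missing
    labels; an all-missing column is an error.
    """
    out = pd.DataFrame(index=params.index)
    for col in ("ahi", "t90", "odi"):
        if col in params and params[col].notna().sum() == 0:
            raise ValueError(f"all values of {col} are missing")

    ahi = params["ahi"].to_numpy(float)
    out["ahi_group"] = _cut_left_closed(ahi, [5.0, 15.0, 30.0], AHI_SEVERITY_LEVELS)

    t90 = params["t90"].to_numpy(float)
    positive = t90[(~np.isnan(t90)) & (t90 > 0)]
    if positive.size == 0:
        raise ValueError("no positive T90 values to form tertiles")
    breaks = np.quantile(positive, [1.0 / 3.0, 2.0 / 3.0])
    codes = 1 + np.searchsorted(breaks, t90, side="left")
    codes = np.where(t90 == 0, 0, codes)
    codes = np.where(np.isnan(t90), -1, codes)
    out["t90_group"] = pd.Categorical.from_codes(codes.astype(int), categories=list(T90_GROUP_LEVELS))

    odi = params["odi"].to_numpy(float)
    out["odi_group"] = _quantile_groups(odi, [0.25, 0.5, 0.75], ODI_GROUP_LEVELS)
    return out


def clean_energy_intake(energy: pd.Series) -> pd.Series:
    """Flag implausible dietary reports as missing.

    Entries whose ln(energy) lies more than 3 SD from the sample mean of
    ln(energy) are set to missing; the mean and SD come from the non-missing
    analysis sample before any flagging.  With SD = 0 (all values equal)
    nothing is flagged.  Non-positive energies are an error.
    """
    e = energy.astype(float)
    obs = e.dropna()
    if (obs <= 0).any():
        raise ValueError("energy intake must be positive")
    ln = np.log(obs)
    mu, sd = ln.mean(), ln.std(ddof=1) if len(ln) > 1 else 0.0
    if sd == 0 or np.isnan(sd):
        return e.copy()
    out = e.copy()
    flag = (np.log(e) - mu).abs() > 3.0 * sd
    out[flag.fillna(False)] = np.nan
    return out
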