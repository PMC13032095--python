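"""Participant-level pain-modulation indexes.

From the epoch-means table this module derives, per participant:

* the temporal augmentation index (TAI) at each temperature — the mean over
  that temperature's stimuli of (epoch C mean - epoch A mean), a behavioral
  proxy for temporal summation / windup;
* the contrast-condition means at the 46 degC target — the mean full-window
  rating over trials preceded by 36 degC (low contrast) and by 48 degC (high
  contrast) — and the contrast magnitude, low minus high;
* the mean 46 degC intensity used for the VAS-NRS consistency filter and the
  sensitivity median split.

The ratio windup index C/A is exposed only as a diagnostic: with healthy
cohorts, initial ratings are often near zero, which makes the ratio unstable
(undefined marker when the epoch-A mean is 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .protocol import StimulusProtocol

INDEX_COLUMNS = [
    "participant_id",
    "tai_36", "tai_44", "tai_46", "tai_48",
    "vas_low_contrast_46", "vas_high_contrast_46", "contrast_magnitude",
    "mean_vas_46",
]


@dataclass
class ExclusionReport:
    """Auditable record of the VAS-NRS consistency filter."""

    threshold: float
    kept_ids: list[str]
    excluded: list[dict]

    @property
    def n_input(self) -> int:
        return len(self.kept_ids) + len(self.excluded)

    @property
    def exclusion_rate_pct(self) -> float:
        from .utils import percentage

        return percentage(len(self.excluded), self.n_input)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_input": self.n_input,
            "n_kept": len(self.kept_ids),
            "n_excluded": len(self.excluded),
            "exclusion_rate_pct": self.exclusion_rate_pct,
            "excluded": self.excluded,
        }


def compute_tai(epochs: pd.DataFrame, temperature: float) -> tuple[float, float]:
    """(TAI, ratio diagnostic) for one participant at one temperature.

    ``epochs`` holds that participant's retained epoch-mean rows.  TAI is the
    unweighted mean over the temperature's stimuli of (mean_C - mean_A).  The
    ratio diagnostic is mean_C / mean_A of the aggregated epoch means, NaN
    when the aggregated epoch-A mean is 0 (its documented instability).
    Returns (NaN, NaN) when the participant has no retained stimulus at the
    temperature — missing data, never zero.
    """
    sub = epochs[epochs["target_temp_c"] == temperature]
    if sub.empty:
        return float("nan"), float("nan")
    tai = float((sub["mean_C"] - sub["mean_A"]).mean())
    mean_a = float(sub["mean_A"].mean())
    mean_c = float(sub["mean_C"].mean())
    ratio = mean_c / mean_a if mean_a != 0 else float("nan")
    return tai, ratio


def compute_contrast(
    epochs: pd.DataFrame, protocol: StimulusProtocol
) -> tuple[float, float, float]:
    """(low-contrast mean, high-contrast mean, magnitude) at the 46 degC target.

    The condition rating of a trial is its full-window mean, taken as the
    equal-weight mean of the three epoch means.  Under the default sequence
    there is exactly one low-contrast trial (stimulus 16) and three
    high-contrast trials (4, 9, 20); the 46-after-46 trial (5) belongs to
    neither condition.  A missing condition yields NaN throughout.
    """
    low_idx, high_idx = protocol.contrast_trial_indices()
    full = (epochs["mean_A"] + epochs["mean_B"] + epochs["mean_C"]) / 3.0
    low_vals = full[epochs["stimulus_index"].isin(low_idx)]
    high_vals = full[epochs["stimulus_index"].isin(high_idx)]
    if low_vals.empty or high_vals.empty:
        return float("nan"), float("nan"), float("nan")
    low, high = float(low_vals.mean()), float(high_vals.mean())
    return low, high, low - high


def build_profiles(
    epoch_table: pd.DataFrame, protocol: StimulusProtocol
) -> pd.DataFrame:
    """Participant-level index table from the cohort epoch-means table.

    Vectorized equivalent of applying :func:`compute_tai` and
    :func:`compute_contrast` per participant (asserted equal in the test
    suite); missing conditions stay missing markers (NaN), never zero.
    """
    cols = (
        ["participant_id"]
        + [f"tai_{int(t)}" for t in protocol.temperatures()]
        + ["vas_low_contrast_46", "vas_high_contrast_46", "contrast_magnitude",
           "mean_vas_46"]
    )
    if epoch_table.empty:
        return pd.DataFrame(columns=cols)
    df = epoch_table.copy()
    df["tai"] = df["mean_C"] - df["mean_A"]
    df["full"] = (df["mean_A"] + df["mean_B"] + df["mean_C"]) / 3.0
    out = pd.DataFrame(
        {"participant_id": np.sort(df["participant_id"].unique())}
    )
    tai = df.groupby(["participant_id", "target_temp_c"])["tai"].mean().unstack()
    for temp in protocol.temperatures():
        if temp in tai.columns:
            out[f"tai_{int(temp)}"] = out["participant_id"].map(tai[temp])
        else:
            out[f"tai_{int(temp)}"] = np.nan
    low_idx, high_idx = protocol.contrast_trial_indices()
    low = df[df["stimulus_index"].isin(low_idx)].groupby("participant_id")["full"].mean()
    high = df[df["stimulus_index"].isin(high_idx)].groupby("participant_id")["full"].mean()
    m46 = (
        df[df["target_temp_c"] == protocol.contrast_target_temp_c]
        .groupby("participant_id")["full"].mean()
    )
    out["vas_low_contrast_46"] = out["participant_id"].map(low)
    out["vas_high_contrast_46"] = out["participant_id"].map(high)
    out["contrast_magnitude"] = out["vas_low_contrast_46"] - out["vas_high_contrast_46"]
    out["mean_vas_46"] = out["participant_id"].map(m46)
    return out[cols]


def exclusion_filter(
    profiles: pd.DataFrame,
    nrs_table: pd.DataFrame,
    threshold: float = 3.0,
) -> ExclusionReport:
    """VAS-NRS consistency filter.

    A participant is excluded when |mean 46 degC VAS / 10 - NRS| exceeds
    ``threshold`` on the 0-10 scale (reason ``vas_nrs_discrepancy``), or when
    no NRS report is available (reason ``missing_nrs``, flagged unassessable).
    """
    if threshold <= 0:
        raise ConfigurationError("exclusion threshold must be positive")
    nrs_map = dict(zip(nrs_table["participant_id"], nrs_table["nrs"]))
    kept, excluded = [], []
    for _, row in profiles.iterrows():
        pid = row["participant_id"]
        vas10 = row["mean_vas_46"] / 10.0
        nrs = nrs_map.get(pid)
        if nrs is None or np.isnan(nrs):
            excluded.append(
                {"participant_id": pid, "reason": "missing_nrs", "discrepancy": None}
            )
            continue
        disc = abs(vas10 - nrs)
        if disc > threshold:
            excluded.append(
                {
                    "participant_id": pid,
                    "reason": "vas_nrs_discrepancy",
                    "discrepancy": float(disc),
                }
            )
        else:
            kept.append(pid)
    return ExclusionReport(threshold=threshold, kept_ids=kept, excluded=excluded)


def median_split(profiles: pd.DataFrame) -> pd.DataFrame:
    """Assign low/high sensitivity groups by the cohort median of mean_vas_46.

    Participants at or below the median go to the low group (deterministic
    tie rule); participants with missing mean_vas_46 get no group.  A cohort
    with a single distinct value degenerates to all-low with a warning.
    """
    out = profiles.copy()
    vals = out["mean_vas_46"].dropna()
    if len(vals) < 2:
        raise ConfigurationError("median split needs >= 2 participants with mean_vas_46")
    med = float(vals.median())
    if vals.nunique() == 1:
        warnings.warn("degenerate median split: all mean_vas_46 identical; all low")
    group = np.where(out["mean_vas_46"] <= med, "low", "high")
    group = np.where(out["mean_vas_46"].isna(), None, group)
    out["sensitivity_group"] = group
    return out
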