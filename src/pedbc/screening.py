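"""Wear-time quality screening for wrist-device activity and sleep data.

The screen reproduces a sequential daily-data filter for consumer wrist
devices worn over an ~11-day window:

1. aggregate raw epochs to calendar days (midnight delimiter for steps and
   activity; a sleep episode starting between 18:00 and noon the next day is
   credited to the wake day);
2. drop each subject's first and last three wear days (device handling
   days);
3. keep a day only if monitored time / 1440 > 0.8 **and** total activity
   (light+moderate+vigorous) / 1440 > 0.1 (strict inequalities, checked in
   that order);
4. drop day-level steps and sleep values outside mean +/- 2 sample SDs of
   the screening population (inclusive bounds, single pass), computed
   cohort-wide within measurement year by default;
5. average the surviving days per participant-year.

Every input day ends up in exactly one of ``retained`` or ``excluded``
(with the first failed criterion as its reason).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_CATEGORIES",
    "ScreeningResult",
    "aggregate_daily",
    "trim_edge_days",
    "relative_durations",
    "apply_wear_filters",
    "apply_sd_filter",
    "participant_year_means",
    "mvpa_compliance",
    "screen_days",
]

ACTIVITY_CATEGORIES = ("sedentary", "light", "moderate", "vigorous")
MINUTES_PER_DAY = 1440.0

#: exclusion reasons in the order the criteria are applied
EXCLUSION_REASONS = (
    "edge_day",
    "low_monitor",
    "low_activity",
    "steps_outlier",
    "sleep_outlier",
)


@dataclass
class ScreeningResult:
    """Partition of input days into retained/excluded plus per-year means."""

    retained: pd.DataFrame
    excluded: pd.DataFrame  # columns: subject_id, date, reason
    summaries: pd.DataFrame  # one row per (subject_id, wave)
    bounds: dict = field(default_factory=dict)  # audit: sd-filter bounds


def aggregate_daily(epochs: pd.DataFrame) -> pd.DataFrame:
    """Aggregate epoch records to one row per subject-day.

    ``epochs`` columns: ``subject_id``, ``timestamp``, ``kind`` in
    {activity, steps, sleep}, ``category`` (activity only), ``duration_min``
    (activity/sleep), ``steps`` (steps only). Steps and activity minutes go
    to the calendar day containing the epoch start; a sleep episode starting
    in [18:00, 24:00) of day D or [00:00, 12:00] of day D+1 is credited to
    day D+1 (episodes starting between noon and 18:00 fall outside the
    recording window and are dropped). Overlapping activity epochs within a
    subject-day raise.
    """
    df = epochs.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    records: dict[tuple, dict] = {}

    def day_rec(subject, day) -> dict:
        key = (subject, day)
        if key not in records:
            records[key] = {
                "subject_id": subject,
                "date": day,
                **{f"{c}_min": 0.0 for c in ACTIVITY_CATEGORIES},
                "steps": 0,
                "sleep_min": 0.0,
            }
        return records[key]

    act = df[df["kind"] == "activity"].sort_values("timestamp")
    for (subject, day), grp in act.groupby(
        ["subject_id", act["timestamp"].dt.normalize()]
    ):
        starts = grp["timestamp"].to_numpy()
        ends = starts + pd.to_timedelta(grp["duration_min"], unit="m").to_numpy()
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            raise ValueError(
                f"overlapping activity epochs for {subject} on {day.date()}: "
                f"{grp['timestamp'].iloc[i]} and {grp['timestamp'].iloc[i + 1]}"
            )
        rec = day_rec(subject, day)
        for cat, dur in zip(grp["category"], grp["duration_min"]):
            if cat not in ACTIVITY_CATEGORIES:
                raise ValueError(f"unknown activity category {cat!r}")
            rec[f"{cat}_min"] += float(dur)

    for _, row in df[df["kind"] == "steps"].iterrows():
        rec = day_rec(row["subject_id"], row["timestamp"].normalize())
        rec["steps"] += int(row["steps"])

    for _, row in df[df["kind"] == "sleep"].iterrows():
        start = row["timestamp"]
        day = start.normalize()
        hour = start.hour + start.minute / 60.0
        if hour >= 18.0:
            wake_day = day + pd.Timedelta(days=1)
        elif hour <= 12.0:
            wake_day = day
        else:
            continue  # outside the 18:00-noon recording window
        rec = day_rec(row["subject_id"], wake_day)
        rec["sleep_min"] += float(row["duration_min"])

    out = pd.DataFrame(records.values())
    if out.empty:
        return out
    out["monitored_min"] = sum(out[f"{c}_min"] for c in ACTIVITY_CATEGORIES)
    return out.sort_values(["subject_id", "date"], ignore_index=True)


def trim_edge_days(days: pd.DataFrame, n_edge: int = 3):
    """Drop each subject's first and last ``n_edge`` distinct wear dates.

    Weekdays and holidays are treated alike. A subject with at most
    ``2 * n_edge`` distinct dates loses all days (with a warning). Returns
    ``(kept, excluded)`` where ``excluded`` carries reason ``edge_day``.
    """
    if n_edge < 0:
        raise ValueError("n_edge must be >= 0")
    kept_parts, excluded_parts = [], []
    for subject, grp in days.groupby("subject_id", sort=False):
        dates = np.sort(grp["date"].unique())
        if n_edge == 0:
            edge = set()
        elif len(dates) <= 2 * n_edge:
            warnings.warn(
                f"subject {subject}: only {len(dates)} wear days; all excluded "
                f"as edge days",
                stacklevel=2,
            )
            edge = set(dates)
        else:
            edge = set(dates[:n_edge]) | set(dates[-n_edge:])
        is_edge = grp["date"].isin(edge)
        kept_parts.append(grp[~is_edge])
        excluded_parts.append(grp[is_edge])
    kept = pd.concat(kept_parts) if kept_parts else days.iloc[:0]
    excluded = pd.concat(excluded_parts) if excluded_parts else days.iloc[:0]
    excluded = excluded.assign(reason="edge_day")
    return kept.reset_index(drop=True), excluded.reset_index(drop=True)


def relative_durations(day) -> dict[str, float]:
    """Per-category, monitored and total-activity proportions of 1440 min."""
    out = {
        c: float(day[f"{c}_min"]) / MINUTES_PER_DAY for c in ACTIVITY_CATEGORIES
    }
    out["monitored"] = float(day["monitored_min"]) / MINUTES_PER_DAY
    out["total_activity"] = (
        float(day["light_min"]) + float(day["moderate_min"]) + float(day["vigorous_min"])
    ) / MINUTES_PER_DAY
    return out


def apply_wear_filters(
    days: pd.DataFrame,
    monitor_threshold: float = 0.8,
    activity_threshold: float = 0.1,
):
    """Keep days with monitored proportion > 0.8 and activity > 0.1.

    Both inequalities are strict; a failing day's reason is the first failed
    criterion (``low_monitor`` before ``low_activity``).
    """
    monitored = days["monitored_min"].to_numpy(float) / MINUTES_PER_DAY
    activity = (
        days["light_min"].to_numpy(float)
        + days["moderate_min"].to_numpy(float)
        + days["vigorous_min"].to_numpy(float)
    ) / MINUTES_PER_DAY
    low_monitor = ~(monitored > monitor_threshold)
    low_activity = ~low_monitor & ~(activity > activity_threshold)
    kept = days[~(low_monitor | low_activity)].reset_index(drop=True)
    excluded = days[low_monitor | low_activity].copy()
    excluded["reason"] = np.where(
        low_monitor[low_monitor | low_activity], "low_monitor", "low_activity"
    )
    return kept, excluded.reset_index(drop=True)


def apply_sd_filter(values: np.ndarray, n_sd: float = 2.0):
    """Inclusive mean +/- ``n_sd`` sample-SD acceptance mask.

    Returns ``(mask, (lower, upper))``. With zero SD every value is kept
    (warned), since the band is degenerate.
    """
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need at least two values for the SD filter")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD in outlier filter; all values kept", stacklevel=2)
        return np.ones(len(values), bool), (mean, mean)
    lower, upper = mean - n_sd * sd, mean + n_sd * sd
    return (values >= lower) & (values <= upper), (lower, upper)


def participant_year_means(retained: pd.DataFrame) -> pd.DataFrame:
    """Mean steps / activity / MVPA / sleep per (subject_id, wave).

    ``activity_min`` is light+moderate+vigorous; ``mvpa_min`` is
    moderate+vigorous. Subject-waves present in the input but with zero
    retained days yield all-null rows (handled downstream as missing data).
    """
    df = retained.copy()
    df["activity_min"] = df["light_min"] + df["moderate_min"] + df["vigorous_min"]
    df["mvpa_min"] = df["moderate_min"] + df["vigorous_min"]
    keys = ["subject_id", "wave"] if "wave" in df.columns else ["subject_id"]
    return (
        df.groupby(keys, sort=True)[["steps", "activity_min", "mvpa_min", "sleep_min"]]
        .mean()
        .rename(columns={"steps": "steps_per_day"})
        .reset_index()
    )


def mvpa_compliance(summaries: pd.DataFrame, threshold: float = 60.0) -> float:
    """Fraction of subject-waves meeting a mean daily MVPA threshold (min)."""
    vals = summaries["mvpa_min"].dropna().to_numpy(float)
    if len(vals) == 0:
        raise ValueError("no MVPA summaries to assess")
    return float(np.mean(vals >= threshold))


def screen_days(
    days: pd.DataFrame,
    n_edge: int = 3,
    sd_scope: str = "cohort",
    n_sd: float = 2.0,
) -> ScreeningResult:
    """Run the full daily screen and summarize per participant-year.

    ``sd_scope``: ``"cohort"`` pools the +/-2SD filter across subjects
    within each measurement year (wave); ``"subject"`` computes the band per
    subject. The SD bands use only days that survived the wear filters.
    """
    if sd_scope not in ("cohort", "subject"):
        raise ValueError("sd_scope must be 'cohort' or 'subject'")
    days = days.reset_index(drop=True)
    all_keys = days[["subject_id", "date"]]
    kept, excluded_edge = trim_edge_days(days, n_edge=n_edge)
    kept, excluded_wear = apply_wear_filters(kept)

    bounds: dict = {}
    excl_outlier_parts = []
    if len(kept) >= 2:
        if sd_scope == "cohort" and "wave" in kept.columns:
            groups = list(kept.groupby("wave", sort=True))
        elif sd_scope == "subject":
            groups = list(kept.groupby("subject_id", sort=True))
        else:
            groups = [("all", kept)]
        keep_mask = pd.Series(True, index=kept.index)
        reason = pd.Series("", index=kept.index)
        for gname, grp in groups:
            if len(grp) < 2:
                continue
            for col, rname in (("steps", "steps_outlier"), ("sleep_min", "sleep_outlier")):
                mask, band = apply_sd_filter(grp[col].to_numpy(float), n_sd=n_sd)
                bounds[(gname, col)] = band
                bad = grp.index[~mask]
                newly = bad[keep_mask[bad]]
                keep_mask[newly] = False
                reason[newly] = rname
        excl = kept[~keep_mask].copy()
        excl["reason"] = reason[~keep_mask]
        excl_outlier_parts.append(excl)
        kept = kept[keep_mask].reset_index(drop=True)

    excluded = pd.concat(
        [excluded_edge, excluded_wear, *excl_outlier_parts], ignore_index=True
    )
    # partition check: every input day in exactly one bucket
    n_out = len(kept) + len(excluded)
    if n_out != len(all_keys):
        raise AssertionError(
            f"screening lost or duplicated days: {n_out} != {len(all_keys)}"
        )
    summaries = participant_year_means(kept) if len(kept) else pd.DataFrame(
        columns=["subject_id", "wave", "steps_per_day", "activity_min", "mvpa_min", "sleep_min"]
    )
    # subject-waves screened out entirely -> explicit all-null summary rows
    keys = ["subject_id", "wave"] if "wave" in days.columns else ["subject_id"]
    all_units = days[keys].drop_duplicates()
    summaries = all_units.merge(summaries, on=keys, how="left").sort_values(
        keys, ignore_index=True
    )
    excluded_cols = keys + ["date", "reason"]
    return ScreeningResult(
        retained=kept,
        excluded=excluded[[c for c in excluded_cols if c in excluded.columns]],
        summaries=summaries,
        bounds=bounds,
    )
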