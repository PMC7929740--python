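"""From epoch/minute records to imputed, validity-flagged 1440-minute days.

A day is the 24-hour local-clock interval. A day is *valid* when at least
960 minutes (16 hours) are observed; a subject is *included* when they
contribute at least one valid weekday and one valid weekend day. Missing
minutes on valid days are imputed with the subject's own data at the same
time of day, averaged over the other valid days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime

import numpy as np
import pandas as pd

from .basis import MINUTES_PER_DAY
from .errors import DataIntegrityError

logger = logging.getLogger(__name__)

VALID_DAY_MIN_MINUTES = 960  # 16 hours x 60, inclusive boundary

_SEASONS = ("winter", "spring", "summer", "autumn")


def season_of(day: "str | _date | datetime") -> str:
    """Season of a calendar date, by fixed astronomical boundaries.

    Winter Dec 21 - Mar 20, spring Mar 21 - Jun 20, summer Jun 21 - Sep 20,
    autumn Sep 21 - Dec 20 (so e.g. September 25 is autumn).
    """
    if isinstance(day, str):
        day = _date.fromisoformat(day)
    elif isinstance(day, datetime):
        day = day.date()
    elif isinstance(day, pd.Timestamp):
        day = day.date()
    md = (day.month, day.day)
    if md >= (12, 21) or md < (3, 21):
        return "winter"
    if md < (6, 21):
        return "spring"
    if md < (9, 21):
        return "summer"
    return "autumn"


def aggregate_epochs_to_minutes(epoch_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse 5-second epochs into minute sums.

    ``epoch_records`` needs columns ``subject_id, timestamp, activity``
    with ISO-8601 timestamps aligned to 5-second boundaries. Each minute is
    the sum of its 12 epochs and is marked unobserved when any constituent
    epoch is absent (its activity is then reported as missing).

    Raises
    ------
    DataIntegrityError
        On duplicate (subject, timestamp) pairs or misaligned timestamps.
    """
    df = epoch_records.copy()
    ts = pd.to_datetime(df["timestamp"])
    if df.duplicated(subset=["subject_id", "timestamp"]).any():
        dup = df[df.duplicated(subset=["subject_id", "timestamp"])].iloc[0]
        raise DataIntegrityError(
            f"duplicate epoch for subject {dup['subject_id']} "
            f"at {dup['timestamp']}"
        )
    secs = ts.dt.second + ts.dt.microsecond / 1e6
    if not np.all(np.mod(secs, 5) == 0):
        raise DataIntegrityError("epoch timestamps must align to 5-second boundaries")
    df["date"] = ts.dt.date.astype(str)
    df["minute_of_day"] = ts.dt.hour * 60 + ts.dt.minute
    grouped = df.groupby(["subject_id", "date", "minute_of_day"], sort=True)[
        "activity"
    ].agg(["sum", "count"])
    out = grouped.reset_index()
    out["observed"] = out.pop("count") == 12
    out["activity"] = np.where(out["observed"], out.pop("sum"), np.nan)
    return out[["subject_id", "date", "minute_of_day", "activity", "observed"]]


@dataclass
class DayCurveSet:
    """All subject-days of a study as aligned 1440-minute arrays.

    ``values`` holds activity (NaN where unobserved), ``observed`` the wear
    mask, and ``meta`` one row per subject-day with ``subject_id, date,
    weekend, workday, season, n_observed, valid``.
    """

    values: np.ndarray
    observed: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.values.shape != self.observed.shape or (
            self.values.shape[1] != MINUTES_PER_DAY
        ):
            raise DataIntegrityError(
                f"day curves must be (n, {MINUTES_PER_DAY}) arrays"
            )
        if len(self.meta) != self.values.shape[0]:
            raise DataIntegrityError("meta rows must match curve rows")

    @classmethod
    def from_minute_records(
        cls,
        minute_records: pd.DataFrame,
        day_covariates: pd.DataFrame | None = None,
    ) -> "DayCurveSet":
        """Pivot a long minute table into aligned day arrays.

        Minutes flagged unobserved (or absent) become NaN. Work/school-day
        flags are joined from ``day_covariates`` when given; weekend and
        season derive from the date.
        """
        df = minute_records
        if df.duplicated(subset=["subject_id", "date", "minute_of_day"]).any():
            raise DataIntegrityError("duplicate (subject, date, minute) rows")
        m = df["minute_of_day"].to_numpy()
        if ((m < 0) | (m >= MINUTES_PER_DAY)).any():
            raise DataIntegrityError("minute_of_day outside [0, 1439]")

        keys = df[["subject_id", "date"]].drop_duplicates().reset_index(drop=True)
        idx = pd.MultiIndex.from_frame(keys)
        row = pd.Series(np.arange(len(keys)), index=idx)
        r = row.loc[pd.MultiIndex.from_frame(df[["subject_id", "date"]])].to_numpy()

        values = np.full((len(keys), MINUTES_PER_DAY), np.nan)
        observed = np.zeros((len(keys), MINUTES_PER_DAY), dtype=bool)
        obs_flag = df["observed"].to_numpy(bool)
        values[r, m] = np.where(obs_flag, df["activity"].to_numpy(float), np.nan)
        observed[r, m] = obs_flag

        dates = pd.to_datetime(keys["date"])
        meta = keys.copy()
        meta["weekend"] = dates.dt.weekday >= 5
        meta["season"] = [season_of(d) for d in keys["date"]]
        meta["workday"] = pd.NA
        if day_covariates is not None:
            cov = day_covariates[["subject_id", "date", "workday"]]
            meta = meta.drop(columns="workday").merge(
                cov, on=["subject_id", "date"], how="left", validate="1:1"
            )
        meta["n_observed"] = observed.sum(axis=1)
        meta["valid"] = False
        return cls(values, observed, meta)

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "DayCurveSet":
        return DayCurveSet(
            self.values.copy(), self.observed.copy(), self.meta.copy()
        )

    def subset(self, mask) -> "DayCurveSet":
        mask = np.asarray(mask)
        return DayCurveSet(
            self.values[mask],
            self.observed[mask],
            self.meta.loc[mask].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide per-day matrix: metadata columns then m0000..m1439."""
        wide = pd.DataFrame(
            self.values, columns=[f"m{m:04d}" for m in range(MINUTES_PER_DAY)]
        )
        return pd.concat([self.meta.reset_index(drop=True), wide], axis=1)


def flag_valid_days(
    day_curves: DayCurveSet, min_minutes: int = VALID_DAY_MIN_MINUTES
) -> DayCurveSet:
    """Set the ``valid`` flag: at least ``min_minutes`` observed (inclusive)."""
    out = day_curves.copy()
    out.meta["valid"] = out.meta["n_observed"] >= min_minutes
    return out


def check_inclusion(
    day_curves: DayCurveSet,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the usable-data rule: >=1 valid weekday and >=1 valid weekend day.

    Returns the included subject ids and an exclusion log with one reason
    per dropped subject.
    """
    meta = day_curves.meta
    included: list[str] = []
    log_rows = []
    for sid, grp in meta.groupby("subject_id", sort=False):
        valid = grp[grp["valid"]]
        n_week = int((~valid["weekend"]).sum())
        n_wend = int(valid["weekend"].sum())
        if n_week >= 1 and n_wend >= 1:
            included.append(sid)
        else:
            reason = (
                "no valid days"
                if len(valid) == 0
                else ("no valid weekend day" if n_wend == 0 else "no valid weekday")
            )
            log_rows.append(
                {
                    "subject_id": sid,
                    "reason": reason,
                    "n_valid_days": len(valid),
                    "n_valid_weekdays": n_week,
                    "n_valid_weekend_days": n_wend,
                }
            )
            logger.info("excluding subject %s: %s", sid, reason)
    log = pd.DataFrame(
        log_rows,
        columns=[
            "subject_id",
            "reason",
            "n_valid_days",
            "n_valid_weekdays",
            "n_valid_weekend_days",
        ],
    )
    return included, log


def impute_missing(day_curves: DayCurveSet) -> DayCurveSet:
    """Fill unobserved minutes on valid days from the same subject.

    Each missing minute is replaced with the subject's activity at the same
    time of day averaged across their *other* valid days (the day being
    filled never contributes — it is unobserved there). A minute observed
    on no valid day at all falls back to linear interpolation of the
    subject's mean daily profile across the minute grid, with a warning.

    Observed values are never altered and invalid days are left untouched,
    so the operation is idempotent.
    """
    out = day_curves.copy()
    meta = out.meta
    for sid, grp in meta.groupby("subject_id", sort=False):
        rows = grp.index[grp["valid"]].to_numpy()
        if rows.size == 0:
            continue
        obs = out.observed[rows]
        vals = out.values[rows]
        donor_cnt = obs.sum(axis=0)
        donor_sum = np.where(obs, vals, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            donor_mean = np.where(donor_cnt > 0, donor_sum / np.maximum(donor_cnt, 1), np.nan)
        orphan = donor_cnt == 0
        if orphan.any() and (~orphan).any():
            grid = np.arange(MINUTES_PER_DAY)
            fallback = np.interp(
                grid[orphan], grid[~orphan], donor_mean[~orphan]
            )
            logger.warning(
                "subject %s: %d minute(s) observed on no valid day; "
                "interpolating the mean profile",
                sid,
                int(orphan.sum()),
            )
            donor_mean[orphan] = fallback
        for r in rows:
            miss = ~out.observed[r]
            out.values[r, miss] = donor_mean[miss]
    return out


def preprocess_minute_records(
    minute_records: pd.DataFrame,
    day_covariates: pd.DataFrame | None = None,
    min_minutes: int = VALID_DAY_MIN_MINUTES,
) -> tuple[DayCurveSet, pd.DataFrame]:
    """Full preprocessing chain on a long minute table.

    Builds day curves, flags validity, applies the inclusion rule (dropping
    all days of excluded subjects), and imputes missing minutes on valid
    days. Returns the imputed curve set (valid and invalid days of included
    subjects) and the exclusion log.
    """
    curves = DayCurveSet.from_minute_records(minute_records, day_covariates)
    curves = flag_valid_days(curves, min_minutes)
    included, log = check_inclusion(curves)
    keep = curves.meta["subject_id"].isin(included).to_numpy()
    curves = curves.subset(keep)
    curves = impute_missing(curves)
    n_valid = int(curves.meta["valid"].sum())
    logger.info(
        "preprocess: %d days read, %d valid, %d subjects included, %d excluded",
        len(keep),
        n_valid,
        len(included),
        len(log),
    )
    return curves, log
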