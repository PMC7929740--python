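import logging

import numpy as np
import pandas as pd
import pytest

from actifda.basis import MINUTES_PER_DAY
from actifda.errors import DataIntegrityError
from actifda.preprocess import (
    DayCurveSet,
    aggregate_epochs_to_minutes,
    check_inclusion,
    flag_valid_days,
    impute_missing,
    preprocess_minute_records,
    season_of,
)

from conftest import minute_table

# 2016-01-04 is a Monday; 2016-01-09/10 are Saturday/Sunday
MON, TUE, SAT, SUN = "2016-01-04", "2016-01-05", "2016-01-09", "2016-01-10"


def _epoch_table(subject, day, minute, values):
    ts = [
        f"{day}T{minute // 60:02d}:{minute % 60:02d}:{5 * i:02d}"
        for i in range(len(values))
    ]
    return pd.DataFrame(
        {"subject_id": subject, "timestamp": ts, "activity": values}
    )


class TestEpochAggregation:
    def test_minute_is_the_sum_of_its_twelve_epochs(self):
        tab = _epoch_table("A", MON, 600, [2.0] * 12)
        out = aggregate_epochs_to_minutes(tab)
        assert len(out) == 1
        assert out.loc[0, "activity"] == 24.0
        assert bool(out.loc[0, "observed"])

    def test_any_missing_epoch_marks_the_minute_unobserved(self):
        tab = _epoch_table("A", MON, 600, [2.0] * 11)
        out = aggregate_epochs_to_minutes(tab)
        assert not out.loc[0, "observed"]
        assert np.isnan(out.loc[0, "activity"])

    def test_duplicate_epochs_are_a_data_integrity_error(self):
        tab = _epoch_table("A", MON, 600, [1.0] * 12)
        tab = pd.concat([tab, tab.iloc[[0]]], ignore_index=True)
        with pytest.raises(DataIntegrityError, match="duplicate"):
            aggregate_epochs_to_minutes(tab)

    def test_misaligned_timestamps_rejected(self):
        tab = _epoch_table("A", MON, 600, [1.0] * 12)
        tab.loc[0, "timestamp"] = f"{MON}T10:00:03"
        with pytest.raises(DataIntegrityError, match="5-second"):
            aggregate_epochs_to_minutes(tab)

    def test_matches_brute_force_groupby_oracle(self):
        rng = np.random.default_rng(0)
        frames = []
        for minute in rng.choice(1440, size=25, replace=False):
            k = rng.integers(1, 13)
            frames.append(
                _epoch_table("A", MON, int(minute), rng.poisson(3, k).astype(float))
            )
        tab = pd.concat(frames, ignore_index=True)
        out = aggregate_epochs_to_minutes(tab).set_index("minute_of_day")
        # independent nested-loop recomputation
        for minute in out.index:
            ts = pd.to_datetime(tab["timestamp"])
            sel = (ts.dt.hour * 60 + ts.dt.minute) == minute
            vals = tab.loc[sel, "activity"]
            if len(vals) == 12:
                assert out.loc[minute, "activity"] == pytest.approx(vals.sum())
                assert out.loc[minute, "observed"]
            else:
                assert not out.loc[minute, "observed"]


def _curves_with_observed(obs_counts, dates=None):
    n = len(obs_counts)
    curves = np.full((n, MINUTES_PER_DAY), 10.0)
    observed = np.zeros((n, MINUTES_PER_DAY), dtype=bool)
    for i, c in enumerate(obs_counts):
        observed[i, :c] = True
    curves[~observed] = np.nan
    tab = minute_table(
        np.nan_to_num(curves, nan=0.0),
        observed,
        subject_ids=["A"] * n,
        dates=dates or [MON, TUE, SAT, SUN][:n],
    )
    return DayCurveSet.from_minute_records(tab)


class TestValidityAndInclusion:
    @pytest.mark.parametrize(
        "n_observed, expected", [(960, True), (959, False), (1440, True)]
    )
    def test_sixteen_hour_boundary_is_inclusive(self, n_observed, expected):
        dcs = flag_valid_days(_curves_with_observed([n_observed]))
        assert bool(dcs.meta.loc[0, "valid"]) is expected

    @pytest.mark.parametrize(
        "dates, included",
        [
            ([SAT, SUN], False),  # weekend only
            ([MON, SAT], True),  # one of each
            ([MON, TUE], False),  # weekdays only
        ],
    )
    def test_inclusion_needs_a_weekday_and_a_weekend_day(self, dates, included):
        dcs = flag_valid_days(_curves_with_observed([1440] * len(dates), dates))
        inc, log = check_inclusion(dcs)
        assert (["A"] == inc) is included
        assert len(log) == (0 if included else 1)

    def test_subject_count_is_conserved(self, small_dataset):
        dcs = DayCurveSet.from_minute_records(small_dataset.minute_records)
        dcs = flag_valid_days(dcs)
        inc, log = check_inclusion(dcs)
        assert len(inc) + len(log) == dcs.meta["subject_id"].nunique()


class TestImputation:
    def _three_day_subject(self):
        curves = np.stack(
            [
                np.full(MINUTES_PER_DAY, 30.0),
                np.full(MINUTES_PER_DAY, 20.0),
                np.full(MINUTES_PER_DAY, 50.0),
            ]
        )
        observed = np.ones_like(curves, dtype=bool)
        observed[1, 600] = False  # minute 600 missing on day 2
        curves[1, 600] = np.nan
        tab = minute_table(
            np.nan_to_num(curves),
            observed,
            subject_ids=["A"] * 3,
            dates=[MON, TUE, SAT],
        )
        return flag_valid_days(DayCurveSet.from_minute_records(tab))

    def test_same_minute_mean_over_other_valid_days(self):
        out = impute_missing(self._three_day_subject())
        assert out.values[1, 600] == pytest.approx((30.0 + 50.0) / 2)

    def test_fully_observed_input_is_unchanged(self, small_dataset):
        tab = small_dataset.minute_records.copy()
        tab["observed"] = True
        dcs = flag_valid_days(DayCurveSet.from_minute_records(tab))
        out = impute_missing(dcs)
        assert np.array_equal(out.values, dcs.values, equal_nan=True)

    def test_matches_brute_force_per_minute_oracle(self):
        rng = np.random.default_rng(4)
        n_days = 5
        curves = rng.poisson(40, size=(n_days, MINUTES_PER_DAY)).astype(float)
        observed = rng.random((n_days, MINUTES_PER_DAY)) > 0.1
        tab = minute_table(
            curves,
            observed,
            subject_ids=["A"] * n_days,
            dates=[MON, TUE, "2016-01-06", SAT, SUN],
        )
        dcs = flag_valid_days(DayCurveSet.from_minute_records(tab))
        assert dcs.meta["valid"].all()
        out = impute_missing(dcs)
        for d in range(n_days):
            for m in np.nonzero(~observed[d])[0]:
                donors = [
                    curves[o, m]
                    for o in range(n_days)
                    if o != d and observed[o, m]
                ]
                if donors:
                    assert out.values[d, m] == pytest.approx(np.mean(donors))

    def test_imputation_is_idempotent_and_preserves_observed(self):
        dcs = self._three_day_subject()
        once = impute_missing(dcs)
        twice = impute_missing(once)
        assert np.array_equal(once.values, twice.values, equal_nan=True)
        assert np.array_equal(
            once.values[dcs.observed], dcs.values[dcs.observed]
        )

    def test_minute_missing_on_all_days_falls_back_with_warning(self, caplog):
        curves = np.tile(np.arange(MINUTES_PER_DAY, dtype=float), (2, 1))
        observed = np.ones_like(curves, dtype=bool)
        observed[:, 700] = False  # nobody observed minute 700
        curves[:, 700] = np.nan
        tab = minute_table(
            np.nan_to_num(curves), observed, subject_ids=["A"] * 2,
            dates=[MON, SAT],
        )
        dcs = flag_valid_days(DayCurveSet.from_minute_records(tab))
        with caplog.at_level(logging.WARNING):
            out = impute_missing(dcs)
        assert "no valid day" in caplog.text
        # linear interpolation of the (identity) mean profile
        assert out.values[0, 700] == pytest.approx(700.0)


class TestSeason:
    @pytest.mark.parametrize(
        "day, season",
        [
            ("2016-09-25", "autumn"),
            ("2016-12-25", "winter"),
            ("2016-03-21", "spring"),
            ("2016-03-20", "winter"),
            ("2016-06-21", "summer"),
            ("2016-12-20", "autumn"),
            ("2016-01-15", "winter"),
        ],
    )
    def test_fixed_boundaries(self, day, season):
        assert season_of(day) == season

    def test_invalid_date_raises(self):
        with pytest.raises(ValueError):
            season_of("2016-13-40")


def test_full_chain_counts(small_dataset):
    curves, log = preprocess_minute_records(
        small_dataset.minute_records, small_dataset.day_covariates
    )
    valid = curves.meta["valid"]
    # every valid day is fully imputed
    assert not np.isnan(curves.values[valid.to_numpy()]).any()
    n_subj = small_dataset.subject_covariates.shape[0]
    assert curves.meta["subject_id"].nunique() + len(log) == n_subj
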