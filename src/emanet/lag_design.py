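"""Lagged regression design for within-day VAR(1) estimation.

Builds the (t-1 -> t) predictor/outcome rows from an EMA dataset.  Lags
are taken only between *consecutive scheduled beeps of the same day*: the
interval between a day's last beep and the next morning's first beep is
far longer than the nominal sampling interval, so no overnight prediction
is formed.  Lagged predictors are centered at person means (the
"stationary means"), which separates the within-person temporal dynamics
from stable between-person differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ema_data import EMADataset

__all__ = ["PersonMeans", "LaggedDesign", "person_statistics", "build_lagged"]

LAG_PREFIX = "lag_"
CENTERED_PREFIX = "c_"
OUTCOME_PREFIX = "y_"


@dataclass
class PersonMeans:
    """Per-person, per-item means over all non-missing occasions.

    ``means`` is persons x items; ``counts`` the number of observations
    behind each cell.  A person with zero observations of an item has a
    missing mean (flagged via ``counts == 0``).
    """

    means: pd.DataFrame
    counts: pd.DataFrame

    @property
    def item_names(self) -> list[str]:
        return list(self.means.columns)

    def sd_across_persons(self) -> pd.Series:
        """Sample SD of the person means per item (between-person spread)."""
        return self.means.std(ddof=1)


def person_statistics(dataset: EMADataset) -> PersonMeans:
    """Compute person means over *all* non-missing occasions of each item."""
    g = dataset.data.groupby(level="person_id", sort=False)
    return PersonMeans(means=g.mean(), counts=g.count())


@dataclass
class LaggedDesign:
    """Within-day lag-1 design rows.

    ``table`` has one row per usable (predictor beep -> outcome beep) pair
    with columns ``person_id, day, beep`` (the *outcome* beep), then per
    item: ``y_<item>`` (outcome), ``lag_<item>`` (raw value at the previous
    beep) and ``c_<item>`` (lagged value minus that person's mean).  Pairs
    whose predictor or outcome occasion was fully missed are absent;
    partially missing occasions are kept (node-wise models apply their own
    complete-case rule).
    """

    table: pd.DataFrame
    means: PersonMeans
    item_names: list[str]
    rows_per_person: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.rows_per_person is None:
            self.rows_per_person = (
                self.table.groupby("person_id").size()
                if len(self.table)
                else pd.Series(dtype=int)
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0

    def outcome(self, item: str) -> pd.Series:
        return self.table[OUTCOME_PREFIX + item]

    def centered_lag(self, item: str) -> pd.Series:
        return self.table[CENTERED_PREFIX + item]

    def export_table(self, path=None) -> pd.DataFrame:
        """Flat audit table (written as CSV when ``path`` is given)."""
        out = self.table.copy()
        if path is not None:
            out.to_csv(path, index=False)
        return out


def build_lagged(dataset: EMADataset, means: PersonMeans | None = None) -> LaggedDesign:
    """Build the within-day lag-1 design.

    One candidate row exists per consecutive scheduled beep pair (b-1, b),
    b = 2..beeps_per_day, per person-day.  Candidates are dropped when the
    predictor or the outcome occasion is fully missed.  With complete data
    this yields n_days * (beeps_per_day - 1) rows per person.  Lags are
    never taken across days, and never across a gap (a missed beep removes
    both pairs it participates in; beep 1 -> beep 3 is not a valid lag).
    """
    if dataset.schedule.beeps_per_day < 2:
        raise ValueError("lagging requires at least 2 beeps per day")
    if means is None:
        means = person_statistics(dataset)
    items = dataset.item_names

    df = dataset.data.sort_index()
    # previous scheduled beep within the same person-day; the full grid is
    # materialised, so shift(1) within (person, day) is exactly "beep - 1"
    lagged = df.groupby(level=["person_id", "day"], sort=False).shift(1)

    answered = dataset.beep_answered().sort_index()
    prev_answered = answered.groupby(level=["person_id", "day"], sort=False).shift(
        1, fill_value=False
    )
    beep = df.index.get_level_values("beep")
    keep = (beep >= 2) & answered.to_numpy() & prev_answered.to_numpy()

    out = pd.DataFrame(index=df.index[keep])
    persons = out.index.get_level_values("person_id")
    for it in items:
        out[OUTCOME_PREFIX + it] = df.loc[keep, it].to_numpy()
        raw_lag = lagged.loc[df.index[keep], it].to_numpy()
        out[LAG_PREFIX + it] = raw_lag
        out[CENTERED_PREFIX + it] = raw_lag - means.means[it].reindex(persons).to_numpy()
    out = out.reset_index()
    return LaggedDesign(table=out, means=means, item_names=list(items))
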