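"""Data model for ecological momentary assessment (EMA) studies.

An EMA study prompts each participant ("beeps") at fixed clock times,
several times a day, for a fixed number of days.  Every prompt presents a
battery of 0-100 slider items.  This module defines the beep schedule, the
item battery, a long-format dataset container with explicit representation
of missed beeps, reading/writing of delimited text, descriptive statistics,
compliance rates, and the per-beep aggregation of eating-episode ratings.

Conventions
-----------
* Day and beep indices are 1-based everywhere a user sees them (files,
  reports, error messages).
* A *fully missed beep* (participant never answered the prompt) is stored
  as a row whose item values are all missing; it is distinguishable from a
  row that is simply absent from an input file only in the sense that the
  reader materialises the full schedule grid, so after loading, every
  scheduled occasion exists exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeepSchedule",
    "ItemSpec",
    "EMADataset",
    "ComplianceResult",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "stress_affect_eating_items",
    "read_ema_csv",
    "read_episodes_csv",
    "write_ema_csv",
    "aggregate_goal_congruence",
    "describe",
    "compliance_rate",
]

INDEX_COLS = ("person_id", "day", "beep")

#: Consistency scaling constant for the median absolute deviation
#: (makes the MAD a consistent estimator of sigma under normality).
MAD_NORMAL_CONSTANT = 1.4826


class SchemaError(ValueError):
    """An input table does not have the expected columns."""


class IntegrityError(ValueError):
    """Duplicate keys or keys outside the beep schedule."""


class ValidationError(ValueError):
    """Observed values violate item ranges; carries row coordinates."""

    def __init__(self, problems: Sequence[tuple]):
        self.problems = list(problems)
        lines = ", ".join(
            f"(person={p}, day={d}, beep={b}, item={it}, value={v!r})"
            for p, d, b, it, v in self.problems[:10]
        )
        more = "" if len(self.problems) <= 10 else f" ... ({len(self.problems)} total)"
        super().__init__(f"values outside item range: {lines}{more}")


@dataclass(frozen=True)
class BeepSchedule:
    """Fixed daily prompt schedule.

    The default is four prompts per day at 9:00, 13:00, 17:00 and 21:00
    over 14 consecutive days, i.e. 56 scheduled occasions per person.
    """

    beeps_per_day: int = 4
    n_days: int = 14
    prompt_labels: tuple[str, ...] = ("09:00", "13:00", "17:00", "21:00")

    def __post_init__(self) -> None:
        if self.beeps_per_day < 2:
            raise ValueError("beeps_per_day must be >= 2 (lagging needs adjacent pairs)")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if len(self.prompt_labels) != self.beeps_per_day:
            raise ValueError(
                f"prompt_labels has {len(self.prompt_labels)} entries, "
                f"expected beeps_per_day={self.beeps_per_day}"
            )

    @property
    def n_occasions(self) -> int:
        """Total scheduled occasions per person."""
        return self.beeps_per_day * self.n_days


@dataclass(frozen=True)
class ItemSpec:
    """One slider item of the EMA battery.

    ``skippable`` marks an item a participant may leave unanswered inside
    an otherwise complete questionnaire (here: the eating item, skipped
    when no eating episode occurred since the last beep).
    """

    name: str
    label: str = ""
    group: str = "other"
    range_min: float = 0.0
    range_max: float = 100.0
    skippable: bool = False

    def __post_init__(self) -> None:
        if not self.range_min < self.range_max:
            raise ValueError(f"item {self.name}: range_min must be < range_max")


def stress_affect_eating_items() -> list[ItemSpec]:
    """The 15-item stress / affect / eating battery.

    Five positive affects, five negative affects, two stress-coping items,
    hunger, food craving and goal-congruent eating (the only skippable
    item).  Order follows the descriptive-table convention: eating-related
    items first, then coping, then affects.
    """
    return [
        ItemSpec("hunger", "Hunger", "eating"),
        ItemSpec("craving", "Food craving", "eating"),
        ItemSpec("goal_congruent_eating", "Goal-congruent eating", "eating", skippable=True),
        ItemSpec("present_coping", "Present stress coping", "stress_coping"),
        ItemSpec("anticipated_coping", "Anticipated stress coping", "stress_coping"),
        ItemSpec("active", "Active", "positive_affect"),
        ItemSpec("cheerful", "Cheerful", "positive_affect"),
        ItemSpec("enthusiastic", "Enthusiastic", "positive_affect"),
        ItemSpec("relaxed", "Relaxed", "positive_affect"),
        ItemSpec("calm", "Calm", "positive_affect"),
        ItemSpec("bored", "Bored", "negative_affect"),
        ItemSpec("depressed", "Depressed", "negative_affect"),
        ItemSpec("irritated", "Irritated", "negative_affect"),
        ItemSpec("nervous_stressed", "Nervous/stressed", "negative_affect"),
        ItemSpec("worried", "Worried", "negative_affect"),
    ]


@dataclass
class EMADataset:
    """Long-format EMA data keyed by (person_id, day, beep).

    ``data`` is a DataFrame with a three-level MultiIndex
    (person_id, day, beep) — day and beep 1-based — and one float column
    per item; NaN means missing.  The full schedule grid is materialised
    for every person, so a fully missed beep is an all-NaN row.

    ``attrs`` carries provenance (simulation seed, ground truth, clipping
    fraction) and is propagated by the pipeline, never interpreted here.
    """

    data: pd.DataFrame
    schedule: BeepSchedule = field(default_factory=BeepSchedule)
    items: list[ItemSpec] = field(default_factory=stress_affect_eating_items)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def person_ids(self) -> list:
        return list(self.data.index.get_level_values("person_id").unique())

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def item(self, name: str) -> ItemSpec:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    @property
    def skippable_items(self) -> list[str]:
        return [it.name for it in self.items if it.skippable]

    def copy(self) -> "EMADataset":
        return replace(self, data=self.data.copy(), attrs=dict(self.attrs))

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if list(df.index.names) != list(INDEX_COLS):
            raise SchemaError(f"index must be {INDEX_COLS}, got {df.index.names}")
        missing_cols = [n for n in self.item_names if n not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing item columns: {missing_cols}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate (person, day, beep) keys: {dups[:5]}")
        days = df.index.get_level_values("day")
        beeps = df.index.get_level_values("beep")
        if len(df) and (
            days.min() < 1
            or days.max() > self.schedule.n_days
            or beeps.min() < 1
            or beeps.max() > self.schedule.beeps_per_day
        ):
            raise IntegrityError(
                "keys outside schedule: day must be in "
                f"[1, {self.schedule.n_days}], beep in [1, {self.schedule.beeps_per_day}]"
            )
        problems = []
        for it in self.items:
            col = df[it.name]
            bad = col.notna() & ((col < it.range_min) | (col > it.range_max))
            for (p, d, b), v in col[bad].items():
                problems.append((p, d, b, it.name, v))
        if problems:
            raise ValidationError(problems)

    # -- missingness -----------------------------------------------------
    def beep_answered(self) -> pd.Series:
        """Boolean per scheduled occasion: any non-skippable item observed."""
        core = [it.name for it in self.items if not it.skippable]
        return self.data[core].notna().any(axis=1)

    def fully_missed(self) -> pd.Series:
        return ~self.beep_answered()

    def write_csv(self, path) -> None:
        write_ema_csv(self, path)


def _full_grid(persons: Sequence, schedule: BeepSchedule) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(persons), range(1, schedule.n_days + 1), range(1, schedule.beeps_per_day + 1)],
        names=INDEX_COLS,
    )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_ema_csv(
    path,
    schedule: BeepSchedule | None = None,
    items: Sequence[ItemSpec] | None = None,
    schema: Mapping[str, str] | None = None,
    episodes_path=None,
) -> EMADataset:
    """Read a long-format EMA table.

    Expected columns: ``person_id, day, beep`` plus one column per item;
    empty cells are missing.  ``schema`` maps canonical names to the file's
    column names (canonical -> file).  Rows absent from the file but inside
    the schedule become fully missed beeps.  If ``episodes_path`` is given,
    per-episode goal-congruence ratings are aggregated (mean over at most
    three episodes per beep) into the skippable item.
    """
    schedule = schedule or BeepSchedule()
    items = list(items) if items is not None else stress_affect_eating_items()
    schema = dict(schema or {})

    raw = pd.read_csv(path)
    wanted = list(INDEX_COLS) + [it.name for it in items]
    colmap = {name: schema.get(name, name) for name in wanted}
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"input file {path} lacks columns: {missing}")
    df = raw[[colmap[n] for n in wanted]].copy()
    df.columns = wanted
    try:
        df["day"] = df["day"].astype(int)
        df["beep"] = df["beep"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"day/beep columns must be integers: {exc}") from exc
    df = df.set_index(list(INDEX_COLS))
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate (person, day, beep) rows in {path}: {dups[:5]}")

    persons = df.index.get_level_values("person_id").unique()
    df = df.reindex(_full_grid(persons, schedule)).astype(float)

    if episodes_path is not None:
        skippable = [it.name for it in items if it.skippable]
        if len(skippable) != 1:
            raise SchemaError("episode aggregation needs exactly one skippable item")
        agg = read_episodes_csv(episodes_path)
        df[skippable[0]] = agg.reindex(df.index)

    return EMADataset(df, schedule=schedule, items=items)


def read_episodes_csv(path) -> pd.Series:
    """Aggregate a per-episode table to per-beep goal-congruence scores.

    Columns: ``person_id, day, beep, episode_index, goal_congruence`` with
    1-3 episodes per beep.  Returns a Series indexed by (person_id, day,
    beep); beeps with no episode simply do not appear (missing downstream).
    """
    raw = pd.read_csv(path)
    need = ["person_id", "day", "beep", "episode_index", "goal_congruence"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise SchemaError(f"episode file {path} lacks columns: {missing}")
    counts = raw.groupby(list(INDEX_COLS))["episode_index"].count()
    if (counts > 3).any():
        bad = counts[counts > 3].index.tolist()
        raise ValidationError([(p, d, b, "episode_index", ">3 episodes") for p, d, b in bad])
    out = raw.groupby(list(INDEX_COLS))["goal_congruence"].apply(
        lambda s: aggregate_goal_congruence(s.tolist())
    )
    out.name = "goal_congruence"
    return out


def write_ema_csv(dataset: EMADataset, path) -> None:
    """Write the long format read by :func:`read_ema_csv` (lossless)."""
    dataset.data.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-beep aggregation
# ---------------------------------------------------------------------------

def aggregate_goal_congruence(episode_ratings: Iterable[float]) -> float:
    """Mean goal-congruence over the (at most three) eating episodes of one beep.

    Returns NaN when no episode was reported — the item was skipped because
    the participant did not eat, which downstream stages treat as missing.
    """
    ratings = [float(r) for r in episode_ratings]
    if len(ratings) > 3:
        raise ValueError(f"at most 3 eating episodes per beep, got {len(ratings)}")
    for r in ratings:
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"episode rating {r} outside [0, 100]")
    if not ratings:
        return math.nan
    return float(np.mean(ratings))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def describe(dataset: EMADataset, mad_constant: float = MAD_NORMAL_CONSTANT) -> pd.DataFrame:
    """Per-item descriptive statistics pooled over persons and occasions.

    Columns: M (mean), SD (n-1 standard deviation), Median, MAD (median
    absolute deviation times ``mad_constant``; pass 1.0 for the raw MAD)
    and n (non-missing entries).  Items with no observations are flagged in
    ``all_missing`` rather than raising.  The scaling constant used is
    recorded both as a column and in ``DataFrame.attrs['mad_constant']``.
    """
    rows = []
    for it in dataset.items:
        x = dataset.data[it.name].dropna().to_numpy()
        if x.size == 0:
            rows.append((it.name, np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        med = float(np.median(x))
        mad = mad_constant * float(np.median(np.abs(x - med)))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows.append((it.name, float(np.mean(x)), sd, med, mad, int(x.size), False))
    out = pd.DataFrame(
        rows, columns=["item", "M", "SD", "Median", "MAD", "n", "all_missing"]
    ).set_index("item")
    out["mad_constant"] = mad_constant
    out.attrs["mad_constant"] = mad_constant
    return out


@dataclass(frozen=True)
class ComplianceResult:
    """Answered-beep rates: overall mean of per-person rates, plus detail."""

    overall: float
    per_person: pd.Series
    answered: pd.Series
    scheduled: int


def compliance_rate(dataset: EMADataset) -> ComplianceResult:
    """Proportion of scheduled beeps answered.

    A beep counts as answered when any non-skippable item is non-missing
    (the eating item may legitimately be skipped, so it never decides).
    The overall rate is the mean of per-person rates; under a shared
    schedule this equals the pooled answered/scheduled ratio.
    """
    answered = dataset.beep_answered().groupby(level="person_id").sum()
    scheduled = dataset.schedule.n_occasions
    per_person = answered / scheduled
    return ComplianceResult(
        overall=float(per_person.mean()),
        per_person=per_person,
        answered=answered,
        scheduled=scheduled,
    )
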