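"""Categorical engagement indicators from a roster and a raw event log.

Engagement with each website feature is coded one of two ways,
mirroring how the feature was expected to be used:

* **Consistency** (log-ins, weight tracker): the exposure period from
  enrollment to delivery is tiled with 45-day intervals and a
  participant is ``consistent`` if every completed interval contains at
  least one event, ``almost_consistent`` if at least half do,
  ``inconsistent`` if she has any event but covers fewer than half of
  her intervals, and ``never`` with no events at all.
* **Quantity** (health information, blogs, local resources, physical
  activity and diet goal-setting): total use is ``high`` if at or above
  the median count among participants who used the feature, ``low``
  below it, and ``never`` at zero.

All day values are integer offsets from consent (day 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from engage.defaults import (
    CONSISTENCY_FEATURES,
    FEATURES,
    QUANTITY_FEATURES,
)

logger = logging.getLogger(__name__)

CONSISTENT = "consistent"
ALMOST_CONSISTENT = "almost_consistent"
INCONSISTENT = "inconsistent"
NEVER = "never"
HIGH = "high"
LOW = "low"

#: total order on consistency categories, most engaged first
CONSISTENCY_ORDER = {CONSISTENT: 3, ALMOST_CONSISTENT: 2, INCONSISTENT: 1, NEVER: 0}
QUANTITY_ORDER = {HIGH: 2, LOW: 1, NEVER: 0}


@dataclass(frozen=True)
class IntervalScheme:
    """Tiling of one participant's exposure window by fixed-width intervals.

    ``windows`` are half-open day ranges ``[start, start + width)``
    covering ``[enrollment_day, delivery_day)`` without gaps or overlap;
    the last window is truncated at delivery when the exposure is not an
    exact multiple of the width.
    """

    enrollment_day: int
    delivery_day: int
    width: int
    windows: tuple[tuple[int, int], ...] = field(repr=False)
    n_completed: int
    has_partial: bool

    @property
    def denominator_windows(self) -> tuple[tuple[int, int], ...]:
        """Windows counted when judging consistency.

        Only completed windows count; a participant whose whole exposure
        is shorter than one width has no completed window, in which case
        the single partial window stands in as the denominator.
        """
        if self.n_completed == 0:
            return self.windows
        return self.windows[: self.n_completed]

    def window_index(self, day: int) -> int:
        """Index of the window containing ``day``.

        Events on the delivery day itself are included and attributed to
        the last window.
        """
        if not self.enrollment_day <= day <= self.delivery_day:
            raise ValueError(
                f"day {day} outside exposure "
                f"[{self.enrollment_day}, {self.delivery_day}]"
            )
        return min((day - self.enrollment_day) // self.width, len(self.windows) - 1)


def build_interval_scheme(
    enrollment_day: int, delivery_day: int, width: int = 45
) -> IntervalScheme:
    """Tile ``[enrollment_day, delivery_day)`` with ``width``-day windows.

    Raises
    ------
    TypeError
        for non-integer inputs.
    ValueError
        if the exposure has non-positive length or ``width < 1``.
    """
    for name, value in (
        ("enrollment_day", enrollment_day),
        ("delivery_day", delivery_day),
        ("width", width),
    ):
        if not isinstance(value, (int,)) or isinstance(value, bool):
            raise TypeError(f"{name} must be an integer, got {value!r}")
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    exposure = delivery_day - enrollment_day
    if exposure <= 0:
        raise ValueError(
            f"exposure must be positive: enrollment_day={enrollment_day}, "
            f"delivery_day={delivery_day}"
        )
    n_completed = exposure // width
    windows = [
        (enrollment_day + i * width, enrollment_day + (i + 1) * width)
        for i in range(n_completed)
    ]
    has_partial = exposure % width != 0
    if has_partial:
        windows.append((enrollment_day + n_completed * width, delivery_day))
    return IntervalScheme(
        enrollment_day=enrollment_day,
        delivery_day=delivery_day,
        width=width,
        windows=tuple(windows),
        n_completed=n_completed,
        has_partial=has_partial,
    )


def categorize_consistency(event_days: Iterable[int], scheme: IntervalScheme) -> str:
    """Code a feature's use across the participant's intervals.

    The cascade is first-match: ``consistent`` when every denominator
    window contains at least one event; ``almost_consistent`` when at
    least half do; ``inconsistent`` with any event at all; ``never``
    otherwise. Events in a trailing partial window do not help toward
    consistency but do preclude ``never``.
    """
    days = set(event_days)
    if not days:
        return NEVER
    denominator = scheme.denominator_windows
    hit = set()
    for day in days:
        idx = scheme.window_index(day)
        if idx < len(denominator):
            hit.add(idx)
    n_win = len(denominator)
    if len(hit) == n_win:
        return CONSISTENT
    if len(hit) / n_win >= 0.5:
        return ALMOST_CONSISTENT
    return INCONSISTENT


def compute_user_median(counts: Sequence[int]) -> float:
    """Median count among users (participants with a positive count).

    Raises ``ValueError`` when nobody used the feature, since a
    high/low split is undefined without users.
    """
    positive = [c for c in counts if c > 0]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if not positive:
        raise ValueError("no users: all counts are zero")
    return float(median(positive))


def categorize_quantity(count: int, user_median: float) -> str:
    """Code a count as high (>= median among users), low, or never (0)."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if user_median <= 0:
        raise ValueError(f"user_median must be positive, got {user_median}")
    if count == 0:
        return NEVER
    return HIGH if count >= user_median else LOW


def _validate_roster(roster: pd.DataFrame) -> None:
    required = {"participant_id", "enrollment_day", "delivery_day"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"roster missing columns: {sorted(missing)}")
    dupes = roster["participant_id"][roster["participant_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate participant_id in roster: {sorted(set(dupes))}")


def build_profiles(
    roster: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 45,
    medians: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build the seven-indicator engagement profile for every roster row.

    Parameters
    ----------
    roster
        One row per participant with ``participant_id``,
        ``enrollment_day`` and ``delivery_day`` columns.
    events
        Long event log with ``participant_id``, ``feature`` and ``day``
        columns. Events outside a participant's exposure window are
        dropped (the count is logged); events for unknown participants
        or unknown features are an error.
    window_days
        Width of the consistency intervals.
    medians
        Optional fixed per-feature medians for the high/low split. When
        omitted, each quantity feature's median is computed across the
        users of that feature in this dataset. A feature nobody used
        keeps no median (every participant is ``never``).

    Returns
    -------
    profiles, medians_used
        ``profiles`` has one row per participant: ``participant_id``
        plus the seven indicator columns. ``medians_used`` maps each
        quantity feature to the median actually applied.
    """
    _validate_roster(roster)
    for col in ("participant_id", "feature", "day"):
        if col not in events.columns:
            raise ValueError(f"events missing column: {col!r}")
    unknown_features = set(events["feature"]) - set(FEATURES)
    if unknown_features:
        raise ValueError(f"unknown feature labels: {sorted(unknown_features)}")
    known_ids = set(roster["participant_id"])
    unknown_ids = set(events["participant_id"]) - known_ids
    if unknown_ids:
        raise ValueError(
            f"events reference participants absent from roster: "
            f"{sorted(unknown_ids)[:5]}"
        )

    schemes = {
        row.participant_id: build_interval_scheme(
            int(row.enrollment_day), int(row.delivery_day), window_days
        )
        for row in roster.itertuples(index=False)
    }

    # drop out-of-window events once, up front
    if len(events):
        enroll = events["participant_id"].map(
            {pid: s.enrollment_day for pid, s in schemes.items()}
        )
        deliver = events["participant_id"].map(
            {pid: s.delivery_day for pid, s in schemes.items()}
        )
        in_window = (events["day"] >= enroll) & (events["day"] <= deliver)
        n_dropped = int((~in_window).sum())
        if n_dropped:
            logger.info("dropped %d events outside exposure windows", n_dropped)
        events = events[in_window]

    by_participant_feature = {
        key: grp["day"] for key, grp in events.groupby(["participant_id", "feature"])
    }

    # feature-wise medians over users of that feature
    medians_used: dict[str, float] = {}
    for feature in QUANTITY_FEATURES:
        if medians is not None:
            if feature not in medians:
                raise ValueError(f"medians missing quantity feature {feature!r}")
            if medians[feature] <= 0:
                raise ValueError(f"median for {feature!r} must be positive")
            medians_used[feature] = float(medians[feature])
        else:
            counts = [
                len(by_participant_feature[(pid, feature)])
                for pid in schemes
                if (pid, feature) in by_participant_feature
            ]
            if counts:
                medians_used[feature] = compute_user_median(counts)

    rows = []
    for pid, scheme in schemes.items():
        record: dict[str, object] = {"participant_id": pid}
        for feature in CONSISTENCY_FEATURES:
            days = by_participant_feature.get((pid, feature), ())
            record[feature] = categorize_consistency(days, scheme)
        for feature in QUANTITY_FEATURES:
            count = len(by_participant_feature.get((pid, feature), ()))
            if count == 0:
                record[feature] = NEVER
            else:
                record[feature] = categorize_quantity(count, medians_used[feature])
        rows.append(record)

    profiles = pd.DataFrame(rows, columns=["participant_id"] + FEATURES)
    return profiles, medians_used
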