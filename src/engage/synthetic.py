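"""Synthetic cohorts with known engagement-class and subgroup structure.

The generator emulates the study conditions of the pregnancy
intervention cohort: participants belong to one of four demographic/BMI
subgroups and one of six engagement-pattern classes, drawn with the
published prevalences; given the class, categorical indicators are
drawn independently from the published class-conditional probability
tables — exactly the local-independence structure latent class analysis
assumes. Exposure windows are drawn uniformly between 2 and 9 months
(60–270 days).

Raw event logs are rendered from the true category vectors so the whole
pipeline, including the event categorizer, is exercisable end to end;
ground-truth labels are retained separately for recovery tests. The
event renderer is the inverse of the engagement categorization
conditional on a fixed set of reference medians (the real median is
sample-dependent, so invertibility needs the medians pinned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from engage import defaults
from engage.engagement import IntervalScheme, build_interval_scheme
from engage.lca import IndicatorSpec, engagement_spec, subgroup_spec

logger = logging.getLogger(__name__)

# stream tags keeping the per-stage RNGs independent but seed-deterministic
_ROSTER_STREAM = 11
_CLASS_STREAM = 23
_EVENT_STREAM = 37


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort: four subgroups with
    prevalences (.2051, .1302, .1154, .5493), six engagement classes
    with prevalences (.1302, .1400, .1499, .2199, .1598, .2002), the
    corresponding class-conditional probability tables, and exposures
    of 60–270 days. ``engagement_gamma_by_subgroup`` optionally makes
    engagement-class prevalence depend on the true subgroup (for
    association power tests); by default the two are independent.
    """

    n: int = defaults.ANALYSIS_SAMPLE_SIZE
    seed: int = 0
    subgroup_gamma: np.ndarray = field(
        default_factory=lambda: defaults.normalized_gamma(defaults.SUBGROUP_GAMMA)
    )
    subgroup_rho: Mapping[str, np.ndarray] = field(
        default_factory=lambda: defaults.normalized_rho(defaults.SUBGROUP_RHO)
    )
    engagement_gamma: np.ndarray = field(
        default_factory=lambda: defaults.normalized_gamma(defaults.ENGAGEMENT_GAMMA)
    )
    engagement_rho: Mapping[str, np.ndarray] = field(
        default_factory=lambda: defaults.normalized_rho(defaults.ENGAGEMENT_RHO)
    )
    exposure_days: tuple[int, int] = (60, 270)
    reference_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.REFERENCE_MEDIANS)
    )
    window_days: int = 45
    engagement_gamma_by_subgroup: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        object.__setattr__(
            self, "subgroup_gamma", defaults.normalized_gamma(list(self.subgroup_gamma))
        )
        object.__setattr__(
            self, "engagement_gamma",
            defaults.normalized_gamma(list(self.engagement_gamma)),
        )
        object.__setattr__(
            self, "subgroup_rho",
            defaults.normalized_rho({k: np.asarray(v).tolist()
                                     for k, v in self.subgroup_rho.items()}),
        )
        object.__setattr__(
            self, "engagement_rho",
            defaults.normalized_rho({k: np.asarray(v).tolist()
                                     for k, v in self.engagement_rho.items()}),
        )
        if len(self.subgroup_gamma) != len(defaults.SUBGROUP_CLASSES):
            raise ValueError("subgroup_gamma must have one entry per subgroup")
        if len(self.engagement_gamma) != len(defaults.ENGAGEMENT_CLASSES):
            raise ValueError("engagement_gamma must have one entry per class")
        lo, hi = self.exposure_days
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid exposure range {self.exposure_days}")
        for feature, med in self.reference_medians.items():
            if med <= 0:
                raise ValueError(f"reference median for {feature!r} must be positive")


def _stream(config: GeneratorConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([tag, config.seed])


def simulate_profiles(
    spec: IndicatorSpec,
    gamma: np.ndarray,
    rho: Mapping[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
    class_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw ``n`` categorical response vectors from a latent class model.

    Generic workhorse: class from ``gamma``, then each item
    independently from its class row of ``rho``. Returns the profiles
    (level tokens) and the true class labels.
    """
    gamma = np.asarray(gamma, dtype=float)
    classes = rng.choice(len(gamma), size=n, p=gamma)
    data = {}
    for item in spec.items:
        table = np.asarray(rho[item], dtype=float)
        cum = table.cumsum(axis=1)
        u = rng.random(n)
        codes = (u[:, None] > cum[classes]).sum(axis=1)
        levels = np.asarray(spec.levels[item])
        data[item] = levels[codes]
    labels = (
        pd.Series([class_names[c] for c in classes])
        if class_names is not None
        else pd.Series(classes)
    )
    return pd.DataFrame(data), labels


def gen_roster(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the participant roster and its ground-truth subgroups.

    Each participant draws a subgroup, then demographic/BMI categories
    from that subgroup's response rows, and an exposure window of
    uniform length within ``exposure_days`` (enrollment at day 0).
    """
    rng = _stream(config, _ROSTER_STREAM)
    spec = subgroup_spec()
    demo, subgroup = simulate_profiles(
        spec, config.subgroup_gamma, config.subgroup_rho, config.n, rng,
        class_names=defaults.SUBGROUP_CLASSES,
    )
    lo, hi = config.exposure_days
    exposure = rng.integers(lo, hi + 1, size=config.n)
    roster = pd.DataFrame(
        {
            "participant_id": [f"p{i:05d}" for i in range(config.n)],
            "enrollment_day": 0,
            "delivery_day": exposure,
        }
    )
    roster = pd.concat([roster, demo], axis=1)
    truth = pd.DataFrame(
        {"participant_id": roster["participant_id"], "true_subgroup": subgroup}
    )
    return roster, truth


def gen_engagement_categories(
    roster: pd.DataFrame,
    config: GeneratorConfig,
    subgroup_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Draw each participant's engagement class and true category vector.

    With ``engagement_gamma_by_subgroup`` set (and ``subgroup_labels``
    provided), class prevalences vary by subgroup; otherwise every
    participant shares ``engagement_gamma``.
    """
    rng = _stream(config, _CLASS_STREAM)
    spec = engagement_spec()
    n = len(roster)
    if config.engagement_gamma_by_subgroup is not None:
        if subgroup_labels is None:
            raise ValueError(
                "subgroup_labels required with engagement_gamma_by_subgroup"
            )
        frames = []
        # draw per subgroup with its own prevalence vector, then restore order
        for sg, idx in pd.Series(range(n)).groupby(list(subgroup_labels)):
            gamma = defaults.normalized_gamma(
                list(config.engagement_gamma_by_subgroup[sg])
            )
            prof, labels = simulate_profiles(
                spec, gamma, config.engagement_rho, len(idx), rng,
                class_names=defaults.ENGAGEMENT_CLASSES,
            )
            prof.index = idx.to_numpy()
            prof["true_class"] = labels.to_numpy()
            frames.append(prof)
        out = pd.concat(frames).sort_index()
    else:
        prof, labels = simulate_profiles(
            spec, config.engagement_gamma, config.engagement_rho, n, rng,
            class_names=defaults.ENGAGEMENT_CLASSES,
        )
        prof["true_class"] = labels.to_numpy()
        out = prof
    out.insert(0, "participant_id", roster["participant_id"].to_numpy())
    return out


def render_events(
    categories: Mapping[str, str],
    scheme: IntervalScheme,
    reference_medians: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[list[dict], dict[str, str]]:
    """Emit an event log realizing a true category vector.

    The inverse of the categorization rules, conditional on the given
    reference medians: a ``consistent`` feature gets one event per
    denominator window; ``almost_consistent`` events in ``ceil(w/2)`` of
    the ``w`` windows; ``inconsistent`` in ``max(1, ceil(w/2) - 1)``;
    quantity features get a count at/above (high) or below (low) the
    reference median. Categories unrealizable on a given scheme (e.g.
    ``inconsistent`` with fewer than three denominator windows, or
    ``low`` with a median of 1) are degraded to the nearest realizable
    category, which is logged and reflected in the returned realized
    vector.

    Returns the event records and the category vector the categorizer
    will actually reproduce from them.
    """
    events: list[dict] = []
    realized: dict[str, str] = {}
    denom = scheme.denominator_windows
    w = len(denom)

    for feature in defaults.CONSISTENCY_FEATURES:
        cat = categories[feature]
        if cat == "never":
            realized[feature] = "never"
            continue
        if cat == "consistent":
            n_hit = w
        elif cat == "almost_consistent":
            n_hit = ceil(w / 2)
        elif cat == "inconsistent":
            n_hit = max(1, ceil(w / 2) - 1)
        else:
            raise ValueError(f"unknown consistency category {cat!r}")
        # what the categorizer will say for this hit pattern
        if n_hit == w:
            realized[feature] = "consistent"
        elif n_hit / w >= 0.5:
            realized[feature] = "almost_consistent"
        else:
            realized[feature] = "inconsistent"
        if realized[feature] != cat:
            logger.debug(
                "category %r for %s unrealizable on %d windows; rendering %r",
                cat, feature, w, realized[feature],
            )
        chosen = rng.choice(w, size=n_hit, replace=False)
        for idx in chosen:
            start, end = denom[idx]
            day = int(rng.integers(start, end))
            events.append({"feature": feature, "day": day})

    for feature in defaults.QUANTITY_FEATURES:
        cat = categories[feature]
        med = reference_medians[feature]
        if cat == "never":
            realized[feature] = "never"
            continue
        if cat == "high":
            count = int(ceil(med)) + int(rng.integers(0, 3))
            realized[feature] = "high"
        elif cat == "low":
            if med <= 1:
                logger.debug(
                    "category 'low' for %s unrealizable with median %s; "
                    "rendering 'never'", feature, med,
                )
                realized[feature] = "never"
                continue
            count = int(rng.integers(1, int(ceil(med))))
            realized[feature] = "low"
        else:
            raise ValueError(f"unknown quantity category {cat!r}")
        days = rng.integers(scheme.enrollment_day, scheme.delivery_day, size=count)
        events.extend({"feature": feature, "day": int(day)} for day in days)

    return events, realized


@dataclass(frozen=True)
class SyntheticBundle:
    """Generated cohort: observed files plus retained ground truth."""

    roster: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    reference_medians: dict[str, float]

    def write(self, out_dir) -> None:
        """Write roster.csv, events.csv and truth.csv under ``out_dir``.

        The truth file is for diagnostics only and must never feed the
        analysis stages.
        """
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(out / "roster.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def gen_dataset(config: GeneratorConfig) -> SyntheticBundle:
    """Compose roster, true categories and rendered events into one cohort.

    The truth table records each participant's subgroup, engagement
    class, and both the drawn and the realized (renderable) category
    vectors; the realized vector is what profiling the emitted events
    with the reference medians reproduces.
    """
    roster, subgroup_truth = gen_roster(config)
    categories = gen_engagement_categories(
        roster, config, subgroup_labels=subgroup_truth["true_subgroup"]
    )
    rng = _stream(config, _EVENT_STREAM)
    event_rows = []
    realized_rows = []
    for row in roster.itertuples(index=False):
        scheme = build_interval_scheme(
            int(row.enrollment_day), int(row.delivery_day), config.window_days
        )
        cats = categories.loc[
            categories["participant_id"] == row.participant_id, defaults.FEATURES
        ].iloc[0]
        events, realized = render_events(
            cats.to_dict(), scheme, config.reference_medians, rng
        )
        for ev in events:
            event_rows.append({"participant_id": row.participant_id, **ev})
        realized_rows.append(realized)

    events = pd.DataFrame(event_rows, columns=["participant_id", "feature", "day"])
    realized = pd.DataFrame(realized_rows).add_prefix("realized_")
    truth = subgroup_truth.merge(categories, on="participant_id")
    truth = pd.concat([truth.reset_index(drop=True), realized], axis=1)
    return SyntheticBundle(
        roster=roster,
        events=events,
        truth=truth,
        reference_medians=dict(config.reference_medians),
    )
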