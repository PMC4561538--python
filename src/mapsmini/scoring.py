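"""Score audited routes into participant-level microscale-environment scores.

Each item is aggregated within a route (segment- and crossing-level items
are averaged across their observation units), summed into a total over the
items included in the total score, and expressed as a percentage of the
possible maximum so scores remain roughly comparable across catalog
variants.  Participants can then be ranked into quintiles of the percent
score for effect-size contrasts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .audit import (
    AuditDataset,
    Category,
    ItemDefinition,
    Level,
    RouteObservation,
    default_catalog,
)

__all__ = [
    "BikeFacility",
    "ScoreConfig",
    "ParticipantScore",
    "score_bike_facility",
    "aggregate_item",
    "total_score",
    "percent_of_max",
    "assign_quintiles",
    "score_dataset",
    "scores_to_frame",
]


class BikeFacility(str, enum.Enum):
    NONE = "none"
    SHARROWS = "sharrows"
    PAINTED_LANE = "painted_lane"
    PHYSICALLY_PROTECTED = "physically_protected"


#: Bicycle-facility scoring: graded by how well cyclists are protected from
#: cars.  Sharrow markings designate space but provide no protection, so
#: they score the same as no facility at all.
_BIKE_SCORES = {
    BikeFacility.NONE: 0,
    BikeFacility.SHARROWS: 0,
    BikeFacility.PAINTED_LANE: 1,
    BikeFacility.PHYSICALLY_PROTECTED: 2,
}


def score_bike_facility(facility: BikeFacility | str) -> int:
    """Score the designated-bike-facility item (0, 1, or 2)."""
    try:
        facility = BikeFacility(facility)
    except ValueError:
        raise ValueError(
            f"unknown bicycle facility {facility!r}; expected one of "
            f"{[m.value for m in BikeFacility]}")
    return _BIKE_SCORES[facility]


class MissingPolicy(str, enum.Enum):
    RENORMALIZE = "renormalize"
    FAIL = "fail"


@dataclass
class ScoreConfig:
    """How to turn item scores into a total.

    ``include_bike_in_total`` adds the 0-2 bicycle-facility item to the
    total (off by default, matching the validation analyses which used the
    14 tabled items minus the two aesthetics items).  ``missing_policy``
    controls what happens when an in-total item has no observations on a
    route (e.g. the crossing items on a crossing-free route):
    ``renormalize`` drops the item from both the total and the maximum,
    ``fail`` raises.
    """

    catalog: list[ItemDefinition] = field(default_factory=default_catalog)
    include_bike_in_total: bool = False
    missing_policy: MissingPolicy = MissingPolicy.RENORMALIZE

    def __post_init__(self) -> None:
        self.missing_policy = MissingPolicy(self.missing_policy)
        if not self.in_total_ids():
            raise ValueError("degenerate config: no items contribute to the total score")

    def in_total_ids(self) -> list[str]:
        ids = [it.item_id for it in self.catalog if it.in_total]
        if self.include_bike_in_total:
            ids += [it.item_id for it in self.catalog
                    if it.category is Category.BICYCLE_FACILITIES
                    and it.item_id not in ids]
        return ids


@dataclass
class ParticipantScore:
    participant_id: str
    item_scores: dict[str, Optional[float]]
    total: float
    max_possible: float
    percent_of_max: float
    quintile: Optional[int] = None


def aggregate_item(route: RouteObservation, item: ItemDefinition) -> Optional[float]:
    """Aggregate one item within a route.

    Route-level items return their single response; segment- and
    crossing-level items return the arithmetic mean over units with a
    non-missing response.  Returns ``None`` when no unit carries a response
    (e.g. any crossing item on a route with zero crossings).
    """
    if item.level is Level.ROUTE:
        v = route.route_responses.get(item.item_id)
        return None if v is None else float(v)
    units = route.segments if item.level is Level.SEGMENT else route.crossings
    values = [u.responses[item.item_id] for u in units if item.item_id in u.responses]
    if not values:
        return None
    return float(np.mean(values))


def percent_of_max(total: float, max_possible: float) -> float:
    """100 x total / max_possible."""
    if max_possible <= 0:
        raise ValueError(f"max_possible must be positive, got {max_possible}")
    if not 0 <= total <= max_possible:
        raise ValueError(f"total {total} outside [0, {max_possible}]")
    return 100.0 * total / max_possible


def total_score(route: RouteObservation, cfg: Optional[ScoreConfig] = None) -> ParticipantScore:
    """Score one route: per-item aggregates, total, and percent of maximum."""
    cfg = cfg if cfg is not None else ScoreConfig()
    items = {it.item_id: it for it in cfg.catalog}
    item_scores = {iid: aggregate_item(route, it) for iid, it in items.items()}

    total = 0.0
    max_possible = 0.0
    for iid in cfg.in_total_ids():
        score = item_scores[iid]
        if score is None:
            if cfg.missing_policy is MissingPolicy.FAIL:
                raise ValueError(
                    f"participant {route.participant_id}: in-total item "
                    f"{iid!r} has no observations and missing_policy is 'fail'")
            continue  # renormalize: drop from numerator and denominator
        total += score
        max_possible += items[iid].max_score
    if max_possible <= 0:
        raise ValueError(
            f"participant {route.participant_id}: every in-total item is "
            "missing; percent of maximum is undefined")
    return ParticipantScore(
        participant_id=route.participant_id,
        item_scores=item_scores,
        total=total,
        max_possible=max_possible,
        percent_of_max=percent_of_max(total, max_possible),
    )


def assign_quintiles(scores: Sequence[ParticipantScore]) -> list[ParticipantScore]:
    """Rank participants into quintiles of percent-of-max (1 = lowest fifth).

    Ties receive the average rank of the tied block, so tied scores always
    share a quintile; with all scores equal everyone lands in quintile 3.
    """
    if len(scores) < 5:
        raise ValueError(f"need at least 5 participants to form quintiles, got {len(scores)}")
    pct = np.array([s.percent_of_max for s in scores], dtype=float)
    ranks = rankdata(pct, method="average")
    quintiles = np.ceil(5.0 * ranks / len(scores)).astype(int)
    quintiles = np.clip(quintiles, 1, 5)
    return [replace(s, quintile=int(q)) for s, q in zip(scores, quintiles)]


def score_dataset(
    ds: AuditDataset,
    cfg: Optional[ScoreConfig] = None,
    quintiles: bool = True,
) -> list[ParticipantScore]:
    cfg = cfg if cfg is not None else ScoreConfig(catalog=list(ds.catalog))
    scores = [total_score(r, cfg) for r in ds.routes]
    if quintiles and len(scores) >= 5:
        scores = assign_quintiles(scores)
    return scores


def scores_to_frame(scores: Iterable[ParticipantScore]) -> pd.DataFrame:
    """Participant-score table: one row per participant, 15 item columns,
    total, max_possible, percent_of_max (full precision), quintile."""
    rows = []
    for s in scores:
        rec: dict = {"participant_id": s.participant_id}
        rec.update({k: (np.nan if v is None else v) for k, v in s.item_scores.items()})
        rec["total"] = s.total
        rec["max_possible"] = s.max_possible
        rec["percent_of_max"] = s.percent_of_max
        rec["quintile"] = s.quintile if s.quintile is not None else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
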