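"""Domain types and I/O for MAPS-Mini streetscape audit data.

MAPS-Mini is a 15-item audit of microscale, mostly modifiable streetscape
features (sidewalks, crosswalks, benches, street lights, bicycle facilities)
observed along a quarter-mile route from a residence toward the nearest
non-residential destination.  Items are observed at one of three levels:

* ``route``    — one response summarising the whole route,
* ``segment``  — one response per street block face along the route,
* ``crossing`` — one response per intersection traversal.

Raw responses are recorded directly on the item's score scale (0/1 or
0/1/2).  Missing responses are a first-class state, distinct from a score
of zero, and survive round trips through CSV as empty cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Level",
    "Category",
    "ItemDefinition",
    "SegmentObservation",
    "CrossingObservation",
    "RouteObservation",
    "AuditDataset",
    "Violation",
    "AuditFormatError",
    "AuditValidationError",
    "default_catalog",
    "load_catalog",
    "save_catalog",
    "read_audit_tables",
    "write_audit_tables",
    "validate_dataset",
]


class AuditFormatError(ValueError):
    """A CSV table is structurally malformed (e.g. a required column is absent)."""


class AuditValidationError(ValueError):
    """A response value violates the item catalog (e.g. out-of-range score)."""


class Level(str, enum.Enum):
    ROUTE = "route"
    SEGMENT = "segment"
    CROSSING = "crossing"


class Category(str, enum.Enum):
    DESTINATIONS_LAND_USE = "destinations_land_use"
    STREETSCAPE = "streetscape"
    AESTHETICS_SOCIAL = "aesthetics_social"
    CROSSINGS_INTERSECTIONS = "crossings_intersections"
    STREET_SEGMENTS = "street_segments"
    BICYCLE_FACILITIES = "bicycle_facilities"


@dataclass(frozen=True)
class ItemDefinition:
    """One audit item: where it is observed, how it is scored, and whether
    it contributes to the total score."""

    item_id: str
    label: str
    level: Level
    category: Category
    score_levels: tuple[int, ...] = (0, 1)
    in_total: bool = True

    def __post_init__(self) -> None:
        levels = tuple(self.score_levels)
        if levels not in ((0, 1), (0, 1, 2)):
            raise ValueError(
                f"item {self.item_id!r}: score_levels must be (0, 1) or "
                f"(0, 1, 2), got {levels!r}"
            )
        object.__setattr__(self, "score_levels", levels)

    @property
    def max_score(self) -> int:
        return max(self.score_levels)


def default_catalog() -> list[ItemDefinition]:
    """The 15-item MAPS-Mini catalog.

    The two aesthetics/social items are excluded from the total score by
    default; the bicycle-facility item is scored 0-1-2 and its inclusion in
    the total is controlled by :class:`mapsmini.scoring.ScoreConfig`.  All
    other items default to binary 0-1 scoring; the published instrument
    states only that items are scored 0-1 or 0-1-2, so the per-item ranges
    (and the route/segment assignment of the streetscape items) are
    user-editable assumptions.
    """
    R, S, C = Level.ROUTE, Level.SEGMENT, Level.CROSSING
    return [
        ItemDefinition("public_park", "Public park", R, Category.DESTINATIONS_LAND_USE),
        ItemDefinition("transit_stops", "Transit stops", R, Category.STREETSCAPE),
        ItemDefinition("street_lights", "Street lights", S, Category.STREETSCAPE),
        ItemDefinition("benches", "Benches", S, Category.STREETSCAPE),
        ItemDefinition(
            "building_maintenance", "Building maintenance", R,
            Category.AESTHETICS_SOCIAL, in_total=False,
        ),
        ItemDefinition(
            "graffiti_absent", "Absence of graffiti", R,
            Category.AESTHETICS_SOCIAL, in_total=False,
        ),
        ItemDefinition("crosswalk", "Crosswalk", C, Category.CROSSINGS_INTERSECTIONS),
        ItemDefinition("curb_cuts", "Curb cuts", C, Category.CROSSINGS_INTERSECTIONS),
        ItemDefinition("crossing_signal", "Crossing signal", C, Category.CROSSINGS_INTERSECTIONS),
        ItemDefinition("commercial", "Commercial", S, Category.STREET_SEGMENTS),
        ItemDefinition("sidewalk", "Sidewalk", S, Category.STREET_SEGMENTS),
        ItemDefinition("sidewalk_buffer", "Sidewalk buffer", S, Category.STREET_SEGMENTS),
        ItemDefinition("trees_coverage", "Trees and overhead coverage", S, Category.STREET_SEGMENTS),
        ItemDefinition("trip_hazards_absent", "Absence of trip hazards", S, Category.STREET_SEGMENTS),
        ItemDefinition(
            "bike_facility", "Designated bike facility", R,
            Category.BICYCLE_FACILITIES, score_levels=(0, 1, 2), in_total=False,
        ),
    ]


def save_catalog(catalog: Iterable[ItemDefinition], path: str | Path) -> Path:
    path = Path(path)
    records = [
        {
            "item_id": it.item_id,
            "label": it.label,
            "level": it.level.value,
            "category": it.category.value,
            "score_levels": list(it.score_levels),
            "in_total": it.in_total,
        }
        for it in catalog
    ]
    path.write_text(yaml.safe_dump(records, sort_keys=False))
    return path


def load_catalog(path: str | Path) -> list[ItemDefinition]:
    records = yaml.safe_load(Path(path).read_text())
    return [
        ItemDefinition(
            item_id=r["item_id"],
            label=r.get("label", r["item_id"]),
            level=Level(r["level"]),
            category=Category(r["category"]),
            score_levels=tuple(r.get("score_levels", [0, 1])),
            in_total=bool(r.get("in_total", True)),
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# Observations

Responses = dict[str, float]  # item_id -> raw response; absent key = missing


@dataclass
class SegmentObservation:
    segment_index: int
    responses: Responses = field(default_factory=dict)


@dataclass
class CrossingObservation:
    crossing_index: int
    responses: Responses = field(default_factory=dict)


@dataclass
class RouteObservation:
    """One participant's audited quarter-mile route."""

    participant_id: str
    route_id: str
    block_group_id: str
    route_responses: Responses = field(default_factory=dict)
    segments: list[SegmentObservation] = field(default_factory=list)
    crossings: list[CrossingObservation] = field(default_factory=list)


@dataclass
class AuditDataset:
    catalog: list[ItemDefinition]
    routes: list[RouteObservation]

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.catalog:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    participant_id: Optional[str]
    item_id: Optional[str]
    rule: str
    message: str


def _check_responses(
    responses: Responses,
    items: Mapping[str, ItemDefinition],
    expected_level: Level,
    participant_id: str,
    where: str,
    out: list[Violation],
) -> None:
    for item_id, value in responses.items():
        it = items.get(item_id)
        if it is None:
            out.append(Violation(participant_id, item_id, "unknown_item",
                                 f"{where}: item {item_id!r} not in catalog"))
            continue
        if it.level is not expected_level:
            out.append(Violation(participant_id, item_id, "wrong_level",
                                 f"{where}: item {item_id!r} is {it.level.value}-level"))
            continue
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue  # explicit missing
        if float(value) not in [float(v) for v in it.score_levels]:
            out.append(Violation(
                participant_id, item_id, "response_not_in_levels",
                f"{where}: response {value!r} for {item_id!r} not in "
                f"{it.score_levels}"))


def validate_dataset(ds: AuditDataset) -> list[Violation]:
    """Check every dataset invariant; violations are returned as data, not
    raised.  An empty list means the dataset is valid."""
    out: list[Violation] = []
    items = {it.item_id: it for it in ds.catalog}
    if len(items) != len(ds.catalog):
        out.append(Violation(None, None, "duplicate_item", "catalog has duplicate item_ids"))

    seen_participants: set[str] = set()
    for route in ds.routes:
        pid = route.participant_id
        if pid in seen_participants:
            out.append(Violation(pid, None, "duplicate_participant",
                                 f"participant {pid!r} has more than one route"))
        seen_participants.add(pid)

        if len(route.segments) < 1:
            out.append(Violation(pid, None, "min_one_segment",
                                 "route must contain at least one segment"))
        seg_idx = [s.segment_index for s in route.segments]
        if len(seg_idx) != len(set(seg_idx)):
            out.append(Violation(pid, None, "duplicate_segment_index",
                                 f"segment indices {seg_idx} are not unique"))
        cross_idx = [c.crossing_index for c in route.crossings]
        if len(cross_idx) != len(set(cross_idx)):
            out.append(Violation(pid, None, "duplicate_crossing_index",
                                 f"crossing indices {cross_idx} are not unique"))

        _check_responses(route.route_responses, items, Level.ROUTE, pid, "route", out)
        for seg in route.segments:
            _check_responses(seg.responses, items, Level.SEGMENT, pid,
                             f"segment {seg.segment_index}", out)
        for cr in route.crossings:
            _check_responses(cr.responses, items, Level.CROSSING, pid,
                             f"crossing {cr.crossing_index}", out)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: UTF-8, comma-separated, header row, empty cell = missing response.

ROUTE_KEY_COLS = ["participant_id", "route_id", "block_group_id"]


def _items_at(catalog: Iterable[ItemDefinition], level: Level) -> list[ItemDefinition]:
    return [it for it in catalog if it.level is level]


def _responses_from_row(row: pd.Series, items: list[ItemDefinition]) -> Responses:
    resp: Responses = {}
    for it in items:
        if it.item_id not in row.index:
            continue
        v = row[it.item_id]
        if pd.isna(v):
            continue
        resp[it.item_id] = float(v)
    return resp


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise AuditFormatError(f"{path}: missing required column(s) {missing}")


def read_audit_tables(
    route_path: str | Path,
    segment_path: str | Path,
    crossing_path: str | Path,
    catalog: Optional[list[ItemDefinition]] = None,
) -> AuditDataset:
    """Read the three audit CSVs into a validated :class:`AuditDataset`.

    Missing responses (empty cells) are preserved as missing, never coerced
    to zero.  Raises :class:`AuditFormatError` for structural problems and
    :class:`AuditValidationError` when a response is outside its item's
    score levels.
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    routes_df = pd.read_csv(route_path)
    segments_df = pd.read_csv(segment_path)
    crossings_df = pd.read_csv(crossing_path)

    _require_columns(routes_df, ROUTE_KEY_COLS, route_path)
    _require_columns(segments_df, ["participant_id", "segment_index"], segment_path)
    _require_columns(crossings_df, ["participant_id", "crossing_index"], crossing_path)

    route_items = _items_at(catalog, Level.ROUTE)
    seg_items = _items_at(catalog, Level.SEGMENT)
    cross_items = _items_at(catalog, Level.CROSSING)

    seg_by_pid = dict(tuple(segments_df.groupby("participant_id", sort=False)))
    cross_by_pid = dict(tuple(crossings_df.groupby("participant_id", sort=False)))

    routes: list[RouteObservation] = []
    for _, row in routes_df.iterrows():
        pid = str(row["participant_id"])
        segments = []
        if pid in seg_by_pid:
            sdf = seg_by_pid[pid].sort_values("segment_index")
            for _, srow in sdf.iterrows():
                segments.append(SegmentObservation(
                    segment_index=int(srow["segment_index"]),
                    responses=_responses_from_row(srow, seg_items)))
        crossings = []
        if pid in cross_by_pid:
            cdf = cross_by_pid[pid].sort_values("crossing_index")
            for _, crow in cdf.iterrows():
                crossings.append(CrossingObservation(
                    crossing_index=int(crow["crossing_index"]),
                    responses=_responses_from_row(crow, cross_items)))
        routes.append(RouteObservation(
            participant_id=pid,
            route_id=str(row["route_id"]),
            block_group_id=str(row["block_group_id"]),
            route_responses=_responses_from_row(row, route_items),
            segments=segments,
            crossings=crossings,
        ))

    ds = AuditDataset(catalog=catalog, routes=routes)
    violations = validate_dataset(ds)
    if violations:
        v = violations[0]
        raise AuditValidationError(
            f"{len(violations)} validation error(s); first: participant="
            f"{v.participant_id} item={v.item_id} rule={v.rule}: {v.message}")
    return ds


def write_audit_tables(ds: AuditDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three audit CSVs in the dialect :func:`read_audit_tables`
    accepts (lossless round trip).  Returns the paths keyed by table name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    route_items = _items_at(ds.catalog, Level.ROUTE)
    seg_items = _items_at(ds.catalog, Level.SEGMENT)
    cross_items = _items_at(ds.catalog, Level.CROSSING)

    route_rows, seg_rows, cross_rows = [], [], []
    for r in ds.routes:
        rec = {"participant_id": r.participant_id, "route_id": r.route_id,
               "block_group_id": r.block_group_id}
        for it in route_items:
            rec[it.item_id] = r.route_responses.get(it.item_id, np.nan)
        route_rows.append(rec)
        for seg in r.segments:
            srec = {"participant_id": r.participant_id,
                    "segment_index": seg.segment_index}
            for it in seg_items:
                srec[it.item_id] = seg.responses.get(it.item_id, np.nan)
            seg_rows.append(srec)
        for cr in r.crossings:
            crec = {"participant_id": r.participant_id,
                    "crossing_index": cr.crossing_index}
            for it in cross_items:
                crec[it.item_id] = cr.responses.get(it.item_id, np.nan)
            cross_rows.append(crec)

    paths = {
        "routes": out_dir / "routes.csv",
        "segments": out_dir / "segments.csv",
        "crossings": out_dir / "crossings.csv",
    }
    pd.DataFrame(route_rows, columns=ROUTE_KEY_COLS + [i.item_id for i in route_items]
                 ).to_csv(paths["routes"], index=False)
    pd.DataFrame(seg_rows, columns=["participant_id", "segment_index"]
                 + [i.item_id for i in seg_items]).to_csv(paths["segments"], index=False)
    pd.DataFrame(cross_rows, columns=["participant_id", "crossing_index"]
                 + [i.item_id for i in cross_items]).to_csv(paths["crossings"], index=False)
    return paths
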