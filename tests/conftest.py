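import pytest

from mapsmini.audit import (
    AuditDataset,
    CrossingObservation,
    RouteObservation,
    SegmentObservation,
    default_catalog,
)
from mapsmini.synthetic import SimConfig, simulate_study


def make_route(pid="P1", bg="BG1", seg_responses=None, cross_responses=None,
               route_responses=None):
    """A small hand-built route: seg_responses / cross_responses are lists of
    response dicts, one per segment / crossing."""
    seg_responses = seg_responses if seg_responses is not None else [{}]
    cross_responses = cross_responses if cross_responses is not None else []
    return RouteObservation(
        participant_id=pid,
        route_id=f"R-{pid}",
        block_group_id=bg,
        route_responses=dict(route_responses or {}),
        segments=[SegmentObservation(i, dict(r)) for i, r in enumerate(seg_responses)],
        crossings=[CrossingObservation(i, dict(r)) for i, r in enumerate(cross_responses)],
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_study():
    """A 160-participant study without accelerometer streams, shared across
    tests that only need tabular structure."""
    cfg = SimConfig(seed=42, n_block_groups=10,
                    participants={g: 40 for g in ("child", "adolescent", "adult", "older_adult")},
                    simulate_accel=False)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_accel_study():
    """A 24-participant study with full epoch streams for the three
    accelerometer-wearing groups."""
    cfg = SimConfig(seed=7, n_block_groups=4,
                    participants={g: 6 for g in ("child", "adolescent", "adult", "older_adult")},
                    simulate_accel=True)
    return simulate_study(cfg)
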