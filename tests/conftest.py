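"""Shared fixtures and independent oracles for the test suite.

The brute-force partition oracle here is deliberately naive: an O(n^2)
pairwise distance scan feeding networkx connected components.  It shares no
code with the package's k-d-tree clustering path, so agreement between the
two is evidence, not tautology.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

import networkx as nx
import numpy as np
import pytest

from gpscluster.model import GpsFix, StudyConfig

T0 = datetime(2014, 5, 1, 0, 0, 0, tzinfo=timezone.utc)


def make_fix(x, y, minutes=0.0, animal="W1", **kw):
    return GpsFix(
        animal_id=animal, timestamp=T0 + timedelta(minutes=float(minutes)), x=x, y=y, **kw
    )


def make_config(**over) -> StudyConfig:
    base = dict(
        label="study",
        buffer_m=30.0,
        min_locations=2,
        period_start="2014-05-01 00:00:00",
        period_end="2014-05-31 00:00:00",
        crs_epsg=32633,
    )
    base.update(over)
    return StudyConfig(**base)


@pytest.fixture
def config():
    return make_config()


def brute_force_partition(fixes, buffer_m, min_locations):
    """Independent oracle: O(n^2) edge scan + networkx connected components.

    Returns (clusters, singles) with clusters as a set of frozensets of
    indices and singles as a frozenset.
    """
    n = len(fixes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    limit = 2.0 * buffer_m
    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(fixes[i].x - fixes[j].x, fixes[i].y - fixes[j].y) <= limit:
                g.add_edge(i, j)
    clusters = set()
    singles = set()
    for comp in nx.connected_components(g):
        if len(comp) >= min_locations:
            clusters.add(frozenset(comp))
        else:
            singles.update(comp)
    return clusters, frozenset(singles)


def random_instance(rng: np.random.Generator, n: int, animal="A"):
    """A mixed random instance: a few tight clumps plus diffuse scatter."""
    pts = []
    n_clumps = int(rng.integers(1, 6))
    centers = rng.uniform(0, 5000, size=(n_clumps, 2))
    for i in range(n):
        if rng.random() < 0.6:
            c = centers[rng.integers(n_clumps)]
            p = c + rng.normal(0, rng.uniform(5, 80), size=2)
        else:
            p = rng.uniform(0, 5000, size=2)
        pts.append(p)
    return [make_fix(p[0], p[1], minutes=60.0 * i, animal=animal) for i, p in enumerate(pts)]
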