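"""Shared fixtures and oracle helpers for the test suite."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenokit import build_graph, generate_table1_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    """The canonical bronchiectasis worked-example fixture, pre-built."""
    release, read_codes, mappings, history = generate_table1_fixture()
    return SimpleNamespace(
        release=release,
        read_codes=read_codes,
        mappings=mappings,
        history=history,
        graph=build_graph(release),
    )


def isa_edges_of(release):
    """Active is-a edges (child, parent) between active concepts, read
    straight from the relationship table (independent of ConceptGraph)."""
    active = set(release.concepts.loc[release.concepts["active"], "id"])
    rel = release.relationships
    rows = rel[rel["active"] & (rel["typeId"] == 116680003)]
    return [
        (int(r.sourceId), int(r.destinationId))
        for r in rows.itertuples(index=False)
        if r.sourceId in active and r.destinationId in active
    ]


def simplify_oracle(graph, ids):
    """Exhaustive minimal-subset oracle: the smallest M ⊆ ids covering ids
    with descendants_or_self. Unique because every subsumption-maximal
    member of ids must belong to any cover."""
    import itertools

    ids = set(ids)
    desc = {i: graph.descendants_or_self({i}) for i in ids}
    for r in range(len(ids) + 1):
        for combo in itertools.combinations(sorted(ids), r):
            covered = set().union(*(desc[c] for c in combo)) if combo else set()
            if ids <= covered:
                return set(combo)
    return ids


def closure_descendants(release, roots):
    """Brute-force transitive-closure oracle via boolean matrix powers.

    descendants_or_self(roots) = all nodes with a child->parent path into
    a root, plus the roots.
    """
    active = sorted(set(release.concepts.loc[release.concepts["active"], "id"]))
    index = {cid: i for i, cid in enumerate(active)}
    n = len(active)
    adj = np.zeros((n, n), dtype=bool)
    for child, parent in isa_edges_of(release):
        adj[index[child], index[parent]] = True
    reach = np.eye(n, dtype=bool)
    power = np.eye(n, dtype=bool)
    for _ in range(n):
        power = power @ adj
        if not power.any():
            break
        reach |= power
    root_cols = [index[r] for r in roots]
    hits = reach[:, root_cols].any(axis=1)
    return {active[i] for i in np.flatnonzero(hits)}
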