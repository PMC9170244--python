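"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import grnseg as g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Three well-separated groups of four neurons each; fast to generate."""
    return g.SyntheticConfig(
        n_groups=3,
        group_sizes=[4, 4, 4],
        zone_centers=np.array([[40.0, 10.0, 0.0], [-30.0, 30.0, 5.0], [0.0, -45.0, -5.0]]),
        zone_spread=4.0,
        branch_depth=2,
        p_within=0.6,
        p_between=0.05,
        lambda_within=6.0,
        lambda_between=1.5,
        external_input_rate=50.0,
        external_output_rate=50.0,
        seed=7,
        class_labels=("bitter", "sugar", "water"),
    )


@pytest.fixture
def small_data(small_config):
    return g.generate(small_config)


@pytest.fixture
def chain_skeleton():
    """Three-node chain along x (parents -1, 1, 2)."""
    return g.NeuronSkeleton(
        neuron_id="chain",
        node_ids=[1, 2, 3],
        parent_ids=[-1, 1, 2],
        coords=[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
        radii=[0.5, 0.5, 0.5],
        labels=[1, 2, 2],
    )


def random_dotprops(rng, n_points, scale=10.0, neuron_id="dp"):
    """Random point cloud with random unit tangents (oracle-side helper)."""
    pts = rng.uniform(-scale, scale, size=(n_points, 3))
    tan = rng.normal(size=(n_points, 3))
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return g.DotProps(neuron_id, pts, tan)


def brute_force_raw_score(query, target, f):
    """Exhaustive nearest-neighbour NBLAST raw score: O(n*m) all-pairs."""
    total = 0.0
    for p, u in zip(query.points, query.tangents):
        d2 = ((target.points - p) ** 2).sum(axis=1)
        j = int(np.argmin(d2))  # argmin returns the lowest index on ties
        adot = abs(float(np.dot(u, target.tangents[j])))
        total += float(f(np.sqrt(d2[j]), min(adot, 1.0)))
    return total


def naive_ward(x):
    """O(n^3) greedy Ward agglomeration via cluster centroids.

    Returns (merges, partitions): merges are (a, b, joining_cost, size)
    rows in scipy cluster indexing; partitions[k] is the set of frozensets
    of leaf indices present when k clusters remain.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    clusters = {i: (frozenset([i]), x[i].copy(), 1) for i in range(n)}
    partitions = {n: {frozenset([i]) for i in range(n)}}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                _, ca, na = clusters[a]
                _, cb, nb = clusters[b]
                cost = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        sa, ca, na = clusters.pop(a)
        sb, cb, nb = clusters.pop(b)
        merged = sa | sb
        centroid = (na * ca + nb * cb) / (na + nb)
        clusters[next_id] = (merged, centroid, na + nb)
        merges.append((a, b, cost, na + nb))
        partitions[len(clusters)] = {s for s, _, _ in clusters.values()}
        next_id += 1
    return merges, partitions


def partition_sets(assignment):
    """A GroupAssignment as a set of frozensets of row indices."""
    groups = {}
    for i, lab in enumerate(assignment.labels):
        groups.setdefault(int(lab), set()).add(i)
    return {frozenset(v) for v in groups.values()}
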