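"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's up_dist arithmetic: they walk
the edge graph step by step, summing edge lengths along explicit downstream
paths, so they can certify the matrix implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

import streamnet as sn
from streamnet.covariance import CovarianceComponent, CovarianceParams
from streamnet.network import Site, StreamNetwork, segment_weight


# ---------------------------------------------------------------------------
# small hand-checkable networks


@pytest.fixture
def fork_network() -> StreamNetwork:
    """Two headwater edges (1, 2) joining into outlet edge 3.

    Lengths 2, 4, 10; additive attribute 30, 10, 40 so the junction weights
    are 0.75 / 0.25.
    """
    net = sn.build_network(
        [
            {"edge_id": 1, "down_edge_id": 3, "length": 2.0, "additive_attr": 30.0},
            {"edge_id": 2, "down_edge_id": 3, "length": 4.0, "additive_attr": 10.0},
            {"edge_id": 3, "down_edge_id": None, "length": 10.0, "additive_attr": 40.0},
        ]
    )
    return sn.compute_afv(net)


@pytest.fixture
def single_edge_network() -> StreamNetwork:
    net = sn.build_network(
        [{"edge_id": 1, "down_edge_id": None, "length": 5.0, "additive_attr": 1.0}]
    )
    return sn.compute_afv(net)


def random_network(seed: int, n_edges: int = 40, **kw) -> StreamNetwork:
    cfg = sn.NetworkGeneratorConfig(n_edges=n_edges, seed=seed, **kw)
    return sn.generate_network(cfg)


def random_sites(net: StreamNetwork, n: int, seed: int) -> list[Site]:
    rng = np.random.default_rng(seed)
    edge_ids = sorted(net.edges)
    lengths = np.array([net.edges[e].length for e in edge_ids])
    p = lengths / lengths.sum()
    recs = []
    for i in range(n):
        eid = edge_ids[rng.choice(len(edge_ids), p=p)]
        e = net.edges[eid]
        ratio = float(rng.uniform())
        recs.append(
            {
                "site_id": i + 1,
                "edge_id": eid,
                "ratio": ratio,
                "x": e.x_down + ratio * (e.x_up - e.x_down),
                "y": e.y_down + ratio * (e.y_up - e.y_down),
                "x1": float(rng.normal()),
            }
        )
    return sn.locate_sites(recs, net)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_pair(net: StreamNetwork, si: Site, sj: Site):
    """(D[i,j], D[j,i]) by explicit edge-walk; inf for different networks."""
    ei, ej = net.edges[si.edge_id], net.edges[sj.edge_id]
    if ei.net_id != ej.net_id:
        return np.inf, np.inf

    def walk(site):
        """List of (edge_id, distance from site to that edge's downstream node)."""
        e = net.edges[site.edge_id]
        d = site.ratio * e.length
        out = [(e.edge_id, d)]
        while e.down_edge_id is not None:
            e = net.edges[e.down_edge_id]
            d += e.length
            out.append((e.edge_id, d))
        return out

    pi, pj = walk(si), walk(sj)
    path_i = {e: d for e, d in pi}
    path_j = {e: d for e, d in pj}

    # same edge: direct comparison along the segment
    if si.edge_id == sj.edge_id:
        di = si.ratio * ei.length
        dj = sj.ratio * ej.length
        return max(di - dj, 0.0), max(dj - di, 0.0)
    # sj's edge on si's path: si flows past sj's location (or vice versa)
    if sj.edge_id in path_i:
        d_to_node = path_i[sj.edge_id]  # si -> downstream node of sj's edge
        d = d_to_node - sj.ratio * ej.length
        return d, 0.0
    if si.edge_id in path_j:
        d_to_node = path_j[si.edge_id]
        d = d_to_node - si.ratio * ei.length
        return 0.0, d
    # flow-unconnected: first edge of si's walk shared with sj's walk; the
    # meeting point is that edge's upstream node
    for e, d in pi:
        if e in path_j:
            up_len = net.edges[e].length
            return d - up_len, path_j[e] - up_len
    raise AssertionError("same-network sites must share a downstream edge")


def brute_force_weight(net: StreamNetwork, si: Site, sj: Site) -> float:
    """Tail-up weight as sqrt of the product of junction segment weights
    crossed between the two sites' edges on the connecting path."""
    dij, dji = brute_force_pair(net, si, sj)
    if not np.isfinite(dij) or min(dij, dji) > 0.0:
        return 0.0
    upstream, downstream = (si, sj) if dij >= dji else (sj, si)
    # product of omega over edges from the upstream site's edge down to,
    # but excluding, the downstream site's edge
    prod = 1.0
    e = net.edges[upstream.edge_id]
    while e.edge_id != downstream.edge_id:
        prod *= segment_weight(net, e.edge_id)
        e = net.edges[e.down_edge_id]
    return float(np.sqrt(prod))


# ---------------------------------------------------------------------------
# canonical model configuration used throughout (tail-up exponential,
# tail-down spherical, Euclidean gaussian, plus a nugget)


@pytest.fixture(scope="session")
def reference_params() -> CovarianceParams:
    return CovarianceParams(
        tailup=CovarianceComponent("exponential", 2.0, 6.0),
        taildown=CovarianceComponent("spherical", 2.0, 6.0),
        euclid=CovarianceComponent("gaussian", 1.0, 5.0),
        nugget=0.5,
    )
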