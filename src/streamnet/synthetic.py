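"""Random dendritic networks, sites, and covariates for simulation studies.

The generator grows a tree edge-by-edge upstream from the outlet, embeds it
in the plane with jittered headings, accumulates upstream stream length as a
watershed-area proxy for the additive attribute, and places observed sites
uniformly over total stream length plus a systematic, fixed-spacing
prediction set along every edge.  Everything is driven by one seed, so any
dataset used in a test or study is reproducible without shipping files.

The planar embedding may self-intersect; only network distances and point
Euclidean distances enter the model, so geometric realism is not attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import StreamNetwork, build_network, compute_afv, locate_sites, Site

__all__ = ["NetworkGeneratorConfig", "generate_network", "generate_sites"]


@dataclass
class NetworkGeneratorConfig:
    """Knobs for the synthetic generator.

    Defaults give a mid-sized study network: 200 reaches with log-normal
    lengths (median 1 distance unit), 100 observed and 50 requested
    prediction sites.  ``branching_prob`` is the chance a new reach attaches
    at an existing single-upstream junction rather than extending a tip.
    """

    n_edges: int = 200
    branching_prob: float = 0.5
    length_log_mean: float = 0.0
    length_log_sd: float = 0.5
    n_obs: int = 100
    n_pred: int = 50
    pred_spacing: Optional[float] = None  # derived from n_pred when None
    heading_jitter: float = 0.5  # radians
    seed: int = 0


def generate_network(config: NetworkGeneratorConfig) -> StreamNetwork:
    """Grow a random dendritic network with planar embedding and AFVs."""
    if config.n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    rng = np.random.default_rng(config.seed)
    lengths = np.exp(
        rng.normal(config.length_log_mean, config.length_log_sd, config.n_edges)
    )

    down: dict[int, Optional[int]] = {1: None}
    children: dict[int, int] = {1: 0}
    # planar embedding: edge goes from its downstream node toward upstream
    heading: dict[int, float] = {1: math.pi / 2}
    down_xy: dict[int, tuple[float, float]] = {1: (0.0, 0.0)}
    up_xy: dict[int, tuple[float, float]] = {
        1: (
            lengths[0] * math.cos(heading[1]),
            lengths[0] * math.sin(heading[1]),
        )
    }

    for k in range(2, config.n_edges + 1):
        tips = [e for e, c in children.items() if c == 0]
        junctions = [e for e, c in children.items() if c == 1]
        if junctions and (not tips or rng.random() < config.branching_prob):
            parent = int(rng.choice(junctions))
        else:
            parent = int(rng.choice(tips))
        down[k] = parent
        children[parent] += 1
        children[k] = 0
        base = heading[parent]
        offset = (0.7 if children[parent] == 2 else 0.0) * rng.choice([-1.0, 1.0])
        heading[k] = base + offset + rng.normal(0.0, config.heading_jitter)
        down_xy[k] = up_xy[parent]
        L = lengths[k - 1]
        up_xy[k] = (
            down_xy[k][0] + L * math.cos(heading[k]),
            down_xy[k][1] + L * math.sin(heading[k]),
        )

    # additive attribute: accumulated upstream stream length incl. own edge,
    # a simple stand-in for cumulative watershed area
    upstream: dict[int, list[int]] = {e: [] for e in down}
    for e, d in down.items():
        if d is not None:
            upstream[d].append(e)
    attr: dict[int, float] = {}
    # iterative postorder accumulation from the outlet
    order: list[int] = []
    stack = [1]
    while stack:
        e = stack.pop()
        order.append(e)
        stack.extend(upstream[e])
    for e in reversed(order):
        attr[e] = float(lengths[e - 1]) + sum(attr[u] for u in upstream[e])

    records = [
        {
            "edge_id": e,
            "down_edge_id": down[e],
            "length": float(lengths[e - 1]),
            "additive_attr": attr[e],
            "x_down": down_xy[e][0],
            "y_down": down_xy[e][1],
            "x_up": up_xy[e][0],
            "y_up": up_xy[e][1],
        }
        for e in sorted(down)
    ]
    net = build_network(records)
    compute_afv(net)
    return net


def _point_on_edge(net: StreamNetwork, edge_id: int, ratio: float) -> tuple[float, float]:
    e = net.edges[edge_id]
    if e.x_down is None:
        raise ValueError("network has no planar embedding")
    return (
        e.x_down + ratio * (e.x_up - e.x_down),
        e.y_down + ratio * (e.y_up - e.y_down),
    )


def generate_sites(
    net: StreamNetwork, config: NetworkGeneratorConfig
) -> tuple[list[Site], list[Site]]:
    """Observed and prediction site collections with covariates.

    Observed sites are uniform over total stream length.  Prediction sites
    are systematic: on each edge of length L with spacing s, positions at
    ratios k*s/L for k = 1..floor(L/s), plus one site at the outlet itself,
    so at least one prediction site always exists.  Covariates: ``x1``
    standard normal and ``elev``, an elevation-like gradient increasing with
    upstream distance plus noise.
    """
    rng = np.random.default_rng(config.seed + 1)
    edge_ids = sorted(net.edges)
    lengths = np.array([net.edges[e].length for e in edge_ids])
    probs = lengths / lengths.sum()

    def covs(up_dist: float) -> dict[str, float]:
        return {
            "x1": float(rng.normal()),
            "elev": float(10.0 + 0.5 * up_dist + rng.normal(0.0, 0.5)),
        }

    obs_records = []
    chosen = rng.choice(len(edge_ids), size=config.n_obs, p=probs)
    for i, idx in enumerate(chosen):
        eid = edge_ids[idx]
        ratio = float(rng.uniform())
        x, y = _point_on_edge(net, eid, ratio)
        e = net.edges[eid]
        rec = {
            "site_id": i + 1,
            "edge_id": eid,
            "ratio": ratio,
            "x": x,
            "y": y,
        }
        rec.update(covs(e.up_dist_lower + ratio * e.length))
        obs_records.append(rec)

    if config.pred_spacing is not None:
        spacing = config.pred_spacing
    else:
        # per-edge placement loses on average half a spacing per edge to
        # flooring, so aim the spacing accordingly to land near n_pred
        spacing = net.total_length() / max(config.n_pred + net.n_edges / 2, 1)
    pred_records = []
    pid = 0
    for eid in edge_ids:
        e = net.edges[eid]
        positions = []
        if e.down_edge_id is None:
            positions.append(0.0)  # the outlet itself, always present
        k = 1
        while k * spacing <= e.length:
            positions.append(k * spacing / e.length)
            k += 1
        for ratio in positions:
            pid += 1
            x, y = _point_on_edge(net, eid, ratio)
            rec = {
                "site_id": pid,
                "edge_id": eid,
                "ratio": ratio,
                "x": x,
                "y": y,
            }
            rec.update(covs(e.up_dist_lower + ratio * e.length))
            pred_records.append(rec)

    return locate_sites(obs_records, net), locate_sites(pred_records, net)
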