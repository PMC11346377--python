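"""Dendritic stream-network representation.

A stream network is a directed tree of edges (reaches): every edge has at
most one downstream neighbor, and exactly one edge per network (the outlet)
has none.  Hydrologic position is tracked through ``up_dist``, the distance
from the network outlet measured along the stream.  Branching is summarized
by the additive function value (AFV), a per-edge number in (0, 1] derived
from an additive attribute such as cumulative watershed area; the AFV drives
the spatial weights of the tail-up covariance.

Conventions
-----------
* ``ratio`` locates a point on an edge as the fraction of edge length
  measured from the DOWNSTREAM node (0 = downstream end, 1 = upstream end).
* ``up_dist_lower``/``up_dist_upper`` of an edge are the hydrologic
  distances from the outlet to its downstream and upstream nodes.
* Multiple disconnected networks may coexist in one dataset, keyed by
  ``net_id``; each must have exactly one outlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CycleError, TopologyError

__all__ = [
    "StreamEdge",
    "StreamNetwork",
    "Site",
    "build_network",
    "compute_afv",
    "locate_sites",
]


@dataclass
class StreamEdge:
    """One stream reach.

    ``additive_attr`` is the additive variable (e.g., cumulative watershed
    area) from which AFVs are computed; it must be strictly positive.
    """

    edge_id: int
    down_edge_id: Optional[int]
    length: float
    additive_attr: float
    net_id: int = 1
    afv: Optional[float] = None
    up_dist_lower: float = math.nan  # outlet -> downstream node
    up_dist_upper: float = math.nan  # outlet -> upstream node
    # optional planar embedding of the (straight) edge segment
    x_down: Optional[float] = None
    y_down: Optional[float] = None
    x_up: Optional[float] = None
    y_up: Optional[float] = None


@dataclass
class StreamNetwork:
    """A validated collection of dendritic networks keyed by ``net_id``."""

    edges: dict[int, StreamEdge]
    outlets: dict[int, int]  # net_id -> outlet edge_id
    adjacency: dict[int, list[int]]  # edge_id -> upstream edge_ids

    def downstream_path(self, edge_id: int) -> list[int]:
        """Edge ids from ``edge_id`` (inclusive) down to the outlet."""
        try:
            return self._path_cache[edge_id]
        except AttributeError:
            self._path_cache: dict[int, list[int]] = {}
        except KeyError:
            pass
        path = []
        cur: Optional[int] = edge_id
        while cur is not None:
            path.append(cur)
            cur = self.edges[cur].down_edge_id
        self._path_cache[edge_id] = path
        return path

    def downstream_path_set(self, edge_id: int) -> frozenset[int]:
        try:
            cache = self._pathset_cache
        except AttributeError:
            cache = self._pathset_cache = {}
        if edge_id not in cache:
            cache[edge_id] = frozenset(self.downstream_path(edge_id))
        return cache[edge_id]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_length(self, net_id: Optional[int] = None) -> float:
        return sum(
            e.length
            for e in self.edges.values()
            if net_id is None or e.net_id == net_id
        )


@dataclass
class Site:
    """A point located on an edge of a stream network.

    ``up_dist`` = up_dist_lower(edge) + ratio * length(edge).  Prediction
    sites carry ``response=None``.
    """

    site_id: int | str
    edge_id: int
    ratio: float
    x: float
    y: float
    up_dist: float = math.nan
    net_id: int = 1
    afv: float = math.nan
    response: Optional[float] = None
    covariates: dict[str, float] = field(default_factory=dict)


def build_network(edge_records: Iterable[Mapping]) -> StreamNetwork:
    """Validate an edge table and assemble a :class:`StreamNetwork`.

    Parameters
    ----------
    edge_records
        Iterable of mappings with keys ``edge_id``, ``down_edge_id`` (None,
        NaN or missing at the outlet), ``length``, ``additive_attr`` and
        optionally ``net_id``.

    Raises
    ------
    TopologyError
        Duplicate ids, dangling downstream references, self references,
        nonpositive lengths/attributes, or not exactly one outlet per
        network.
    CycleError
        Following downstream pointers revisits an edge.
    """
    edges: dict[int, StreamEdge] = {}
    for rec in edge_records:
        eid = int(rec["edge_id"])
        if eid in edges:
            raise TopologyError(f"duplicate edge_id {eid}")
        down = rec.get("down_edge_id")
        if down is not None and isinstance(down, float) and math.isnan(down):
            down = None
        if down is not None:
            down = int(down)
            if down == eid:
                raise TopologyError(f"edge {eid} references itself downstream")
        length = float(rec["length"])
        attr = float(rec["additive_attr"])
        if length <= 0:
            raise TopologyError(f"edge {eid}: length must be > 0, got {length}")
        if attr <= 0:
            raise ValueError(
                f"edge {eid}: additive_attr must be > 0, got {attr}"
            )
        edges[eid] = StreamEdge(
            edge_id=eid,
            down_edge_id=down,
            length=length,
            additive_attr=attr,
            net_id=int(rec.get("net_id", 1) or 1),
            x_down=rec.get("x_down"),
            y_down=rec.get("y_down"),
            x_up=rec.get("x_up"),
            y_up=rec.get("y_up"),
        )

    adjacency: dict[int, list[int]] = {eid: [] for eid in edges}
    outlets: dict[int, int] = {}
    for e in edges.values():
        if e.down_edge_id is None:
            if e.net_id in outlets:
                raise TopologyError(
                    f"network {e.net_id} has more than one outlet "
                    f"({outlets[e.net_id]} and {e.edge_id})"
                )
            outlets[e.net_id] = e.edge_id
        else:
            if e.down_edge_id not in edges:
                raise TopologyError(
                    f"edge {e.edge_id} references unknown downstream edge "
                    f"{e.down_edge_id}"
                )
            if edges[e.down_edge_id].net_id != e.net_id:
                raise TopologyError(
                    f"edge {e.edge_id} (net {e.net_id}) flows into a "
                    f"different network"
                )
            adjacency[e.down_edge_id].append(e.edge_id)

    # cycle detection: follow downstream pointers from every edge
    state: dict[int, int] = {}  # 0 visiting, 1 done
    for start in edges:
        if state.get(start) == 1:
            continue
        chain = []
        cur: Optional[int] = start
        while cur is not None and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise CycleError(
                    f"cycle detected through edge {cur} while walking "
                    f"downstream from edge {start}"
                )
            state[cur] = 0
            chain.append(cur)
            cur = edges[cur].down_edge_id
        for eid in chain:
            state[eid] = 1

    for e in edges.values():
        if e.net_id not in outlets:
            raise TopologyError(f"network {e.net_id} has no outlet")

    net = StreamNetwork(edges=edges, outlets=outlets, adjacency=adjacency)
    _compute_updist(net)
    return net


def _compute_updist(net: StreamNetwork) -> None:
    """Fill up_dist_lower/up_dist_upper by sweeping upstream from outlets."""
    for outlet in net.outlets.values():
        stack = [(outlet, 0.0)]
        while stack:
            eid, lower = stack.pop()
            e = net.edges[eid]
            e.up_dist_lower = lower
            e.up_dist_upper = lower + e.length
            for up in net.adjacency[eid]:
                stack.append((up, e.up_dist_upper))


def compute_afv(net: StreamNetwork) -> StreamNetwork:
    """Populate additive function values on every edge, in place.

    The outlet edge gets AFV 1.  At every junction, each upstream edge u of
    edge d receives the segment weight
    ``omega(u) = additive_attr(u) / sum(additive_attr over siblings)`` and
    ``afv(u) = afv(d) * omega(u)``.  AFVs therefore lie in (0, 1] and are
    non-increasing upstream.
    """
    for e in net.edges.values():
        if e.additive_attr <= 0:
            raise ValueError(
                f"edge {e.edge_id}: additive_attr must be > 0 to compute AFVs"
            )
    for outlet in net.outlets.values():
        net.edges[outlet].afv = 1.0
        stack = [outlet]
        while stack:
            eid = stack.pop()
            d = net.edges[eid]
            ups = net.adjacency[eid]
            if not ups:
                continue
            total = sum(net.edges[u].additive_attr for u in ups)
            for u in ups:
                net.edges[u].afv = d.afv * net.edges[u].additive_attr / total
                stack.append(u)
    return net


def segment_weight(net: StreamNetwork, edge_id: int) -> float:
    """Junction weight omega of an edge relative to its siblings (1 at outlet)."""
    e = net.edges[edge_id]
    if e.down_edge_id is None:
        return 1.0
    sibs = net.adjacency[e.down_edge_id]
    total = sum(net.edges[s].additive_attr for s in sibs)
    return e.additive_attr / total


def locate_sites(site_records: Iterable[Mapping], net: StreamNetwork) -> list[Site]:
    """Place raw site rows on the network, computing up_dist and AFV.

    Raises ``KeyError`` for an unknown edge_id and ``ValueError`` for a
    ratio outside [0, 1].
    """
    out: list[Site] = []
    reserved = {
        "site_id", "edge_id", "ratio", "x", "y", "net_id", "netID", "response",
    }
    for rec in site_records:
        eid = int(rec["edge_id"])
        if eid not in net.edges:
            raise KeyError(f"site {rec.get('site_id')}: unknown edge_id {eid}")
        ratio = float(rec["ratio"])
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(
                f"site {rec.get('site_id')}: ratio must be in [0, 1], "
                f"got {ratio}"
            )
        edge = net.edges[eid]
        resp = rec.get("response")
        if resp is not None and isinstance(resp, float) and math.isnan(resp):
            resp = None
        covs = {
            k: float(v)
            for k, v in rec.items()
            if k not in reserved and v is not None
            and not (isinstance(v, float) and math.isnan(v))
        }
        out.append(
            Site(
                site_id=rec["site_id"],
                edge_id=eid,
                ratio=ratio,
                x=float(rec["x"]),
                y=float(rec["y"]),
                up_dist=edge.up_dist_lower + ratio * edge.length,
                net_id=edge.net_id,
                afv=edge.afv if edge.afv is not None else math.nan,
                response=None if resp is None else float(resp),
                covariates=covs,
            )
        )
    return out
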