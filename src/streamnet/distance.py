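"""Hydrologic distance matrices and tail-up spatial weights.

For a pair of sites on the same network, the downstream distance
``D[i, j]`` is the distance from site i downstream to the closest point on
the network that is also at-or-downstream of site j.  Writing
``a = max(D[i,j], D[j,i])`` and ``b = min(D[i,j], D[j,i])``, the total
stream distance is ``h = a + b`` and the pair is flow-connected exactly
when ``b = 0`` (one site lies on the other's downstream path).  Pairs on
different networks get infinite stream distance; only the Euclidean
covariance component can act across networks.

Tail-up weights use additive function values: for a flow-connected pair
with upstream-site AFV ``A_u`` and downstream-site AFV ``A_d``,
``W = sqrt(A_u / A_d)``, which equals the square root of the product of the
junction segment weights crossed on the connecting path.  Flow-unconnected
pairs get weight 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import Site, StreamNetwork

__all__ = [
    "HydroDistances",
    "downstream_distance_matrix",
    "tailup_weights",
    "euclidean_distance_matrix",
    "save_distances",
    "load_distances",
]


@dataclass
class HydroDistances:
    """Pairwise stream-distance decomposition between two site collections.

    ``d_rows[i, j]`` is the downstream distance from row site i to the
    closest common downstream point with column site j; ``d_cols[i, j]`` is
    the same from column site j.  Entries are ``inf`` across networks.
    """

    d_rows: np.ndarray
    d_cols: np.ndarray

    @property
    def h(self) -> np.ndarray:
        """Total stream distance a + b."""
        return self.d_rows + self.d_cols

    @property
    def a(self) -> np.ndarray:
        return np.maximum(self.d_rows, self.d_cols)

    @property
    def b(self) -> np.ndarray:
        return np.minimum(self.d_rows, self.d_cols)

    @property
    def same_network(self) -> np.ndarray:
        return np.isfinite(self.d_rows)

    @property
    def flow_connected(self) -> np.ndarray:
        """True where one site is on the other's downstream path."""
        return self.same_network & (self.b == 0.0)

    @property
    def D(self) -> np.ndarray:
        """Alias for the asymmetric row->column downstream distances."""
        return self.d_rows


def _pair_geometry(net: StreamNetwork, e_r: int, e_c: int):
    """Relation of two edges: how sites on them connect downstream.

    Returns ("same", None), ("row_up", None) meaning the row edge is
    strictly upstream of the column edge, ("col_up", None), or
    ("fu", junction_up_dist) for flow-unconnected edges, where
    junction_up_dist is the up_dist of the closest common downstream node.
    Cross-network pairs return ("disjoint", None).
    """
    if e_r == e_c:
        return ("same", None)
    er = net.edges[e_r]
    ec = net.edges[e_c]
    if er.net_id != ec.net_id:
        return ("disjoint", None)
    set_c = net.downstream_path_set(e_c)
    if e_r in set_c:
        return ("col_up", None)  # column edge drains through the row edge
    set_r = net.downstream_path_set(e_r)
    if e_c in set_r:
        return ("row_up", None)
    # first edge of the row path that lies on the column path: the common
    # downstream point is that edge's upstream node
    for eid in net.downstream_path(e_r):
        if eid in set_c:
            return ("fu", net.edges[eid].up_dist_upper)
    raise AssertionError("edges on one network must share a downstream path")


def downstream_distance_matrix(
    rows: Sequence[Site], cols: Sequence[Site], net: StreamNetwork
) -> HydroDistances:
    """Asymmetric downstream-distance matrices between two site sets.

    Supports square observed x observed blocks as well as rectangular
    observed x prediction blocks; the same object may be passed as both
    arguments.
    """
    n, m = len(rows), len(cols)
    d_rows = np.zeros((n, m))
    d_cols = np.zeros((n, m))
    geom_cache: dict[tuple[int, int], tuple] = {}
    for i, si in enumerate(rows):
        for j, sj in enumerate(cols):
            key = (si.edge_id, sj.edge_id)
            rel = geom_cache.get(key)
            if rel is None:
                rel = _pair_geometry(net, si.edge_id, sj.edge_id)
                geom_cache[key] = rel
            kind, jup = rel
            if kind == "same":
                if si.up_dist >= sj.up_dist:
                    d_rows[i, j] = si.up_dist - sj.up_dist
                else:
                    d_cols[i, j] = sj.up_dist - si.up_dist
            elif kind == "col_up":
                d_cols[i, j] = sj.up_dist - si.up_dist
            elif kind == "row_up":
                d_rows[i, j] = si.up_dist - sj.up_dist
            elif kind == "fu":
                d_rows[i, j] = si.up_dist - jup
                d_cols[i, j] = sj.up_dist - jup
            else:  # disjoint networks
                d_rows[i, j] = math.inf
                d_cols[i, j] = math.inf
    return HydroDistances(d_rows=d_rows, d_cols=d_cols)


def tailup_weights(
    rows: Sequence[Site],
    cols: Sequence[Site],
    net: StreamNetwork,
    dists: HydroDistances | None = None,
) -> np.ndarray:
    """Tail-up spatial weight matrix sqrt(A_up / A_down), 0 when unconnected.

    Because AFVs never increase moving upstream, the upstream member of a
    flow-connected pair always holds the smaller AFV; the ratio min/max is
    therefore orientation-free and also covers sites co-located at a
    junction but assigned to different edges.
    """
    afr = np.array([s.afv for s in rows])
    afc = np.array([s.afv for s in cols])
    if np.any(~np.isfinite(afr)) or np.any(~np.isfinite(afc)):
        raise ValueError("AFVs missing: run compute_afv before tailup_weights")
    if np.any(afr <= 0) or np.any(afc <= 0):
        raise ValueError("AFVs must be strictly positive")
    if dists is None:
        dists = downstream_distance_matrix(rows, cols, net)
    W = np.zeros(dists.d_rows.shape)
    fc = dists.flow_connected
    # AFV is non-increasing upstream, so on a flow-connected pair the
    # upstream member always carries the smaller AFV: A_up/A_down = min/max.
    # This also handles co-located sites assigned to different edges.
    outer_r = np.broadcast_to(afr[:, None], W.shape)
    outer_c = np.broadcast_to(afc[None, :], W.shape)
    ratio = np.minimum(outer_r, outer_c) / np.maximum(outer_r, outer_c)
    W[fc] = np.sqrt(ratio[fc])
    return W


def euclidean_distance_matrix(
    rows: Sequence[Site], cols: Sequence[Site]
) -> np.ndarray:
    """Straight-line distances between two site collections."""
    xr = np.array([(s.x, s.y) for s in rows], dtype=float)
    xc = np.array([(s.x, s.y) for s in cols], dtype=float)
    diff = xr[:, None, :] - xc[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def save_distances(
    dists: HydroDistances,
    directory: str | Path,
    name: str = "obs",
    row_ids: Sequence | None = None,
    col_ids: Sequence | None = None,
    overwrite: bool = False,
) -> Path:
    """Persist a distance block to ``directory/name.npz`` with id indexes.

    Mirrors the distance-matrix folder a stream-network workflow writes next
    to its data; one file per (network, prediction-set) block.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    target = directory / f"{name}.npz"
    if target.exists() and not overwrite:
        raise FileExistsError(
            f"{target} exists; pass overwrite=True to replace it"
        )
    np.savez_compressed(
        target,
        d_rows=dists.d_rows,
        d_cols=dists.d_cols,
        row_ids=np.asarray(row_ids if row_ids is not None else []),
        col_ids=np.asarray(col_ids if col_ids is not None else []),
    )
    return target


def load_distances(directory: str | Path, name: str = "obs") -> HydroDistances:
    with np.load(Path(directory) / f"{name}.npz", allow_pickle=False) as z:
        return HydroDistances(d_rows=z["d_rows"], d_cols=z["d_cols"])
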