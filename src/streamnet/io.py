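"""Reading and writing stream-network datasets.

A dataset on disk is a directory with an edge table, an observed-site table,
and zero or more named prediction-site tables, as CSV (``edges.csv``,
``obs.csv``, ``pred_<name>.csv``) or GeoJSON (same stems, ``.geojson``).
GeoJSON edges are LineString features and sites are Point features; all
tabular attributes ride in ``properties``.  Coordinates are assumed planar
(projected); there is no geodesic support.

The classic ``.ssn`` folder (shapefile-based) is a compatibility dialect
behind :func:`read_ssn_folder`; it needs the optional ``geopandas``
dependency and is not required by anything else in the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, SchemaError
from .network import Site, StreamNetwork, build_network, compute_afv, locate_sites

__all__ = ["SSNDataset", "read_dataset", "write_dataset", "sites_to_frame"]

_EDGE_COLS = ["edge_id", "down_edge_id", "length", "additive_attr"]
_SITE_COLS = ["site_id", "edge_id", "ratio", "x", "y"]
_EDGE_OPTIONAL = ["net_id", "x_down", "y_down", "x_up", "y_up"]


@dataclass
class SSNDataset:
    """In-memory stream-network dataset: network, observed sites, prediction sets."""

    network: StreamNetwork
    obs: list[Site]
    preds: dict[str, list[Site]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def sites_to_frame(sites: Sequence[Site]) -> pd.DataFrame:
    """Flatten Site objects (covariates included) into a DataFrame."""
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "edge_id": s.edge_id,
            "ratio": s.ratio,
            "x": s.x,
            "y": s.y,
            "net_id": s.net_id,
            "up_dist": s.up_dist,
            "afv": s.afv,
            "response": s.response,
        }
        row.update(s.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix == ".geojson":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
        rows = []
        for feat in gj.get("features", []):
            rec = dict(feat.get("properties") or {})
            geom = feat.get("geometry") or {}
            if geom.get("type") == "Point":
                rec.setdefault("x", geom["coordinates"][0])
                rec.setdefault("y", geom["coordinates"][1])
            elif geom.get("type") == "LineString":
                cs = geom["coordinates"]
                # convention: LineString runs downstream -> upstream
                rec.setdefault("x_down", cs[0][0])
                rec.setdefault("y_down", cs[0][1])
                rec.setdefault("x_up", cs[-1][0])
                rec.setdefault("y_up", cs[-1][1])
            rows.append(rec)
        return pd.DataFrame(rows)
    raise FormatError(f"unrecognized table format: {path}")


def _find_table(directory: Path, stem: str) -> Optional[Path]:
    for ext in (".csv", ".geojson"):
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    return None


def _validate_columns(df: pd.DataFrame, required: list[str], what: str,
                      violations: list[str]) -> None:
    for col in required:
        if col not in df.columns:
            violations.append(f"{what}: missing required column {col!r}")


def read_dataset(
    path: str | Path,
    predpts: Optional[Sequence[str]] = None,
    require_response: bool = True,
) -> SSNDataset:
    """Read and fully validate a dataset directory.

    ``predpts`` restricts/asserts which prediction sets to load; by default
    every ``pred_<name>`` table found is loaded.  All schema violations are
    collected and reported in one :class:`SchemaError`.
    ``require_response=False`` admits observed sites without responses, e.g.
    a freshly generated design awaiting simulation.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a dataset directory")
    edges_path = _find_table(path, "edges")
    obs_path = _find_table(path, "obs")
    violations: list[str] = []
    if edges_path is None:
        violations.append("edges table (edges.csv or edges.geojson) not found")
    if obs_path is None:
        violations.append("observed-site table (obs.csv or obs.geojson) not found")

    available = {}
    for p in sorted(path.glob("pred_*.csv")) + sorted(path.glob("pred_*.geojson")):
        available.setdefault(p.stem[len("pred_"):], p)
    if predpts is None:
        wanted = dict(available)
    else:
        wanted = {}
        for name in predpts:
            if name not in available:
                violations.append(f"prediction set {name!r} not found in {path}")
            else:
                wanted[name] = available[name]
    if violations:
        raise SchemaError(violations)

    edges_df = _read_table(edges_path)
    obs_df = _read_table(obs_path)
    pred_dfs = {name: _read_table(p) for name, p in wanted.items()}

    if "netID" in edges_df.columns and "net_id" not in edges_df.columns:
        edges_df = edges_df.rename(columns={"netID": "net_id"})
    _validate_columns(edges_df, _EDGE_COLS, "edges", violations)
    _validate_columns(obs_df, _SITE_COLS, "obs", violations)
    for name, df in pred_dfs.items():
        _validate_columns(df, _SITE_COLS, f"pred_{name}", violations)
    if not violations:
        if edges_df["edge_id"].duplicated().any():
            violations.append("edges: duplicate edge_id values")
        known = set(edges_df["edge_id"].astype(int))
        for what, df in [("obs", obs_df)] + [
            (f"pred_{k}", v) for k, v in pred_dfs.items()
        ]:
            bad = set(df["edge_id"].astype(int)) - known
            if bad:
                violations.append(f"{what}: unknown edge_id values {sorted(bad)}")
            out = df[(df["ratio"] < 0) | (df["ratio"] > 1)]
            if len(out):
                violations.append(
                    f"{what}: ratio outside [0, 1] for site_id "
                    f"{out['site_id'].tolist()}"
                )
            if df["site_id"].duplicated().any():
                violations.append(f"{what}: duplicate site_id values")
    if violations:
        raise SchemaError(violations)

    net = build_network(edges_df.to_dict("records"))
    compute_afv(net)
    obs = locate_sites(obs_df.to_dict("records"), net)
    if require_response:
        missing = [s.site_id for s in obs if s.response is None]
        if missing:
            raise SchemaError(
                [f"obs: sites without a response value: {missing[:10]}"]
            )
    preds = {
        name: locate_sites(df.to_dict("records"), net)
        for name, df in pred_dfs.items()
    }
    return SSNDataset(
        network=net,
        obs=obs,
        preds=preds,
        provenance={"source": str(path), "format": edges_path.suffix.lstrip(".")},
    )


def _edge_records(net: StreamNetwork) -> list[dict]:
    recs = []
    for eid in sorted(net.edges):
        e = net.edges[eid]
        recs.append(
            {
                "edge_id": e.edge_id,
                "down_edge_id": e.down_edge_id,
                "length": e.length,
                "additive_attr": e.additive_attr,
                "net_id": e.net_id,
                "x_down": e.x_down,
                "y_down": e.y_down,
                "x_up": e.x_up,
                "y_up": e.y_up,
            }
        )
    return recs


def _site_key(s: Site):
    try:
        return (0, float(s.site_id), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(s.site_id))


def _site_records(sites: Sequence[Site]) -> tuple[list[dict], list[str]]:
    cov_names = sorted({k for s in sites for k in s.covariates})
    recs = []
    for s in sorted(sites, key=_site_key):
        rec = {
            "site_id": s.site_id,
            "edge_id": s.edge_id,
            "ratio": s.ratio,
            "x": s.x,
            "y": s.y,
            "response": s.response,
        }
        for k in cov_names:
            rec[k] = s.covariates.get(k)
        recs.append(rec)
    return recs, cov_names


def write_dataset(
    dataset: SSNDataset, path: str | Path, format: str = "csv"
) -> Path:
    """Write a dataset directory with deterministic row and column order.

    Rows are sorted by id and floats rendered with repr-round-trip
    precision, so writing the same dataset twice yields byte-identical
    files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format not in ("csv", "geojson"):
        raise ValueError("format must be 'csv' or 'geojson'")

    edge_recs = _edge_records(dataset.network)
    tables: list[tuple[str, list[dict], str]] = [("edges", edge_recs, "edge")]
    obs_recs, _ = _site_records(dataset.obs)
    tables.append(("obs", obs_recs, "site"))
    for name in sorted(dataset.preds):
        recs, _ = _site_records(dataset.preds[name])
        tables.append((f"pred_{name}", recs, "site"))

    for stem, recs, kind in tables:
        if format == "csv":
            df = pd.DataFrame(recs)
            df.to_csv(path / f"{stem}.csv", index=False)
        else:
            feats = []
            for rec in recs:
                rec = {
                    k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in rec.items()
                }
                if kind == "edge":
                    has_geom = rec.get("x_down") is not None
                    geom = (
                        {
                            "type": "LineString",
                            "coordinates": [
                                [rec["x_down"], rec["y_down"]],
                                [rec["x_up"], rec["y_up"]],
                            ],
                        }
                        if has_geom
                        else None
                    )
                else:
                    geom = {"type": "Point", "coordinates": [rec["x"], rec["y"]]}
                feats.append(
                    {"type": "Feature", "geometry": geom, "properties": rec}
                )
            with open(path / f"{stem}.geojson", "w") as fh:
                json.dump(
                    {"type": "FeatureCollection", "features": feats},
                    fh,
                    indent=1,
                    sort_keys=True,
                )
    return path


def read_ssn_folder(path: str | Path, predpts: Optional[Sequence[str]] = None):
    """Read a classic shapefile-based ``.ssn`` folder (compatibility dialect).

    Requires the optional geospatial dependency ``geopandas``.  Attribute
    names (``rid``, ``ratio``, ``upDist``, ``afvArea``, ...) are matched
    case-insensitively.
    """
    try:
        import geopandas  # noqa: F401
    except ImportError as err:
        raise ImportError(
            "reading classic .ssn folders requires the optional geospatial "
            "dependency 'geopandas'; install it or convert the data to the "
            "CSV/GeoJSON layout documented in streamnet.io"
        ) from err
    raise NotImplementedError(
        "shapefile .ssn import is not available in this build; convert to "
        "the CSV/GeoJSON layout"
    )
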