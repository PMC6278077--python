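"""District geography: contiguity graphs, synthetic grids, and cluster linkage.

Household-survey clusters carry deliberately displaced coordinates: reported
points are moved up to 2 km (urban) or 5 km (rural) from the true location to
protect respondent confidentiality.  Linking a displaced point to the district
polygon that contains it can therefore mis-assign clusters near borders.  The
buffer protocol implemented here assigns each cluster to the district
containing its reported point and flags it as *ambiguous* whenever a circular
buffer of the displacement radius also reaches any other district.

All coordinates are planar and in meters.  Geographic (lon/lat) input is
rejected rather than silently projected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from shapely.geometry import Point, box, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
from shapely.validation import explain_validity


class GeometryError(ValueError):
    """Invalid or unusable district geometry."""


class LinkageError(RuntimeError):
    """Cluster-to-district linkage cannot be performed."""


@dataclass(frozen=True)
class ClusterLocation:
    """A survey cluster with (displaced) planar coordinates in meters."""

    cluster_id: str
    x: float
    y: float
    urban: bool
    assigned_district: str | None = None
    ambiguous: bool = False
    # pre-displacement coordinates, known only for simulated clusters
    true_x: float | None = None
    true_y: float | None = None

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass
class DistrictGraph:
    """Districts with symmetric contiguity structure and optional polygons.

    ``district_ids`` fixes the canonical node order used everywhere downstream
    (precision matrices, random-effect vectors, estimate tables).
    """

    district_ids: tuple[str, ...]
    adjacency: dict[str, frozenset[str]]
    components: tuple[frozenset[str], ...]
    polygons: dict[str, BaseGeometry] | None = None

    def __post_init__(self) -> None:
        ids = set(self.district_ids)
        if len(ids) != len(self.district_ids):
            raise GeometryError("duplicate district ids")
        for d, nbrs in self.adjacency.items():
            if d in nbrs:
                raise GeometryError(f"adjacency is reflexive at {d!r}")
            for k in nbrs:
                if d not in self.adjacency.get(k, frozenset()):
                    raise GeometryError(f"adjacency not symmetric: {d!r}-{k!r}")
        self._index = {d: i for i, d in enumerate(self.district_ids)}

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.district_ids)

    def index(self, district_id: str) -> int:
        return self._index[district_id]

    def neighbors(self, district_id: str) -> frozenset[str]:
        return self.adjacency[district_id]

    def edges(self) -> Iterator[tuple[str, str]]:
        for d in self.district_ids:
            for k in sorted(self.adjacency[d]):
                if d < k:
                    yield (d, k)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric 0/1 neighbor matrix W in ``district_ids`` order."""
        n = self.n
        rows: list[int] = []
        cols: list[int] = []
        for a, b in self.edges():
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _as_polygon_items(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
) -> list[tuple[str, BaseGeometry]]:
    if isinstance(polygons, Mapping):
        return list(polygons.items())
    return list(polygons)


def build_adjacency(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
) -> DistrictGraph:
    """Build a rook-contiguity district graph from planar polygons.

    Two districts are neighbors iff their boundaries share more than a single
    point (a segment of positive length).  Corner-touching cells of a grid are
    therefore *not* neighbors.

    Raises :class:`GeometryError` naming the offending district for invalid or
    empty geometry.
    """
    items = _as_polygon_items(polygons)
    if not items:
        raise GeometryError("no district polygons supplied")
    for did, geom in items:
        if geom is None or geom.is_empty:
            raise GeometryError(f"district {did!r} has empty geometry")
        if not geom.is_valid:
            raise GeometryError(
                f"district {did!r} has invalid geometry: {explain_validity(geom)}"
            )
    ids = tuple(did for did, _ in items)
    geoms = [geom for _, geom in items]
    tree = STRtree(geoms)
    adjacency: dict[str, set[str]] = {d: set() for d in ids}
    for i, gi in enumerate(geoms):
        for j in tree.query(gi):
            j = int(j)
            if j <= i:
                continue
            inter = gi.intersection(geoms[j])
            if not inter.is_empty and inter.length > 0.0:
                adjacency[ids[i]].add(ids[j])
                adjacency[ids[j]].add(ids[i])
    return _finalize(ids, adjacency, dict(items))


def _finalize(
    ids: Sequence[str],
    adjacency: Mapping[str, set[str]],
    polygons: dict[str, BaseGeometry] | None,
) -> DistrictGraph:
    g = nx.Graph()
    g.add_nodes_from(ids)
    for d, nbrs in adjacency.items():
        g.add_edges_from((d, k) for k in nbrs)
    comps = tuple(
        sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    )
    return DistrictGraph(
        district_ids=tuple(ids),
        adjacency={d: frozenset(adjacency[d]) for d in ids},
        components=comps,
        polygons=polygons,
    )


def synthetic_district_grid(rows: int, cols: int, cell_km: float = 10.0) -> DistrictGraph:
    """A rows x cols grid of square districts with rook adjacency.

    The grid is the workhorse fixture: its edge count has the closed form
    ``2*rows*cols - rows - cols`` and its symmetries make exchangeability
    checks easy.  Cells are ``cell_km`` kilometers on a side, row-major order,
    ids ``d<row><col>`` zero-padded.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    side = cell_km * 1000.0
    items = []
    for r in range(rows):
        for c in range(cols):
            did = f"d{r:02d}{c:02d}"
            items.append((did, box(c * side, r * side, (c + 1) * side, (r + 1) * side)))
    return build_adjacency(items)


def _looks_geographic(clusters: Sequence[ClusterLocation]) -> bool:
    return bool(clusters) and all(
        abs(c.x) <= 180.0 and abs(c.y) <= 90.0 for c in clusters
    )


def link_clusters(
    clusters: Sequence[ClusterLocation],
    graph: DistrictGraph,
    urban_buffer_m: float = 2000.0,
    rural_buffer_m: float = 5000.0,
) -> list[ClusterLocation]:
    """Assign displaced clusters to districts with the 2 km / 5 km buffer rule.

    Each cluster is assigned to the district containing its reported point.
    It is flagged ``ambiguous`` when the displacement buffer (radius 2 km for
    urban, 5 km for rural points) reaches any other district, i.e. the true
    location could lie across the border.  Points outside every polygon are
    assigned to the nearest district within the buffer radius, else left
    unassigned.  Deterministic: ties break on the lexicographically smallest
    district id.
    """
    if graph.polygons is None:
        raise LinkageError(
            "district graph has no polygons; supply district ids directly "
            "instead of linking by coordinates"
        )
    if urban_buffer_m <= 0 or rural_buffer_m <= 0:
        raise ValueError("buffer radii must be positive")
    if _looks_geographic(clusters):
        raise GeometryError(
            "cluster coordinates look like lon/lat degrees; supply projected "
            "coordinates in meters"
        )
    ids = list(graph.district_ids)
    geoms = [graph.polygons[d] for d in ids]
    tree = STRtree(geoms)
    out: list[ClusterLocation] = []
    for cl in clusters:
        pt = cl.point
        radius = urban_buffer_m if cl.urban else rural_buffer_m
        near = [int(j) for j in tree.query(pt.buffer(radius).envelope)]
        containing = sorted(
            ids[j] for j in near if geoms[j].covers(pt)
        )
        within = {
            ids[j]: geoms[j].distance(pt)
            for j in near
            if geoms[j].distance(pt) < radius
        }
        if containing:
            assigned = containing[0]
            ambiguous = any(d != assigned for d in within)
        elif within:
            assigned = min(within, key=lambda d: (within[d], d))
            ambiguous = len(within) > 1
        else:
            assigned = None
            ambiguous = False
        out.append(replace(cl, assigned_district=assigned, ambiguous=ambiguous))
    return out


# -- interchange formats -------------------------------------------------


def write_geojson(graph: DistrictGraph, path: str | Path) -> None:
    """Write district polygons as a GeoJSON FeatureCollection."""
    if graph.polygons is None:
        raise GeometryError("graph has no polygons to write")
    features = [
        {
            "type": "Feature",
            "properties": {"district_id": d},
            "geometry": mapping(graph.polygons[d]),
        }
        for d in graph.district_ids
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_geojson(path: str | Path) -> DistrictGraph:
    """Read a FeatureCollection with a ``district_id`` property per feature."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    items = []
    for feat in obj.get("features", []):
        props = feat.get("properties") or {}
        if "district_id" not in props:
            raise GeometryError(f"{path}: feature missing 'district_id' property")
        items.append((str(props["district_id"]), shape(feat["geometry"])))
    return build_adjacency(items)


def write_adjacency(graph: DistrictGraph, path: str | Path) -> None:
    """Write the contiguity structure as a plain-text undirected edge list.

    Format: header ``#districts: n``, one ``#isolated: id`` comment per
    degree-zero district (so islands survive the round trip), then one
    ``id_a<TAB>id_b`` line per undirected edge.
    """
    lines = [f"#districts: {graph.n}"]
    for d in graph.district_ids:
        if not graph.adjacency[d]:
            lines.append(f"#isolated: {d}")
    lines += [f"{a}\t{b}" for a, b in graph.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_adjacency(path: str | Path) -> DistrictGraph:
    """Read the edge-list interchange format; polygons are absent."""
    n_expected = None
    ids: set[str] = set()
    edges: list[tuple[str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#districts:"):
            n_expected = int(line.split(":", 1)[1])
        elif line.startswith("#isolated:"):
            ids.add(line.split(":", 1)[1].strip())
        elif line.startswith("#"):
            continue
        else:
            a, b = line.split("\t")
            ids.update((a, b))
            edges.append((a, b))
    ordered = tuple(sorted(ids))
    if n_expected is not None and n_expected != len(ordered):
        raise GeometryError(
            f"{path}: header says {n_expected} districts, found {len(ordered)}"
        )
    adjacency: dict[str, set[str]] = {d: set() for d in ordered}
    for a, b in edges:
        if a != b:
            adjacency[a].add(b)
            adjacency[b].add(a)
    return _finalize(ordered, adjacency, None)
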