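"""Region-labeled triangle meshes of cell geometries.

A FLIP model domain is a 2-D cell cross-section partitioned into cytoplasm,
nucleus and zero or more protein aggregates (inclusion bodies), with a
circular bleach region inside the nucleus.  This module builds such meshes
synthetically from parametric outlines, imports/exports them in the Gmsh MSH
text format, and classifies mesh edges into the four interface classes the
discontinuous Galerkin discretization needs:

* ``BOUNDARY`` -- the outer cell boundary (zero-flux),
* ``INTERIOR`` -- edges between two triangles of the same compartment
  (carry the interior-penalty diffusion coupling),
* ``MEMBRANE`` -- the nuclear membrane (cytoplasm | nucleus),
* ``AGGREGATE`` -- aggregate boundaries (cytoplasm | aggregate).

All coordinates are physical micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "CYTOPLASM",
    "NUCLEUS",
    "aggregate_tag",
    "aggregate_id",
    "is_aggregate",
    "BOUNDARY",
    "INTERIOR",
    "MEMBRANE",
    "AGGREGATE",
    "Circle",
    "Ellipse",
    "SyntheticGeometrySpec",
    "TriangleMesh",
    "EdgeSet",
    "InvalidSpecError",
    "MeshingError",
    "MeshFormatError",
    "build_synthetic_cell",
    "classify_edges",
    "read_gmsh_mesh",
    "write_gmsh_mesh",
    "pixel_to_physical",
    "unit_square_mesh",
]

# ---------------------------------------------------------------------------
# compartment tags and edge classes
# ---------------------------------------------------------------------------

CYTOPLASM = 0
NUCLEUS = 1
_AGGREGATE_BASE = 2  # aggregate with 1-based id k carries tag 1 + k


def aggregate_tag(agg_id: int) -> int:
    """Compartment tag of the aggregate with 1-based id ``agg_id``."""
    if agg_id < 1:
        raise ValueError("aggregate ids are 1-based")
    return 1 + agg_id


def is_aggregate(tag) -> np.ndarray | bool:
    return np.asarray(tag) >= _AGGREGATE_BASE


def aggregate_id(tag: int) -> int:
    if tag < _AGGREGATE_BASE:
        raise ValueError(f"tag {tag} is not an aggregate tag")
    return tag - 1


BOUNDARY = 0
INTERIOR = 1
MEMBRANE = 2
AGGREGATE = 3


class InvalidSpecError(ValueError):
    """Synthetic-geometry spec violates a containment/disjointness invariant."""


class MeshingError(RuntimeError):
    """Mesh generation failed (an interface chord was lost or a triangle degenerated)."""


class MeshFormatError(ValueError):
    """MSH file could not be interpreted."""


# ---------------------------------------------------------------------------
# parametric outlines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Negative inside, positive outside."""
        pts = np.atleast_2d(pts)
        return np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1]) - self.radius

    def perimeter(self) -> float:
        return 2.0 * math.pi * self.radius

    def area(self) -> float:
        return math.pi * self.radius**2

    def sample(self, h: float) -> np.ndarray:
        n = max(8, int(math.ceil(self.perimeter() / h)))
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return np.column_stack(
            [self.center[0] + self.radius * np.cos(t), self.center[1] + self.radius * np.sin(t)]
        )


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_x: float
    semi_y: float

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        # radially scaled pseudo-distance; adequate for containment margins
        pts = np.atleast_2d(pts)
        q = np.hypot((pts[:, 0] - self.center[0]) / self.semi_x,
                     (pts[:, 1] - self.center[1]) / self.semi_y)
        return (q - 1.0) * min(self.semi_x, self.semi_y)

    def perimeter(self) -> float:
        a, b = self.semi_x, self.semi_y
        # Ramanujan approximation
        hh = ((a - b) / (a + b)) ** 2
        return math.pi * (a + b) * (1.0 + 3.0 * hh / (10.0 + math.sqrt(4.0 - 3.0 * hh)))

    def area(self) -> float:
        return math.pi * self.semi_x * self.semi_y

    def sample(self, h: float) -> np.ndarray:
        n = max(8, int(math.ceil(self.perimeter() / h)))
        # equalize arc length approximately by resampling a fine polyline
        t = np.linspace(0.0, 2.0 * math.pi, 40 * n, endpoint=False)
        xy = np.column_stack(
            [self.center[0] + self.semi_x * np.cos(t), self.center[1] + self.semi_y * np.sin(t)]
        )
        seg = np.hypot(*np.diff(np.vstack([xy, xy[:1]]), axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        target = np.linspace(0.0, s[-1] + seg[-1], n, endpoint=False)
        idx = np.searchsorted(s, target)
        return xy[np.clip(idx, 0, len(xy) - 1)]


Outline = Circle | Ellipse


@dataclass
class SyntheticGeometrySpec:
    """Parametric stand-in for a segmented cell geometry.

    ``cell`` and ``nucleus`` are closed convex outlines (circle or ellipse);
    ``aggregates`` are discs strictly inside the cytoplasm; ``bleach`` is a
    disc strictly inside the nucleus.  ``h`` is the target mesh edge length
    in micrometres.
    """

    cell: Outline
    nucleus: Outline
    aggregates: Sequence[Circle] = field(default_factory=list)
    bleach: Circle | None = None
    h: float = 1.5

    def validate(self) -> None:
        if self.h <= 0:
            raise InvalidSpecError("target edge length h must be positive")
        if not _strictly_inside(self.nucleus, self.cell):
            raise InvalidSpecError("nucleus must lie strictly inside the cell")
        for i, agg in enumerate(self.aggregates, start=1):
            if not _strictly_inside(agg, self.cell):
                raise InvalidSpecError(f"aggregate {i} not strictly inside the cell")
            if _overlaps_outline(agg, self.nucleus):
                raise InvalidSpecError(f"aggregate {i} overlaps the nucleus")
        for i in range(len(self.aggregates)):
            for j in range(i + 1, len(self.aggregates)):
                a, b = self.aggregates[i], self.aggregates[j]
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.radius + b.radius:
                    raise InvalidSpecError(f"aggregates {i + 1} and {j + 1} overlap")
        if self.bleach is not None and not _strictly_inside(self.bleach, self.nucleus):
            raise InvalidSpecError("bleach disc must lie strictly inside the nucleus")


def _strictly_inside(inner: Outline, outer: Outline) -> bool:
    pts = inner.sample(max(inner.perimeter() / 64.0, 1e-6))
    return bool(np.all(outer.signed_distance(pts) < -1e-9))


def _overlaps_outline(disc: Circle, outline: Outline) -> bool:
    pts = disc.sample(max(disc.perimeter() / 64.0, 1e-6))
    inside = outline.signed_distance(pts) < 1e-9
    center_inside = outline.signed_distance(np.array([disc.center]))[0] < 0
    return bool(np.any(inside) or center_inside)


# ---------------------------------------------------------------------------
# mesh containers
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Conforming triangle mesh with per-triangle compartment tags.

    ``vertices``: (nv, 2) float coordinates in micrometres.
    ``triangles``: (nt, 3) vertex indices, counter-clockwise.
    ``compartment``: (nt,) int tags (CYTOPLASM / NUCLEUS / aggregate_tag(k)).
    ``bleach_flag``: (nt,) bool, True on nucleus triangles inside the bleach disc.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    compartment: np.ndarray
    bleach_flag: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.compartment = np.asarray(self.compartment, dtype=np.int64)
        self.bleach_flag = np.asarray(self.bleach_flag, dtype=bool)
        nt = len(self.triangles)
        if not (len(self.compartment) == len(self.bleach_flag) == nt):
            raise ValueError("per-triangle array lengths disagree")
        self._orient_ccw()
        if np.any(self.bleach_flag & (self.compartment != NUCLEUS)):
            raise ValueError("bleach flag set on a non-nucleus triangle")

    def _orient_ccw(self) -> None:
        a = self.signed_areas()
        if np.any(np.abs(a) < 1e-14):
            raise ValueError("mesh contains a degenerate (zero-area) triangle")
        flip = a < 0
        if np.any(flip):
            tri = self.triangles.copy()
            tri[flip, 1], tri[flip, 2] = self.triangles[flip, 2], self.triangles[flip, 1]
            self.triangles = tri

    # geometry -----------------------------------------------------------
    def signed_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def areas(self) -> np.ndarray:
        return np.abs(self.signed_areas())

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def region_area(self, tag: int) -> float:
        return float(self.areas()[self.compartment == tag].sum())

    def bleach_area(self) -> float:
        return float(self.areas()[self.bleach_flag].sum())

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def aggregate_ids(self) -> list[int]:
        tags = np.unique(self.compartment)
        return sorted(aggregate_id(int(t)) for t in tags if t >= _AGGREGATE_BASE)


@dataclass
class EdgeSet:
    """Classified edges of a conforming triangle mesh.

    ``tri_minus`` / ``tri_plus``: adjacent triangle pair; ``tri_plus`` is -1
    on boundary edges.  For MEMBRANE and AGGREGATE edges the minus side is the
    cytoplasm triangle, so the indicator "minus side is cytoplasm" of the
    directional interface forms holds by construction.  ``normal`` is the unit
    normal of the minus side (pointing out of the minus triangle).
    """

    vert_a: np.ndarray
    vert_b: np.ndarray
    length: np.ndarray
    edge_class: np.ndarray
    tri_minus: np.ndarray
    tri_plus: np.ndarray
    normal: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.length)

    def of_class(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.edge_class == cls)

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.edge_class == c)) for c in (BOUNDARY, INTERIOR, MEMBRANE, AGGREGATE)}

    def class_length(self, cls: int) -> float:
        return float(self.length[self.edge_class == cls].sum())


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------


def classify_edges(mesh: TriangleMesh) -> EdgeSet:
    """Assign every mesh edge to exactly one of the four interface classes.

    Raises :class:`MeshingError` on non-conforming meshes (an edge shared by
    more than two triangles) and rejects nucleus-aggregate adjacency, which
    the exchange model does not define.
    """
    edge_map: dict[tuple[int, int], list[int]] = {}
    tri = mesh.triangles
    for t in range(len(tri)):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[t, a], tri[t, b]), max(tri[t, a], tri[t, b]))
            edge_map.setdefault(key, []).append(t)

    va, vb, length, cls, tmin, tplus, normals = [], [], [], [], [], [], []
    tags = mesh.compartment
    cents = mesh.centroids()
    for (i, j), ts in sorted(edge_map.items()):
        if len(ts) > 2:
            raise MeshingError(f"edge ({i},{j}) shared by {len(ts)} triangles: mesh is non-conforming")
        if len(ts) == 1:
            c, mn, pl = BOUNDARY, ts[0], -1
        else:
            t0, t1 = ts
            g0, g1 = int(tags[t0]), int(tags[t1])
            if g0 == g1:
                c = INTERIOR
                mn, pl = (t0, t1) if t0 < t1 else (t1, t0)
            else:
                pair = {g0, g1}
                if pair == {CYTOPLASM, NUCLEUS}:
                    c = MEMBRANE
                elif CYTOPLASM in pair and any(g >= _AGGREGATE_BASE for g in pair):
                    c = AGGREGATE
                elif NUCLEUS in pair and any(g >= _AGGREGATE_BASE for g in pair):
                    raise MeshingError("aggregate touches the nucleus; exchange across that interface is undefined")
                else:
                    raise MeshingError(f"adjacent aggregates with tags {g0},{g1} share an edge")
                # cytoplasm is always the minus side on physical interfaces
                mn, pl = (t0, t1) if g0 == CYTOPLASM else (t1, t0)
        pa, pb = mesh.vertices[i], mesh.vertices[j]
        ell = float(np.hypot(*(pb - pa)))
        if ell <= 0:
            raise MeshingError("zero-length edge")
        t_hat = (pb - pa) / ell
        n_hat = np.array([t_hat[1], -t_hat[0]])
        # orient the normal out of the minus triangle
        cen = cents[mn]
        mid = 0.5 * (pa + pb)
        if np.dot(n_hat, mid - cen) < 0:
            n_hat = -n_hat
        va.append(i), vb.append(j), length.append(ell), cls.append(c)
        tmin.append(mn), tplus.append(pl), normals.append(n_hat)

    return EdgeSet(
        vert_a=np.array(va, dtype=np.int64),
        vert_b=np.array(vb, dtype=np.int64),
        length=np.array(length),
        edge_class=np.array(cls, dtype=np.int64),
        tri_minus=np.array(tmin, dtype=np.int64),
        tri_plus=np.array(tplus, dtype=np.int64),
        normal=np.array(normals),
    )


# ---------------------------------------------------------------------------
# synthetic meshing
# ---------------------------------------------------------------------------


def build_synthetic_cell(spec: SyntheticGeometrySpec) -> TriangleMesh:
    """Mesh a parametric cell geometry with interfaces resolved as mesh edges.

    Interface curves (nuclear membrane, aggregate boundaries, bleach outline)
    are sampled as closed point chains; a hexagonal background lattice is laid
    over the cell with a cleared protection band around every curve so that the
    curve chords are locally Delaunay and appear as edges of the scipy Delaunay
    triangulation.  Chord recovery is verified and a :class:`MeshingError` is
    raised if any interface segment is missing.  Compartments are then assigned
    by point-in-region tests on triangle centroids.
    """
    spec.validate()
    h = spec.h

    curves: list[tuple[str, Outline]] = [("cell", spec.cell), ("nucleus", spec.nucleus)]
    curves += [(f"aggregate_{i}", a) for i, a in enumerate(spec.aggregates, start=1)]
    if spec.bleach is not None:
        curves.append(("bleach", spec.bleach))

    chains: dict[str, np.ndarray] = {}
    pts_list: list[np.ndarray] = []
    offsets: dict[str, tuple[int, int]] = {}
    n0 = 0
    for name, curve in curves:
        p = curve.sample(h)
        chains[name] = p
        offsets[name] = (n0, n0 + len(p))
        n0 += len(p)
        pts_list.append(p)

    # hexagonal background lattice, cleared near every constrained curve
    lat = _hex_lattice(spec.cell, h)
    keep = spec.cell.signed_distance(lat) < -0.55 * h
    for _, curve in curves[1:]:
        keep &= np.abs(curve.signed_distance(lat)) > 0.55 * h
    pts_list.append(lat[keep])
    points = np.vstack(pts_list)

    try:
        dela = Delaunay(points)
    except Exception as exc:  # pragma: no cover - qhull failure is pathological
        raise MeshingError(f"Delaunay triangulation failed: {exc}") from exc
    triangles = dela.simplices

    edge_set = set()
    for t in triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edge_set.add((min(t[a], t[b]), max(t[a], t[b])))
    for name, _ in curves:
        s, e = offsets[name]
        n = e - s
        for k in range(n):
            i, j = s + k, s + (k + 1) % n
            if (min(i, j), max(i, j)) not in edge_set:
                raise MeshingError(
                    f"interface chord {k} of '{name}' was not recovered; "
                    "reduce h or increase curve separation"
                )

    centroids = points[triangles].mean(axis=1)
    tags = np.full(len(triangles), CYTOPLASM, dtype=np.int64)
    in_nuc = spec.nucleus.signed_distance(centroids) < 0
    tags[in_nuc] = NUCLEUS
    for i, agg in enumerate(spec.aggregates, start=1):
        tags[agg.signed_distance(centroids) < 0] = aggregate_tag(i)
    flags = np.zeros(len(triangles), dtype=bool)
    if spec.bleach is not None:
        flags = (spec.bleach.signed_distance(centroids) < 0) & (tags == NUCLEUS)

    return TriangleMesh(points, triangles, tags, flags)


def _hex_lattice(cell: Outline, h: float) -> np.ndarray:
    if isinstance(cell, Circle):
        cx, cy = cell.center
        rx = ry = cell.radius
    else:
        cx, cy = cell.center
        rx, ry = cell.semi_x, cell.semi_y
    dy = h * math.sqrt(3.0) / 2.0
    ys = np.arange(cy - ry, cy + ry + dy, dy)
    rows = []
    for k, y in enumerate(ys):
        x0 = cx - rx + (0.5 * h if k % 2 else 0.0)
        xs = np.arange(x0, cx + rx + h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(rows)


def unit_square_mesh(n: int, tag: int = CYTOPLASM) -> TriangleMesh:
    """Structured right-triangle mesh of the unit square (2*n*n triangles).

    A single-compartment fixture used by the convergence and operator tests.
    """
    xs = np.linspace(0.0, 1.0, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    verts = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(n):
        for i in range(n):
            v00 = j * (n + 1) + i
            v10 = v00 + 1
            v01 = v00 + (n + 1)
            v11 = v01 + 1
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    nt = len(tris)
    return TriangleMesh(verts, np.array(tris), np.full(nt, tag), np.zeros(nt, dtype=bool))


# ---------------------------------------------------------------------------
# Gmsh MSH I/O
# ---------------------------------------------------------------------------

_CANONICAL_GROUPS = ("cytoplasm", "nucleus", "bleach")


def _region_to_tag(region: str) -> tuple[int, bool]:
    """Map a canonical region key to (compartment tag, bleach flag)."""
    if region == "cytoplasm":
        return CYTOPLASM, False
    if region == "nucleus":
        return NUCLEUS, False
    if region == "bleach":
        return NUCLEUS, True
    if region.startswith("aggregate_"):
        return aggregate_tag(int(region.split("_", 1)[1])), False
    raise MeshFormatError(f"unknown region key '{region}'")


def _default_physical_id(region: str) -> int:
    if region == "cytoplasm":
        return 1
    if region == "nucleus":
        return 2
    if region == "bleach":
        return 9
    return 10 + int(region.split("_", 1)[1])


def write_gmsh_mesh(mesh: TriangleMesh, path) -> None:
    """Write the mesh as Gmsh MSH 2.2 ASCII with named physical groups.

    Bleach-flagged nucleus triangles go into a separate ``bleach`` group so
    the flag round-trips through the file format.
    """
    regions: dict[int, str] = {}
    phys = np.empty(mesh.n_triangles, dtype=np.int64)
    for t in range(mesh.n_triangles):
        tag = int(mesh.compartment[t])
        if mesh.bleach_flag[t]:
            region = "bleach"
        elif tag == CYTOPLASM:
            region = "cytoplasm"
        elif tag == NUCLEUS:
            region = "nucleus"
        else:
            region = f"aggregate_{aggregate_id(tag)}"
        pid = _default_physical_id(region)
        regions[pid] = region
        phys[t] = pid

    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(regions))]
    for pid in sorted(regions):
        lines.append(f'2 {pid} "{regions[pid]}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_vertices))
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {x:.16g} {y:.16g} 0")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_triangles))
    for t in range(mesh.n_triangles):
        a, b, c = mesh.triangles[t] + 1
        lines.append(f"{t + 1} 2 2 {phys[t]} {phys[t]} {a} {b} {c}")
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gmsh_mesh(path, region_map: Mapping | None = None,
                   pixel_size: float | None = None) -> TriangleMesh:
    """Read a Gmsh MSH file (version 2.2 or 4.1 ASCII) into a tagged mesh.

    ``region_map`` maps physical-group names (or, for files without a
    ``$PhysicalNames`` section, integer physical ids) to the canonical region
    keys ``cytoplasm`` / ``nucleus`` / ``aggregate_<id>`` / ``bleach``.  When
    omitted, group names that already are canonical keys map to themselves.
    A physical group present in the file but absent from the map is an error
    naming the group.
    """
    with open(path) as fh:
        text = fh.read()
    sections = _split_msh_sections(text)
    if "MeshFormat" not in sections:
        raise MeshFormatError("missing $MeshFormat section")
    version = sections["MeshFormat"][0].split()[0]
    phys_names = _parse_physical_names(sections.get("PhysicalNames"))

    if version.startswith("2"):
        nodes, node_ids, elements = _parse_msh2(sections)
    elif version.startswith("4"):
        nodes, node_ids, elements = _parse_msh4(sections)
    else:
        raise MeshFormatError(f"unsupported MSH version {version}")

    if not elements:
        raise MeshFormatError("file contains no 2-D triangle elements")

    id_to_row = {nid: k for k, nid in enumerate(node_ids)}
    tris, groups = [], []
    for phys, conn in elements:
        tris.append([id_to_row[c] for c in conn])
        groups.append(phys)
    tris_arr = np.array(tris, dtype=np.int64)

    used = np.zeros(len(nodes), dtype=bool)
    used[tris_arr.ravel()] = True
    if not used.all():
        raise MeshFormatError(f"{int((~used).sum())} dangling vertices not referenced by any triangle")

    tags = np.empty(len(tris_arr), dtype=np.int64)
    flags = np.zeros(len(tris_arr), dtype=bool)
    for t, phys in enumerate(groups):
        key = phys_names.get(phys, phys)
        if region_map is not None and key in region_map:
            region = region_map[key]
        elif region_map is not None and phys in region_map:
            region = region_map[phys]
        elif region_map is None and isinstance(key, str):
            region = key
        else:
            raise MeshFormatError(f"physical group '{key}' has no entry in region_map")
        tags[t], flags[t] = _region_to_tag(region)

    return TriangleMesh(nodes[:, :2], tris_arr, tags, flags, pixel_size=pixel_size)


def _split_msh_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("$End"):
            current = None
        elif line.startswith("$"):
            current = line[1:]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _parse_physical_names(lines: list[str] | None) -> dict[int, str]:
    names: dict[int, str] = {}
    if not lines:
        return names
    for line in lines[1:]:
        parts = line.split(None, 2)
        if len(parts) == 3:
            names[int(parts[1])] = parts[2].strip().strip('"')
    return names


def _parse_msh2(sections) -> tuple[np.ndarray, list[int], list[tuple[int, list[int]]]]:
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshFormatError("missing $Nodes or $Elements section")
    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    nodes, node_ids = [], []
    for line in node_lines[1 : 1 + n_nodes]:
        parts = line.split()
        node_ids.append(int(parts[0]))
        nodes.append([float(parts[1]), float(parts[2]), float(parts[3])])
    elements = []
    elem_lines = sections["Elements"]
    n_elem = int(elem_lines[0])
    for line in elem_lines[1 : 1 + n_elem]:
        parts = [int(p) for p in line.split()]
        etype, ntags = parts[1], parts[2]
        conn = parts[3 + ntags :]
        if etype == 2:
            phys = parts[3] if ntags >= 1 else 0
            elements.append((phys, conn))
        elif etype in (1, 15):  # boundary lines / points are ignored
            continue
        else:
            raise MeshFormatError(f"unsupported 2-D element type {etype} (triangles only)")
    return np.array(nodes), node_ids, elements


def _parse_msh4(sections) -> tuple[np.ndarray, list[int], list[tuple[int, list[int]]]]:
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshFormatError("missing $Nodes or $Elements section")
    # surface entity -> physical tag
    surf_phys: dict[int, int] = {}
    ent = sections.get("Entities")
    if ent:
        counts = [int(x) for x in ent[0].split()]
        n_pts, n_crv, n_srf = counts[0], counts[1], counts[2]
        rows = ent[1:]
        for line in rows[n_pts + n_crv : n_pts + n_crv + n_srf]:
            parts = line.split()
            tag = int(parts[0])
            n_phys = int(parts[7])
            surf_phys[tag] = int(parts[8]) if n_phys >= 1 else 0

    node_lines = sections["Nodes"]
    header = node_lines[0].split()
    n_blocks = int(header[0])
    nodes, node_ids = [], []
    k = 1
    for _ in range(n_blocks):
        _, _, _, n_in_block = (int(x) for x in node_lines[k].split())
        k += 1
        ids = [int(node_lines[k + i]) for i in range(n_in_block)]
        k += n_in_block
        for i in range(n_in_block):
            parts = node_lines[k + i].split()
            nodes.append([float(parts[0]), float(parts[1]), float(parts[2])])
        k += n_in_block
        node_ids.extend(ids)

    elements = []
    elem_lines = sections["Elements"]
    n_blocks = int(elem_lines[0].split()[0])
    k = 1
    for _ in range(n_blocks):
        dim, etag, etype, n_in_block = (int(x) for x in elem_lines[k].split())
        k += 1
        for i in range(n_in_block):
            parts = [int(p) for p in elem_lines[k + i].split()]
            if dim == 2:
                if etype != 2:
                    raise MeshFormatError(f"unsupported 2-D element type {etype} (triangles only)")
                elements.append((surf_phys.get(etag, etag), parts[1:4]))
        k += n_in_block
    return np.array(nodes), node_ids, elements


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------


def pixel_to_physical(n_pixels: float, pixel_size: float) -> float:
    """Convert a pixel count to micrometres (``n_pixels * pixel_size``)."""
    if n_pixels < 0:
        raise ValueError("pixel count must be nonnegative")
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    return float(n_pixels) * float(pixel_size)
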