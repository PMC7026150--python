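"""Mesh and landmark geometry: the 11 facial distances and facial area.

Distances come in two kinds: *linear* (straight-line Euclidean between two
landmarks) and *geodesic* (shortest path constrained to the mesh surface).
Geodesics are approximated by Dijkstra over a graph that augments the mesh
edge graph with evenly spaced Steiner points on every edge, fully
connected within each face; endpoints are snapped to the nearest graph
node and the off-node offsets are added back, which keeps every geodesic
at or above the straight-line distance by the triangle inequality.

Units are millimetres throughout; mesh files are assumed to be in mm.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "LANDMARK_NAMES",
    "DISTANCE_REGISTRY",
    "DEFAULT_AREA_TRIANGULATION",
    "FaceMesh",
    "LandmarkSet",
    "FeatureVector",
    "GeodesicSolver",
    "load_mesh",
    "save_mesh",
    "geodesic_distance",
    "facial_area",
    "extract_features",
    "features_to_frame",
]

SNAP_TOLERANCE_MM = 2.0  # matches the stated scanner precision


class MeshFormatError(ValueError):
    """File could not be parsed as the requested mesh format."""


class MeshConnectivityError(ValueError):
    """The mesh region spanned by the landmarks is not connected."""


class DegenerateTriangleError(ValueError):
    """A triangle references the same landmark/vertex more than once."""


class LandmarkOffSurfaceError(ValueError):
    """A query point lies farther than the snap tolerance from the mesh."""


class MissingLandmarkError(KeyError):
    """A required named landmark is absent."""


#: The 13 canonical anthropometric landmark names.
LANDMARK_NAMES: tuple[str, ...] = (
    "trichion",
    "nasion",
    "pronasale",
    "subnasale",
    "labiale_superius",
    "stomion",
    "exocanthion_left",
    "exocanthion_right",
    "alare_left",
    "alare_right",
    "frontotemporale_left",
    "frontotemporale_right",
    "zygion_right",
)

#: feature name -> (landmark a, landmark b, "linear" | "geodesic").
#: Overridable: pass a modified copy to extract_features.
DISTANCE_REGISTRY: dict[str, tuple[str, str, str]] = {
    "linear_alar_base_width": ("alare_left", "alare_right", "linear"),
    "linear_nose_height": ("nasion", "subnasale", "linear"),
    "linear_upper_lip_height": ("subnasale", "stomion", "linear"),
    "geodesic_outer_canthal_width": ("exocanthion_left", "exocanthion_right", "geodesic"),
    "geodesic_forehead_height": ("trichion", "nasion", "geodesic"),
    "geodesic_forehead_width": ("frontotemporale_left", "frontotemporale_right", "geodesic"),
    "geodesic_right_upper_cheek_height": ("exocanthion_right", "zygion_right", "geodesic"),
    "geodesic_nasal_tip_protrusion": ("subnasale", "pronasale", "geodesic"),
    "geodesic_nose_height": ("nasion", "subnasale", "geodesic"),
    "geodesic_upper_lip_height": ("subnasale", "stomion", "geodesic"),
    "geodesic_nasal_bridge_length": ("nasion", "pronasale", "geodesic"),
}

# Fixed, documented triangulation used for facial area: triangle fans from
# three midline apexes over the facial outline, giving a layered coverage
# of the face region comparable in magnitude to published facial areas.
_OUTLINE = (
    "trichion", "frontotemporale_left", "exocanthion_left", "alare_left",
    "stomion", "alare_right", "zygion_right", "exocanthion_right",
    "frontotemporale_right",
)
_FAN_APEXES = ("nasion", "pronasale", "labiale_superius")
DEFAULT_AREA_TRIANGULATION: tuple[tuple[str, str, str], ...] = tuple(
    (apex, _OUTLINE[i], _OUTLINE[(i + 1) % len(_OUTLINE)])
    for apex in _FAN_APEXES
    for i in range(len(_OUTLINE))
)


@dataclass
class FaceMesh:
    """Triangulated surface: vertices (n, 3) in mm, faces (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be (m, 3)")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def validate(self) -> None:
        """Raise if face indices are out of range or any face is degenerate."""
        if self.n_faces and self.faces.max() >= self.n_vertices:
            raise MeshFormatError("face index exceeds vertex count")
        if self.n_faces and self.faces.min() < 0:
            raise MeshFormatError("negative face index")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas <= 0.0):
            raise DegenerateTriangleError(
                f"{int((areas <= 0).sum())} zero-area face(s) in mesh {self.subject_id!r}"
            )

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with col0 < col1."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def is_connected(self) -> bool:
        e = self.edges()
        g = csr_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        n_comp, _ = connected_components(g, directed=False)
        return n_comp == 1

    def surface_area(self) -> float:
        tri = self.vertices[self.faces]
        return float(0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum())


@dataclass
class LandmarkSet:
    """Named 3D anthropometric points for one subject."""

    points: dict[str, np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(f"landmark {name!r} missing for {self.subject_id!r}")

    def require(self, names: Iterable[str] = LANDMARK_NAMES) -> None:
        missing = sorted(set(names) - set(self.points))
        if missing:
            raise MissingLandmarkError(
                f"subject {self.subject_id!r} missing landmarks: {', '.join(missing)}"
            )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None, scale: float = 1.0) -> "LandmarkSet":
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return LandmarkSet(
            {k: scale * (R @ v) + t for k, v in self.points.items()}, self.subject_id
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": self.subject_id, "landmark": k, "x": v[0], "y": v[1], "z": v[2]}
            for k, v in self.points.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None) -> "LandmarkSet":
        if subject_id is not None:
            df = df[df.subject_id == subject_id]
        sid = str(df.subject_id.iloc[0]) if len(df) else (subject_id or "")
        return cls({r.landmark: np.array([r.x, r.y, r.z]) for r in df.itertuples()}, sid)

    @classmethod
    def from_csv(cls, path: str | Path, subject_id: str | None = None) -> "LandmarkSet":
        return cls.from_frame(pd.read_csv(path), subject_id)


@dataclass
class FeatureVector:
    """The 11 facial distances (mm) and facial area (mm^2) of one subject."""

    subject_id: str
    distances: dict[str, float]
    facial_area: float
    sex: str | None = None
    group: str | None = None

    def as_dict(self) -> dict[str, float]:
        out = dict(self.distances)
        out["facial_area"] = self.facial_area
        return out

    def validate(self, registry: Mapping[str, tuple[str, str, str]] = DISTANCE_REGISTRY) -> None:
        for k, v in self.distances.items():
            if not v > 0:
                raise ValueError(f"{self.subject_id}: distance {k} must be > 0, got {v}")
        if not self.facial_area > 0:
            raise ValueError(f"{self.subject_id}: facial_area must be > 0")


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical CSV schema."""
    from .tables import FEATURES  # canonical column order

    rows = []
    for fv in features:
        row = {"subject_id": fv.subject_id, "sex": fv.sex, "group": fv.group}
        row.update({f: fv.distances.get(f, np.nan) for f in FEATURES})
        row["facial_area"] = fv.facial_area
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mesh file I/O (PLY ascii / binary little-endian, OBJ v/f records)
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _load_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    raw = path.read_bytes()
    if not raw.startswith(b"ply"):
        raise MeshFormatError(f"{path}: not a PLY file")
    end = raw.find(b"end_header\n")
    if end < 0:
        raise MeshFormatError(f"{path}: unterminated PLY header")
    header = raw[: end].decode("ascii", errors="replace").splitlines()
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str, str | None]]]] = []
    for line in header[1:]:
        parts = line.split()
        if not parts or parts[0] == "comment":
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if parts[1] == "list":
                elements[-1][2].append((parts[4], parts[3], parts[2]))
            else:
                elements[-1][2].append((parts[2], parts[1], None))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"{path}: unsupported PLY format {fmt!r}")

    verts: np.ndarray | None = None
    faces: list[Sequence[int]] = []
    if fmt == "ascii":
        lines = body.decode("ascii").split("\n")
        cursor = 0
        for name, count, props in elements:
            rows = lines[cursor: cursor + count]
            cursor += count
            if name == "vertex":
                idx = {p[0]: i for i, (p) in enumerate(props)}
                data = np.array([[float(t) for t in ln.split()] for ln in rows])
                verts = data[:, [idx["x"], idx["y"], idx["z"]]]
            elif name == "face":
                for ln in rows:
                    toks = ln.split()
                    k = int(toks[0])
                    faces.append([int(t) for t in toks[1: 1 + k]])
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                fmt_str = "<" + "".join(_PLY_TYPES[p[1]] for p in props)
                stride = struct.calcsize(fmt_str)
                names = [p[0] for p in props]
                data = np.zeros((count, 3))
                for i in range(count):
                    vals = struct.unpack_from(fmt_str, body, offset + i * stride)
                    rec = dict(zip(names, vals))
                    data[i] = (rec["x"], rec["y"], rec["z"])
                offset += count * stride
                verts = data
            elif name == "face":
                (pname, itype, ltype), = props
                lsize = struct.calcsize(_PLY_TYPES[ltype])
                isize = struct.calcsize(_PLY_TYPES[itype])
                for _ in range(count):
                    (k,) = struct.unpack_from("<" + _PLY_TYPES[ltype], body, offset)
                    offset += lsize
                    idxs = struct.unpack_from("<" + _PLY_TYPES[itype] * k, body, offset)
                    offset += isize * k
                    faces.append(list(idxs))
            else:
                raise MeshFormatError(f"{path}: cannot skip binary element {name!r}")
    if verts is None:
        raise MeshFormatError(f"{path}: no vertex element")
    return verts, _triangulate(faces)


def _load_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(t) for t in parts[1:4]])
        elif parts[0] == "f":
            idxs = [int(t.split("/")[0]) for t in parts[1:]]
            faces.append([i - 1 if i > 0 else len(verts) + i for i in idxs])
    if not verts:
        raise MeshFormatError(f"{path}: no vertices found")
    return np.array(verts, dtype=float), _triangulate(faces)


def _triangulate(polys: Sequence[Sequence[int]]) -> np.ndarray:
    tris = []
    for poly in polys:
        for i in range(1, len(poly) - 1):
            tris.append((poly[0], poly[i], poly[i + 1]))
    return np.array(tris, dtype=np.int64).reshape(-1, 3)


def load_mesh(path: str | Path, fmt: str | None = None, subject_id: str | None = None) -> FaceMesh:
    """Read a PLY or OBJ mesh (format inferred from the extension)."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: no such file")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        verts, faces = _load_ply(path)
    elif fmt == "obj":
        verts, faces = _load_obj(path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    mesh = FaceMesh(verts, faces, subject_id=subject_id or path.stem)
    mesh.validate()
    return mesh


def save_mesh(mesh: FaceMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as ascii PLY or OBJ."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        lines = [
            "ply", "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property double x", "property double y", "property double z",
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
        lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "obj":
        lines = [f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
        lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# Geodesics
# ---------------------------------------------------------------------------

class GeodesicSolver:
    """Shortest surface paths over a Steiner-augmented mesh graph.

    Refinement level r places 2**r - 1 evenly spaced extra nodes on every
    mesh edge (dyadic positions, so edge midpoints are always included);
    all nodes on a face's boundary are pairwise connected by straight
    segments inside that face. refinement=0 reduces to plain Dijkstra over
    the mesh edge graph.
    """

    def __init__(self, mesh: FaceMesh, refinement: int = 2,
                 snap_tol: float = SNAP_TOLERANCE_MM) -> None:
        mesh.validate()
        self.mesh = mesh
        self.refinement = int(refinement)
        self.snap_tol = float(snap_tol)
        self._dist_cache: dict[int, np.ndarray] = {}
        self._build_graph()

    def _build_graph(self) -> None:
        mesh = self.mesh
        r = 2**self.refinement - 1  # Steiner points per edge
        nodes = [mesh.vertices]
        edge_nodes: dict[tuple[int, int], np.ndarray] = {}
        next_id = mesh.n_vertices
        if r > 0:
            fracs = (np.arange(1, r + 1) / (r + 1))[:, None]
            for i, j in mesh.edges():
                pts = (1 - fracs) * mesh.vertices[i] + fracs * mesh.vertices[j]
                nodes.append(pts)
                edge_nodes[(i, j)] = np.arange(next_id, next_id + r)
                next_id += r
        self.nodes = np.vstack(nodes)

        weights: dict[tuple[int, int], float] = {}
        for f in mesh.faces:
            ids = list(f)
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                if key in edge_nodes:
                    ids.extend(edge_nodes[key])
            ids = np.asarray(ids)
            pts = self.nodes[ids]
            for u in range(len(ids)):
                for v in range(u + 1, len(ids)):
                    key = (min(ids[u], ids[v]), max(ids[u], ids[v]))
                    if key not in weights:
                        weights[key] = float(np.linalg.norm(pts[u] - pts[v]))
        if weights:
            rows, cols = np.array(list(weights.keys())).T
            vals = np.fromiter(weights.values(), dtype=float)
        else:
            rows = cols = np.array([], dtype=int)
            vals = np.array([])
        n = len(self.nodes)
        self.graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
        self._tree = cKDTree(self.nodes)

    def snap(self, point: Sequence[float]) -> tuple[int, float]:
        """Nearest graph node and its distance from the query point."""
        p = np.asarray(point, dtype=float).reshape(3)
        dist, idx = self._tree.query(p)
        if dist > self.snap_tol:
            raise LandmarkOffSurfaceError(
                f"point {p} is {dist:.3f} mm from the surface (tolerance {self.snap_tol} mm)"
            )
        return int(idx), float(dist)

    def _distances_from(self, src: int) -> np.ndarray:
        if src not in self._dist_cache:
            self._dist_cache[src] = dijkstra(self.graph, directed=False, indices=src)
        return self._dist_cache[src]

    def distance(self, a: Sequence[float], b: Sequence[float]) -> float:
        ia, da = self.snap(a)
        ib, db = self.snap(b)
        if ia == ib:
            return da + db
        graph_d = float(self._distances_from(ia)[ib])
        if not np.isfinite(graph_d):
            raise MeshConnectivityError(
                f"no surface path between nodes {ia} and {ib} in mesh {self.mesh.subject_id!r}"
            )
        return da + graph_d + db


def geodesic_distance(mesh: FaceMesh, a: Sequence[float], b: Sequence[float],
                      refinement: int = 2, snap_tol: float = SNAP_TOLERANCE_MM) -> float:
    """One-off surface distance; build a :class:`GeodesicSolver` for batches."""
    return GeodesicSolver(mesh, refinement=refinement, snap_tol=snap_tol).distance(a, b)


# ---------------------------------------------------------------------------
# Facial area and feature extraction
# ---------------------------------------------------------------------------

def facial_area(
    landmarks: LandmarkSet,
    triangulation: Sequence[tuple[str, str, str]] = DEFAULT_AREA_TRIANGULATION,
) -> float:
    """Sum of landmark-triangle areas (mm^2); rigid-motion invariant."""
    total = 0.0
    for tri in triangulation:
        if len(set(tri)) != 3:
            raise DegenerateTriangleError(f"triangle {tri} repeats a landmark")
        a, b, c = (landmarks[name] for name in tri)
        total += 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))
    return total


def extract_features(
    mesh: FaceMesh,
    landmarks: LandmarkSet,
    registry: Mapping[str, tuple[str, str, str]] = DISTANCE_REGISTRY,
    area_triangulation: Sequence[tuple[str, str, str]] = DEFAULT_AREA_TRIANGULATION,
    refinement: int = 2,
    snap_tol: float = SNAP_TOLERANCE_MM,
    sex: str | None = None,
    group: str | None = None,
) -> FeatureVector:
    """Measure all registry distances plus facial area for one subject."""
    needed = {n for a, b, _ in registry.values() for n in (a, b)}
    landmarks.require(needed | set(n for t in area_triangulation for n in t))
    solver = GeodesicSolver(mesh, refinement=refinement, snap_tol=snap_tol)
    distances: dict[str, float] = {}
    for feat, (a, b, kind) in registry.items():
        pa, pb = landmarks[a], landmarks[b]
        if kind == "linear":
            distances[feat] = float(np.linalg.norm(pa - pb))
        elif kind == "geodesic":
            distances[feat] = solver.distance(pa, pb)
        else:
            raise ValueError(f"unknown distance kind {kind!r} for {feat}")
    fv = FeatureVector(
        subject_id=landmarks.subject_id or mesh.subject_id,
        distances=distances,
        facial_area=facial_area(landmarks, area_triangulation),
        sex=sex,
        group=group,
    )
    fv.validate(registry)
    return fv
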