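"""Triangle-mesh and point-cloud I/O plus mesh cleaning.

This module owns the units/coordinate contract of the pipeline: all
coordinates are millimetres. STL carries no unit metadata, so the
convention is documented here rather than enforced.

STL reading keeps the raw triangle soup (one vertex record per facet
corner); welding is an explicit :func:`clean_mesh` step so the file as
written can be inspected unmodified.
"""

from __future__ import annotations

import heapq
import io
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from trimesh.exchange.stl import export_stl, export_stl_ascii, load_stl

from .errors import FormatError, GeometryError, ParameterError

__all__ = [
    "TriangleMesh",
    "read_stl",
    "write_stl",
    "read_xyz",
    "write_xyz",
    "clean_mesh",
]


@dataclass
class TriangleMesh:
    """A triangle surface mesh in millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        Vertex-index triples.
    name : str
        Free-text label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("mesh vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        """Per-face area in mm^2."""
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)


def read_stl(path: str | os.PathLike) -> TriangleMesh:
    """Read a binary or ASCII STL file.

    The dialect is auto-detected. The returned mesh keeps one vertex
    record per facet corner exactly as stored in the file; apply
    :func:`clean_mesh` to weld shared corners.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"STL file not found: {path}")
    try:
        with open(path, "rb") as handle:
            raw = load_stl(handle)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise FormatError(f"malformed STL file {path!r}: {exc}") from exc
    if "vertices" not in raw or len(raw.get("faces", ())) == 0:
        # trimesh falls back to an empty scene on truncated binary files
        raise FormatError(
            f"malformed STL file {path!r}: facet data truncated or missing"
        )
    return TriangleMesh(
        np.asarray(raw["vertices"], dtype=float),
        np.asarray(raw["faces"], dtype=np.int64),
        name=os.path.splitext(os.path.basename(path))[0],
    )


def write_stl(mesh: TriangleMesh, path: str | os.PathLike, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL.

    Coordinates are stored at 32-bit float precision (the STL format's
    native width); topology round-trips exactly.
    """
    if mesh.n_faces == 0:
        raise ParameterError("STL requires at least one facet; mesh is empty")
    if dialect not in ("binary", "ascii"):
        raise ParameterError(f"unknown STL dialect {dialect!r}")
    import trimesh as _tm

    tm = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        if dialect == "binary":
            data = export_stl(tm)
            with open(path, "wb") as handle:
                handle.write(data)
        else:
            text = export_stl_ascii(tm)
            with open(path, "w") as handle:
                handle.write(text)
    except OSError as exc:
        raise FormatError(f"cannot write STL to {path!r}: {exc}") from exc


def read_xyz(path: str | os.PathLike):
    """Read a whitespace-separated XYZ point cloud.

    Each non-comment line holds 3 columns (a point) or 6 columns
    (point followed by its normal). ``#`` starts a comment line.

    Returns
    -------
    PointCloud
    """
    from .pointcloud import PointCloud

    points, normals = [], []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) not in (3, 6):
                raise FormatError(
                    f"{path}:{lineno}: expected 3 or 6 columns, got {len(tokens)}"
                )
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric token in {stripped!r}"
                ) from exc
            points.append(values[:3])
            if len(values) == 6:
                normals.append(values[3:])
    if normals and len(normals) != len(points):
        raise FormatError(f"{path}: mixed 3- and 6-column lines")
    return PointCloud(
        np.asarray(points, dtype=float).reshape(-1, 3),
        normals=np.asarray(normals, dtype=float) if normals else None,
    )


def write_xyz(cloud, path: str | os.PathLike) -> None:
    """Write a point cloud as XYZ text (6 columns when normals exist)."""
    with open(path, "w") as handle:
        if cloud.normals is not None:
            data = np.hstack([cloud.points, cloud.normals])
        else:
            data = cloud.points
        for row in data:
            handle.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# cleaning


def _weld_vertices(vertices: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol``; returns (new_vertices, index map)."""
    n = len(vertices)
    if n == 0:
        return vertices, np.empty(0, dtype=np.int64)
    if tol <= 0:
        # exact duplicates only
        _, remap, inverse = np.unique(
            vertices, axis=0, return_index=True, return_inverse=True
        )
        return vertices[remap], inverse
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(n)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    uniq, inverse = np.unique(roots, return_inverse=True)
    return vertices[uniq], inverse


def _drop_degenerate_faces(mesh: TriangleMesh, area_tol: float = 0.0) -> TriangleMesh:
    faces = mesh.faces
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    mesh = TriangleMesh(mesh.vertices, faces[distinct], mesh.name)
    keep = mesh.face_areas() > area_tol
    return TriangleMesh(mesh.vertices, mesh.faces[keep], mesh.name)


def _drop_unreferenced(mesh: TriangleMesh) -> TriangleMesh:
    used = np.unique(mesh.faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[mesh.faces], mesh.name)


def clean_mesh(
    mesh: TriangleMesh,
    weld_tol: float = 1e-6,
    target_faces: int | None = None,
) -> TriangleMesh:
    """Weld duplicate vertices, drop degenerate faces, optionally decimate.

    Parameters
    ----------
    weld_tol : float
        Vertices closer than this (mm) are merged. The default 1e-6 mm is
        far below CT resolution and only merges numerically duplicated
        facet corners.
    target_faces : int, optional
        When given, quadric edge-collapse decimation reduces the face
        count to at most this value.
    """
    if weld_tol < 0:
        raise ParameterError("weld_tol must be >= 0")
    if target_faces is not None and target_faces <= 0:
        raise ParameterError("target_faces must be positive")
    vertices, inverse = _weld_vertices(mesh.vertices, weld_tol)
    out = TriangleMesh(vertices, inverse[mesh.faces], mesh.name)
    out = _drop_degenerate_faces(out)
    out = _drop_unreferenced(out)
    if target_faces is not None and out.n_faces > target_faces:
        out = _decimate_quadric(out, target_faces)
        out = _drop_degenerate_faces(out)
        out = _drop_unreferenced(out)
    return out


# ---------------------------------------------------------------------------
# quadric edge-collapse decimation (Garland–Heckbert style)


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """4x4 plane quadric of each face, weighted by face area."""
    tri = vertices[faces]
    normal = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(normal, axis=1)
    norm = np.linalg.norm(normal, axis=1)
    norm[norm == 0] = 1.0
    normal = normal / norm[:, None]
    d = -np.einsum("ij,ij->i", normal, tri[:, 0])
    plane = np.hstack([normal, d[:, None]])  # (F, 4)
    quad = plane[:, :, None] * plane[:, None, :]  # (F, 4, 4)
    return quad * area[:, None, None]


def _quadric_cost(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal collapse position and cost for vertex quadric sum ``q``."""
    system = q[:3, :3]
    rhs = -q[:3, 3]
    candidates = [a, b, 0.5 * (a + b)]
    try:
        # fall back to endpoint candidates when the quadric is flat
        if np.linalg.cond(system) < 1e8:
            candidates.insert(0, np.linalg.solve(system, rhs))
    except np.linalg.LinAlgError:
        pass
    best_cost, best_pos = np.inf, candidates[-1]
    for pos in candidates:
        h = np.append(pos, 1.0)
        cost = float(h @ q @ h)
        if cost < best_cost:
            best_cost, best_pos = cost, pos
    return best_cost, best_pos


def _decimate_quadric(mesh: TriangleMesh, target_faces: int) -> TriangleMesh:
    """Edge-collapse decimation with quadric error metric.

    Collapses the cheapest valid edge until the live face count reaches
    ``target_faces``. Collapses that would flip a surviving face normal
    are rejected to preserve local shape.
    """
    vertices = mesh.vertices.copy()
    faces = mesh.faces.copy()
    n_v = len(vertices)
    quadrics = np.zeros((n_v, 4, 4))
    fq = _face_quadrics(vertices, faces)
    for corner in range(3):
        np.add.at(quadrics, faces[:, corner], fq)

    vertex_faces: list[set[int]] = [set() for _ in range(n_v)]
    for fi, f in enumerate(faces):
        for v in f:
            vertex_faces[v].add(fi)
    face_alive = np.ones(len(faces), dtype=bool)
    n_alive = len(faces)

    edges = set()
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(a, b), max(a, b)))

    heap: list[tuple[float, int, int, int]] = []
    version = np.zeros(n_v, dtype=np.int64)

    def push(a: int, b: int) -> None:
        cost, _ = _quadric_cost(quadrics[a] + quadrics[b], vertices[a], vertices[b])
        heapq.heappush(heap, (cost, int(version[a] + version[b]), a, b))

    for a, b in edges:
        push(a, b)

    merged_into = np.arange(n_v)

    def resolve(v: int) -> int:
        while merged_into[v] != v:
            v = merged_into[v]
        return v

    while n_alive > target_faces and heap:
        cost, ver, a, b = heapq.heappop(heap)
        a, b = resolve(a), resolve(b)
        if a == b or ver != version[a] + version[b]:
            continue
        new_pos = _quadric_cost(quadrics[a] + quadrics[b], vertices[a], vertices[b])[1]

        # reject collapses that flip any surviving incident face
        affected = (vertex_faces[a] | vertex_faces[b])
        flipped = False
        for fi in affected:
            if not face_alive[fi]:
                continue
            f = faces[fi]
            if a in f and b in f:
                continue  # face dies with the collapse
            tri_old = vertices[f]
            tri_new = tri_old.copy()
            for c in range(3):
                if f[c] == a or f[c] == b:
                    tri_new[c] = new_pos
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if np.dot(n_old, n_new) <= 0:
                flipped = True
                break
        if flipped:
            continue

        vertices[a] = new_pos
        quadrics[a] = quadrics[a] + quadrics[b]
        merged_into[b] = a
        version[a] += 1
        version[b] += 1
        neighbors = set()
        for fi in list(vertex_faces[b]):
            f = faces[fi]
            if a in f and face_alive[fi]:
                face_alive[fi] = False
                n_alive -= 1
                for v in f:
                    vertex_faces[v].discard(fi)
            else:
                faces[fi] = np.where(f == b, a, f)
                vertex_faces[a].add(fi)
        for fi in vertex_faces[a]:
            if face_alive[fi]:
                f = faces[fi]
                if len(set(int(v) for v in f)) < 3:
                    face_alive[fi] = False
                    n_alive -= 1
                else:
                    for v in f:
                        if v != a:
                            neighbors.add(int(v))
        for v in neighbors:
            push(a, v)

    out_faces = faces[face_alive]
    return _drop_unreferenced(
        _drop_degenerate_faces(TriangleMesh(vertices, out_faces, mesh.name))
    )
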