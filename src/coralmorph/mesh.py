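"""Triangle-mesh ingestion, repair and geometric primitives.

Photogrammetric reconstructions of coral colonies arrive as Wavefront OBJ
surface meshes.  Everything downstream — total surface area (TSA),
effective surface area (ESA, living tissue only), enclosed volume — reduces
to a handful of primitives on an indexed triangle mesh: per-face areas,
the divergence-theorem volume of a closed surface, boundary-loop detection
and flat hole filling for the open models that segmentation produces.

Vertices are stored in model units until scale calibration converts them
to centimetres (see :mod:`coralmorph.calibration`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "LIVING",
    "NONLIVING_CONTACT",
    "BACKGROUND",
    "CLASSES",
    "Mesh",
    "FaceLabelMask",
    "MeshError",
    "ObjParseError",
    "MeshStructureError",
    "NotWatertightError",
    "NonOrientableError",
    "EmptySelectionError",
    "DegenerateFaceWarning",
    "read_obj",
    "write_obj",
    "surface_area",
    "face_areas",
    "enclosed_volume",
    "boundary_loops",
    "fill_holes_flat",
    "FillResult",
    "segment",
    "SegmentResult",
]

# face classes of the segmentation mask
LIVING = "living"
NONLIVING_CONTACT = "nonliving_contact"
BACKGROUND = "background"
CLASSES = frozenset({LIVING, NONLIVING_CONTACT, BACKGROUND})


class MeshError(Exception):
    """Base class for mesh structural and I/O errors."""


class ObjParseError(MeshError):
    """Malformed OBJ content; message names the offending line."""


class MeshStructureError(MeshError):
    """Face indices out of range, non-manifold edges, repeated vertices."""


class NotWatertightError(MeshError):
    """Enclosed volume requested on a mesh with boundary edges.

    Open models occur routinely in practice: complex growth forms
    (tabular, foliose) often fail to reconstruct as coherent solids, so
    volume is reported as not computable rather than guessed.
    """


class NonOrientableError(MeshError):
    """Face windings cannot be made globally consistent."""


class EmptySelectionError(MeshError):
    """Segmentation selected no faces (distinct from a zero-area warning)."""


class DegenerateFaceWarning(UserWarning):
    """Zero-area faces were encountered; they contribute no area."""


@dataclass(frozen=True)
class Mesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array, model units or centimetres.
    faces : (m, 3) int array of vertex indices (0-based).
    texcoords : optional (n, 2) float array of per-vertex UV coordinates.
    units : ``"model"`` or ``"cm"``; scale calibration sets ``"cm"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    texcoords: Optional[np.ndarray] = None
    units: str = "model"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.texcoords is not None:
            t = np.asarray(self.texcoords, dtype=np.float64).reshape(-1, 2)
            object.__setattr__(self, "texcoords", t)
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshStructureError(
                f"face index out of range [0, {len(v)}): "
                f"min={f.min() if f.size else None}, max={f.max() if f.size else None}"
            )
        if f.size and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise MeshStructureError("a face references the same vertex twice")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def translated(self, offset) -> "Mesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, float))

    def scaled(self, s: float) -> "Mesh":
        return replace(self, vertices=self.vertices * float(s))

    def transformed(self, rotation, translation) -> "Mesh":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(self, vertices=self.vertices @ R.T + t)


@dataclass(frozen=True)
class FaceLabelMask:
    """Partition of mesh faces into living / non-living-contact / background.

    ``labels[i]`` is the class of face ``i``; the mask length must equal the
    face count of its mesh (checked where the pair is used together).
    """

    labels: np.ndarray  # array of str, one per face

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=object)
        bad = sorted(set(lab.tolist()) - CLASSES)
        if bad:
            raise ValueError(f"unknown face classes: {bad}; allowed: {sorted(CLASSES)}")
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.labels)

    def in_classes(self, classes: Iterable[str]) -> np.ndarray:
        cls = set(classes)
        bad = cls - CLASSES
        if bad:
            raise ValueError(f"unknown face classes: {sorted(bad)}")
        return np.isin(self.labels, list(cls))

    def relabel(self, indices, new_class: str) -> "FaceLabelMask":
        if new_class not in CLASSES:
            raise ValueError(f"unknown class {new_class!r}")
        lab = self.labels.copy()
        lab[np.asarray(indices, int)] = new_class
        return FaceLabelMask(lab)

    @classmethod
    def uniform(cls, n_faces: int, label: str = LIVING) -> "FaceLabelMask":
        return cls(np.full(n_faces, label, dtype=object))

    # CSV layout: one header line, then `face_index,class`, 0-based
    def to_csv(self, path) -> None:
        lines = ["face_index,class"]
        lines += [f"{i},{c}" for i, c in enumerate(self.labels)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path, n_faces: Optional[int] = None) -> "FaceLabelMask":
        rows = Path(path).read_text().strip().splitlines()[1:]
        pairs = [r.split(",") for r in rows if r.strip()]
        idx = np.array([int(i) for i, _ in pairs])
        n = n_faces if n_faces is not None else (idx.max() + 1 if len(idx) else 0)
        lab = np.full(n, BACKGROUND, dtype=object)
        for i, c in pairs:
            lab[int(i)] = c.strip()
        return cls(lab)


def _check_mask(mesh: Mesh, mask: FaceLabelMask) -> None:
    if len(mask) != mesh.n_faces:
        raise ValueError(
            f"mask covers {len(mask)} faces but mesh has {mesh.n_faces}"
        )


# ---------------------------------------------------------------------------
# OBJ I/O


def read_obj(path) -> Mesh:
    """Read a Wavefront OBJ file into a :class:`Mesh`.

    Polygonal faces with more than three vertices are fan-triangulated.
    1-based OBJ indices (and negative, end-relative indices) are mapped to
    0-based; ``mtllib``/``usemtl`` and normals are ignored.  Texture
    coordinates, where present, are resolved per vertex.
    """
    path = Path(path)
    verts: list = []
    raw_texcoords: list = []
    faces: list = []
    vert_tc: dict = {}

    def resolve(idx: int, n: int, lineno: int) -> int:
        if idx > 0:
            j = idx - 1
        elif idx < 0:
            j = n + idx
        else:
            raise ObjParseError(f"{path.name}:{lineno}: OBJ index 0 is invalid")
        if not (0 <= j < n):
            raise MeshStructureError(
                f"{path.name}:{lineno}: face index {idx} out of range (have {n})"
            )
        return j

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                try:
                    verts.append([float(x) for x in parts[1:4]])
                except (ValueError, IndexError):
                    raise ObjParseError(f"{path.name}:{lineno}: malformed vertex line: {line!r}")
            elif tag == "vt":
                try:
                    raw_texcoords.append([float(x) for x in parts[1:3]])
                except (ValueError, IndexError):
                    raise ObjParseError(f"{path.name}:{lineno}: malformed texcoord line: {line!r}")
            elif tag == "f":
                corners = []
                for tok in parts[1:]:
                    fields = tok.split("/")
                    try:
                        vi = resolve(int(fields[0]), len(verts), lineno)
                    except ValueError:
                        raise ObjParseError(
                            f"{path.name}:{lineno}: malformed face token {tok!r}"
                        )
                    if len(fields) > 1 and fields[1]:
                        ti = resolve(int(fields[1]), len(raw_texcoords), lineno)
                        vert_tc[vi] = ti
                    corners.append(vi)
                if len(corners) < 3:
                    raise ObjParseError(
                        f"{path.name}:{lineno}: face with {len(corners)} vertices"
                    )
                for k in range(1, len(corners) - 1):  # fan triangulation
                    faces.append([corners[0], corners[k], corners[k + 1]])
            # every other tag (vn, o, g, s, mtllib, usemtl, ...) is ignored

    texcoords = None
    if vert_tc and raw_texcoords:
        texcoords = np.zeros((len(verts), 2))
        tc = np.asarray(raw_texcoords, float)
        for vi, ti in vert_tc.items():
            texcoords[vi] = tc[ti]
    return Mesh(
        vertices=np.asarray(verts, float).reshape(-1, 3),
        faces=np.asarray(faces, np.int64).reshape(-1, 3),
        texcoords=texcoords,
        units="model",
    )


def write_obj(mesh: Mesh, path) -> None:
    """Write ``mesh`` as OBJ with 1-based indices and fixed 9-decimal
    formatting, so identical meshes serialize to identical bytes."""
    lines = []
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}")
    has_tc = mesh.texcoords is not None
    if has_tc:
        for t in mesh.texcoords:
            lines.append(f"vt {t[0]:.9f} {t[1]:.9f}")
    for f in mesh.faces:
        if has_tc:
            lines.append(f"f {f[0]+1}/{f[0]+1} {f[1]+1}/{f[1]+1} {f[2]+1}/{f[2]+1}")
        else:
            lines.append(f"f {f[0]+1} {f[1]+1} {f[2]+1}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometric primitives


def face_areas(mesh: Mesh) -> np.ndarray:
    """Per-face triangle areas (half cross-product magnitude)."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def surface_area(
    mesh: Mesh,
    mask: Optional[FaceLabelMask] = None,
    classes: Optional[Iterable[str]] = None,
) -> float:
    """Surface area of the mesh, optionally restricted to labelled classes.

    With no mask this is the total surface area (TSA).  With a mask and
    ``classes={"living"}`` it is the effective surface area (ESA): the
    living-tissue surface after non-living contact areas are excluded.
    Degenerate (zero-area) faces contribute nothing and raise a
    :class:`DegenerateFaceWarning` with a count.
    """
    areas = face_areas(mesh)
    if mask is not None:
        _check_mask(mesh, mask)
        if classes is None or not set(classes):
            raise ValueError("a non-empty class set is required when a mask is given")
        areas = areas[mask.in_classes(classes)]
    elif classes is not None:
        raise ValueError("classes given without a mask")
    n_degen = int(np.count_nonzero(areas == 0.0))
    if n_degen:
        warnings.warn(
            f"{n_degen} degenerate (zero-area) face(s) contributed no area",
            DegenerateFaceWarning,
            stacklevel=2,
        )
    return float(areas.sum())


def _sorted_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def _edge_face_counts(faces: np.ndarray):
    """Unique undirected edges, their incidence counts, and the inverse map."""
    edges = _sorted_edges(faces)
    uniq, inverse, counts = np.unique(
        edges, axis=0, return_inverse=True, return_counts=True
    )
    return uniq, inverse, counts


def _require_edge_manifold(faces: np.ndarray) -> None:
    uniq, _, counts = _edge_face_counts(faces)
    bad = uniq[counts > 2]
    if len(bad):
        listing = ", ".join(f"({a},{b})" for a, b in bad[:10])
        raise MeshStructureError(
            f"{len(bad)} non-manifold edge(s) with >2 incident faces: {listing}"
        )


def _orient_consistently(mesh: Mesh) -> Mesh:
    """Make face windings globally consistent by flood fill from the
    largest face; raises :class:`NonOrientableError` on a Möbius-like
    surface.  The absolute value in the volume formula absorbs the global
    inward/outward choice."""
    faces = mesh.faces.copy()
    m = len(faces)
    if m == 0:
        return mesh
    _require_edge_manifold(faces)
    _, inverse, _ = _edge_face_counts(faces)
    owner = np.concatenate([np.arange(m)] * 3)  # face owning each edge entry
    edge_faces: dict[int, list[int]] = {}
    for entry, edge_id in enumerate(inverse):
        edge_faces.setdefault(int(edge_id), []).append(int(owner[entry]))
    adjacency: dict[int, set[int]] = {}
    for fs in edge_faces.values():
        for fa in fs:
            for fb in fs:
                if fa != fb:
                    adjacency.setdefault(fa, set()).add(fb)

    def directed_edges(fi):
        a, b, c = faces[fi]
        return {(a, b), (b, c), (c, a)}

    areas = face_areas(mesh)
    seen = np.zeros(m, bool)
    while not seen.all():
        start = int(np.argmax(np.where(seen, -np.inf, areas)))
        seen[start] = True
        stack = [start]
        while stack:
            fi = stack.pop()
            own = directed_edges(fi)
            for fj in adjacency.get(fi, ()):
                # consistent neighbours traverse the shared edge oppositely
                same_dir = bool(own & directed_edges(fj))
                if not seen[fj]:
                    if same_dir:
                        faces[fj] = faces[fj, ::-1]
                    seen[fj] = True
                    stack.append(fj)
                elif same_dir:
                    raise NonOrientableError(
                        f"faces {fi} and {fj} cannot be oriented consistently"
                    )
    if np.array_equal(faces, mesh.faces):
        return mesh
    return replace(mesh, faces=faces)


def is_watertight(mesh: Mesh) -> bool:
    if mesh.n_faces == 0:
        return False
    _, _, counts = _edge_face_counts(mesh.faces)
    return bool((counts == 2).all())


def enclosed_volume(mesh: Mesh) -> float:
    """Enclosed volume of a watertight mesh by the divergence theorem.

    Each triangle contributes the signed volume of the tetrahedron it spans
    with the origin, ``det(v0, v1, v2) / 6``; the sum over a closed,
    consistently wound surface is the enclosed volume independent of the
    origin (hence invariant under rigid motion).  Non-watertight meshes
    raise :class:`NotWatertightError` — segmentation of complex growth
    forms frequently leaves open shells whose volume is simply not
    computable; callers repair holes first (:func:`fill_holes_flat`).
    """
    if mesh.n_faces == 0:
        raise NotWatertightError("empty mesh has no enclosed volume")
    _require_edge_manifold(mesh.faces)
    _, _, counts = _edge_face_counts(mesh.faces)
    n_boundary = int((counts == 1).sum())
    if n_boundary:
        raise NotWatertightError(
            f"mesh has {n_boundary} boundary edge(s); volume is not computable "
            "(fill holes first)"
        )
    oriented = _orient_consistently(mesh)
    v = oriented.vertices - oriented.vertices.mean(axis=0)  # conditioning only
    f = oriented.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    return abs(float(signed.sum()) / 6.0)


# ---------------------------------------------------------------------------
# boundary loops and hole filling


def boundary_loops(mesh: Mesh) -> list[list[int]]:
    """Closed cycles of boundary edges (edges bordering exactly one face).

    Returns one ordered vertex list per hole; empty iff the mesh is
    watertight.  Each loop is ordered so that a centroid-fan fill has the
    same winding as the adjacent surface, and is canonicalized to start at
    its smallest vertex index.
    """
    _require_edge_manifold(mesh.faces)
    faces = mesh.faces
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inverse] == 1
    # a boundary edge (u, v) in its face is traversed (v, u) around the hole
    succ: dict[int, int] = {}
    for (u, v) in directed[boundary]:
        succ[int(v)] = int(u)
    loops = []
    remaining = dict(succ)
    while remaining:
        start = min(remaining)
        loop = [start]
        cur = remaining.pop(start)
        while cur != start:
            loop.append(cur)
            cur = remaining.pop(cur)
        loops.append(loop)
    return loops


class FillResult(NamedTuple):
    mesh: Mesh
    added_faces: list[int]  # indices into mesh.faces of the fill triangles


def fill_holes_flat(mesh: Mesh) -> FillResult:
    """Close every boundary loop with a flat centroid-fan patch.

    Each hole is triangulated by fanning from the loop centroid, which is
    planar for the planar break surfaces left by physical sampling and
    well defined for any loop.  Original faces are untouched; the indices
    of the added faces are returned so callers can label them as
    non-living contact surface.  Idempotent: a watertight mesh is returned
    unchanged.
    """
    loops = boundary_loops(mesh)
    if not loops:
        return FillResult(mesh, [])
    verts = mesh.vertices
    new_verts = [verts]
    new_faces = [mesh.faces]
    added = []
    next_vid = mesh.n_vertices
    next_fid = mesh.n_faces
    for loop in loops:
        if len(loop) == 3:
            tri = np.array([[loop[0], loop[1], loop[2]]], np.int64)
            new_faces.append(tri)
            added.append(next_fid)
            next_fid += 1
            continue
        centroid = verts[loop].mean(axis=0, keepdims=True)
        new_verts.append(centroid)
        cid = next_vid
        next_vid += 1
        tris = np.array(
            [[loop[i], loop[(i + 1) % len(loop)], cid] for i in range(len(loop))],
            np.int64,
        )
        new_faces.append(tris)
        added.extend(range(next_fid, next_fid + len(tris)))
        next_fid += len(tris)
    texcoords = None
    if mesh.texcoords is not None:
        pad = np.zeros((next_vid - mesh.n_vertices, 2))
        texcoords = np.vstack([mesh.texcoords, pad])
    filled = Mesh(
        vertices=np.vstack(new_verts),
        faces=np.vstack(new_faces),
        texcoords=texcoords,
        units=mesh.units,
    )
    return FillResult(filled, added)


class SegmentResult(NamedTuple):
    mesh: Mesh
    face_map: np.ndarray  # original face index of each kept face


def segment(mesh: Mesh, mask: FaceLabelMask, classes: Iterable[str]) -> SegmentResult:
    """Extract the submesh of faces whose label is in ``classes``.

    Mirrors segmenting the colony from the surrounding 3D environment:
    unreferenced vertices are dropped, indices compacted, texture
    coordinates carried over.  Selecting no faces is an error (distinct
    from a degenerate-area warning).
    """
    _check_mask(mesh, mask)
    keep = mask.in_classes(classes)
    if not keep.any():
        raise EmptySelectionError(f"no faces labelled {sorted(set(classes))}")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, np.int64)
    remap[used] = np.arange(len(used))
    sub = Mesh(
        vertices=mesh.vertices[used],
        faces=remap[faces],
        texcoords=mesh.texcoords[used] if mesh.texcoords is not None else None,
        units=mesh.units,
    )
    return SegmentResult(sub, np.flatnonzero(keep))
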