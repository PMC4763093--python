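"""Parametric synthetic coral colonies with analytic ground truth.

Field meshes from photogrammetry have no ground truth, so every pipeline
stage is exercised on parametric colonies that mimic the gross growth
forms while keeping closed-form surface areas and volumes:

``massive``
    hemisphere closed by a base disc (SA ``3*pi*r**2``, V ``2/3*pi*r**3``);
``branched``
    an overlap-free union of closed tapered frusta — a trunk and several
    branches standing clear of each other — so the closed-form per-primitive
    sums are exact;
``tabular``
    a thin circular plate hovering over a stalk frustum;
``foliose``
    an open thin shell (a spherical cap with no base), intentionally
    non-watertight to exercise the volume-refusal path that real foliose
    and tabular colonies trigger.

Each colony sits over a seafloor annulus labelled ``background``; basal
contact surfaces are ``nonliving_contact``; everything else is ``living``.
Simulated sampling detaches a connected living patch (the hammer-and-chisel
fragment) and flat-fills the break; simulated bleaching erodes the living
surface inward by the tissue thickness.  All generators are deterministic
for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np

from .mesh import (
    BACKGROUND,
    LIVING,
    NONLIVING_CONTACT,
    FaceLabelMask,
    Mesh,
    MeshError,
    boundary_loops,
    enclosed_volume,
    face_areas,
    fill_holes_flat,
    segment,
)

__all__ = [
    "SyntheticColonySpec",
    "GroundTruth",
    "Colony",
    "SamplingResult",
    "make_colony",
    "apply_sampling",
    "apply_bleaching",
    "synthetic_measurements",
]


@dataclass(frozen=True)
class SyntheticColonySpec:
    growth_form: str = "massive"  # massive | branched | tabular | foliose
    size_cm: float = 5.0  # characteristic radius/height
    resolution: int = 4  # subdivision level; segments scale linearly with it
    seed: int = 0
    sample_patch_fraction: float = 0.0  # fraction of living area to detach
    tissue_thickness_cm: float = 0.0  # tissue-to-skeleton surface offset

    def __post_init__(self):
        if self.growth_form not in ("massive", "branched", "tabular", "foliose"):
            raise ValueError(f"unknown growth form {self.growth_form!r}")
        if self.size_cm <= 0:
            raise ValueError("size_cm must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if not (0.0 <= self.sample_patch_fraction <= 0.5):
            raise ValueError("sample_patch_fraction must be in [0, 0.5]")
        if self.tissue_thickness_cm < 0:
            raise ValueError("tissue_thickness_cm must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic quantities of a synthetic colony (smooth closed forms)."""

    true_sa: float  # cm², total colony surface incl. basal closure
    true_v: float  # cm³; 0 for open (foliose) colonies, which refuse volume
    removed_patch_sa: float = 0.0
    removed_fragment_v: float = 0.0


class Colony(NamedTuple):
    mesh: Mesh
    mask: FaceLabelMask
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# primitive builders (vertices appended to shared lists; faces labelled)


class _Builder:
    def __init__(self):
        self.verts: list = []
        self.faces: list = []
        self.labels: list = []

    def add_vertex(self, p) -> int:
        self.verts.append(tuple(p))
        return len(self.verts) - 1

    def add_face(self, a, b, c, label):
        self.faces.append((a, b, c))
        self.labels.append(label)

    def build(self) -> tuple[Mesh, FaceLabelMask]:
        mesh = Mesh(
            vertices=np.asarray(self.verts, float),
            faces=np.asarray(self.faces, np.int64),
            units="cm",
        )
        return mesh, FaceLabelMask(np.asarray(self.labels, dtype=object))


def _ring(b: _Builder, r, z, n, cx=0.0, cy=0.0):
    ang = 2 * np.pi * np.arange(n) / n
    return [b.add_vertex((cx + r * math.cos(a), cy + r * math.sin(a), z)) for a in ang]


def _lace(b, ring_lo, ring_hi, label):
    """Quad strip between two same-length rings, outward winding (CCW seen
    from outside when ring_hi is above ring_lo)."""
    n = len(ring_lo)
    for i in range(n):
        j = (i + 1) % n
        b.add_face(ring_lo[i], ring_lo[j], ring_hi[j], label)
        b.add_face(ring_lo[i], ring_hi[j], ring_hi[i], label)


def _cap(b, ring, center_idx, label, up: bool):
    """Fan cap over a ring; ``up`` True gives +z-facing winding."""
    n = len(ring)
    for i in range(n):
        j = (i + 1) % n
        if up:
            b.add_face(ring[i], ring[j], center_idx, label)
        else:
            b.add_face(ring[j], ring[i], center_idx, label)


def _hemisphere(b: _Builder, r, n_theta, n_phi, close_base: bool, base_label=NONLIVING_CONTACT,
                cap_label=LIVING, theta_max=np.pi / 2):
    """UV hemisphere (pole at +z); optionally closed by a base disc."""
    thetas = np.linspace(0.0, theta_max, n_theta + 1)[1:]
    rings = []
    pole = b.add_vertex((0.0, 0.0, r))
    for th in thetas:
        rings.append(_ring(b, r * math.sin(th), r * math.cos(th), n_phi))
    _cap(b, rings[0], pole, cap_label, up=True)
    for lo, hi in zip(rings[1:], rings[:-1]):
        _lace(b, lo, hi, cap_label)
    if close_base:
        center = b.add_vertex((0.0, 0.0, r * math.cos(theta_max)))
        _cap(b, rings[-1], center, base_label, up=False)
    return rings[-1]


def _frustum(b: _Builder, r_bot, r_top, h, n_phi, cx=0.0, cy=0.0, z0=0.0,
             side_label=LIVING, top_label=LIVING, bot_label=NONLIVING_CONTACT):
    ring_b = _ring(b, r_bot, z0, n_phi, cx, cy)
    ring_t = _ring(b, r_top, z0 + h, n_phi, cx, cy)
    _lace(b, ring_b, ring_t, side_label)
    top_c = b.add_vertex((cx, cy, z0 + h))
    bot_c = b.add_vertex((cx, cy, z0))
    _cap(b, ring_t, top_c, top_label, up=True)
    _cap(b, ring_b, bot_c, bot_label, up=False)


def _seafloor(b: _Builder, r_in, r_out, n_phi):
    ring_i = _ring(b, r_in, 0.0, n_phi)
    ring_o = _ring(b, r_out, 0.0, n_phi)
    _lace(b, ring_o, ring_i, BACKGROUND)  # flat annulus, +z facing


def _frustum_sa_v(r_bot, r_top, h):
    slant = math.hypot(r_bot - r_top, h)
    sa = math.pi * (r_bot + r_top) * slant + math.pi * (r_bot**2 + r_top**2)
    v = math.pi * h / 3.0 * (r_bot**2 + r_bot * r_top + r_top**2)
    return sa, v


def make_colony(spec: SyntheticColonySpec) -> Colony:
    """Build a colony mesh, its face-label mask, and analytic ground truth."""
    r = spec.size_cm
    n_phi = 16 * spec.resolution
    n_theta = 8 * spec.resolution
    if n_phi < 8:
        raise ValueError("resolution too low to realize the growth form")
    b = _Builder()
    if spec.growth_form == "massive":
        _hemisphere(b, r, n_theta, n_phi, close_base=True)
        gt = GroundTruth(true_sa=3 * math.pi * r**2, true_v=2.0 / 3.0 * math.pi * r**3)
    elif spec.growth_form == "branched":
        sa = v = 0.0
        # trunk and four branches, all standing clear of each other
        parts = [(0.0, 0.0, 0.25 * r, 0.15 * r, 1.0 * r)]
        for k in range(4):
            a = 2 * np.pi * (k + 0.5) / 4
            parts.append((0.55 * r * math.cos(a), 0.55 * r * math.sin(a),
                          0.10 * r, 0.06 * r, 0.6 * r))
        for cx, cy, rb, rt, h in parts:
            _frustum(b, rb, rt, h, n_phi, cx, cy)
            psa, pv = _frustum_sa_v(rb, rt, h)
            sa += psa
            v += pv
        gt = GroundTruth(true_sa=sa, true_v=v)
    elif spec.growth_form == "tabular":
        _frustum(b, 0.15 * r, 0.12 * r, 0.5 * r, n_phi)  # stalk
        _frustum(b, r, r, 0.1 * r, n_phi, z0=0.55 * r,  # plate, hovers free
                 bot_label=LIVING)
        sa1, v1 = _frustum_sa_v(0.15 * r, 0.12 * r, 0.5 * r)
        sa2, v2 = _frustum_sa_v(r, r, 0.1 * r)
        gt = GroundTruth(true_sa=sa1 + sa2, true_v=v1 + v2)
    else:  # foliose: open shell, no basal closure
        theta_max = math.radians(70.0)
        rim = _hemisphere(b, r, n_theta, n_phi, close_base=False, theta_max=theta_max)
        # basal contact ring: the lowest band of shell faces
        gt = GroundTruth(true_sa=2 * math.pi * r**2 * (1 - math.cos(theta_max)), true_v=0.0)
    mesh, mask = b.build()
    if spec.growth_form == "foliose":
        # relabel the lowest band of faces as the contact ring
        centz = mesh.vertices[mesh.faces].mean(axis=1)[:, 2]
        zmin = centz.min()
        band = centz <= zmin + 0.02 * r
        mask = mask.relabel(np.flatnonzero(band), NONLIVING_CONTACT)
    # seafloor annulus around every colony
    b2 = _Builder()
    b2.verts = [tuple(p) for p in mesh.vertices]
    b2.faces = [tuple(f) for f in mesh.faces]
    b2.labels = list(mask.labels)
    _seafloor(b2, 1.4 * r, 2.5 * r, n_phi)
    mesh, mask = b2.build()
    return Colony(mesh, mask, gt)


# ---------------------------------------------------------------------------
# simulated sampling (hammer and chisel)


class SamplingResult(NamedTuple):
    sampled_mesh: Mesh  # colony with the patch detached, break flat-filled
    sampled_mask: FaceLabelMask
    sampled_break_faces: np.ndarray  # fill-face indices in sampled_mesh
    sample_mesh: Mesh  # the detached fragment, closed by the same break
    sample_mask: FaceLabelMask
    sample_break_faces: np.ndarray
    ground_truth: GroundTruth


def _fill_and_label(mesh: Mesh, mask: FaceLabelMask):
    filled, added = fill_holes_flat(mesh)
    labels = np.concatenate([mask.labels, np.full(len(added), NONLIVING_CONTACT, object)])
    return filled, FaceLabelMask(labels), np.asarray(added, int)


def apply_sampling(mesh: Mesh, mask: FaceLabelMask, spec: SyntheticColonySpec) -> SamplingResult:
    """Detach a connected living patch of ``sample_patch_fraction`` of the
    living area and flat-fill the resulting break surfaces.

    The patch grows breadth-first over edge-adjacent living faces from a
    seed face chosen by the spec's RNG; both the remaining colony and the
    fragment are closed with centroid-fan patches labelled
    ``nonliving_contact`` (the fresh break surface).  Only the colony
    proper is returned — the surrounding seafloor plays no further part.
    """
    if spec.sample_patch_fraction <= 0:
        raise ValueError("sample_patch_fraction must be > 0 to sample")
    colony, fmap = segment(mesh, mask, {LIVING, NONLIVING_CONTACT})
    labels = mask.labels[fmap]
    areas = face_areas(colony)
    living = np.flatnonzero(labels == LIVING)
    target = spec.sample_patch_fraction * areas[living].sum()

    # edge-adjacency over living faces
    f = colony.faces
    edges = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    owner = np.concatenate([np.arange(len(f))] * 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = (edges[1:] == edges[:-1]).all(axis=1)
    adj: dict[int, list[int]] = {}
    for k in np.flatnonzero(same):
        a, bface = int(owner[k]), int(owner[k + 1])
        adj.setdefault(a, []).append(bface)
        adj.setdefault(bface, []).append(a)

    rng = np.random.default_rng(spec.seed)
    living_set = set(living.tolist())
    seed_face = int(living[rng.integers(len(living))])
    patch = []
    got = 0.0
    seen = {seed_face}
    queue = [seed_face]
    while queue and got < target:
        fi = queue.pop(0)
        patch.append(fi)
        got += areas[fi]
        for fj in sorted(adj.get(fi, ())):
            if fj in living_set and fj not in seen:
                seen.add(fj)
                queue.append(fj)
    if got < target:
        raise MeshError(
            "connected living patch cannot reach the requested area fraction"
        )
    patch = np.asarray(patch, int)
    keep = np.ones(len(f), bool)
    keep[patch] = False

    keep_labels = FaceLabelMask(np.where(keep, labels, BACKGROUND))
    colony_open, cmap = segment(colony, keep_labels, {LIVING, NONLIVING_CONTACT})
    patch_labels = FaceLabelMask(np.where(keep, BACKGROUND, LIVING))
    sample_open, _ = segment(colony, patch_labels, {LIVING})

    sampled, sampled_mask, s_break = _fill_and_label(
        colony_open, FaceLabelMask(labels[cmap])
    )
    sample, sample_mask, f_break = _fill_and_label(
        sample_open, FaceLabelMask.uniform(sample_open.n_faces, LIVING)
    )
    removed_sa = float(areas[patch].sum())
    try:
        frag_v = enclosed_volume(sample)
    except MeshError:
        frag_v = 0.0
    return SamplingResult(
        sampled, sampled_mask, s_break, sample, sample_mask, f_break,
        GroundTruth(
            true_sa=float(areas.sum()),
            true_v=frag_v,  # placeholder totals refined by caller if needed
            removed_patch_sa=removed_sa,
            removed_fragment_v=frag_v,
        ),
    )


# ---------------------------------------------------------------------------
# simulated bleaching (tissue erosion)


def _outward(mesh: Mesh) -> Mesh:
    """Consistently oriented copy with outward-facing normals."""
    from .mesh import _orient_consistently  # internal reuse

    m = _orient_consistently(mesh)
    v = m.vertices - m.vertices.mean(axis=0)
    f = m.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
    if signed < 0:
        return replace(m, faces=m.faces[:, ::-1])
    return m


def apply_bleaching(mesh: Mesh, mask: FaceLabelMask, spec: SyntheticColonySpec) -> Mesh:
    """Erode the living surface inward by ``tissue_thickness_cm``.

    Vertices whose incident faces are all living move along their inward
    area-weighted normal; vertices on label boundaries (the basal rim,
    break surfaces) stay put, mimicking tissue that ends where bare
    substrate begins.  Thickness 0 returns the mesh unchanged.  The offset
    is capped per vertex at 45% of the shortest incident edge to avoid
    self-intersection; capping emits a warning.
    """
    t = spec.tissue_thickness_cm
    if t == 0:
        return mesh
    if len(mask) != mesh.n_faces:
        raise ValueError("mask does not match mesh")
    m = _outward(mesh)
    v = m.vertices
    f = m.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # area-weighted
    vnorm = np.zeros_like(v)
    for c in range(3):
        np.add.at(vnorm, f[:, c], fn)
    lens = np.linalg.norm(vnorm, axis=1)
    lens[lens == 0] = 1.0
    vnorm /= lens[:, None]

    living_faces = mask.labels == LIVING
    all_living = np.ones(m.n_vertices, bool)
    touched = np.zeros(m.n_vertices, bool)
    for c in range(3):
        np.logical_and.at(all_living, f[:, c], living_faces)
        touched[f[:, c]] = True
    movable = all_living & touched

    # offset, then locally back off wherever a face would invert
    offset = np.where(movable, t, 0.0)
    reduced = False
    for _ in range(12):
        v_new = v - vnorm * offset[:, None]
        fn_new = np.cross(
            v_new[f[:, 1]] - v_new[f[:, 0]], v_new[f[:, 2]] - v_new[f[:, 0]]
        )
        flipped = np.einsum("ij,ij->i", fn_new, fn) <= 0.0
        if not flipped.any():
            break
        bad_verts = np.unique(f[flipped])
        offset[bad_verts] *= 0.5
        reduced = True
    if reduced:
        import warnings

        warnings.warn(
            "tissue offset reduced locally to avoid self-intersection",
            UserWarning,
            stacklevel=2,
        )
    return replace(m, vertices=v - vnorm * offset[:, None])


# ---------------------------------------------------------------------------
# end-to-end synthetic measurement protocol


def synthetic_measurements(spec: SyntheticColonySpec, name: str = "synthetic"):
    """Run the full measurement protocol on one synthetic colony.

    Mirrors the field pipeline: the unsampled colony is measured
    underwater (surface area over living faces — the basal closure stands
    in for the hidden reef attachment and is not part of the visible
    model; volume on the closed colony), a patch is detached and the
    sampled colony re-measured, then the fragment is measured fresh
    ("tissue") and after simulated bleaching ("skeleton").  Returns the
    raw :class:`~coralmorph.metrics.ColonyMeasurements` and the colony's
    :class:`GroundTruth` (with removed-patch quantities filled in).

    Water-displacement volume is a physical bench measurement with no
    digital counterpart, so ``tv_water`` is left absent.
    """
    from .metrics import ColonyMeasurements

    colony = make_colony(spec)
    mesh, mask, gt = colony
    unsampled_sa = float(face_areas(mesh)[mask.in_classes({LIVING})].sum())
    colony_only, _ = segment(mesh, mask, {LIVING, NONLIVING_CONTACT})
    try:
        unsampled_v = enclosed_volume(colony_only)
    except MeshError:
        unsampled_v = None

    s = apply_sampling(mesh, mask, spec)
    living_s = s.sampled_mask.in_classes({LIVING})
    esa_sampled = float(face_areas(s.sampled_mesh)[living_s].sum())
    break_area = float(face_areas(s.sampled_mesh)[s.sampled_break_faces].sum())
    tsa_sampled = esa_sampled + break_area
    try:
        tv_sampled = enclosed_volume(s.sampled_mesh)
    except MeshError:
        tv_sampled = None

    def dry_measurements(sample_mesh, sample_mask):
        tsa = float(face_areas(sample_mesh).sum())
        esa = float(face_areas(sample_mesh)[sample_mask.in_classes({LIVING})].sum())
        try:
            tv = enclosed_volume(sample_mesh)
        except MeshError:
            tv = None
        return tsa, esa, tv

    tsa_tissue, esa_tissue, tv_tissue = dry_measurements(s.sample_mesh, s.sample_mask)
    skeleton = apply_bleaching(s.sample_mesh, s.sample_mask, spec)
    tsa_skel, esa_skel, tv_skel = dry_measurements(skeleton, s.sample_mask)

    growth_map = {"massive": "massive", "branched": "branched",
                  "tabular": "tabular", "foliose": "foliose"}
    m = ColonyMeasurements(
        name=name,
        growth_form=growth_map[spec.growth_form],
        unsampled_sa=unsampled_sa,
        tsa_sampled=tsa_sampled,
        esa_sampled=esa_sampled,
        tsa_tissue=tsa_tissue,
        esa_tissue=esa_tissue,
        tsa_skeleton=tsa_skel,
        esa_skeleton=esa_skel,
        unsampled_v=unsampled_v,
        tv_sampled=tv_sampled,
        tv_tissue=tv_tissue if tv_tissue is not None else 0.0,
        tv_skeleton=tv_skel if tv_skel is not None else 0.0,
        tv_water=None,
    )
    gt = replace(
        gt,
        removed_patch_sa=s.ground_truth.removed_patch_sa,
        removed_fragment_v=s.ground_truth.removed_fragment_v,
    )
    return m, gt
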