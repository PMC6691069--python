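"""Labelled tetrahedral geometry: synthetic cochlea-like duct and analytic fixtures.

The synthetic duct emulates the topology of the cochlear canals without
claiming anatomical fidelity: three fluid chambers (scala tympani, media,
vestibuli) stacked in z and separated by two zero-thickness membrane surfaces
(basilar, Reissner's), a soft-tissue shell, a nerve-tissue block (the
cochlear partition, carrying the organ of Corti) sitting on the basilar
membrane, and an 8-electrode array carried by an insulating rod inside the
scala tympani.  Electrode metal is not meshed: each electrode is a band of
boundary faces on the carved-out carrier surface (equipotential Dirichlet
patches in the field solver).

Meshing is structured: a uniform grid of cubes, each split into six
positively oriented tetrahedra sharing the cube's main diagonal (Kuhn
decomposition, conforming across cells and under uniform refinement).
Membranes are represented by duplicated node sheets: every node strictly
inside the membrane footprint is doubled, tetrahedra above the plane use the
duplicate, and the paired triangle sheets are later coupled by a contact
impedance.  Rim nodes (where the membrane is attached to the surrounding
tissue) stay shared.

Coordinates are in meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "REGION_NAMES", "ELECTRODE_SURFACES", "MEMBRANE_SURFACES",
    "TissueMesh", "MembraneSurface", "ElectrodeConfig", "ArraySpec", "DuctSpec",
    "build_duct_geometry", "build_slab_fixture", "electrode_configuration",
    "validate_mesh",
]

REGION_NAMES = ("scala_tympani", "scala_media", "scala_vestibuli",
                "soft_tissue", "partition")
ELECTRODE_SURFACES = tuple(f"electrode_{i}" for i in range(1, 9))
MEMBRANE_SURFACES = ("basilar_membrane", "reissner_membrane")
SURFACE_NAMES = ELECTRODE_SURFACES + MEMBRANE_SURFACES + ("outer",)


@dataclass
class MembraneSurface:
    """Zero-thickness two-sided surface with paired duplicate nodes.

    Triangles are stored per side; ``node_pairs`` maps side-1 node ids to
    side-2 ids (rim nodes attached to the surround map to themselves).
    """

    tris_side1: np.ndarray     # (T, 3) int
    tris_side2: np.ndarray     # (T, 3) int
    node_pairs: np.ndarray     # (P, 2) int, [side1_id, side2_id]

    def pair_map(self) -> dict[int, int]:
        return {int(a): int(b) for a, b in self.node_pairs}


@dataclass
class TissueMesh:
    """Conforming labelled tetrahedral mesh.

    nodes           : (N, 3) float, meters
    tets            : (M, 4) int, positively oriented
    tet_regions     : (M,) int -> region_names
    boundary_tris   : (B, 3) int, exterior faces
    boundary_labels : (B,) int -> surface_names
    membranes       : label -> MembraneSurface (interior two-sided sheets)
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_regions: np.ndarray
    region_names: dict[int, str]
    boundary_tris: np.ndarray
    boundary_labels: np.ndarray
    surface_names: dict[int, str]
    membranes: dict[str, MembraneSurface] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    def region_id(self, name: str) -> int:
        for i, n in self.region_names.items():
            if n == name:
                return i
        raise ValidationError(f"region {name!r} not present in mesh")

    def surface_id(self, name: str) -> int:
        for i, n in self.surface_names.items():
            if n == name:
                return i
        raise ValidationError(f"surface {name!r} not present in mesh")

    def surface_tris(self, name: str) -> np.ndarray:
        if name in self.membranes:
            return self.membranes[name].tris_side1
        sid = self.surface_id(name)
        return self.boundary_tris[self.boundary_labels == sid]

    def surface_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.surface_tris(name))

    def present_regions(self) -> list[str]:
        return [self.region_names[i] for i in np.unique(self.tet_regions)]

    def present_surfaces(self) -> list[str]:
        out = [self.surface_names[i] for i in np.unique(self.boundary_labels)]
        return out + list(self.membranes)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def tri_areas(self, tris: np.ndarray) -> np.ndarray:
        p = self.nodes[tris]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


@dataclass
class ElectrodeConfig:
    """Role of each electrode in the 8-channel array."""

    roles: tuple[str, ...]
    name: str = "custom"

    def __post_init__(self):
        for r in self.roles:
            if r not in ("anode", "cathode", "floating"):
                raise ValidationError(f"unknown electrode role {r!r}")
        if "anode" not in self.roles or "cathode" not in self.roles:
            raise ValidationError(
                "a stimulation configuration needs at least one anode and one cathode")

    def electrodes(self, role: str) -> list[str]:
        return [f"electrode_{i + 1}" for i, r in enumerate(self.roles) if r == role]

    @property
    def anodes(self) -> list[str]:
        return self.electrodes("anode")

    @property
    def cathodes(self) -> list[str]:
        return self.electrodes("cathode")


def electrode_configuration(spec) -> ElectrodeConfig:
    """Named ('alternate' / 'tandem') or explicit 8-role electrode configuration.

    'alternate': anode/cathode interleaved A,C,A,C,...; 'tandem': the first
    four electrodes ganged as anode, the next four as cathode.
    """
    if isinstance(spec, ElectrodeConfig):
        return spec
    if isinstance(spec, str):
        if spec == "alternate":
            return ElectrodeConfig(("anode", "cathode") * 4, name="alternate")
        if spec == "tandem":
            return ElectrodeConfig(("anode",) * 4 + ("cathode",) * 4, name="tandem")
        raise ValidationError(f"unknown configuration name {spec!r}")
    roles = tuple({"a": "anode", "c": "cathode", "f": "floating"}.get(
        str(r).lower()[:1], str(r).lower()) for r in spec)
    return ElectrodeConfig(roles)


@dataclass
class ArraySpec:
    """Cylindrical 8-electrode array dimensions (meters)."""

    electrode_diameter: float = 350e-6
    electrode_length: float = 300e-6
    gap: float = 300e-6
    n_electrodes: int = 8

    def __post_init__(self):
        if min(self.electrode_diameter, self.electrode_length, self.gap) <= 0:
            raise ValidationError("array dimensions must be > 0")
        if self.n_electrodes < 1:
            raise ValidationError("need at least one electrode")

    @property
    def span(self) -> float:
        """Distance from the leading edge of the first to the trailing edge
        of the last electrode band."""
        return (self.n_electrodes * self.electrode_length
                + (self.n_electrodes - 1) * self.gap)


@dataclass
class DuctSpec:
    """Cross-section and length of the synthetic duct (meters).

    z-stacking (bottom to top): wall | scala tympani | basilar membrane |
    scala media + partition | Reissner's membrane | scala vestibuli | wall.
    The partition occupies the far-y side of the scala-media layer.  The
    electrode carrier is an insulating rod of square cross-section carved out
    of the scala tympani.

    Length scales follow the guinea-pig cochlea: an unrolled duct of about
    16 mm, the array inserted at the basal end (offset `array_offset`), and
    the membranes terminating `helicotrema_length` before the apical wall so
    that the scalae communicate at the apex (the helicotrema), which is the
    return path that lets stimulation current spread beyond the array.
    """

    length: float = 16.0e-3
    array_offset: float = 1.2e-3
    helicotrema_length: float = 1.0e-3
    wall: float = 0.3e-3
    fluid_width: float = 1.0e-3
    st_height: float = 0.7e-3
    sm_height: float = 0.3e-3
    sv_height: float = 0.6e-3
    partition_width: float = 0.3e-3
    carrier_side: float = 0.3e-3
    carrier_clear_y: float = 0.3e-3   # carrier offset from the near fluid wall
    carrier_clear_z: float = 0.2e-3   # carrier offset from the duct floor

    def __post_init__(self):
        if min(self.length, self.array_offset, self.helicotrema_length,
               self.wall, self.fluid_width, self.st_height,
               self.sm_height, self.sv_height, self.partition_width,
               self.carrier_side, self.carrier_clear_y, self.carrier_clear_z) <= 0:
            raise ValidationError("duct dimensions must be > 0")
        if self.partition_width >= self.fluid_width:
            raise ValidationError("partition must be narrower than the fluid duct")
        if self.carrier_clear_y + self.carrier_side >= self.fluid_width:
            raise ValidationError("carrier does not fit the duct width")
        if self.carrier_clear_z + self.carrier_side >= self.st_height:
            raise ValidationError("carrier does not fit the scala tympani height")


# ---------------------------------------------------------------------------
# structured meshing primitives
# ---------------------------------------------------------------------------

# Kuhn decomposition: six tets around the main diagonal (0,0,0)-(1,1,1).
# Corner bit order: index = ix + 2*iy + 4*iz.
_KUHN_PATHS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
_AXIS_BIT = (1, 2, 4)


def _kuhn_tets():
    tets = []
    for path in _KUHN_PATHS:
        c = [0]
        for ax in path:
            c.append(c[-1] | _AXIS_BIT[ax])
        tets.append(c)
    return np.asarray(tets)


_KUHN = _kuhn_tets()


def _snap_index(coord: float, h: float) -> int:
    return int(round(coord / h))


def _build_grid(nx: int, ny: int, nz: int, h: float, origin=(0.0, 0.0, 0.0)):
    """Nodes of a uniform grid and the node-id function."""
    ii, jj, kk = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                             np.arange(nz + 1), indexing="ij")
    nodes = np.column_stack([
        origin[0] + ii.ravel() * h,
        origin[1] + jj.ravel() * h,
        origin[2] + kk.ravel() * h,
    ])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    return nodes, nid


def _structured_mesh(nx, ny, nz, h, region_of: Callable, origin=(0.0, 0.0, 0.0)):
    """Uniform Kuhn tet mesh of an nx*ny*nz cell grid.

    region_of(cx, cy, cz) -> region name or None (None carves the cell out).
    """
    nodes, nid = _build_grid(nx, ny, nz, h, origin)
    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    cx = origin[0] + (ci + 0.5) * h
    cy = origin[1] + (cj + 0.5) * h
    cz = origin[2] + (ck + 0.5) * h
    regions = region_of(cx, cy, cz)  # vectorized: array of str or None
    keep = np.asarray([r is not None for r in regions])
    ci, cj, ck = ci[keep], cj[keep], ck[keep]
    regions = [r for r in regions if r is not None]

    # region name <-> id
    names = sorted(set(regions))
    rid_of = {n: i for i, n in enumerate(names)}
    region_ids = np.asarray([rid_of[r] for r in regions])

    # corner node ids per kept cell: (ncell, 8) in bit order
    corners = np.empty((ci.size, 8), dtype=np.int64)
    for b in range(8):
        corners[:, b] = nid(ci + (b & 1), cj + ((b >> 1) & 1), ck + ((b >> 2) & 1))
    tets = corners[:, _KUHN].reshape(-1, 4)
    tet_regions = np.repeat(region_ids, 6)

    # drop nodes orphaned by carved-out cells and renumber
    used = np.unique(tets)
    remap = np.full(nodes.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = nodes[used]
    tets = remap[tets]

    # orient positively
    p = nodes[tets]
    vol = np.linalg.det(p[:, 1:] - p[:, :1])
    flip = vol < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    region_names = {i: n for n, i in rid_of.items()}
    return nodes, tets, tet_regions, region_names


def _tet_faces(tets: np.ndarray) -> np.ndarray:
    """All 4 faces of each tet, outward node order irrelevant: (4M, 3)."""
    f = np.concatenate([
        tets[:, [1, 2, 3]], tets[:, [0, 3, 2]],
        tets[:, [0, 1, 3]], tets[:, [0, 2, 1]],
    ])
    return f


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one tet (exterior + membrane sheets)."""
    faces = _tet_faces(tets)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def _insert_membrane(nodes, tets, tet_regions, z_m, footprint_strict, h):
    """Split the mesh along plane z = z_m inside a footprint.

    footprint_strict(x, y) -> bool mask of nodes to DUPLICATE (rim excluded).
    Tets with centroid above the plane are remapped onto the duplicates.
    Returns (nodes, tets, MembraneSurface).
    """
    tol = 1e-6 * h
    on_plane = np.abs(nodes[:, 2] - z_m) < tol
    dup_mask = on_plane & footprint_strict(nodes[:, 0], nodes[:, 1])
    dup_ids = np.flatnonzero(dup_mask)
    if dup_ids.size == 0:
        raise ValidationError("membrane footprint contains no interior nodes "
                              "(mesh too coarse for the membrane extent)")
    new_ids = np.arange(nodes.shape[0], nodes.shape[0] + dup_ids.size)
    nodes = np.vstack([nodes, nodes[dup_ids]])
    remap = np.arange(nodes.shape[0])
    remap_upper = remap.copy()
    remap_upper[dup_ids] = new_ids

    centroids_z = nodes[tets].mean(axis=1)[:, 2]
    above = centroids_z > z_m
    tets = tets.copy()
    tets[above] = remap_upper[tets[above]]

    # side-1 (below) membrane triangles: plane faces of below tets inside footprint
    below_touch = ~above & np.any(np.isin(tets, dup_ids), axis=1)
    faces = _tet_faces(tets[below_touch])
    on = np.all(np.abs(nodes[faces][:, :, 2] - z_m) < tol, axis=1)
    faces = faces[on]
    # keep faces with at least one duplicated (strict-interior) node
    keep = np.any(np.isin(faces, dup_ids), axis=1)
    tris1 = np.unique(np.sort(faces[keep], axis=1), axis=0)
    tris2 = remap_upper[tris1]
    pairs = np.column_stack([dup_ids, new_ids])
    return nodes, tets, MembraneSurface(tris1, tris2, pairs)


def _label_boundary(nodes, tets, membranes, labeller):
    """Exterior faces (minus membrane sheets) labelled via `labeller`.

    labeller(centroids (F,3)) -> array of surface names.
    """
    faces = _boundary_faces(tets)
    if membranes:
        mem_keys = set()
        for m in membranes.values():
            for tri in np.vstack([m.tris_side1, m.tris_side2]):
                mem_keys.add(tuple(sorted(tri)))
        keep = np.asarray([tuple(sorted(f)) not in mem_keys for f in faces])
        faces = faces[keep]
    cents = nodes[faces].mean(axis=1)
    names = labeller(cents)
    uniq = sorted(set(names))
    sid_of = {n: i for i, n in enumerate(uniq)}
    labels = np.asarray([sid_of[n] for n in names])
    surface_names = {i: n for n, i in sid_of.items()}
    return faces, labels, surface_names


# ---------------------------------------------------------------------------
# fixtures and the duct
# ---------------------------------------------------------------------------

def build_slab_fixture(dims: Sequence[float] = (1e-3, 1e-3, 1e-3),
                       mesh_size: float = 0.25e-3,
                       membrane: bool = False,
                       membrane_label: str = "basilar_membrane",
                       electrode_fraction: float = 1.0) -> TissueMesh:
    """Rectangular column: electrode_1 on the z=0 face, electrode_2 opposite.

    With ``membrane=True`` a full-cross-section membrane sheet is inserted at
    the mid-plane (all plane nodes duplicated: the two halves are coupled
    only through the contact impedance).  ``electrode_fraction < 1`` shrinks
    the electrode patches to a centered sub-square of the faces, producing a
    constriction problem with a non-trivial (curved) solution for
    refinement studies.
    """
    lx, ly, lz = dims
    if min(lx, ly, lz) <= 0:
        raise ValidationError("slab dimensions must be > 0")
    h = mesh_size
    nx, ny, nz = (max(1, _snap_index(d, h)) for d in (lx, ly, lz))
    if membrane and nz < 2:
        raise ValidationError("mesh too coarse for a mid-plane membrane")
    if nz % 2 == 1 and membrane:
        nz += 1  # mid-plane must be a grid plane

    def region_of(cx, cy, cz):
        return ["scala_tympani"] * cx.size

    nodes, tets, tet_regions, region_names = _structured_mesh(
        nx, ny, nz, h, region_of)
    # actual extents after snapping
    LX, LY, LZ = nx * h, ny * h, nz * h

    membranes = {}
    if membrane:
        nodes, tets, surf = _insert_membrane(
            nodes, tets, tet_regions, LZ / 2.0,
            lambda x, y: np.ones(x.size, dtype=bool), h)
        membranes[membrane_label] = surf

    frac = float(electrode_fraction)
    if not (0 < frac <= 1):
        raise ValidationError("electrode_fraction must be in (0, 1]")
    x0, x1 = (1 - frac) / 2 * LX, (1 + frac) / 2 * LX
    y0, y1 = (1 - frac) / 2 * LY, (1 + frac) / 2 * LY

    def labeller(c):
        tol = 1e-6 * h
        names = np.full(c.shape[0], "outer", dtype=object)
        in_patch = (c[:, 0] > x0 - tol) & (c[:, 0] < x1 + tol) & \
                   (c[:, 1] > y0 - tol) & (c[:, 1] < y1 + tol)
        names[(c[:, 2] < tol) & in_patch] = "electrode_1"
        names[(c[:, 2] > LZ - tol) & in_patch] = "electrode_2"
        return list(names)

    faces, labels, surface_names = _label_boundary(nodes, tets, membranes, labeller)
    mesh = TissueMesh(nodes, tets, tet_regions, region_names,
                      faces, labels, surface_names, membranes)
    validate_mesh(mesh)
    return mesh


def build_duct_geometry(array: ArraySpec | None = None,
                        duct: DuctSpec | None = None,
                        mesh_size: float = 0.1e-3,
                        spiral: bool = False,
                        spiral_radius: float = 3.0e-3,
                        spiral_pitch: float = 1.0e-3,
                        spiral_radius_taper: float = 0.2e-3) -> TissueMesh:
    """Synthetic multi-chamber duct with an embedded 8-electrode array.

    Feature coordinates are snapped to the structured grid; the mesh size
    must resolve the electrode length with at least three elements.  With
    ``spiral=True`` the straight duct is bent onto a spiral of variable
    radius and uniform pitch (a smooth coordinate map; labels unchanged).
    """
    array = array or ArraySpec()
    duct = duct or DuctSpec()
    h = mesh_size
    if array.electrode_length / h < 3.0 - 1e-9:
        raise ValidationError(
            f"mesh size {h:g} m violates the resolution rule: need >= 3 "
            f"elements per electrode length ({array.electrode_length:g} m)")

    # z layout
    z_wall0 = duct.wall
    z_bm = z_wall0 + duct.st_height                 # basilar membrane plane
    z_rm = z_bm + duct.sm_height                    # Reissner's membrane plane
    z_top_fluid = z_rm + duct.sv_height
    LZ = z_top_fluid + duct.wall
    LY = duct.fluid_width + 2 * duct.wall
    LX = duct.length
    y_f0, y_f1 = duct.wall, duct.wall + duct.fluid_width
    y_part = y_f1 - duct.partition_width            # partition on far-y side

    # carrier and electrode bands (x); array inserted at the basal end
    span = array.span
    x_arr0 = duct.array_offset
    if x_arr0 + span + duct.carrier_side + duct.wall >= LX:
        raise ValidationError("duct too short for the electrode array")
    if x_arr0 - duct.carrier_side <= duct.wall:
        raise ValidationError("array offset leaves no room for the carrier tip")
    y_c0 = y_f0 + duct.carrier_clear_y
    y_c1 = y_c0 + duct.carrier_side
    z_c0 = z_wall0 + duct.carrier_clear_z
    z_c1 = z_c0 + duct.carrier_side
    x_c0 = x_arr0 - duct.carrier_side
    x_c1 = x_arr0 + span + duct.carrier_side

    # snap everything to the grid
    def S(v):
        return _snap_index(v, h) * h

    z_bm, z_rm, z_wall0, z_top_fluid = S(z_bm), S(z_rm), S(z_wall0), S(z_top_fluid)
    y_f0, y_f1, y_part = S(y_f0), S(y_f1), S(y_part)
    y_c0, y_c1, z_c0, z_c1 = S(y_c0), S(y_c1), S(z_c0), S(z_c1)
    x_c0, x_c1, x_arr0 = S(x_c0), S(x_c1), S(x_arr0)
    band_w = S(array.electrode_length)
    pitch = S(array.electrode_length + array.gap)
    if band_w <= 0 or pitch <= band_w:
        raise ValidationError("mesh size too coarse for the electrode bands")
    if y_c1 <= y_c0 or z_c1 <= z_c0:
        raise ValidationError("mesh size too coarse for the electrode carrier")
    nx, ny, nz = _snap_index(LX, h), _snap_index(LY, h), _snap_index(LZ, h)
    LX, LY, LZ = nx * h, ny * h, nz * h
    x_fl0, x_fl1 = S(duct.wall), S(LX - duct.wall)   # fluid x-extent
    x_heli = S(x_fl1 - duct.helicotrema_length)      # membranes end here

    def region_of(cx, cy, cz):
        out = []
        for x, y, z in zip(cx, cy, cz):
            in_fluid_xy = (x_fl0 < x < x_fl1) and (y_f0 < y < y_f1)
            if not in_fluid_xy or not (z_wall0 < z < z_top_fluid):
                out.append("soft_tissue")
                continue
            if z < z_bm:     # scala tympani layer
                if x_c0 < x < x_c1 and y_c0 < y < y_c1 and z_c0 < z < z_c1:
                    out.append(None)  # carved carrier
                else:
                    out.append("scala_tympani")
            elif z < z_rm:   # scala media layer (+ partition); open at the apex
                if x > x_heli:
                    out.append("scala_media")
                else:
                    out.append("partition" if y > y_part else "scala_media")
            else:
                out.append("scala_vestibuli")
        return out

    nodes, tets, tet_regions, region_names = _structured_mesh(
        nx, ny, nz, h, region_of)

    def strict_inside(x, y):
        tol = 1e-6 * h
        return (x > x_fl0 + tol) & (x < x_heli - tol) & \
               (y > y_f0 + tol) & (y < y_f1 - tol)

    membranes = {}
    nodes, tets, surf = _insert_membrane(nodes, tets, tet_regions, z_bm,
                                         strict_inside, h)
    membranes["basilar_membrane"] = surf
    nodes, tets, surf = _insert_membrane(nodes, tets, tet_regions, z_rm,
                                         strict_inside, h)
    membranes["reissner_membrane"] = surf

    def labeller(c):
        tol = 1e-6 * h
        names = []
        on_carrier = (c[:, 0] > x_c0 - tol) & (c[:, 0] < x_c1 + tol) & \
                     (c[:, 1] > y_c0 - tol) & (c[:, 1] < y_c1 + tol) & \
                     (c[:, 2] > z_c0 - tol) & (c[:, 2] < z_c1 + tol)
        for x, carrier in zip(c[:, 0], on_carrier):
            name = "outer"
            if carrier:
                rel = x - x_arr0
                k = int(np.floor(rel / pitch))
                if 0 <= k < array.n_electrodes and (rel - k * pitch) < band_w - tol:
                    name = f"electrode_{k + 1}"
            names.append(name)
        return names

    faces, labels, surface_names = _label_boundary(nodes, tets, membranes, labeller)

    if spiral:
        nodes = _spiral_transform(nodes, LX, LY, spiral_radius, spiral_pitch,
                                  spiral_radius_taper)
        # re-orient after the coordinate map
        p = nodes[tets]
        vol = np.linalg.det(p[:, 1:] - p[:, :1])
        flip = vol < 0
        tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()

    mesh = TissueMesh(nodes, tets, tet_regions, region_names,
                      faces, labels, surface_names, membranes)
    validate_mesh(mesh)
    missing = [e for e in ELECTRODE_SURFACES[:array.n_electrodes]
               if e not in mesh.present_surfaces()]
    if missing:
        raise ValidationError(f"electrode surfaces not generated: {missing}")
    return mesh


def _spiral_transform(nodes, LX, LY, r0, pitch, taper):
    """Bend the duct axis (x) onto a spiral of variable radius, uniform pitch."""
    theta = nodes[:, 0] / r0
    r = r0 - taper * theta + (nodes[:, 1] - LY / 2.0)
    if np.any(r <= 0):
        raise ValidationError("spiral radius too small for the duct width")
    out = np.empty_like(nodes)
    out[:, 0] = r * np.cos(theta)
    out[:, 1] = r * np.sin(theta)
    out[:, 2] = nodes[:, 2] + pitch * theta / (2.0 * np.pi)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TissueMesh) -> None:
    """Check all mesh invariants; raise ValidationError on the first failure.

    Checks: positive tet orientation, conformity (each interior face shared
    by exactly two tets), every exterior face accounted for (labelled or on a
    membrane sheet), membrane node pairing a coordinate-identical bijection,
    and electrode surfaces adjacent to scala tympani.
    """
    vols = mesh.tet_volumes()
    if np.any(vols <= 0):
        raise ValidationError(
            f"{int(np.sum(vols <= 0))} non-positively-oriented tetrahedra")

    faces = _tet_faces(mesh.tets)
    key = np.sort(faces, axis=1)
    uf, counts = np.unique(key, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise ValidationError("non-conforming mesh: face shared by > 2 tets")
    exterior = {tuple(f) for f in uf[counts == 1]}

    accounted = {tuple(sorted(f)) for f in mesh.boundary_tris}
    for m in mesh.membranes.values():
        accounted |= {tuple(sorted(f)) for f in m.tris_side1}
        accounted |= {tuple(sorted(f)) for f in m.tris_side2}
    dangling = [f for f in accounted if f not in exterior]
    if dangling:
        raise ValidationError(
            f"{len(dangling)} labelled faces are not faces of exactly one tet")
    unaccounted = exterior - accounted
    if unaccounted:
        raise ValidationError(
            f"{len(unaccounted)} exterior faces carry no surface label")

    for name, m in mesh.membranes.items():
        a, b = m.node_pairs[:, 0], m.node_pairs[:, 1]
        if len(set(a.tolist())) != a.size or len(set(b.tolist())) != b.size:
            raise ValidationError(f"membrane {name}: node pairing not a bijection")
        if not np.allclose(mesh.nodes[a], mesh.nodes[b], atol=0.0, rtol=0.0):
            raise ValidationError(f"membrane {name}: paired nodes not co-located")
        if m.tris_side1.shape != m.tris_side2.shape:
            raise ValidationError(f"membrane {name}: unpaired triangle sheets")

    # electrode faces must belong to a tet in scala tympani
    try:
        st = mesh.region_id("scala_tympani")
    except ValidationError:
        st = None
    if st is not None:
        face_of = {}
        st_tets = mesh.tets[mesh.tet_regions == st]
        for f in _tet_faces(st_tets):
            face_of[tuple(sorted(f))] = True
        for sid, name in mesh.surface_names.items():
            if not name.startswith("electrode_"):
                continue
            for f in mesh.boundary_tris[mesh.boundary_labels == sid]:
                if tuple(sorted(f)) not in face_of:
                    raise ValidationError(
                        f"{name} face not adjacent to scala tympani")
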