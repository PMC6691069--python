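"""Mesh interchange: Gmsh MSH 4.1 (ASCII) in/out and VTU (XML VTK) out.

Physical-group vocabulary: volume groups must be named after the tissue
regions (scala_tympani, scala_media, scala_vestibuli, soft_tissue,
partition); surface groups after electrode_1..electrode_8, outer, or a
membrane side  "<membrane>:side1" / "<membrane>:side2"  (e.g.
"basilar_membrane:side1").  Membrane node pairing is reconstructed from
co-located coordinates on re-read.
"""

from __future__ import annotations

import io
from xml.sax.saxutils import escape

import numpy as np

from .errors import FormatError, ValidationError
from .geometry import (TissueMesh, MembraneSurface, REGION_NAMES,
                       ELECTRODE_SURFACES, validate_mesh)

__all__ = ["write_msh", "read_mesh", "write_fields"]

_ACCEPTED_SURFACES = set(ELECTRODE_SURFACES) | {"outer"}


def write_msh(path, mesh: TissueMesh) -> None:
    """Write a TissueMesh as ASCII Gmsh MSH 4.1 with named physical groups."""
    # physical groups: (dim, tag, name)
    phys = []
    vol_tag = {}
    for rid in sorted(mesh.region_names):
        tag = len(phys) + 1
        phys.append((3, tag, mesh.region_names[rid]))
        vol_tag[rid] = tag
    surf_tag = {}
    for sid in sorted(mesh.surface_names):
        tag = len(phys) + 1
        phys.append((2, tag, mesh.surface_names[sid]))
        surf_tag[("b", sid)] = tag
    for name, m in mesh.membranes.items():
        for side in (1, 2):
            tag = len(phys) + 1
            phys.append((2, tag, f"{name}:side{side}"))
            surf_tag[("m", name, side)] = tag

    # one discrete entity per physical group, entity tag = physical tag
    surf_entities = [(t, pt) for (t, pt) in
                     [(tag, tag) for d, tag, _ in phys if d == 2]]
    vol_entities = [(tag, tag) for d, tag, _ in phys if d == 3]

    out = io.StringIO()
    out.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    out.write("$PhysicalNames\n%d\n" % len(phys))
    for d, tag, name in phys:
        out.write(f'{d} {tag} "{name}"\n')
    out.write("$EndPhysicalNames\n")

    out.write("$Entities\n0 0 %d %d\n" % (len(surf_entities), len(vol_entities)))
    for tag, ptag in surf_entities:
        out.write(f"{tag} 0 0 0 0 0 0 1 {ptag} 0\n")
    for tag, ptag in vol_entities:
        out.write(f"{tag} 0 0 0 0 0 0 1 {ptag} 0\n")
    out.write("$EndEntities\n")

    n = mesh.nodes.shape[0]
    first_vol = vol_entities[0][0]
    out.write("$Nodes\n1 %d 1 %d\n" % (n, n))
    out.write(f"3 {first_vol} 0 {n}\n")
    out.write("\n".join(str(i + 1) for i in range(n)))
    out.write("\n")
    for p in mesh.nodes:
        out.write("%.17g %.17g %.17g\n" % (p[0], p[1], p[2]))
    out.write("$EndNodes\n")

    # element blocks
    blocks = []  # (dim, entity_tag, elem_type, connectivity array)
    for rid in sorted(mesh.region_names):
        conn = mesh.tets[mesh.tet_regions == rid]
        if conn.size:
            blocks.append((3, vol_tag[rid], 4, conn))
    for sid in sorted(mesh.surface_names):
        conn = mesh.boundary_tris[mesh.boundary_labels == sid]
        if conn.size:
            blocks.append((2, surf_tag[("b", sid)], 2, conn))
    for name, m in mesh.membranes.items():
        blocks.append((2, surf_tag[("m", name, 1)], 2, m.tris_side1))
        blocks.append((2, surf_tag[("m", name, 2)], 2, m.tris_side2))

    n_elem = sum(b[3].shape[0] for b in blocks)
    out.write("$Elements\n%d %d 1 %d\n" % (len(blocks), n_elem, n_elem))
    eid = 1
    for dim, etag, etype, conn in blocks:
        out.write(f"{dim} {etag} {etype} {conn.shape[0]}\n")
        for row in conn:
            out.write(str(eid) + " " + " ".join(str(v + 1) for v in row) + "\n")
            eid += 1
    out.write("$EndElements\n")

    with open(path, "w") as fh:
        fh.write(out.getvalue())


def _read_sections(path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("$End"):
                name = None
            elif line.startswith("$"):
                name = line[1:]
                sections[name] = []
            elif name is not None:
                sections[name].append(line)
    return sections


def read_mesh(path) -> TissueMesh:
    """Read an ASCII Gmsh MSH 4.1 file with the package's physical-group names."""
    sec = _read_sections(path)
    for required in ("MeshFormat", "Nodes", "Elements"):
        if required not in sec:
            raise FormatError(f"{path}: missing ${required} section")
    version = sec["MeshFormat"][0].split()[0]
    if not version.startswith("4"):
        raise FormatError(f"{path}: unsupported MSH version {version} (need 4.x)")

    phys_name = {}
    for line in sec.get("PhysicalNames", [])[1:]:
        parts = line.split(None, 2)
        phys_name[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    # entity -> physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    ent_lines = sec.get("Entities", [])
    if ent_lines:
        np_, nc, ns, nv = (int(v) for v in ent_lines[0].split())
        idx = 1
        idx += np_ + nc  # points/curves irrelevant
        for dim, count in ((2, ns), (3, nv)):
            for _ in range(count):
                vals = ent_lines[idx].split()
                idx += 1
                tag = int(vals[0])
                nphys = int(vals[7])
                if nphys > 0:
                    ent_phys[(dim, tag)] = int(vals[8])

    # nodes
    lines = sec["Nodes"]
    n_blocks, n_nodes = int(lines[0].split()[0]), int(lines[0].split()[1])
    tags, coords = [], []
    idx = 1
    for _ in range(n_blocks):
        nb = int(lines[idx].split()[3])
        idx += 1
        btags = [int(lines[idx + i]) for i in range(nb)]
        idx += nb
        for i in range(nb):
            coords.append([float(v) for v in lines[idx + i].split()[:3]])
        idx += nb
        tags.extend(btags)
    tag2idx = {t: i for i, t in enumerate(tags)}
    nodes = np.asarray(coords)

    # elements
    lines = sec["Elements"]
    n_blocks = int(lines[0].split()[0])
    idx = 1
    tets, tet_names = [], []
    tris: dict[str, list] = {}
    for _ in range(n_blocks):
        dim, etag, etype, nb = (int(v) for v in lines[idx].split())
        idx += 1
        pname = phys_name.get((dim, ent_phys.get((dim, etag), etag)),
                              phys_name.get((dim, etag)))
        for i in range(nb):
            vals = lines[idx + i].split()
            conn = [tag2idx[int(v)] for v in vals[1:]]
            if etype == 4:
                if pname is None:
                    raise FormatError(f"{path}: volume elements without a "
                                      "physical group name")
                tets.append(conn)
                tet_names.append(pname)
            elif etype == 2:
                if pname is None:
                    raise FormatError(f"{path}: surface elements without a "
                                      "physical group name")
                tris.setdefault(pname, []).append(conn)
        idx += nb

    if not tets:
        raise FormatError(f"{path}: no tetrahedra found")
    bad = sorted(set(tet_names) - set(REGION_NAMES))
    if bad:
        raise FormatError(f"{path}: unknown region group(s) {bad}; accepted: "
                          f"{sorted(REGION_NAMES)}")

    region_names = {i: n for i, n in enumerate(sorted(set(tet_names)))}
    rid_of = {n: i for i, n in region_names.items()}
    tets_arr = np.asarray(tets)
    tet_regions = np.asarray([rid_of[n] for n in tet_names])

    # orient positively
    p = nodes[tets_arr]
    vol = np.linalg.det(p[:, 1:] - p[:, :1])
    flip = vol < 0
    tets_arr[flip, 2], tets_arr[flip, 3] = \
        tets_arr[flip, 3].copy(), tets_arr[flip, 2].copy()

    membranes: dict[str, MembraneSurface] = {}
    boundary, blabels = [], []
    surf_names: dict[int, str] = {}
    mem_sides: dict[str, dict[int, np.ndarray]] = {}
    for pname, conn in tris.items():
        if ":side" in pname:
            base, side = pname.rsplit(":side", 1)
            mem_sides.setdefault(base, {})[int(side)] = np.asarray(conn)
        else:
            if pname not in _ACCEPTED_SURFACES:
                raise FormatError(
                    f"{path}: unknown surface group {pname!r}; accepted: "
                    f"{sorted(_ACCEPTED_SURFACES)} or '<membrane>:side1/2'")
            sid = len(surf_names)
            surf_names[sid] = pname
            arr = np.asarray(conn)
            boundary.append(arr)
            blabels.append(np.full(arr.shape[0], sid))

    for base, sides in mem_sides.items():
        if set(sides) != {1, 2}:
            raise FormatError(f"{path}: membrane {base!r} needs both sides")
        t1, t2 = sides[1], sides[2]
        n1, n2 = set(np.unique(t1).tolist()), set(np.unique(t2).tolist())
        # pair co-located nodes (side-2-only node at the coords of a side-1 node)
        key = {}
        for i in sorted(n1 - n2):
            key[tuple(np.round(nodes[i], 12))] = i
        pairs = []
        for j in sorted(n2 - n1):
            k = tuple(np.round(nodes[j], 12))
            if k not in key:
                raise FormatError(
                    f"{path}: membrane {base!r}: side-2 node {j} has no "
                    "co-located side-1 partner")
            pairs.append((key[k], j))
        membranes[base] = MembraneSurface(t1, t2, np.asarray(pairs))

    mesh = TissueMesh(
        nodes=nodes, tets=tets_arr, tet_regions=tet_regions,
        region_names=region_names,
        boundary_tris=np.vstack(boundary) if boundary else np.empty((0, 3), int),
        boundary_labels=np.concatenate(blabels) if blabels else np.empty(0, int),
        surface_names=surf_names, membranes=membranes)
    validate_mesh(mesh)
    return mesh


def write_fields(path, mesh: TissueMesh, point_data=None, cell_data=None) -> None:
    """Write the tetrahedral mesh with named fields as ASCII VTU.

    point_data: name -> (N,) nodal array (e.g. potential "V");
    cell_data : name -> (M,) per-tet array (e.g. "E_mag_V_per_m").
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    n, m = mesh.nodes.shape[0], mesh.tets.shape[0]
    for name, arr in point_data.items():
        if np.asarray(arr).shape[0] != n:
            raise ValidationError(f"point field {name!r} has wrong length")
    for name, arr in cell_data.items():
        if np.asarray(arr).shape[0] != m:
            raise ValidationError(f"cell field {name!r} has wrong length")

    def data_array(name, arr, ncomp=1):
        body = "\n".join(" ".join("%.9g" % v for v in np.atleast_1d(row))
                         for row in arr)
        return (f'<DataArray type="Float64" Name="{escape(name)}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n'
                f'</DataArray>\n')

    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        fh.write("<Points>\n")
        fh.write(data_array("points", mesh.nodes, 3))
        fh.write("</Points>\n<Cells>\n")
        conn = "\n".join(" ".join(str(v) for v in row) for row in mesh.tets)
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n'
                 + conn + "\n</DataArray>\n")
        offs = " ".join(str(4 * (i + 1)) for i in range(m))
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n'
                 + offs + "\n</DataArray>\n")
        types = " ".join("10" for _ in range(m))
        fh.write('<DataArray type="UInt8" Name="types" format="ascii">\n'
                 + types + "\n</DataArray>\n")
        fh.write("</Cells>\n")
        fh.write("<PointData>\n")
        for name, arr in point_data.items():
            fh.write(data_array(name, np.asarray(arr, dtype=float)))
        fh.write("</PointData>\n<CellData>\n")
        fh.write(data_array("region", mesh.tet_regions.astype(float)))
        for name, arr in cell_data.items():
            fh.write(data_array(name, np.asarray(arr, dtype=float)))
        fh.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
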