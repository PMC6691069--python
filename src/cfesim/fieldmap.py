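"""Field-strength area analysis on target surfaces.

For gene electrotransfer the quantity of interest is how much target-tissue
area experiences an electric field within the window effective for
transfection (and how much sees fields high enough to risk damage).  This
module bins the per-element |E| adjacent to a target surface (the basilar
membrane by default) into field-strength levels and accumulates triangle
areas per level and per sample time, then compares electrode
configurations.

Levels are half-open intervals [lo, hi) in V/cm; the default edges
(4, 8, 20, 100, 500, 1000) bracket the reported windows of interest:
4-8 and 20-100 V/cm (effective transfection) and 500-1000 V/cm (damage
risk), plus under/overflow bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import TissueMesh
from .fem_poisson import FieldSolution, electric_field_magnitude

__all__ = ["DEFAULT_BIN_EDGES_V_PER_CM", "FieldAreaReport",
           "bin_field_areas", "compare_configurations", "ComparisonReport"]

DEFAULT_BIN_EDGES_V_PER_CM = (4.0, 8.0, 20.0, 100.0, 500.0, 1000.0)


def _adjacent_elements(mesh: TissueMesh, surface_label: str, side: str):
    """Element index adjacent to each surface triangle.

    For a membrane surface, 'side1' (scala-tympani / array side, the
    default), 'side2', or 'mean' selects which neighbouring element
    evaluates |E| on the sheet.
    """
    from .geometry import _tet_faces

    def owner_map(tris):
        want = {tuple(sorted(t)): i for i, t in enumerate(map(tuple, tris))}
        owners = np.full(len(want), -1, dtype=np.int64)
        faces = _tet_faces(mesh.tets)
        elem = np.tile(np.arange(mesh.tets.shape[0]), 4)
        for f, e in zip(map(tuple, np.sort(faces, axis=1)), elem):
            i = want.get(f)
            if i is not None:
                owners[i] = e
        if np.any(owners < 0):
            raise ValidationError(
                f"{surface_label!r}: some triangles are not element faces")
        return owners

    if surface_label in mesh.membranes:
        m = mesh.membranes[surface_label]
        if side == "side1":
            return m.tris_side1, (owner_map(m.tris_side1),)
        if side == "side2":
            return m.tris_side1, (owner_map(m.tris_side2),)
        if side == "mean":
            return m.tris_side1, (owner_map(m.tris_side1),
                                  owner_map(m.tris_side2))
        raise ValidationError(f"unknown side {side!r}")
    # ordinary boundary surface
    tris = mesh.surface_tris(surface_label)
    if tris.shape[0] == 0:
        raise ValidationError(f"surface {surface_label!r} not present")
    return tris, (owner_map(tris),)


@dataclass
class FieldAreaReport:
    """Per-time, per-field-level areas of a target surface.

    bin_edges : interior edges in V/cm (ascending); bins are
                [0, e0), [e0, e1), ..., [e_last, inf) -- underflow and
                overflow included, so rows sum to the total surface area.
    areas     : (n_times, n_edges + 1) in m^2
    """

    bin_edges: np.ndarray
    times: np.ndarray
    areas: np.ndarray
    surface: str
    config_name: str = ""
    plateau_time: float | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if self.areas.shape != (self.times.size, self.bin_edges.size + 1):
            raise ValidationError("area matrix shape mismatch")
        if np.any(self.areas < 0):
            raise ValidationError("negative areas")

    def bin_labels(self) -> list[str]:
        e = self.bin_edges
        labels = [f"<{e[0]:g}"]
        labels += [f"[{a:g},{b:g})" for a, b in zip(e[:-1], e[1:])]
        labels.append(f">={e[-1]:g}")
        return labels

    def total_area(self) -> float:
        return float(self.areas[0].sum())

    def plateau_index(self) -> int:
        if self.plateau_time is None:
            return int(self.times.size - 1)
        return int(np.argmin(np.abs(self.times - self.plateau_time)))

    def area_in(self, lo: float, hi: float, time_index: int | None = None) -> float:
        """Total area (m^2) with |E| in [lo, hi) V/cm at one sample time."""
        i = self.plateau_index() if time_index is None else time_index
        e = self.bin_edges
        cols = []
        bounds = np.concatenate([[0.0], e, [np.inf]])
        for b in range(bounds.size - 1):
            if bounds[b] >= lo - 1e-12 and bounds[b + 1] <= hi + 1e-12:
                cols.append(b)
        if not cols:
            raise ValidationError(f"[{lo}, {hi}) is not a union of report bins")
        return float(self.areas[i, cols].sum())

    def to_csv(self, path) -> None:
        """CSV in mm^2: time_s then one column per bin."""
        import pandas as pd
        df = pd.DataFrame(self.areas * 1e6,
                          columns=[f"area_mm2 {l}" for l in self.bin_labels()])
        df.insert(0, "time_s", self.times)
        df.to_csv(path, index=False, float_format="%.9g")

    def summary(self) -> dict:
        i = self.plateau_index()
        return {
            "surface": self.surface,
            "configuration": self.config_name,
            "time_s": float(self.times[i]),
            "areas_mm2": {l: float(a * 1e6) for l, a in
                          zip(self.bin_labels(), self.areas[i])},
            "total_area_mm2": self.total_area() * 1e6,
        }


def bin_field_areas(solutions,
                    mesh: TissueMesh | None = None,
                    surface_label: str = "basilar_membrane",
                    bin_edges=DEFAULT_BIN_EDGES_V_PER_CM,
                    times=None,
                    side: str = "side1",
                    config_name: str = "") -> FieldAreaReport:
    """Bin per-triangle |E| (V/cm) into field levels, accumulating areas.

    `solutions` is either a coupling.SimulationResult (mesh/times taken from
    it) or a sequence of FieldSolution objects with explicit `mesh` and
    `times`.  Each surface triangle contributes its full area to the
    half-open bin [lo, hi) containing the adjacent element's |E|.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be non-empty, strictly increasing")

    plateau_time = None
    if hasattr(solutions, "unit_solution"):   # SimulationResult
        result = solutions
        mesh = result.plan.mesh
        times = result.times
        emag_unit = electric_field_magnitude(result.unit_solution) / 100.0
        tris, owners = _adjacent_elements(mesh, surface_label, side)
        e_tri_unit = np.mean([emag_unit[o] for o in owners], axis=0)
        emag_t = np.abs(np.asarray(result.scales))[:, None] * e_tri_unit[None, :]
        plateau_time = result.plan.pulse.width
        if not config_name:
            config_name = result.config.name
    else:
        if mesh is None:
            raise ValidationError("mesh required with a plain solution sequence")
        sols = list(solutions)
        if times is None:
            times = np.arange(len(sols), dtype=float)
        times = np.asarray(times, dtype=float)
        if times.size != len(sols):
            raise ValidationError("times and solutions length mismatch")
        tris, owners = _adjacent_elements(mesh, surface_label, side)
        rows = []
        for s in sols:
            em = electric_field_magnitude(s) / 100.0
            rows.append(np.mean([em[o] for o in owners], axis=0))
        emag_t = np.asarray(rows)

    tri_areas = mesh.tri_areas(tris)
    nbins = edges.size + 1
    which = np.searchsorted(edges, emag_t, side="right")  # [lo, hi) convention
    areas = np.zeros((emag_t.shape[0], nbins))
    for b in range(nbins):
        areas[:, b] = np.where(which == b, tri_areas[None, :], 0.0).sum(axis=1)

    return FieldAreaReport(bin_edges=edges, times=np.asarray(times, float),
                           areas=areas, surface=surface_label,
                           config_name=config_name, plateau_time=plateau_time)


@dataclass
class ComparisonReport:
    """Elementwise area ratios A/B per bin over time.

    0/0 entries are NaN ("undefined"), x/0 entries are +inf.
    """

    bin_edges: np.ndarray
    times: np.ndarray
    ratios: np.ndarray
    surface: str
    name_a: str
    name_b: str
    plateau_ratios: dict[str, float]

    def to_json(self, path=None):
        payload = {
            "surface": self.surface,
            "numerator": self.name_a,
            "denominator": self.name_b,
            "plateau_ratios": {k: (None if np.isnan(v) else
                                   ("inf" if np.isinf(v) else float(v)))
                               for k, v in self.plateau_ratios.items()},
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def compare_configurations(report_a: FieldAreaReport,
                           report_b: FieldAreaReport) -> ComparisonReport:
    """Per-bin area ratios report_a / report_b (e.g. tandem over alternate)."""
    if not np.array_equal(report_a.bin_edges, report_b.bin_edges):
        raise ValidationError("reports have different bin edges")
    if report_a.surface != report_b.surface:
        raise ValidationError("reports target different surfaces")
    if report_a.times.size != report_b.times.size:
        raise ValidationError("reports have different sample-time grids")

    a, b = report_a.areas, report_b.areas
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a / b
    r[(a == 0) & (b == 0)] = np.nan
    r[(a > 0) & (b == 0)] = np.inf

    ia = report_a.plateau_index()
    labels = report_a.bin_labels()
    plateau = {lab: float(r[ia, j]) for j, lab in enumerate(labels)}
    return ComparisonReport(
        bin_edges=report_a.bin_edges, times=report_a.times, ratios=r,
        surface=report_a.surface,
        name_a=report_a.config_name or "A",
        name_b=report_b.config_name or "B",
        plateau_ratios=plateau)
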