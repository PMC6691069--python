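"""Quasi-static volume-conductor finite elements on labelled tet meshes.

Solves div(-sigma grad V) = 0 with piecewise-constant isotropic conductivity
per tissue region, equipotential Dirichlet patches on electrode surfaces,
natural (zero-flux) conditions elsewhere, and thin-membrane contact
impedances: a membrane of conductivity sigma_m and numerical thickness d_s
carries a normal current density

    n . J = (sigma_m / d_s) (V_1 - V_2)

between its two sides, discretized with the triangle mass matrix on the
paired duplicate-node sheets (total conductance (sigma_m/d_s) * area).

Discretization is linear (P1) tetrahedral elements; the per-element electric
field E = -grad V is exact for the element's linear potential.  Electrode
currents are computed from the assembled-matrix residual at Dirichlet nodes
(the consistent / conservative flux), not by gradient sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ValidationError, SolverError
from .geometry import TissueMesh

__all__ = [
    "ConductivityMap", "MembraneSpec", "FieldSolution", "LinearSystem",
    "assemble", "solve_potential", "extract_resistance",
    "electric_field_magnitude", "DEFAULT_CONDUCTIVITIES", "DEFAULT_MEMBRANES",
]

#: tissue conductivities, S/m (scalae as body fluid; surround as tendon;
#: cochlear partition as nerve tissue; membranes per the cited literature)
DEFAULT_CONDUCTIVITIES = {
    "scala_tympani": 1.5,
    "scala_media": 1.5,
    "scala_vestibuli": 1.5,
    "soft_tissue": 0.25092,
    "partition": 0.017126,
}

#: membrane label -> (sigma_m S/m, numerical thickness d_s m)
DEFAULT_MEMBRANES = {
    "basilar_membrane": (0.2904, 90e-6),
    "reissner_membrane": (0.2904, 20e-6),
}


@dataclass
class ConductivityMap:
    """Region label -> specific conductivity sigma (S/m)."""

    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))

    def __post_init__(self):
        for name, s in self.values.items():
            if s <= 0:
                raise ValidationError(f"conductivity of {name!r} must be > 0")

    def __getitem__(self, name: str) -> float:
        if name not in self.values:
            raise ValidationError(f"no conductivity mapped for region {name!r}")
        return self.values[name]


@dataclass
class MembraneSpec:
    """Membrane label -> (sigma_m S/m, thickness d_s m) contact impedances."""

    values: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MEMBRANES))

    def __post_init__(self):
        for name, (s, d) in self.values.items():
            if s <= 0 or d <= 0:
                raise ValidationError(
                    f"membrane {name!r}: sigma_m and d_s must be > 0")

    def __getitem__(self, name: str) -> tuple[float, float]:
        if name not in self.values:
            raise ValidationError(f"no contact impedance mapped for membrane {name!r}")
        return self.values[name]


@dataclass
class FieldSolution:
    """Solved potential and derived fields.

    potential : (N,) V nodal
    E         : (M, 3) V/m per-element field vectors (-grad V)
    electrode_currents : surface label -> A flowing from the electrode into
                         the tissue (positive out of the electrode)
    """

    potential: np.ndarray
    E: np.ndarray
    electrode_currents: dict[str, float]
    iterations: int
    residual: float

    def scaled(self, alpha: float) -> "FieldSolution":
        """Linearity: the solution for alpha-scaled Dirichlet data."""
        return FieldSolution(
            potential=self.potential * alpha,
            E=self.E * alpha,
            electrode_currents={k: v * alpha
                                for k, v in self.electrode_currents.items()},
            iterations=self.iterations, residual=self.residual)


@dataclass
class LinearSystem:
    """Assembled stiffness matrix + element geometry cache."""

    mesh: TissueMesh
    K: sp.csr_matrix
    grads: np.ndarray        # (M, 4, 3) P1 basis gradients per tet
    volumes: np.ndarray      # (M,)
    _lu_cache: dict = field(default_factory=dict, repr=False)


def _p1_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Basis-function gradients and volumes for all tets (vectorized)."""
    p = nodes[tets]                       # (M, 4, 3)
    e = p[:, 1:] - p[:, :1]               # (M, 3, 3) edge matrix
    vol = np.linalg.det(e) / 6.0
    if np.any(vol <= 0):
        raise ValidationError(
            f"{int(np.sum(vol <= 0))} non-positive element volumes")
    einv = np.linalg.inv(e)               # rows of inv give gradient coords
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1:, :] = np.transpose(einv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


_TRI_MASS = (np.ones((3, 3)) + np.eye(3)) / 12.0


def assemble(mesh: TissueMesh,
             cond: ConductivityMap | None = None,
             membranes: MembraneSpec | None = None) -> LinearSystem:
    """Assemble the symmetric positive semi-definite stiffness matrix.

    Every region present in the mesh must be mapped in `cond`; every
    membrane surface in `membranes`.  Membrane coupling blocks use the
    triangle mass matrix scaled by sigma_m/d_s (units S/m^2).
    """
    cond = cond or ConductivityMap()
    membranes = membranes or MembraneSpec()
    n = mesh.nodes.shape[0]
    grads, vol = _p1_gradients(mesh.nodes, mesh.tets)

    sigma = np.empty(mesh.tets.shape[0])
    for rid, name in mesh.region_names.items():
        sigma[mesh.tet_regions == rid] = cond[name]

    # element stiffness: sigma * vol * G G^T  -> (M,4,4)
    ke = np.einsum("m,mik,mjk->mij", sigma * vol, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n))

    # membrane contact-impedance blocks
    extra_r, extra_c, extra_v = [], [], []
    for name, m in mesh.membranes.items():
        sig_m, d_s = membranes[name]
        g = sig_m / d_s
        areas = mesh.tri_areas(m.tris_side1)
        for tris_a, tris_b, sign in ((m.tris_side1, m.tris_side1, 1.0),
                                     (m.tris_side2, m.tris_side2, 1.0),
                                     (m.tris_side1, m.tris_side2, -1.0),
                                     (m.tris_side2, m.tris_side1, -1.0)):
            # block per triangle: sign * g * A * TRI_MASS
            w = (sign * g * areas)[:, None, None] * _TRI_MASS[None, :, :]
            extra_r.append(np.repeat(tris_a, 3, axis=1).ravel())
            extra_c.append(np.tile(tris_b, (1, 3)).ravel())
            extra_v.append(w.ravel())
    if extra_r:
        Km = sp.coo_matrix(
            (np.concatenate(extra_v),
             (np.concatenate(extra_r), np.concatenate(extra_c))), shape=(n, n))
        K = (K + Km)

    K = K.tocsr()
    K.sum_duplicates()
    return LinearSystem(mesh=mesh, K=K, grads=grads, volumes=vol)


def _dirichlet_nodes(mesh: TissueMesh, dirichlet: dict[str, float]):
    """(node index array, value array); later labels override earlier ones."""
    val = {}
    for label, v in dirichlet.items():
        for nid in mesh.surface_nodes(label):
            val[int(nid)] = float(v)
    idx = np.fromiter(val.keys(), dtype=np.int64)
    vals = np.fromiter(val.values(), dtype=float)
    order = np.argsort(idx)
    return idx[order], vals[order]


def solve_potential(system: LinearSystem,
                    dirichlet: dict[str, float],
                    method: str = "direct",
                    rtol: float = 1e-8) -> FieldSolution:
    """Solve with Dirichlet elimination; direct sparse LU or CG (+ Jacobi).

    The factorization is cached per Dirichlet node set, so repeated solves
    with different electrode voltages on the same patches are cheap.
    """
    if not dirichlet:
        raise SolverError("no Dirichlet surfaces: system is singular")
    mesh, K = system.mesh, system.K
    n = K.shape[0]
    d_idx, d_val = _dirichlet_nodes(mesh, dirichlet)
    if d_idx.size == 0:
        raise SolverError("Dirichlet surfaces contain no nodes")
    free = np.ones(n, dtype=bool)
    free[d_idx] = False
    f_idx = np.flatnonzero(free)

    vfull = np.zeros(n)
    vfull[d_idx] = d_val
    rhs = -K[f_idx][:, d_idx] @ d_val
    Kff_key = hash(d_idx.tobytes())

    if method == "direct":
        lu = system._lu_cache.get(Kff_key)
        if lu is None:
            Kff = K[f_idx][:, f_idx].tocsc()
            lu = spla.splu(Kff)
            system._lu_cache[Kff_key] = lu
        x = lu.solve(rhs)
        iters = 1
    elif method == "cg":
        Kff = K[f_idx][:, f_idx]
        dinv = 1.0 / Kff.diagonal()
        M = spla.LinearOperator(Kff.shape, matvec=lambda v: dinv * v)
        history = []
        x, info = spla.cg(Kff, rhs, rtol=rtol, atol=0.0, maxiter=20000, M=M,
                          callback=lambda xk: history.append(1))
        if info != 0:
            raise SolverError(f"CG did not converge (info={info})",
                              residual_history=history)
        iters = len(history)
    else:
        raise ValidationError(f"unknown solve method {method!r}")
    vfull[f_idx] = x

    resid = K @ vfull
    rel = float(np.linalg.norm(resid[f_idx]) /
                max(np.linalg.norm(K.diagonal() * vfull), 1e-300))

    E = -np.einsum("mi,mik->mk", vfull[mesh.tets], system.grads)

    currents = {}
    for label in mesh.surface_names.values():
        if label.startswith("electrode_"):
            nids = mesh.surface_nodes(label)
            currents[label] = float(np.sum(resid[nids]))
    return FieldSolution(potential=vfull, E=E, electrode_currents=currents,
                         iterations=iters, residual=rel)


def electric_field_magnitude(solution: FieldSolution) -> np.ndarray:
    """Per-element |E| in V/m (constant per P1 element)."""
    return np.linalg.norm(solution.E, axis=1)


def v_per_cm(emag_v_per_m: np.ndarray) -> np.ndarray:
    """Convert field magnitudes from V/m to V/cm."""
    return np.asarray(emag_v_per_m) / 100.0


def extract_resistance(mesh: TissueMesh,
                       cond: ConductivityMap | None = None,
                       membranes: MembraneSpec | None = None,
                       config=None,
                       test_voltage: float = 1.0,
                       system: LinearSystem | None = None,
                       method: str = "direct") -> tuple[float, FieldSolution]:
    """Tissue resistance between the anode and cathode banks.

    Applies +test/2 on anodes, -test/2 on cathodes (any split gives the same
    R by linearity), floating electrodes stay zero-flux; returns
    (R = test_voltage / total anode current, unit solution).
    """
    from .geometry import electrode_configuration
    if test_voltage <= 0:
        raise ValidationError("test voltage must be > 0")
    config = electrode_configuration(config or "tandem")
    if system is None:
        system = assemble(mesh, cond, membranes)
    dirichlet = {a: +test_voltage / 2.0 for a in config.anodes}
    dirichlet.update({c: -test_voltage / 2.0 for c in config.cathodes})
    sol = solve_potential(system, dirichlet, method=method)
    i_an = sum(sol.electrode_currents[a] for a in config.anodes)
    i_ca = sum(sol.electrode_currents[c] for c in config.cathodes)
    if abs(i_an + i_ca) > 1e-6 * max(abs(i_an), abs(i_ca)) + 1e-15:
        raise SolverError(
            f"anode/cathode current mismatch: {i_an:+.6e} vs {i_ca:+.6e} A")
    if i_an <= 0:
        raise SolverError("non-positive anode current; check configuration")
    return test_voltage / i_an, sol
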