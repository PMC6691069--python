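"""Finite-element solver: analytic slabs, membranes, conservation, convergence."""

import numpy as np
import pytest

from cfesim.geometry import build_slab_fixture
from cfesim.fem_poisson import (ConductivityMap, MembraneSpec, assemble,
                                solve_potential, extract_resistance,
                                electric_field_magnitude, v_per_cm,
                                _TRI_MASS)
from cfesim.errors import ValidationError, SolverError
from tests.conftest import SLAB_CONFIG

SIGMA_FLUID = 1.5          # S/m, body-fluid conductivity of the scalae
R_SLAB = 1e-3 / (SIGMA_FLUID * 1e-6)              # L/(sigma A) = 666.67 ohm
R_MEMBRANE = 90e-6 / (0.2904 * 1e-6)              # d_s/(sigma_m A) = 309.9 ohm


class TestAssembly:
    def test_stiffness_rows_sum_to_zero(self, slab):
        K = assemble(slab).K
        np.testing.assert_allclose(K @ np.ones(K.shape[0]), 0.0, atol=1e-12)

    def test_matrix_symmetric(self, slab_membrane):
        K = assemble(slab_membrane).K
        assert abs(K - K.T).max() < 1e-14

    def test_membrane_block_matches_hand_assembly(self, slab_membrane):
        """Dual route: membrane contribution vs an independent loop assembly."""
        import scipy.sparse as sp
        sig_m, d_s = 0.2904, 90e-6
        K_with = assemble(slab_membrane,
                          membranes=MembraneSpec({"basilar_membrane":
                                                  (sig_m, d_s)})).K
        # near-zero coupling isolates the volume part
        K_wo = assemble(slab_membrane,
                        membranes=MembraneSpec({"basilar_membrane":
                                                (1e-300, 1.0)})).K
        delta = (K_with - K_wo).tocoo()

        n = slab_membrane.nodes.shape[0]
        ref = sp.lil_matrix((n, n))
        m = slab_membrane.membranes["basilar_membrane"]
        g = sig_m / d_s
        pair = m.pair_map()
        for tri in m.tris_side1:
            p = slab_membrane.nodes[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            tri2 = [pair[int(i)] for i in tri]
            block = g * area * _TRI_MASS
            for a in range(3):
                for b in range(3):
                    ref[tri[a], tri[b]] += block[a, b]
                    ref[tri2[a], tri2[b]] += block[a, b]
                    ref[tri[a], tri2[b]] -= block[a, b]
                    ref[tri2[a], tri[b]] -= block[a, b]
        assert abs(delta.tocsr() - ref.tocsr()).max() < 1e-9 * g

    def test_unmapped_region_rejected(self, slab):
        with pytest.raises(ValidationError, match="scala_tympani"):
            assemble(slab, ConductivityMap({"soft_tissue": 1.0}))


class TestSlabAnalytics:
    def test_uniform_slab_resistance(self, slab):
        R, _ = extract_resistance(slab, config=SLAB_CONFIG)
        assert R == pytest.approx(R_SLAB, rel=1e-9)

    def test_uniform_field_and_current(self, slab):
        system = assemble(slab)
        sol = solve_potential(system, {"electrode_1": 1.0, "electrode_2": 0.0})
        em = electric_field_magnitude(sol)
        np.testing.assert_allclose(em, 1000.0, rtol=1e-9)   # 1 V / 1 mm
        np.testing.assert_allclose(v_per_cm(em), 10.0, rtol=1e-9)
        assert sol.electrode_currents["electrode_1"] == \
            pytest.approx(1.5e-3, rel=1e-9)                 # sigma A dV / L

    def test_membrane_adds_series_resistance(self, slab_membrane):
        R, _ = extract_resistance(slab_membrane, config=SLAB_CONFIG)
        assert R == pytest.approx(R_SLAB + R_MEMBRANE, rel=0.01)

    def test_dirichlet_scaling_linearity(self, slab):
        system = assemble(slab)
        s1 = solve_potential(system, {"electrode_1": 1.0, "electrode_2": 0.0})
        s3 = solve_potential(system, {"electrode_1": 3.0, "electrode_2": 0.0})
        np.testing.assert_allclose(s3.potential, 3.0 * s1.potential, atol=1e-12)
        np.testing.assert_allclose(s3.E, 3.0 * s1.E, atol=1e-9)

    def test_resistance_independent_of_dirichlet_split(self, slab):
        system = assemble(slab)
        a = solve_potential(system, {"electrode_1": 0.5, "electrode_2": -0.5})
        b = solve_potential(system, {"electrode_1": 1.0, "electrode_2": 0.0})
        ra = 1.0 / a.electrode_currents["electrode_1"]
        rb = 1.0 / b.electrode_currents["electrode_1"]
        assert ra == pytest.approx(rb, rel=1e-9)

    def test_discrete_maximum_principle(self, slab_membrane):
        system = assemble(slab_membrane)
        sol = solve_potential(system, {"electrode_1": 1.0, "electrode_2": -1.0})
        assert sol.potential.max() <= 1.0 + 1e-10
        assert sol.potential.min() >= -1.0 - 1e-10


class TestConservationAndSymmetry:
    def test_current_conservation(self, slab_membrane):
        _, sol = extract_resistance(slab_membrane, config=SLAB_CONFIG)
        i = sol.electrode_currents
        assert abs(i["electrode_1"] + i["electrode_2"]) <= \
            1e-6 * abs(i["electrode_1"])

    def test_reciprocity_role_swap_negates_potentials(self, slab_membrane):
        system = assemble(slab_membrane)
        fwd = solve_potential(system, {"electrode_1": 0.5, "electrode_2": -0.5})
        rev = solve_potential(system, {"electrode_1": -0.5, "electrode_2": 0.5})
        np.testing.assert_allclose(fwd.potential, -rev.potential, atol=1e-12)

    def test_cg_agrees_with_direct(self, slab_membrane):
        system = assemble(slab_membrane)
        d = {"electrode_1": 0.5, "electrode_2": -0.5}
        a = solve_potential(system, d, method="direct")
        b = solve_potential(system, d, method="cg", rtol=1e-10)
        np.testing.assert_allclose(b.potential, a.potential, atol=1e-7)

    def test_no_dirichlet_is_an_error(self, slab):
        system = assemble(slab)
        with pytest.raises(SolverError):
            solve_potential(system, {})


class TestMembraneLimits:
    def test_transparent_limit_recovers_membrane_free(self, slab_membrane):
        R, _ = extract_resistance(
            slab_membrane, membranes=MembraneSpec({"basilar_membrane":
                                                   (1e6, 1e-6)}),
            config=SLAB_CONFIG)
        assert R == pytest.approx(R_SLAB, rel=1e-6)

    def test_insulating_limit_decouples_halves(self, slab_membrane):
        R, sol = extract_resistance(
            slab_membrane, membranes=MembraneSpec({"basilar_membrane":
                                                   (1e-9, 1e-3)}),
            config=SLAB_CONFIG)
        assert R > 1e9
        # each half-column floats at its electrode potential
        z = slab_membrane.nodes[:, 2]
        lower = sol.potential[z < 0.5e-3 - 1e-9]
        np.testing.assert_allclose(lower, 0.5, atol=1e-3)


class TestRefinementConvergence:
    def test_patch_resistance_converges_monotonically(self):
        """Constriction problem (quarter-area electrodes): the P1 resistance
        increases toward the exact value under nested uniform refinement and
        the increments shrink."""
        rs = []
        for h in (0.25e-3, 0.125e-3, 0.0625e-3):
            mesh = build_slab_fixture(mesh_size=h, electrode_fraction=0.5)
            R, _ = extract_resistance(mesh, config=SLAB_CONFIG)
            rs.append(R)
        assert rs[0] < rs[1] < rs[2]
        assert (rs[2] - rs[1]) < (rs[1] - rs[0])


def test_dipole_field_decays_along_bisector():
    """Two small patches on one face of a bath: |E| decays with distance
    along the perpendicular bisector (far-field trend of a dipole)."""
    mesh = build_slab_fixture(dims=(4e-3, 4e-3, 4e-3), mesh_size=0.25e-3,
                              electrode_fraction=0.125)
    system = assemble(mesh)
    sol = solve_potential(system, {"electrode_1": 1.0, "electrode_2": -1.0})
    em = electric_field_magnitude(sol)
    cents = mesh.nodes[mesh.tets].mean(axis=1)
    # bisector: the line x = y = 2 mm, sampled away from the electrodes
    sel = (np.abs(cents[:, 0] - 2e-3) < 0.3e-3) & \
          (np.abs(cents[:, 1] - 2e-3) < 0.3e-3)
    z = cents[sel, 2]
    e = em[sel]
    order = np.argsort(z)
    z, e = z[order], e[order]
    # bin by z from the source patch toward the cube centre: monotone decay
    zb = np.linspace(0.25e-3, 2.0e-3, 6)
    means = [e[(z >= a) & (z < b)].mean() for a, b in zip(zb[:-1], zb[1:])]
    assert all(m0 > m1 for m0, m1 in zip(means[:-1], means[1:]))
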