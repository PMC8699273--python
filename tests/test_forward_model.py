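"""Frequency-domain diffusion FEM forward model."""

import numpy as np
import pytest
from scipy.special import kv

from dotiqa.forward_model import (FDSettings, MeasurementSet,
                                  OpticalProperties, _element_matrices,
                                  assemble_fem_system, boundary_measurements,
                                  diffusion_coefficient, read_measurements,
                                  solve_fluence, write_measurements)
from dotiqa.mesh import TriangularMesh
from dotiqa.phantoms import make_phantom, table1_cases


@pytest.mark.parametrize("mua,musp,expected", [
    (0.01, 1.0, 0.330033),
    (0.02, 2.0, 0.1650165),
    (0.03, 0.89, 0.3623188),
])
def test_diffusion_coefficient_values(mua, musp, expected):
    assert diffusion_coefficient(mua, musp) == pytest.approx(expected,
                                                             rel=1e-6)


@pytest.mark.parametrize("mua,musp", [(0.0, 1.0), (0.01, 0.0), (-0.01, 1.0)])
def test_diffusion_coefficient_rejects_nonpositive(mua, musp):
    with pytest.raises(ValueError):
        diffusion_coefficient(mua, musp)


def test_single_triangle_stiffness_matches_cotangent_formula():
    """P1 stiffness of one triangle: K_ij = (cot θ_k)/2 for off-diagonals."""
    nodes = np.array([[0.0, 0.0], [2.0, 0.0], [0.5, 1.5]])
    mesh = TriangularMesh(nodes=nodes, triangles=np.array([[0, 1, 2]]),
                          boundary_nodes=np.array([0, 1, 2]), radius=2.0)
    k_unit, m_unit, area = _element_matrices(mesh)
    k = k_unit[0]

    def cot(a, b, c):
        """cotangent of the angle at vertex a."""
        u, v = nodes[b] - nodes[a], nodes[c] - nodes[a]
        return (u @ v) / abs(u[0] * v[1] - u[1] * v[0])

    expected = np.empty((3, 3))
    cots = [cot(0, 1, 2), cot(1, 2, 0), cot(2, 0, 1)]
    for i in range(3):
        for j in range(3):
            if i != j:
                opp = 3 - i - j
                expected[i, j] = -0.5 * cots[opp]
    for i in range(3):
        expected[i, i] = -sum(expected[i, j] for j in range(3) if j != i)
    np.testing.assert_allclose(k, expected, atol=1e-12)
    # mass matrix integrates constants exactly: row sums = area/3
    np.testing.assert_allclose(m_unit[0].sum(axis=1), area[0] / 3,
                               atol=1e-12)


def test_zero_frequency_system_real_spd(small_mesh):
    props = OpticalProperties.homogeneous(small_mesh.n_nodes, 0.01, 1.0)
    settings = FDSettings(modulation_frequency=1e-9)   # effectively omega=0
    system = assemble_fem_system(small_mesh, props, settings)
    a = system.matrix.toarray()
    assert np.max(np.abs(a.imag)) < 1e-12
    np.testing.assert_allclose(a, a.T, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(a.real) > 0)


def test_system_sparsity_follows_edges(small_mesh, fd_settings):
    props = OpticalProperties.homogeneous(small_mesh.n_nodes, 0.01, 1.0)
    system = assemble_fem_system(small_mesh, props, fd_settings)
    coo = system.matrix.tocoo()
    edges = {tuple(e) for e in small_mesh.unique_edges()}
    for i, j in zip(coo.row, coo.col):
        if i != j:
            assert (min(i, j), max(i, j)) in edges


def test_property_length_mismatch_rejected(small_mesh, fd_settings):
    props = OpticalProperties.homogeneous(small_mesh.n_nodes - 1, 0.01, 1.0)
    with pytest.raises(ValueError):
        assemble_fem_system(small_mesh, props, fd_settings)


class TestFluence:
    def test_amplitude_positive_and_min_near_antipode(self, meshes,
                                                      homogeneous_forward):
        _, fields, data = homogeneous_forward
        assert all(np.all(np.abs(f) > 0) for f in fields)
        # for source 1 at 0°, dimmest detector is nearest 180°
        la = data.log_amplitude[:16]
        dimmest = np.argmin(la)
        det_angle = meshes.fine_layout.detector_angles[dimmest]
        assert min(abs(det_angle - 180.0), 360 - abs(det_angle - 180.0)) <= 22.5

    def test_linearity_of_superposition(self, homogeneous_forward, meshes):
        system, fields, _ = homogeneous_forward
        n = system.matrix.shape[0]
        rhs = np.zeros(n, dtype=complex)
        s1, s2 = meshes.fine_layout.source_nodes[:2]
        rhs[s1] = 1.0
        rhs[s2] = 1.0
        combined = system.solve(rhs)
        np.testing.assert_allclose(combined, fields[0] + fields[1],
                                   rtol=1e-10)

    def test_matches_modified_bessel_kernel(self, meshes, homogeneous_forward,
                                            fd_settings):
        """Interior amplitude tracks the infinite-medium K0(kr) kernel.

        RMS relative amplitude deviation over nodes at least 10 mm from
        both the source and the boundary stays below 15% after a single
        proportionality fit.
        """
        _, fields, _ = homogeneous_forward
        phi = fields[0]
        mesh = meshes.fine
        src = mesh.nodes[meshes.fine_layout.source_nodes[0]]
        r = np.hypot(*(mesh.nodes - src).T)
        r_boundary = mesh.radius - np.hypot(*mesh.nodes.T)
        sel = (r >= 10.0) & (r_boundary >= 10.0)
        d = diffusion_coefficient(0.01, 1.0)
        k = np.sqrt((0.01 + 1j * fd_settings.omega_over_c) / d)
        kernel = kv(0, k * r[sel])
        log_ratio = np.log(np.abs(phi[sel])) - np.log(np.abs(kernel))
        resid = log_ratio - log_ratio.mean()
        rms = float(np.sqrt(np.mean((np.exp(resid) - 1.0) ** 2)))
        assert rms < 0.15

    def test_reciprocity(self, meshes, homogeneous_forward):
        system, fields, _ = homogeneous_forward
        s = meshes.fine_layout.source_nodes[0]
        d = meshes.fine_layout.detector_nodes[5]
        y_sd = fields[0][d]
        y_ds = solve_fluence(system, d)[s]
        assert abs(y_sd - y_ds) / abs(y_sd) < 1e-8


class TestBoundaryMeasurements:
    def test_record_count_and_ordering(self, homogeneous_forward):
        _, _, data = homogeneous_forward
        assert len(data) == 256
        assert np.array_equal(data.source, np.repeat(np.arange(1, 17), 16))
        assert np.array_equal(data.detector, np.tile(np.arange(1, 17), 16))

    def test_phase_shift_peaks_near_antipode(self, meshes,
                                             homogeneous_forward):
        _, _, data = homogeneous_forward
        ph = data.phase[:16]
        deepest = np.argmax(np.abs(ph))
        # strongest lag at detectors facing away from source 1 (d4..d9 zone)
        assert 3 <= deepest <= 9

    def test_zero_frequency_phases_vanish(self):
        # small disc keeps the dynamic range resolvable on a coarse mesh
        from dotiqa.mesh import build_disc_mesh, place_optodes
        mesh = build_disc_mesh(8, 2, 15.0)
        layout = place_optodes(mesh, 16, 16, 0.0)
        props = OpticalProperties.homogeneous(mesh.n_nodes, 0.01, 1.0)
        settings = FDSettings(modulation_frequency=1e-9)
        system = assemble_fem_system(mesh, props, settings)
        fields = [solve_fluence(system, n) for n in layout.source_nodes]
        data = boundary_measurements(fields, layout)
        assert np.max(np.abs(data.phase)) < 1e-10

    def test_field_count_mismatch_rejected(self, small_layout):
        with pytest.raises(ValueError):
            boundary_measurements([np.ones(5, dtype=complex)], small_layout)


def test_heterogeneity_signature(meshes, homogeneous_forward, fd_settings):
    """The visible inclusion perturbs detectors facing it beyond the 1%
    noise floor, while the detector next to the source barely changes."""
    _, _, homog = homogeneous_forward
    spec = table1_cases("A1")[2]
    props = make_phantom(spec, meshes.fine)
    system = assemble_fem_system(meshes.fine, props, fd_settings)
    fields = [solve_fluence(system, n)
              for n in meshes.fine_layout.source_nodes]
    hetero = boundary_measurements(fields, meshes.fine_layout)
    delta = np.abs(hetero.log_amplitude[:16] - homog.log_amplitude[:16])
    angles = meshes.fine_layout.detector_angles
    assert delta.max() > 0.01
    facing = np.abs(((angles - 90.0) + 180) % 360 - 180) <= 90
    assert facing[np.argmax(delta)]
    assert delta[0] < delta.max() / 3       # detector adjacent to the source


def test_measurement_csv_roundtrip(tmp_path, homogeneous_forward):
    _, _, data = homogeneous_forward
    path = tmp_path / "meas.csv"
    write_measurements(data, path)
    back = read_measurements(path)
    np.testing.assert_array_equal(back.source, data.source)
    np.testing.assert_array_equal(back.detector, data.detector)
    np.testing.assert_allclose(back.log_amplitude, data.log_amplitude,
                               rtol=0, atol=0)
    np.testing.assert_allclose(back.phase, data.phase, rtol=0, atol=0)
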