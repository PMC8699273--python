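"""Frequency-domain diffusion-equation forward model on a triangular mesh.

The photon fluence Φ(r, ω) in a highly scattering medium driven by a source
amplitude-modulated at angular frequency ω obeys

    -∇·(D ∇Φ) + (μa + iω/c) Φ = S0,        D = 1 / (3 (μs' + μa)),

with the mixed (Robin) boundary condition -D ∇Φ·n̂ = αΦ modelling internal
reflection at the tissue surface.  A Galerkin piecewise-linear FEM turns
this into a sparse complex-symmetric system; a point load at a boundary
source node stands in for the modulated source fibre.  Boundary data are
the log amplitude and (unwrapped) phase of Φ at the detector nodes.

Units: lengths in mm, time in ns, so the speed of light in vacuum is
299.792458 mm/ns and ω/c ≈ 2.9e-3 mm⁻¹ at 100 MHz in tissue (n = 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

C_VACUUM_MM_PER_NS = 299.792458

__all__ = [
    "FDSettings",
    "OpticalProperties",
    "MeasurementSet",
    "FEMSystem",
    "diffusion_coefficient",
    "assemble_fem_system",
    "assemble_from_mua_D",
    "solve_fluence",
    "boundary_measurements",
    "write_measurements",
    "read_measurements",
]


def _default_robin_alpha(r_eff: float = 0.493) -> float:
    # internal-reflection approximation: alpha = (1 - R_eff) / (2 (1 + R_eff))
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


@dataclass
class FDSettings:
    """Frequency-domain acquisition settings.

    modulation_frequency : source modulation frequency in Hz (default 100 MHz)
    refractive_index     : tissue refractive index (default 1.4)
    robin_alpha          : Robin boundary coefficient α in (0, 1]
    literal_paper_sign   : use (μa - iω/c) instead of the standard (μa + iω/c)
    """

    modulation_frequency: float = 100e6
    refractive_index: float = 1.4
    robin_alpha: float = field(default_factory=_default_robin_alpha)
    literal_paper_sign: bool = False

    def __post_init__(self):
        if self.modulation_frequency <= 0:
            raise ValueError("modulation_frequency must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if not (0 < self.robin_alpha <= 1):
            raise ValueError("robin_alpha must be in (0, 1]")

    @property
    def speed_in_medium(self) -> float:
        """Speed of light in the medium, mm/ns."""
        return C_VACUUM_MM_PER_NS / self.refractive_index

    @property
    def omega_over_c(self) -> float:
        """ω/c in mm⁻¹ (ω in rad/ns)."""
        omega_rad_per_ns = 2.0 * np.pi * self.modulation_frequency * 1e-9
        return omega_rad_per_ns / self.speed_in_medium


@dataclass
class OpticalProperties:
    """Per-node absorption μa and reduced scattering μs' fields (mm⁻¹)."""

    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self):
        self.mua = np.atleast_1d(np.asarray(self.mua, dtype=float))
        self.musp = np.atleast_1d(np.asarray(self.musp, dtype=float))
        if self.mua.shape != self.musp.shape:
            raise ValueError("mua and musp must have the same length")
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("optical properties must be strictly positive")

    @property
    def diffusion(self) -> np.ndarray:
        return diffusion_coefficient(self.mua, self.musp)

    @classmethod
    def homogeneous(cls, n_nodes: int, mua: float, musp: float
                    ) -> "OpticalProperties":
        return cls(np.full(n_nodes, mua), np.full(n_nodes, musp))


def diffusion_coefficient(mua, musp):
    """Diffusion coefficient D = 1 / (3 (μs' + μa)), in mm."""
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("mua and musp must be strictly positive")
    return 1.0 / (3.0 * (musp + mua))


# ---------------------------------------------------------------------------
# FEM assembly

def _element_matrices(mesh):
    """Unit-coefficient P1 stiffness and mass matrices per element.

    Returns (K_unit, M_unit, areas): arrays of shape (F, 3, 3), (F, 3, 3), (F,).
    K is the gradient (stiffness) matrix for D = 1; M the mass matrix for a
    unit reaction coefficient.
    """
    tri = mesh.triangles
    p = mesh.nodes
    a, b, c = p[tri[:, 0]], p[tri[:, 1]], p[tri[:, 2]]
    # edge vectors opposite each vertex
    e0 = c - b
    e1 = a - c
    e2 = b - a
    area = 0.5 * (e2[:, 0] * (-e1[:, 1]) - e2[:, 1] * (-e1[:, 0]))
    if np.any(area <= 0):
        raise ValueError("degenerate or inverted triangle in mesh")
    edges = np.stack([e0, e1, e2], axis=1)            # (F, 3, 2)
    dots = np.einsum("fik,fjk->fij", edges, edges)    # (F, 3, 3)
    k_unit = dots / (4.0 * area)[:, None, None]
    m_pat = (np.ones((3, 3)) + np.eye(3)) / 12.0
    m_unit = area[:, None, None] * m_pat
    return k_unit, m_unit, area


def _boundary_edge_list(mesh):
    """Boundary edges as consecutive pairs of the CCW-ordered boundary nodes."""
    b = mesh.boundary_nodes
    return np.stack([b, np.roll(b, -1)], axis=1)


def _boundary_mass(mesh):
    """Robin boundary mass matrix for unit α (sparse, node-count square)."""
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for i, j in _boundary_edge_list(mesh):
        ell = float(np.hypot(*(mesh.nodes[j] - mesh.nodes[i])))
        local = ell / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
        for r, gr in enumerate((i, j)):
            for s, gs in enumerate((i, j)):
                rows.append(gr)
                cols.append(gs)
                vals.append(local[r, s])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


class FEMSystem:
    """Assembled sparse complex FEM system with a cached LU factorization."""

    def __init__(self, matrix: sp.csc_matrix, mesh):
        self.matrix = matrix
        self.mesh = mesh
        self._lu = None

    @property
    def lu(self):
        if self._lu is None:
            try:
                self._lu = splu(self.matrix)
            except RuntimeError as exc:
                raise RuntimeError(f"singular FEM system: {exc}") from exc
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.lu.solve(rhs)


def assemble_from_mua_D(mesh, mua: np.ndarray, D: np.ndarray,
                        settings: FDSettings) -> FEMSystem:
    """Assemble the FD diffusion FEM system from nodal μa and D directly.

    Element coefficients are the means of the three nodal values, which
    makes the parameter Jacobian of the assembled operator piecewise
    constant and cheap to evaluate (see :mod:`dotiqa.inverse_solver`).
    """
    mua = np.asarray(mua, dtype=float)
    D = np.asarray(D, dtype=float)
    if len(mua) != mesh.n_nodes or len(D) != mesh.n_nodes:
        raise ValueError("mua/D length must equal mesh node count")
    k_unit, m_unit, _ = _element_matrices(mesh)
    tri = mesh.triangles
    d_e = D[tri].mean(axis=1)
    sign = -1.0 if settings.literal_paper_sign else 1.0
    react_e = mua[tri].mean(axis=1) + sign * 1j * settings.omega_over_c

    local = (d_e[:, None, None] * k_unit
             + react_e[:, None, None] * m_unit)     # (F, 3, 3) complex
    rows = np.repeat(tri, 3, axis=1).reshape(-1)
    cols = np.tile(tri, (1, 3)).reshape(-1)
    n = mesh.n_nodes
    a = sp.coo_matrix((local.reshape(-1), (rows, cols)), shape=(n, n)).tocsc()
    a = a + settings.robin_alpha * _boundary_mass(mesh).astype(complex)
    return FEMSystem(a.tocsc(), mesh)


def assemble_fem_system(mesh, props: OpticalProperties,
                        settings: FDSettings) -> FEMSystem:
    """Assemble the sparse complex-symmetric FD diffusion system."""
    if len(props.mua) != mesh.n_nodes:
        raise ValueError(
            f"optical property length {len(props.mua)} != node count "
            f"{mesh.n_nodes}")
    return assemble_from_mua_D(mesh, props.mua, props.diffusion, settings)


def solve_fluence(system: FEMSystem, source_node: int,
                  source_strength: float = 1.0) -> np.ndarray:
    """Solve for the complex fluence with a point load at ``source_node``."""
    n = system.matrix.shape[0]
    if not (0 <= source_node < n):
        raise ValueError(f"source node {source_node} out of range")
    rhs = np.zeros(n, dtype=complex)
    rhs[source_node] = source_strength
    phi = system.solve(rhs)
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("non-finite fluence: singular or ill-posed system")
    return phi


# ---------------------------------------------------------------------------
# Boundary data

@dataclass
class MeasurementSet:
    """256-record (for the 16×16 layout) boundary data set.

    Stored as parallel arrays in deterministic source-major, CCW
    detector-order; ``log_amplitude`` is ln|Φ| and ``phase`` is the phase of
    Φ in radians, unwrapped along each source's detector sequence.
    """

    source: np.ndarray
    detector: np.ndarray
    log_amplitude: np.ndarray
    phase: np.ndarray
    noise_applied: bool = False
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.source)

    def stacked_data(self) -> np.ndarray:
        """Log-amplitude rows then phase rows, the inverse-solver data vector."""
        return np.concatenate([self.log_amplitude, self.phase])

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(self.source.copy(), self.detector.copy(),
                              self.log_amplitude.copy(), self.phase.copy(),
                              self.noise_applied, self.seed)


def boundary_measurements(fields: list[np.ndarray], layout) -> MeasurementSet:
    """Extract log amplitude / unwrapped phase at the detectors, per source.

    ``fields`` holds one complex nodal field per source, in source order.
    """
    if len(fields) != layout.n_sources:
        raise ValueError("need exactly one fluence field per source")
    src_idx, det_idx, logamp, phase = [], [], [], []
    for s, phi in enumerate(fields):
        vals = phi[layout.detector_nodes]
        amp = np.abs(vals)
        if np.any(amp == 0):
            raise ValueError(f"zero amplitude at a detector for source {s + 1}")
        ph = np.unwrap(np.angle(vals))
        src_idx.append(np.full(layout.n_detectors, s + 1))
        det_idx.append(np.arange(1, layout.n_detectors + 1))
        logamp.append(np.log(amp))
        phase.append(ph)
    return MeasurementSet(
        source=np.concatenate(src_idx),
        detector=np.concatenate(det_idx),
        log_amplitude=np.concatenate(logamp),
        phase=np.concatenate(phase),
    )


def write_measurements(data: MeasurementSet, path) -> None:
    df = pd.DataFrame({
        "source": data.source,
        "detector": data.detector,
        "log_amplitude": data.log_amplitude,
        "phase": data.phase,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path) -> MeasurementSet:
    df = pd.read_csv(path, float_precision="round_trip")
    return MeasurementSet(
        source=df["source"].to_numpy(int),
        detector=df["detector"].to_numpy(int),
        log_amplitude=df["log_amplitude"].to_numpy(float),
        phase=df["phase"].to_numpy(float),
    )
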