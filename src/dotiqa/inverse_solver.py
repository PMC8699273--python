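"""Tikhonov-damped Gauss–Newton reconstruction of μa and D on a coarse mesh.

The inverse problem minimizes the data misfit χ² = ‖ΔΦ‖² between measured
and model boundary data (stacked log amplitude and phase), updating the
nodal absorption μa and diffusion D through the damped normal equations

    (JᵀJ + λ²I) Δχ = Jᵀ ΔΦ,

where J is the adjoint-method Jacobian of the boundary data with respect to
the nodal parameters.  The reduced scattering image follows from the
reconstructed D by inverting D = 1/(3(μs' + μa)).

Measured data are generated on a finer mesh than the one inverted here, so
the discretizations differ (inverse-crime avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation
from scipy.linalg import cho_factor, cho_solve

from .forward_model import (FDSettings, MeasurementSet, OpticalProperties,
                            _element_matrices, assemble_from_mua_D,
                            boundary_measurements)

__all__ = [
    "JacobianMatrix",
    "ReconstructionResult",
    "GaussNewtonConfig",
    "compute_jacobian",
    "tikhonov_step",
    "reconstruct",
    "musp_from_D",
    "circular_profile",
]


@dataclass
class JacobianMatrix:
    """Stacked data Jacobian.

    ``matrix`` has 2·n_measurements rows (log-amplitude rows first, then
    phase rows) and 2·n_nodes columns (∂/∂μa block first, then ∂/∂D block).
    ``column_scale`` records any column normalization applied (None = raw).
    """

    matrix: np.ndarray
    n_nodes: int
    column_scale: np.ndarray | None = None

    @property
    def mua_block(self) -> np.ndarray:
        return self.matrix[:, :self.n_nodes]

    @property
    def d_block(self) -> np.ndarray:
        return self.matrix[:, self.n_nodes:]


def _forward_fields(mesh, mua, D, settings, layout):
    """Factorize once; solve source loads and detector adjoint loads."""
    system = assemble_from_mua_D(mesh, mua, D, settings)
    n = mesh.n_nodes
    rhs = np.zeros((n, layout.n_sources + layout.n_detectors), dtype=complex)
    rhs[layout.source_nodes, np.arange(layout.n_sources)] = 1.0
    rhs[layout.detector_nodes,
        layout.n_sources + np.arange(layout.n_detectors)] = 1.0
    sol = system.solve(rhs)
    phi_src = sol[:, :layout.n_sources].T          # (n_src, n)
    psi_det = sol[:, layout.n_sources:].T          # (n_det, n)
    return system, phi_src, psi_det


def compute_jacobian(coarse_mesh, props: OpticalProperties,
                     settings: FDSettings, layout) -> JacobianMatrix:
    """Adjoint-method Jacobian of (log amplitude, phase) w.r.t. nodal (μa, D).

    Uses the symmetry of the FEM operator: for measurement y = ψ_dᵀ A⁻¹ e_s,
    ∂y/∂p = -ψ_dᵀ (∂A/∂p) φ_s with ψ_d = A⁻¹ e_d.  Element coefficients are
    nodal means, so ∂A/∂μa_n (resp. ∂A/∂D_n) gathers one third of the unit
    mass (resp. stiffness) matrix of each element touching node n.
    """
    mua = props.mua
    D = props.diffusion
    _, phi_src, psi_det = _forward_fields(coarse_mesh, mua, D, settings,
                                          layout)
    return _jacobian_from_fields(coarse_mesh, phi_src, psi_det, layout)


def _jacobian_from_fields(mesh, phi_src, psi_det, layout) -> JacobianMatrix:
    k_unit, m_unit, _ = _element_matrices(mesh)
    tri = mesh.triangles                            # (F, 3)
    n_src, n_det = layout.n_sources, layout.n_detectors
    n_pairs = n_src * n_det
    n = mesh.n_nodes

    phi_e = phi_src[:, tri]                         # (n_src, F, 3)
    psi_e = psi_det[:, tri]                         # (n_det, F, 3)
    # per (source, element): Mᵉφ and Kᵉφ contracted later with ψ per detector
    m_phi = np.einsum("eij,sej->sei", m_unit, phi_e)
    k_phi = np.einsum("eij,sej->sei", k_unit, phi_e)
    # pair-major scalars per element: S[s, d, e]
    s_mass = np.einsum("dei,sei->sde", psi_e, m_phi)
    s_stiff = np.einsum("dei,sei->sde", psi_e, k_phi)
    s_mass = s_mass.reshape(n_pairs, -1)
    s_stiff = s_stiff.reshape(n_pairs, -1)

    # scatter one third of each element scalar to its three nodes
    scatter = np.zeros((len(tri), n))
    np.add.at(scatter, (np.repeat(np.arange(len(tri)), 3), tri.reshape(-1)),
              1.0 / 3.0)
    jc_mua = -(s_mass @ scatter)                    # (n_pairs, n) complex
    jc_d = -(s_stiff @ scatter)

    y = phi_src[:, layout.detector_nodes].reshape(n_pairs, 1)  # complex data
    jc_mua = jc_mua / y
    jc_d = jc_d / y
    j = np.concatenate([
        np.concatenate([jc_mua.real, jc_d.real], axis=1),   # log-amp rows
        np.concatenate([jc_mua.imag, jc_d.imag], axis=1),   # phase rows
    ])
    if not np.all(np.isfinite(j)):
        raise RuntimeError("non-finite Jacobian entries")
    return JacobianMatrix(matrix=j, n_nodes=n)


def tikhonov_step(jacobian: JacobianMatrix, residual: np.ndarray,
                  lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve (JᵀJ + λ²I)Δχ = Jᵀr exactly; return (Δμa, ΔD).

    For the wide matrices arising here (rows ≪ columns) the equivalent dual
    form Δχ = Jᵀ(JJᵀ + λ²I)⁻¹r is solved; the identity is exact for λ > 0.
    """
    if lam <= 0:
        raise ValueError("regularization parameter must be positive")
    residual = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual contains non-finite entries")
    j = jacobian.matrix
    m, p = j.shape
    if len(residual) != m:
        raise ValueError(f"residual length {len(residual)} != {m} rows")
    if m <= p:
        gram = j @ j.T
        gram[np.diag_indices_from(gram)] += lam ** 2
        delta = j.T @ cho_solve(cho_factor(gram), residual)
    else:
        gram = j.T @ j
        gram[np.diag_indices_from(gram)] += lam ** 2
        delta = cho_solve(cho_factor(gram), j.T @ residual)
    n = jacobian.n_nodes
    return delta[:n], delta[n:]


def musp_from_D(D, mua):
    """Invert D = 1/(3(μs' + μa)) for the reduced scattering coefficient."""
    D = np.asarray(D, dtype=float)
    mua = np.asarray(mua, dtype=float)
    if np.any(D <= 0):
        raise ValueError("D must be positive")
    if np.any(mua < 0):
        raise ValueError("mua must be non-negative")
    musp = 1.0 / (3.0 * D) - mua
    if np.any(musp <= 0):
        raise ValueError("unphysical reconstruction: 1/(3D) <= mua")
    return musp


@dataclass
class GaussNewtonConfig:
    """Iteration controls for :func:`reconstruct`.

    λ² is set to ``lambda0 * max(diag(JᵀJ))`` of the column-scaled Jacobian
    and ``lambda0`` halves each iteration down to ``lambda_floor``
    (Levenberg–Marquardt-style damping).  Fields are clipped to
    ``clip_range`` times the background after every accepted update.
    """

    max_iterations: int = 20
    chi2_rel_tol: float = 0.02
    lambda0: float = 0.01
    lambda_floor: float = 1e-4
    clip_range: tuple[float, float] = (0.2, 5.0)
    max_step_halvings: int = 6
    # discrepancy principle: stop once chi2 reaches the expected noise
    # level instead of fitting measurement noise (0 disables)
    chi2_floor: float = 0.0


@dataclass
class ReconstructionResult:
    mua: np.ndarray
    musp: np.ndarray
    chi2_trace: list[float]
    iterations: int
    converged: bool
    message: str = ""


def _model_data(mesh, mua, D, settings, layout):
    system = assemble_from_mua_D(mesh, mua, D, settings)
    n = mesh.n_nodes
    rhs = np.zeros((n, layout.n_sources + layout.n_detectors), dtype=complex)
    rhs[layout.source_nodes, np.arange(layout.n_sources)] = 1.0
    rhs[layout.detector_nodes,
        layout.n_sources + np.arange(layout.n_detectors)] = 1.0
    sol = system.solve(rhs)
    phi_src = sol[:, :layout.n_sources].T
    psi_det = sol[:, layout.n_sources:].T
    fields = [phi_src[s] for s in range(layout.n_sources)]
    return boundary_measurements(fields, layout), phi_src, psi_det


def reconstruct(measured: MeasurementSet, coarse_mesh,
                initial: OpticalProperties, settings: FDSettings, layout,
                config: GaussNewtonConfig | None = None
                ) -> ReconstructionResult:
    """Gauss–Newton loop with Tikhonov damping and step halving.

    ``layout`` must be an optode layout on the coarse mesh (snapped to its
    boundary nodes).  The χ² trace over accepted iterates is non-increasing;
    if χ² cannot be decreased even after step halving the loop stops and the
    result is flagged unconverged with the trace attached.
    """
    cfg = config or GaussNewtonConfig()
    data = measured.stacked_data()
    mua = initial.mua.copy()
    D = initial.diffusion.copy()
    mua_bg = float(np.median(mua))
    d_bg = float(np.median(D))
    lo, hi = cfg.clip_range

    model, phi_src, psi_det = _model_data(coarse_mesh, mua, D, settings,
                                          layout)
    residual = data - model.stacked_data()
    chi2 = float(residual @ residual)
    trace = [chi2]
    lam0 = cfg.lambda0
    converged = False
    message = ""
    if chi2 <= cfg.chi2_floor:
        converged = True
        message = "initial chi2 already at the noise floor"

    it = 0
    for it in range(1, cfg.max_iterations + 1):
        if converged:
            break
        jac = _jacobian_from_fields(coarse_mesh, phi_src, psi_det, layout)
        # relative-parameter column scaling: balances the μa (~0.01) and
        # D (~0.3) blocks in the shared damping term
        scale = np.concatenate([np.full(jac.n_nodes, mua_bg),
                                np.full(jac.n_nodes, d_bg)])
        jac_s = JacobianMatrix(jac.matrix * scale[None, :], jac.n_nodes,
                               column_scale=scale)
        lam = np.sqrt(lam0 * float(
            np.max(np.einsum("ij,ij->j", jac_s.matrix, jac_s.matrix))))
        d_mua_s, d_d_s = tikhonov_step(jac_s, residual, lam)
        d_mua = d_mua_s * mua_bg
        d_d = d_d_s * d_bg

        step = 1.0
        accepted = False
        for _ in range(cfg.max_step_halvings + 1):
            mua_try = np.clip(mua + step * d_mua, lo * mua_bg, hi * mua_bg)
            d_try = np.clip(D + step * d_d, lo * d_bg, hi * d_bg)
            model, phi_try, psi_try = _model_data(coarse_mesh, mua_try, d_try,
                                                  settings, layout)
            res_try = data - model.stacked_data()
            chi2_try = float(res_try @ res_try)
            if chi2_try <= chi2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            if it > 1:
                # stalled at the residual floor set by the forward/inverse
                # discretization mismatch: no step direction helps anymore
                converged = True
                message = (f"stalled at iteration {it}: step halving could "
                           f"not reduce chi2 below {chi2:.6g}")
            else:
                message = (f"divergence: chi2 could not be decreased at "
                           f"iteration {it} (chi2={chi2:.6g})")
            break
        mua, D = mua_try, d_try
        phi_src, psi_det = phi_try, psi_try
        residual = res_try
        improvement = (chi2 - chi2_try) / chi2 if chi2 > 0 else 0.0
        chi2 = chi2_try
        trace.append(chi2)
        lam0 = max(lam0 * 0.5, cfg.lambda_floor)
        if chi2 <= cfg.chi2_floor:
            converged = True
            message = f"discrepancy stop: chi2 {chi2:.4g} at the noise floor"
            break
        if improvement < cfg.chi2_rel_tol:
            converged = True
            break
    else:
        converged = True
        message = "iteration cap reached"

    return ReconstructionResult(
        mua=mua, musp=musp_from_D(D, mua), chi2_trace=trace,
        iterations=it, converged=converged, message=message)


def circular_profile(field: np.ndarray, mesh, profile_radius: float,
                     n_samples: int = 360) -> tuple[np.ndarray, np.ndarray]:
    """Sample a nodal field on a circle about the domain centre.

    Returns (angles_deg, values): linear barycentric interpolation at
    ``n_samples`` equally spaced angles.  With ``profile_radius`` equal to
    the inclusion centre distance the profile passes through the inclusion.
    """
    if profile_radius >= mesh.radius:
        raise ValueError("profile radius must be inside the domain")
    ang = np.linspace(0.0, 360.0, n_samples, endpoint=False)
    rad = np.radians(ang)
    x = profile_radius * np.cos(rad)
    y = profile_radius * np.sin(rad)
    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    vals = LinearTriInterpolator(tri, np.asarray(field, dtype=float))(x, y)
    return ang, np.asarray(vals.filled(np.nan))
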