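"""Simulation phantoms, case grids, and the two study noise conditions.

The study geometry is a homogeneous disc (background μa = 0.01 mm⁻¹,
μs' = 1 mm⁻¹) with one circular inclusion centred 20 mm from the domain
centre at 90° (counterclockwise from east).  Case family A holds the
homogeneous / invisible / visible demonstration cases; case families B1
and B2 are the 7-radius × 3-contrast assessment grids:

* B1 — radii 2.5…10 mm, inclusion μa = 0.02 mm⁻¹, μs' ∈ {2, 2.5, 3} mm⁻¹
* B2 — radii 2.5…10 mm, inclusion μs' = 0.89 mm⁻¹, μa ∈ {0.02, 0.025, 0.03} mm⁻¹

Both grids are run under two noise conditions: 1% amplitude noise, and 10%
amplitude + phase + optical-property noise, giving 2 × 2 × 21 = 84
reconstructions and 168 optical-property images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .forward_model import MeasurementSet, OpticalProperties

__all__ = [
    "PhantomSpec",
    "NoiseModel",
    "BACKGROUND_MUA",
    "BACKGROUND_MUSP",
    "B_RADII_MM",
    "make_phantom",
    "case_grid",
    "table1_cases",
    "add_measurement_noise",
    "perturb_initial_guess",
    "derive_seed",
]

BACKGROUND_MUA = 0.01    # mm^-1
BACKGROUND_MUSP = 1.0    # mm^-1
B_RADII_MM = (2.5, 3.75, 5.0, 6.25, 7.5, 8.75, 10.0)
B1_INCLUSION_MUA = 0.02
B1_MUSP_LEVELS = (2.0, 2.5, 3.0)
B2_INCLUSION_MUSP = 0.89
B2_MUA_LEVELS = (0.02, 0.025, 0.03)
INCLUSION_ANGLE_DEG = 90.0
INCLUSION_CENTRE_DISTANCE_MM = 20.0
DOMAIN_RADIUS_MM = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    """One simulated tissue phantom: background plus at most one inclusion.

    ``inclusion_radius = 0`` denotes the homogeneous phantom (inclusion
    optical values ignored).
    """

    case_label: str
    background_mua: float = BACKGROUND_MUA
    background_musp: float = BACKGROUND_MUSP
    inclusion_radius: float = 0.0
    inclusion_mua: float = 0.0
    inclusion_musp: float = 0.0
    inclusion_angle: float = INCLUSION_ANGLE_DEG
    inclusion_centre_distance: float = INCLUSION_CENTRE_DISTANCE_MM
    domain_radius: float = DOMAIN_RADIUS_MM

    def __post_init__(self):
        if self.inclusion_radius > 0:
            if (self.inclusion_centre_distance + self.inclusion_radius
                    >= self.domain_radius):
                raise ValueError("inclusion extends outside the domain")
            if self.inclusion_mua <= 0 or self.inclusion_musp <= 0:
                raise ValueError("inclusion optical values must be positive")

    @property
    def inclusion_centre(self) -> np.ndarray:
        a = np.radians(self.inclusion_angle)
        return self.inclusion_centre_distance * np.array([np.cos(a),
                                                          np.sin(a)])

    @property
    def contrast(self) -> float:
        """Largest relative optical deviation of the inclusion from background."""
        if self.inclusion_radius == 0:
            return 0.0
        return max(abs(self.inclusion_mua / self.background_mua - 1.0),
                   abs(self.inclusion_musp / self.background_musp - 1.0))


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement / initial-guess perturbation model.

    amplitude_fraction : multiplicative amplitude noise, |Φ|·(1+ε)
    phase_fraction     : additive phase noise with σ proportional to |phase|
    optical_fraction   : relative perturbation of the homogeneous initial guess
    """

    amplitude_fraction: float = 0.0
    phase_fraction: float = 0.0
    optical_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.amplitude_fraction, self.phase_fraction,
               self.optical_fraction) < 0:
            raise ValueError("noise fractions must be non-negative")

    @classmethod
    def one_percent(cls, seed: int = 0) -> "NoiseModel":
        """1% amplitude noise (study condition '1%')."""
        return cls(amplitude_fraction=0.01, seed=seed)

    @classmethod
    def ten_percent(cls, seed: int = 0) -> "NoiseModel":
        """10% amplitude + phase + optical-property noise."""
        return cls(amplitude_fraction=0.10, phase_fraction=0.10,
                   optical_fraction=0.10, seed=seed)


def make_phantom(spec: PhantomSpec, mesh) -> OpticalProperties:
    """Node-wise optical property assignment for a phantom spec."""
    mua = np.full(mesh.n_nodes, spec.background_mua)
    musp = np.full(mesh.n_nodes, spec.background_musp)
    if spec.inclusion_radius > 0:
        d = np.hypot(*(mesh.nodes - spec.inclusion_centre).T)
        inside = d <= spec.inclusion_radius
        mua[inside] = spec.inclusion_mua
        musp[inside] = spec.inclusion_musp
    return OpticalProperties(mua, musp)


def table1_cases(case_id: str) -> list[PhantomSpec]:
    """Homogeneous / invisible / visible demonstration cases (A1, A2)."""
    if case_id == "A1":
        rows = [(0.0, 0.0, 0.0), (2.5, 0.02, 2.0), (10.0, 0.02, 3.0)]
    elif case_id == "A2":
        rows = [(0.0, 0.0, 0.0), (2.5, 0.02, 0.89), (10.0, 0.03, 0.89)]
    else:
        raise ValueError(f"unknown Table-1 case id {case_id!r}")
    return [PhantomSpec(case_label=case_id, inclusion_radius=r,
                        inclusion_mua=mua, inclusion_musp=musp)
            for r, mua, musp in rows]


def case_grid(case_id: str, noise_id: str | None = None) -> list[PhantomSpec]:
    """Full factorial 7-radius × 3-contrast assessment grid (21 specs)."""
    if case_id == "B1":
        levels = [(B1_INCLUSION_MUA, musp) for musp in B1_MUSP_LEVELS]
    elif case_id == "B2":
        levels = [(mua, B2_INCLUSION_MUSP) for mua in B2_MUA_LEVELS]
    else:
        raise ValueError(f"unknown case id {case_id!r}; expected B1 or B2")
    if noise_id is not None and noise_id not in ("1pct", "10pct"):
        raise ValueError(f"unknown noise id {noise_id!r}")
    return [PhantomSpec(case_label=case_id, inclusion_radius=r,
                        inclusion_mua=mua, inclusion_musp=musp)
            for mua, musp in levels for r in B_RADII_MM]


def add_measurement_noise(data: MeasurementSet,
                          model: NoiseModel) -> MeasurementSet:
    """Apply multiplicative amplitude and proportional phase noise.

    Amplitude: |Φ| ← |Φ|(1+ε), ε ~ N(0, f_amp²), i.e. log-amplitude shifts
    by log(1+ε).  Phase: additive N(0, (f_phase·|phase|)²) per record.
    Deterministic under the model's seed; fractions of 0 leave the data
    bit-for-bit unchanged.
    """
    out = data.copy()
    if model.amplitude_fraction == 0 and model.phase_fraction == 0:
        return out
    rng = np.random.default_rng(model.seed)
    if model.amplitude_fraction > 0:
        eps = rng.normal(0.0, model.amplitude_fraction, size=len(data))
        eps = np.clip(eps, -0.99, None)   # keep amplitudes positive
        out.log_amplitude = out.log_amplitude + np.log1p(eps)
    if model.phase_fraction > 0:
        sigma = model.phase_fraction * np.abs(out.phase)
        out.phase = out.phase + rng.normal(0.0, 1.0, size=len(data)) * sigma
    out.noise_applied = True
    out.seed = model.seed
    return out


def perturb_initial_guess(props: OpticalProperties, fraction: float,
                          seed: int) -> OpticalProperties:
    """Perturb a homogeneous initial guess by one relative draw per property."""
    if fraction == 0:
        return OpticalProperties(props.mua.copy(), props.musp.copy())
    rng = np.random.default_rng(seed)
    f_mua, f_musp = 1.0 + rng.normal(0.0, fraction, size=2)
    f_mua = max(f_mua, 0.1)
    f_musp = max(f_musp, 0.1)
    return OpticalProperties(props.mua * f_mua, props.musp * f_musp)


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic per-task seed below 2^31 from a master seed and keys."""
    tag = zlib.crc32("|".join(str(k) for k in keys).encode())
    return int(np.random.SeedSequence([master_seed, tag])
               .generate_state(1)[0] % (2 ** 31))
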