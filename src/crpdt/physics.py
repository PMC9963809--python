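"""Cerenkov emission, positron slowing-down and annihilation primitives.

The charged-particle model is deliberately minimal: deterministic
(continuous-slowing-down) energy loss from a tabulated stopping power,
straight-line transport, and closed-form Frank-Tamm photon yields.  A
positron of kinetic energy ``T`` in a medium of refractive index ``n``
radiates while ``beta * n > 1``; the number of optical photons per unit
path on a wavelength band ``[lmin, lmax]`` is

    dN/dx = 2 * pi * alpha * (1 - 1/(beta^2 n^2)) * (1/lmin - 1/lmax)

with spectral density proportional to ``lambda^-2`` and emission on a
cone of half-angle ``theta_c = arccos(1/(beta n))`` about the particle
direction.  When the positron has spent its kinetic energy it
annihilates into two back-to-back 511 keV gamma quanta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ELECTRON_REST_KEV, FINE_STRUCTURE

__all__ = [
    "StoppingPower",
    "Medium",
    "ChargedParticleState",
    "CerenkovBand",
    "Photon",
    "WATER_STOPPING_TABLE",
    "water",
    "tissue",
    "beta_from_kinetic",
    "cerenkov_threshold",
    "cerenkov_angle",
    "frank_tamm_yield",
    "sample_cerenkov_wavelengths",
    "sample_cerenkov_photons",
    "step_positron",
    "annihilate",
]

# Piecewise-linear approximation of the collisional stopping power of
# electrons/positrons in liquid water (MeV/cm at unit density); columns
# are kinetic energy (keV) and stopping power.  Approximate tabulation,
# swappable via config -- the observables used downstream are
# fold-changes, insensitive to few-percent stopping-power errors.
WATER_STOPPING_TABLE = np.array(
    [
        (10.0, 22.56),
        (20.0, 12.00),
        (30.0, 8.49),
        (50.0, 6.60),
        (100.0, 4.12),
        (200.0, 2.79),
        (300.0, 2.36),
        (400.0, 2.15),
        (500.0, 2.03),
        (600.0, 1.96),
        (700.0, 1.92),
        (800.0, 1.89),
        (1000.0, 1.85),
        (1500.0, 1.82),
        (2000.0, 1.82),
    ]
)


@dataclass(frozen=True)
class StoppingPower:
    """Piecewise-linear stopping power model, MeV/cm vs kinetic energy (keV)."""

    energies_kev: np.ndarray
    values_mev_per_cm: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        s = np.asarray(self.values_mev_per_cm, dtype=float)
        if e.ndim != 1 or e.shape != s.shape:
            raise ValueError("stopping power table must be two matched 1-d columns")
        if not np.all(np.diff(e) > 0):
            raise ValueError("stopping power energies must be strictly increasing")
        if not np.all(s > 0):
            raise ValueError("stopping power must be positive everywhere")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "values_mev_per_cm", s)

    @classmethod
    def from_table(cls, table: np.ndarray) -> "StoppingPower":
        table = np.asarray(table, dtype=float)
        return cls(table[:, 0], table[:, 1])

    def __call__(self, kinetic_energy_kev):
        """Interpolated stopping power (MeV/cm); clamped outside the table."""
        return np.interp(
            kinetic_energy_kev, self.energies_kev, self.values_mev_per_cm
        )


def _default_stopping() -> StoppingPower:
    return StoppingPower.from_table(WATER_STOPPING_TABLE)


@dataclass(frozen=True)
class Medium:
    """Optical/transport medium with a constant refractive index.

    No dispersion is modelled: the only wavelength dependence retained in
    the Cerenkov model is the lambda^-2 spectral law itself.
    """

    name: str
    refractive_index: float
    density_g_cm3: float = 1.0
    stopping_power: StoppingPower = field(default_factory=_default_stopping)

    def __post_init__(self) -> None:
        if self.refractive_index <= 1.0:
            raise ValueError(
                f"medium {self.name!r}: refractive_index must exceed 1 for a "
                "condensed medium"
            )
        if self.density_g_cm3 <= 0:
            raise ValueError(f"medium {self.name!r}: density must be positive")


def water() -> Medium:
    """Liquid water, n = 1.33."""
    return Medium("water", 1.33)


def tissue() -> Medium:
    """Generic soft biological tissue, n = 1.35."""
    return Medium("tissue", 1.35)


@dataclass
class ChargedParticleState:
    """Positron (or electron) phase-space point; energies keV, positions µm."""

    kinetic_energy_kev: float
    position_um: np.ndarray
    direction: np.ndarray
    particle: str = "positron"

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.kinetic_energy_kev < 0:
            raise ValueError("kinetic energy must be non-negative")
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (|1 - ||d||| <= 1e-9)")


@dataclass(frozen=True)
class CerenkovBand:
    """Wavelength band on which Cerenkov photons are generated, nm."""

    lambda_min_nm: float = 250.0
    lambda_max_nm: float = 800.0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_min_nm < self.lambda_max_nm):
            raise ValueError("band requires 0 < lambda_min < lambda_max")


@dataclass
class Photon:
    """Tracked quantum: optical (wavelength set) or gamma (energy set)."""

    position_um: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    origin: str = "cerenkov"
    wavelength_nm: float | None = None
    energy_kev: float | None = None

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)


def beta_from_kinetic(kinetic_energy_kev, rest_energy_kev: float = ELECTRON_REST_KEV):
    """v/c of a particle of given kinetic and rest energy (relativistic)."""
    gamma = 1.0 + np.asarray(kinetic_energy_kev, dtype=float) / rest_energy_kev
    return np.sqrt(1.0 - 1.0 / gamma**2)


def cerenkov_threshold(medium: Medium, rest_energy_kev: float = ELECTRON_REST_KEV) -> float:
    """Kinetic-energy threshold for Cerenkov emission in ``medium`` (keV).

    Closed form ``T_th = m c^2 (1/sqrt(1 - n^-2) - 1)``: the kinetic energy
    at which the particle speed equals the phase velocity of light, c/n.
    Strictly decreasing in the refractive index; diverges as n -> 1+.
    """
    n = medium.refractive_index
    if n <= 1.0:
        raise ValueError("no Cerenkov emission possible: refractive index <= 1")
    return rest_energy_kev * (1.0 / np.sqrt(1.0 - n**-2) - 1.0)


def cerenkov_angle(beta: float, medium: Medium) -> float:
    """Cone half-angle arccos(1/(beta n)), radians; requires beta*n > 1."""
    bn = beta * medium.refractive_index
    if bn <= 1.0:
        raise ValueError("below Cerenkov threshold (beta * n <= 1)")
    return float(np.arccos(1.0 / bn))


def frank_tamm_yield(beta, medium: Medium, band: CerenkovBand):
    """Cerenkov photons emitted per nm of path on ``band`` (count/nm).

    Clamped to zero below threshold (beta * n <= 1).  Accepts scalar or
    array ``beta``.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValueError("beta must lie strictly in (0, 1)")
    n = medium.refractive_index
    factor = 1.0 - 1.0 / (beta**2 * n**2)
    factor = np.clip(factor, 0.0, None)
    per_nm = (
        2.0
        * np.pi
        * FINE_STRUCTURE
        * factor
        * (1.0 / band.lambda_min_nm - 1.0 / band.lambda_max_nm)
    )
    return per_nm if per_nm.ndim else float(per_nm)


def sample_cerenkov_wavelengths(n: int, band: CerenkovBand, rng: np.random.Generator):
    """Draw ``n`` wavelengths (nm) from the lambda^-2 Cerenkov density on ``band``.

    Inverse CDF: with u ~ U(0,1),
    ``lambda = 1 / (1/lmin - u (1/lmin - 1/lmax))``.
    """
    u = rng.random(n)
    inv = 1.0 / band.lambda_min_nm - u * (
        1.0 / band.lambda_min_nm - 1.0 / band.lambda_max_nm
    )
    return 1.0 / inv


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` and each other."""
    a = np.asarray(axis, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def directions_on_cone(
    axis: np.ndarray, cos_theta: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` unit vectors at fixed polar angle about ``axis``, uniform azimuth."""
    e1, e2 = _orthonormal_frame(axis)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta**2))
    return (
        cos_theta * np.asarray(axis)[None, :]
        + sin_theta * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` unit vectors uniform on the sphere."""
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack(
        (sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t)
    )


def sample_cerenkov_photons(
    state: ChargedParticleState,
    step_length_um: float,
    medium: Medium,
    band: CerenkovBand,
    rng: np.random.Generator,
) -> list[Photon]:
    """Cerenkov photons emitted over one straight step of the particle.

    The count is Poisson with mean ``step * dN/dx``; wavelengths follow the
    lambda^-2 density on ``band``; directions lie on the Cerenkov cone
    (cos(theta) = 1/(beta n)) about the particle direction with uniform
    azimuth.  Below threshold the list is empty.
    """
    beta = float(beta_from_kinetic(state.kinetic_energy_kev))
    if beta * medium.refractive_index <= 1.0:
        return []
    mean = step_length_um * 1e3 * frank_tamm_yield(beta, medium, band)
    count = int(rng.poisson(mean))
    if count == 0:
        return []
    wavelengths = sample_cerenkov_wavelengths(count, band, rng)
    cos_theta = 1.0 / (beta * medium.refractive_index)
    dirs = directions_on_cone(state.direction, cos_theta, count, rng)
    # emission points uniform along the step
    s = rng.uniform(0.0, step_length_um, count)
    positions = state.position_um[None, :] + s[:, None] * state.direction[None, :]
    return [
        Photon(
            position_um=positions[i],
            direction=dirs[i],
            weight=1.0,
            origin="cerenkov",
            wavelength_nm=float(wavelengths[i]),
        )
        for i in range(count)
    ]


def step_positron(
    state: ChargedParticleState, medium: Medium, step_length_um: float
) -> ChargedParticleState:
    """Advance the particle one straight step with deterministic energy loss.

    Energy decreases by ``stopping_power(T) * step`` and floors at zero; the
    direction never changes (no multiple scattering at these path lengths).
    """
    if step_length_um < 0:
        raise ValueError("step length must be non-negative")
    # stopping power is MeV/cm; 1 cm = 1e4 µm; convert to keV/µm
    loss_kev = (
        float(medium.stopping_power(state.kinetic_energy_kev)) * 1e3 / 1e4
    ) * step_length_um
    new_energy = max(0.0, state.kinetic_energy_kev - loss_kev)
    return replace(
        state,
        kinetic_energy_kev=new_energy,
        position_um=state.position_um + step_length_um * state.direction,
    )


def annihilate(position_um, rng: np.random.Generator) -> tuple[Photon, Photon]:
    """Positron annihilation at rest: two back-to-back 511 keV gamma quanta.

    The pair axis is isotropic; the two momenta sum to zero exactly.
    """
    axis = isotropic_directions(1, rng)[0]
    pos = np.asarray(position_um, dtype=float)
    make = lambda d: Photon(
        position_um=pos.copy(),
        direction=d,
        weight=1.0,
        origin="annihilation",
        energy_kev=ELECTRON_REST_KEV,
    )
    return make(axis), make(-axis)
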