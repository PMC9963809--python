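"""Spectra, fluorophores, scintillators, and radiative coupling primitives.

A :class:`Spectrum` is a non-negative intensity (emission) or
per-encounter absorption probability (absorption) on a strictly
increasing wavelength grid.  The packaged Tb/Gd/P1/SOSG spectra are
closed-form Gaussian mixtures that reproduce the qualitative features of
the measured curves: the four Tb emission peaks (490/545/585/622 nm,
dominant 545 nm, the 5D4 -> 7F5 line), the single deep-UV Gd line near
311 nm, the porphyrin Soret band (~412 nm) with weak Q bands
(500-650 nm), and porphyrin fluorescence at 652 nm.

Energy transfer from the scintillator to the photosensitizer is modelled
as radiative reabsorption: a photon emitted inside the nanoparticle
cluster is absorbed with probability proportional to the photosensitizer
absorption spectrum times a geometric ``transfer_efficiency``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import OPTICAL_BAND_NM, GRID_STEP_NM
from .physics import Photon, isotropic_directions

__all__ = [
    "Spectrum",
    "Fluorophore",
    "ScintillatorSpec",
    "default_grid",
    "gaussian_mixture",
    "tb_emission_spectrum",
    "gd_emission_spectrum",
    "tb_uv_absorption_spectrum",
    "gd_uv_absorption_spectrum",
    "p1_absorption_spectrum",
    "p1_emission_spectrum",
    "sosg_excitation_spectrum",
    "sosg_emission_spectrum",
    "tb_scintillator",
    "gd_scintillator",
    "p1_fluorophore",
    "sample_emission",
    "scintillate",
    "lanthanide_uv_fluorescence",
    "ps_absorb",
    "ps_emit",
    "overlap_integral",
]


@dataclass
class Spectrum:
    """Wavelength-gridded curve; ``kind`` is ``"emission"`` or ``"absorption"``."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or w.shape != v.shape:
            raise ValueError("wavelengths and values must be matched 1-d arrays")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.kind not in ("emission", "absorption"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "absorption" and np.any(v > 1.0):
            raise ValueError("absorption probabilities must lie in [0, 1]")
        self.wavelengths_nm = w
        self.values = v

    def __call__(self, wavelength_nm):
        """Linear interpolation; zero outside the grid."""
        return np.interp(
            wavelength_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0
        )

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def normalized(self) -> "Spectrum":
        """Unit-area copy (emission spectra only)."""
        total = self.integral
        if total <= 0:
            raise ValueError("degenerate emission spectrum: zero integral")
        return Spectrum(self.wavelengths_nm, self.values / total, self.kind)

    def mode_nm(self) -> float:
        """Wavelength of the global maximum."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])


@dataclass
class Fluorophore:
    """Absorber/emitter (the photosensitizer P1 or the SOSG probe)."""

    name: str
    absorption: Spectrum
    emission: Spectrum
    quantum_yield: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")


@dataclass
class ScintillatorSpec:
    """Lanthanide scintillator: emission, UV absorption band, light yield."""

    element: str
    emission: Spectrum
    uv_absorption: Spectrum
    photons_per_mev: float = 1e4

    def __post_init__(self) -> None:
        if self.element not in ("Tb", "Gd"):
            raise ValueError("scintillator element must be 'Tb' or 'Gd'")
        if self.photons_per_mev <= 0:
            raise ValueError("scintillation yield must be positive")


def default_grid() -> np.ndarray:
    lo, hi = OPTICAL_BAND_NM
    return np.arange(lo, hi + GRID_STEP_NM / 2, GRID_STEP_NM)


def gaussian_mixture(
    grid: np.ndarray,
    centers_nm,
    heights,
    sigmas_nm,
) -> np.ndarray:
    """Sum of Gaussians evaluated on ``grid`` (peak heights, not areas)."""
    g = np.zeros_like(grid, dtype=float)
    for c, h, s in zip(centers_nm, heights, sigmas_nm):
        g += h * np.exp(-0.5 * ((grid - c) / s) ** 2)
    return g


# ---------------------------------------------------------------------------
# Packaged fixture spectra (closed-form, deterministic, config-swappable)
# ---------------------------------------------------------------------------

_TB_PEAKS = ((490.0, 0.55, 6.0), (545.0, 1.0, 6.0), (585.0, 0.35, 6.0), (622.0, 0.25, 6.0))
_GD_PEAK = ((311.0, 1.0, 6.0),)
_P1_SORET = (412.0, 1.0, 12.0)
_P1_Q_BANDS = ((512.0, 0.06, 8.0), (546.0, 0.05, 8.0), (590.0, 0.04, 8.0), (646.0, 0.05, 8.0))
_P1_EMISSION = ((652.0, 1.0, 10.0),)


def _mixture_spectrum(peaks, kind: str, grid: np.ndarray | None = None) -> Spectrum:
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    centers, heights, sigmas = zip(*peaks)
    return Spectrum(grid, gaussian_mixture(grid, centers, heights, sigmas), kind)


def tb_emission_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Tb(III) scintillation: four peaks, dominant 545 nm (5D4 -> 7F5)."""
    return _mixture_spectrum(_TB_PEAKS, "emission", grid)


def gd_emission_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Gd(III) emission: single deep-UV line near 311 nm."""
    return _mixture_spectrum(_GD_PEAK, "emission", grid)


def _uv_edge(grid: np.ndarray, edge_nm: float, plateau: float, width_nm: float = 5.0):
    """Smooth logistic absorption edge: ``plateau`` below ``edge_nm``, 0 above."""
    return plateau / (1.0 + np.exp((grid - edge_nm) / width_nm))


def tb_uv_absorption_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Tb UV absorption band: photons below ~400 nm can excite the 5D states."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(grid, _uv_edge(grid, 395.0, 0.8), "absorption")


def gd_uv_absorption_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Gd UV absorption band, confined below its ~311 nm emission line."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(grid, _uv_edge(grid, 300.0, 0.8), "absorption")


def p1_absorption_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Porphyrin P1 absorption: Soret band ~412 nm plus four weak Q bands."""
    peaks = (_P1_SORET,) + _P1_Q_BANDS
    spec = _mixture_spectrum(peaks, "emission", grid)  # build then clip kind
    return Spectrum(spec.wavelengths_nm, np.clip(spec.values, 0.0, 1.0), "absorption")


def p1_emission_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """Porphyrin P1 fluorescence, single band at 652 nm."""
    return _mixture_spectrum(_P1_EMISSION, "emission", grid)


def sosg_excitation_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """SOSG excitation band (operated at 473 nm)."""
    return _mixture_spectrum(((473.0, 1.0, 15.0),), "emission", grid)


def sosg_emission_spectrum(grid: np.ndarray | None = None) -> Spectrum:
    """SOSG emission band (read out at 525 nm)."""
    return _mixture_spectrum(((525.0, 1.0, 15.0),), "emission", grid)


def tb_scintillator(photons_per_mev: float = 1e4) -> ScintillatorSpec:
    return ScintillatorSpec(
        "Tb", tb_emission_spectrum(), tb_uv_absorption_spectrum(), photons_per_mev
    )


def gd_scintillator(photons_per_mev: float = 1e4) -> ScintillatorSpec:
    return ScintillatorSpec(
        "Gd", gd_emission_spectrum(), gd_uv_absorption_spectrum(), photons_per_mev
    )


def p1_fluorophore(singlet_oxygen_yield: float = 0.5) -> Fluorophore:
    """The photosensitizer P1.

    ``quantum_yield`` here stores the singlet-oxygen quantum yield
    Phi_Delta used by :func:`ps_emit` (default 0.5; affects absolute, not
    relative, singlet-oxygen counts).
    """
    return Fluorophore(
        "P1", p1_absorption_spectrum(), p1_emission_spectrum(), singlet_oxygen_yield
    )


# ---------------------------------------------------------------------------
# Sampling and coupling operations
# ---------------------------------------------------------------------------


def sample_emission(spec: Spectrum, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` wavelengths distributed as the emission spectrum.

    Inverse-CDF sampling of the trapezoid-integrated spectrum with linear
    interpolation inside bins.
    """
    if spec.kind != "emission":
        raise ValueError("sample_emission requires an emission-kind spectrum")
    w, v = spec.wavelengths_nm, spec.values
    bin_mass = 0.5 * (v[1:] + v[:-1]) * np.diff(w)
    total = bin_mass.sum()
    if total <= 0:
        raise ValueError("degenerate emission spectrum: all-zero values")
    cdf = np.concatenate(([0.0], np.cumsum(bin_mass))) / total
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right") - 1
    idx = np.clip(idx, 0, len(bin_mass) - 1)
    frac = (u - cdf[idx]) / np.maximum(cdf[idx + 1] - cdf[idx], 1e-300)
    return w[idx] + frac * (w[idx + 1] - w[idx])


def scintillate(
    deposited_energy_kev: float,
    spec: ScintillatorSpec,
    rng: np.random.Generator,
    position_um=(0.0, 0.0, 0.0),
) -> list[Photon]:
    """Convert deposited ionizing energy into scintillation photons.

    Photon count is Poisson with mean ``photons_per_MeV * E/1000``;
    wavelengths follow the scintillator emission spectrum; directions are
    isotropic.
    """
    if deposited_energy_kev < 0:
        raise ValueError("deposited energy must be non-negative")
    mean = spec.photons_per_mev * deposited_energy_kev / 1e3
    count = int(rng.poisson(mean)) if mean > 0 else 0
    if count == 0:
        return []
    wavelengths = sample_emission(spec.emission, count, rng)
    dirs = isotropic_directions(count, rng)
    pos = np.asarray(position_um, dtype=float)
    return [
        Photon(
            position_um=pos.copy(),
            direction=dirs[i],
            weight=1.0,
            origin="scintillation",
            wavelength_nm=float(wavelengths[i]),
        )
        for i in range(count)
    ]


def lanthanide_uv_fluorescence(
    photon: Photon, spec: ScintillatorSpec, rng: np.random.Generator
) -> tuple[bool, Photon]:
    """UV photon absorption by the lanthanide with re-emission.

    The photon is absorbed with probability ``uv_absorption(lambda)``; if
    absorbed, one photon is re-emitted from the scintillator emission
    spectrum (same sampler as scintillation), tagged
    ``"lanthanide_fluorescence"``.  Otherwise the photon passes through
    unchanged.
    """
    if photon.wavelength_nm is None:
        raise ValueError("lanthanide_uv_fluorescence requires an optical photon")
    p_abs = float(spec.uv_absorption(photon.wavelength_nm))
    if rng.random() >= p_abs:
        return False, photon
    wavelength = float(sample_emission(spec.emission, 1, rng)[0])
    direction = isotropic_directions(1, rng)[0]
    return True, Photon(
        position_um=photon.position_um.copy(),
        direction=direction,
        weight=photon.weight,
        origin="lanthanide_fluorescence",
        wavelength_nm=wavelength,
    )


def ps_absorb(
    photon: Photon,
    ps: Fluorophore,
    transfer_efficiency: float,
    rng: np.random.Generator,
) -> bool:
    """Single-encounter photosensitizer absorption decision.

    Probability = ``absorption(lambda) * transfer_efficiency`` where the
    transfer efficiency is the geometric coupling factor for photons born
    on the same nanoparticle (pass 1.0 for far-field photons).
    """
    if not 0.0 <= transfer_efficiency <= 1.0:
        raise ValueError("transfer_efficiency must lie in [0, 1]")
    if photon.wavelength_nm is None:
        raise ValueError("ps_absorb requires an optical photon")
    p = float(ps.absorption(photon.wavelength_nm)) * transfer_efficiency
    return bool(rng.random() < p)


def ps_emit(
    ps: Fluorophore, rng: np.random.Generator, position_um=(0.0, 0.0, 0.0)
) -> tuple[Photon, bool]:
    """De-excitation of the photosensitizer after an absorbed excitation.

    Emits one fluorescence photon from the emission spectrum and
    independently flags a singlet-oxygen generation event with probability
    Phi_Delta (stored as ``ps.quantum_yield``).
    """
    wavelength = float(sample_emission(ps.emission, 1, rng)[0])
    direction = isotropic_directions(1, rng)[0]
    photon = Photon(
        position_um=np.asarray(position_um, dtype=float),
        direction=direction,
        weight=1.0,
        origin="ps_fluorescence",
        wavelength_nm=wavelength,
    )
    singlet_oxygen = bool(rng.random() < ps.quantum_yield)
    return photon, singlet_oxygen


def overlap_integral(emission: Spectrum, absorption: Spectrum) -> float:
    """Spectral overlap: integral of unit-area emission times absorption.

    Both curves are resampled onto the union grid over the intersection of
    their supports; disjoint supports give 0.
    """
    lo = max(emission.wavelengths_nm[0], absorption.wavelengths_nm[0])
    hi = min(emission.wavelengths_nm[-1], absorption.wavelengths_nm[-1])
    grid = np.union1d(emission.wavelengths_nm, absorption.wavelengths_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        return 0.0
    em = emission(grid)
    total = emission.integral
    if total <= 0:
        raise ValueError("degenerate emission spectrum: zero integral")
    return float(np.trapezoid(em / total * absorption(grid), grid))
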