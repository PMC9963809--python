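"""Physical constants used across the package.

Values are CODATA/standard nuclear data; kinetic energies are in keV,
wavelengths in nm, lengths in µm unless noted otherwise.
"""

#: Fine-structure constant (dimensionless).
FINE_STRUCTURE = 1.0 / 137.035999

#: Electron/positron rest energy, keV.
ELECTRON_REST_KEV = 511.0

#: Ga-68 physical half-life, minutes (standard nuclear data).
GA68_HALF_LIFE_MIN = 67.71

#: Mean Ga-68 positron kinetic energy, keV.
GA68_MEAN_POSITRON_KEV = 844.0

#: Optical band of interest: Cerenkov spectra are recorded on 250-800 nm.
OPTICAL_BAND_NM = (250.0, 800.0)

#: Default wavelength grid spacing for packaged spectra, nm.
GRID_STEP_NM = 1.0
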