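"""Synthetic-data generators for every pipeline input.

These generators define the study conditions the analyses are tested
under: a decay-driven SOSG series sampled every 5 min over 20 min with
1% multiplicative noise, Poisson colony counts with n = 12 replicates
and a survival effect confined to the Tb-P1 arm at >= 1 MBq, and the
closed-form Gaussian-mixture spectra fixtures.  Everything is
seeded-deterministic; the spectra need no seed at all.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import spectra as sp
from .clonostats import CloneCountTable
from .constants import GA68_HALF_LIFE_MIN
from .kinetics import KineticsSeries

__all__ = [
    "QUENCH_FACTORS",
    "DEFAULT_ARMS",
    "gen_sosg_series",
    "gen_clone_counts",
    "gen_spectra_fixtures",
]

#: Amplitude suppression by singlet-oxygen quenchers ("almost inhibited");
#: generator defaults of this package, not measured values.
QUENCH_FACTORS = {None: 0.0, "none": 0.0, "NaN3": 0.95, "BSA": 0.90}

#: Default clonogenic design: 5 nanoparticle arms x 5 activities, with a
#: survival deficit only for the scintillator+photosensitizer arm at >= 1 MBq.
DEFAULT_ARMS: list[tuple[str, float, float]] = [
    (cond, act, frac)
    for cond in ("none", "Tb", "Gd", "Tb-P1", "Gd-P1")
    for act, frac in (
        (0.0, 1.0),
        (0.1, 1.0),
        (0.5, 1.0),
        (1.0, 0.5 if cond == "Tb-P1" else 1.0),
        (3.0, 0.3 if cond == "Tb-P1" else 1.0),
    )
]


def gen_sosg_series(
    slope_per_min: float = np.log(2.0) / GA68_HALF_LIFE_MIN,
    amplitude: float = 100.0,
    duration_min: float = 20.0,
    step_min: float = 5.0,
    noise_cv: float = 0.01,
    quencher: str | None = None,
    seed: int = 0,
) -> KineticsSeries:
    """Simulate an accumulating SOSG fluorescence series under decay drive.

    Per-interval signal increments decay exponentially at ``slope_per_min``
    (evaluated at interval midpoints, so a log-slope fit of the increments
    recovers the slope exactly at zero noise), scaled by ``amplitude`` and
    by ``1 - quench_factor``, with multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``.
    """
    if slope_per_min <= 0:
        raise ValueError("slope must be positive (decaying production)")
    if quencher not in QUENCH_FACTORS:
        raise ValueError(f"unknown quencher {quencher!r}")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + step_min / 2, step_min)
    mids = 0.5 * (times[1:] + times[:-1])
    increments = amplitude * (1.0 - QUENCH_FACTORS[quencher]) * np.exp(
        -slope_per_min * mids
    )
    if noise_cv > 0:
        increments = increments * (1.0 + noise_cv * rng.standard_normal(mids.size))
    increments = np.clip(increments, 0.0, None)
    signal = np.concatenate(([0.0], np.cumsum(increments)))
    return KineticsSeries(times_min=times, signal=signal, quencher=quencher)


def gen_clone_counts(
    arms: list[tuple[str, float, float]] | None = None,
    n_reps: int = 12,
    baseline_mean: float = 150.0,
    seed: int = 0,
) -> CloneCountTable:
    """Poisson colony counts for a grid of treatment arms.

    Each arm is (condition, activity_MBq, surviving_fraction); counts are
    Poisson with mean ``baseline_mean * fraction``.  The default baseline
    of 150 colonies per well corresponds to a 30% plating efficiency of
    500 seeded cells.
    """
    arms = DEFAULT_ARMS if arms is None else arms
    for cond, act, frac in arms:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"surviving fraction out of [0,1] for arm {cond}@{act}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, act, frac in arms:
        counts = rng.poisson(baseline_mean * frac, size=n_reps)
        for rep, c in enumerate(counts):
            rows.append((cond, act, rep, int(c)))
    df = pd.DataFrame(rows, columns=["condition", "activity_MBq", "replicate", "clone_count"])
    return CloneCountTable(data=df)


#: fixture name -> builder; the files gen_spectra_fixtures writes.
FIXTURE_BUILDERS = {
    "tb_emission": sp.tb_emission_spectrum,
    "gd_emission": sp.gd_emission_spectrum,
    "tb_uv_absorption": sp.tb_uv_absorption_spectrum,
    "gd_uv_absorption": sp.gd_uv_absorption_spectrum,
    "p1_absorption": sp.p1_absorption_spectrum,
    "p1_emission": sp.p1_emission_spectrum,
    "sosg_excitation": sp.sosg_excitation_spectrum,
    "sosg_emission": sp.sosg_emission_spectrum,
}


def gen_spectra_fixtures(out_dir) -> list[Path]:
    """Write every packaged spectrum fixture as CSV; byte-stable, no RNG."""
    from .io import write_spectrum_csv  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, builder in FIXTURE_BUILDERS.items():
        path = out_dir / f"{name}.csv"
        write_spectrum_csv(builder(), path)
        paths.append(path)
    return paths
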