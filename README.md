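# crpdt — Cerenkov-induced photodynamic therapy, at desk scale

Photodynamic therapy needs light; deep tumours have none. One proposed
workaround is to let a positron-emitting radionuclide such as ⁶⁸Ga act
as an internal, unsealed light source: Cerenkov photons emitted along
the positron track — and scintillation light produced when the 511 keV
annihilation γ-rays or the UV part of the Cerenkov spectrum excite a
lanthanide nanoscintillator (Tb) — can activate a porphyrin
photosensitizer (P1), which generates cytotoxic singlet oxygen
(¹O₂, type II photoreaction).

`crpdt` is a small scientific Python package for exploring that cascade
quantitatively. It provides:

* **physics** — closed-form Cerenkov primitives: the threshold
  T_th = m(1/√(1−n⁻²) − 1), the Frank–Tamm photon yield
  dN/dx = 2πα(1 − 1/(β²n²))(1/λ₁ − 1/λ₂) with its λ⁻² spectral density,
  cone-angle emission sampling, deterministic positron slowing-down, and
  annihilation into back-to-back 511 keV γ quanta;
* **spectra** — wavelength-gridded emission/absorption curves, packaged
  Tb/Gd/P1/SOSG fixtures, inverse-CDF emission samplers, scintillation,
  UV re-emission, photosensitizer coupling and overlap integrals;
* **engine** — a seeded, weighted (non-analogue) Monte Carlo of five
  scenario arms (water only, PS only, Tb+PS, Tb only, Gd+PS) in a
  cell/cluster/nanoparticle geometry, with per-origin wavelength tallies
  and exact statistical-weight conservation;
* **analysis** — band intensities, fold changes with Monte Carlo σ,
  spectral power-law fits, and the split of photosensitizer excitations
  across the three activation pathways;
* **kinetics** — ⁶⁸Ga decay (T½ = 67.71 min), singlet-oxygen production
  rates, log-slope fitting of SOSG time series and slope comparison
  against the decay constant;
* **clonostats** — Kruskal–Wallis and Dunn's post hoc rank tests
  implemented from the formulas (tie-corrected), plus surviving-fraction
  summaries of clonogenic assays;
* **synthetic** — seeded generators for every input: decay-driven SOSG
  series, Poisson colony-count tables, and byte-stable spectra fixtures.

The model, its calibrated parameters, and its limitations are described
in [docs/methods.md](docs/methods.md).

## Worked example

Run the five-arm simulation comparison at a reduced size (~30 s):

```bash
python examples/scenario_comparison.py
```

```
water_only  ran in 2.5 s
ps_only     ran in 0.7 s
tb_ps       ran in 0.7 s
tb_only     ran in 0.7 s
gd_ps       ran in 0.6 s

Cerenkov spectral exponent (water only): -2.002 +- 0.002
tb_ps/ps_only ps_fluor: 2.10 +- 0.09
gd_ps/ps_only ps_fluor: 1.02 +- 0.05
tb_only/tb_ps peak_545: 3.69 +- 0.05

Tb+PS excitation pathways:
  direct_cerenkov              48.15%
  uv_lanthanide                12.59%
  annihilation_scintillation   39.25%
```

Reading these numbers: the raw Cerenkov spectrum falls off as λ⁻²
(exponent −2); adding the Tb nanoscintillator to a PS-bearing
nanoparticle roughly **doubles** photosensitizer fluorescence, while
substituting Gd (whose deep-UV emission cannot excite P1) changes
nothing — the null control; and the 545 nm Tb scintillation peak drops
by a factor of ~3.7 when P1 is present, the signature of Tb→P1 energy
transfer. The pathway split shows all three activation routes
contributing.

The other examples are one capability each: `cerenkov_physics.py`
(thresholds: 264 keV in water, 250 keV in tissue), `sosg_kinetics.py`
(the fitted SOSG log-slope magnitude ≈ 0.0103 min⁻¹ tracks the ⁶⁸Ga
decay constant ln2/67.71 = 0.010237 min⁻¹; the slope pair
(0.0119, 0.0103) differs by 15%), `clonogenic_stats.py` (only the
Tb-P1 arm at ≥ 1 MBq loses colonies, flagged by Kruskal–Wallis + Dunn),
and `spectral_overlap.py` (why Tb couples to P1 and Gd does not).

A thin CLI wraps the same library:

```bash
crpdt simulate --scenario tb_ps --primaries 100000 --seed 1 --out runs/tb_ps
crpdt analyze --runs runs/tb_ps --runs runs/ps_only --out summary.json
crpdt kin simulate --seed 1 --out series.csv && crpdt kin fit --input series.csv
crpdt synth clones --seed 1 --out data/ && crpdt clono --input data/clone_counts.csv \
    --reference "none @ 0 MBq" --out clono.json
```

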