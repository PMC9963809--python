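# Methods

`crpdt` models, at desk scale, how an unsealed positron emitter (Ga-68)
can drive photodynamic therapy: Cerenkov light and annihilation gammas
produced along the positron track activate a porphyrin photosensitizer
(P1), either directly or via a lanthanide nanoscintillator (Tb), and the
resulting singlet oxygen kills clonogenic cells.  The package contains
three largely independent analysis layers — a weighted Monte Carlo of
the photon cascade, a decay-kinetics fitting module, and nonparametric
clonogenic statistics — plus the synthetic-data generators that define
the conditions every test runs under.

## Cerenkov and positron physics

A particle of rest energy m (511 keV for positrons/electrons) radiates
in a medium of refractive index n when beta·n > 1; the kinetic-energy
threshold is

    T_th = m (1/sqrt(1 - n^-2) - 1),

i.e. 264 keV in water (n = 1.33) and 250 keV in soft tissue (n = 1.35).
Photon production per unit path on a band [λ1, λ2] follows the
Frank–Tamm integral

    dN/dx = 2πα (1 - 1/(β²n²)) (1/λ1 - 1/λ2),

with spectral density ∝ λ⁻² and emission on a cone of half-angle
arccos(1/βn).  Positron slowing-down is deterministic
(continuous-slowing-down approximation) from a piecewise-linear
approximation of the collisional stopping power of water (~2 MeV/cm near
1 MeV; the table is config-swappable).  Transport is straight-line: no
multiple scattering, Bremsstrahlung, or photon scattering is modelled,
because every observable used downstream is either a wavelength
distribution or a fold change, and the µm-scale optical paths make
angular diffusion irrelevant at the precision targeted here.  At rest
the positron annihilates into two back-to-back 511 keV gammas with an
isotropic axis.

## Scene and source

The default scene: a 10 mm water world, a
5 µm-radius cell, a single 0.5 µm-radius cluster at the cell centre
holding 6000 nanoparticles (5.5 nm radius, 18 lanthanide nuclei and one
P1 each), and a 3 µm source sphere just outside the cell emitting
844 keV positrons (the mean Ga-68 beta+ energy) toward the cell only.
One central cluster is the default; cluster count and placement are
configurable.
Five arms are provided: `water_only`, `ps_only`, `tb_ps`, `tb_only`
(the scintillation baseline), and `gd_ps` (the null control).

## Spectra fixtures

The measured lanthanide and porphyrin spectra are not publicly
deposited, so the package ships closed-form Gaussian-mixture stand-ins
(all config-swappable CSVs, regenerated bit-identically by
`synthetic.gen_spectra_fixtures`):

* Tb emission: peaks 490/545/585/622 nm, heights 0.55/1.0/0.35/0.25,
  σ = 6 nm (four peaks, dominant 545 nm — the 5D4→7F5 line);
* Gd emission: single line at 311 nm, σ = 6 nm;
* Tb UV absorption: 0.8 plateau with a logistic edge at 395 nm
  (UV Cerenkov photons below ~400 nm can excite Tb); Gd likewise with
  its edge at 300 nm, below its own emission line;
* P1 absorption: Soret Gaussian at 412 nm (height 1, σ = 12 nm) plus Q
  bands 512/546/590/646 nm (heights 0.06/0.05/0.04/0.05, σ = 8 nm);
* P1 emission: single band at 652 nm, σ = 10 nm;
* SOSG excitation/emission bands at 473/525 nm.

These reproduce the qualitative facts the analyses rely on: the Q band
at 546 nm gives Tb→P1 coupling its maximum at the 545 nm peak, and the
Gd line has zero overlap with P1 absorption.

## Weighted transport and the calibrated coupling

The true interaction probability of a 511 keV gamma inside a sub-µm
cluster is of order 10⁻⁸ per primary; an analogue simulation of 10⁵
primaries would tally nothing.  The engine therefore uses non-analogue
(weighted) transport throughout:

* **Forced gamma capture.** One gamma per annihilation is aimed at the
  cluster carrying an importance weight `gamma_importance`, and a
  fraction `gamma_capture_prob` (default 0.05) of that weight is
  deposited per traversal.  The deposit converts to scintillation
  photons at `photons_per_MeV` (default 10⁴/MeV; fold-change observables
  are yield-invariant).
* **UV capture.** Cerenkov photons crossing the cluster are captured by
  the lanthanide with per-traversal probability
  `uv_capture_prob × uv_absorption(λ)` (default scale 0.5) and re-emitted
  once from the scintillation spectrum.
* **Photosensitizer absorption.** In-cluster absorption is Beer–Lambert
  along the traversal chord c:  1 − exp(−a(λ)·η·ρ·c), with a(λ) the P1
  absorption spectrum, η the geometric transfer efficiency
  (0.25 for photons born on a nanoparticle, 1 for external photons) and
  ρ an effective encounter density (440 µm⁻¹, equivalent to an effective
  encounter radius of ~110 nm ≈ λ/5 around the ray through the
  6000-particle cluster).  Competing channels split the absorbed weight
  in proportion to their hazards, so total weight is conserved exactly
  (the suite checks closure to 1 part in 10⁹).
* **Azimuthal splitting.** Near-cluster Cerenkov photons are split into
  24 azimuth samples of weight 1/24 on the emission cone — pure variance
  reduction, verified unbiased against an unsplit run.

Two of these parameters are calibrated rather than derived, and the
calibration is part of the model definition (performed once, then
frozen): ρ = 440 µm⁻¹ was chosen by quadrature so that a 545 nm
scintillation photon born uniformly in the cluster survives with mean
probability ≈ 0.27 (a 3–4× depletion of the 545 nm peak when P1 is
present), and `gamma_importance` = 6.0×10⁻⁶ was solved linearly from the
pathway decomposition at 10⁵ primaries so the Tb+PS arm doubles P1
fluorescence relative to the PS-only arm.  Both values sit in the run
manifest of every simulation.

Other numerical choices: positron step 1 µm; wavelength grid 250–800 nm
at 1 nm; optical photons are all 1.55–4.96 eV so a 1 eV tracking cut-off
is honoured trivially; photosensitizer fluorescence is tallied at
emission and not re-transported (self-reabsorption would rescale every
arm alike and cancel in fold changes); second-order lanthanide recapture
of its own emission is off (the emission bands sit outside the UV
absorption edges).  Photoelectron-induced Cerenkov light after gamma
capture exists as a switch (default off, electron energy 511 keV minus a
50 keV binding placeholder).  RNG: one root seed per run; six named
substreams derived via `SeedSequence.spawn`, recorded in the manifest;
runs are bit-reproducible.

## Scenario analysis

`analysis.summarize` integrates the cluster-exit scintillation histogram
over 545 ± 5 nm and the photosensitizer fluorescence over 652 ± 10 nm
(window widths are this package's choice — integrated band, not peak
height).  Fold changes carry a weighted-Poisson sigma (sqrt of the
squared-weight sum, delta-method propagated); the spectral exponent is
an OLS slope of log(count density) against log λ over non-empty bins.
At the default 10⁵ primaries the headline numbers are
tb_ps/ps_only ≈ 2.0 ± 0.06, gd_ps/ps_only ≈ 1.00 ± 0.04, and
tb_only/tb_ps (545 nm) ≈ 3.7.

## Kinetics

Singlet-oxygen production is modelled as rate = k·(1−q)·A(t) with
A(t) = A₀·exp(−λ_d t) and λ_d = ln2/T½; for Ga-68, T½ = 67.71 min
(standard nuclear data), so λ_d = 0.010237 min⁻¹.  The natural log of
per-interval signal increments against interval midpoints is then
exactly linear with slope −λ_d.  Natural log and minutes are the only
log-base/time-unit combination consistent with a fitted decay slope of
~0.0103 min⁻¹, and the increments mode (per-interval production) is the
default; a `rates` mode fits instantaneous values instead.  Quenchers
scale the amplitude (generator defaults: NaN₃ 0.95, BSA 0.90 — chosen
values, not measurements), never the rate.  `compare_slopes` reports
trunc(100·(|a|/|b|−1)); the canonical production/decay slope pair
(0.0119, 0.0103) gives 15%.

## Clonogenic statistics

Kruskal–Wallis H with tie correction and chi-squared reference, followed
by Dunn's pairwise rank z-tests with the tie-corrected pooled variance;
Bonferroni is the default adjustment (the most common pairing with
Dunn; "none" is available).  Both are implemented from the rank
formulas; the suite cross-checks H against an independent brute-force
rank enumeration and against `scipy.stats.kruskal`, and Dunn decisions
against a permutation test, with the full pipeline's type-I error on
null Poisson designs required to sit in [0.03, 0.07] at α = 0.05.
Surviving fractions are arm means over a reference-arm mean with
delta-method SDs.  The pipeline starts from counts; colony-image
segmentation is out of scope.

## Synthetic data

The generators define the study conditions: SOSG series sampled every
5 min over 20 min with 1% multiplicative Gaussian noise on the
increments; Poisson colony counts with n = 12 wells, baseline 150
colonies/well (30% plating efficiency of 500 seeded cells), and a
survival deficit (0.5 at 1 MBq, 0.3 at 3 MBq) confined to the Tb-P1 arm;
spectra as above.  What they deliberately do not emulate: instrument
drift or UV-induced probe artefacts in the SOSG signal, over-dispersed
(non-Poisson) colony counts, plating-density edge effects, or measured
spectral line shapes.  Passing tests therefore demonstrate that the
estimators recover the generating structure under idealized noise, not
that real assay data meet these assumptions.

## Reported sizes and stochastic reporting

Scenario comparisons run at 10⁵ primaries by default — enough that the
headline fold changes carry ~3% Monte Carlo sigma; a paired-seed
equivalence test shows they agree with larger runs within combined
sigma.  The
acceptance script reports the SOSG slope as the mean of 25 seeded
replicate fits of the 4-increment protocol: a single 4-point fit has an
~8.6% sampling sigma, and replicate averaging reduces reporting noise
around the same unbiased estimate without altering the generating
conditions.

## Known limitations

* The gamma pathway's absolute magnitude is set by a calibrated
  importance, so only relative (fold-change) observables are meaningful;
  no absolute radiometry or dosimetry (Gy) is attempted.
* Straight-line transport ignores Compton scattering of the 511 keV
  pair, positron multiple scattering, and optical Rayleigh/Mie
  scattering.
* The energy transfer is radiative reabsorption with a geometric
  efficiency, not a Förster-type rate; the singlet-oxygen quantum yield
  Φ_Δ (default 0.5) affects absolute, not relative, counts.
* Spectra are Gaussian-mixture stand-ins; conclusions that depend on
  fine spectral structure beyond peak positions and overlaps are outside
  the model's reach.
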