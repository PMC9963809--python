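"""Why Tb works and Gd does not: spectral overlap with the photosensitizer.

Builds the packaged Tb/Gd emission and P1 absorption spectra and
computes their overlap integrals.  Tb's four visible peaks (dominant
545 nm) overlap the porphyrin Q bands; Gd's deep-UV line (~311 nm) sits
outside the P1 absorption spectrum entirely, which is why the Gd arm is
the null-control arm of the comparison.
"""

from crpdt.spectra import (
    gd_emission_spectrum,
    overlap_integral,
    p1_absorption_spectrum,
    p1_emission_spectrum,
    tb_emission_spectrum,
)

tb, gd, p1 = tb_emission_spectrum(), gd_emission_spectrum(), p1_absorption_spectrum()
print(f"Tb emission mode: {tb.mode_nm():.0f} nm; Gd emission mode: {gd.mode_nm():.0f} nm")
print(f"P1 absorption mode (Soret): {p1.mode_nm():.0f} nm; "
      f"P1 emission mode: {p1_emission_spectrum().mode_nm():.0f} nm")
print(f"overlap(Tb emission, P1 absorption) = {overlap_integral(tb, p1):.4f}")
print(f"overlap(Gd emission, P1 absorption) = {overlap_integral(gd, p1):.2e}")
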