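"""Phonon-modulated charge-carrier band structure of dsDNA homopolymers.

Solves the band quadratic for polyG-polyC and polyA-polyT at phonon
wavevector q = 0 and q = q* = pi/xi, printing band widths, direct gaps
and the phonon-induced gap reduction.
"""

import numpy as np

import helixct as hx

frame = hx.derive_frame(hx.default_params("GC").geometry)

print("Band-structure summary (meV), gamma = 0:")
print(hx.band_table(["GC", "AT"]).to_string(index=False))

for species in ("GC", "AT"):
    params = hx.default_params(species)
    eg0 = hx.bandgap_closed_form(params, 0.0, 0.0, frame)
    eg_star = hx.bandgap_closed_form(params, 0.0, frame.qstar, frame)
    red = (eg0 - eg_star) / eg0 * 100
    print(
        f"\npoly{species[0]}-poly{species[1]}: Eg(0,0) = {eg0*1e3:.1f} meV, "
        f"Eg(0,q*) = {eg_star*1e3:.1f} meV  ->  {red:.1f}% reduction"
    )

print(
    "\nA synchronized helical phonon at the zone boundary weakens the pi-pi"
    "\nhopping t(q) and narrows the direct gap at kappa=0: collective"
    "\noscillations enhance charge transfer."
)

# semiconductor-semimetal transition under backbone gating
params = hx.default_params("GC")
df, closures = hx.gamma_scan(params, np.linspace(0.0, 2.0, 401), 0.0, frame)
print(f"\nGap closes at backbone on-site energy gamma = {closures[0]:.3f} eV")
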