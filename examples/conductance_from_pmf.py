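"""Unitary conductance from a full-channel PMF via first-passage times.

Sweeps the transmembrane potential, converts each tilted profile into
forward and reverse permeation rates through the mean-first-passage-time
integral, fits the I-V slope, and applies the Debye multi-ion correction.
A flat profile is compared against the analytic small-voltage limit.
"""

import numpy as np

from permion import (
    ChannelParams,
    PMFProfile,
    compute_conductance,
    corrected_conductance,
    flat_profile_conductance_closed_form,
)

p = ChannelParams()
z = np.linspace(0.0, p.L, 1025)
small_sweep = (-10, -8, -6, -4, -2, 2, 4, 6, 8, 10)

flat = PMFProfile(z=z, w=np.zeros_like(z), tag="full_channel")
res = compute_conductance(flat, p, small_sweep)
print(f"flat profile gamma0            : {res.gamma0_pS:.2f} pS")
print(f"analytic 4q^2D/(3kBT L^2)      : {flat_profile_conductance_closed_form(p):.2f} pS")

for h in (5.0, 10.0, 20.0):
    w = h * np.exp(-((z - p.L / 2) ** 2) / 2.0)
    barrier = PMFProfile(z=z, w=w, tag="full_channel")
    out = corrected_conductance(barrier, p, small_sweep)
    print(
        f"{h:4.0f} kJ/mol barrier: gamma0 = {out.gamma0_pS:8.4f} pS, "
        f"N_I = {out.N_I:.2f}, multi-ion gamma = {out.gamma_pS:8.3f} pS"
    )

print(
    "\nRaising the central barrier suppresses the permeation rate\n"
    "exponentially (an Arrhenius-like factor e^{-beta dW}), which is how a\n"
    "structural change of a few kJ/mol translates into an order-of-\n"
    "magnitude conductance loss."
)
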