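"""Electrolyte screening and the multi-ion conductance correction.

Computes the Debye length of a physiological KCl solution, the number of
K+ ions that can permeate a 17.2 nm gap-junction channel simultaneously
without interacting, and scales two single-ion conductances by that count.
"""

from permion import ChannelParams, debye_length, ion_count, multi_ion_correction

p = ChannelParams()  # 300 K, 0.15 M, L = 17.2 nm, eps_r = 78.4

lam = debye_length(p)
n_i = ion_count(p, rounding="printed")

print(f"Debye length lambda_D          : {lam:.4f} nm (~{lam:.2f} nm)")
print(f"simultaneous ion count N_I     : {n_i:.2f}  (L / 2 lambda_D)")

for label, gamma0 in (("wild type   ", 9.64), ("M34T mutant ", 0.92)):
    gamma = multi_ion_correction(gamma0, n_i)
    print(f"{label}: gamma0 = {gamma0:5.2f} pS -> multi-ion gamma = {gamma:6.1f} pS")

print(
    "\nIons farther apart than a Debye diameter are electrically screened\n"
    "from each other, so N_I of them permeate near-independently and the\n"
    "single-ion conductance scales by N_I. The mutant/wild-type ratio is\n"
    f"unchanged by the correction: {0.92 / 9.64:.1%}."
)
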