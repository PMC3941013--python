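"""Six-fold symmetry statistics of two hexamer-ring conditions.

Generates two synthetic ring trajectories — one nearly symmetric, one with
a stronger single-axis stretch — measures the eccentricity coefficient
E = D_max/d_min over residues 2-14 and 100 frames, and compares the two
distributions with a two-sided Mann-Whitney U test.
"""

from permion import (
    HexSynthSpec,
    angle_series,
    eccentricity_series,
    gen_hex_traj,
    mann_whitney_u,
    pooled_angles,
)

residues = list(range(2, 15))

cond_a = gen_hex_traj(HexSynthSpec(n_frames=100, a=1.05, noise_sd=0.05, seed=10))
cond_b = gen_hex_traj(HexSynthSpec(n_frames=100, a=1.20, noise_sd=0.05, seed=11))

ea = eccentricity_series(cond_a, residues)
eb = eccentricity_series(cond_b, residues)
print(f"condition A (a = 1.05): E = {ea['mean']:.3f} +- {ea['sem']:.3f} (n = {ea['n']})")
print(f"condition B (a = 1.20): E = {eb['mean']:.3f} +- {eb['sem']:.3f} (n = {eb['n']})")

test = mann_whitney_u(ea["values"], eb["values"])
print(f"Mann-Whitney U = {test.U:.0f}, two-sided p = {test.p_value:.2e} ({test.method})")

ang_a = pooled_angles(angle_series(cond_a, 5))
ang_b = pooled_angles(angle_series(cond_b, 5))
print(f"T5-ring angles: A {ang_a.mean():.1f} +- {ang_a.std():.1f} deg, "
      f"B {ang_b.mean():.1f} +- {ang_b.std():.1f} deg")

print(
    "\nE = 1 is perfect six-fold symmetry; the stretched condition sits\n"
    "significantly higher, and its hexagon angles spread further from the\n"
    "regular 120 degrees."
)
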