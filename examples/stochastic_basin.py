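"""Stochastic basin of attraction of the low-concentration state.

The deterministic basin of x- is replaced by a noise-aware construct:
a core K = {u >= u*} where the mean residence time is long, plus the set
M of outside points that return to K with probability above p*.  The
basin size |K| + |M| measures how stable the low state is under a given
noise law.
"""

import numpy as np

from levyswitch import Domain1D, ModelParams, NoiseSpec, solve_mfet, stochastic_basin, ustar_for_width

params = ModelParams(6.0, 10.0, 1.0, 0.4)
B = Domain1D.interval(0.0, 1.48971)   # deterministic basin of x-
window = Domain1D.interval(0.0, 6.0)  # search window for returning points

# pick u* per noise law so every core K has the same width 0.55
for label, noise in {
    "Brownian": NoiseSpec(1.0, 0.0, 2.0),
    "alpha=1.5": NoiseSpec(0.0, 0.5, 1.5),
    "alpha=0.5": NoiseSpec(0.0, 0.5, 0.5),
}.items():
    u = solve_mfet(B, params, noise, J=400)
    u_star = ustar_for_width(u, 0.55)
    r = stochastic_basin(params, noise, window, u_star, p_star=0.5, J=400)
    m_str = " U ".join(f"[{a:.4f}, {b:.4f}]" for a, b in r.M)
    print(f"{label:>10s}: K = [{r.K[0]:.4f}, {r.K[1]:.4f}]  M = {m_str}")
    print(f"{'':>10s}  basin size |K|+|M| = {r.sba_size:.4f}")
print()
print("At matched |K| and the same return threshold p* = 0.5 the basin is")
print("largest for Brownian noise and smallest for alpha = 0.5: frequent")
print("small fluctuations pull distant states back, rare large jumps do not.")
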