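"""Fixed points and double-well potential of the TF-A switch.

Locates the equilibria of the autoregulation drift for the standard rate
set, classifies their stability, and evaluates the potential V (with
V' = -f) at each, confirming the double-well landscape: two minima
separated by a barrier at the unstable threshold.
"""

from levyswitch import ModelParams, classify_stability, find_equilibria, potential

params = ModelParams(k_f=6.0, K_d=10.0, k_d=1.0, R_bas=0.4)
eq = find_equilibria(params)

print("fixed points of dx/dt = k_f x^2/(x^2+K_d) - k_d x + R_bas:")
for root in eq.roots:
    v = potential(root, params)
    print(f"  x = {root:8.5f} nM   {classify_stability(params, root):>8}   V = {v:+.4f}")
print()
print("The low state x- and high state x+ sit in the two wells; the middle")
print("root x_u is the barrier top: noise must push the concentration past")
print("x_u for the switch to flip from low to high expression.")
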