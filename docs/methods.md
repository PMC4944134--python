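# Methods

## Model

The state variable is the concentration x (nM) of a transcription factor
activator (TF-A) that up-regulates its own gene: phosphorylated TF-A
homodimers bind a responsive element, activating transcription at maximal
rate `k_f`; the monomer degrades at rate `k_d` and is synthesised at a
basal rate `R_bas`. With fast dimer binding (dissociation constant `K_d`)
the deterministic kinetics reduce to

    dx/dt = f(x) = k_f x^2 / (x^2 + K_d) - k_d x + R_bas .

The standard rate set (k_f, K_d, k_d, R_bas) = (6, 10, 1, 0.4) (units
1/min, –, 1/min, nM/min) is bistable: a low state x− ≈ 0.62685, an
unstable threshold x_u ≈ 1.48971 and a high state x+ ≈ 4.28343.
Bistability is decided by counting sign-change roots of f on
[0, search_max] (default 10, covering every rate set used here); roots
are refined by bisection to bracket width 1e-12. An analytic bistability
inequality exists in principle but adds nothing over root counting and is
not used. The potential V (V' = −f, V(0) = 0) is computed by adaptive
quadrature of −f so the code stays generic in the drift; several
routines accept any callable drift in place of `ModelParams`, which is
how textbook drifts (f ≡ 0, f = −x) enter the test oracles.

## Stochastic model

Fluctuations in the synthesis reaction are modelled as two independent
additive noises on the rate equation:

    dX = f(X) dt + sigma dB_t + epsilon dL_t^alpha ,

with B a standard Brownian motion and L a standard *symmetric* α-stable
Lévy motion (pure jump, characteristic function exp(−t|ξ|^α), jump
measure ν_α(dy) = C_α |y|^{−1−α} dy with
C_α = α Γ((1+α)/2) / (2^{1−α} √π Γ(1−α/2)); C_1 = 1/π). Asymmetric
stable laws are out of scope. The index α ∈ (0, 2] trades jump size
against frequency — α near 0 gives rare huge jumps, α = 2 degenerates to
a Gaussian with variance 2. Under the constraint σ + ε = 1 the mix is
parametrised by the relative contribution factor λ = ε/σ.

Sampling uses the Chambers–Mallows–Stuck transform with the tan(U)
special case at α = 1 and a direct N(0, 2) draw at α = 2. The
Euler–Maruyama step is

    X_{n+1} = X_n + f(X_n) dt + sigma sqrt(dt) G_n + epsilon dt^{1/alpha} S_n ,

the dt^{1/α} scaling being the self-similarity of the stable motion.
Draw order is fixed (Gaussian, then stable; absent streams not drawn) so
ensembles reproduce exactly from (seed, dt, n_paths). Exit bookkeeping
keeps the post-jump overshoot as the exit state, with no boundary
interpolation even for the Gaussian part — an O(√dt) bias accepted at
the default dt = 1e-3 min. Negative concentrations are allowed in the
raw process (they live in the exterior region and are immediately
recorded as exits when the domain starts at 0); the drift is evaluated
as written. Monte Carlo runs continue until every path exits or a hard
cap of 1e6 steps; censoring above 5% attaches a warning because it
biases the mean exit time low.

## Nonlocal exit equations

The generator of the jump diffusion is

    A u(x) = f u' + (sigma^2/2) u'' + eps^alpha PV∫ (u(x+y) − u(x)) ν_α(dy) ,

where ε^α is the intensity scaling implied by self-similarity
(ε L_t ≙ standard motion run at speed ε^α) and the small-jump drift
compensator vanishes by symmetry. The mean first exit time (MFET) from
an open set D solves A u = −1 with u = 0 on the entire complement; the
first escape probability (FEP) to a target E ⊂ D^c solves A p = 0 with
p = 1 on E and 0 on the rest of D^c (Balayage–Dirichlet exterior
condition — jumps can land anywhere outside, so the condition lives on
the whole complement, including (−∞, 0]).

### Discretisation

Each interval of D is mapped affinely to z ∈ (−1, 1) and carries J
uniform cells (default J = 400, ≥ 16 interior nodes enforced). At an
interior node x_j:

* drift: central difference; where the cell Péclet number
  |f| h / (2 ν_loc) exceeds 1 (ν_loc = σ²/2 plus the singular-cell
  correction below) the node switches to first-order upwind. This keeps
  the matrix an M-matrix in the jump-dominated small-α regime, where
  central differencing of a transport-dominated row would oscillate; the
  extra numerical diffusion |f| h/2 is negligible against the nonlocal
  mass in exactly the regime where the switch activates, and the
  Brownian-dominated cases never trigger it.
* Gaussian part: second central difference; α = 2 jump noise is routed
  here as an extra ε² diffusion (variance 2 of the standard 2-stable law).
* jump integral: the singular cell |y| < h is replaced by its Taylor
  effective diffusion (C_α h^{2−α}/(2−α)) u''; the rest of D is a
  punched-hole composite trapezoid over the lattice (half weights at the
  hole edges and interval endpoints, endpoint values taken from the
  exterior condition); *everything outside D is integrated against ν_α
  analytically*, piece by constant-value piece:
  ∫_c^d ν_α = (C_α/α)(|c−x_j|^{−α} − |d−x_j|^{−α}) for a piece right of
  x_j (mirrored on the left, far endpoint may be +∞). There is therefore
  no numerical truncation of the jump integral: semi-infinite Scenario-1
  targets and the detached Scenario-2 target [3, 5] are exact in the far
  field, and a pure-Gaussian run reproduces the detached-target null
  identically. For multi-interval domains (the return problem of the
  stochastic basin) one block system couples all interior nodes; the gap
  between intervals is an analytic exterior piece.

By construction the scheme annihilates constants exactly (every term is
a difference of nodal/exterior values), which the tests assert to 1e-8
across an (α, σ, ε) lattice. Linear systems are dense-factorised
(≤ a few thousand nodes); the pure-diffusion path is tridiagonal and
solved banded. `refine_until` doubles J until the relative sup-norm
change between successive solutions drops below a tolerance (default
1e-3, cap J = 6400).

### Validation oracles

Two independent routes check the solver:

* **Brownian closed forms** — with ψ(x) = exp(−(2/σ²)∫_a^x f), the
  right-exit probability is ∫_a^x ψ / ∫_a^b ψ and the exit time is the
  classical double quadrature u = (2/σ²)[p(x) G(b) − G(x)],
  G(x) = ∫_a^x ψ(t) ∫_a^t ψ^{−1}. The nested antiderivatives are
  accumulated by adaptive integration (rtol 1e-11). At J = 400 the
  solver agrees to ~2e-5 relative (MFET) and ~3e-6 absolute (FEP);
  observed convergence order ≈ 2.
* **Pure-jump closed form** — the driftless standard α-stable motion
  exits (−1, 1) in mean time
  (1 − x²)^{α/2} √π / (2^α Γ(1+α/2) Γ((1+α)/2)); the solver matches to
  ~0.1–0.2% at J = 400 (first-order convergence here, limited by the
  (1−x²)^{α/2} boundary layer).
* **Monte Carlo** — solver MFET/FEP agree with n = 1e4-path ensembles at
  dt = 1e-3 within three standard errors for α ∈ {0.5, 1.5}, ε = 0.5.

The constant of the singular-cell correction is validated by these
oracle equivalences rather than taken on faith; the half-weight
trapezoid at the hole edge is the pairing consistent with the Taylor
correction (a full weight would only shift the effective-diffusion
constant at the same order).

## Escape analysis

`sweep_mfet` / `sweep_fep` run one solve per noise setting and
interpolate at the requested start points, tagging every row with the
full parameter tuple. Scenario 1 targets the adjacent half-line
[x_u, ∞) (boundary value 1 at x_u for the diffusive part); Scenario 2
requires a detached target, reachable only by jumps — its pure-Gaussian
probability is identically zero.

The stochastic basin of attraction (SBA) of the low state is computed
as: (i) MFET u on the deterministic basin interval (0, x_u); (ii) core
K = the connected superlevel component {u ≥ u*} containing the maximiser
(leftmost maximiser on ties), endpoints interpolated linearly and
reported to 4 decimals; (iii) the return probability p to K solved on
the two-interval region window \ K with the indicator of K as exterior
condition (everything outside the window counts 0); (iv) M = {p > p*}
as a union of intervals; (v) size = |K| + |M| (volume = interval
length). Interval ends touching K belong to K itself, so their
prescribed value 1 cannot seed an M component alone; they inherit the
adjacent node's superlevel status, which also makes "p* above every
nodal value ⇒ M empty" hold exactly. The search window defaults to
(0, 6) rather than the deterministic basin, so returns from beyond the
barrier are counted; both are configurable. Because the thresholds u*,
p* are free inputs, cross-noise comparisons are made at *matched core
width* via `ustar_for_width` (bisection on u*).

## Defaults and reproducibility

| parameter | default | notes |
|---|---|---|
| J (cells per interval) | 400 | Brownian oracle error ≲ 2e-5 rel; pure-jump ≲ 0.2% |
| dt | 1e-3 min | Euler step; exit-time bias O(dt) not visible at 3 SE with n = 1e4 |
| n_paths | 1e4 | SE ≈ 1% of the mean exit time |
| step cap | 1e6 | censoring warning above 5% |
| seed | 20160714 | fixed documented default; all randomness flows through one `numpy` Generator |

Result CSVs embed their producing configuration as `# key=value` header
lines; configs round-trip through JSON/TOML with unknown keys rejected.

## What the simulator does and does not emulate

The simulator generates exactly the statistical structure the analysis
assumes: the stated drift, additive Gaussian noise, additive symmetric
α-stable jumps, mutually independent. Passing cross-checks therefore
validate the numerics, not the biology: real transcriptional bursting
need not be α-stable, noise may be multiplicative or state-dependent,
and molecular-discreteness effects (low copy number) are outside the
diffusion picture altogether. Conclusions about the model transfer to a
cell only insofar as the heavy-tail abstraction of bursting holds.

## Known limitations

* One-dimensional state only; no asymmetric or tempered stable laws.
* Euler–Maruyama has no jump-adapted refinement; overshoot semantics
  make the MC exit state exact in law only as dt → 0.
* The nonlocal solve is dense: J much beyond 6400 per interval is slow
  and memory-hungry.
* Near-tangent (saddle-node) rate sets are rejected rather than resolved.
* For α close to 2 with ε ≫ σ the singular-cell correction dominates
  the true diffusion; accuracy degrades gracefully (observed, not
  catastrophic) but warrants a finer grid.
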