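# Methods

## Model

The carrier's conformational change is treated as one-dimensional diffusion
along a discrete coordinate `c = -n_half .. +n_half` (default 21 steps),
with `c = -10` the cytoplasmic conformation, `c = 0` the occluded
intermediate and `c = +10` the matrix conformation. The system state is
⟨c, s⟩ where the single binding site `s` is empty or holds one of N
mutually exclusive substrates; with the default two species ("labelled" ADP
outside, "unlabelled" ADP inside) there are 63 states, 60 conformational
reaction pairs and 4 binding reaction pairs.

All energies are standard chemical potentials in millivolts (single
elementary-charge scale; 10.36 mV = 1 kJ/mol), so they can be compared
directly with electrochemical potentials. The potential of a state is

    mu0(c, s) = dE_M * exp(-((c + n)/w_M)^2)        matrix network
              + dE_C * exp(-((c - n)/w_C)^2)        cytoplasmic network
              + [bound] dE_S * exp(-(c/w_S)^2)      induced fit
              + [bound] dE_B,   dE_B = -kBT ln([S]/K_d)

with n = n_half. The matrix network is engaged in the cytoplasmic
conformation (its Gaussian peaks at c = -n) and the cytoplasmic network in
the matrix conformation; the induced fit peaks in the intermediate. The
Gaussian widths default to (n/2, n/2, 0.4 n) — 5, 5 and 4 on the standard
grid — and scale with `n_half` so that refining the grid keeps the profile
shape fixed.

Conformational rates split the step free energy symmetrically about the base
rate k_c:

    k(c->c+1) = k_c e^(-dG0/2kBT),  k(c+1->c) = k_c e^(+dG0/2kBT),
    dG0 = mu0(c+1, s) - mu0(c, s)

so forward/reverse = e^(-dG0/kBT) exactly (detailed balance along the
ladder; the concentration term dE_B cancels in dG0). Substrate binds only in
the end conformations, with on-rate k_f[S] and off-rate k_r; the identity
k_r = k_f K_d is enforced at construction. With these rates every closed
cycle has zero affinity when a species has equal concentrations on both
sides: the model does no work without a gradient (property-tested to 1e-10).

### Binding-edge thermodynamics

The literal end-conformation binding rates ignore the small induced-fit tail
dE_S e^(-(n/w_S)^2) (≈ -1 mV at dE_S = -550) that the bound-state potential
carries at c = ±n, so the chain's implied binding free energy differs from
the potential difference by that amount. The offset is symmetric and cancels
around every cycle. The flag `consistent_binding_edges` folds the tail into
the release rate for exact agreement with the bound profile; it is off by
default (the plain k_f[S] / k_r rates are the model as published) and moves
headline results by well under 1%.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| dE_M, dE_C | -550 | mV | formation energies of matrix / cytoplasmic networks (negative = stabilising) |
| dE_S | -550 | mV | induced-fit binding energy at the intermediate |
| K_d | 4e-5 | M | dissociation constant in the end conformations |
| k_f | 2.5e10 | /M/s | binding rate constant (mean binding time 40 ns at 1 mM) |
| k_r | 1e6 | /s | release rate constant (= k_f K_d) |
| k_c | 5.66e6 | /s | conformational base rate at dG0 = 0 |
| temperature | 37 | °C | kBT = 26.73 mV, recomputed from T |
| n_half | 10 | – | 21 conformations |

These defaults are the published calibration of the fungal ADP/ATP carrier
against reconstituted-vesicle transport assays (wild-type turnover ≈ 40
ADP/s, K_M matched at weak cytoplasmic networks). kBT is recomputed from the
temperature rather than fixed at the printed rounding 26.7 mV; this choice
moves barrier-dominated rates by ~2% (the model's k_cat computes to 41.4 /s
rather than 40.5 /s with the rounded constant). The salt-bridge ↔ millivolt
registration dE(mV) = -130 N - 240 is taken as given, not re-estimated.

The default concentration scenario (5 mM labelled ADP outside, 5 mM
unlabelled inside) mirrors the radiolabel exchange experiments the
calibration derives from; both species share all rate constants, so the
labelled influx is a pure tracer measurement of exchange.

## Solvers

**Steady state.** The dense generator Q (columns sum to zero; off-diagonal
(i, j) holds the j→i rate) is assembled and one balance row replaced by the
normalisation row; the 63×63 system is solved with partial pivoting and the
residual of the full balance equations reported (typically ~1e-10 of the
largest rate). Rate entries stay within ~e^(±1) of k_c per step, so
conditioning is benign even when probabilities span twelve decades.
Probabilities more negative than -1e-12·max(P) abort the solve; smaller
negatives are clipped and renormalised. Bound ladders of a substrate absent
from both compartments are unreachable and are pruned with a warning rather
than solving a singular system.

**Stochastic.** Exact SSA (exponential waiting times, propensity-
proportional event choice) over the same directed-transition table, seeded
through `numpy.random.default_rng`; a fixed seed reproduces the event log
bit-identically. The default initial state is the empty carrier in the
cytoplasmic conformation, and the first 10% of the horizon is discarded as
burn-in before counting (start-state independence of the estimates is
asserted in the tests). Episodes still open at the horizon are dropped and
counted separately (bias O(1/episodes)). The transport estimator is
(class-1 − class-4 episodes)/t with a Poisson standard error
sqrt(n1 + n4)/t.

**Cross-validation.** Time-weighted SSA occupancies are compared to the
master-equation distribution with batch-means standard errors (20 equal time
batches): binomial errors on correlated dwell-time samples are
anti-conservative by an order of magnitude, while batch means give correctly
scaled z-values. The comparison is run at a fast-mixing parameter point
(-200 mV networks, 100 uM substrate per side) so that a 1e6-event run covers
many barrier crossings; at the -550 mV calibration point a single crossing
takes ~25 ms ≈ 3e6 events, and no feasible run length mixes the two wells.

## Analytic companions

- **Boltzmann profile**: with no induced fit the conformational marginal of
  the driven steady state is exactly thermal (verified to 1e-6 relative);
  at saturating concentrations the bound-profile Boltzmann distribution is a
  ~1% approximation.
- **Forward flux**: J_F = ½ P_I k_c, with P_I the Boltzmann weight of the
  intermediate conformation and the factor ½ the labelled fraction of bound
  carrier. The default computes P_I from the full 21-term partition sum;
  `method="barrier"` uses the two-well closed form ½ e^(-(mu_I - mu_N)/kBT),
  which neglects the near-end states (their Boltzmann factors sum to ~0.39
  of an end weight at -700 mV) and therefore overestimates J_F by ~40%. With
  the default estimator J_F runs ~54–67% above the full-model net flux over
  the -600 .. -700 mV range of the symmetric sweep.
- **Energy barrier**: max − min of the relevant profile, with ties (within
  1e-9 mV) reported — a matched induced fit produces two equal maxima
  flanking the intermediate.
- **Partition decomposition**: Z_s sums Boltzmann weights of the bound net
  profile over all conformations; Z_c and Z_m sum the unbound profile over
  c < 0 and c > 0 with the c = 0 term split equally. The unbound weight is
  concentrated at the ends, so the split choice perturbs the derived K_M by
  < 1% (asserted). Concentration factors are carried symbolically as
  K_d/[S], so zero concentrations need no logarithms. All sums use
  log-sum-exp. K_M^cyt = (Z_c/Z_s) K_d and K_M^mat = (Z_m/Z_s) K_d agree
  with full-model Michaelis–Menten fits to 4–8% wherever K_M is resolvable.

## Experiments and problem sizes

Sweeps use 10 mV panoramic grids with 1 mV refinement around optima (the
transport-maximising cytoplasmic network sits 6–9 mV above the matrix value
on the signed scale — a slightly *weaker* network — so resolving it needs
≤ 1 mV). Michaelis–Menten fits are unweighted Levenberg–Marquardt
(`scipy.optimize.curve_fit`) on transport curves over 0–100 uM, with initial
guesses k_cat = max rate and K_M = concentration at half-max; the reference
procedure uses 0.1 uM steps (1001 points), while in-suite fits use 1–2 uM
steps, which changes fitted parameters by < 0.1%. "Weak" and "strong"
cytoplasmic networks for the K_M asymmetry are pinned to -300 mV and
-700 mV, the ends of the experimentally accessible 0.5–3.5 salt-bridge range
under the -130 N - 240 registration. A fitted K_M below the smallest
nonzero concentration of the grid is an unresolved extrapolation; such
points are reported but only checked qualitatively (submicromolar).

The induced-fit sweep optionally renormalises k_c per network strength with
the tabulated values (0.065, 0.200, 0.721, 2.810, 11.488, 48.76 /us for
-200 .. -700 mV), which equalises the peak transport across strengths to
within ~1%.

## Numerical and design notes

- Transport maximum vs induced fit: the sweep peaks at dE_S = -519 mV for
  -550 mV networks (1.2 kBT short of exact matching); the sharper invariant
  is that the *intermediate-state potential* at the optimum matches the
  network strength within 0.5 kBT, and that is what the tests pin down.
- Grid refinement: doubling n_half at fixed profile shape slows transport
  ~fourfold — the expected diffusive 1/n² scaling of a random walk, not a
  discretisation error. The 21-step grid is part of the calibration (k_c
  absorbs the step count), so n_half is exposed for exploration but not a
  convergence knob.
- Zero substrate concentration short-circuits to on-rate 0 (the binding
  energy logarithm is never evaluated on the rate path; `binding_energy`
  returns +inf as a sentinel for analysis code).
- Sign convention: positive flux is cytoplasm → matrix (import of cytosolic
  ADP).

## Limitations

The model is electroneutral and single-species: no membrane potential, no
ADP³⁻/ATP⁴⁻ charge asymmetry, and no distinct substrate affinities (labelled
and unlabelled ADP are identical by construction). Interaction energies are
temperature-independent inputs; there are no ionic-strength or pressure
corrections. Only the stationary regime is computed — no relaxation
(time-dependent master equation) solutions — and the SSA is exact but
unaccelerated, which is ample for the 63-state network but makes
deep-barrier regimes (strong networks at millimolar substrate) impractical
to sample stochastically; those regimes are the domain of the deterministic
solver. Agreement of the model with published kinetics says nothing about
structural details outside its four energy parameters.
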