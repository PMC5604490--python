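# carrierflux

A kinetic model of the mitochondrial ADP/ATP carrier (adenine nucleotide
translocase) built on the free-energy profile of its conformational change.
The carrier works by alternating access: a single substrate-binding site is
exposed either to the intermembrane space or to the mitochondrial matrix, and
the switch between the two states requires sequential disruption and
formation of a matrix and a cytoplasmic salt-bridge network. `carrierflux`
treats the carrier as a nanomachine diffusing along a discretised
conformational coordinate under thermal noise, and computes transport rates,
Michaelis–Menten parameters and uniport/exchange behaviour directly from the
interaction energies of the two networks and of substrate binding.

It is aimed at people studying mitochondrial carriers (and alternating-access
transporters generally) who want to connect structural features — how many
salt bridges close each side of the carrier, how much tighter the substrate
binds in the occluded intermediate — to measurable kinetics.

## The model

The conformational change is discretised into 21 steps, `c = -10`
(cytoplasmic conformation) through `c = 0` (intermediate) to `c = +10`
(matrix conformation). A state is a pair ⟨c, s⟩ of conformation and
binding-site occupancy (empty or one of N substrates), giving 21(N+1) states
joined by 20(N+1) conformational and 2N binding reaction pairs.

The standard chemical potential of each state (in mV; 10.36 mV = 1 kJ/mol) is
a sum of Gaussian interaction terms,

    mu0(c, s) = dE_M exp(-((c+10)/5)^2) + dE_C exp(-((c-10)/5)^2)
                + [s bound] ( dE_S exp(-(c/4)^2) + dE_B ),

where `dE_M` and `dE_C` are the formation energies of the matrix and
cytoplasmic networks (the matrix network is engaged in the *cytoplasmic*
conformation and vice versa), `dE_S` is the induced-fit binding energy peaked
in the intermediate conformation, and `dE_B = -kBT ln([S]/K_d)` is the
concentration-dependent binding energy. Rates between neighbouring
conformations split the free-energy change symmetrically,

    k(c -> c+1) = k_c exp(-dG0 / 2 kBT),   k(c+1 -> c) = k_c exp(+dG0 / 2 kBT),

which enforces detailed balance along the ladder, and substrate binds only in
the two end conformations with `k_on = k_f [S]`, `k_off = k_r = k_f K_d`.

The steady state of the chemical master equation is solved by direct linear
algebra; the same network can be simulated exactly with the Gillespie
algorithm, with every bind→release episode classified by its entry and exit
side. Analytic companions — Boltzmann conformational distributions, max−min
energy barriers, and the partition-function decomposition
`K_M^cyt = (Z_c/Z_s) K_d`, `K_M^mat = (Z_m/Z_s) K_d` — explain the full
model's behaviour in closed form.

Default parameters are the published calibration for the fungal ADP/ATP
carrier: `dE_M = dE_C = dE_S = -550 mV`, `K_d = 40 uM`, `k_f = 25 /ns/M`,
`k_r = 1e6 /s`, `k_c = 5.66e6 /s`, 37 °C (kBT ≈ 26.7 mV).

## Worked example

```python
from carrierflux import ModelParams, build_network, solve_steady_state

params = ModelParams()            # wild-type calibration, 5 mM ADP both sides
network = build_network(params)   # 63 states, 64 reaction pairs
result = solve_steady_state(network)
print(f"{result.transport_rate:.2f} /s")
```

prints `41.29 /s`: the influx of labelled ADP, equal to the efflux of
unlabelled ADP — the carrier is a strict one-for-one exchanger turning over
at the measured wild-type rate of roughly 40 ADP/s. Fitting the transport
rate against cytoplasmic substrate concentration (0–100 uM against 5 mM
inside) gives `k_cat = 41.4 /s`, `K_M = 8.9 uM`:

```python
from carrierflux import michaelis_menten_curve
concs, rates, fit = michaelis_menten_curve(params, side="cytoplasmic")
print(f"k_cat = {fit.k_cat:.1f} /s, K_M = {fit.K_M * 1e6:.1f} uM")
```

The `examples/` directory has one short script per capability — steady-state
exchange, energy barriers, stochastic episode classification, K_M/k_cat
sweeps, and uniport vs exchange scenarios — each printing the numbers it
computes and what they mean. The same functionality is available from a thin
CLI:

```bash
carrierflux steady --out run/            # transport rate + state table
carrierflux profile --dE-M -550 --dE-C -550 --dE-S 0 --out run/
carrierflux sweep fig6 --out run/        # K_M/k_cat vs network strength
```

Every command writes a `manifest.json` (resolved parameters, seed, version,
output checksums) from which deterministic runs reproduce bit-identically.

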