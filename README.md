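# photoswitch-sim

Continuous-time Markov chain simulation of cyanine (Cy5) photoswitching
photophysics under dSTORM conditions, with multi-fluorophore energy
transfer, a camera detection model, and the analysis stack used on real
single-molecule data — including photoswitching fingerprint analysis (PFA).

## The problem

In dSTORM super-resolution imaging, Cy5-class dyes cycle between a
fluorescent ON state and a long-lived dark OFF state (the thiol adduct
Cy5-SR⁻). When several fluorophores sit within ~10 nm of each other,
Förster resonance energy transfer (FRET) between an excited singlet donor
and dark acceptors changes the blinking statistics in a distance-dependent
way. The cumulative distribution of photon arrival times (the
*photoswitching fingerprint*) then curves upward early: the global
bleaching rate increases as distances shrink or fluorophore numbers grow.
This package simulates that physics exactly, so fingerprint signatures,
fluorescence lifetimes, correlation functions and photon antibunching can
be studied for hypothetical multi-fluorophore arrangements.

## The model

A single fluorophore occupies one of seven states — S0, S1, T1, cis
isomer, OFF (Cy5-SR⁻), R (radical anion Cy5⁻∙), B (photobleached) — with
elementary transitions: photoexcitation, fluorescence, internal
conversion, intersystem crossing (both directions), isomerisation and
back-isomerisation, photobleaching from T1, thiol-mediated photoinduced
electron transfer (PET) branching into geminate recombination / OFF
formation / radical escape, OFF recovery (thermal elimination +
photoinduced uncaging), and re-oxidation of R. An N-fluorophore system
(N ≤ 4) lives on the product state space (7^N states); for every ordered
donor–acceptor pair, energy-transfer transitions are added with rate
k(r) = k_ref · (r_ref/r)⁶:

| pathway | acceptor state | effect |
|---------|----------------|--------|
| SSA | S1 | donor quenched (singlet–singlet annihilation) |
| STA | T1 | donor quenched (singlet–triplet annihilation) |
| CET | cis | donor quenched; acceptor recycled to S0 with efficiency η |
| OET | OFF | donor quenched; OFF rescued to S0 with efficiency η = 10⁻⁴ |
| RET | R  | donor quenched; optional acceptor recycling |

Trajectories are generated with the exact stochastic simulation
(Gillespie) algorithm; deterministic predictions (limiting distribution π
with πQ = 0, embedded-jump-chain occurrence probabilities, state
lifetimes, transition recurrence times) come from the generator matrix.
Emitted photons pass a detection chain — solid-angle collection
(1−cos θ)/2 with θ = arcsin(NA/n), bandpass/mirror/lens losses, camera
quantum efficiency (total 0.146), Poisson dark counts, 1 ms frames, a
photon-count threshold — before ON/OFF period analysis.

The shipped rate table is a documented reconstruction calibrated against
published reference behaviours; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from photoswitch_sim import (build_single_model, simulate_stats,
                             stationary_distribution, lifetime_from_chain)
from photoswitch_sim.presets import cy5_rate_table

model = build_single_model(cy5_rate_table(), bleaching=False)
stats = simulate_stats(model, t_max=5.0, max_steps=10_000_000, seed=1)

pi = stationary_distribution(model.rate_matrix(), initial=model.initial_state)
print("occupation OFF (predicted):", round(pi[4], 3))
print("occupation OFF (simulated):", round(stats.occupancy[4], 3))
print("fluorescence lifetime (ns):", round(lifetime_from_chain(stats).tau_flu * 1e9, 3))
```

prints

```
occupation OFF (predicted): 0.995
occupation OFF (simulated): 0.994
fluorescence lifetime (ns): 1.697
```

i.e. the simulated single Cy5 spends ~99% of its time in the dark thiol
adduct (strong dSTORM blinking), matches the limiting distribution of the
chain, and shows the unquenched 1.69 ns fluorescence lifetime.

The command line exposes the same machinery:

```bash
photoswitch-sim scenario --name fingerprint_N4_d3 --seed 1 --out out/   # fingerprint run
photoswitch-sim analyze lifetime --variant ID5 --seed 1 --out out/
photoswitch-sim fixtures --out configs/                          # YAML presets
```

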