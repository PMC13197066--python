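# Methods

## Model

Each fluorophore is a continuous-time Markov chain on seven photophysical
states: trans ground state S0, first excited singlet S1, triplet T1, cis
isomer, thiol adduct OFF (Cy5-SR⁻), radical anion R (Cy5⁻∙), and a
photobleached sink B. The elementary transitions and their default rates
(s⁻¹) are:

| process | transition | default | origin |
|---|---|---|---|
| photoexcitation | S0→S1 | 7.69e6 | σ·I/E_phot at 2.5 kW cm⁻², 640 nm, ε = 2.5e5 M⁻¹cm⁻¹ |
| fluorescence | S1→S0 | 1.66e8 | quantum yield ≈ 0.28 at τ = 1.69 ns |
| internal conversion | S1→S0 | 3.735e8 | balance of the S1 budget |
| intersystem crossing | S1→T1 | 2.0e7 | reconstruction (see below) |
| intersystem crossing | T1→S0 | 5.0e5 | ~µs intrinsic triplet decay |
| isomerisation | S1→cis | 3.0e7 | ~5% yield per excitation |
| back-isomerisation | cis→S0 | 1.0e6 | thermal + photoinduced, lumped |
| photobleaching | T1→B | 880 | desk-scale choice (see below) |
| PET from S1 | S1→{S0,OFF,R} | 3.07e6 total | 1e9 M⁻¹s⁻¹ × 100 mM × thiolate fraction |
| PET from T1 | T1→{S0,OFF,R} | 9.20e6 total | 3e9 M⁻¹s⁻¹, same buffer |
| OFF recovery | OFF→S0 | 0.05 + 0.15 | thermal elimination + photoinduced uncaging |
| oxidation | R→S0 | 4130 | desk-scale choice (see below) |

The PET branch splits with probabilities p(geminate recombination) =
0.999, p(OFF) = 2e-4, p(radical escape) = 8e-4; the enhanced-radical
model variants multiply the T1→R channel rate by 10 or 100. The thiolate
fraction follows Henderson–Hasselbalch, 1/(1+10^(pKa−pH)) ≈ 0.0307 at
pKa 9.0, pH 7.5.

Energy transfer acts between every ordered donor–acceptor pair with the
Förster distance dependence k(r) = k_ref (r_ref/r)⁶, donor always S1 →
S0. Reference rates at 3 nm: SSA 5e9 (acceptor S1), STA 5e9 (acceptor
T1), CET 9e9 (acceptor cis, recycle efficiency 0.5), OET 5e9 (acceptor
OFF, recycle efficiency 1e-4), and — in the radical-transfer variants —
RET 1e9 (acceptor R). Vibrationally hot intermediates (S2, T2) are never
represented: SSA and STA leave the acceptor in its original state, CET,
OET and RET split their total rate into a recycled ([S0, S0]) and a
non-recycled outcome by the recycle efficiency. Reverse intersystem
crossing from T2 is disregarded. The non-recycling outcome still
de-excites the donor without photon emission, since transfer quenches the
donor regardless of acceptor fate.

Geometries: pair, equilateral triangle, square (diagonals d√2) for
N = 2, 3, 4 with nearest-neighbour spacing d. These arrangements are
assumptions of this package; any symmetric distance matrix can be
supplied instead.

## Provenance of the rate table

The rate constants are a *reconstruction*: magnitudes follow the Cy5 /
dSTORM photophysics literature where stated (excitation conditions,
buffer composition, detection chain, the 0.999 geminate-recombination
probability, the 1e-4 OET recycle efficiency, the 1e9 s⁻¹
radical-transfer rate at 3 nm), and the remaining freedom — the split of
the S1 budget, the PET branch probabilities, the OET reference rate and
the radical re-oxidation rate — was calibrated once so that the
simulated fluorescence lifetimes of the reference conditions reproduce
the published benchmark values (1.69 ns without energy transfer, 1.63 ns
with the standard pathways at 3 nm, 0.72/1.07 ns for the
radical-transfer variant with four/two dyes). Two caveats follow from
that calibration. First, the spectral-overlap relation that would place
the OFF-acceptor transfer at five times the R-acceptor transfer is
satisfied (5e9 vs 1e9), but this was recovered by calibration, not
imposed. Second, the triplet yield implied by kISC = 2e7 (~3%) is high
for free Cy5; it stands in for all OFF-formation routes so that the dark
state dominates the duty cycle as in real dSTORM imaging.

## Desk-scale time compression

Wet-lab dSTORM runs for hundreds of seconds with OFF lifetimes of
seconds and bleaching over minutes. To keep simulated experiments within
seconds-to-a-minute of simulated time (10⁶–10⁹ jumps), the slow rates
are uniformly faster than wet-lab values: OFF recovery 0.2 s⁻¹, R
re-oxidation 4130 s⁻¹, photobleaching 880 s⁻¹ from T1. The quantities
this package reports — pooled fluorescence lifetimes, duty-cycle-driven
fingerprint orderings, occupancy distributions — depend on rate *ratios*
(duty cycles, branch probabilities), not on the absolute OFF-state
timescale, so the compression changes run time, not conclusions.
Fingerprint ensembles use 60 s windows in which bleaching completes at
short distances and the OFF state dominates at 9 nm.

## Fingerprint analysis

The photoswitching fingerprint is the empirical CDF of detected photon
arrival times over the observation window. The analytical model is a
mixture of window-truncated exponentials,

F(t) = Σ_m w_m (1 − e^(−k_m (t−t0))) / (1 − e^(−k_m (T−t0))),

whose k → 0 component degenerates to the uniform (linear) term; it is
fitted by bounded least squares on the eCDF sampled on a uniform time
grid (so the objective approximates ∫(F̂−F)² dt), with multistart rates
{1, 10, 100}/T. A linear eCDF indicates no photobleaching within the
window; an early steep rise indicates an increased global bleaching
rate. Ensemble estimates pool the photon times of 25 runs per fit
(combining time series, as is standard for this analysis) and report the
median across pools; per-run fits of bleach-out cascades are strongly
bimodal (fast cascade + slow lone-survivor tail) and their median is not
a stable estimator.

## Second-order coherence

g²(0) is measured from the histogram of photon-pair delays in windows of
0.1 ns (short against the antibunching recovery time 1/(kEXC + k_S1) ≈
1.7 ns), normalised by the mean pair count over a reference band of
delays in the upper half of the 20 ns histogram — long enough for the
antibunching dip to recover, short enough that blinking modulates the
zero bin and the reference band identically and cancels. Normalising by
the global mean rate instead would multiply g²(0) by the inverse duty
cycle of a blinking emitter and destroy the single-emitter g²(0) ≈ 0
limit; the reference band estimates the same uncorrelated expectation
locally. A small positive bias of order w/(2·1.7 ns) ≈ 0.03 remains
because the window has finite width.

## Correlation analysis

The multiple-tau estimator evaluates G(τ) = ⟨I(t)I(t+τ)⟩/⟨I(t)⟩⟨I(t+τ)⟩ − 1
with 2m linear lags at the base binning and m further lags per octave
after successive pairwise coarsening, with symmetric (per-lag) mean
normalisation. Its oracle is the direct correlator at the same lags;
values agree exactly at base-resolution lags and within coarsening error
at octave lags.

## Numerical choices

- Exact Gillespie simulation on the composite state space (7^N ≤ 2401
  states); transitions stored in CSR-like arrays, kernels compiled with
  numba, randomness from NumPy PCG-64 generators. Ensembles spawn
  independent child streams from one master seed (SeedSequence.spawn),
  so results are reproducible and independent of execution order.
- Chains start with all fluorophores in S0. Stop criteria: absorption in
  all-bleached, then t_max, then max-step budget; the reason is recorded.
- The stationary distribution solves πQ = 0 by dense linear algebra with
  a normalisation row replacement, restricted to the unique recurrent
  communicating class (strongly connected components of the positive-rate
  graph, optionally after a reachability pass from the initial state —
  the product space contains disconnected subspaces, e.g. bleached
  states when bleaching is disabled).
- Dwell statistics are accumulated in a streaming kernel (count, sum,
  sum of squares per fluorophore, plus a bounded sample buffer), so
  lifetime estimates scale to 10⁸–10⁹ jumps without storing trajectories.
- Uniformity checks of pooled arrival times discard a 20 s burn-in
  (chains start synchronised in the ON state) and evaluate the KS
  statistic on a random subsample sparse against the ON-burst
  structure, so the i.i.d. assumption of the test holds effectively.

## What the generator does and does not emulate

Synthetic fixtures (homogeneous Poisson streams, two-state telegraph
emitters, window-truncated exponential arrival times) have closed-form
statistics and serve as oracles for the analysis stack. The simulation
itself emulates photophysics, not instruments: no point-spread function,
localisation fitting, EMCCD gain conversion, drift, or structured
background; detection is Bernoulli thinning plus Poisson dark counts and
frame binning. Passing tests therefore validate the photophysical model
and the estimators, not camera artefacts of real data.

## Known limitations

- N ≤ 4 fluorophores (the product space grows as 7^N).
- The rate table is a calibrated reconstruction, not a literature
  compilation; absolute slow-state timescales are deliberately
  compressed (see above).
- The radical cation, homo-FRET, a second chemically distinct OFF
  isomer, and phosphorescence-donor transfers are outside the model.
- Fluorescence lifetimes are chain-internal quantities; no
  instrument-response convolution is applied.
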