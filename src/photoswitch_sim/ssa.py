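"""Exact stochastic simulation (Gillespie) of composite photophysical models.

Two execution modes share one compiled kernel family:

- :func:`simulate_chain` records the full event list (time, composite state,
  transition) — the natural object for small and medium runs;
- :func:`simulate_stats` streams over the chain and keeps only aggregate
  statistics (state occupancy, transition counts, photon emission times,
  fluorescence-terminated S1 dwell times), which scales to 10^8 jumps
  without storing the trajectory.

Randomness comes from NumPy PCG-64 generators; ensembles spawn independent
child streams from a master seed, so results are reproducible and
independent of scheduling order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .model import CompositeModel, FluorState

__all__ = [
    "Chain",
    "SimStats",
    "EnsembleResult",
    "simulate_chain",
    "simulate_stats",
    "run_ensemble",
    "spawn_seeds",
]

STOP_ABSORBED = 0
STOP_TMAX = 1
STOP_MAXSTEPS = 2
STOP_BUFFER = 3
_STOP_NAMES = {0: "absorbed", 1: "t_max", 2: "max_steps", 3: "buffer_full"}


class _Kinetics:
    """Flat transition arrays sorted by source state, for the kernels."""

    def __init__(self, model: CompositeModel):
        perm = np.argsort(model.src, kind="stable")
        self.perm = perm.astype(np.int64)
        self.src = model.src[perm]
        self.dst = model.dst[perm]
        self.rate = model.rate[perm]
        self.is_flu = model.is_flu[perm]
        self.actor = model.actor[perm]
        counts = np.bincount(self.src, minlength=model.n_states)
        self.indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.exit_rate = np.zeros(model.n_states)
        np.add.at(self.exit_rate, self.src, self.rate)
        self.states = np.ascontiguousarray(model.states)
        self.n_fluor = model.n_fluor

    def unsort_counts(self, counts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(counts)
        out[self.perm] = counts
        return out


def _kinetics(model: CompositeModel) -> _Kinetics:
    kin = getattr(model, "_kinetics_cache", None)
    if kin is None:
        kin = _Kinetics(model)
        model._kinetics_cache = kin
    return kin


@njit(cache=True)
def _kernel_events(gen, indptr, dst, rate, exit_rate, state0, t0, t_max, max_steps,
                   times, states, trans):
    cap = times.shape[0]
    cur = state0
    t = t0
    n = 0
    stop = STOP_MAXSTEPS
    while n < max_steps:
        total = exit_rate[cur]
        if total <= 0.0:
            stop = STOP_ABSORBED
            break
        t = t - np.log(1.0 - gen.random()) / total
        if t > t_max:
            t = t_max
            stop = STOP_TMAX
            break
        if n >= cap:
            stop = STOP_BUFFER
            break
        pick = gen.random() * total
        lo = indptr[cur]
        hi = indptr[cur + 1]
        acc = 0.0
        k = lo
        for k in range(lo, hi):
            acc += rate[k]
            if pick < acc:
                break
        cur = dst[k]
        times[n] = t
        states[n] = cur
        trans[n] = k
        n += 1
    return n, cur, t, stop


@njit(cache=True)
def _kernel_stats(gen, indptr, dst, rate, exit_rate, is_flu, actor, state_table,
                  state0, t0, t_max, max_steps,
                  occ_time, trans_count,
                  photon_times, photon_emitter,
                  dwell_samples, entry_time, dwell_acc):
    """Streaming Gillespie: accumulates occupancy, transition counts, photon
    times and fluorescence-terminated S1 dwell statistics.

    dwell_acc rows per fluorophore: [count, sum, sum of squares].
    Returns (steps, final state, final time, number of photons,
    number of stored dwell samples, stop reason).
    """
    S1 = 1
    n_fluor = state_table.shape[1]
    p_cap = photon_times.shape[0]
    d_cap = dwell_samples.shape[0]
    cur = state0
    t = t0
    n_photon = 0
    n_dwell = 0
    steps = 0
    stop = STOP_MAXSTEPS
    while steps < max_steps:
        total = exit_rate[cur]
        if total <= 0.0:
            stop = STOP_ABSORBED
            break
        dt = -np.log(1.0 - gen.random()) / total
        if t + dt > t_max:
            occ_time[cur] += t_max - t
            t = t_max
            stop = STOP_TMAX
            break
        occ_time[cur] += dt
        t = t + dt
        pick = gen.random() * total
        lo = indptr[cur]
        hi = indptr[cur + 1]
        acc = 0.0
        k = lo
        for k in range(lo, hi):
            acc += rate[k]
            if pick < acc:
                break
        nxt = dst[k]
        trans_count[k] += 1
        emitted = is_flu[k]
        if emitted:
            if n_photon < p_cap:
                photon_times[n_photon] = t
                photon_emitter[n_photon] = actor[k]
            n_photon += 1
        for i in range(n_fluor):
            old = state_table[cur, i]
            new = state_table[nxt, i]
            if old == new:
                continue
            if old == S1:
                if emitted and actor[k] == i:
                    dwell = t - entry_time[i]
                    dwell_acc[i, 0] += 1.0
                    dwell_acc[i, 1] += dwell
                    dwell_acc[i, 2] += dwell * dwell
                    if n_dwell < d_cap:
                        dwell_samples[n_dwell] = dwell
                        n_dwell += 1
            if new == S1:
                entry_time[i] = t
        cur = nxt
        steps += 1
        if emitted and p_cap > 0 and n_photon >= p_cap:
            stop = STOP_BUFFER
            break
    return steps, cur, t, n_photon, n_dwell, stop


@dataclass
class Chain:
    """One realised trajectory of a composite model.

    ``times``/``states``/``transitions`` describe the jump at each event:
    the composite state *after* the jump and the index of the fired
    transition into ``model.transitions``.
    """

    model: CompositeModel
    times: np.ndarray
    states: np.ndarray
    transitions: np.ndarray
    t_end: float
    seed: int
    stop_reason: str

    def __len__(self) -> int:
        return len(self.times)

    @property
    def state_sequence(self) -> np.ndarray:
        """Composite state indices including the initial state."""
        return np.concatenate(([self.model.initial_state], self.states))

    def fluor_states(self) -> np.ndarray:
        """(n_events + 1, N) per-fluorophore state codes over time."""
        return self.model.states[self.state_sequence]

    def photon_times(self) -> np.ndarray:
        mask = self.model.is_flu[self.transitions]
        return self.times[mask]

    def photon_emitters(self) -> np.ndarray:
        mask = self.model.is_flu[self.transitions]
        return self.model.actor[self.transitions[mask]]

    def to_dataframe(self):
        import pandas as pd

        labels = [self.model.transitions[i].label for i in self.transitions]
        return pd.DataFrame(
            {
                "time": self.times,
                "state": [self.model.state_label(s) for s in self.states],
                "transition": labels,
            }
        )

    def save(self, prefix) -> None:
        """Write the event list as ``<prefix>.csv`` plus a ``<prefix>.json``
        sidecar holding the run metadata (seed, stop reason, system size)."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.to_dataframe().to_csv(prefix.with_suffix(".csv"), index=False,
                                   float_format="%.9e")
        sidecar = {
            "n_fluor": self.model.n_fluor,
            "n_events": len(self),
            "t_end": self.t_end,
            "seed": self.seed,
            "stop_reason": self.stop_reason,
            "bleaching_enabled": self.model.spec.bleaching_enabled,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class SimStats:
    """Aggregate output of a streaming simulation."""

    model: CompositeModel
    occupancy_time: np.ndarray      # seconds spent per composite state
    transition_counts: np.ndarray   # firings per transition (model ordering)
    photon_times: np.ndarray
    photon_emitters: np.ndarray
    dwell_samples: np.ndarray       # first recorded FLU-terminated S1 dwells
    dwell_count: np.ndarray         # per fluorophore
    dwell_sum: np.ndarray
    dwell_sumsq: np.ndarray
    steps: int
    t_end: float
    seed: int
    stop_reason: str

    @property
    def tau_flu(self) -> float:
        """Pooled mean S1 dwell time over dwells that ended in fluorescence."""
        total = self.dwell_count.sum()
        if total == 0:
            raise ValueError("no fluorescence-terminated S1 dwells recorded")
        return float(self.dwell_sum.sum() / total)

    @property
    def occupancy(self) -> np.ndarray:
        tot = self.occupancy_time.sum()
        return self.occupancy_time / tot if tot > 0 else self.occupancy_time


def _generator(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def simulate_chain(
    model: CompositeModel,
    t_max: float,
    max_steps: int,
    seed: int | np.random.SeedSequence,
) -> Chain:
    """Exact Gillespie simulation recording every jump.

    The chain starts with all fluorophores in S0 and stops at absorption
    (all bleached), at ``t_max`` or after ``max_steps`` jumps, whichever
    comes first.  Identical seeds give identical chains.
    """
    kin = _kinetics(model)
    gen = _generator(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    start = model.initial_state
    if kin.exit_rate[start] <= 0.0:
        import warnings

        warnings.warn("initial state is absorbing; returning an empty chain")
        return Chain(model, np.empty(0), np.empty(0, np.int32), np.empty(0, np.int64),
                     0.0, seed_int, "absorbed")
    chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    cap = int(min(max_steps, 4_000_000))
    cur, t, done = start, 0.0, 0
    while True:
        times = np.empty(cap)
        states = np.empty(cap, np.int32)
        trans = np.empty(cap, np.int64)
        n, cur, t, stop = _kernel_events(
            gen, kin.indptr, kin.dst, kin.rate, kin.exit_rate,
            cur, t, float(t_max), max_steps - done, times, states, trans,
        )
        chunks.append((times[:n], states[:n], trans[:n]))
        done += n
        if stop != STOP_BUFFER:
            break
    times = np.concatenate([c[0] for c in chunks])
    states = np.concatenate([c[1] for c in chunks])
    trans = kin.perm[np.concatenate([c[2] for c in chunks])]
    return Chain(model, times, states, trans, float(t), seed_int, _STOP_NAMES[stop])


def simulate_stats(
    model: CompositeModel,
    t_max: float,
    max_steps: int,
    seed: int | np.random.SeedSequence,
    *,
    photon_capacity: int = 0,
    dwell_capacity: int = 0,
) -> SimStats:
    """Streaming Gillespie simulation (no trajectory storage).

    ``photon_capacity`` > 0 records up to that many photon emission times;
    the buffer grows automatically if it fills before another stop
    condition. ``dwell_capacity`` stores individual fluorescence-terminated
    S1 dwell times (their count/mean/variance are always accumulated).
    """
    kin = _kinetics(model)
    gen = _generator(seed)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    n_states, n_fluor = model.n_states, model.n_fluor
    occ = np.zeros(n_states)
    tcount = np.zeros(len(kin.rate), np.int64)
    dwell_samples = np.empty(max(dwell_capacity, 0))
    dwell_acc = np.zeros((n_fluor, 3))
    entry = np.zeros(n_fluor)
    photon_chunks: list[np.ndarray] = []
    emitter_chunks: list[np.ndarray] = []
    dwell_chunks: list[np.ndarray] = []
    cap = max(photon_capacity, 0)
    cur, t, done = model.initial_state, 0.0, 0
    while True:
        ptimes = np.empty(cap)
        pemit = np.empty(cap, np.int8)
        steps, cur, t, n_ph, n_dw, stop = _kernel_stats(
            gen, kin.indptr, kin.dst, kin.rate, kin.exit_rate, kin.is_flu,
            kin.actor, kin.states, cur, t, float(t_max), max_steps - done,
            occ, tcount, ptimes, pemit, dwell_samples, entry, dwell_acc,
        )
        done += steps
        photon_chunks.append(ptimes[: min(n_ph, cap)])
        emitter_chunks.append(pemit[: min(n_ph, cap)])
        dwell_chunks.append(dwell_samples[:n_dw].copy())
        dwell_samples = dwell_samples[n_dw:]
        if stop != STOP_BUFFER:
            break
        cap = max(2 * cap, 1024)
    photons = np.concatenate(photon_chunks) if photon_chunks else np.empty(0)
    emitters = np.concatenate(emitter_chunks) if emitter_chunks else np.empty(0, np.int8)
    dwells = np.concatenate(dwell_chunks) if dwell_chunks else np.empty(0)
    return SimStats(
        model=model,
        occupancy_time=occ,
        transition_counts=kin.unsort_counts(tcount),
        photon_times=photons,
        photon_emitters=emitters,
        dwell_samples=dwells,
        dwell_count=dwell_acc[:, 0].astype(np.int64),
        dwell_sum=dwell_acc[:, 1].copy(),
        dwell_sumsq=dwell_acc[:, 2].copy(),
        steps=done,
        t_end=float(t),
        seed=seed_int,
        stop_reason=_STOP_NAMES[stop],
    )


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent child seed sequences derived from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


@dataclass
class EnsembleResult:
    """Chains (or streamed statistics) from independent repeat simulations."""

    runs: list
    master_seed: int

    def __len__(self) -> int:
        return len(self.runs)

    def pooled_photon_times(self) -> np.ndarray:
        times = [
            r.photon_times() if isinstance(r, Chain) else r.photon_times
            for r in self.runs
        ]
        return np.sort(np.concatenate(times)) if times else np.empty(0)


def run_ensemble(
    model: CompositeModel,
    n_runs: int,
    t_max: float,
    master_seed: int,
    *,
    max_steps: int = 10_000_000,
    mode: str = "chain",
    photon_capacity: int = 0,
    dwell_capacity: int = 0,
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations of the same model.

    Each run gets its own PCG-64 stream spawned from ``master_seed``; the
    ensemble is therefore reproducible and order-independent.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = spawn_seeds(master_seed, n_runs)
    runs = []
    for s in seeds:
        if mode == "chain":
            runs.append(simulate_chain(model, t_max, max_steps, s))
        elif mode == "stats":
            runs.append(
                simulate_stats(
                    model, t_max, max_steps, s,
                    photon_capacity=photon_capacity,
                    dwell_capacity=dwell_capacity,
                )
            )
        else:
            raise ValueError("mode must be 'chain' or 'stats'")
    return EnsembleResult(runs=runs, master_seed=master_seed)
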