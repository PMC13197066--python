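"""Deterministic predictions from the generator matrix of the photophysical
chain: stationary (limiting) distribution, embedded-jump-chain occurrence
probabilities, state lifetimes and transition recurrence times.

These are the closed-form counterparts of the empirical per-state and
per-transition statistics measured from simulated chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ReducibleChainError",
    "recurrent_class",
    "stationary_distribution",
    "state_statistics",
    "transition_statistics",
    "dwell_rate",
    "state_report",
    "transition_report",
]


class ReducibleChainError(ValueError):
    """Raised when the chain has several recurrent communicating classes."""


def _check_generator(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-6 * max(1.0, np.max(np.abs(Q))):
        raise ValueError("row sums of a generator matrix must vanish")
    return Q


def recurrent_class(Q: np.ndarray, initial: int | None = None) -> np.ndarray:
    """Indices of the unique recurrent communicating class of ``Q``.

    Transient states (e.g. the unreachable corners of the product state
    space, or everything outside an absorbing bleached state) are dropped.
    With ``initial`` given, only states reachable from it are considered;
    otherwise states with neither incoming nor outgoing transitions are
    ignored.  If more than one recurrent class remains the chain has no
    unique stationary distribution and a :class:`ReducibleChainError`
    names them.
    """
    Q = _check_generator(Q)
    n = Q.shape[0]
    adj = (np.abs(Q) > 0) & ~np.eye(n, dtype=bool)
    if initial is not None:
        from scipy.sparse.csgraph import breadth_first_order

        reach = breadth_first_order(csr_matrix(adj), initial, return_predecessors=False)
        keep_mask = np.zeros(n, dtype=bool)
        keep_mask[reach] = True
    else:
        keep_mask = adj.any(axis=0) | adj.any(axis=1)
        if not keep_mask.any():
            raise ValueError("chain has no transitions at all")
    sub = np.flatnonzero(keep_mask)
    graph = csr_matrix(adj[np.ix_(sub, sub)])
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # a strongly connected component is recurrent iff it has no edge leaving it
    has_exit = np.zeros(n_comp, dtype=bool)
    src, dst = graph.nonzero()
    leaving = labels[src] != labels[dst]
    has_exit[labels[src[leaving]]] = True
    recurrent = [c for c in range(n_comp) if not has_exit[c]]
    if len(recurrent) != 1:
        members = {c: sub[np.flatnonzero(labels == c)].tolist() for c in recurrent}
        raise ReducibleChainError(
            f"chain has {len(recurrent)} recurrent classes: {members}"
        )
    return sub[np.flatnonzero(labels == recurrent[0])]


def stationary_distribution(
    Q: np.ndarray, *, restrict: bool = True, initial: int | None = None
) -> np.ndarray:
    """Stationary probability vector pi with pi Q = 0 and sum(pi) = 1.

    With ``restrict`` (default) the distribution is computed on the unique
    recurrent class and zero-padded back onto the full state space.
    """
    Q = _check_generator(Q)
    n = Q.shape[0]
    if restrict:
        keep = recurrent_class(Q, initial)
    else:
        keep = np.arange(n)
    Qr = Q[np.ix_(keep, keep)]
    m = len(keep)
    # solve pi Qr = 0 with the normalisation replacing one equation
    A = Qr.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi_r = np.linalg.solve(A, b)
    pi_r = np.clip(pi_r, 0.0, None)
    pi_r /= pi_r.sum()
    pi = np.zeros(n)
    pi[keep] = pi_r
    return pi


def dwell_rate(Q: np.ndarray, state: int) -> float:
    """Exponential rate parameter of the dwell time in ``state`` (= total
    exit rate |Q_ss|)."""
    Q = _check_generator(Q)
    rate = -Q[state, state]
    if rate <= 0:
        raise ValueError(f"state {state} is absorbing; dwell time is infinite")
    return float(rate)


@dataclass
class StateStatistics:
    """Per-state predictions matching the empirical chain statistics:

    - ``occurrence``: stationary distribution of the embedded jump chain
      (how often a state is visited);
    - ``lifetime``: mean dwell time 1/|Q_ss| per visit (inf if absorbing);
    - ``occupation``: long-run fraction of time spent in the state (the
      limiting distribution pi).
    """

    occurrence: np.ndarray
    lifetime: np.ndarray
    occupation: np.ndarray


def state_statistics(Q: np.ndarray, *, initial: int | None = None) -> StateStatistics:
    Q = _check_generator(Q)
    pi = stationary_distribution(Q, initial=initial)
    exit_rates = -np.diag(Q)
    with np.errstate(divide="ignore"):
        lifetime = np.where(exit_rates > 0, 1.0 / np.where(exit_rates > 0, exit_rates, 1.0), np.inf)
    # embedded-chain visit frequency: nu_i proportional to pi_i * |Q_ii|
    nu = pi * exit_rates
    total = nu.sum()
    if total <= 0:
        raise ValueError("chain has no transitions in its recurrent class")
    return StateStatistics(occurrence=nu / total, lifetime=lifetime, occupation=pi)


@dataclass
class TransitionStatistics:
    """Per-transition predictions.

    - ``occurrence``: long-run fraction of jumps using each transition;
    - ``recurrence_time``: mean time between successive firings,
      1 / (pi_i * Q_ij);
    - ``rate``: long-run firing rate pi_i * Q_ij (per second).

    ``source``/``target`` give the state indices of each listed transition.
    """

    source: np.ndarray
    target: np.ndarray
    occurrence: np.ndarray
    recurrence_time: np.ndarray
    rate: np.ndarray


def transition_statistics(Q: np.ndarray, *, initial: int | None = None) -> TransitionStatistics:
    Q = _check_generator(Q)
    pi = stationary_distribution(Q, initial=initial)
    off = Q - np.diag(np.diag(Q))
    src, dst = np.nonzero(off > 0)
    flux = pi[src] * off[src, dst]
    total = flux.sum()
    if total <= 0:
        raise ValueError("no transitions fire in the recurrent class")
    with np.errstate(divide="ignore"):
        recurrence = np.where(flux > 0, 1.0 / np.where(flux > 0, flux, 1.0), np.inf)
    return TransitionStatistics(
        source=src,
        target=dst,
        occurrence=flux / total,
        recurrence_time=recurrence,
        rate=flux,
    )


def state_report(model) -> "pandas.DataFrame":
    """Per-state statistics table (occurrence, mean lifetime, occupation)
    for a composite model, restricted to its reachable recurrent class."""
    import pandas as pd

    stats = state_statistics(model.rate_matrix(), initial=model.initial_state)
    live = stats.occupation > 0
    idx = np.flatnonzero(live)
    return pd.DataFrame(
        {
            "state": [model.state_label(i) for i in idx],
            "occurrence": stats.occurrence[idx],
            "lifetime_s": stats.lifetime[idx],
            "occupation": stats.occupation[idx],
        }
    )


def transition_report(model) -> "pandas.DataFrame":
    """Per-transition statistics table (occurrence probability and mean
    recurrence time).  Parallel channels that share source and target
    states (e.g. radiative and non-radiative S1 -> S0) are reported under
    their combined generator entry."""
    import pandas as pd

    stats = transition_statistics(model.rate_matrix(), initial=model.initial_state)
    labels = []
    for k in range(len(stats.source)):
        kinds = sorted(
            {t.kind for t in model.transitions
             if t.source == stats.source[k] and t.target == stats.target[k]}
        )
        labels.append(
            f"{model.state_label(stats.source[k])}->{model.state_label(stats.target[k])}"
            f" ({'+'.join(kinds)})"
        )
    return pd.DataFrame(
        {
            "transition": labels,
            "occurrence": stats.occurrence,
            "recurrence_time_s": stats.recurrence_time,
            "rate_per_s": stats.rate,
        }
    )
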