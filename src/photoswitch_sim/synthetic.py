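"""Synthetic trace generators with closed-form statistics.

These streams (homogeneous Poisson, two-state telegraph emission,
window-truncated exponential arrival times) are the analytical oracles for
the analysis stack: their correlation functions, duty cycles and arrival
CDFs are known exactly.
"""

from __future__ import annotations

import numpy as np

from .detection import FrameTrace, PhotonTrace

__all__ = [
    "poisson_photons",
    "telegraph_photons",
    "telegraph_frames",
    "truncated_exponential_times",
    "generate_synthetic_trace",
]


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def poisson_photons(rate: float, T: float, seed) -> PhotonTrace:
    """Homogeneous Poisson photon stream of the given rate on [0, T)."""
    if rate < 0 or T <= 0:
        raise ValueError("rate must be >= 0 and T > 0")
    rng = _rng(seed)
    n = rng.poisson(rate * T)
    return PhotonTrace(times=np.sort(rng.uniform(0.0, T, size=n)))


def _telegraph_states(k_on: float, k_off: float, T: float, rng):
    """(start, end, is_on) intervals of a stationary two-state telegraph.

    ``k_on`` is the OFF->ON rate and ``k_off`` the ON->OFF rate; the
    stationary ON probability is k_on / (k_on + k_off).
    """
    p_on = k_on / (k_on + k_off)
    on = rng.random() < p_on
    t = 0.0
    intervals = []
    while t < T:
        rate = k_off if on else k_on
        dwell = rng.exponential(1.0 / rate)
        end = min(t + dwell, T)
        intervals.append((t, end, on))
        t = end
        on = not on
    return intervals


def telegraph_photons(
    k_on: float, k_off: float, rate_on: float, T: float, seed
) -> PhotonTrace:
    """Photon stream of a telegraph emitter: Poisson emission at
    ``rate_on`` while ON, silent while OFF.  Duty cycle k_on/(k_on+k_off)."""
    rng = _rng(seed)
    times = []
    for start, end, on in _telegraph_states(k_on, k_off, T, rng):
        if not on:
            continue
        n = rng.poisson(rate_on * (end - start))
        times.append(rng.uniform(start, end, size=n))
    allt = np.sort(np.concatenate(times)) if times else np.empty(0)
    return PhotonTrace(times=allt)


def telegraph_frames(
    k_on: float, k_off: float, rate_on: float, T: float, frame_time: float,
    seed, threshold: int = 1,
) -> FrameTrace:
    """Frame-binned telegraph emission (no detection losses)."""
    tr = telegraph_photons(k_on, k_off, rate_on, T, seed)
    n_frames = int(np.ceil(T / frame_time))
    idx = np.minimum((tr.times / frame_time).astype(np.int64), n_frames - 1)
    counts = np.bincount(idx, minlength=n_frames)
    return FrameTrace(counts=counts, frame_time=frame_time, threshold=threshold)


def truncated_exponential_times(k_b: float, T: float, n_events: int, seed) -> np.ndarray:
    """Event times with density k_b exp(-k_b t) truncated to [0, T],
    sampled by inverse CDF.  Mean event time: 1/k_b - T exp(-k_b T) /
    (1 - exp(-k_b T))."""
    if k_b <= 0 or T <= 0:
        raise ValueError("k_b and T must be positive")
    rng = _rng(seed)
    u = rng.random(n_events)
    times = -np.log1p(u * np.expm1(-k_b * T)) / k_b
    return np.sort(times)


def generate_synthetic_trace(kind: str, params: dict, seed):
    """Dispatch on ``kind`` in {poisson, telegraph, truncated_exponential}."""
    if kind == "poisson":
        return poisson_photons(params["rate"], params["T"], seed)
    if kind == "telegraph":
        if "frame_time" in params:
            return telegraph_frames(
                params["k_on"], params["k_off"], params["rate_on"], params["T"],
                params["frame_time"], seed, params.get("threshold", 1),
            )
        return telegraph_photons(
            params["k_on"], params["k_off"], params["rate_on"], params["T"], seed
        )
    if kind == "truncated_exponential":
        return PhotonTrace(
            times=truncated_exponential_times(params["k_b"], params["T"],
                                              params["n_events"], seed)
        )
    raise ValueError(f"unknown synthetic trace kind {kind!r}")
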