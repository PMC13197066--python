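"""Experiment-style analyses of photon and frame traces.

Covers the photoswitching-fingerprint analysis (empirical CDF of photon
arrival times and its global-bleaching-rate fit), multiple-tau fluorescence
correlation, second-order coherence g2, ON/OFF blinking histograms and
fluorescence lifetime estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .detection import BlinkPeriods, FrameTrace, PhotonTrace
from .model import FluorState

__all__ = [
    "EcdfFit",
    "CorrelationCurve",
    "CoincidenceResult",
    "LifetimeEstimate",
    "pfa_ecdf",
    "pfa_model_cdf",
    "fit_pfa_model",
    "multiple_tau_correlation",
    "direct_correlation",
    "second_order_coherence",
    "lifetime_from_chain",
    "pooled_lifetime",
    "histogram_suite",
]


# ---------------------------------------------------------------------------
# Photoswitching fingerprint analysis (PFA)
# ---------------------------------------------------------------------------

@dataclass
class EcdfFit:
    """Empirical CDF of event times on a window, with optional fitted
    global-bleaching model parameters."""

    times: np.ndarray           # sorted event times inside the window
    values: np.ndarray          # eCDF at each time, ending at 1
    t_start: float              # truncation start t0
    t_end: float                # observation window end T
    weights: np.ndarray | None = None
    rates: np.ndarray | None = None
    residual: float | None = None
    converged: bool | None = None

    @property
    def dominant_rate(self) -> float:
        """Fitted bleach rate of the heaviest mixture component."""
        if self.rates is None:
            raise ValueError("fit_pfa_model has not been run")
        return float(self.rates[int(np.argmax(self.weights))])


def pfa_ecdf(event_times, truncate_start: float = 0.0, T: float | None = None) -> EcdfFit:
    """Empirical CDF of pooled event times within [truncate_start, T].

    A linear eCDF marks a stationary (bleaching-free) emitter; curvature
    toward early times is the photoswitching fingerprint of an increased
    global bleaching rate.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    if T is None:
        T = float(t[-1]) if len(t) else 0.0
    if not T > truncate_start >= 0:
        raise ValueError("need T > truncate_start >= 0")
    t = t[(t >= truncate_start) & (t <= T)]
    if len(t) == 0:
        raise ValueError("no events inside the observation window")
    values = np.arange(1, len(t) + 1, dtype=float) / len(t)
    return EcdfFit(times=t, values=values, t_start=float(truncate_start), t_end=float(T))


def pfa_model_cdf(t, weights, rates, t_start: float, t_end: float) -> np.ndarray:
    """Analytical arrival-time CDF: mixture of exponentials truncated to the
    observation window,

        F(t) = sum_m w_m (1 - exp(-k_m (t - t0))) / (1 - exp(-k_m (T - t0)))

    where a component with k_m -> 0 degenerates to the uniform (linear)
    term (t - t0) / (T - t0).
    """
    t = np.asarray(t, dtype=float)
    u = t - t_start
    span = t_end - t_start
    w = np.asarray(weights, dtype=float)
    k = np.asarray(rates, dtype=float)
    out = np.zeros_like(u)
    for wm, km in zip(w, k):
        if km * span < 1e-9:
            out = out + wm * u / span
        else:
            out = out + wm * np.expm1(-km * u) / math.expm1(-km * span)
    return out


def _ecdf_grid(ecdf: EcdfFit, n_grid: int):
    """Evaluation points for fitting: the empirical CDF sampled on a uniform
    time grid over the observation window, so the least-squares objective
    approximates the integrated squared CDF distance rather than weighting
    by event density."""
    t = np.linspace(ecdf.t_start, ecdf.t_end, n_grid)
    y = np.searchsorted(ecdf.times, t, side="right") / len(ecdf.times)
    return t, y


def fit_pfa_model(ecdf: EcdfFit, n_components: int = 1, *, n_grid: int = 512) -> EcdfFit:
    """Bounded least-squares fit of the truncated-exponential mixture to the
    eCDF, with multistart initial rates spread over {1/T, 10/T, 100/T}.

    Mixture weights are optimised on the simplex (normalised internally);
    rates are bounded below at zero, so a component may pin to the uniform
    limit.  The fitted parameters are written back onto ``ecdf`` and the
    same object is returned.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t, y = _ecdf_grid(ecdf, n_grid)
    span = ecdf.t_end - ecdf.t_start
    m = n_components

    def unpack(theta):
        k = theta[:m]
        if m == 1:
            w = np.ones(1)
        else:
            raw = np.clip(theta[m:], 1e-12, None)
            w = raw / raw.sum()
        return w, k

    def resid(theta):
        w, k = unpack(theta)
        return pfa_model_cdf(t, w, k, ecdf.t_start, ecdf.t_end) - y

    base_inits = np.array([1.0, 10.0, 100.0]) / span
    best = None
    for start in base_inits:
        k0 = start * np.logspace(0, m - 1, m)
        theta0 = np.concatenate([k0, np.full(m, 1.0 / m)]) if m > 1 else k0
        lb = np.concatenate([np.zeros(m), np.full(m, 1e-9)]) if m > 1 else np.zeros(m)
        ub = np.concatenate([np.full(m, np.inf), np.ones(m)]) if m > 1 else np.full(m, np.inf)
        sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    w, k = unpack(best.x)
    order = np.argsort(k)
    ecdf.weights, ecdf.rates = w[order], k[order]
    ecdf.residual = float(np.sqrt(2.0 * best.cost / len(t)))
    ecdf.converged = bool(best.success)
    return ecdf


# ---------------------------------------------------------------------------
# Fluorescence correlation (multiple tau)
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCurve:
    """Normalised autocorrelation G(tau) on a quasi-logarithmic lag grid."""

    lags: np.ndarray   # seconds, strictly increasing
    G: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def _as_intensity(trace, bin_time: float | None):
    if isinstance(trace, FrameTrace):
        return trace.counts.astype(float), trace.frame_time
    if isinstance(trace, PhotonTrace):
        if bin_time is None:
            raise ValueError("photon input requires bin_time")
        n_bins = int(np.ceil(trace.times[-1] / bin_time)) if len(trace) else 0
        if n_bins < 4:
            raise ValueError("trace too short to correlate")
        idx = np.minimum((trace.times / bin_time).astype(np.int64), n_bins - 1)
        return np.bincount(idx, minlength=n_bins).astype(float), bin_time
    x = np.asarray(trace, dtype=float)
    if bin_time is None:
        raise ValueError("raw intensity input requires bin_time")
    return x, bin_time


def _corr_at_lag(x: np.ndarray, lag: int) -> float:
    """Symmetrically normalised correlator at an integer lag."""
    a = x[:-lag] if lag else x
    b = x[lag:] if lag else x
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        return np.nan
    return float((a * b).mean() / (ma * mb) - 1.0)


def multiple_tau_correlation(trace, m: int = 16, *, bin_time: float | None = None,
                             max_levels: int | None = None) -> CorrelationCurve:
    """Multiple-tau autocorrelation G(tau) = <dI(t) dI(t+tau)> / <I>^2.

    The first 2*m lags are evaluated at the base bin width; the trace is
    then repeatedly coarsened by summing pairs of bins, adding m lags per
    octave.  Mean intensity must be positive.
    """
    x, dt = _as_intensity(trace, bin_time)
    if x.mean() <= 0:
        raise ValueError("trace has non-positive mean intensity")
    if len(x) < 4 * m:
        raise ValueError("trace too short for the requested lag grid")
    lags: list[float] = []
    values: list[float] = []
    for lag in range(1, 2 * m + 1):
        lags.append(lag * dt)
        values.append(_corr_at_lag(x, lag))
    level = 0
    while True:
        if len(x) < 2:
            break
        if len(x) % 2:
            x = x[:-1]
        x = x[0::2] + x[1::2]
        dt *= 2.0
        level += 1
        if max_levels is not None and level > max_levels:
            break
        if len(x) < 2 * m + 1:
            break
        for lag in range(m + 1, 2 * m + 1):
            lags.append(lag * dt)
            values.append(_corr_at_lag(x, lag))
    lags_arr = np.asarray(lags)
    vals_arr = np.asarray(values)
    ok = ~np.isnan(vals_arr)
    return CorrelationCurve(lags=lags_arr[ok], G=vals_arr[ok])


def direct_correlation(trace, lags: np.ndarray, *, bin_time: float | None = None) -> CorrelationCurve:
    """Brute-force correlator at the given lag times (oracle for the
    multiple-tau estimator; exact at lags that are multiples of the base
    bin)."""
    x, dt = _as_intensity(trace, bin_time)
    out = []
    for tau in np.asarray(lags, dtype=float):
        lag = int(round(tau / dt))
        out.append(_corr_at_lag(x, lag))
    return CorrelationCurve(lags=np.asarray(lags, dtype=float), G=np.asarray(out))


# ---------------------------------------------------------------------------
# Second-order coherence
# ---------------------------------------------------------------------------

@dataclass
class CoincidenceResult:
    """Inter-photon delay histogram and the zero-delay coherence."""

    bin_edges: np.ndarray       # seconds
    counts: np.ndarray          # photon pairs per delay bin
    g2: np.ndarray              # counts normalised to the reference level
    g2_zero: float
    window: float


def _pair_delays(times: np.ndarray, max_delay: float) -> np.ndarray:
    """Delays t_j - t_i (j > i) up to ``max_delay`` for sorted times."""
    n = len(times)
    hi = np.searchsorted(times, times + max_delay, side="right")
    starts = np.arange(1, n + 1)
    counts = np.maximum(hi - starts, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    flat = np.arange(total)
    partner = flat - np.repeat(offsets, counts) + np.repeat(starts, counts)
    return times[partner] - np.repeat(times, counts)


def second_order_coherence(
    photons: PhotonTrace,
    window: float,
    *,
    max_delay: float | None = None,
    ref_fraction: float = 0.5,
) -> CoincidenceResult:
    """Second-order coherence from the start-stop coincidence histogram.

    Photon-pair delays are histogrammed in bins of ``window`` seconds up to
    ``max_delay`` (default 100 windows).  g2 normalises each bin by the
    mean pair count over the reference band (the last ``ref_fraction`` of
    the delay range), i.e. delays long enough for the antibunching dip to
    have recovered but short against blinking, so intermittency cancels
    out.  g2_zero is the normalised count of the first bin.
    """
    if window <= 0:
        raise ValueError("coincidence window must be positive")
    if len(photons) < 2:
        raise ValueError("need at least two photons")
    if max_delay is None:
        max_delay = 100.0 * window
    delays = _pair_delays(np.asarray(photons.times, dtype=float), max_delay)
    edges = np.arange(0.0, max_delay + window, window)
    counts, _ = np.histogram(delays, bins=edges)
    n_bins = len(counts)
    ref_lo = int(n_bins * (1.0 - ref_fraction))
    ref = counts[ref_lo:].mean()
    if ref <= 0:
        raise ValueError("empty reference band; increase photons or max_delay")
    g2 = counts / ref
    return CoincidenceResult(
        bin_edges=edges, counts=counts, g2=g2, g2_zero=float(g2[0]), window=window
    )


# ---------------------------------------------------------------------------
# Fluorescence lifetimes
# ---------------------------------------------------------------------------

@dataclass
class LifetimeEstimate:
    """Mean S1 dwell time over dwells that ended with photon emission."""

    tau_flu: float        # seconds
    n_events: int
    std: float = float("nan")  # spread over repeat simulations, if pooled


def lifetime_from_chain(chain) -> LifetimeEstimate:
    """Fluorescence lifetime from a recorded chain: the mean duration of S1
    dwells whose exit transition was radiative, pooled over fluorophores.

    This readout uses only chain-internal times and is therefore invariant
    under every detection-chain parameter.
    """
    from .ssa import Chain, SimStats

    if isinstance(chain, SimStats):
        n = int(chain.dwell_count.sum())
        if n == 0:
            raise ValueError("chain contains no fluorescence events")
        return LifetimeEstimate(tau_flu=chain.tau_flu, n_events=n)
    if not isinstance(chain, Chain):
        raise TypeError("expected a Chain or SimStats")
    S1 = int(FluorState.S1)
    fs = chain.fluor_states()              # (n_events + 1, N)
    times = np.concatenate(([0.0], chain.times))
    flu_mask = chain.model.is_flu[chain.transitions]
    actor = chain.model.actor[chain.transitions]
    dwells = []
    for i in range(chain.model.n_fluor):
        s = fs[:, i].astype(np.int8)
        in_s1 = s == S1
        enter = np.flatnonzero(in_s1[1:] & ~in_s1[:-1]) + 1
        leave = np.flatnonzero(~in_s1[1:] & in_s1[:-1]) + 1
        if in_s1[0]:
            enter = np.concatenate(([0], enter))
        n_pairs = min(len(enter), len(leave))
        enter, leave = enter[:n_pairs], leave[:n_pairs]
        # the transition that produced state row k is event k-1
        via_flu = flu_mask[leave - 1] & (actor[leave - 1] == i)
        dwells.append(times[leave[via_flu]] - times[enter[via_flu]])
    pooled = np.concatenate(dwells) if dwells else np.empty(0)
    if len(pooled) == 0:
        raise ValueError("chain contains no fluorescence events")
    return LifetimeEstimate(tau_flu=float(pooled.mean()), n_events=len(pooled))


def pooled_lifetime(estimates) -> LifetimeEstimate:
    """Combine repeat simulations: event-weighted mean and the standard
    deviation of the per-run means."""
    taus = np.array([e.tau_flu for e in estimates])
    ns = np.array([e.n_events for e in estimates])
    if ns.sum() == 0:
        raise ValueError("no fluorescence events")
    mean = float(np.average(taus, weights=ns))
    std = float(np.std(taus, ddof=1)) if len(taus) > 1 else float("nan")
    return LifetimeEstimate(tau_flu=mean, n_events=int(ns.sum()), std=std)


# ---------------------------------------------------------------------------
# Blinking histograms
# ---------------------------------------------------------------------------

def _int_histogram(values, min_length: int = 0) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=np.int64)
    if len(values) == 0:
        return np.empty(0, np.int64), np.empty(0)
    counts = np.bincount(values, minlength=min_length)
    return np.arange(len(counts)), counts / counts.sum()


def histogram_suite(
    frames: FrameTrace | None = None,
    periods: BlinkPeriods | None = None,
    photons: PhotonTrace | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalised probability histograms of the standard blinking readouts
    (integer bins): photon counts per frame, ON- and OFF-period lengths,
    and the total detected photon count.

    Returns a dict mapping histogram name to (bin values, probabilities);
    each probability vector sums to one.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if frames is not None:
        out["photons_per_frame"] = _int_histogram(frames.counts)
    if periods is not None:
        out["on_periods"] = _int_histogram(periods.on_periods)
        out["off_periods"] = _int_histogram(periods.off_periods)
        out["n_on_events"] = (np.array([periods.n_on_events]), np.array([1.0]))
    if photons is not None:
        out["total_photons"] = (np.array([len(photons)]), np.array([1.0]))
    if not out:
        raise ValueError("no inputs given")
    return out
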