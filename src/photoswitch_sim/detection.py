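"""Detection chain: from emitted photons to camera-like frame traces.

The optical path is reduced to a chain of independent Bernoulli losses
(solid-angle collection, bandpass filter, mirror, two lenses, camera
quantum efficiency), followed by binning into fixed-length frames,
additive Poisson dark counts and a photon-count threshold that labels
frames ON or OFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionConfig",
    "PhotonTrace",
    "FrameTrace",
    "collection_efficiency",
    "total_detection_efficiency",
    "extract_photons",
    "apply_detection",
    "bin_frames",
    "on_off_periods",
    "BlinkPeriods",
]


def collection_efficiency(NA: float, n_medium: float) -> float:
    """Fraction of isotropically emitted photons collected by an objective
    of numerical aperture ``NA`` in a medium of refractive index
    ``n_medium``: (1 - cos(theta)) / 2 with theta = arcsin(NA / n)."""
    if NA <= 0 or n_medium <= 0:
        raise ValueError("NA and n_medium must be positive")
    if NA > n_medium:
        raise ValueError("NA cannot exceed the medium refractive index")
    theta = math.asin(NA / n_medium)
    return (1.0 - math.cos(theta)) / 2.0


@dataclass(frozen=True)
class DetectionConfig:
    """Optical and camera parameters of the simulated microscope.

    Defaults follow a high-NA TIRF setup for Cy5: NA 1.45 objective in
    n = 1.51 medium, a 665-731 nm bandpass (efficiency 0.54), a 90/100
    mirror, two lenses at 0.99 transmittance each, and an EMCCD with
    quantum efficiency 0.85 read out at 1 ms frames. Dark counts default
    to zero (Poisson noise can be switched on via ``dark_rate``,
    counts/frame).
    """

    NA: float = 1.45
    n_medium: float = 1.51
    filter_eff: float = 0.54
    mirror_eff: float = 0.90
    lens_transmittance: float = 0.99
    camera_qe: float = 0.85
    dark_rate: float = 0.0
    frame_time: float = 1e-3
    photon_threshold: int = 10
    acquisition_start: float = 0.0

    def __post_init__(self) -> None:
        for name in ("filter_eff", "mirror_eff", "lens_transmittance", "camera_qe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.photon_threshold < 0 or self.dark_rate < 0:
            raise ValueError("threshold and dark rate must be non-negative")


def total_detection_efficiency(cfg: DetectionConfig) -> float:
    """Product of all loss factors along the optical path (the two lenses
    each contribute one factor of the transmittance)."""
    return (
        collection_efficiency(cfg.NA, cfg.n_medium)
        * cfg.filter_eff
        * cfg.mirror_eff
        * cfg.lens_transmittance ** 2
        * cfg.camera_qe
    )


@dataclass
class PhotonTrace:
    """Photon arrival times in seconds (nondecreasing), with the emitting
    fluorophore index where known (-1 otherwise)."""

    times: np.ndarray
    emitters: np.ndarray | None = None
    detected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("photon times must be nondecreasing")
        if self.emitters is not None:
            self.emitters = np.asarray(self.emitters)
            if self.emitters.shape != self.times.shape:
                raise ValueError("emitters must match times in length")

    def __len__(self) -> int:
        return len(self.times)

    def save(self, path) -> None:
        np.savetxt(path, self.times, fmt="%.9e")

    @classmethod
    def load(cls, path) -> "PhotonTrace":
        times = np.atleast_1d(np.loadtxt(path, dtype=float))
        return cls(times=times)


@dataclass
class FrameTrace:
    """Per-frame photon counts with an ON/OFF threshold label."""

    counts: np.ndarray
    frame_time: float
    threshold: int
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def on(self) -> np.ndarray:
        """Boolean ON label per frame (count >= threshold)."""
        return self.counts >= self.threshold

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.start_frame, self.start_frame + len(self.counts)),
                "count": self.counts,
                "on": self.on.astype(int),
            }
        )

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def extract_photons(chain_or_stats) -> PhotonTrace:
    """One photon per radiative S1 -> S0 transition of a simulated chain."""
    from .ssa import Chain, SimStats

    if isinstance(chain_or_stats, Chain):
        times = chain_or_stats.photon_times()
        emitters = chain_or_stats.photon_emitters()
    elif isinstance(chain_or_stats, SimStats):
        times = chain_or_stats.photon_times
        emitters = chain_or_stats.photon_emitters
    else:
        raise TypeError("expected a Chain or SimStats")
    return PhotonTrace(times=np.asarray(times, float), emitters=np.asarray(emitters))


def apply_detection(
    photons: PhotonTrace, cfg: DetectionConfig, seed: int | np.random.SeedSequence
) -> PhotonTrace:
    """Bernoulli thinning of the emitted photon stream with the total
    detection efficiency; seeded and reproducible."""
    p = total_detection_efficiency(cfg)
    rng = np.random.Generator(np.random.PCG64(seed))
    keep = rng.random(len(photons)) < p
    return PhotonTrace(
        times=photons.times[keep],
        emitters=None if photons.emitters is None else photons.emitters[keep],
        detected=True,
    )


def bin_frames(
    photons: PhotonTrace,
    cfg: DetectionConfig,
    t_max: float,
    seed: int | np.random.SeedSequence | None = None,
) -> FrameTrace:
    """Bin detected photons into half-open frames [k*dt, (k+1)*dt) on
    [0, t_max), add Poisson dark counts, and drop frames before
    ``cfg.acquisition_start``."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    dt = cfg.frame_time
    n_frames = int(np.ceil(t_max / dt))
    idx = np.floor(photons.times / dt).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_frames)]
    counts = np.bincount(idx, minlength=n_frames)
    if cfg.dark_rate > 0:
        if seed is None:
            raise ValueError("dark noise requires a seed")
        rng = np.random.Generator(np.random.PCG64(seed))
        counts = counts + rng.poisson(cfg.dark_rate, size=n_frames)
    first = int(np.ceil(cfg.acquisition_start / dt)) if cfg.acquisition_start > 0 else 0
    return FrameTrace(
        counts=counts[first:],
        frame_time=dt,
        threshold=cfg.photon_threshold,
        start_frame=first,
    )


@dataclass
class BlinkPeriods:
    """Maximal runs of ON and OFF frames (lengths in frames)."""

    on_periods: np.ndarray
    off_periods: np.ndarray

    @property
    def n_on_events(self) -> int:
        return len(self.on_periods)


def on_off_periods(frames: FrameTrace) -> BlinkPeriods:
    """Run-length encode the thresholded frame trace into maximal ON/OFF
    periods; the ON-event count is the number of ON runs."""
    on = frames.on
    if len(on) == 0:
        return BlinkPeriods(np.empty(0, np.int64), np.empty(0, np.int64))
    change = np.flatnonzero(np.diff(on.astype(np.int8)) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(on)]))
    lengths = ends - starts
    labels = on[starts]
    return BlinkPeriods(
        on_periods=lengths[labels],
        off_periods=lengths[~labels],
    )
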