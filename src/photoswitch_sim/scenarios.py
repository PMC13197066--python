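"""Named, reproducible experiment scenarios.

A scenario bundles a fluorophore system, detection settings and simulation
controls; running one writes photon/frame traces, analysis tables and a
manifest (config, seeds, hash) so that a rerun with the same config and
seed reproduces the numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, detection, presets
from .detection import DetectionConfig, FrameTrace, PhotonTrace
from .model import EnergyTransferSpec, RateTable, SystemSpec, build_multi_model
from .ssa import simulate_stats, spawn_seeds

__all__ = [
    "ExperimentConfig",
    "run_scenario",
    "scenario_config",
    "list_scenarios",
    "save_config",
    "load_config",
]


@dataclass
class ExperimentConfig:
    """Everything needed to rerun one simulated experiment."""

    name: str
    system: SystemSpec
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    t_max: float = 20.0
    n_runs: int = 1
    master_seed: int = 0
    max_steps: int = 50_000_000
    truncate_start: float = 0.0
    analyses: tuple[str, ...] = ("pfa",)
    pfa_components: int = 1

    def validate(self) -> None:
        known = {"pfa", "lifetime", "blink", "fcs", "g2"}
        bad = set(self.analyses) - known
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}; expected subset of {sorted(known)}")
        if self.t_max <= 0 or self.n_runs < 1 or self.max_steps < 1:
            raise ValueError("t_max, n_runs and max_steps must be positive")


# -- config (de)serialisation ------------------------------------------------

def config_to_dict(cfg: ExperimentConfig) -> dict:
    sys_ = cfg.system
    return {
        "name": cfg.name,
        "rates": dataclasses.asdict(sys_.rate_table),
        "system": {
            "n_fluor": sys_.n_fluor,
            "distances": None if sys_.distances is None else np.asarray(sys_.distances).tolist(),
            "bleaching_enabled": sys_.bleaching_enabled,
        },
        "energy_transfers": [dataclasses.asdict(t) for t in sys_.transfers],
        "detection": dataclasses.asdict(cfg.detection),
        "simulation": {
            "t_max": cfg.t_max,
            "n_runs": cfg.n_runs,
            "master_seed": cfg.master_seed,
            "max_steps": cfg.max_steps,
            "truncate_start": cfg.truncate_start,
            "analyses": list(cfg.analyses),
            "pfa_components": cfg.pfa_components,
        },
    }


def config_from_dict(d: dict) -> ExperimentConfig:
    system = SystemSpec(
        n_fluor=d["system"]["n_fluor"],
        rate_table=RateTable(**d["rates"]),
        distances=None if d["system"]["distances"] is None else np.asarray(d["system"]["distances"]),
        transfers=tuple(EnergyTransferSpec(**t) for t in d["energy_transfers"]),
        bleaching_enabled=d["system"]["bleaching_enabled"],
    )
    sim = d["simulation"]
    cfg = ExperimentConfig(
        name=d["name"],
        system=system,
        detection=DetectionConfig(**d["detection"]),
        t_max=sim["t_max"],
        n_runs=sim["n_runs"],
        master_seed=sim["master_seed"],
        max_steps=sim["max_steps"],
        truncate_start=sim.get("truncate_start", 0.0),
        analyses=tuple(sim.get("analyses", ("pfa",))),
        pfa_components=sim.get("pfa_components", 1),
    )
    cfg.validate()
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# -- scenario registry -------------------------------------------------------

def _single_cy5(**kw) -> ExperimentConfig:
    spec = SystemSpec(n_fluor=1, rate_table=presets.cy5_rate_table(),
                      bleaching_enabled=False)
    return ExperimentConfig(name="single_cy5", system=spec, t_max=20.0,
                            analyses=("pfa", "fcs", "blink", "lifetime"), **kw)


def _single_cy5_bleaching(**kw) -> ExperimentConfig:
    spec = SystemSpec(n_fluor=1, rate_table=presets.cy5_rate_table(),
                      bleaching_enabled=True)
    return ExperimentConfig(name="single_cy5_bleaching", system=spec, t_max=20.0,
                            n_runs=20, analyses=("pfa", "blink"), **kw)


def _fingerprint(n: int, d: float, **kw) -> ExperimentConfig:
    spec = presets.fingerprint_spec(n, d)
    kw.setdefault("n_runs", 100)
    kw.setdefault("t_max", 20.0)
    return ExperimentConfig(name=f"fingerprint_N{n}_d{int(d)}", system=spec,
                            analyses=("pfa", "blink"), **kw)


def _benchmark(variant: str, **kw) -> ExperimentConfig:
    spec = presets.benchmark_spec(variant)
    kw.setdefault("n_runs", 10)
    kw.setdefault("t_max", 6.0)
    kw.setdefault("max_steps", 300_000_000)
    return ExperimentConfig(name=f"lifetime_{variant}", system=spec,
                            analyses=("lifetime",), **kw)


def list_scenarios() -> list[str]:
    names = ["single_cy5", "single_cy5_bleaching"]
    names += [f"fingerprint_N{n}_d{d}" for n in (2, 3, 4) for d in (3, 6, 9)]
    names += [f"lifetime_{v}" for v in presets.BENCHMARK_VARIANTS]
    return names


def scenario_config(name: str, **kw) -> ExperimentConfig:
    """Build a named preset scenario (see :func:`list_scenarios`)."""
    if name == "single_cy5":
        return _single_cy5(**kw)
    if name == "single_cy5_bleaching":
        return _single_cy5_bleaching(**kw)
    if name.startswith("fingerprint_N"):
        body = name.removeprefix("fingerprint_N")
        n, d = body.split("_d")
        return _fingerprint(int(n), float(d), **kw)
    if name.startswith("lifetime_"):
        variant = name.removeprefix("lifetime_")
        if variant not in presets.BENCHMARK_VARIANTS:
            raise KeyError(f"unknown benchmark variant {variant}")
        return _benchmark(variant, **kw)
    raise KeyError(f"unknown scenario {name!r}; known: {list_scenarios()}")


def fingerprint_ensemble(
    n_fluor: int,
    distance: float,
    n_runs: int,
    t_max: float,
    master_seed: int,
    *,
    det: DetectionConfig | None = None,
    max_steps: int = 100_000_000,
    n_components: int = 1,
    pool_size: int = 25,
) -> np.ndarray:
    """Pooled fitted global bleach rates for one fingerprint condition.

    Each run simulates N fluorophores (OET + photobleaching) over
    ``[0, t_max]`` and passes the emitted photons through the detection
    chain.  Following the combined-time-series methodology, the detected
    arrival times of ``pool_size`` runs are pooled into one eCDF and the
    window-truncated exponential model is fitted per pool.  Returns the
    array of fitted rates (s^-1), one per pool; the ensemble estimate is
    the median across pools.
    """
    det = det or DetectionConfig()
    spec = presets.fingerprint_spec(n_fluor, distance)
    model = build_multi_model(spec)
    seeds = spawn_seeds(master_seed, n_runs)
    pooled_times: list[np.ndarray] = []
    for s in seeds:
        st = simulate_stats(model, t_max, max_steps, s, photon_capacity=1 << 16)
        trace = PhotonTrace(times=st.photon_times)
        detected = detection.apply_detection(trace, det, s.spawn(1)[0])
        pooled_times.append(detected.times)
    rates = []
    for lo in range(0, n_runs - pool_size + 1, pool_size):
        times = np.sort(np.concatenate(pooled_times[lo:lo + pool_size]))
        if len(times) < 50:
            rates.append(np.nan)
            continue
        ecdf = analysis.pfa_ecdf(times, 0.0, t_max)
        analysis.fit_pfa_model(ecdf, n_components=n_components)
        rates.append(ecdf.dominant_rate)
    return np.asarray(rates)


# -- execution ---------------------------------------------------------------

def run_scenario(cfg: ExperimentConfig, out_dir) -> dict:
    """Run a scenario end to end and write its result bundle to ``out_dir``.

    Outputs (all CSV/JSON text): pooled photon times, per-run frame traces,
    the requested analysis tables, and ``manifest.json`` recording the full
    config, its hash and every per-run seed.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_multi_model(cfg.system)
    seeds = spawn_seeds(cfg.master_seed, cfg.n_runs)
    runs = []
    for s in seeds:
        runs.append(
            simulate_stats(model, cfg.t_max, cfg.max_steps, s,
                           photon_capacity=4096, dwell_capacity=0)
        )
    # pooled emitted photons
    photon_df = pd.concat(
        [pd.DataFrame({"run": i, "t": r.photon_times}) for i, r in enumerate(runs)],
        ignore_index=True,
    )
    photon_df.to_csv(out / "photons.csv", index=False, float_format="%.9e")

    results: dict = {"name": cfg.name, "n_runs": cfg.n_runs}
    frame_traces = []
    for i, r in enumerate(runs):
        trace = PhotonTrace(times=r.photon_times, emitters=r.photon_emitters)
        det = detection.apply_detection(trace, cfg.detection, seeds[i].spawn(1)[0])
        frame_traces.append(detection.bin_frames(det, cfg.detection, cfg.t_max,
                                                 seeds[i].spawn(2)[1]))

    if "pfa" in cfg.analyses:
        pooled = np.sort(photon_df["t"].to_numpy())
        ecdf = analysis.pfa_ecdf(pooled, cfg.truncate_start, cfg.t_max)
        analysis.fit_pfa_model(ecdf, cfg.pfa_components)
        pd.DataFrame({"t": ecdf.times, "ecdf": ecdf.values}).to_csv(
            out / "pfa_ecdf.csv", index=False, float_format="%.9e")
        results["pfa"] = {
            "weights": ecdf.weights.tolist(),
            "rates_per_s": ecdf.rates.tolist(),
            "residual": ecdf.residual,
        }
    if "lifetime" in cfg.analyses:
        ests = []
        for s in seeds:
            st = simulate_stats(model, cfg.t_max, cfg.max_steps, s.spawn(3)[2])
            ests.append(analysis.lifetime_from_chain(st))
        pooled_est = analysis.pooled_lifetime(ests)
        results["lifetime"] = {
            "tau_flu_s": pooled_est.tau_flu,
            "std_s": pooled_est.std,
            "n_events": pooled_est.n_events,
        }
        pd.DataFrame(
            {"run": range(len(ests)),
             "tau_flu_s": [e.tau_flu for e in ests],
             "n_events": [e.n_events for e in ests]}
        ).to_csv(out / "lifetime.csv", index=False)
    if "blink" in cfg.analyses:
        rows = []
        for i, ft in enumerate(frame_traces):
            periods = detection.on_off_periods(ft)
            rows.append({"run": i, "n_on_events": periods.n_on_events,
                         "mean_on": float(periods.on_periods.mean()) if len(periods.on_periods) else 0.0,
                         "mean_off": float(periods.off_periods.mean()) if len(periods.off_periods) else 0.0})
        pd.DataFrame(rows).to_csv(out / "blink.csv", index=False)
        results["blink"] = {"mean_on_events": float(np.mean([r["n_on_events"] for r in rows]))}
    if "fcs" in cfg.analyses:
        curve = analysis.multiple_tau_correlation(frame_traces[0])
        pd.DataFrame({"lag_s": curve.lags, "G": curve.G}).to_csv(
            out / "fcs.csv", index=False, float_format="%.9e")
    if "g2" in cfg.analyses:
        trace = PhotonTrace(times=np.sort(runs[0].photon_times))
        coin = analysis.second_order_coherence(trace, window=1e-10)
        results["g2"] = {"g2_zero": coin.g2_zero, "window_s": coin.window}

    manifest = {
        "config": config_to_dict(cfg),
        "config_hash": config_hash(cfg),
        "seeds": [list(map(int, s.spawn_key)) for s in seeds],
        "stop_reasons": [r.stop_reason for r in runs],
        "steps": [int(r.steps) for r in runs],
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return results
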