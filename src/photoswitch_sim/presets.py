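"""Default parameter sets and named model variants.

The shipped Cy5 rate table is a documented reconstruction: magnitudes follow
the published Cy5/dSTORM photophysics literature (excitation cross section,
fluorescence quantum yield around 0.28, thiolate-mediated electron transfer
at pKa 9 / pH 7.5 / 100 mM, weak triplet yield, microsecond cis isomer,
long-lived thiol-adduct OFF state) and the remaining freedom is calibrated
so that the simulated fluorescence lifetimes of the reference conditions
reproduce the published values (see docs/methods.md).  OFF-state and
radical relaxation use desk-scale absolute rates that preserve the duty
cycles of the slow states while keeping equilibration times short.
"""

from __future__ import annotations

import numpy as np

from .model import (
    EnergyTransferSpec,
    RateTable,
    SystemSpec,
    cross_section_from_extinction,
    excitation_rate_from_irradiance,
    geometry_distances,
    pet_rate_from_thiol,
)

__all__ = [
    "EXCITATION",
    "BUFFER",
    "cy5_rate_table",
    "dstorm_transfers",
    "radical_transfer",
    "benchmark_spec",
    "fingerprint_spec",
    "BENCHMARK_VARIANTS",
]

#: excitation conditions: 640 nm at 2.5 kW/cm^2, Cy5 extinction 2.5e5 /M/cm
EXCITATION = {"wavelength_nm": 640.0, "irradiance_W_cm2": 2500.0, "extinction_M_cm": 2.5e5}

#: switching buffer: 100 mM mercaptoethylamine at pH 7.5 (thiol pKa 9.0)
BUFFER = {"pKa": 9.0, "pH": 7.5, "conc_M": 0.1, "k_bimol_S1": 1.0e9, "k_bimol_T1": 3.0e9}


def default_excitation_rate() -> float:
    sigma = cross_section_from_extinction(EXCITATION["extinction_M_cm"])
    return excitation_rate_from_irradiance(
        EXCITATION["irradiance_W_cm2"], EXCITATION["wavelength_nm"], sigma
    )


def cy5_rate_table(**overrides) -> RateTable:
    """Reconstructed Cy5 dSTORM rate constants (s^-1).

    The S1 deactivation channels sum to 1/(1.69 ns); the PET rates derive
    from the buffer composition via Henderson-Hasselbalch.
    """
    values = dict(
        kEXC=default_excitation_rate(),
        kFLU=1.66e8,
        kIC=3.735e8,
        kISC_S1T1=2.0e7,
        kISC_T1S0=5.0e5,
        kISO=3.0e7,
        kBISO=1.0e6,
        kBLE=880.0,
        kPET_S=pet_rate_from_thiol(BUFFER["pKa"], BUFFER["pH"], BUFFER["conc_M"],
                                   BUFFER["k_bimol_S1"]),
        kPET_T=pet_rate_from_thiol(BUFFER["pKa"], BUFFER["pH"], BUFFER["conc_M"],
                                   BUFFER["k_bimol_T1"]),
        kTE=0.05,
        kPU=0.15,
        kOXI=4130.0,
        p_GRC=0.999,
        p_OFF=2.0e-4,
        p_RE=8.0e-4,
    )
    values.update(overrides)
    return RateTable(**values)


#: reference transfer rates at 3 nm (s^-1) and acceptor-recycle efficiencies
TRANSFER_DEFAULTS = {
    "SSA": {"k_ref": 5.0e9, "recycle_efficiency": 0.0},
    "STA": {"k_ref": 5.0e9, "recycle_efficiency": 0.0},
    "CET": {"k_ref": 9.0e9, "recycle_efficiency": 0.5},
    "OET": {"k_ref": 5.0e9, "recycle_efficiency": 1.0e-4},
}

#: FRET to the radical anion: 1e9 /s at 3 nm, acceptor not recycled unless
#: an efficiency is requested (the "2.x" model variants)
RADICAL_TRANSFER = {"k_ref": 1.0e9, "recycle_efficiency": 0.0}


def dstorm_transfers(
    *,
    cet_scale: float = 1.0,
    sta_scale: float = 1.0,
    cet_recycle: float | None = None,
    oet_recycle: float | None = None,
) -> list[EnergyTransferSpec]:
    """The four standard pathways (SSA, STA, CET, OET) at their defaults,
    with the scaling hooks used by the model variants."""
    out = []
    for name, cfg in TRANSFER_DEFAULTS.items():
        k = cfg["k_ref"]
        eta = cfg["recycle_efficiency"]
        if name == "CET":
            k *= cet_scale
            if cet_recycle is not None:
                eta = cet_recycle
        if name == "STA":
            k *= sta_scale
        if name == "OET" and oet_recycle is not None:
            eta = oet_recycle
        out.append(EnergyTransferSpec(pathway=name, k_ref=k, recycle_efficiency=eta))
    return out


def radical_transfer(recycle_efficiency: float = 0.0) -> EnergyTransferSpec:
    return EnergyTransferSpec(pathway="RET", recycle_efficiency=recycle_efficiency,
                              **{"k_ref": RADICAL_TRANSFER["k_ref"]})


#: named lifetime-benchmark variants: (N, transfers?, RET recycle or None,
#: T1->R rate multiplier, extra transfer tweaks)
BENCHMARK_VARIANTS = {
    "ID1": dict(n_fluor=4, transfers=False, ret=None, pet_t_re_scale=1.0),
    "ID2": dict(n_fluor=4, transfers=True, ret=None, pet_t_re_scale=1.0),
    "ID3": dict(n_fluor=4, transfers=True, ret=None, pet_t_re_scale=1.0,
                cet_scale=0.01, cet_recycle=0.0, sta_scale=0.1),
    "ID4": dict(n_fluor=4, transfers=True, ret=0.0, pet_t_re_scale=10.0),
    "ID5": dict(n_fluor=4, transfers=True, ret=0.0, pet_t_re_scale=100.0),
    "ID6": dict(n_fluor=3, transfers=True, ret=0.0, pet_t_re_scale=100.0),
    "ID7": dict(n_fluor=2, transfers=True, ret=0.0, pet_t_re_scale=100.0),
    "ID8": dict(n_fluor=4, transfers=True, ret=1.0e-4, pet_t_re_scale=100.0),
    "ID9": dict(n_fluor=4, transfers=True, ret=1.0e-3, pet_t_re_scale=100.0),
}


def benchmark_spec(variant: str, distance: float = 3.0) -> SystemSpec:
    """System for one lifetime-benchmark condition (bleaching disabled,
    nearest-neighbour spacing 3 nm)."""
    cfg = BENCHMARK_VARIANTS[variant]
    rates = cy5_rate_table(pet_t_re_scale=cfg["pet_t_re_scale"])
    transfers: list[EnergyTransferSpec] = []
    if cfg["transfers"]:
        transfers = dstorm_transfers(
            cet_scale=cfg.get("cet_scale", 1.0),
            sta_scale=cfg.get("sta_scale", 1.0),
            cet_recycle=cfg.get("cet_recycle"),
        )
    if cfg["ret"] is not None:
        transfers.append(radical_transfer(cfg["ret"]))
    return SystemSpec(
        n_fluor=cfg["n_fluor"],
        rate_table=rates,
        distances=geometry_distances(cfg["n_fluor"], distance),
        transfers=tuple(transfers),
        bleaching_enabled=False,
    )


def fingerprint_spec(
    n_fluor: int,
    distance: float,
    *,
    oet: bool = True,
    bleaching: bool = True,
    oet_recycle: float = 1.0e-4,
) -> SystemSpec:
    """System for the photoswitching-fingerprint (PFA) scans: N fluorophores
    at the given spacing with the OET pathway and photobleaching."""
    transfers = ()
    if oet and n_fluor > 1:
        cfg = TRANSFER_DEFAULTS["OET"]
        transfers = (
            EnergyTransferSpec(pathway="OET", k_ref=cfg["k_ref"],
                               recycle_efficiency=oet_recycle),
        )
    return SystemSpec(
        n_fluor=n_fluor,
        rate_table=cy5_rate_table(),
        distances=geometry_distances(n_fluor, distance),
        transfers=transfers,
        bleaching_enabled=bleaching,
    )
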