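"""Photophysical model of Cy5 under dSTORM conditions.

Builds the single-fluorophore state/transition scheme (trans ground state S0,
excited singlet S1, triplet T1, cis isomer, thiol-adduct OFF state, radical
anion R, photobleached B) and composes N-fluorophore systems in which excited
singlet donors transfer energy to neighbouring acceptors with the classic
Forster 1/r^6 distance dependence.

All rates are s^-1, times are seconds, distances are nm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np

__all__ = [
    "FluorState",
    "RateTable",
    "EnergyTransferSpec",
    "SystemSpec",
    "Transition",
    "CompositeModel",
    "build_single_model",
    "build_multi_model",
    "fret_rate_at_distance",
    "pet_rate_from_thiol",
    "excitation_rate_from_irradiance",
    "cross_section_from_extinction",
    "PATHWAYS",
]

PLANCK = 6.62607015e-34  # J s
LIGHTSPEED = 2.99792458e8  # m / s
AVOGADRO = 6.02214076e23  # 1 / mol

PATHWAYS = ("SSA", "STA", "CET", "OET", "RET")

#: acceptor state required by each energy-transfer pathway (donor is always S1)
_PATHWAY_ACCEPTOR = {
    "SSA": "S1",
    "STA": "T1",
    "CET": "CIS",
    "OET": "OFF",
    "RET": "R",
}


class FluorState(enum.IntEnum):
    """Photophysical states of a single fluorophore."""

    S0 = 0   # trans ground state
    S1 = 1   # trans first excited singlet
    T1 = 2   # first excited triplet
    CIS = 3  # cis isomer (non-absorbing at 640 nm, non-radiative)
    OFF = 4  # thiol adduct Cy5-SR- (long-lived dark state)
    R = 5    # radical anion Cy5-. (dark, re-oxidises to S0)
    B = 6    # photobleached (absorbing)


N_FLUOR_STATES = len(FluorState)


def fret_rate_at_distance(k_ref: float, r_ref: float, r: float) -> float:
    """Forster transfer rate at distance ``r`` given the rate at ``r_ref``.

    k(r) = k_ref * (r_ref / r)**6
    """
    if r <= 0 or r_ref <= 0:
        raise ValueError("distances must be positive")
    return k_ref * (r_ref / r) ** 6


def pet_rate_from_thiol(pKa: float, pH: float, conc: float, k_bimol: float) -> float:
    """Pseudo-first-order photoinduced-electron-transfer rate from a thiol.

    Only the deprotonated thiolate is reactive; its fraction follows
    Henderson-Hasselbalch: 1 / (1 + 10**(pKa - pH)).  ``conc`` is the total
    thiol concentration in mol/L, ``k_bimol`` the bimolecular quenching rate
    in L mol^-1 s^-1.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    thiolate_fraction = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return k_bimol * conc * thiolate_fraction


def cross_section_from_extinction(epsilon: float) -> float:
    """Absorption cross section (cm^2) from a molar extinction coefficient
    (M^-1 cm^-1): sigma = ln(10) * epsilon * 1000 / N_A."""
    return math.log(10.0) * epsilon * 1e3 / AVOGADRO


def excitation_rate_from_irradiance(
    irradiance: float, wavelength: float, cross_section: float
) -> float:
    """Photon absorption rate (s^-1) for ``irradiance`` in W cm^-2,
    ``wavelength`` in nm and ``cross_section`` in cm^2."""
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if wavelength <= 0 or cross_section <= 0:
        raise ValueError("wavelength and cross section must be positive")
    photon_energy = PLANCK * LIGHTSPEED / (wavelength * 1e-9)  # J
    return cross_section * irradiance / photon_energy


@dataclass(frozen=True)
class RateTable:
    """Single-fluorophore rate constants (all s^-1, probabilities unitless).

    The photoinduced-electron-transfer (PET) branch fires from S1 at total
    rate ``kPET_S`` and from T1 at total rate ``kPET_T``; each firing ends in
    geminate recombination back to S0 (probability ``p_GRC``), in the thiol
    adduct OFF state (``p_OFF``), or as an escaped radical anion R
    (``p_RE``).  ``pet_t_re_scale`` multiplies the T1 -> R channel rate only
    (used by the enhanced-radical-formation model variants).
    """

    kEXC: float          # S0 -> S1 photoexcitation
    kFLU: float          # S1 -> S0 radiative (photon emitted)
    kIC: float           # S1 -> S0 internal conversion
    kISC_S1T1: float     # S1 -> T1 intersystem crossing
    kISC_T1S0: float     # T1 -> S0 intersystem crossing
    kISO: float          # S1 -> CIS photoisomerisation
    kBISO: float         # CIS -> S0 back-isomerisation (thermal + photoinduced)
    kBLE: float          # T1 -> B photobleaching
    kPET_S: float        # total PET rate out of S1
    kPET_T: float        # total PET rate out of T1
    kTE: float           # OFF -> S0 thermal elimination
    kPU: float           # OFF -> S0 photoinduced uncaging
    kOXI: float          # R -> S0 oxidation
    p_GRC: float = 0.999
    p_OFF: float = 0.0005
    p_RE: float = 0.0005
    pet_t_re_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "kEXC", "kFLU", "kIC", "kISC_S1T1", "kISC_T1S0", "kISO",
            "kBISO", "kBLE", "kPET_S", "kPET_T", "kTE", "kPU", "kOXI",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        probs = (self.p_GRC, self.p_OFF, self.p_RE)
        if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError("PET branch probabilities must be >= 0 and sum to 1")
        if self.pet_t_re_scale < 0:
            raise ValueError("pet_t_re_scale must be non-negative")

    @property
    def k_S1_total(self) -> float:
        """Total exit rate of S1 in the absence of energy transfer."""
        return self.kFLU + self.kIC + self.kISC_S1T1 + self.kISO + self.kPET_S

    def with_(self, **changes) -> "RateTable":
        return replace(self, **changes)


@dataclass(frozen=True)
class EnergyTransferSpec:
    """One energy-transfer pathway between an excited singlet donor and an
    acceptor in a pathway-specific state.

    ``k_ref`` is the transfer rate at reference distance ``r_ref`` (nm);
    the rate at distance r scales as (r_ref/r)**6.  ``recycle_efficiency``
    is the probability that the acceptor leaves its state upon transfer
    (returning to S0); it applies to CET/OET/RET and is ignored for SSA and
    STA, whose acceptors relax back to their original state on a negligible
    timescale.
    """

    pathway: str
    k_ref: float
    r_ref: float = 3.0
    recycle_efficiency: float = 0.0

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}; expected one of {PATHWAYS}")
        if self.k_ref < 0:
            raise ValueError("k_ref must be non-negative")
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")
        if not 0.0 <= self.recycle_efficiency <= 1.0:
            raise ValueError("recycle_efficiency must lie in [0, 1]")

    def rate_at(self, r: float) -> float:
        return fret_rate_at_distance(self.k_ref, self.r_ref, r)


@dataclass(frozen=True)
class SystemSpec:
    """An N-fluorophore system (N in 1..4) with pairwise distances in nm."""

    n_fluor: int
    rate_table: RateTable
    distances: np.ndarray | None = None
    transfers: tuple[EnergyTransferSpec, ...] = ()
    bleaching_enabled: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.n_fluor <= 4:
            raise ValueError("n_fluor must be between 1 and 4")
        object.__setattr__(self, "transfers", tuple(self.transfers))
        if self.n_fluor > 1:
            if self.distances is None:
                raise ValueError("distances matrix required for n_fluor > 1")
            d = np.asarray(self.distances, dtype=float)
            if d.shape != (self.n_fluor, self.n_fluor):
                raise ValueError("distances must be an (N, N) matrix")
            if not np.allclose(d, d.T):
                raise ValueError("distances must be symmetric")
            off = d[~np.eye(self.n_fluor, dtype=bool)]
            if np.any(off <= 0):
                raise ValueError("off-diagonal distances must be positive")
            object.__setattr__(self, "distances", d)

    def distance(self, i: int, j: int) -> float:
        if self.distances is None:
            raise ValueError("no distances defined")
        return float(self.distances[i, j])


@dataclass(frozen=True)
class Transition:
    """One transition of the composite model."""

    source: int          # composite state index
    target: int          # composite state index
    rate: float          # s^-1
    kind: str            # e.g. "FLU", "PET_S:GRC", "OET:recycle"
    actor: int           # fluorophore index (donor index for energy transfer)
    acceptor: int = -1   # acceptor fluorophore index for energy transfer
    is_flu: bool = False  # True exactly for radiative S1 -> S0

    @property
    def label(self) -> str:
        if self.acceptor >= 0:
            return f"{self.kind}[{self.actor}->{self.acceptor}]"
        return f"{self.kind}[{self.actor}]"


def _single_transitions(rates: RateTable, bleaching: bool):
    """(source state, target state, rate, kind, is_flu) for one fluorophore."""
    S = FluorState
    out = [
        (S.S0, S.S1, rates.kEXC, "EXC", False),
        (S.S1, S.S0, rates.kFLU, "FLU", True),
        (S.S1, S.S0, rates.kIC, "IC", False),
        (S.S1, S.T1, rates.kISC_S1T1, "ISC_S1T1", False),
        (S.T1, S.S0, rates.kISC_T1S0, "ISC_T1S0", False),
        (S.S1, S.CIS, rates.kISO, "ISO", False),
        (S.CIS, S.S0, rates.kBISO, "BISO", False),
        # PET branch from S1: geminate recombination / OFF formation / radical escape
        (S.S1, S.S0, rates.kPET_S * rates.p_GRC, "PET_S:GRC", False),
        (S.S1, S.OFF, rates.kPET_S * rates.p_OFF, "PET_S:OFF", False),
        (S.S1, S.R, rates.kPET_S * rates.p_RE, "PET_S:RE", False),
        # PET branch from T1
        (S.T1, S.S0, rates.kPET_T * rates.p_GRC, "PET_T:GRC", False),
        (S.T1, S.OFF, rates.kPET_T * rates.p_OFF, "PET_T:OFF", False),
        (S.T1, S.R, rates.kPET_T * rates.p_RE * rates.pet_t_re_scale, "PET_T:RE", False),
        (S.OFF, S.S0, rates.kTE, "TE", False),
        (S.OFF, S.S0, rates.kPU, "PU", False),
        (S.R, S.S0, rates.kOXI, "OXI", False),
    ]
    if bleaching:
        out.append((S.T1, S.B, rates.kBLE, "BLE", False))
    return [t for t in out if t[2] > 0.0]


class CompositeModel:
    """State space and transition list of an N-fluorophore system.

    States are N-tuples of :class:`FluorState`; the full product space of
    7**N states is enumerated (unreachable states are harmless — they simply
    never occur in a simulation and are excluded from stationary analyses).
    """

    def __init__(self, spec: SystemSpec):
        self.spec = spec
        self.n_fluor = spec.n_fluor
        states = list(product(range(N_FLUOR_STATES), repeat=spec.n_fluor))
        self.states = np.array(states, dtype=np.int8)
        self.state_index = {tuple(s): i for i, s in enumerate(states)}
        self.transitions: list[Transition] = []
        self._build(spec)
        self._finalize()

    # -- construction -----------------------------------------------------
    def _build(self, spec: SystemSpec) -> None:
        single = _single_transitions(spec.rate_table, spec.bleaching_enabled)
        n = spec.n_fluor
        for idx, state in enumerate(map(tuple, self.states)):
            # intra-fluorophore transitions
            for i in range(n):
                for src, dst, rate, kind, is_flu in single:
                    if state[i] != src:
                        continue
                    new = list(state)
                    new[i] = int(dst)
                    self.transitions.append(
                        Transition(idx, self.state_index[tuple(new)], rate, kind, i, -1, is_flu)
                    )
            # energy transfer for every ordered donor/acceptor pair
            for et in spec.transfers:
                acc_state = FluorState[_PATHWAY_ACCEPTOR[et.pathway]]
                for i in range(n):
                    if state[i] != FluorState.S1:
                        continue
                    for j in range(n):
                        if j == i or state[j] != acc_state:
                            continue
                        rate = et.rate_at(spec.distance(i, j))
                        if rate <= 0.0:
                            continue
                        self._add_transfer(idx, state, et, i, j, rate)

    def _add_transfer(self, idx, state, et, i, j, rate) -> None:
        """Donor i (S1 -> S0) transfers onto acceptor j; the acceptor either
        keeps its state or is recycled to S0, splitting the total pathway
        rate by the recycle efficiency."""
        donor_down = list(state)
        donor_down[i] = int(FluorState.S0)
        if et.pathway in ("SSA", "STA"):
            # acceptor promoted to S2/T2 relaxes back on a negligible timescale
            self.transitions.append(
                Transition(idx, self.state_index[tuple(donor_down)], rate, et.pathway, i, j)
            )
            return
        eta = et.recycle_efficiency
        if eta > 0.0:
            recycled = list(donor_down)
            recycled[j] = int(FluorState.S0)
            self.transitions.append(
                Transition(
                    idx, self.state_index[tuple(recycled)], rate * eta,
                    f"{et.pathway}:recycle", i, j,
                )
            )
        if eta < 1.0:
            self.transitions.append(
                Transition(
                    idx, self.state_index[tuple(donor_down)], rate * (1.0 - eta),
                    et.pathway, i, j,
                )
            )

    def _finalize(self) -> None:
        nt = len(self.transitions)
        self.src = np.fromiter((t.source for t in self.transitions), np.int32, nt)
        self.dst = np.fromiter((t.target for t in self.transitions), np.int32, nt)
        self.rate = np.fromiter((t.rate for t in self.transitions), np.float64, nt)
        self.is_flu = np.fromiter((t.is_flu for t in self.transitions), np.bool_, nt)
        self.actor = np.fromiter((t.actor for t in self.transitions), np.int32, nt)

    # -- views -------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def initial_state(self) -> int:
        """All fluorophores in the trans ground state S0."""
        return self.state_index[(0,) * self.n_fluor]

    def state_label(self, idx: int) -> str:
        return "|".join(FluorState(s).name for s in self.states[idx])

    def rate_matrix(self) -> np.ndarray:
        """Dense generator matrix Q with zero row sums."""
        n = self.n_states
        Q = np.zeros((n, n))
        np.add.at(Q, (self.src, self.dst), self.rate)
        Q[np.arange(n), np.arange(n)] -= Q.sum(axis=1)
        return Q

    def exit_rates(self) -> np.ndarray:
        out = np.zeros(self.n_states)
        np.add.at(out, self.src, self.rate)
        return out

    def csr(self):
        """Transitions grouped by source state: (indptr, order) such that
        transitions ``order[indptr[s]:indptr[s+1]]`` leave state ``s``."""
        order = np.argsort(self.src, kind="stable").astype(np.int64)
        counts = np.bincount(self.src, minlength=self.n_states)
        indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        return indptr, order


def build_single_model(rates: RateTable, bleaching: bool = True) -> CompositeModel:
    """Single-fluorophore model with the eleven elementary processes
    (photoexcitation, fluorescence, internal conversion, two intersystem
    crossings, isomerisation and back-isomerisation, photobleaching, the
    three-way PET branches from S1 and T1, OFF-state recovery, oxidation)."""
    spec = SystemSpec(n_fluor=1, rate_table=rates, bleaching_enabled=bleaching)
    return CompositeModel(spec)


def build_multi_model(spec: SystemSpec) -> CompositeModel:
    """Composite model for up to four interacting fluorophores."""
    return CompositeModel(spec)


def dimer_distances(d: float) -> np.ndarray:
    """Two fluorophores separated by ``d`` nm."""
    return np.array([[0.0, d], [d, 0.0]])


def triangle_distances(d: float) -> np.ndarray:
    """Equilateral triangle with side ``d`` nm."""
    m = np.full((3, 3), d)
    np.fill_diagonal(m, 0.0)
    return m


def square_distances(d: float) -> np.ndarray:
    """Square with side ``d`` nm (diagonals d*sqrt(2))."""
    m = np.full((4, 4), d)
    m[0, 2] = m[2, 0] = m[1, 3] = m[3, 1] = d * math.sqrt(2.0)
    np.fill_diagonal(m, 0.0)
    return m


def geometry_distances(n_fluor: int, d: float) -> np.ndarray | None:
    """Canonical arrangement for N fluorophores with nearest-neighbour
    spacing ``d``: pair, equilateral triangle, square."""
    if n_fluor == 1:
        return None
    if n_fluor == 2:
        return dimer_distances(d)
    if n_fluor == 3:
        return triangle_distances(d)
    if n_fluor == 4:
        return square_distances(d)
    raise ValueError("n_fluor must be 1..4")
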