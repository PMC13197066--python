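import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photoswitch_sim.model import (
    EnergyTransferSpec,
    FluorState,
    SystemSpec,
    build_multi_model,
    build_single_model,
    cross_section_from_extinction,
    dimer_distances,
    excitation_rate_from_irradiance,
    fret_rate_at_distance,
    pet_rate_from_thiol,
    square_distances,
)
from photoswitch_sim.presets import cy5_rate_table

from conftest import toy_rates


class TestFretRate:
    def test_identity_at_reference(self):
        assert fret_rate_at_distance(1e9, 3.0, 3.0) == 1e9

    def test_inverse_sixth_power(self):
        # doubling the distance divides the rate by 2**6
        assert fret_rate_at_distance(1e9, 3.0, 6.0) == pytest.approx(1.5625e7)

    @given(st.floats(min_value=0.1, max_value=50.0), st.floats(min_value=0.1, max_value=50.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted([r1, r2])
        assert fret_rate_at_distance(1e9, 3.0, lo) > fret_rate_at_distance(1e9, 3.0, hi)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            fret_rate_at_distance(1e9, 3.0, 0.0)


class TestPetRate:
    def test_henderson_hasselbalch(self):
        # independent arithmetic: thiolate fraction 1/(1 + 10**(9-7.5))
        frac = 1.0 / (1.0 + 10.0 ** 1.5)
        assert frac == pytest.approx(0.030653, abs=1e-5)
        assert pet_rate_from_thiol(9.0, 7.5, 0.1, 1e9) == pytest.approx(1e8 * frac)

    def test_half_dissociation_at_pka(self):
        assert pet_rate_from_thiol(9.0, 9.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_zero_concentration(self):
        assert pet_rate_from_thiol(9.0, 7.5, 0.0, 1e9) == 0.0


class TestExcitationRate:
    def test_reference_conditions(self):
        # sigma from epsilon = 2.5e5 /M/cm; 2.5 kW/cm^2 at 640 nm
        sigma = cross_section_from_extinction(2.5e5)
        assert sigma == pytest.approx(9.56e-16, rel=1e-3)
        k = excitation_rate_from_irradiance(2500.0, 640.0, sigma)
        assert k == pytest.approx(7.7e6, rel=0.01)

    def test_linearity_and_zero(self):
        sigma = 1e-16
        k1 = excitation_rate_from_irradiance(1000.0, 640.0, sigma)
        assert excitation_rate_from_irradiance(2000.0, 640.0, sigma) == pytest.approx(2 * k1)
        assert excitation_rate_from_irradiance(0.0, 640.0, sigma) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            excitation_rate_from_irradiance(1000.0, -1.0, 1e-16)


class TestSingleModel:
    def test_full_scheme_transition_kinds(self, cy5_rates):
        model = build_single_model(cy5_rates, bleaching=True)
        kinds = {t.kind for t in model.transitions}
        assert kinds == {
            "EXC", "FLU", "IC", "ISC_S1T1", "ISC_T1S0", "ISO", "BISO", "BLE",
            "PET_S:GRC", "PET_S:OFF", "PET_S:RE",
            "PET_T:GRC", "PET_T:OFF", "PET_T:RE",
            "TE", "PU", "OXI",
        }
        assert model.n_states == 7

    def test_flu_tag_only_on_radiative(self, cy5_rates):
        model = build_single_model(cy5_rates, bleaching=True)
        flu = [t for t in model.transitions if t.is_flu]
        assert all(t.kind == "FLU" for t in flu) and len(flu) == 1
        assert flu[0].rate == cy5_rates.kFLU

    def test_disabled_bleaching_has_no_path_to_b(self, cy5_rates):
        model = build_single_model(cy5_rates, bleaching=False)
        B = int(FluorState.B)
        assert not any(model.states[t.target][0] == B for t in model.transitions)

    def test_zero_rate_channels_omitted(self):
        model = build_single_model(toy_rates(kEXC=1e3, kFLU=1e3), bleaching=True)
        assert {t.kind for t in model.transitions} == {"EXC", "FLU"}

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            toy_rates(kEXC=-1.0)

    def test_pet_branch_probabilities_validated(self):
        with pytest.raises(ValueError):
            cy5_rate_table(p_GRC=0.9, p_OFF=0.2, p_RE=0.2)


class TestMultiModel:
    def test_n1_isomorphic_to_single(self, cy5_rates):
        single = build_single_model(cy5_rates, bleaching=True)
        multi = build_multi_model(
            SystemSpec(n_fluor=1, rate_table=cy5_rates, bleaching_enabled=True)
        )
        key = lambda m: sorted((t.source, t.target, t.rate, t.kind) for t in m.transitions)
        assert key(single) == key(multi)

    def test_state_space_size_is_seven_to_the_n(self, cy5_rates):
        for n in (2, 3):
            spec = SystemSpec(
                n_fluor=n, rate_table=cy5_rates,
                distances=np.full((n, n), 3.0) - 3.0 * np.eye(n),
            )
            assert build_multi_model(spec).n_states == 7 ** n

    def test_dimer_oet_adds_two_pairs_times_two_outcomes(self, cy5_rates):
        # enumeration oracle: 2 ordered pairs, recycle/no-recycle split each,
        # per composite state with donor S1 and acceptor OFF (7 per donor
        # choice of the remaining fluorophore's... exactly states (S1, OFF)
        # and (OFF, S1) -> 2 states x 2 outcomes = 4 extra transitions
        base = SystemSpec(n_fluor=2, rate_table=cy5_rates, distances=dimer_distances(3.0))
        oet = SystemSpec(
            n_fluor=2, rate_table=cy5_rates, distances=dimer_distances(3.0),
            transfers=(EnergyTransferSpec(pathway="OET", k_ref=1e7,
                                          recycle_efficiency=1e-4),),
        )
        extra = len(build_multi_model(oet).transitions) - len(build_multi_model(base).transitions)
        assert extra == 4

    def test_twelve_ordered_pairs_per_pathway_at_n4(self, cy5_rates):
        transfers = tuple(
            EnergyTransferSpec(pathway=p, k_ref=1e8, recycle_efficiency=0.1)
            for p in ("SSA", "STA", "CET", "OET")
        )
        spec = SystemSpec(n_fluor=4, rate_table=cy5_rates,
                          distances=square_distances(3.0), transfers=transfers)
        model = build_multi_model(spec)
        for pathway in ("SSA", "STA", "CET", "OET"):
            pairs = {
                (t.actor, t.acceptor)
                for t in model.transitions
                if t.kind.startswith(pathway)
            }
            assert len(pairs) == 12  # N(N-1) ordered pairs

    def test_transfer_donor_always_s1_to_s0(self, cy5_rates):
        spec = SystemSpec(
            n_fluor=2, rate_table=cy5_rates, distances=dimer_distances(3.0),
            transfers=(EnergyTransferSpec(pathway="RET", k_ref=1e9,
                                          recycle_efficiency=0.5),),
        )
        model = build_multi_model(spec)
        S1, S0 = int(FluorState.S1), int(FluorState.S0)
        ets = [t for t in model.transitions if t.acceptor >= 0]
        assert ets
        for t in ets:
            assert model.states[t.source][t.actor] == S1
            assert model.states[t.target][t.actor] == S0

    def test_outcome_split_rates_sum_to_pathway_total(self, cy5_rates):
        eta = 0.37
        spec = SystemSpec(
            n_fluor=2, rate_table=cy5_rates, distances=dimer_distances(4.5),
            transfers=(EnergyTransferSpec(pathway="CET", k_ref=1e9, r_ref=3.0,
                                          recycle_efficiency=eta),),
        )
        model = build_multi_model(spec)
        state = model.state_index[(int(FluorState.S1), int(FluorState.CIS))]
        rates = [t.rate for t in model.transitions
                 if t.source == state and t.kind.startswith("CET")]
        assert len(rates) == 2
        assert sum(rates) == pytest.approx(fret_rate_at_distance(1e9, 3.0, 4.5))

    def test_generator_rows_sum_to_zero(self, cy5_rates):
        spec = SystemSpec(
            n_fluor=2, rate_table=cy5_rates, distances=dimer_distances(3.0),
            transfers=(EnergyTransferSpec(pathway="OET", k_ref=1e7,
                                          recycle_efficiency=1e-4),),
        )
        Q = build_multi_model(spec).rate_matrix()
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-6

    def test_spec_validation(self, cy5_rates):
        with pytest.raises(ValueError):
            SystemSpec(n_fluor=5, rate_table=cy5_rates, distances=np.eye(5))
        with pytest.raises(ValueError):
            SystemSpec(n_fluor=2, rate_table=cy5_rates)  # missing distances
        bad = np.array([[0.0, 3.0], [4.0, 0.0]])
        with pytest.raises(ValueError):
            SystemSpec(n_fluor=2, rate_table=cy5_rates, distances=bad)
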