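"""Delivery-time model: momentum scaling, transitions, spill ledger, BDT."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbs4d.machine import (
    MachineParameters,
    UnservablePlanError,
    beam_delivery_time,
    list_machine_presets,
    load_machine,
    proton_momentum,
    scanning_speed_at_energy,
    simulate_delivery,
    spot_transition_time,
)
from pbs4d.plan import EnergyLayer, Spot, TreatmentPlan, build_layer_rescanning_plan

from naive_oracle import naive_walk, random_machine, random_toy_plan


@pytest.fixture(scope="module")
def m2015():
    return load_machine("2015")


class TestProtonMomentum:
    @pytest.mark.parametrize(
        "energy, expected",
        [
            (938.272, 938.272 * math.sqrt(3.0)),  # E = m0c^2 makes pc = m0c^2*sqrt(3)
            (230.0, 696.0640200441336),
            (71.3, 372.6677839577765),
        ],
    )
    def test_closed_form(self, energy, expected):
        assert proton_momentum(energy) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_energy(self):
        with pytest.raises(ValueError):
            proton_momentum(0.0)
        with pytest.raises(ValueError):
            proton_momentum(-10.0)


class TestScanningSpeed:
    def test_identity_at_max_energy(self, m2015):
        assert scanning_speed_at_energy(m2015, 230.0) == (6.0, 10.0)

    def test_rigidity_scaling_at_lowest_energy(self, m2015):
        ratio = proton_momentum(230.0) / proton_momentum(71.3)
        vx, vy = scanning_speed_at_energy(m2015, 71.3)
        assert vx == pytest.approx(6.0 * ratio, rel=1e-12)
        assert vy == pytest.approx(10.0 * ratio, rel=1e-12)
        # lower-momentum beams always sweep at least as fast
        assert vx >= 6.0 and vy >= 10.0

    def test_energy_above_max_rejected(self, m2015):
        with pytest.raises(ValueError):
            scanning_speed_at_energy(m2015, 231.0)


class TestSpotTransition:
    def test_zero_travel_is_prep_only(self, m2015):
        assert spot_transition_time(m2015, (5.0, -3.0), (5.0, -3.0), 230.0) == pytest.approx(
            0.0019
        )

    def test_x_travel(self, m2015):
        # 10 mm in x at 6 m/s plus magnet preparation
        t = spot_transition_time(m2015, (0, 0), (10, 0), 230.0)
        assert t == pytest.approx(0.0019 + 0.010 / 6.0, abs=1e-12)

    def test_concurrent_axes_take_max(self, m2015):
        # 6 mm at 6 m/s and 10 mm at 10 m/s both take 1 ms; y does not add
        t = spot_transition_time(m2015, (0, 0), (6, 10), 230.0)
        assert t == pytest.approx(0.0029, abs=1e-12)


class TestSimulateDelivery:
    def test_three_spot_timeline(self, m2015, toy_plan):
        tl = simulate_delivery(toy_plan, m2015)
        tl.validate()
        assert beam_delivery_time(tl) == pytest.approx(
            3 * 0.25 + 2 * (0.0019 + 0.010 / 6.0), abs=1e-4
        )
        assert tl.n_spills() == 1

    def test_spill_ledger_five_heavy_spots(self, m2015):
        # 5 x 10 MU against a 20 MU spill: refills after spots 2 and 4
        plan = TreatmentPlan(
            layers=(EnergyLayer(230.0, tuple(Spot(0, 0, 10.0) for _ in range(5))),)
        )
        tl = simulate_delivery(plan, m2015)
        tl.validate()
        assert beam_delivery_time(tl) == pytest.approx(10.2576, abs=1e-4)
        assert tl.n_spill_changes() == 2
        assert tl.n_spills() == 3
        spill_of_event = [e.spill_index for e in tl.events]
        assert spill_of_event == [0, 0, 1, 1, 2]

    def test_oversized_spot_unservable(self, m2015):
        plan = TreatmentPlan(layers=(EnergyLayer(230.0, (Spot(0, 0, 50.0),)),))
        with pytest.raises(UnservablePlanError):
            simulate_delivery(plan, m2015)

    def test_single_event_bdt(self, m2015):
        plan = TreatmentPlan(layers=(EnergyLayer(230.0, (Spot(0, 0, 1.0),)),))
        assert beam_delivery_time(simulate_delivery(plan, m2015)) == pytest.approx(0.125)

    def test_rescanning_strictly_lengthens_delivery(self, m2015, toy_plan):
        bdt1 = beam_delivery_time(simulate_delivery(toy_plan, m2015))
        bdt2 = beam_delivery_time(
            simulate_delivery(build_layer_rescanning_plan(toy_plan, 2), m2015)
        )
        assert bdt2 > bdt1

    def test_timeline_export_columns(self, m2015, toy_plan):
        df = simulate_delivery(toy_plan, m2015).to_dataframe()
        assert set(df.columns) == {
            "event_kind", "layer_index", "spot_index", "rescan_pass",
            "mu", "t_start", "t_end", "spill_index",
        }
        assert df.t_start.is_monotonic_increasing


class TestOracleEquivalence:
    def test_random_plans_match_naive_walk(self):
        """Event-for-event agreement with an independently coded cursor walk."""
        rng = np.random.default_rng(20240)
        for _ in range(60):
            machine = random_machine(rng)
            plan = random_toy_plan(rng, max_mu=machine.max_mu_per_spill * 0.9)
            tl = simulate_delivery(plan, machine)
            tl.validate()
            ev, gaps = naive_walk(plan, machine)
            assert len(ev) == len(tl.events)
            for (lj, t0, t1, mu, spill), e in zip(ev, tl.events):
                assert e.layer_index == lj
                assert e.spill_index == spill
                assert e.t_start == pytest.approx(t0, abs=1e-9)
                assert e.t_end == pytest.approx(t1, abs=1e-9)
            assert [g.kind for g in tl.gaps] == [k for k, _, _ in gaps]


class TestTimingProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 8))
    def test_beam_on_time_conserved_under_rescanning(self, seed, n):
        """Total beam-on time is total MU / current, whatever the spill split."""
        rng = np.random.default_rng(seed)
        machine = random_machine(rng)
        plan = random_toy_plan(rng, max_mu=machine.max_mu_per_spill * 0.9)
        tl = simulate_delivery(build_layer_rescanning_plan(plan, n), machine)
        assert tl.beam_on_time() == pytest.approx(
            plan.total_mu / machine.beam_current, rel=1e-9
        )

    def test_bdt_monotone_in_rescan_number(self, m2015, toy_plan):
        bdts = [
            beam_delivery_time(simulate_delivery(build_layer_rescanning_plan(toy_plan, n), m2015))
            for n in (1, 2, 4, 8, 16, 24)
        ]
        assert all(b >= a for a, b in zip(bdts, bdts[1:]))

    def test_generation_dominance(self, machines):
        """Faster operating points never deliver the same plan more slowly."""
        rng = np.random.default_rng(7)
        m2015, m2025a, m2025b = machines
        for _ in range(20):
            plan = random_toy_plan(rng, max_mu=18.0)
            b15 = beam_delivery_time(simulate_delivery(plan, m2015))
            b25a = beam_delivery_time(simulate_delivery(plan, m2025a))
            b25b = beam_delivery_time(simulate_delivery(plan, m2025b))
            assert b25b <= b25a <= b15


class TestPresets:
    def test_all_three_ship(self):
        assert list_machine_presets() == ["2015", "2025A", "2025B"]

    def test_2025b_unlimited_mee(self):
        m = load_machine("2025B")
        assert m.max_mee_layers_per_spill is None
        assert m.recapture_efficiency == 1.0
        assert m.beam_current == 40.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MachineParameters(
                name="bad", scan_speed_x_max_energy=-1, scan_speed_y_max_energy=10,
                magnet_prep_time=0.001, spill_change_time=2, max_mu_per_spill=20,
                max_mee_layers_per_spill=4, recapture_efficiency=0.5,
                mee_layer_switch_time=0.2, beam_current=8,
            )
        with pytest.raises(ValueError):
            MachineParameters(
                name="bad", scan_speed_x_max_energy=6, scan_speed_y_max_energy=10,
                magnet_prep_time=0.001, spill_change_time=2, max_mu_per_spill=20,
                max_mee_layers_per_spill=4, recapture_efficiency=1.5,
                mee_layer_switch_time=0.2, beam_current=8,
            )
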