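"""Two-unit RNA->protein model and n-unit chain/web tests."""

import numpy as np
import pytest

import ageflux as af


@pytest.fixture
def model_high_dpa():
    """Demand for protein activity far above anything the pool can reach."""
    return af.default_coupled_model(af.ConstantDemand(1000.0))


class TestDeriveUpstreamDemand:
    @pytest.mark.parametrize("dpa,tpa,gain,expected", [
        (100.0, 100.0, 1.0, 0.0),   # no deficit
        (100.0, 40.0, 1.0, 60.0),   # deficit passthrough
        (100.0, 120.0, 2.0, 0.0),   # clamped at zero
        (100.0, 40.0, 2.0, 120.0),  # gain scaling
    ])
    def test_examples(self, dpa, tpa, gain, expected):
        assert af.derive_upstream_demand(dpa, tpa, gain) == expected

    def test_rejects_negative_inputs(self):
        with pytest.raises(af.ValidationError):
            af.derive_upstream_demand(-1.0, 0.0, 1.0)


class TestSimulateCoupled:
    def test_unattainable_demand_peaks_at_nascent_amounts(self,
                                                          model_high_dpa):
        # protein activity never covers the demand, so both units pulse
        # every step: production rates peak at the nascent amounts
        trajs = af.simulate_coupled(model_high_dpa, 80)
        assert trajs.rna.produced[1:].max() == 100.0
        assert trajs.protein.produced.max() == 48.0
        # late in the run both pulse continuously
        assert np.all(trajs.rna.produced[-20:] == 100.0)
        assert np.all(trajs.protein.produced[-20:] == 48.0)

    def test_attainable_demand_gives_periodic_orbits(self):
        trajs = af.simulate_coupled(
            af.default_coupled_model(af.ConstantDemand(25.0)), 300)
        assert af.classify_regimes(trajs) == ("cycling", "cycling")

    def test_unattainable_demand_stabilizes_both_levels(self, model_high_dpa):
        trajs = af.simulate_coupled(model_high_dpa, 120)
        assert af.classify_regimes(trajs) == ("stable", "stable")

    def test_both_units_conserve_mass(self, model_high_dpa):
        trajs = af.simulate_coupled(model_high_dpa, 60)
        for traj in (trajs.rna, trajs.protein):
            assert np.all(traj.conservation_residual() < 1e-9)

    def test_zero_gain_silences_rna_and_starves_protein(self):
        model = af.default_coupled_model(af.ConstantDemand(100.0),
                                         coupling_gain=0.0)
        trajs = af.simulate_coupled(model, 60)
        assert np.all(trajs.rna.produced == 0.0)
        assert np.all(trajs.rna.tb == 0.0)
        # no RNA substrate -> no translation ever
        assert np.all(trajs.protein.produced == 0.0)
        assert trajs.protein.tb[-1] == 0.0

    def test_protein_pulses_wait_for_rna(self, model_high_dpa):
        trajs = af.simulate_coupled(model_high_dpa, 10)
        # at t=1 there was no RNA activity yet at t=0
        assert trajs.protein.produced[1] == 0.0
        assert trajs.rna.produced[1] == 100.0
        assert trajs.protein.produced[2] == 48.0

    def test_rna_proportional_translation_variant(self):
        model = af.default_coupled_model(af.ConstantDemand(1000.0))
        model.rna_proportional = True
        model.beta = 0.1
        trajs = af.simulate_coupled(model, 40)
        # pulse magnitude capped by available RNA activity
        expected = np.minimum(48.0, 0.1 * trajs.rna.ta[1:-1])
        produced = trajs.protein.produced[2:]
        np.testing.assert_allclose(produced, expected[:produced.size])


class TestRateRatios:
    def test_constant_rates_give_constant_ratio(self, model_high_dpa):
        trajs = af.simulate_coupled(model_high_dpa, 100)
        summary = af.rate_ratio_summary(trajs.rna, trajs.protein,
                                        window=10, skip_transient=20)
        lo, hi = summary.rate_ratio_range
        assert lo == hi == pytest.approx(0.48)

    def test_tr_zero_with_protein_is_flagged_unbounded(self):
        profile = af.make_profile("B", "A")
        rna = af.Trajectory(
            time=np.arange(3), tb=np.array([0.0, 0.0, 0.0]),
            ta=np.zeros(3), da=np.zeros(3), produced=np.zeros(3),
            degraded=np.zeros(3), acc_production=np.zeros(3),
            acc_degradation=np.zeros(3), ages=np.zeros((3, 11)))
        protein = af.Trajectory(
            time=np.arange(3), tb=np.array([5.0, 5.0, 5.0]),
            ta=np.zeros(3), da=np.zeros(3), produced=np.zeros(3),
            degraded=np.zeros(3), acc_production=np.zeros(3),
            acc_degradation=np.zeros(3), ages=np.zeros((3, 11)))
        summary = af.rate_ratio_summary(rna, protein, window=1)
        assert np.all(np.isinf(summary.tpro_tr_ratio))
        assert np.all(summary.unbounded_steps)

    def test_attainable_demand_transcription_rate_band(self):
        # cycling regime: windowed transcription rates vary, translation
        # rates move in a narrower band, per-window ratios stay bounded
        trajs = af.simulate_coupled(
            af.default_coupled_model(af.ConstantDemand(25.0)), 300)
        summary = af.rate_ratio_summary(trajs.rna, trajs.protein,
                                        window=10, skip_transient=50)
        lo, hi = summary.transcription_rate_range
        assert 0.0 < lo < hi < 100.0


class TestChain:
    def test_single_unit_chain_equals_core_simulator(self, type_b_profile,
                                                     pulse100):
        spec = af.ChainSpec.chain(
            [af.UnitSpec(type_b_profile, pulse100)], af.ConstantDemand(50.0))
        chain_traj = af.simulate_chain(spec, 80)[0]
        core_traj = af.simulate(type_b_profile, pulse100,
                                af.ConstantDemand(50.0), 80)
        np.testing.assert_array_equal(chain_traj.tb, core_traj.tb)
        np.testing.assert_array_equal(chain_traj.ages, core_traj.ages)

    def test_two_unit_chain_equals_coupled_model(self, model_high_dpa):
        spec = af.ChainSpec.chain(
            [af.UnitSpec(model_high_dpa.rna_profile,
                         model_high_dpa.rna_policy, label="rna"),
             af.UnitSpec(model_high_dpa.protein_profile,
                         model_high_dpa.protein_policy, label="protein")],
            model_high_dpa.dpa)
        chain = af.simulate_chain(spec, 80)
        coupled = af.simulate_coupled(model_high_dpa, 80)
        np.testing.assert_array_equal(chain[0].tb, coupled.rna.tb)
        np.testing.assert_array_equal(chain[1].tb, coupled.protein.tb)
        np.testing.assert_array_equal(chain[0].produced, coupled.rna.produced)
        np.testing.assert_array_equal(chain[1].produced,
                                      coupled.protein.produced)

    def test_three_unit_chain_with_silent_middle(self, type_b_profile):
        # the middle unit never produces, so the terminal unit starves and
        # its deficit propagates upstream: unit 0 saturates at every-step
        # pulsing; verified against a hand-stepped oracle
        pulse = af.PulsePolicy(100.0)
        silent = af.PulsePolicy(0.0, "silent")
        spec = af.ChainSpec.chain(
            [af.UnitSpec(type_b_profile, pulse),
             af.UnitSpec(type_b_profile, silent),
             af.UnitSpec(type_b_profile, pulse)],
            af.ConstantDemand(500.0))
        trajs = af.simulate_chain(spec, 10)
        assert np.all(trajs[1].tb == 0.0)
        assert np.all(trajs[2].tb == 0.0)  # no substrate from unit 1
        # the full terminal deficit (500, above the reachable pool total)
        # passes through the silent unit, so unit 0 pulses every step;
        # equivalent hand-stepped oracle: the one-unit run at demand 500
        assert np.all(trajs[0].produced[1:] == 100.0)
        oracle = af.simulate(type_b_profile, pulse, af.ConstantDemand(500.0),
                             10)
        np.testing.assert_array_equal(trajs[0].tb, oracle.tb)

    def test_cyclic_topology_rejected(self, type_b_profile, pulse100):
        spec = af.ChainSpec(
            units=[af.UnitSpec(type_b_profile, pulse100),
                   af.UnitSpec(type_b_profile, pulse100)],
            demand=af.ConstantDemand(10.0),
            edges=[(0, 1, 1.0), (1, 0, 1.0)])
        with pytest.raises(af.ConfigurationError):
            af.simulate_chain(spec, 5)

    def test_web_demand_sums_weighted_deficits(self, type_b_profile):
        # one upstream unit feeding two silent consumers: its demand is the
        # weighted sum of both deficits
        silent = af.PulsePolicy(0.0, "silent")
        pulse = af.PulsePolicy(100.0)
        spec = af.ChainSpec(
            units=[af.UnitSpec(type_b_profile, pulse),
                   af.UnitSpec(type_b_profile, silent),
                   af.UnitSpec(type_b_profile, silent)],
            demand=af.ConstantDemand(30.0),
            edges=[(0, 1, 1.0), (0, 2, 0.5)])
        trajs = af.simulate_chain(spec, 5)
        # both consumers face demand 30 with zero activity: deficits 30
        assert np.all(trajs[0].da[1:] == 30.0 * 1.0 + 30.0 * 0.5)
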