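"""ODE simulation, protocols and forward sensitivities."""

import numpy as np
import pytest

from sloppysys.networks import DNARepairModel, ReactionNetwork, Reaction, Species, dna_repair_rhs
from sloppysys.simulate import (
    DNARepairSimulator,
    ExperimentProtocol,
    NetworkModel,
    dose_segments,
    fd_jacobian,
    sensitivities,
    simulate,
)

from conftest import rk4_integrate


class TestProtocol:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ExperimentProtocol(id="p", times=(1.0, 1.0, 2.0))

    def test_knockout_overexpress_conflict(self):
        with pytest.raises(ValueError, match="knocked out"):
            ExperimentProtocol(id="p", times=(1.0,), knockouts=("A",),
                               overexpress={"A": 2.0})

    def test_total_dose_sums_fractions(self):
        p = ExperimentProtocol(id="p", doses=(9.0, 5.0))
        assert p.total_dose == 14.0

    def test_dose_segments_arithmetic(self):
        p = ExperimentProtocol(id="p", doses=(7.0, 7.0), dose_rate=1.84, rest=4.0)
        segs = dose_segments(p)
        rate_h = 1.84 * 60
        dur = 7.0 / rate_h
        assert segs[0] == pytest.approx((0.0, dur, rate_h))
        assert segs[1] == pytest.approx((dur, dur + 4.0, 0.0))
        assert segs[2][2] == pytest.approx(rate_h)
        # delivered dose = rate x exposure time
        assert sum((t1 - t0) * r for t0, t1, r in segs) == pytest.approx(14.0)


class TestSimulate:
    def test_frozen_dynamics(self, decay_network):
        frozen = decay_network.with_parameters([1e-30])
        proto = ExperimentProtocol(id="p", times=(1.0, 10.0), observables=("S",))
        pred = simulate(frozen, proto)
        assert pred.values == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_exponential_closed_form(self, decay_network):
        times = (0.3, 1.0, 2.5)
        proto = ExperimentProtocol(id="p", times=times, observables=("S", "P"))
        pred = simulate(decay_network, proto)
        expect = []
        for t in times:
            s = np.exp(-0.7 * t)
            expect += [s, 1 - s]
        assert pred.values == pytest.approx(expect, rel=1e-8, abs=1e-10)

    def test_stimulus_clamps_species(self, single_mm_network):
        proto = ExperimentProtocol(id="p", times=(1.0, 5.0),
                                   stimuli={"S": 2.0}, observables=("P",))
        pred = simulate(single_mm_network, proto)
        # with S clamped at 2, product grows linearly at v = kcat*E*2/(KM+2)
        v = 2.0 * 0.05 * 2.0 / (5.0 + 2.0)
        assert pred.values == pytest.approx([v * 1.0, v * 5.0], rel=1e-6)

    def test_knockout_freezes_flux(self, single_mm_network):
        proto = ExperimentProtocol(id="p", times=(5.0,), knockouts=("E",),
                                   observables=("P",))
        assert simulate(single_mm_network, proto).values[0] == pytest.approx(0.0, abs=1e-10)


class TestSensitivities:
    def test_zero_column_for_decoupled_parameter(self):
        # two independent conversions; P1 ignores k2
        net = ReactionNetwork(
            species=[Species("A", 1.0), Species("P1", 0.0),
                     Species("B", 1.0), Species("P2", 0.0)],
            reactions=[
                Reaction(name="r1", kind="mass_action_elementary",
                         substrates=(("A", 1),), products=(("P1", 1),), k="k1"),
                Reaction(name="r2", kind="mass_action_elementary",
                         substrates=(("B", 1),), products=(("P2", 1),), k="k2"),
            ],
            parameters={"k1": 0.5, "k2": 1.5},
            observables={"P1": {"P1": 1.0}})
        proto = ExperimentProtocol(id="p", times=(1.0, 2.0), observables=("P1",))
        pred = sensitivities(net, proto)
        assert np.abs(pred.sens[:, 1]).max() < 1e-8

    def test_log_chain_rule_on_decay(self, decay_network):
        # d S(t) / d log k = -k t S(t) analytically
        proto = ExperimentProtocol(id="p", times=(0.5, 1.5), observables=("S",))
        pred = sensitivities(decay_network, proto)
        for row, t in zip(pred.sens[:, 0], (0.5, 1.5)):
            assert row == pytest.approx(-0.7 * t * np.exp(-0.7 * t), rel=1e-6)

    def test_forward_matches_finite_differences(self, single_mm_network):
        proto = ExperimentProtocol(id="p", times=(0.5, 2.0, 8.0),
                                   observables=("P",))
        model = NetworkModel(single_mm_network, [proto])
        pred = model.predict_with_sens()
        J = fd_jacobian(lambda lp: model.predict(lp).values,
                        model.reference_log_params(), step=1e-4)
        scale = np.abs(J).max()
        assert np.abs(pred.sens - J).max() / scale < 1e-3


class TestDNASimulator:
    MODEL = DNARepairModel(0.5, 0.05, 1.0, 0.05, 1.0, 0.05)

    def test_single_fraction_trajectory_against_rk4(self):
        proto = ExperimentProtocol(id="7gy", doses=(7.0,), dose_rate=1.84)
        sim = DNARepairSimulator(self.MODEL, [proto])
        t_dose = 7.0 / (1.84 * 60)
        times = np.array([t_dose, 0.5, 2.0, 6.0])
        traj = sim.trajectory(proto, times)

        def rhs_factory(r):
            return lambda t, y: dna_repair_rhs(y, t, r, self.MODEL)

        grid1 = np.linspace(0.0, t_dose, 2001)
        seg1 = rk4_integrate(rhs_factory(1.84 * 60), (0.0, 0.0), grid1)
        oracle = {t_dose: seg1[-1]}
        # repair-phase grid hits each observation time exactly
        state = seg1[-1]
        t_prev = t_dose
        for t in times[1:]:
            grid = np.linspace(t_prev, t, 20001)
            state = rk4_integrate(rhs_factory(0.0), state, grid)[-1]
            oracle[t] = state
            t_prev = t
        for i, t in enumerate(times):
            ref = oracle[t]
            assert np.abs(traj[:, i] - ref).max() / np.abs(ref).max() < 1e-6

    def test_survival_sensitivities_match_finite_differences(self):
        protos = [ExperimentProtocol(id="a", doses=(7.0,)),
                  ExperimentProtocol(id="b", doses=(4.0, 10.0), rest=4.0)]
        sim = DNARepairSimulator(self.MODEL, protos)
        pred = sim.predict_with_sens()
        J = fd_jacobian(lambda lp: sim.predict(lp).values,
                        sim.reference_log_params(), step=1e-4)
        assert np.abs(pred.sens - J).max() / np.abs(J).max() < 1e-3

    def test_survival_is_poisson_zero_class(self):
        proto = ExperimentProtocol(id="7gy", doses=(7.0,))
        sim = DNARepairSimulator(self.MODEL, [proto])
        surv = sim.predict().values[0]
        traj = sim.trajectory(proto, np.array([200.0]))
        assert surv == pytest.approx(np.exp(-traj[1, 0]), rel=1e-5)

    def test_split_dose_sparing(self):
        # splitting a dose with a long rest spares repairable damage
        single = ExperimentProtocol(id="s", doses=(14.0,))
        split = ExperimentProtocol(id="d", doses=(7.0, 7.0), rest=8.0)
        sim = DNARepairSimulator(self.MODEL, [single, split])
        v = sim.predict().values
        assert v[1] > v[0]


class TestSolverRobustness:
    def test_tolerance_halving_is_below_noise_floor(self, single_mm_network):
        proto = ExperimentProtocol(id="p", times=(1.0, 4.0, 16.0),
                                   observables=("P",))
        loose = simulate(single_mm_network, proto)
        tight = simulate(single_mm_network, proto, rtol=5e-9, atol=5e-11)
        # far below a 10%-of-signal noise floor
        assert np.abs(loose.values - tight.values).max() < 1e-6 * np.abs(tight.values).max()
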