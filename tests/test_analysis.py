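"""Lifespan evaluation, interventions and sensitivity analyses."""

import numpy as np
import pytest

from fuzzycell import (
    FitnessCriteria,
    SimulationConfig,
    accumulated_energy,
    lifespan,
    rate_magnitude_regression,
    run_blockade_experiment,
    run_mtor_experiment,
    sensor_sweep,
    sof_screen,
    simulate,
)
from fuzzycell.analysis import OXPROT_ONLY, SOFRecord
from fuzzycell.engine import SimulationResult
from fuzzycell.model_spec import parse_model


def synthetic_result(**series):
    """Hand-built trajectory container for criterion arithmetic."""
    n = len(next(iter(series.values())))
    times = np.linspace(0, 40, n)
    return SimulationResult(
        times=times,
        series={k: np.asarray(v, dtype=float) for k, v in series.items()},
        config=SimulationConfig(n_steps=n - 1),
    )


class TestLifespan:
    def test_linear_ramp_crosses_at_midpoint(self):
        n = 4001
        result = synthetic_result(
            OXPROT=np.linspace(0, 0.8, n),
            ROS=np.full(n, 0.1),
            ATPconsume=np.full(n, 0.8),
        )
        ls = lifespan(result)
        assert ls.lifespan == pytest.approx(20.0, abs=0.02)
        assert ls.triggering_criterion == "OXPROT_ge_0.4"

    def test_flat_series_censored_at_horizon(self):
        n = 101
        result = synthetic_result(
            OXPROT=np.full(n, 0.1), ROS=np.full(n, 0.1),
            ATPconsume=np.full(n, 0.8))
        ls = lifespan(result)
        assert ls.censored and ls.lifespan == 40.0

    def test_earliest_of_three_wins(self):
        n = 4001
        result = synthetic_result(
            OXPROT=np.linspace(0, 0.8, n),          # crosses at 20
            ROS=np.linspace(0, 1.6, n),             # crosses at 10
            ATPconsume=np.full(n, 0.8),
        )
        ls = lifespan(result)
        assert ls.triggering_criterion == "ROS_ge_0.4"
        assert ls.lifespan == pytest.approx(10.0, abs=0.02)

    def test_missing_criterion_node_is_an_error(self):
        result = synthetic_result(OXPROT=np.full(11, 0.0))
        with pytest.raises(KeyError, match="ROS"):
            lifespan(result)

    def test_raising_threshold_never_shortens_life(self, ar_run):
        lifespans = [
            lifespan(ar_run, FitnessCriteria(oxprot_max=x)).lifespan
            for x in (0.2, 0.3, 0.4, 0.5)
        ]
        assert lifespans == sorted(lifespans)


class TestAccumulatedEnergy:
    def test_constant_consumption_rectangle(self):
        result = synthetic_result(ATPconsume=np.full(1001, 0.8))
        assert accumulated_energy(result) == pytest.approx(32.0)

    def test_zero_series_integrates_to_zero(self):
        result = synthetic_result(ATPconsume=np.zeros(101))
        assert accumulated_energy(result) == 0.0

    def test_lifespan_cutoff_restricts_the_integral(self):
        result = synthetic_result(ATPconsume=np.full(1001, 0.5))
        assert accumulated_energy(result, until=20.0) == pytest.approx(10.0)

    def test_ar_turns_over_more_energy_than_vc_over_life(self, vc_run, ar_run):
        vc_life = lifespan(vc_run, OXPROT_ONLY).lifespan
        ar_life = lifespan(ar_run, OXPROT_ONLY).lifespan
        assert (accumulated_energy(ar_run, until=ar_life)
                > accumulated_energy(vc_run, until=vc_life))


class TestBlockade:
    def test_blockade_at_horizon_end_changes_nothing(self, ar_model):
        config = SimulationConfig(t_end=10, n_steps=1000)
        outcome = run_blockade_experiment(ar_model, blockade_time=10.0,
                                          config=config)
        for node in outcome.baseline.node_names:
            assert np.array_equal(outcome.baseline[node], outcome.blocked[node])

    def test_midlife_blockade_accelerates_ros_without_extending_life(
            self, ar_model, ar_run):
        life = lifespan(ar_run, OXPROT_ONLY).lifespan
        outcome = run_blockade_experiment(ar_model, blockade_time=life / 2)
        assert outcome.ros_slope_blocked > outcome.ros_slope_baseline
        assert (outcome.lifespan_blocked.lifespan
                <= outcome.lifespan_baseline.lifespan)

    def test_model_without_sensor_is_rejected(self, vc_model):
        with pytest.raises(ValueError, match="NFkB"):
            run_blockade_experiment(vc_model, blockade_time=5.0)


class TestMtorExperiment:
    def test_unit_factor_reproduces_baseline(self, ar_model):
        config = SimulationConfig(t_end=10, n_steps=1000)
        outcome = run_mtor_experiment(ar_model, 1.0, config)
        for node in outcome.baseline.node_names:
            assert np.array_equal(outcome.baseline[node], outcome.perturbed[node])

    def test_reduced_atp_sensitivity_dips_then_rises_and_shortens_life(
            self, ar_model):
        outcome = run_mtor_experiment(ar_model, 0.8)
        perturbed = outcome.perturbed["MTOR"]
        times = outcome.perturbed.times
        # early dip below the initial activity, late rise above the
        # unperturbed trajectory
        early = perturbed[times <= 15]
        assert early.min() < perturbed[0] - 0.05
        late = times >= 30
        assert perturbed[late].mean() > outcome.baseline["MTOR"][late].mean()
        assert (outcome.lifespan_perturbed.lifespan
                < outcome.lifespan_baseline.lifespan)

    def test_model_without_mtor_is_rejected(self, vc_model):
        with pytest.raises(ValueError, match="MTOR_ATP"):
            run_mtor_experiment(vc_model, 0.8)


class TestSofScreen:
    def test_zero_perturbation_rejected(self, vc_model):
        with pytest.raises(ValueError):
            sof_screen(vc_model, perturbation=0.0)

    def test_inert_reaction_scores_exactly_zero(self):
        # An isolated decay reaction cannot move any criterion node.
        text = (
            "node OXPROT 0.0\nnode ROS 0.1\nnode ATPconsume 0.8\nnode X 0.5\n"
            "Reaction ox 0.02\npro OXPROT 5 5 5 5 5 5\n"
            "Reaction decay 0.3\nsub X 0 1 2 3 4 5\n"
        )
        model = parse_model(text)
        records = {r.reaction: r for r in sof_screen(
            model, config=SimulationConfig(t_end=40, n_steps=2000))}
        assert records["decay"].sof == 0.0
        assert not records["decay"].significant

    def test_sof_arithmetic_from_definition(self):
        record = SOFRecord(
            reaction="toy", rate_coefficient=1.0, perturbation=0.05,
            lifespan_baseline=20.0, lifespan_perturbed=25.0,
            lifespan_change=0.25, sof=5.0, significant=True)
        assert record.sof == record.lifespan_change / record.perturbation
        assert abs(record.sof) > 2.5

    def test_positive_and_negative_perturbations_agree_in_sign(
            self, ar_model, ar_screen):
        """Local smoothness: for reactions flagged significant by the +5%
        screen, a -5% perturbation moves lifespan the opposite way."""
        up = {r.reaction: r for r in ar_screen}
        significant = [name for name, r in up.items() if r.significant]
        down = {r.reaction: r for r in sof_screen(ar_model, -0.05)}
        agreeing = sum(
            1 for name in significant
            if np.sign(down[name].sof) == np.sign(up[name].sof)
            or down[name].sof == 0.0
        )
        assert agreeing >= len(significant) - 2


class TestSensorSweep:
    def test_zero_delta_is_bit_exact_baseline(self, ar_model, ar_run):
        config = SimulationConfig()
        runs = sensor_sweep(ar_model, "mtor", [0.0], config=config)
        assert np.array_equal(runs[0].result["MTOR"], ar_run["MTOR"])

    def test_unknown_sensor_rejected(self, ar_model):
        with pytest.raises(ValueError, match="sensor"):
            sensor_sweep(ar_model, "p53", [0.0])

    def test_mtor_lifespan_rises_with_atp_sensitivity(self, ar_model):
        deltas = [-0.2, -0.1, 0.0, 0.1, 0.2]
        runs = sensor_sweep(ar_model, "mtor", deltas)
        lifespans = [r.lifespan.lifespan for r in runs]
        assert all(b >= a for a, b in zip(lifespans, lifespans[1:]))
        assert lifespans[-1] > lifespans[0]

    def test_only_strong_nfkb_loss_cuts_lifespan(self, ar_model):
        runs = sensor_sweep(ar_model, "nfkb", [-0.5, -0.2, 0.0, 0.2, 1.0])
        lifespans = {r.delta: r.lifespan.lifespan for r in runs}
        assert lifespans[-0.5] == min(lifespans.values())
        assert lifespans[-0.5] < lifespans[0.0] - 2.0

    def test_nfkb_trajectories_spread_at_midlife_and_reconverge(self, ar_model):
        runs = sensor_sweep(ar_model, "nfkb",
                            [-0.5, -0.2, -0.1, 0.0, 0.1, 0.2, 1.0])
        shortest = min(len(r.result.times) for r in runs)
        stack = np.array([r.result["NFkB"][:shortest] for r in runs])
        spread = stack.max(axis=0) - stack.min(axis=0)
        third = shortest // 3
        assert spread[third:2 * third].max() > spread[2 * third:].max()


class TestRateMagnitudeRegression:
    @staticmethod
    def _records(rates, changes):
        return [
            SOFRecord(reaction=f"r{i}", rate_coefficient=k, perturbation=0.05,
                      lifespan_baseline=30.0, lifespan_perturbed=30.0 * (1 + c),
                      lifespan_change=c, sof=c / 0.05,
                      significant=abs(c / 0.05) > 2.5)
            for i, (k, c) in enumerate(zip(rates, changes))
        ]

    def test_perfect_line_is_recovered(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5]
        records = self._records(rates, [2 * k for k in rates])
        slope, intercept, pvalue = rate_magnitude_regression(records)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert pvalue < 1e-6

    def test_pure_noise_rarely_flags_significance(self):
        rng = np.random.default_rng(7)
        false_positives = 0
        for _ in range(100):
            rates = rng.uniform(0.05, 1.0, size=20)
            records = self._records(rates, rng.normal(0, 1, size=20))
            _, _, pvalue = rate_magnitude_regression(records)
            false_positives += pvalue < 0.05
        assert false_positives <= 10

    def test_reference_screen_shows_no_rate_size_relationship(self, ar_screen):
        _, _, pvalue = rate_magnitude_regression(ar_screen)
        assert pvalue > 0.05

    def test_degenerate_predictor_rejected(self):
        records = self._records([0.3, 0.3, 0.3], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            rate_magnitude_regression(records)
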