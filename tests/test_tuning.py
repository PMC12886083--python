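import numpy as np
import pytest

import ventwave as vw
from conftest import make_breath_train

TUNED = vw.AlgorithmParams.tuned()


def _settings(**kwargs):
    defaults = dict(
        run_id="r1", set_insp_volume=500.0, set_exp_volume=500.0,
        set_peak_pressure=20.0, set_rate=10.0, duration=120.0,
    )
    defaults.update(kwargs)
    return vw.RunSettings(**defaults)


def _detected_run(n_breaths=20, period=6.0, duration=120.0):
    rec = make_breath_train(n_breaths=n_breaths, period=period)
    events, measures = vw.analyze_recording(rec, TUNED)
    return rec, events, measures


class TestMatchBreaths:
    def test_full_detection_pairs_every_breath_and_rate(self):
        _, events, measures = _detected_run()
        pairs = vw.match_breaths(events, measures, _settings())
        by = {}
        for p in pairs:
            by.setdefault(p.measure, []).append(p)
        assert len(by["insp_volume"]) == 20
        assert len(by["exp_volume"]) == 20
        assert len(by["peak_pressure"]) == 20
        assert len(by["rate"]) == 19  # first breath has no instantaneous rate

    def test_missed_breaths_contribute_zero_pairs(self):
        pairs = vw.match_breaths([], [], _settings(set_exp_volume=None, set_peak_pressure=None))
        insp = [p for p in pairs if p.measure == "insp_volume"]
        assert len(insp) == 20  # round(10/min * 120 s / 60)
        assert all(p.measured == 0.0 and p.set_value == 500.0 for p in insp)
        assert not any(p.measure == "rate" for p in pairs)

    def test_synchronous_run_has_no_rate_pairs_or_miss_penalty(self):
        _, events, measures = _detected_run(n_breaths=5)
        pairs = vw.match_breaths(
            events, measures, _settings(cpr_mode="synchronous", set_rate=None)
        )
        assert not any(p.measure == "rate" for p in pairs)
        assert len([p for p in pairs if p.measure == "insp_volume"]) == 5

    def test_miss_penalty_switchable(self):
        pairs = vw.match_breaths([], [], _settings(), include_missed=False)
        assert pairs == []

    def test_truncated_breaths_are_excluded(self):
        _, events, measures = _detected_run(n_breaths=3)
        from dataclasses import replace

        events = list(events)
        events[-1] = replace(events[-1], truncated=True)
        pairs = vw.match_breaths(events, measures, _settings(set_rate=None))
        assert len([p for p in pairs if p.measure == "insp_volume"]) == 2

    def test_excluded_expiratory_runs_produce_no_exp_pairs(self):
        _, events, measures = _detected_run(n_breaths=3)
        pairs = vw.match_breaths(events, measures, _settings(exclude_exp=True, set_rate=None))
        assert not any(p.measure == "exp_volume" for p in pairs)


class TestStandardizedObjective:
    def test_single_measure_arithmetic(self):
        # deviations {10, 20} ml with set-value SD 100 ml -> 0.15
        pairs = [
            vw.MeasurePair("insp_volume", 510.0, 500.0, "a"),
            vw.MeasurePair("insp_volume", 280.0, 300.0, "b"),
        ]
        settings = [
            _settings(run_id="a", set_insp_volume=500.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None),
            _settings(run_id="b", set_insp_volume=300.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None),
        ]
        sd = np.std([500.0, 300.0], ddof=1)
        objective, devs = vw.standardized_objective(pairs, settings)
        assert objective == pytest.approx(15.0 / sd)
        assert devs == {"insp_volume": pytest.approx(15.0 / sd)}

    def test_perfect_detection_scores_zero(self):
        pairs = [
            vw.MeasurePair("insp_volume", 500.0, 500.0, "a"),
            vw.MeasurePair("insp_volume", 300.0, 300.0, "b"),
        ]
        settings = [
            _settings(run_id="a", set_exp_volume=None, set_peak_pressure=None, set_rate=None),
            _settings(run_id="b", set_insp_volume=300.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None),
        ]
        objective, _ = vw.standardized_objective(pairs, settings)
        assert objective == 0.0

    def test_objective_is_unweighted_mean_over_measures(self):
        settings = [
            _settings(run_id="a", set_insp_volume=400.0, set_exp_volume=380.0,
                      set_peak_pressure=None, set_rate=None),
            _settings(run_id="b", set_insp_volume=600.0, set_exp_volume=580.0,
                      set_peak_pressure=None, set_rate=None),
        ]
        sd = np.std([400.0, 600.0], ddof=1)  # same for exp by construction
        pairs = [
            vw.MeasurePair("insp_volume", 400.0 + 0.2 * sd, 400.0, "a"),
            vw.MeasurePair("exp_volume", 380.0 + 0.4 * sd, 380.0, "a"),
        ]
        objective, devs = vw.standardized_objective(pairs, settings)
        assert devs["insp_volume"] == pytest.approx(0.2)
        assert devs["exp_volume"] == pytest.approx(0.4)
        assert objective == pytest.approx(0.3)

    def test_zero_sd_measure_excluded_with_warning(self):
        settings = [
            _settings(run_id="a", set_rate=10.0, set_exp_volume=None, set_peak_pressure=None),
            _settings(run_id="b", set_insp_volume=300.0, set_rate=10.0,
                      set_exp_volume=None, set_peak_pressure=None),
        ]
        pairs = [
            vw.MeasurePair("insp_volume", 500.0, 500.0, "a"),
            vw.MeasurePair("rate", 12.0, 10.0, "a"),
        ]
        with pytest.warns(UserWarning, match="rate"):
            _, devs = vw.standardized_objective(pairs, settings)
        assert "rate" not in devs

    def test_no_usable_measure_is_degenerate(self):
        settings = [_settings(run_id="a", set_exp_volume=None, set_peak_pressure=None,
                              set_rate=None)]
        pairs = [vw.MeasurePair("insp_volume", 500.0, 500.0, "a")]
        with pytest.warns(UserWarning):
            with pytest.raises(vw.DegenerateInputError):
                vw.standardized_objective(pairs, settings)

    def test_unit_rescaling_invariance(self):
        settings = [
            _settings(run_id="a", set_exp_volume=None, set_peak_pressure=None, set_rate=None),
            _settings(run_id="b", set_insp_volume=300.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None),
        ]
        pairs = [
            vw.MeasurePair("insp_volume", 480.0, 500.0, "a"),
            vw.MeasurePair("insp_volume", 310.0, 300.0, "b"),
        ]
        obj_ml, _ = vw.standardized_objective(pairs, settings)
        litres = [
            vw.MeasurePair(p.measure, p.measured / 1000, p.set_value / 1000, p.run_id)
            for p in pairs
        ]
        settings_l = [
            vw.RunSettings(run_id=s.run_id, set_insp_volume=s.set_insp_volume / 1000)
            for s in settings
        ]
        obj_l, _ = vw.standardized_objective(litres, settings_l)
        assert obj_l == pytest.approx(obj_ml, rel=1e-12)

    def test_adding_a_perfect_run_never_increases_deviations(self):
        settings = [
            _settings(run_id="a", set_exp_volume=None, set_peak_pressure=None, set_rate=None),
            _settings(run_id="b", set_insp_volume=300.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None),
        ]
        pairs = [
            vw.MeasurePair("insp_volume", 450.0, 500.0, "a"),
            vw.MeasurePair("insp_volume", 330.0, 300.0, "b"),
        ]
        _, devs_before = vw.standardized_objective(pairs, settings)
        # a third run in perfect agreement, with a set value at the mean so the
        # across-run SD cannot shrink
        settings2 = settings + [
            _settings(run_id="c", set_insp_volume=400.0, set_exp_volume=None,
                      set_peak_pressure=None, set_rate=None)
        ]
        pairs2 = pairs + [vw.MeasurePair("insp_volume", 400.0, 400.0, "c")]
        _, devs_after = vw.standardized_objective(pairs2, settings2)
        assert devs_after["insp_volume"] <= devs_before["insp_volume"]


def _two_run_dataset(flow_amp=(20.0, 30.0), pressure_amp=(5.0, 7.0), n_breaths=5):
    """Two 30-s runs whose plateaus sit below the high grid threshold A=10."""
    dataset = []
    for i in range(2):
        rec = make_breath_train(
            n_breaths=n_breaths, period=6.0, flow_amp=flow_amp[i],
            pressure_amp=pressure_amp[i], tail=3.0,
        )
        insp = flow_amp[i] / 60.0 * 1.0 * 1000.0  # constant flow for 1 s
        settings = vw.RunSettings(
            run_id=f"r{i}", set_insp_volume=insp, set_exp_volume=insp,
            set_peak_pressure=pressure_amp[i], set_rate=10.0,
            duration=rec.duration,
        )
        dataset.append((rec, settings))
    return dataset


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self):
        dataset = _two_run_dataset(pressure_amp=(20.0, 22.0))
        grid = vw.GridSpec(
            pressure_threshold_A=(8.0,), pressure_duration_B=(0.3,),
            ventilation_lead_C=(0.3,), abs_flow_threshold_D=(5.0,),
            inactive_delay_E=(0.2,),
        )
        result = vw.grid_search(dataset, grid)
        assert len(result.table) == 1
        assert result.best.pressure_threshold_A == 8.0
        pairs = []
        for rec, settings in dataset:
            events, measures = vw.analyze_recording(rec, TUNED)
            pairs.extend(vw.match_breaths(events, measures, settings))
        objective, _ = vw.standardized_objective(pairs, [s for _, s in dataset])
        assert result.best_objective == pytest.approx(objective, rel=1e-12)

    def test_low_threshold_wins_when_high_threshold_misses_all_breaths(self):
        # Plateaus of 5 and 7 cmH2O: A=2 detects every breath, A=10 none;
        # the miss penalty dominates and the argmin takes A=2.
        dataset = _two_run_dataset()
        grid = vw.GridSpec(
            pressure_threshold_A=(2.0, 10.0), pressure_duration_B=(0.3,),
            ventilation_lead_C=(0.3,), abs_flow_threshold_D=(5.0,),
            inactive_delay_E=(0.2,),
        )
        result = vw.grid_search(dataset, grid)
        assert len(result.table) == 2
        assert result.best.pressure_threshold_A == 2.0
        objectives = dict(zip(result.table["A"], result.table["objective"]))
        assert objectives[2.0] < objectives[10.0]

    def test_reevaluating_best_point_reproduces_tabled_objective(self):
        dataset = _two_run_dataset(pressure_amp=(20.0, 22.0))
        grid = vw.GridSpec(
            pressure_threshold_A=(2.0, 8.0), pressure_duration_B=(0.1, 0.3),
            ventilation_lead_C=(0.3,), abs_flow_threshold_D=(1.0, 5.0),
            inactive_delay_E=(0.2,),
        )
        result = vw.grid_search(dataset, grid)
        pairs = []
        for rec, settings in dataset:
            events, measures = vw.analyze_recording(rec, result.best)
            pairs.extend(vw.match_breaths(events, measures, settings))
        objective, _ = vw.standardized_objective(pairs, [s for _, s in dataset])
        assert objective == result.best_objective  # exact, no state leakage

    def test_any_table_row_matches_from_scratch_evaluation(self):
        dataset = _two_run_dataset(pressure_amp=(20.0, 22.0))
        grid = vw.GridSpec(
            pressure_threshold_A=(2.0, 8.0), pressure_duration_B=(0.3,),
            ventilation_lead_C=(0.0, 0.3), abs_flow_threshold_D=(5.0,),
            inactive_delay_E=(0.2,),
        )
        result = vw.grid_search(dataset, grid)
        row = result.table.iloc[2]
        params = TUNED.replace(
            pressure_threshold_A=row["A"], pressure_duration_B=row["B"],
            ventilation_lead_C=row["C"], abs_flow_threshold_D=row["D"],
            inactive_delay_E=row["E"],
        )
        pairs = []
        for rec, settings in dataset:
            events, measures = vw.analyze_recording(rec, params)
            pairs.extend(vw.match_breaths(events, measures, settings))
        objective, _ = vw.standardized_objective(pairs, [s for _, s in dataset])
        assert objective == row["objective"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(vw.ParameterError):
            vw.grid_search([])

    def test_default_grid_has_2400_points(self):
        assert vw.GridSpec().n_points == 2400


class TestProfiles:
    def test_tuned_profile_values(self):
        p = vw.get_profile("tuned")
        assert (p.pressure_threshold_A, p.pressure_duration_B, p.ventilation_lead_C,
                p.abs_flow_threshold_D, p.inactive_delay_E) == (8.0, 0.3, 0.3, 5.0, 0.2)

    def test_optimized_profile_values(self):
        p = vw.get_profile("optimized")
        assert (p.pressure_threshold_A, p.pressure_duration_B, p.ventilation_lead_C,
                p.abs_flow_threshold_D, p.inactive_delay_E) == (2.0, 0.3, 0.1, 1.0, 0.2)

    def test_unknown_profile_rejected(self):
        with pytest.raises(vw.ParameterError):
            vw.get_profile("nope")
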