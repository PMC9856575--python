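import numpy as np
import pytest

from coiscal.classifiers import ClassifierSpec
from coiscal.harness import (
    AccuracyRecord,
    ExperimentConfig,
    confidence_interval,
    count_test_evaluations,
    relative_improvement,
    run_experiment,
    summarize,
)


def make_records(values, family="SVM", approach="S"):
    return [
        AccuracyRecord("s", "c", approach, family, run, v)
        for run, v in enumerate(values)
    ]


class TestRelativeImprovement:
    def test_table_worked_example(self):
        assert relative_improvement(70.95, 58.33) == pytest.approx(
            21.64, abs=0.005
        )

    def test_equal_accuracies(self):
        assert relative_improvement(50.0, 50.0) == 0.0

    def test_double_is_hundred(self):
        assert relative_improvement(80.0, 40.0) == pytest.approx(100.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(10.0, 0.0)


class TestConfidenceInterval:
    def test_constant_values_zero_width(self):
        low, high = confidence_interval([0.7] * 10)
        assert low == pytest.approx(high)

    def test_contains_mean(self, rng):
        vals = rng.random(30)
        low, high = confidence_interval(vals)
        assert low <= vals.mean() <= high

    def test_width_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        population = 0.7 + 0.05 * rng.standard_normal(200_000)
        widths = []
        for n in (10, 40, 160):
            # average many interval widths at each n to beat sampling noise
            ws = []
            for _ in range(300):
                sample = rng.choice(population, n, replace=False)
                low, high = confidence_interval(sample)
                ws.append(high - low)
            widths.append(np.mean(ws))
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.15)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.15)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([0.5])


class TestSummarize:
    def test_global_average_excludes_cnn2(self):
        records = []
        cells = {"SVM": 0.5833, "RF": 0.7530, "KNN": 0.5885,
                 "MLP": 0.7584, "CNN1": 0.7768, "CNN2": 0.8118}
        for family, acc in cells.items():
            records += make_records([acc], family=family)
        table = summarize(records)
        expected = np.mean([v for f, v in cells.items() if f != "CNN2"]) * 100
        assert table.loc["GlobalAverage", "S"] == pytest.approx(expected)
        assert list(table.index).index("CNN2") > list(table.index).index(
            "GlobalAverage"
        )

    def test_single_record(self):
        table = summarize(make_records([0.8]))
        assert table.loc["SVM", "S"] == pytest.approx(80.0)

    def test_mean_reproducible_from_records(self, rng):
        vals = rng.random(50)
        table = summarize(make_records(vals))
        assert table.loc["SVM", "S"] == pytest.approx(
            vals.mean() * 100, abs=1e-10
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestBookkeeping:
    def test_per_run_test_count_and_total(self):
        assert count_test_evaluations(195, 2, 4, 5, 1) == 390

    def test_fifty_runs_total(self):
        assert count_test_evaluations(195, 2, 4, 5, 50) == 19500


@pytest.fixture(scope="module")
def tiny_setup():
    from coiscal.ensembles import TrialEnsemble
    from coiscal.wavelet import FrequencyGrid, WaveletParams

    rng = np.random.default_rng(0)
    grid = FrequencyGrid.logarithmic(5.0, 22.0, 6)  # 13 bands: CNN2-poolable
    params = WaveletParams(cycles=4)
    t = np.arange(40) / 50.0
    burst = np.sin(2 * np.pi * 10 * t)
    ens = {
        "A": TrialEnsemble(
            2.0 * burst + rng.standard_normal((30, 40)), 50.0, label="A"
        ),
        "B": TrialEnsemble(
            0.5 * burst + rng.standard_normal((30, 40)), 50.0, label="B"
        ),
    }
    config = ExperimentConfig(grid, params, m=3, k_folds=3, n_runs=2)
    specs = {
        "KNN": ClassifierSpec("KNN", {"k": 5}),
        "RF": ClassifierSpec("RF"),
    }
    return ens, config, specs


class TestRunExperiment:
    def test_records_complete_and_bounded(self, tiny_setup):
        ens, config, specs = tiny_setup
        records = run_experiment(ens, config, specs, master_seed=1)
        assert len(records) == 2 * 2 * 4  # runs x families x approaches
        assert all(0.0 <= r.accuracy <= 1.0 for r in records)

    def test_determinism(self, tiny_setup):
        ens, config, specs = tiny_setup
        a = run_experiment(ens, config, specs, master_seed=3)
        b = run_experiment(ens, config, specs, master_seed=3)
        assert [(r.approach, r.family, r.run, r.accuracy) for r in a] == [
            (r.approach, r.family, r.run, r.accuracy) for r in b
        ]

    def test_single_fold_rejected(self, tiny_setup):
        ens, config, specs = tiny_setup
        from dataclasses import replace

        with pytest.raises(ValueError):
            run_experiment(ens, replace(config, k_folds=1), specs)

    def test_cnn2_skipped_for_ragged_approaches(self, tiny_setup):
        ens, config, specs = tiny_setup
        specs = dict(specs)
        specs["CNN2"] = ClassifierSpec(
            "CNN2",
            {"filters": 2, "fc": (8,), "epochs": 1},
            input_form="matrix",
        )
        records = run_experiment(ens, config, specs, master_seed=1)
        cnn2 = {r.approach for r in records if r.family == "CNN2"}
        assert cnn2 == {"S", "Z"}


@pytest.mark.slow
class TestTrendProperty:
    """The core claim at desk scale: V >= Z >= S, Vbar near chance."""

    @pytest.mark.parametrize("family", ["SVM", "RF", "KNN"])
    def test_ordering(self, trend_table, family):
        row = trend_table.loc[family]
        assert row["V"] >= row["Z"] >= row["S"]

    def test_vbar_near_chance(self, trend_table):
        vbar = trend_table.loc[["SVM", "RF", "KNN"], "Vbar"]
        assert ((vbar >= 0.45) & (vbar <= 0.60)).all()
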