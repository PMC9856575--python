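import numpy as np
import pytest

from coiscal.ensembles import TrialEnsemble
from coiscal.synthetic import ClassTemplateSpec, Component
from coiscal.wavelet import FrequencyGrid, WaveletParams, compute_coi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    # 18 log-spaced bands, 4-30 Hz
    return FrequencyGrid.logarithmic(4.0, 30.0, 6)


@pytest.fixture
def params():
    return WaveletParams(cycles=5)


@pytest.fixture
def small_coi(small_grid, params):
    return compute_coi(small_grid, 100, 100.0, params)


@pytest.fixture
def random_ensembles(rng):
    """Two 60-trial white-noise class ensembles, 16 samples each."""
    return {
        label: TrialEnsemble(rng.standard_normal((60, 16)), 100.0, label=label)
        for label in ("A", "B")
    }


def trend_specs():
    """Two-class specs whose discriminative content sits inside the COI.

    Loud, heavily jittered shared bursts at both epoch edges make the
    out-of-COI (edge-affected) coefficients high-variance and
    class-irrelevant; the class difference is a short mid-epoch 10 Hz
    burst.  Used with the 32-band trend grid (2-30 Hz, 8 voices) whose
    low rho (~0.38) leaves most scalogram cells outside the COI, so the
    standard full-scalogram features are heavily diluted by artifacts.
    """
    shared = (Component(8, 4.0, 0.0, 0.2), Component(12, 4.0, 0.8, 0.2))
    base = dict(
        n_samples=100,
        fs=100.0,
        n_trials=60,
        latency_jitter=0.06,
        amplitude_jitter=0.5,
        noise_sigma=1.2,
    )
    spec_a = ClassTemplateSpec(shared + (Component(10, 1.0, 0.4, 0.2),), **base)
    spec_b = ClassTemplateSpec(shared + (Component(10, 0.35, 0.4, 0.2),), **base)
    return spec_a, spec_b


def trend_grid():
    return FrequencyGrid.logarithmic(2.0, 30.0, 8)


@pytest.fixture(scope="session")
def trend_table():
    """20-run S/Z/V/Vbar comparison for SVM, RF, KNN (accuracy fractions).

    Session-scoped: this is the most expensive fixture in the suite and
    is shared between the harness property tests and the acceptance
    criteria.
    """
    from coiscal.classifiers import ClassifierSpec
    from coiscal.harness import ExperimentConfig, run_experiment, summarize
    from coiscal.synthetic import generate_trials

    spec_a, spec_b = trend_specs()
    rng = np.random.default_rng(11)
    ens = {
        "A": generate_trials(spec_a, rng.spawn(1)[0], label="A"),
        "B": generate_trials(spec_b, rng.spawn(1)[0], label="B"),
    }
    config = ExperimentConfig(
        trend_grid(), WaveletParams(cycles=5), m=4, k_folds=5, n_runs=20
    )
    specs = {
        "SVM": ClassifierSpec(
            "SVM", {"c_grid": [1.0, 10.0], "gamma_grid": [1e-3, 1e-2]}
        ),
        "RF": ClassifierSpec("RF"),
        "KNN": ClassifierSpec("KNN"),
    }
    records = run_experiment(ens, config, specs, master_seed=5)
    return summarize(records, as_percent=False)


@pytest.fixture(scope="session")
def rrs_recovery_hits():
    """How often (out of 20 seeds) RRS ranks the largest-gain channel first."""
    from coiscal.ranking import rank_channels, score_dataset
    from coiscal.synthetic import generate_dataset

    spec_a = ClassTemplateSpec(
        (Component(10, 1.6, 0.2, 0.4),),
        n_samples=80, fs=100.0, n_trials=200, noise_sigma=1.0,
    )
    spec_b = ClassTemplateSpec(
        (Component(10, 0.8, 0.2, 0.4),),
        n_samples=80, fs=100.0, n_trials=200, noise_sigma=1.0,
    )
    gains = {"g3": 3.0, "g2": 2.0, "g1": 1.0, "g0": 0.0}
    hits = 0
    for seed in range(20):
        ds = generate_dataset(spec_a, spec_b, gains, ["s"], seed=seed)
        table = rank_channels(score_dataset(ds), sorted(gains))
        hits += table.ordering[0] == "g3"
    return hits
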