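"""Cross-validated comparison of the S/Z/V/Vbar feature approaches.

One experiment = ``n_runs`` repetitions of: fresh fold partition ->
m-subsample-averaged train/test ensembles -> one scalogram per m-ERP ->
feature vectors per approach -> every classifier family trained and
evaluated on the identical splits.  The per-run accuracy pools correct
test decisions over all folds and both classes; final accuracies average
the per-run accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    VECTOR_FAMILIES,
    ClassifierSpec,
    Family,
    evaluate,
    train,
)
from .ensembles import MERPEnsemble, RunPlan, TrialEnsemble, build_run
from .features import APPROACHES, Approach, extract
from .wavelet import (
    COIBoundary,
    FrequencyGrid,
    Signal,
    WaveletParams,
    compute_coi,
    cwt_scalogram,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyRecord",
    "ExperimentConfig",
    "run_experiment",
    "relative_improvement",
    "confidence_interval",
    "summarize",
    "count_test_evaluations",
]


@dataclass(frozen=True)
class AccuracyRecord:
    subject: str
    channel: str
    approach: Approach
    family: Family
    run: int
    accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class ExperimentConfig:
    grid: FrequencyGrid
    params: WaveletParams
    m: int = 4
    k_folds: int = 5
    n_runs: int = 50
    kind: str = "power"
    standardize: bool = True


def _feature_block(
    ens: MERPEnsemble,
    grid: FrequencyGrid,
    params: WaveletParams,
    coi: COIBoundary,
    approaches: Sequence[Approach],
    kind: str,
) -> dict[Approach, np.ndarray]:
    """One scalogram per m-ERP, shared by every requested approach."""
    per_approach: dict[Approach, list[np.ndarray]] = {a: [] for a in approaches}
    matrices = []
    for row in ens.merps:
        _, scal = cwt_scalogram(Signal(row, ens.fs), grid, params, "same", kind)
        matrices.append(scal.G)
        for a in approaches:
            if a == "matrix":
                continue
            per_approach[a].append(extract(scal.G, coi, a).values)
    out = {a: np.vstack(v) for a, v in per_approach.items() if v}
    out["matrix"] = np.stack(matrices)  # for matrix-input families
    return out


def run_experiment(
    ensembles: dict[str, TrialEnsemble],
    config: ExperimentConfig,
    specs: dict[Family, ClassifierSpec],
    approaches: Sequence[Approach] = APPROACHES,
    master_seed: int = 0,
    subject: str = "",
    channel: str = "",
) -> list[AccuracyRecord]:
    """Benchmark every (approach, family) pair on one channel's data.

    ``ensembles`` maps class label -> TrialEnsemble.  All families see the
    identical train/test m-ERPs within each run; CNN2 consumes the S- or
    Z-scalogram matrices and is skipped for V/Vbar (ragged rows).
    """
    if config.k_folds < 2:
        raise ValueError("k_folds must be >= 2 (no held-out data otherwise)")
    first = next(iter(ensembles.values()))
    N = first.n_samples
    coi = compute_coi(config.grid, N, first.fs, config.params)
    records: list[AccuracyRecord] = []
    for run in range(config.n_runs):
        plan = build_run(
            ensembles, config.m, config.k_folds, master_seed, run=run
        )
        # correct/total pooled across folds, per (approach, family)
        correct: dict[tuple, int] = {}
        total: dict[tuple, int] = {}
        for fp in plan.fold_plans:
            train_X: dict[str, np.ndarray] = {}
            test_X: dict[str, np.ndarray] = {}
            y_tr, y_te = [], []
            per_label_train, per_label_test = {}, {}
            for label in sorted(ensembles):
                per_label_train[label] = _feature_block(
                    fp.train[label], config.grid, config.params, coi,
                    approaches, config.kind,
                )
                per_label_test[label] = _feature_block(
                    fp.test[label], config.grid, config.params, coi,
                    approaches, config.kind,
                )
                y_tr += [label] * fp.train[label].n_merps
                y_te += [label] * fp.test[label].n_merps
            y_tr, y_te = np.array(y_tr), np.array(y_te)
            keys = list(per_label_train[sorted(ensembles)[0]])
            for key in keys:
                train_X[key] = np.concatenate(
                    [per_label_train[l][key] for l in sorted(ensembles)]
                )
                test_X[key] = np.concatenate(
                    [per_label_test[l][key] for l in sorted(ensembles)]
                )
            for approach in approaches:
                for family, spec in specs.items():
                    if spec.input_form == "matrix":
                        if approach in ("V", "Vbar"):
                            continue  # ragged rows: unsupported by design
                        X_tr = train_X["matrix"]
                        X_te = test_X["matrix"]
                        if approach == "Z":
                            mask = coi.mask()[None, :, :]
                            X_tr, X_te = X_tr * mask, X_te * mask
                    else:
                        X_tr, X_te = train_X[approach], test_X[approach]
                    model = train(spec, X_tr, y_tr, config.standardize)
                    n_correct = int(
                        np.sum(model.predict(X_te) == y_te)
                    )
                    ckey = (approach, family)
                    correct[ckey] = correct.get(ckey, 0) + n_correct
                    total[ckey] = total.get(ckey, 0) + y_te.size
        for (approach, family), n_correct in correct.items():
            records.append(
                AccuracyRecord(
                    subject,
                    channel,
                    approach,
                    family,
                    run,
                    n_correct / total[(approach, family)],
                )
            )
        logger.info("run %d/%d complete", run + 1, config.n_runs)
    return records


def count_test_evaluations(
    n_trials_per_class: int,
    n_classes: int,
    m: int,
    k_folds: int,
    n_runs: int,
    seed: int = 0,
    fs: float = 1.0,
    n_samples: int = 8,
) -> int:
    """Protocol bookkeeping: total test m-ERPs evaluated per classifier.

    Executes the actual run-building code path (tiny trial length, counts
    do not depend on it) and sums test m-ERPs over folds, classes, runs.
    """
    rng = np.random.default_rng(seed)
    ensembles = {
        f"class{i}": TrialEnsemble(
            rng.standard_normal((n_trials_per_class, n_samples)), fs
        )
        for i in range(n_classes)
    }
    n = 0
    for run in range(n_runs):
        n += build_run(ensembles, m, k_folds, seed, run=run).n_test_merps
    return n


def relative_improvement(alpha_b: float, alpha_a: float) -> float:
    """Percent gain of approach B over approach A: (aB - aA)/aA * 100."""
    if alpha_a <= 0:
        raise ValueError("relative improvement undefined for alpha_a <= 0")
    return (alpha_b - alpha_a) / alpha_a * 100.0


def confidence_interval(
    values: Iterable[float], level: float = 0.95
) -> tuple[float, float]:
    """Student-t interval (mean +/- t * standard error) for run accuracies."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    sem = arr.std(ddof=1) / np.sqrt(arr.size)
    t = stats.t.ppf(0.5 + level / 2.0, arr.size - 1)
    mean = arr.mean()
    return (mean - t * sem, mean + t * sem)


def summarize(
    records: Iterable[AccuracyRecord], as_percent: bool = True
) -> pd.DataFrame:
    """Mean accuracy per (family, approach) plus the global-average row.

    The global average is the mean of the vector-input family rows; the
    matrix-input CNN2 row is appended below it and excluded from the
    average.  Values are percentages by default.
    """
    rows = [
        {
            "family": r.family,
            "approach": r.approach,
            "accuracy": r.accuracy,
        }
        for r in records
    ]
    if not rows:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="family", columns="approach", values="accuracy", aggfunc="mean"
    )
    vector_rows = [f for f in VECTOR_FAMILIES if f in table.index]
    ordered = vector_rows + [f for f in table.index if f not in vector_rows]
    table = table.loc[ordered]
    table.loc["GlobalAverage"] = table.loc[vector_rows].mean()
    if "CNN2" in ordered:  # keep the excluded row below the average
        order = vector_rows + ["GlobalAverage", "CNN2"]
        table = table.loc[order]
    if as_percent:
        table = table * 100.0
    return table
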