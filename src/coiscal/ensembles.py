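"""Subsample-averaged ERP ensembles and the leak-free fold protocol.

An *m-ERP* is the mean of ``m`` single trials drawn without replacement
from an ensemble, with the subsample replaced between draws so arbitrarily
many m-ERPs can be generated from a small single-trial ensemble.  To keep
training and test sets mutually exclusive at the single-trial level, the
trials are partitioned into folds first and m-ERPs are generated from each
side of the partition separately; every m-ERP records the indices of its
source trials so exclusivity is auditable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TrialEnsemble",
    "MERPEnsemble",
    "FoldPlan",
    "RunPlan",
    "msa_generate",
    "partition_folds",
    "build_run",
]


@dataclass(frozen=True)
class TrialEnsemble:
    """Single trials (rows) for one (subject, channel, class)."""

    trials: np.ndarray  # (n_trials, N)
    fs: float
    subject: str = ""
    channel: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=float)
        object.__setattr__(self, "trials", trials)
        if trials.ndim != 2 or trials.shape[0] < 1:
            raise ValueError("trials must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(trials)):
            raise ValueError("trials contain non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return int(self.trials.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.trials.shape[1])

    def subset(self, indices: Sequence[int]) -> "TrialEnsemble":
        return TrialEnsemble(
            self.trials[np.asarray(indices, dtype=int)],
            self.fs,
            self.subject,
            self.channel,
            self.label,
        )


@dataclass(frozen=True)
class MERPEnsemble:
    """m-subsample-averaged trials with recorded provenance."""

    merps: np.ndarray  # (n_out, N)
    m: int
    source_indices: np.ndarray  # (n_out, m), indices into the source ensemble
    origin: Literal["train", "test", ""] = ""
    fs: float = 1.0

    def __post_init__(self) -> None:
        merps = np.asarray(self.merps, dtype=float)
        src = np.asarray(self.source_indices, dtype=int)
        object.__setattr__(self, "merps", merps)
        object.__setattr__(self, "source_indices", src)
        if merps.ndim != 2:
            raise ValueError("merps must be 2-D")
        if src.shape != (merps.shape[0], self.m):
            raise ValueError("source_indices must be (n_out, m)")
        for row in src:
            if np.unique(row).size != row.size:
                raise ValueError("duplicate source index within one m-ERP")

    @property
    def n_merps(self) -> int:
        return int(self.merps.shape[0])


@dataclass(frozen=True)
class FoldPlan:
    """One cross-validation cell: held-out fold plus both m-ERP sets."""

    fold: int
    train_trial_indices: np.ndarray
    test_trial_indices: np.ndarray
    train: dict[str, MERPEnsemble]  # per class label
    test: dict[str, MERPEnsemble]


@dataclass(frozen=True)
class RunPlan:
    """One full repetition: fold assignments and all generated m-ERPs."""

    run: int
    seed: int
    m: int
    k: int
    folds: dict[str, list[np.ndarray]]  # per class: k disjoint index sets
    fold_plans: list[FoldPlan] = field(default_factory=list)

    @property
    def n_test_merps(self) -> int:
        return sum(
            ens.n_merps for fp in self.fold_plans for ens in fp.test.values()
        )

    @property
    def n_train_merps(self) -> int:
        return sum(
            ens.n_merps for fp in self.fold_plans for ens in fp.train.values()
        )


def msa_generate(
    ensemble: TrialEnsemble,
    m: int,
    n_out: int,
    rng: np.random.Generator | int,
    origin: Literal["train", "test", ""] = "",
) -> MERPEnsemble:
    """Generate ``n_out`` m-ERPs by m-subsample averaging.

    Each m-ERP averages ``m`` distinct trials drawn without replacement;
    the subsample is replaced between draws, so different m-ERPs may share
    trials.  Source indices are recorded per m-ERP.
    """
    if not 1 <= m <= ensemble.n_trials:
        raise ValueError(
            f"m={m} must be in [1, {ensemble.n_trials}] for this ensemble"
        )
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    rng = np.random.default_rng(rng)
    indices = np.empty((n_out, m), dtype=int)
    for i in range(n_out):
        indices[i] = rng.choice(ensemble.n_trials, size=m, replace=False)
    merps = ensemble.trials[indices].mean(axis=1)
    return MERPEnsemble(merps, m, indices, origin, ensemble.fs)


def partition_folds(
    n_trials: int, k: int, rng: np.random.Generator | int
) -> list[np.ndarray]:
    """Randomly partition trial indices 0..n_trials-1 into k disjoint folds.

    When k does not divide n_trials the folds are near-equal (sizes differ
    by at most one).
    """
    if k < 1 or k > n_trials:
        raise ValueError(f"need 1 <= k <= n_trials, got k={k}, n={n_trials}")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n_trials)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def build_run(
    ensembles: dict[str, TrialEnsemble],
    m: int,
    k: int,
    seed: int,
    run: int = 0,
    n_train_merps: int | None = None,
    n_test_merps: int | None = None,
) -> RunPlan:
    """Build one run: fresh fold partition plus per-fold m-ERP ensembles.

    Per fold, training m-ERPs are generated only from the k-1 training
    folds' trials and test m-ERPs only from the held-out fold's trials.
    Defaults generate as many m-ERPs as there are source trials on each
    side (mirroring a 156 train / 39 test split at 195 trials, k=5).
    """
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    if not ensembles:
        raise ValueError("need at least one class ensemble")
    master = np.random.default_rng([seed, run])
    folds: dict[str, list[np.ndarray]] = {}
    for label in sorted(ensembles):
        folds[label] = partition_folds(
            ensembles[label].n_trials, k, master.spawn(1)[0]
        )
    min_fold = min(len(f) for fs in folds.values() for f in fs)
    if m > min_fold:
        raise ValueError(
            f"m={m} exceeds the smallest held-out fold size {min_fold}"
        )
    fold_plans: list[FoldPlan] = []
    for j in range(k):
        train_map: dict[str, MERPEnsemble] = {}
        test_map: dict[str, MERPEnsemble] = {}
        tr_idx_all, te_idx_all = [], []
        for label in sorted(ensembles):
            ens = ensembles[label]
            test_idx = folds[label][j]
            train_idx = np.sort(
                np.concatenate([folds[label][i] for i in range(k) if i != j])
            )
            tr_idx_all.append(train_idx)
            te_idx_all.append(test_idx)
            n_tr = len(train_idx) if n_train_merps is None else n_train_merps
            n_te = len(test_idx) if n_test_merps is None else n_test_merps
            sub_rng = master.spawn(1)[0]
            tr = msa_generate(ens.subset(train_idx), m, n_tr, sub_rng, "train")
            te = msa_generate(ens.subset(test_idx), m, n_te, sub_rng, "test")
            # re-express source indices in original-ensemble coordinates
            train_map[label] = MERPEnsemble(
                tr.merps, m, train_idx[tr.source_indices], "train", ens.fs
            )
            test_map[label] = MERPEnsemble(
                te.merps, m, test_idx[te.source_indices], "test", ens.fs
            )
        fold_plans.append(
            FoldPlan(
                j,
                np.concatenate(tr_idx_all),
                np.concatenate(te_idx_all),
                train_map,
                test_map,
            )
        )
    return RunPlan(run, seed, m, k, folds, fold_plans)
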