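"""Rank-of-rank-sum (RRS) channel selection.

Channels are scored by a scatter-normalized separation between class
cluster means, ranked per (subject, class pair) with 1 = most separated,
rank-summed over the class pairs and re-ranked per subject, then
rank-summed over subjects and re-ranked to give the final ordering.
Binary-class and single-subject cases reduce naturally.  Ties receive
average (mid) ranks at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ensembles import TrialEnsemble

__all__ = [
    "SeparationScore",
    "RankTable",
    "interclass_separation",
    "score_dataset",
    "rank_channels",
    "select_top_k",
]


@dataclass(frozen=True)
class SeparationScore:
    value: float
    channel: str = ""
    class_pair: tuple[str, str] = ("", "")
    subject: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("separation score must be nonnegative")


@dataclass(frozen=True)
class RankTable:
    """Per-stage ranks plus the final channel ordering."""

    channels: list[str]
    # (subjects, pairs, channels) mid-ranks, 1 = best per (subject, pair)
    pair_ranks: np.ndarray
    subject_rank_sums: np.ndarray  # (subjects, channels)
    subject_ranks: np.ndarray  # (subjects, channels) per-subject re-rank
    final_rank_sums: np.ndarray  # (channels,)
    final_ranks: np.ndarray  # (channels,) mid-ranks over channels
    ordering: list[str]  # channels sorted best-first

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per channel, best first."""
        order = [self.channels.index(c) for c in self.ordering]
        return pd.DataFrame(
            {
                "channel": self.ordering,
                "final_rank": self.final_ranks[order],
                "rank_sum": self.final_rank_sums[order],
            }
        )


def interclass_separation(
    ens_a: TrialEnsemble | np.ndarray, ens_b: TrialEnsemble | np.ndarray
) -> float:
    """Scatter-normalized separation between two trial clusters.

    Fisher-type trace criterion: ``||mu_a - mu_b||^2 / (tr(S_a) + tr(S_b))``
    where mu is the mean trial vector and tr(S) the summed per-sample
    variances.  Returns 0 for identical degenerate clusters (0/0).
    """
    a = ens_a.trials if isinstance(ens_a, TrialEnsemble) else np.asarray(ens_a)
    b = ens_b.trials if isinstance(ens_b, TrialEnsemble) else np.asarray(ens_b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("ensembles must be 2-D with equal trial length")
    gap = float(np.sum((a.mean(axis=0) - b.mean(axis=0)) ** 2))
    scatter = float(a.var(axis=0).sum() + b.var(axis=0).sum())
    if scatter == 0.0:
        if gap == 0.0:
            return 0.0
        return float("inf")
    return gap / scatter


def score_dataset(
    dataset: dict[str, dict[str, dict[str, TrialEnsemble]]],
) -> np.ndarray:
    """Separation scores for a {subject: {channel: {class: ensemble}}} map.

    Returns a (subjects, pairs, channels) array in sorted-key order, one
    slice per unordered class pair.
    """
    subjects = sorted(dataset)
    channels = sorted(dataset[subjects[0]])
    classes = sorted(dataset[subjects[0]][channels[0]])
    pairs = [
        (classes[i], classes[j])
        for i in range(len(classes))
        for j in range(i + 1, len(classes))
    ]
    scores = np.empty((len(subjects), len(pairs), len(channels)))
    for si, subj in enumerate(subjects):
        for pi, (ca, cb) in enumerate(pairs):
            for ci, ch in enumerate(channels):
                scores[si, pi, ci] = interclass_separation(
                    dataset[subj][ch][ca], dataset[subj][ch][cb]
                )
    return scores


def rank_channels(
    scores: np.ndarray, channels: list[str] | None = None
) -> RankTable:
    """RRS ranking from a (subjects, pairs, channels) score array."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, None, :]
    elif scores.ndim == 2:
        scores = scores[None, :, :]
    if scores.ndim != 3:
        raise ValueError("scores must be (subjects, pairs, channels)")
    if not np.all(np.isfinite(scores) | np.isposinf(scores)):
        raise ValueError("missing or NaN separation scores")
    n_subj, n_pairs, n_ch = scores.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    if len(channels) != n_ch:
        raise ValueError("channel-name count does not match score array")

    # stage 1: per (subject, pair), rank by descending separation
    pair_ranks = np.empty_like(scores)
    for s in range(n_subj):
        for p in range(n_pairs):
            pair_ranks[s, p] = rankdata(-scores[s, p], method="average")
    # stage 2: per subject, sum over pairs and re-rank (low sum = best)
    subject_rank_sums = pair_ranks.sum(axis=1)
    subject_ranks = np.vstack(
        [rankdata(row, method="average") for row in subject_rank_sums]
    )
    # stage 3: sum per-subject ranks over subjects and re-rank
    final_rank_sums = subject_ranks.sum(axis=0)
    final_ranks = rankdata(final_rank_sums, method="average")
    order = np.argsort(final_rank_sums, kind="stable")
    ordering = [channels[i] for i in order]
    return RankTable(
        list(channels),
        pair_ranks,
        subject_rank_sums,
        subject_ranks,
        final_rank_sums,
        final_ranks,
        ordering,
    )


def select_top_k(table: RankTable, k: int) -> list[str]:
    """First k channels of the final ranking, best first."""
    if not 1 <= k <= len(table.channels):
        raise ValueError(f"k must be in [1, {len(table.channels)}]")
    return table.ordering[:k]
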