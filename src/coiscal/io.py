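"""Plain-text import/export for trials, scalograms, features and run plans.

Everything round-trips through delimited text or JSON so artifacts stay
inspectable and diff-able.  Trial data uses a long format with columns
``subject, channel, label, trial`` followed by one column per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensembles import RunPlan, TrialEnsemble
from .features import FeatureVector
from .wavelet import COIBoundary, Scalogram

__all__ = [
    "save_trials",
    "load_trials",
    "save_scalogram",
    "load_scalogram",
    "save_coi",
    "load_coi",
    "save_feature_matrix",
    "save_run_manifest",
]

_META_COLS = ["subject", "channel", "label", "trial"]


def save_trials(path: str | Path, ensembles: list[TrialEnsemble]) -> None:
    """Write trial ensembles to one long-format TSV (fs in a header line)."""
    if not ensembles:
        raise ValueError("nothing to save")
    fs = {e.fs for e in ensembles}
    if len(fs) != 1:
        raise ValueError("mixed sampling rates in one file")
    frames = []
    for ens in ensembles:
        df = pd.DataFrame(ens.trials)
        df.columns = [f"s{i}" for i in range(ens.n_samples)]
        df.insert(0, "trial", np.arange(ens.n_trials))
        df.insert(0, "label", ens.label)
        df.insert(0, "channel", ens.channel)
        df.insert(0, "subject", ens.subject)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={fs.pop()}\n")
        out.to_csv(fh, sep="\t", index=False)


def load_trials(path: str | Path) -> list[TrialEnsemble]:
    """Read ensembles back, one per (subject, channel, label) group."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError("missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    import re

    sample_cols = [c for c in df.columns if re.fullmatch(r"s\d+", c)]
    out = []
    for (subject, channel, label), grp in df.groupby(
        ["subject", "channel", "label"], sort=True, dropna=False
    ):
        grp = grp.sort_values("trial")
        out.append(
            TrialEnsemble(
                grp[sample_cols].to_numpy(float),
                fs,
                str(subject) if pd.notna(subject) else "",
                str(channel) if pd.notna(channel) else "",
                str(label) if pd.notna(label) else "",
            )
        )
    return out


def save_scalogram(path: str | Path, scal: Scalogram) -> None:
    """J x N matrix as TSV with per-row band frequencies in the header."""
    freqs = ",".join(f"{f:.8g}" for f in scal.grid.frequencies)
    with Path(path).open("w") as fh:
        fh.write(f"# kind={scal.kind}\n# frequencies_hz={freqs}\n")
        np.savetxt(fh, scal.G, delimiter="\t")


def load_scalogram(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    """Returns (matrix, band frequencies, kind)."""
    with Path(path).open() as fh:
        kind_line = fh.readline().strip()
        freq_line = fh.readline().strip()
        kind = kind_line.split("=", 1)[1]
        freqs = np.array(
            [float(v) for v in freq_line.split("=", 1)[1].split(",")]
        )
        mat = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return mat, freqs, kind


def save_coi(path: str | Path, coi: COIBoundary) -> None:
    """Per-band COI table: footprint, interval and in-COI count."""
    pd.DataFrame(
        {
            "band": np.arange(coi.J),
            "footprint": coi.footprint,
            "n_start": coi.n_start,
            "n_end": coi.n_end,
            "Nf": coi.Nf,
        }
    ).to_csv(path, sep="\t", index=False)


def load_coi(path: str | Path, N: int) -> COIBoundary:
    df = pd.read_csv(path, sep="\t")
    return COIBoundary(
        df["n_start"].to_numpy(int),
        df["n_end"].to_numpy(int),
        df["footprint"].to_numpy(int),
        N,
    )


def save_feature_matrix(
    path: str | Path,
    vectors: list[FeatureVector],
    layout_path: str | Path | None = None,
) -> None:
    """One row per feature vector; optional (band, time) layout sidecar."""
    if not vectors:
        raise ValueError("nothing to save")
    approach = vectors[0].approach
    if any(v.approach != approach for v in vectors):
        raise ValueError("mixed approaches in one feature matrix")
    mat = np.vstack([v.values for v in vectors])
    with Path(path).open("w") as fh:
        fh.write(f"# approach={approach}\n")
        np.savetxt(fh, mat, delimiter="\t")
    if layout_path is not None:
        pd.DataFrame(
            vectors[0].layout, columns=["band", "time"]
        ).to_csv(layout_path, sep="\t", index=False)


def save_run_manifest(path: str | Path, plan: RunPlan) -> None:
    """JSON manifest: seeds, fold memberships, m-ERP source indices."""
    doc = {
        "run": plan.run,
        "seed": plan.seed,
        "m": plan.m,
        "k": plan.k,
        "folds": {
            label: [f.tolist() for f in folds]
            for label, folds in plan.folds.items()
        },
        "fold_plans": [
            {
                "fold": fp.fold,
                "train": {
                    label: ens.source_indices.tolist()
                    for label, ens in fp.train.items()
                },
                "test": {
                    label: ens.source_indices.tolist()
                    for label, ens in fp.test.items()
                },
            }
            for fp in plan.fold_plans
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
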