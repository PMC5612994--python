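"""Dataset directory layout: betas as 4-D NIfTI plus plain-text sidecars.

A subject directory holds ``mask.nii.gz``, ``trials.tsv`` (one row per
trial), ``betas.nii.gz`` (x, y, z, run*condition volumes) and
``betas.tsv`` describing each 4th-axis volume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BetaPatternSet, DesignSpec, Trial, TrialSequence
from .volume import load_mask, load_volume, save_mask, save_volume

__all__ = [
    "save_trial_table",
    "load_trial_table",
    "save_beta_set",
    "load_beta_set",
    "save_timeseries",
    "load_timeseries",
]


def save_trial_table(design: TrialSequence, path) -> None:
    rows = []
    for r, run in enumerate(design.runs):
        for t in run:
            rows.append(
                {
                    "run": r,
                    "trial_index": t.index,
                    "trial_type": t.trial_type,
                    "identity": "+".join(t.identities),
                    "familiarity": t.familiarity or "",
                    "views": "|".join(t.views),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_trial_table(path, spec: DesignSpec) -> TrialSequence:
    import dataclasses

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    runs = []
    for r in sorted(df["run"].unique()):
        trials = []
        for _, row in df[df["run"] == r].sort_values("trial_index").iterrows():
            idents = tuple(str(row["identity"]).split("+")) if row["identity"] else ()
            views = tuple(str(row["views"]).split("|")) if row["views"] else ()
            fam = str(row["familiarity"]) or None
            trials.append(Trial(int(row["trial_index"]), str(row["trial_type"]), idents, fam, views))
        runs.append(trials)
    return TrialSequence(dataclasses.replace(spec, n_runs=len(runs)), runs)


def save_timeseries(ts, grid, mask, out_dir) -> None:
    """Per-run BOLD-like series as 4-D NIfTI (in-mask voxels filled)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inmask = mask.included
    for r in range(ts.shape[0]):
        vol = np.zeros((*grid.dims, ts.shape[1]))
        vol[inmask, :] = ts[r].T
        save_volume(vol, grid, out / f"bold_run-{r:02d}.nii.gz")


def load_timeseries(in_dir, mask) -> np.ndarray:
    src = Path(in_dir)
    runs = sorted(src.glob("bold_run-*.nii.gz"))
    if not runs:
        raise FileNotFoundError(f"no bold_run-*.nii.gz files in {src}")
    out = []
    for path in runs:
        vol, _ = load_volume(path)
        out.append(vol[mask.included, :].T)
    return np.stack(out)


def save_beta_set(betas: BetaPatternSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mask(betas.mask, out / "mask.nii.gz")
    n_runs, n_cond, _ = betas.betas.shape
    vol = np.zeros((*betas.grid.dims, n_runs * n_cond))
    rows = []
    inmask = betas.mask.included
    for r in range(n_runs):
        for c in range(n_cond):
            v = r * n_cond + c
            frame = np.zeros(betas.grid.dims)
            frame[inmask] = betas.betas[r, c]
            vol[..., v] = frame
            rows.append(
                {
                    "volume": v,
                    "run": betas.run_labels[r],
                    "condition": betas.conditions[c],
                    "familiarity": betas.familiarity[betas.conditions[c]],
                }
            )
    save_volume(vol, betas.grid, out / "betas.nii.gz")
    pd.DataFrame(rows).to_csv(out / "betas.tsv", sep="\t", index=False)


def load_beta_set(in_dir) -> BetaPatternSet:
    src = Path(in_dir)
    mask = load_mask(src / "mask.nii.gz")
    vol, grid = load_volume(src / "betas.nii.gz")
    table = pd.read_csv(src / "betas.tsv", sep="\t")
    runs = sorted(table["run"].unique())
    conditions = list(table[table["run"] == runs[0]].sort_values("volume")["condition"])
    familiarity = dict(zip(table["condition"], table["familiarity"]))
    inmask = mask.included
    betas = np.zeros((len(runs), len(conditions), int(inmask.sum())))
    for _, row in table.iterrows():
        r = runs.index(row["run"])
        c = conditions.index(row["condition"])
        betas[r, c] = vol[..., int(row["volume"])][inmask]
    return BetaPatternSet(betas, conditions, familiarity, runs, grid, mask)
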