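"""Run-wise GLM beta estimation and classifier feature preparation.

Covers the per-run ordinary least squares of voxel time series on
HRF-convolved condition regressors (plus nuisance columns), CompCor-style
noise components, within-run z-scoring, and the condition filter that
retains the 4 familiar + 4 unfamiliar identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import gammaln

from .simulate import FAMILIAR, UNFAMILIAR, BetaPatternSet, DesignSpec, Trial, TrialSequence
from .volume import BrainMask, VolumeGrid

__all__ = [
    "NuisanceSet",
    "double_gamma_hrf",
    "build_design_matrix",
    "estimate_betas",
    "compcor_components",
    "zscore_within_run",
    "filter_conditions",
]


@dataclass
class NuisanceSet:
    """Per-run nuisance regressor matrices (timepoints x regressors)."""

    regressors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.regressors = [np.atleast_2d(np.asarray(r, dtype=float)) for r in self.regressors]
        for r in self.regressors:
            if r.shape[1] > 1:
                # reject duplicated constant columns, which are silently collinear
                const = [j for j in range(r.shape[1]) if np.ptp(r[:, j]) == 0]
                if len(const) > 1:
                    raise ValueError("nuisance matrix contains duplicate constant columns")

    def for_run(self, run: int) -> np.ndarray:
        return self.regressors[run]


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak ~5 s, undershoot ~15 s)."""
    t = np.asarray(t, dtype=float)
    a1, a2, b1, b2, c = 6.0, 16.0, 1.0, 1.0, 1.0 / 6.0

    def gpdf(x, a, b):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((a - 1) * np.log(x[pos]) + a * np.log(b) - b * x[pos] - gammaln(a))
        return out

    return gpdf(t, a1, b1) - c * gpdf(t, a2, b2)


def build_design_matrix(
    run_trials: list[Trial],
    spec: DesignSpec,
    tr_s: float = 2.0,
    trial_slot_s: float = 6.0,
    fixation_s: float = 10.0,
    hrf=double_gamma_hrf,
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved condition regressors for one run.

    One column per identity condition plus ``oddball`` and ``buffer``
    columns; blank trials form the implicit baseline.  Returns the matrix
    without an intercept (the caller appends nuisance/intercept columns).
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    columns = list(spec.identities) + ["oddball", "buffer"]
    stim_s = 3 * spec.stim_duration_ms / 1000.0
    total_s = 2 * fixation_s + len(run_trials) * trial_slot_s
    n_tp = int(np.ceil(total_s / tr_s))
    upsample = 10
    dt = tr_s / upsample
    n_fine = n_tp * upsample
    boxcars = np.zeros((n_fine, len(columns)))
    for i, trial in enumerate(run_trials):
        onset = fixation_s + i * trial_slot_s
        if trial.trial_type == "blank":
            continue
        if trial.trial_type == "normal":
            col = columns.index(trial.identity)
        else:
            col = columns.index(trial.trial_type)
        a, b = int(round(onset / dt)), int(round((onset + stim_s) / dt))
        boxcars[a:b, col] = 1.0
    t = np.arange(0, 32.0, dt)
    kernel = hrf(t)
    X_fine = np.stack(
        [np.convolve(boxcars[:, j], kernel)[:n_fine] * dt for j in range(len(columns))], axis=1
    )
    X = X_fine[::upsample]
    return X, columns


def estimate_betas(
    timeseries: np.ndarray,
    design: TrialSequence,
    grid: VolumeGrid,
    mask: BrainMask,
    nuisance: NuisanceSet | None = None,
    tr_s: float = 2.0,
    trial_slot_s: float = 6.0,
    fixation_s: float = 10.0,
    hrf=double_gamma_hrf,
) -> BetaPatternSet:
    """Per-run OLS of each voxel's series on condition + nuisance regressors.

    Returns the identity-condition betas only (oddball/buffer/nuisance
    columns are estimated and discarded).  Raises on a rank-deficient
    design, naming the collinear columns.
    """
    spec = design.spec
    n_runs = len(design.runs)
    if timeseries.shape[0] != n_runs:
        raise ValueError("timeseries run axis does not match design")
    betas = []
    for r in range(n_runs):
        Xc, columns = build_design_matrix(
            design.runs[r], spec, tr_s=tr_s, trial_slot_s=trial_slot_s, fixation_s=fixation_s, hrf=hrf
        )
        n_tp = timeseries.shape[1]
        if Xc.shape[0] < n_tp:
            raise ValueError("timeseries longer than the design predicts")
        Xc = Xc[:n_tp]
        parts = [Xc, np.ones((n_tp, 1))]
        names = columns + ["intercept"]
        if nuisance is not None:
            nz = nuisance.for_run(r)
            if nz.shape[0] != n_tp:
                raise ValueError("nuisance regressors do not match timepoints")
            parts.append(nz)
            names += [f"nuisance{j}" for j in range(nz.shape[1])]
        X = np.hstack(parts)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify offending columns via pivoted QR
            _, _, piv = scipy.linalg.qr(X, pivoting=True)
            bad = [names[piv[j]] for j in range(rank, X.shape[1])]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
        coef, *_ = np.linalg.lstsq(X, timeseries[r], rcond=None)
        keep = [names.index(c) for c in spec.identities]
        betas.append(coef[keep])
    familiarity = {c: spec.familiarity_of(c) for c in spec.identities}
    return BetaPatternSet(
        np.stack(betas), list(spec.identities), familiarity, list(range(n_runs)), grid, mask
    )


def compcor_components(
    timeseries: np.ndarray,
    confounds: np.ndarray | None = None,
    n_components: int = 5,
) -> np.ndarray:
    """First principal-component time courses of confound-residualized noise voxels.

    ``timeseries`` is timepoints x voxels from a noise mask (e.g. white
    matter).  Voxels are residualized on an intercept plus ``confounds``,
    then PCA'd; the first ``n_components`` component time courses are
    returned, each scaled to unit variance.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} noise voxels")
    n_tp = ts.shape[0]
    C = np.ones((n_tp, 1))
    if confounds is not None:
        C = np.hstack([C, np.atleast_2d(np.asarray(confounds, dtype=float))])
    resid = ts - C @ np.linalg.lstsq(C, ts, rcond=None)[0]
    U, s, _ = np.linalg.svd(resid, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but residual rank is {rank}")
    comps = U[:, :n_components] * s[:n_components]
    comps = comps / comps.std(axis=0, ddof=0)
    return comps


def zscore_within_run(betas: BetaPatternSet, ddof: int = 0) -> BetaPatternSet:
    """Z-score each voxel across conditions, separately per run.

    Population SD (``ddof=0``) by default.  Constant voxels map to zeros
    with a warning rather than NaN.
    """
    if betas.betas.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 conditions per run")
    b = betas.betas
    mean = b.mean(axis=1, keepdims=True)
    sd = b.std(axis=1, keepdims=True, ddof=ddof)
    flat = sd <= 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} run-voxel cells are constant; set to zero")
    sd = np.where(flat, 1.0, sd)
    z = (b - mean) / sd
    z[np.broadcast_to(flat, z.shape)] = 0.0
    return BetaPatternSet(
        z, list(betas.conditions), dict(betas.familiarity), list(betas.run_labels), betas.grid, betas.mask
    )


def filter_conditions(betas: BetaPatternSet) -> BetaPatternSet:
    """Keep only the 4 familiar + 4 unfamiliar identity conditions."""
    keep = [c for c in betas.conditions if betas.familiarity[c] in (FAMILIAR, UNFAMILIAR)]
    n_fam = sum(betas.familiarity[c] == FAMILIAR for c in keep)
    n_unfam = sum(betas.familiarity[c] == UNFAMILIAR for c in keep)
    if n_fam != 4 or n_unfam != 4:
        raise ValueError(
            f"expected 4 familiar and 4 unfamiliar conditions, found {n_fam} and {n_unfam}"
        )
    if keep == betas.conditions:
        return betas
    return betas.select_conditions(keep)
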