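"""Synthetic designs and run-wise beta patterns with planted signal structure.

The generator emulates a slow event-related session: 11 runs of 48 trials
covering 9 identities (4 familiar, 4 unfamiliar, self) plus blank, oddball
and buffer trials, and produces run x condition x voxel beta arrays whose
spatial structure (a familiarity-shared component, identity-specific
components, a view-dependent component, smooth noise) matches what the
downstream decoding and geometry analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import BrainMask, VolumeGrid, make_spherical_roi

__all__ = [
    "FAMILIAR",
    "UNFAMILIAR",
    "SELF",
    "DesignSpec",
    "Trial",
    "TrialSequence",
    "SignalRegion",
    "SignalSpec",
    "BetaPatternSet",
    "generate_design",
    "generate_betas",
    "generate_timeseries",
]

FAMILIAR = "familiar"
UNFAMILIAR = "unfamiliar"
SELF = "self"

_DEFAULT_VIEWS = ("left", "center", "right")
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DesignSpec:
    """Session design: identities, per-run trial composition, timing."""

    n_runs: int = 11
    familiar: tuple[str, ...] = ("F1", "F2", "F3", "F4")
    unfamiliar: tuple[str, ...] = ("U1", "U2", "U3", "U4")
    self_identity: str = "SELF"
    trials_per_identity_per_run: int = 4
    n_blank_per_run: int = 4
    n_oddball_per_run: int = 4
    n_buffer_per_run: int = 4
    views: tuple[str, str, str] = _DEFAULT_VIEWS
    stim_duration_ms: int = 500

    def __post_init__(self) -> None:
        if len(self.familiar) != 4 or len(self.unfamiliar) != 4:
            raise ValueError("design requires 4 familiar and 4 unfamiliar identities")
        if set(self.familiar) & set(self.unfamiliar):
            raise ValueError("familiar and unfamiliar identity labels must be disjoint")
        if self.self_identity in self.familiar + self.unfamiliar:
            raise ValueError("self identity must be distinct")
        if self.n_runs < 1 or self.trials_per_identity_per_run < 1:
            raise ValueError("n_runs and trials_per_identity_per_run must be positive")
        if self.n_buffer_per_run != 4:
            raise ValueError("buffer trials are fixed at 4 per run (3 at start, 1 at end)")
        if min(self.n_blank_per_run, self.n_oddball_per_run) < 0:
            raise ValueError("trial counts must be non-negative")

    @property
    def identities(self) -> tuple[str, ...]:
        return self.familiar + self.unfamiliar + (self.self_identity,)

    def familiarity_of(self, identity: str) -> str:
        if identity in self.familiar:
            return FAMILIAR
        if identity in self.unfamiliar:
            return UNFAMILIAR
        if identity == self.self_identity:
            return SELF
        raise KeyError(identity)

    @property
    def trials_per_run(self) -> int:
        return (
            len(self.identities) * self.trials_per_identity_per_run
            + self.n_blank_per_run
            + self.n_oddball_per_run
            + self.n_buffer_per_run
        )


class Trial(NamedTuple):
    index: int
    trial_type: str  # normal | blank | oddball | buffer
    identities: tuple[str, ...]  # () blank, (id,) normal/buffer, (a, b) oddball
    familiarity: str | None
    views: tuple[str, ...]

    @property
    def identity(self) -> str | None:
        return self.identities[0] if self.identities else None


@dataclass
class TrialSequence:
    """Ordered per-run trial lists for one session."""

    spec: DesignSpec
    runs: list[list[Trial]]

    def __post_init__(self) -> None:
        if len(self.runs) != self.spec.n_runs:
            raise ValueError("run count does not match spec")
        for run in self.runs:
            if len(run) != self.spec.trials_per_run:
                raise ValueError("run length does not match spec")
            if [t.trial_type for t in run[:3]] != ["buffer"] * 3 or run[-1].trial_type != "buffer":
                raise ValueError("buffer trials must be 3 at run start and 1 at run end")

    @property
    def run_labels(self) -> list[int]:
        return list(range(len(self.runs)))

    def identity_trials(self) -> list[tuple[int, Trial]]:
        """(run, trial) pairs for normal identity trials only."""
        return [(r, t) for r, run in enumerate(self.runs) for t in run if t.trial_type == "normal"]

    def counts(self, run: int) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.runs[run]:
            key = t.identity if t.trial_type == "normal" else t.trial_type
            out[key] = out.get(key, 0) + 1
        return out


def _counterbalanced_order(items: list, rng: np.random.Generator, key, trans: dict) -> list:
    """Greedy seeded ordering flattening the first-order transition counts.

    Repeatedly picks, among remaining items, one whose (previous, next)
    category transition has been used least so far; ties are broken by the
    seeded rng.  ``trans`` accumulates across runs so counterbalancing is
    approximated session-wide.  A surrogate for a full optimizer.
    """
    remaining = list(items)
    rng.shuffle(remaining)
    out = [remaining.pop()]
    while remaining:
        prev = key(out[-1])
        costs = np.array([trans.get((prev, key(it)), 0) for it in remaining], dtype=float)
        best = np.flatnonzero(costs == costs.min())
        pick = int(rng.choice(best))
        nxt = remaining.pop(pick)
        trans[(prev, key(nxt))] = trans.get((prev, key(nxt)), 0) + 1
        out.append(nxt)
    return out


def generate_design(spec: DesignSpec, seed: int) -> TrialSequence:
    """Generate a pseudo-randomized session, deterministic given ``seed``.

    Each run holds 3 opening buffers, a counterbalanced middle block
    (identity, blank, oddball trials), and one closing buffer.  Every
    trial shows the 3 head views in seeded random order; oddball trials
    contain two identities.
    """
    rng = np.random.default_rng(seed)
    ids = list(spec.familiar + spec.unfamiliar + (spec.self_identity,))
    runs: list[list[Trial]] = []
    trans: dict[tuple, int] = {}

    def views() -> tuple[str, ...]:
        return tuple(rng.permutation(spec.views))

    for _ in range(spec.n_runs):
        middle: list[tuple[str, tuple[str, ...]]] = []
        for ident in ids:
            middle += [("normal", (ident,))] * spec.trials_per_identity_per_run
        middle += [("blank", ())] * spec.n_blank_per_run
        for _ in range(spec.n_oddball_per_run):
            pair = tuple(rng.choice(ids, size=2, replace=False))
            middle.append(("oddball", pair))
        middle = _counterbalanced_order(
            middle, rng, key=lambda it: it[1][0] if it[0] == "normal" else it[0], trans=trans
        )
        trials: list[Trial] = []
        for _ in range(3):
            trials.append(
                Trial(len(trials), "buffer", (str(rng.choice(ids)),), None, views())
            )
        for ttype, idents in middle:
            fam = spec.familiarity_of(idents[0]) if ttype == "normal" else None
            trials.append(Trial(len(trials), ttype, idents, fam, views() if ttype != "blank" else ()))
        trials.append(Trial(len(trials), "buffer", (str(rng.choice(ids)),), None, views()))
        runs.append(trials)
    return TrialSequence(spec, runs)


# ---------------------------------------------------------------------------
# Beta pattern generation


@dataclass(frozen=True)
class SignalRegion:
    """A spherical region carrying planted signal, with a system label."""

    name: str
    center: tuple[int, int, int]
    radius_vox: float
    familiarity_scale: float = 1.0
    identity_scale: float = 1.0
    view_scale: float = 1.0
    system: str = "core-ventral"


@dataclass(frozen=True)
class SignalSpec:
    """Amplitudes (beta units) of the planted components plus noise."""

    familiarity_amp: float = 0.0
    identity_amp: float = 0.0
    view_amp: float = 0.0
    noise_sd: float = 1.0
    smooth_fwhm_vox: float = 3.0  # 6 mm at nominal 2 mm voxels
    regions: tuple[SignalRegion, ...] = ()
    familiarity_mode: str = "signed"  # signed: +F familiar, -F unfamiliar; additive: +F familiar only
    seed: int = 0

    def __post_init__(self) -> None:
        for amp in (self.familiarity_amp, self.identity_amp, self.view_amp):
            if not np.isfinite(amp) or amp < 0:
                raise ValueError("amplitudes must be finite and non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.familiarity_mode not in ("signed", "additive"):
            raise ValueError("familiarity_mode must be 'signed' or 'additive'")


@dataclass
class BetaPatternSet:
    """runs x conditions x voxels beta array over the in-mask voxels.

    ``betas[r, c, v]`` is the beta of condition ``conditions[c]`` in run
    ``run_labels[r]`` at the ``v``-th in-mask voxel (C-order over the mask).
    """

    betas: np.ndarray
    conditions: list[str]
    familiarity: dict[str, str]
    run_labels: list[int]
    grid: VolumeGrid
    mask: BrainMask

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be runs x conditions x voxels")
        if self.betas.shape[0] != len(self.run_labels):
            raise ValueError("run axis does not match run_labels")
        if self.betas.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.betas.shape[2] != self.mask.n_voxels:
            raise ValueError("voxel axis does not match mask")
        if not np.isfinite(self.betas).all():
            raise ValueError("betas contain missing values inside the mask")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)

    def select_conditions(self, keep: list[str]) -> "BetaPatternSet":
        idx = [self.condition_index(c) for c in keep]
        return BetaPatternSet(
            self.betas[:, idx, :],
            list(keep),
            {c: self.familiarity[c] for c in keep},
            list(self.run_labels),
            self.grid,
            self.mask,
        )

    def select_voxels(self, columns: np.ndarray) -> "BetaPatternSet":
        """Restrict to a voxel subset given as in-mask column indices.

        Columns stay in the mask's C-order (the array/mask correspondence
        is part of the type's contract), so the input order is ignored.
        """
        columns = np.unique(np.asarray(columns))
        sub = np.zeros(self.grid.dims, dtype=bool)
        vox = self.mask.voxel_indices()[columns]
        sub[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        return BetaPatternSet(
            self.betas[:, :, columns],
            list(self.conditions),
            dict(self.familiarity),
            list(self.run_labels),
            self.grid,
            BrainMask(self.grid, sub),
        )


def _smooth_noise(rng: np.random.Generator, grid: VolumeGrid, sd: float, fwhm_vox: float) -> np.ndarray:
    noise = rng.standard_normal(grid.dims)
    if fwhm_vox > 0:
        noise = gaussian_filter(noise, sigma=fwhm_vox * FWHM_TO_SIGMA)
        noise -= noise.mean()  # remove the DC offset smoothing concentrates
        std = noise.std()
        if std > 0:
            noise /= std
    return sd * noise


def generate_betas(
    design: TrialSequence,
    signal: SignalSpec,
    grid: VolumeGrid,
    mask: BrainMask | None = None,
) -> BetaPatternSet:
    """Plant familiarity / identity / view components into run-wise betas.

    The familiarity component F is one spatial pattern shared by all
    familiar identities (sign -1 for unfamiliar in ``signed`` mode, absent
    in ``additive`` mode).  Identity components G are independent patterns
    per identity, constant across runs.  The view component varies by run.
    All structured components are drawn once per dataset from
    ``signal.seed``; smooth Gaussian noise is redrawn per run and condition.
    """
    if mask is None:
        mask = BrainMask.full(grid)
    spec = design.spec
    conditions = list(spec.identities)
    rng = np.random.default_rng(signal.seed)

    amp_f = np.zeros(grid.dims)
    amp_g = np.zeros(grid.dims)
    amp_v = np.zeros(grid.dims)
    if signal.regions:
        for region in signal.regions:
            roi = make_spherical_roi(
                region.name,
                region.center,
                region.radius_vox * min(grid.voxel_size),
                region.system,
                mask,
            )
            vox = roi.voxels
            amp_f[vox[:, 0], vox[:, 1], vox[:, 2]] = signal.familiarity_amp * region.familiarity_scale
            amp_g[vox[:, 0], vox[:, 1], vox[:, 2]] = signal.identity_amp * region.identity_scale
            amp_v[vox[:, 0], vox[:, 1], vox[:, 2]] = signal.view_amp * region.view_scale
    else:
        amp_f[:] = signal.familiarity_amp
        amp_g[:] = signal.identity_amp
        amp_v[:] = signal.view_amp

    inmask = mask.included
    F = rng.standard_normal(grid.dims)[inmask] * amp_f[inmask]
    G = {c: rng.standard_normal(grid.dims)[inmask] * amp_g[inmask] for c in conditions}
    view_patterns = {v: rng.standard_normal(grid.dims)[inmask] * amp_v[inmask] for v in spec.views}

    sign = {FAMILIAR: 1.0, UNFAMILIAR: -1.0 if signal.familiarity_mode == "signed" else 0.0, SELF: 0.0}
    n_runs = len(design.runs)
    betas = np.zeros((n_runs, len(conditions), mask.n_voxels))
    for r in range(n_runs):
        # each run mixes the view patterns with seeded random weights
        w = rng.dirichlet(np.ones(len(spec.views)))
        H = sum(wi * view_patterns[v] for wi, v in zip(w, spec.views))
        for ci, cond in enumerate(conditions):
            fam = spec.familiarity_of(cond)
            noise = _smooth_noise(rng, grid, signal.noise_sd, signal.smooth_fwhm_vox)[inmask]
            betas[r, ci] = sign[fam] * F + G[cond] + H + noise
    familiarity = {c: spec.familiarity_of(c) for c in conditions}
    return BetaPatternSet(betas, conditions, familiarity, list(range(n_runs)), grid, mask)


def generate_timeseries(
    design: TrialSequence,
    betas: BetaPatternSet,
    tr_s: float = 2.0,
    hrf=None,
    trial_slot_s: float = 6.0,
    fixation_s: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """BOLD-like series: condition boxcars convolved with the HRF x betas.

    Returns a (runs, timepoints, voxels) array.  With ``noise_sd=0`` the
    series round-trips exactly through :func:`facegeom.estimation.estimate_betas`.
    """
    from .estimation import build_design_matrix, double_gamma_hrf

    if tr_s <= 0:
        raise ValueError("TR must be positive")
    if hrf is None:
        hrf = double_gamma_hrf
    rng = np.random.default_rng(seed)
    out = []
    for r, run in enumerate(design.runs):
        X, columns = build_design_matrix(
            run, design.spec, tr_s=tr_s, trial_slot_s=trial_slot_s, fixation_s=fixation_s, hrf=hrf
        )
        B = np.zeros((len(columns), betas.betas.shape[2]))
        for ci, col in enumerate(columns):
            if col in betas.conditions:
                B[ci] = betas.betas[r, betas.condition_index(col)]
        ts = X @ B
        if noise_sd > 0:
            ts = ts + noise_sd * rng.standard_normal(ts.shape)
        out.append(ts)
    return np.stack(out)
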