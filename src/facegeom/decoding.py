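"""Linear classification of beta patterns and searchlight accuracy maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import sklearn
from joblib import Parallel, delayed
from sklearn.svm import SVC

from ._fast_svm import FastLinearSVC
from .crossval import LabelPermutation, Split
from .simulate import FAMILIAR, UNFAMILIAR, BetaPatternSet
from .volume import BrainMask, VolumeGrid, sphere_neighborhood

__all__ = [
    "ClassifierSpec",
    "AccuracyMap",
    "train_predict",
    "familiarity_decoding",
    "identity_decoding",
    "searchlight_map",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear large-margin classifier with norm-scaled regularization.

    The effective regularization constant is ``c_base / (mean Euclidean
    norm of the training vectors)**2`` — the classic MVPA-toolkit default
    that scales C by the mean norm of the training data and makes the
    decision rule exactly invariant to a shared rescaling of train and
    test features.  Multiclass problems use one-vs-one voting.

    ``engine`` selects the solver: ``"fast"`` (in-package dual coordinate
    descent, used for searchlight-scale workloads) or ``"svc"`` (libsvm
    via scikit-learn); the two are asserted to agree in the test suite.
    """

    c_base: float = 1.0
    scale_by_norm: bool = True
    engine: str = "fast"

    def __post_init__(self) -> None:
        if self.c_base <= 0:
            raise ValueError("c_base must be positive")
        if self.engine not in ("fast", "svc"):
            raise ValueError("engine must be 'fast' or 'svc'")

    def effective_c(self, train: np.ndarray) -> float:
        if not self.scale_by_norm:
            return self.c_base
        mean_norm = float(np.linalg.norm(train, axis=1).mean())
        if mean_norm == 0:
            return self.c_base
        return self.c_base / mean_norm**2


@dataclass
class AccuracyMap:
    """Voxel-wise classification accuracies on a masked grid (NaN outside)."""

    grid: VolumeGrid
    mask: BrainMask
    values: np.ndarray
    chance: float
    analysis: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError("values shape does not match grid")
        inmask = self.values[self.mask.included]
        if np.nanmin(inmask) < -1e-12 or np.nanmax(inmask) > 1 + 1e-12:
            raise ValueError("accuracies must lie in [0, 1]")
        if self.chance not in (0.25, 0.5):
            raise ValueError("chance must be 0.25 or 0.5")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask.included]


def train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    spec: ClassifierSpec = ClassifierSpec(),
) -> tuple[np.ndarray, float]:
    """Fit the linear classifier and return (predicted labels, accuracy).

    Degenerate all-constant training features yield chance-level behavior
    (constant prediction of the first class) with a warning instead of an
    error, so searchlight maps remain total over the mask.
    """
    train_X = np.ascontiguousarray(train_X, dtype=np.float64)
    test_X = np.ascontiguousarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if np.all(np.ptp(train_X, axis=0) == 0):
        warnings.warn("all-constant training features; predicting the first class")
        pred = np.full(len(test_X), classes[0], dtype=train_y.dtype)
    else:
        pred = _fit_predict(train_X, train_y, test_X, spec)
    acc = float(np.mean(pred == np.asarray(test_y)))
    return pred, acc


def _fit_predict(train_X, train_y, test_X, spec: ClassifierSpec) -> np.ndarray:
    # c_base / mean_norm**2 is applied by rescaling the features to unit
    # mean norm and fitting at C = c_base: the same decision rule, but
    # exactly invariant to shared feature scaling at any solver tolerance.
    if spec.scale_by_norm:
        mean_norm = float(np.linalg.norm(train_X, axis=1).mean())
        if mean_norm > 0:
            train_X = train_X / mean_norm
            test_X = test_X / mean_norm
    if spec.engine == "svc":
        clf = SVC(kernel="linear", C=spec.c_base, decision_function_shape="ovo")
    else:
        clf = FastLinearSVC(C=spec.c_base)
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


class _SplitPlan:
    """Precomputed row indices and labels for a fixed (betas, splits, labels).

    Flattens the beta array to (runs*conditions, voxels) once; each split
    becomes integer row indices plus encoded label arrays, so a
    searchlight center only gathers columns and runs the fits.
    """

    def __init__(self, betas: BetaPatternSet, splits: list[Split], label_of):
        self.samples = betas.betas.reshape(-1, betas.betas.shape[2])
        n_cond = len(betas.conditions)
        run_index = {r: i for i, r in enumerate(betas.run_labels)}
        cond_index = {c: i for i, c in enumerate(betas.conditions)}

        def rows_labels(keys):
            keys = sorted(keys)
            rows = np.array([run_index[r] * n_cond + cond_index[c] for r, c in keys])
            y = np.array([label_of(r, c) for r, c in keys])
            return rows, y

        self.splits = [(rows_labels(s.train), rows_labels(s.test)) for s in splits]
        for (_, ytr), _ in self.splits:
            if len(np.unique(ytr)) < 2:
                raise ValueError("a split's training data contains a single class")

    def mean_accuracy(self, spec: ClassifierSpec, columns: np.ndarray | None = None) -> float:
        X = self.samples if columns is None else self.samples[:, columns]
        X = np.ascontiguousarray(X)
        accs = []
        with sklearn.config_context(assume_finite=True):
            for (tr_rows, tr_y), (te_rows, te_y) in self.splits:
                Xtr = X[tr_rows]
                if np.all(np.ptp(Xtr, axis=0) == 0):
                    pred = np.full(len(te_rows), tr_y[0], dtype=tr_y.dtype)
                else:
                    pred = _fit_predict(Xtr, tr_y, X[te_rows], spec)
                accs.append(float(np.mean(pred == te_y)))
        return float(np.mean(accs))


def _familiarity_plan(
    betas: BetaPatternSet, splits: list[Split], label_map: dict[str, str] | None
) -> _SplitPlan:
    if len(betas.conditions) != 8:
        raise ValueError("familiarity decoding expects the 8 retained identity conditions")
    schemes = {s.scheme for s in splits}
    if not schemes <= {"l2io", "loro"}:
        raise ValueError(f"unsupported split scheme(s) {schemes} for familiarity decoding")
    labels = label_map if label_map is not None else betas.familiarity
    return _SplitPlan(betas, splits, lambda run, cond: labels[cond])


def familiarity_decoding(
    betas: BetaPatternSet,
    splits: list[Split],
    spec: ClassifierSpec = ClassifierSpec(),
    label_map: dict[str, str] | None = None,
    columns: np.ndarray | None = None,
) -> float:
    """Mean familiar-vs-unfamiliar test accuracy across the splits.

    ``label_map`` substitutes permuted familiarity labels (null
    distribution); by default the veridical condition->class map is used.
    Accepts leave-two-identities-out splits (the identity-controlled
    scheme) or leave-one-run-out splits (the uncontrolled comparison).
    """
    return _familiarity_plan(betas, splits, label_map).mean_accuracy(spec, columns)


def _identity_plan(
    betas: BetaPatternSet, splits: list[Split], perm: LabelPermutation | None
) -> _SplitPlan:
    fams = {betas.familiarity[c] for c in betas.conditions}
    if len(fams) != 1 or not fams <= {FAMILIAR, UNFAMILIAR}:
        raise ValueError("identity decoding requires conditions from a single familiarity class")
    if len(betas.conditions) != 4:
        raise ValueError("identity decoding expects exactly 4 conditions")
    if any(s.scheme != "loro" for s in splits):
        raise ValueError("identity decoding requires leave-one-run-out splits")
    run_maps = perm.run_maps() if perm is not None else None

    def label_of(run, cond):
        return run_maps[run][cond] if run_maps is not None else cond

    return _SplitPlan(betas, splits, label_of)


def identity_decoding(
    betas: BetaPatternSet,
    splits: list[Split],
    spec: ClassifierSpec = ClassifierSpec(),
    perm: LabelPermutation | None = None,
    columns: np.ndarray | None = None,
) -> float:
    """4-way identity accuracy averaged over leave-one-run-out splits.

    Must be called separately for the familiar and the unfamiliar
    condition sets; the caller averages the two resulting maps.  ``perm``
    optionally applies a within-run identity relabeling (null scheme).
    """
    return _identity_plan(betas, splits, perm).mean_accuracy(spec, columns)


def searchlight_map(
    betas: BetaPatternSet,
    analysis: str,
    splits: list[Split],
    radius_vox: float = 5.0,
    mask: BrainMask | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    label_map: dict[str, str] | None = None,
    perm: LabelPermutation | None = None,
    n_jobs: int = 1,
) -> AccuracyMap:
    """Sphere-searchlight decoding: accuracy stored at each center voxel.

    ``analysis`` is ``"familiarity"`` or ``"identity"``.  Centers run over
    ``mask`` (default: the betas' own mask), features are the in-mask
    voxels within ``radius_vox`` of each center, and results do not
    depend on execution order.
    """
    if analysis == "familiarity":
        plan = _familiarity_plan(betas, splits, label_map)
    elif analysis == "identity":
        plan = _identity_plan(betas, splits, perm)
    else:
        raise ValueError("analysis must be 'familiarity' or 'identity'")
    if mask is None:
        mask = betas.mask
    elif not np.all(~mask.included | betas.mask.included):
        raise ValueError("searchlight mask must be a subset of the betas' mask")
    lut = betas.mask.column_lookup()
    centers = mask.voxel_indices()

    def decode_center(center) -> float:
        vox = sphere_neighborhood(tuple(center), radius_vox, betas.mask)
        if len(vox) == 0:
            raise ValueError("empty searchlight neighborhood")
        cols = lut[vox[:, 0], vox[:, 1], vox[:, 2]]
        return plan.mean_accuracy(spec, cols)

    if n_jobs == 1:
        accs = [decode_center(c) for c in centers]
    else:
        accs = Parallel(n_jobs=n_jobs)(delayed(decode_center)(c) for c in centers)
    values = np.full(mask.grid.dims, np.nan)
    values[centers[:, 0], centers[:, 1], centers[:, 2]] = accs
    chance = 0.5 if analysis == "familiarity" else 0.25
    return AccuracyMap(mask.grid, mask, values, chance, analysis)
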