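"""Cross-validated RDMs and second-order representational geometry.

Per-ROI condition-by-condition similarity matrices are computed between
split-half run partitions (462 partitions for 11 runs) with all averaging
on the Fisher-z scale; ROI-by-ROI geometry comes in a within-subject
variant (correlation distance between vectorized RDMs, averaged over
subjects) and a between-subject variant (reliability-normalized
dissimilarity index over all subject pairs).  A classical MDS embedding,
the RV matrix-similarity coefficient, and a random-intercept mixed-model
contrast of within- vs between-system correlations complete the analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lme import RandomInterceptFit, fit_random_intercept, parametric_bootstrap
from .simulate import BetaPatternSet
from .volume import ROISpec

__all__ = [
    "RDM",
    "InterROIGeometry",
    "LMEContrastResult",
    "split_half_partitions",
    "crossvalidated_rdm",
    "fisher_average",
    "vectorize_rdm",
    "inter_roi_distances",
    "between_subject_geometry",
    "classical_mds",
    "rv_coefficient",
    "lme_system_contrast",
    "CORE_SYSTEMS",
]

CORE_SYSTEMS = ("core-ventral", "core-dorsal", "core-anterior")
_CLIP = 1.0 - 1e-7


@dataclass
class RDM:
    """Cross-validated condition x condition similarity matrix for one ROI.

    Entries are Pearson correlations between independent data halves, so
    the diagonal estimates pattern reliability and can differ from 1.
    """

    matrix: np.ndarray
    conditions: list[str]
    roi: str
    subject: str | int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.conditions)
        if self.matrix.shape != (n, n):
            raise ValueError("RDM shape does not match condition labels")
        if np.nanmax(np.abs(self.matrix)) > 1 + 1e-9:
            raise ValueError("RDM entries must lie in [-1, 1]")

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T))


def split_half_partitions(runs: list[int]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All partitions of the runs into halves of size ceil(n/2) and floor(n/2).

    For odd n every size-ceil(n/2) subset appears once (462 partitions for
    11 runs); for even n the double counting of complementary halves is
    removed by anchoring the first run in the first half.
    """
    n = len(runs)
    if n < 2:
        raise ValueError("need at least 2 runs to partition")
    k = (n + 1) // 2
    parts = []
    for combo in itertools.combinations(runs, k):
        if n % 2 == 0 and runs[0] not in combo:
            continue
        rest = tuple(r for r in runs if r not in combo)
        parts.append((combo, rest))
    return parts


def _fisher(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    clipped = np.clip(r, -_CLIP, _CLIP)
    if np.any(np.abs(r) > _CLIP):
        warnings.warn("correlations at +/-1 clipped before Fisher transform")
    return np.arctanh(clipped)


def fisher_average(correlations) -> float:
    """tanh(mean(atanh(r))): averaging on the variance-stabilized scale."""
    vals = np.asarray(list(correlations), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot Fisher-average an empty list")
    return float(np.tanh(_fisher(vals).mean()))


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between all rows of A and all rows of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(A, axis=1)
    sb = np.linalg.norm(B, axis=1)
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    return (A @ B.T) / np.outer(sa, sb)


def crossvalidated_rdm(betas: BetaPatternSet, roi: ROISpec, subject=None) -> RDM:
    """Split-half cross-validated RDM over the ROI's voxels.

    For every half/half run partition, condition patterns are averaged
    within each half and correlated across halves (all 8x8 pairs); the
    per-partition matrices are Fisher-averaged, symmetrized by averaging
    with the transpose (still on the z scale), and mapped back to r.
    """
    lut = betas.mask.column_lookup()
    dims = np.asarray(betas.grid.dims)
    if np.any(roi.voxels < 0) or np.any(roi.voxels >= dims):
        raise ValueError(f"ROI {roi.name!r} has voxels outside the betas' mask")
    cols = lut[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]]
    if np.any(cols < 0):
        raise ValueError(f"ROI {roi.name!r} has voxels outside the betas' mask")
    data = betas.betas[:, :, cols]  # runs x conditions x roi voxels
    run_idx = {r: i for i, r in enumerate(betas.run_labels)}
    zsum = np.zeros((len(betas.conditions),) * 2)
    parts = split_half_partitions(betas.run_labels)
    for half1, half2 in parts:
        m1 = data[[run_idx[r] for r in half1]].mean(axis=0)
        m2 = data[[run_idx[r] for r in half2]].mean(axis=0)
        zsum += _fisher(_corr_rows(m1, m2))
    z = zsum / len(parts)
    z = (z + z.T) / 2.0
    return RDM(np.tanh(z), list(betas.conditions), roi.name, subject)


def vectorize_rdm(rdm: RDM, include_diagonal: bool = True) -> np.ndarray:
    """Upper-triangle vectorization; the cross-validated diagonal is kept
    by default since it carries reliability information."""
    n = rdm.matrix.shape[0]
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    return rdm.matrix[iu]


@dataclass
class InterROIGeometry:
    """ROI x ROI geometry: distances, optional reliabilities, MDS, systems."""

    roi_names: list[str]
    systems: list[str]
    D: np.ndarray  # ROI x ROI distances
    r_pair: np.ndarray | None = None  # between-subject variant
    r_reliability: np.ndarray | None = None
    mds_coords: np.ndarray | None = None
    subject_D: np.ndarray | None = None  # subjects x ROI x ROI (within variant)
    variant: str = "within"
    n_subject_pairs: int | None = None  # between-subject variant

    def correlations(self) -> np.ndarray:
        """Distances converted back to correlations (1 - D)."""
        return 1.0 - self.D

    def with_mds(self, k: int = 3) -> "InterROIGeometry":
        self.mds_coords = classical_mds(self.D, k=k)
        return self


def inter_roi_distances(
    rdms_per_subject: list[list[RDM]],
    systems: list[str] | None = None,
    include_diagonal: bool = True,
) -> InterROIGeometry:
    """Within-subject geometry: correlation distance between vectorized RDMs.

    Per subject, distance(a, b) = 1 - Pearson r between the two ROIs'
    vectorized RDMs; subject matrices are averaged (Fisher scale on the
    underlying correlations) into a group matrix.
    """
    roi_names = [r.roi for r in rdms_per_subject[0]]
    n_roi = len(roi_names)
    subj_D = []
    zsum = np.zeros((n_roi, n_roi))
    for rdms in rdms_per_subject:
        if [r.roi for r in rdms] != roi_names:
            raise ValueError("all subjects must share the same ROI list and order")
        V = np.stack([vectorize_rdm(r, include_diagonal) for r in rdms])
        if np.any(V.std(axis=1) == 0):
            bad = roi_names[int(np.argmax(V.std(axis=1) == 0))]
            raise ValueError(f"constant RDM (zero variance) for ROI {bad!r}")
        R = _corr_rows(V, V)
        np.fill_diagonal(R, 1.0)
        subj_D.append(1.0 - R)
        R = R.copy()
        np.fill_diagonal(R, 0.0)  # diagonal is forced back to r=1 below
        zsum += _fisher(R)
    zmean = zsum / len(rdms_per_subject)
    group_R = np.tanh(zmean)
    np.fill_diagonal(group_R, 1.0)
    D = 1.0 - group_R
    np.fill_diagonal(D, 0.0)
    return InterROIGeometry(
        roi_names,
        systems if systems is not None else ["extended"] * n_roi,
        D,
        subject_D=np.stack(subj_D),
        variant="within",
    )


def between_subject_geometry(
    rdms: list[list[RDM]],
    systems: list[str] | None = None,
    include_diagonal: bool = True,
) -> InterROIGeometry:
    """Between-subject geometry with reliability-normalized dissimilarity.

    r_pair(a, b) Fisher-averages corr(RDM_a of subject s1, RDM_b of
    subject s2) over all ordered subject pairs (both directions of the 55
    unordered pairs at 11 subjects); r_reliability(a) is the same with
    a = b.  D = 1 - r_pair / sqrt(r_a * r_b); non-positive reliabilities
    make D undefined and raise.
    """
    n_subj = len(rdms)
    if n_subj < 2:
        raise ValueError("between-subject geometry needs at least 2 subjects")
    roi_names = [r.roi for r in rdms[0]]
    n_roi = len(roi_names)
    V = np.stack(
        [np.stack([vectorize_rdm(r, include_diagonal) for r in subj]) for subj in rdms]
    )  # subjects x rois x cells
    zsum = np.zeros((n_roi, n_roi))
    n_pairs = 0
    for s1, s2 in itertools.combinations(range(n_subj), 2):
        R12 = _fisher(_corr_rows(V[s1], V[s2]))
        zsum += (R12 + R12.T) / 2.0  # both directions of the pair
        n_pairs += 1
    zmean = zsum / n_pairs
    r_full = np.tanh(zmean)  # symmetric by construction
    rel = np.diag(r_full).copy()
    bad = [roi_names[i] for i in range(n_roi) if rel[i] <= 0]
    if bad:
        raise ValueError(f"non-positive RDM reliability for ROI(s) {bad}; dissimilarity index undefined")
    D = 1.0 - r_full / np.sqrt(np.outer(rel, rel))
    D = (D + D.T) / 2.0
    return InterROIGeometry(
        roi_names,
        systems if systems is not None else ["extended"] * n_roi,
        D,
        r_pair=r_full,
        r_reliability=rel,
        variant="between",
        n_subject_pairs=n_pairs,
    )


def classical_mds(distances: np.ndarray, k: int = 3) -> np.ndarray:
    """Classical (Torgerson) MDS: eigendecomposition of the double-centered
    squared-distance matrix; coordinates scaled by sqrt(eigenvalue)."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distances must be symmetric with zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12).sum())
    if k > n_pos:
        raise ValueError(f"requested {k} dimensions but only {n_pos} positive eigenvalues")
    neg_mass = float(-evals[evals < 0].sum())
    if neg_mass > 1e-10:
        warnings.warn(f"classical MDS truncated negative eigenvalue mass {neg_mass:.3g}")
    return evecs[:, :k] * np.sqrt(evals[:k])


def rv_coefficient(A: np.ndarray, B: np.ndarray) -> float:
    """RV coefficient between two symmetric matrices after double-centering."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("inputs must be square matrices of the same shape")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise ValueError("inputs must be symmetric")
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Ac, Bc = J @ A @ J, J @ B @ J
    denom = np.sqrt(np.trace(Ac @ Ac) * np.trace(Bc @ Bc))
    if denom == 0:
        raise ValueError("RV coefficient undefined for a zero (centered) matrix")
    return float(np.trace(Ac @ Bc) / denom)


@dataclass
class LMEContrastResult:
    beta: np.ndarray  # (intercept, within-core, within-extended)
    se: np.ndarray
    tvalues: np.ndarray
    ci: np.ndarray  # 3 x 2 bootstrap percentile intervals
    sigma_z: float
    sigma_eps: float
    n_units: int
    n_bootstrap: int
    fit: RandomInterceptFit = field(repr=False)


def system_indicators(
    systems: list[str], include_diagonal: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (ROI-pair) indicators: both-core C and both-extended E.

    The three core subsystems count as one "core" system for the
    contrast; EV ROIs belong to neither, so their pairs are "between".
    With ``include_diagonal`` the (a, a) cells are kept, giving 465 cells
    for 30 ROIs (the diagonal-inclusive upper-triangle convention).
    """
    is_core = np.array([s in CORE_SYSTEMS for s in systems])
    is_ext = np.array([s == "extended" for s in systems])
    iu = np.triu_indices(len(systems), k=0 if include_diagonal else 1)
    C = (is_core[iu[0]] & is_core[iu[1]]).astype(float)
    E = (is_ext[iu[0]] & is_ext[iu[1]]).astype(float)
    return C, E


def lme_system_contrast(
    correlations: np.ndarray,
    systems: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    include_diagonal: bool = False,
) -> LMEContrastResult:
    """Mixed-model contrast of within-system vs between-system correlations.

    ``correlations`` is (units, n_pairs): per unit (subject, or subject
    pair in the between-subject variant), the upper-triangle ROI-pair
    correlations (distances already converted back via 1 - D).  Fits
    ``r = b0 + b1*C + b2*E + z_unit`` by REML; b1 and b2 are the
    "within core > between" and "within extended > between" contrasts.
    95% CIs come from a parametric bootstrap.
    """
    r = np.asarray(correlations, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need correlations for at least 2 units")
    C, E = system_indicators(systems, include_diagonal=include_diagonal)
    if np.any(C * E != 0):
        raise AssertionError("a pair cannot be within-core and within-extended")
    if r.shape[1] != C.size:
        raise ValueError(f"expected {C.size} ROI pairs per unit, got {r.shape[1]}")
    n_units, n_pairs = r.shape
    X = np.column_stack([np.ones(n_pairs), C, E])
    Xfull = np.tile(X, (n_units, 1))
    groups = np.repeat(np.arange(n_units), n_pairs)
    y = r.ravel()
    fit = fit_random_intercept(y, Xfull, groups)
    boot = parametric_bootstrap(fit, Xfull, groups, n_bootstrap=n_bootstrap, seed=seed)
    ci = np.percentile(boot, [2.5, 97.5], axis=0).T
    return LMEContrastResult(
        beta=fit.beta,
        se=fit.se,
        tvalues=fit.tvalues,
        ci=ci,
        sigma_z=float(np.sqrt(fit.tau2)),
        sigma_eps=float(np.sqrt(fit.sigma2)),
        n_units=n_units,
        n_bootstrap=n_bootstrap,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def rdm_to_frame(rdm: RDM) -> pd.DataFrame:
    return pd.DataFrame(rdm.matrix, index=rdm.conditions, columns=rdm.conditions)


def save_rdm(rdm: RDM, path) -> None:
    rdm_to_frame(rdm).to_csv(path)


def load_rdm(path, roi: str | None = None, subject=None) -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(df.to_numpy(), list(df.columns), roi or "roi", subject)
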