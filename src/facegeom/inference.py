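"""Group-level permutation inference with threshold-free cluster enhancement.

Per-subject accuracy maps (observed and label-permutation nulls) are
centered at chance, TFCE-transformed, and averaged; the group null is
built by repeatedly averaging one randomly sampled permutation map per
subject.  z-scores support three constructions (see ``group_null_zmap``),
defaulting to the FWE-corrected max-statistic variant that makes a fixed
threshold of 1.65 correspond to p < 0.05 one-tailed corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .decoding import AccuracyMap
from .volume import BrainMask, VolumeGrid

__all__ = ["NullMapSet", "ZMap", "tfce_transform", "group_null_zmap", "threshold_zmap"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class NullMapSet:
    """Per-subject lists of permutation accuracy maps, all on one grid."""

    maps: list[list[AccuracyMap]]
    scheme: str

    def __post_init__(self) -> None:
        if not self.maps or any(len(m) < 1 for m in self.maps):
            raise ValueError("every subject needs at least one permutation map")
        ref = self.maps[0][0]
        for subj in self.maps:
            for m in subj:
                if m.grid != ref.grid or not np.array_equal(m.mask.included, ref.mask.included):
                    raise ValueError("all null maps must share grid and mask")


@dataclass
class ZMap:
    grid: VolumeGrid
    mask: BrainMask
    values: np.ndarray  # 3-D, NaN outside mask
    threshold: float = 1.65
    n_group_draws: int = 10000
    variant: str = "max"

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask.included]


def tfce_transform(
    image: np.ndarray,
    e_param: float = 0.5,
    h_param: float = 2.0,
    dh: float | None = None,
    connectivity: int = 6,
) -> np.ndarray:
    """TFCE of a non-negative 3-D image.

    Each voxel accumulates ``extent(h)^e * h^h_param * dh`` over
    thresholds ``h = dh, 2dh, ...`` up to its own height, where
    ``extent(h)`` is the size of the suprathreshold connected component
    containing it.  ``dh`` defaults to max/100.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    top = float(image.max(initial=0.0))
    if top <= 0:
        return np.zeros_like(image)
    if dh is None:
        dh = top / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    out = np.zeros_like(image)
    structure = _STRUCTURES[connectivity]
    h = dh
    while h <= top + 1e-12:
        supra = image >= h
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        out += (sizes[labels] ** e_param) * (h**h_param) * dh
        h += dh
    return out


def _prepare(map_: AccuracyMap, apply_tfce: bool, e: float, hp: float, dh, conn: int) -> np.ndarray:
    """Center at chance, clip negatives (one-tailed), optionally TFCE."""
    vals = np.where(map_.mask.included, map_.values, 0.0)
    vals = np.clip(vals - map_.chance, 0.0, None)
    if apply_tfce:
        vals = tfce_transform(vals, e_param=e, h_param=hp, dh=dh, connectivity=conn)
    return vals[map_.mask.included]


def group_null_zmap(
    observed: list[AccuracyMap],
    nulls: NullMapSet,
    n_draws: int = 10000,
    seed: int = 0,
    variant: str = "max",
    apply_tfce: bool = True,
    e_param: float = 0.5,
    h_param: float = 2.0,
    dh: float | None = None,
    connectivity: int = 6,
    threshold: float = 1.65,
) -> ZMap:
    """z-TFCE map from observed maps and per-subject permutation nulls.

    Group observed = subject mean of the prepared (chance-centered,
    TFCE'd) maps; each of ``n_draws`` null group maps averages one
    uniformly sampled permutation map per subject.  Variants:

    - ``"max"`` (default): voxel p = rank of the observed value within the
      null distribution of the *across-voxel maximum*; z = one-tailed
      normal quantile.  Corrected for multiple comparisons family-wise.
    - ``"voxel"``: z = (observed - null mean) / null SD per voxel.
    - ``"rank"``: voxel-wise empirical p mapped through the normal quantile.
    """
    if len(observed) != len(nulls.maps):
        raise ValueError("observed and null subjects do not match")
    ref = observed[0]
    for m in observed:
        if m.grid != ref.grid or not np.array_equal(m.mask.included, ref.mask.included):
            raise ValueError("observed maps must share grid and mask")
    if not np.array_equal(nulls.maps[0][0].mask.included, ref.mask.included):
        raise ValueError("null masks must match observed masks")
    if variant not in ("max", "voxel", "rank"):
        raise ValueError("variant must be 'max', 'voxel' or 'rank'")

    rng = np.random.default_rng(seed)
    obs = np.mean(
        [_prepare(m, apply_tfce, e_param, h_param, dh, connectivity) for m in observed], axis=0
    )
    prepared = [
        np.stack([_prepare(m, apply_tfce, e_param, h_param, dh, connectivity) for m in subj])
        for subj in nulls.maps
    ]
    n_subj, n_vox = len(prepared), obs.size

    # draw group-mean null maps in chunks to bound memory
    if variant == "voxel":
        run_sum = np.zeros(n_vox)
        run_sq = np.zeros(n_vox)
    elif variant == "max":
        null_max = np.empty(n_draws)
    else:
        exceed = np.zeros(n_vox)
    chunk = max(1, min(n_draws, 2000))
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        acc = np.zeros((c, n_vox))
        for s in range(n_subj):
            idx = rng.integers(0, len(prepared[s]), size=c)
            acc += prepared[s][idx]
        acc /= n_subj
        if variant == "voxel":
            run_sum += acc.sum(axis=0)
            run_sq += (acc**2).sum(axis=0)
        elif variant == "max":
            null_max[done : done + c] = acc.max(axis=1)
        else:
            exceed += (acc >= obs[None, :]).sum(axis=0)
        done += c

    if variant == "voxel":
        mean = run_sum / n_draws
        sd = np.sqrt(np.maximum(run_sq / n_draws - mean**2, 0.0))
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    else:
        if variant == "max":
            exceed = np.array([(null_max >= v).sum() for v in obs], dtype=float)
        # clip to the resolution of the permutation scheme so z stays finite
        p = np.clip((1.0 + exceed) / (n_draws + 1.0), None, n_draws / (n_draws + 1.0))
        z = norm.isf(p)

    values = np.full(ref.grid.dims, np.nan)
    values[ref.mask.included] = z
    return ZMap(ref.grid, ref.mask, values, threshold=threshold, n_group_draws=n_draws, variant=variant)


def threshold_zmap(zmap: ZMap, cutoff: float = 1.65) -> np.ndarray:
    """Boolean map of voxels with z >= cutoff (boundary inclusive)."""
    vals = zmap.masked_values()
    if not np.isfinite(vals).all():
        raise ValueError("z map contains non-finite values inside the mask")
    out = np.zeros(zmap.grid.dims, dtype=bool)
    out[zmap.mask.included] = vals >= cutoff
    return out
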