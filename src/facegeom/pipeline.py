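"""End-to-end orchestration: simulate -> decode -> infer -> rsa.

A single YAML config (one top-level seed, expanded deterministically into
per-stage seeds) drives all stages; outputs land in a run directory with
a machine-readable manifest recording every stage's parameters and the
SHA-256 of every file it wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossval import (
    enumerate_familiarity_permutations,
    identity_permutations_within_run,
    leave_one_run_out_splits,
    leave_two_identities_out_splits,
)
from .decoding import AccuracyMap, ClassifierSpec, searchlight_map
from .estimation import filter_conditions, zscore_within_run
from .inference import NullMapSet, group_null_zmap, threshold_zmap
from .io import save_beta_set, save_trial_table
from .rsa import crossvalidated_rdm, inter_roi_distances, lme_system_contrast
from .simulate import (
    BetaPatternSet,
    DesignSpec,
    SignalRegion,
    SignalSpec,
    generate_betas,
    generate_design,
)
from .volume import BrainMask, VolumeGrid, make_spherical_roi, save_volume

log = logging.getLogger("facegeom")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "simulate_subjects", "decode_subjects", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 3
    stages: tuple[str, ...] = ("simulate", "decode", "infer", "rsa")
    design: DesignSpec = field(default_factory=lambda: DesignSpec(n_runs=6))
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((10, 10, 8)))
    signal: SignalSpec = field(default_factory=SignalSpec)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    analysis: str = "familiarity"
    radius_vox: float = 1.0
    decode_center: tuple[int, int, int] | None = None
    decode_radius_vox: float | None = None
    n_perms_per_subject: int | None = None  # subsample of the exhaustive 35 if set
    n_draws: int = 2000
    variant: str = "max"
    threshold: float = 1.65
    rsa_rois: tuple[SignalRegion, ...] = ()
    rsa_bootstrap: int = 200

    @property
    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return {
            stage: int(child.generate_state(1)[0])
            for stage, child in zip(("simulate", "decode", "infer", "rsa"), children)
        }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("seed", "n_subjects", "analysis", "radius_vox", "n_perms_per_subject",
                "n_draws", "variant", "threshold", "rsa_bootstrap"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "design" in raw:
        kwargs["design"] = DesignSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw["design"].items()})
    if "grid" in raw:
        g = raw["grid"]
        kwargs["grid"] = VolumeGrid(tuple(g["dims"]), tuple(g.get("voxel_size", (2.0, 2.0, 2.0))))
    if "signal" in raw:
        s = dict(raw["signal"])
        regions = tuple(
            SignalRegion(**{k: tuple(v) if k == "center" else v for k, v in r.items()})
            for r in s.pop("regions", [])
        )
        kwargs["signal"] = SignalSpec(regions=regions, **s)
    if "classifier" in raw:
        kwargs["classifier"] = ClassifierSpec(**raw["classifier"])
    if "decode" in raw:
        d = raw["decode"]
        if "analysis" in d:
            kwargs["analysis"] = d["analysis"]
        if "radius_vox" in d:
            kwargs["radius_vox"] = d["radius_vox"]
        if "center" in d:
            kwargs["decode_center"] = tuple(d["center"])
            kwargs["decode_radius_vox"] = d.get("mask_radius_vox", 2.0)
    if "rsa_rois" in raw:
        kwargs["rsa_rois"] = tuple(
            SignalRegion(**{k: tuple(v) if k == "center" else v for k, v in r.items()})
            for r in raw["rsa_rois"]
        )
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    betas: list[BetaPatternSet]
    observed_maps: list[AccuracyMap] | None = None
    null_maps: NullMapSet | None = None
    zmap: object = None
    flagged: np.ndarray | None = None
    geometry: object = None
    lme: object = None
    manifest: dict = field(default_factory=dict)


def simulate_subjects(config: PipelineConfig, seed: int) -> tuple[list, list[BetaPatternSet]]:
    """Per-subject designs and z-scored 8-condition beta sets."""
    designs, all_betas = [], []
    ss = np.random.SeedSequence(seed).spawn(config.n_subjects)
    for s in range(config.n_subjects):
        child = ss[s].generate_state(2)
        design = generate_design(config.design, int(child[0]))
        sig = SignalSpec(
            familiarity_amp=config.signal.familiarity_amp,
            identity_amp=config.signal.identity_amp,
            view_amp=config.signal.view_amp,
            noise_sd=config.signal.noise_sd,
            smooth_fwhm_vox=config.signal.smooth_fwhm_vox,
            regions=config.signal.regions,
            familiarity_mode=config.signal.familiarity_mode,
            seed=int(child[1]),
        )
        betas = generate_betas(design, sig, config.grid)
        betas = zscore_within_run(filter_conditions(betas))
        designs.append(design)
        all_betas.append(betas)
    return designs, all_betas


def _decode_mask(config: PipelineConfig, betas: BetaPatternSet) -> BrainMask:
    if config.decode_center is None:
        return betas.mask
    roi = make_spherical_roi(
        "decode", config.decode_center,
        (config.decode_radius_vox or 2.0) * min(config.grid.voxel_size),
        "core-ventral", betas.mask,
    )
    sub = np.zeros(config.grid.dims, dtype=bool)
    sub[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]] = True
    return BrainMask(config.grid, sub)


def decode_subjects(
    config: PipelineConfig, betas_list: list[BetaPatternSet], seed: int
) -> tuple[list[AccuracyMap], NullMapSet]:
    """Observed searchlight maps plus the per-subject permutation null maps."""
    rng = np.random.default_rng(seed)
    spec = config.classifier
    observed, nulls = [], []
    design = config.design
    for betas in betas_list:
        mask = _decode_mask(config, betas)
        if config.analysis == "familiarity":
            splits = leave_two_identities_out_splits(
                list(design.familiar), list(design.unfamiliar), betas.run_labels
            )
            observed.append(
                searchlight_map(betas, "familiarity", splits, config.radius_vox, mask, spec)
            )
            # the exhaustive set includes the veridical labeling's class
            perms = enumerate_familiarity_permutations(betas.conditions)
            if config.n_perms_per_subject is not None and config.n_perms_per_subject < len(perms):
                idx = rng.choice(len(perms), size=config.n_perms_per_subject, replace=False)
                perms = [perms[i] for i in sorted(idx)]
            subj_nulls = []
            for p in perms:
                # rebuild the splits from the permuted classes so every null
                # decoding keeps the balanced 3+3 train / 1+1 test structure
                pmap = p.familiarity_map()
                fam_p = [c for c in betas.conditions if pmap[c] == "familiar"]
                unfam_p = [c for c in betas.conditions if pmap[c] == "unfamiliar"]
                perm_splits = leave_two_identities_out_splits(fam_p, unfam_p, betas.run_labels)
                subj_nulls.append(
                    searchlight_map(betas, "familiarity", perm_splits, config.radius_vox,
                                    mask, spec, label_map=pmap)
                )
            scheme = "familiarity-exhaustive"
        else:
            fam_sets = {
                "familiar": [c for c in betas.conditions if betas.familiarity[c] == "familiar"],
                "unfamiliar": [c for c in betas.conditions if betas.familiarity[c] == "unfamiliar"],
            }
            n_perms = config.n_perms_per_subject or 20
            half_maps, half_nulls = [], []
            for conds in fam_sets.values():
                sub = betas.select_conditions(conds)
                splits = leave_one_run_out_splits(sub.run_labels, conds)
                half_maps.append(searchlight_map(sub, "identity", splits, config.radius_vox, mask, spec))
                perms = identity_permutations_within_run(
                    conds, sub.run_labels, n_perms=n_perms, seed=int(rng.integers(2**31))
                )
                half_nulls.append([
                    searchlight_map(sub, "identity", splits, config.radius_vox, mask, spec, perm=p)
                    for p in perms
                ])
            avg = (half_maps[0].values + half_maps[1].values) / 2.0
            observed.append(AccuracyMap(config.grid, mask, avg, 0.25, "identity"))
            subj_nulls = [
                AccuracyMap(config.grid, mask, (a.values + b.values) / 2.0, 0.25, "identity")
                for a, b in zip(*half_nulls)
            ]
            scheme = "identity-within-run"
        nulls.append(subj_nulls)
    return observed, NullMapSet(nulls, scheme)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run the configured stages, writing outputs and a hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seeds = config.stage_seeds
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    result = PipelineResult(config=config, betas=[])

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
        }

    try:
        designs, betas_list = simulate_subjects(config, seeds["simulate"])
        result.betas = betas_list
        files = []
        if "simulate" in config.stages:
            for s, (design, betas) in enumerate(zip(designs, betas_list)):
                subj_dir = out / f"sub-{s:02d}"
                save_beta_set(betas, subj_dir)
                save_trial_table(design, subj_dir / "trials.tsv")
                files += sorted(subj_dir.iterdir())
            record("simulate", {"n_subjects": config.n_subjects, "n_runs": config.design.n_runs}, files)
            log.info("simulate: %d subjects", config.n_subjects)

        if "decode" in config.stages:
            observed, nulls = decode_subjects(config, betas_list, seeds["decode"])
            result.observed_maps, result.null_maps = observed, nulls
            files = []
            for s, m in enumerate(observed):
                f = out / f"sub-{s:02d}_accmap.nii.gz"
                save_volume(np.nan_to_num(m.values), m.grid, f)
                files.append(f)
            record("decode", {"analysis": config.analysis, "radius_vox": config.radius_vox,
                              "classifier": {"c_base": config.classifier.c_base}}, files)
            log.info("decode: %s searchlight on %d subjects", config.analysis, len(observed))

        if "infer" in config.stages:
            if result.observed_maps is None:
                raise RuntimeError("stage 'infer' requires stage 'decode'")
            zmap = group_null_zmap(
                result.observed_maps, result.null_maps, n_draws=config.n_draws,
                seed=seeds["infer"], variant=config.variant, threshold=config.threshold,
            )
            flagged = threshold_zmap(zmap, config.threshold)
            result.zmap, result.flagged = zmap, flagged
            fz, ft = out / "zmap.nii.gz", out / "zmap_thresholded.nii.gz"
            save_volume(np.nan_to_num(zmap.values), zmap.grid, fz)
            save_volume(flagged.astype(float), zmap.grid, ft)
            record("infer", {"n_draws": config.n_draws, "variant": config.variant,
                             "threshold": config.threshold}, [fz, ft])
            log.info("infer: %d voxels above z=%.2f", int(flagged.sum()), config.threshold)

        if "rsa" in config.stages and config.rsa_rois:
            rois = [
                make_spherical_roi(r.name, r.center, r.radius_vox * min(config.grid.voxel_size),
                                   r.system, betas_list[0].mask)
                for r in config.rsa_rois
            ]
            rdms = [[crossvalidated_rdm(b, roi, subject=s) for roi in rois]
                    for s, b in enumerate(betas_list)]
            systems = [r.system for r in config.rsa_rois]
            geom = inter_roi_distances(rdms, systems).with_mds(k=min(3, len(rois) - 1))
            result.geometry = geom
            files = []
            fD = out / "roi_distances.csv"
            pd.DataFrame(geom.D, index=geom.roi_names, columns=geom.roi_names).to_csv(fD)
            files.append(fD)
            fM = out / "mds_coords.csv"
            mds = pd.DataFrame(geom.mds_coords, index=geom.roi_names)
            mds["system"] = systems
            mds.to_csv(fM)
            files.append(fM)
            params = {"n_rois": len(rois), "bootstrap": config.rsa_bootstrap}
            if len(rois) >= 3 and geom.subject_D is not None:
                iu = np.triu_indices(len(rois), k=1)
                corr = 1.0 - geom.subject_D[:, iu[0], iu[1]]
                lme = lme_system_contrast(corr, systems, n_bootstrap=config.rsa_bootstrap,
                                          seed=seeds["rsa"])
                result.lme = lme
                fL = out / "lme_contrast.json"
                fL.write_text(json.dumps({
                    "beta": lme.beta.tolist(), "se": lme.se.tolist(),
                    "tvalues": lme.tvalues.tolist(), "ci": lme.ci.tolist(),
                    "sigma_z": lme.sigma_z, "sigma_eps": lme.sigma_eps,
                }, indent=2))
                files.append(fL)
            record("rsa", params, files)
            log.info("rsa: %d ROIs", len(rois))
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    result.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
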