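import pytest

from facegeom.estimation import filter_conditions, zscore_within_run
from facegeom.simulate import (
    DesignSpec,
    SignalRegion,
    SignalSpec,
    generate_betas,
    generate_design,
)
from facegeom.volume import BrainMask, VolumeGrid


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    return VolumeGrid((10, 10, 8))


@pytest.fixture(scope="session")
def full_mask(small_grid) -> BrainMask:
    return BrainMask.full(small_grid)


@pytest.fixture(scope="session")
def default_design():
    return generate_design(DesignSpec(), seed=7)


@pytest.fixture(scope="session")
def short_design():
    return generate_design(DesignSpec(n_runs=6), seed=7)


SIGNAL_REGION = SignalRegion("blob", center=(4, 4, 3), radius_vox=2.0, system="core-ventral")


def make_subject_betas(
    seed: int,
    grid: VolumeGrid,
    n_runs: int = 11,
    familiarity_amp: float = 0.0,
    identity_amp: float = 0.0,
    view_amp: float = 0.0,
    noise_sd: float = 1.0,
    regions=(SIGNAL_REGION,),
    zscored: bool = True,
):
    """One simulated subject's filtered (8-condition) beta set."""
    design = generate_design(DesignSpec(n_runs=n_runs), seed=seed)
    signal = SignalSpec(
        familiarity_amp=familiarity_amp,
        identity_amp=identity_amp,
        view_amp=view_amp,
        noise_sd=noise_sd,
        smooth_fwhm_vox=1.5,
        regions=regions,
        seed=seed + 10_000,
    )
    betas = generate_betas(design, signal, grid)
    betas = filter_conditions(betas)
    if zscored:
        betas = zscore_within_run(betas)
    return betas


@pytest.fixture(scope="session")
def region_columns(full_mask):
    """In-mask column indices of the planted signal region."""
    from facegeom.volume import make_spherical_roi

    roi = make_spherical_roi(
        "blob", SIGNAL_REGION.center, SIGNAL_REGION.radius_vox * 2.0, "core-ventral", full_mask
    )
    lut = full_mask.column_lookup()
    return lut[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]]
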