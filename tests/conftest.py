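import numpy as np
import pytest

from ductcpr.grid import SegmentationMask, Volume3D
from ductcpr.phantom import PhantomSpec, generate_phantom, preset_study_cohort


def straight_duct_spec(
    length_mm: float = 100.0,
    radius_mm: float = 2.5,
    noise_sd_hu: float = 0.0,
    gaps=(),
    spacing=(1.0, 1.0, 1.0),
    seed: int = 0,
) -> PhantomSpec:
    """Straight duct along x with evenly spaced collinear control points."""
    margin = 6.0
    pad = radius_mm + margin + 2.0
    x = np.linspace(pad, pad + length_mm, 6)
    y = np.full_like(x, pad + radius_mm + margin)
    cp = np.column_stack([x, y, y])
    shape = (
        int(np.ceil((x[-1] + pad) / spacing[0])) + 2,
        int(np.ceil((2 * (radius_mm + margin) + 2 * pad) / spacing[1])) + 2,
        int(np.ceil((2 * (radius_mm + margin) + 2 * pad) / spacing[2])) + 2,
    )
    return PhantomSpec(
        grid_shape=shape,
        spacing_mm=spacing,
        duct_control_points=cp,
        duct_radius_mm=radius_mm,
        pancreas_margin_mm=margin,
        noise_sd_hu=noise_sd_hu,
        gaps=list(gaps),
        seed=seed,
    )


@pytest.fixture(scope="session")
def straight_phantom():
    return generate_phantom(straight_duct_spec())


@pytest.fixture(scope="session")
def curved_phantom():
    """One noise-free, ungapped phantom from the dilated study cohort."""
    spec = preset_study_cohort(1, seed=11, gap_fraction=0.0, noise_sd_hu=0.0)[0]
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def gapped_phantom():
    """Straight 100 mm duct with one 10 mm tumor gap in the middle."""
    spec = straight_duct_spec(gaps=[(45.0, 55.0)])
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Dilated (~5 mm) duct with 10 HU Gaussian noise."""
    spec = straight_duct_spec(radius_mm=2.5, noise_sd_hu=10.0, seed=42)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


def rod_mask(length: int = 50, thickness: int = 3) -> SegmentationMask:
    data = np.zeros((length + 4, thickness + 4, thickness + 4), dtype=bool)
    data[2:2 + length, 2:2 + thickness, 2:2 + thickness] = True
    return SegmentationMask(data, (1.0, 1.0, 1.0))


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> Volume3D:
    return Volume3D(np.asarray(data, dtype=np.float32), spacing)
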