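import numpy as np
import pytest

from texsurv.cohort import PhantomSpec, generate_phantom
from texsurv.imaging_io import CTVolume, LesionMask


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic textured lesion phantom shared across tests."""
    spec = PhantomSpec()
    return generate_phantom(spec, seed=42, patient_id="fixture")


@pytest.fixture()
def tiny_volume_mask():
    """4-slice toy volume with a hand-placed 2-slice mask."""
    rng = np.random.default_rng(0)
    vox = rng.normal(50, 20, size=(4, 16, 16))
    volume = CTVolume(vox, (1.25, 0.7, 0.7), patient_id="tiny")
    mask_arr = np.zeros((4, 16, 16), dtype=bool)
    mask_arr[1, 5:10, 6:11] = True
    mask_arr[2, 4:9, 5:12] = True
    mask = LesionMask(mask_arr, reference="tiny")
    return volume, mask


def blob_slice_and_voi(d_mm: float, spacing: float, size: int = 64, amplitude: float = 100.0):
    """A centred Gaussian blob of 'diameter' d (sigma = d / (2*sqrt(2))) and
    the disk VOI covering it — the scale-selectivity phantom."""
    sig = d_mm / (2.0 * np.sqrt(2.0)) / spacing
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = (size - 1) / 2.0
    img = amplitude * np.exp(-(((yy - c) ** 2 + (xx - c) ** 2) / (2 * sig**2)))
    voi = ((yy - c) ** 2 + (xx - c) ** 2) <= (d_mm / 2.0 / spacing) ** 2
    return img, voi
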