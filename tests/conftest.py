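import numpy as np
import pytest

from invadopipe.image import CalibratedImage
from invadopipe.synthetic import ImageSimParams, PeptideSimParams, generate_peptide_table, generate_rosette_field


@pytest.fixture(scope="session")
def clean_field():
    """Three rosettes, no fibers, low noise: the easy segmentation fixture."""
    params = ImageSimParams(n_rosettes=3, n_fibers=0, noise_sd=2.0, seed=7)
    img, truth = generate_rosette_field(params)
    return img, truth


@pytest.fixture(scope="session")
def field_with_fibers():
    params = ImageSimParams(n_rosettes=3, n_fibers=5, noise_sd=2.0, seed=11)
    img, truth = generate_rosette_field(params)
    return img, truth


@pytest.fixture(scope="session")
def noisefree_peptides():
    params = PeptideSimParams(
        n_proteins=20,
        enriched_subset_fraction=0.25,
        enrichment_factor=3.0,
        contaminant_fraction=0.1,
        abundance_noise_cv=0.0,
        seed=3,
    )
    return generate_peptide_table(params)


def constant_image(value: float = 100.0, shape=(64, 64), pixel_size: float = 1.0) -> CalibratedImage:
    return CalibratedImage(np.full(shape, value, dtype=float), pixel_size)
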