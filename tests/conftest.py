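import numpy as np
import pytest

from apc import synthetic


@pytest.fixture(scope="session")
def model():
    return synthetic.MeniscusModel()


@pytest.fixture(scope="session")
def quiet_model():
    """Noise-free meniscus model for exact-value checks."""
    return synthetic.MeniscusModel(noise_sigma=0.0)


@pytest.fixture(scope="session")
def bertrand_concentric(model):
    truth = synthetic.concentric_truth()
    img, truth = synthetic.generate_bertrand_image(truth, model, seed=11)
    return img, truth


@pytest.fixture(scope="session")
def bertrand_offset(model):
    truth = synthetic.concentric_truth(offset=(30.0, -12.0))
    img, truth = synthetic.generate_bertrand_image(truth, model, seed=12)
    return img, truth


def intensity_centroid(image: np.ndarray, threshold: float) -> tuple[float, float]:
    """Brute-force intensity centroid of pixels above a gray threshold."""
    img = np.asarray(image, dtype=float)
    w = np.where(img > threshold, img, 0.0)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    total = w.sum()
    return (float((xx * w).sum() / total), float((yy * w).sum() / total))
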