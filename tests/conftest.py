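import numpy as np
import pytest

from vertmorph import phantom


@pytest.fixture(scope="session")
def tiny_params():
    """Small, fully deterministic phantom: coarse grid, no noise/blur/jitter."""
    return phantom.PhantomParams(
        pixel_spacing=0.02,
        fov_cm=1.0,
        body_height=0.25,
        blur_sigma=0.0,
        noise_sd=0.0,
        cancellous_texture_sd=0.0,
        subject_size_cv=0.0,
        subject_density_cv=0.0,
        measurement_cv=0.0,
    )


@pytest.fixture(scope="session")
def tiny_noisy_params(tiny_params):
    from dataclasses import replace

    return replace(
        tiny_params,
        blur_sigma=0.6,
        noise_sd=12.0,
        cancellous_texture_sd=25.0,
        subject_size_cv=0.01,
        subject_density_cv=0.03,
        measurement_cv=0.002,
    )


@pytest.fixture(scope="session")
def tiny_design():
    return phantom.StudyDesign(
        n_control=2, n_fasting=2, total_days=4, fast_start_day=0,
        fast_end_day=2, imaging_days=(0, 2, 4),
    )


@pytest.fixture
def random_slice_factory():
    """Factory of sparse random-density slices for moment oracle checks."""

    def make(rng: np.random.Generator, n: int = 40, n_pixels: int = 120):
        n_pixels = min(n_pixels, n * n)
        img = np.zeros((n, n))
        mask = np.zeros((n, n), dtype=bool)
        idx = rng.choice(n * n, size=n_pixels, replace=False)
        rows, cols = np.unravel_index(idx, (n, n))
        mask[rows, cols] = True
        img[rows, cols] = rng.uniform(100.0, 1000.0, n_pixels)
        return img, mask

    return make
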