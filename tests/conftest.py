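import dataclasses

import pytest

from fundusavr.phantom import (FramePhantomSpec, VesselPhantom,
                               default_phantom_spec, default_seed_positions,
                               generate_fundus_frame)


@pytest.fixture(scope="session")
def clean_spec():
    """Default paired phantom with noise and blur switched off."""
    return default_phantom_spec(noise_sd=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def clean_frame(clean_spec):
    return generate_fundus_frame(clean_spec, seed=0)[0]


@pytest.fixture(scope="session")
def default_spec():
    """Default paired phantom at realistic degradation (noise 0.01, blur 0.6)."""
    return default_phantom_spec()


@pytest.fixture(scope="session")
def default_frame(default_spec):
    return generate_fundus_frame(default_spec, seed=0)[0]


@pytest.fixture(scope="session")
def seed_positions(clean_spec):
    return default_seed_positions(clean_spec)


@pytest.fixture(scope="session")
def straight_vessel():
    """Factory for a single straight horizontal-ish vessel phantom."""

    def make(fwhm_px=8.0, contrast=0.25, noise_sd=0.0, blur_sigma=0.0,
             centerline=((150.0, 150.0), (500.0, 350.0)), seed=0):
        spec = FramePhantomSpec(
            vessels=(VesselPhantom(centerline=centerline, fwhm_px=fwhm_px,
                                   contrast=contrast, vclass="venule"),),
            noise_sd=noise_sd, blur_sigma=blur_sigma,
        )
        img, truth = generate_fundus_frame(spec, seed=seed)
        return spec, img, truth

    return make


@pytest.fixture()
def respec():
    """dataclasses.replace shorthand for tweaking frozen specs in tests."""
    return dataclasses.replace
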