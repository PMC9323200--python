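import pytest

from cedphantom import (
    PhotoTruth,
    SegmentationParams,
    get_preset,
)


@pytest.fixture(scope="session")
def cortical():
    return get_preset("cortical")


@pytest.fixture(scope="session")
def thalamic():
    return get_preset("thalamic")


@pytest.fixture(scope="session")
def mtl():
    return get_preset("mtl")


@pytest.fixture
def photo_truth():
    """A mid-size noiseless bolus that fits the default frame."""
    return PhotoTruth(h_true=8.0, w_true=4.0, noise_sd=0.0, seed=7)


@pytest.fixture
def seg_params(photo_truth):
    """Segmentation tuned to the generator's dye/background contrast.

    Threshold just below the agar blue value so the whole dyed rim is
    captured; cut row at the cannula tip.
    """
    return SegmentationParams(
        component="blue",
        threshold=230,
        direction="below",
        cut_row=photo_truth.tip[0],
        scale=photo_truth.scale,
    )
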