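import warnings

import numpy as np
import pytest

from retinograph import synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_tree():
    return syn.generate_vessel_tree(3, 9.0, 0.6, seed=11)


@pytest.fixture(scope="session")
def cohort_with_effects():
    spec = syn.CohortSpec(n_subjects=200, seed=5)
    return syn.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def straight_vessel_image(width_px, noise_sd=0.02, seed=0, height=96, length=220):
    """One horizontal vessel of known width rendered on a small frame."""
    n = 180
    poly = np.column_stack([np.linspace(20, 200, n), np.full(n, height / 2.0)])
    seg = syn.TruthSegment(0, poly, width_px, "artery", -1, 180.0, 180.0)
    tree = syn.VesselTreeTruth(
        [seg], [], {"center": (-100, -100), "a": 30, "b": 28, "rotation_deg": 0},
        (height, length),
    )
    img = syn.rasterize_fundus(tree, noise_sd=noise_sd, seed=seed)
    return img, seg
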