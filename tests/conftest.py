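import numpy as np
import pytest

from condensate_kit import synthetic_data as sd


@pytest.fixture(scope="session")
def four_focus_tracks():
    """A moderate trajectory simulation with four planted foci (shared across tests)."""
    cfg = sd.TrajectorySimConfig(
        n_tracks=1500,
        focus_centers=((3.2, 3.2), (9.6, 3.2), (3.2, 9.6), (9.6, 9.6)),
        seed=11,
    )
    tracks, truth = sd.simulate_trajectories(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def cell_image_with_spots():
    """Cell masks + rendered two-channel image with six planted spots."""
    rng = np.random.default_rng(4)
    masks = sd.make_cell_masks((256, 256), n_cells=10, seed=3)
    labels = np.unique(masks[masks > 0])
    foci = []
    for lab in labels[:6]:
        rr, cc = np.nonzero(masks == lab)
        i = rng.integers(len(rr))
        foci.append(((float(rr[i]), float(cc[i])), 1.5, 60.0))
    truth = sd.SyntheticImageTruth(masks, foci, background_level=100.0, noise_sigma=5.0)
    image = sd.render_cell_image(truth, seed=1, second_channel_corr=0.8)
    return truth, image
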