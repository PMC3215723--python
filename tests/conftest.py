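"""Shared fixtures: small synthetic runs reused across test modules."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import rtattn as r
from rtattn.pipeline import RunConfig, make_run_schedule


@pytest.fixture(scope="session")
def run_schedule():
    """Default continuous run: 200 localizer + 300 feedback scans."""
    return make_run_schedule(RunConfig(seed=7))


@pytest.fixture(scope="session")
def phantom_spec():
    return r.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def bold_run(phantom_spec, run_schedule):
    """One simulated default-condition BOLD run (32x32x16, 500 scans)."""
    return r.simulate_bold(phantom_spec, run_schedule)


@pytest.fixture(scope="session")
def localized(bold_run, run_schedule):
    """Localizer products: t-maps, mask, ROI pair with baselines."""
    from rtattn import roi

    tmap_r, tmap_l, state = r.fit_localizer(bold_run.data, run_schedule,
                                            n_scans=200)
    mask = roi.make_mask(bold_run.data[:200].mean(axis=0))
    pair = roi.select_rois(tmap_r, tmap_l, mask)
    pair = roi.compute_baselines(bold_run.data, run_schedule, pair,
                                 n_scans=200)
    return {"tmap_r": tmap_r, "tmap_l": tmap_l, "mask": mask, "pair": pair,
            "state": state}


@pytest.fixture(scope="session")
def smooth_phantom():
    """Asymmetric smooth 3D image with dark background, for registration
    round-trips (rotation must be identifiable, so no symmetric blob)."""
    shape = (24, 20, 12)
    img = np.zeros(shape)
    for c, a in [((6, 5, 4), 800), ((16, 12, 7), 1000), ((10, 14, 5), 600),
                 ((18, 6, 8), 700)]:
        g = np.zeros(shape)
        g[c] = a
        img += gaussian_filter(g, 2.5) * 120
    return img
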