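import numpy as np
import pytest

import ms2gastrula as m


@pytest.fixture(scope="session")
def small_render():
    """A small noise-free-ish rendered embryo shared by imaging-path tests."""
    geom = m.StripeGeometry(x_extent=40, y_me=20, mse_offset=8, ne_offset=14,
                            spacing=6)
    cfg = m.SimConfig(n_mse=6, n_me=4, n_ne=4, stripe_geometry=geom,
                      n_frames=8, noise_sd=2.0, position_noise_sd=0.1,
                      t_onset=0.5, onset_spread=0.5, t_constriction=0.8,
                      t_invagination=0.9, t_end=1.5,
                      invagination_displacement=2.0, me_descent=1.0, seed=4)
    table, gt = m.simulate_traces(cfg)
    grid = m.render_stack(gt.trajectories, table, cfg)
    return cfg, table, gt, grid


@pytest.fixture(scope="session")
def control_cohort():
    """One control embryo at default (moderate) noise, trace level."""
    cfg = m.preset("control", seed=8)
    table, gt = m.simulate_traces(cfg)
    return cfg, table, gt


def rng(seed=0):
    return np.random.default_rng(seed)
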