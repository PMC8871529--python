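"""Shared fixtures: the desk-scale bench and one trained denoiser.

Training the pix2pix generator dominates the suite's runtime, so it runs
once per session and is shared by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from tomodose.study import make_bench, train_desk_denoiser


@pytest.fixture(scope="session")
def bench():
    """Desk-scale phantom + geometry + noiseless projections (seed 1)."""
    return make_bench(seed=1)


@pytest.fixture(scope="session")
def trained(bench):
    """Generator trained at half dose on the bench, plus its epoch curve."""
    gen, curve = train_desk_denoiser(
        bench, dose_label="reduce50", seed=11, epochs=100, n_pairs=64
    )
    return gen, curve


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
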