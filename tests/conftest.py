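import numpy as np
import pytest

from chainabm.sweep import sweep_contact_random, sweep_ecm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ecm_sweeps():
    """Exhaustive ECM sweeps (both track types): screen every set of the
    default 6400-set grid at 100 replicates, refine the top decile at
    400.  Shared by the sweep-level acceptance checks."""
    return {
        True: sweep_ecm(track=True, screen_reps=100, refine_reps=400,
                        refine_top=0.1, seed=101),
        False: sweep_ecm(track=False, screen_reps=100, refine_reps=400,
                         refine_top=0.1, seed=202),
    }


@pytest.fixture(scope="session")
def contact_sweep():
    """Scaled random Contact sweep: 6000 uniformly sampled parameter sets
    at 100 replicates each."""
    return sweep_contact_random(n_sets=6000, reps=100, seed=303)
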