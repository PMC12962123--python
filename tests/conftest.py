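import numpy as np
import pytest

import facedecode as fd
from facedecode import decoding


@pytest.fixture(scope="session")
def tiny_cfg():
    """A 6-stimulus, 4-block design small enough for per-test decoding."""
    return fd.SimConfig.desk_scale(
        n_stimuli=6,
        n_human=5,
        n_raters_valence=4,
        n_raters_sex=4,
        ratings_per_rater=4,
        n_subjects=2,
        n_channels=8,
        trials_per_sequence=3,
        sequences_per_block=2,
        n_blocks=4,
        epoch_window=(-50.0, 150.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    catalog = fd.make_catalog(tiny_cfg)
    schedule = fd.build_schedule(tiny_cfg)
    epochs, truth = fd.simulate_epochs(catalog, schedule, tiny_cfg, subject_seed=99)
    return {"cfg": tiny_cfg, "catalog": catalog, "schedule": schedule, "epochs": epochs, "truth": truth}


@pytest.fixture(scope="session")
def tiny_null_epochs(tiny_cfg):
    from facedecode.synth import null_config

    cfg = null_config(tiny_cfg)
    catalog = fd.make_catalog(cfg)
    schedule = fd.build_schedule(cfg)
    epochs, _ = fd.simulate_epochs(catalog, schedule, cfg, subject_seed=3)
    return epochs


@pytest.fixture(scope="session")
def tiny_pairwise(tiny_world):
    return decoding.pairwise_image_decoding(tiny_world["epochs"], store_pairs=True)
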