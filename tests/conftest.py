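import numpy as np
import pytest

import stressnet as sn
from stressnet.roi_sequences import _apply_stats, channel_stats
from stressnet.train_eval import TrainConfig, split_dataset, train

# desk-scale study conditions: reduced full model on default synthetic data
DESK = dict(n_per_class=24, T=6, H=32, W=32, hidden=32, lr=1e-3, epochs=30,
            data_seed=11, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_archive():
    """Small separable synthetic archive for pipeline tests."""
    return sn.generate_dataset(6, T=3, H=16, W=16, seed=5)


@pytest.fixture(scope="session")
def desk_run():
    """Full-variant model trained under the desk-scale study conditions
    (32x32 frames, 6 dates, 24 sequences/class, hidden 32), shared by the
    tests that need a genuinely trained classifier."""
    archive = sn.generate_dataset(DESK["n_per_class"], T=DESK["T"],
                                  H=DESK["H"], W=DESK["W"],
                                  seed=DESK["data_seed"])
    tr, va = split_dataset(archive, 0.8, seed=DESK["seed"])
    model = sn.StressNet(backbone="compact", hidden_size=DESK["hidden"],
                         variant="full", seed=DESK["seed"])
    cfg = TrainConfig(batch_size=16, learning_rate=DESK["lr"],
                      epochs=DESK["epochs"], seed=DESK["seed"])
    model, history = train(model, tr, va, cfg)
    stats = channel_stats(np.asarray(tr["sequences"], dtype=np.float64),
                          cfg.normalization)
    x_val = _apply_stats(np.asarray(va["sequences"], dtype=np.float64), stats)
    return {"model": model, "history": history, "train": tr, "val": va,
            "x_val": x_val, "config": cfg}
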