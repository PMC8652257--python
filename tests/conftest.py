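import numpy as np
import pytest

from modcaps import (
    TrainConfig,
    generate_modular,
    heatmap_for_model,
    planted_importance_config,
    train_repeats,
)

# Shared desk-scale settings for the planted-signal recovery experiment:
# 5 classes x 10 sources (2 informative per class), 2000 samples, 9 repeats.
PLANTED_SEED = 20240101
PLANTED_EPOCHS = 30


@pytest.fixture(scope="session")
def planted_experiment():
    """Train 9 repeats on the planted-importance fixture once per session.

    Returns (dataset, ground truth, runs, per-repeat overall heatmaps).
    """
    cfg = planted_importance_config(seed=PLANTED_SEED)
    dataset, truth = generate_modular(cfg)
    tcfg = TrainConfig(epochs=PLANTED_EPOCHS, seed=PLANTED_SEED, repeats=9)
    runs = train_repeats(dataset, tcfg)
    heatmaps = [heatmap_for_model(model, dataset) for model, _ in runs]
    return dataset, truth, runs, heatmaps


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
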