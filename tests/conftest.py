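import numpy as np
import pytest

from orbweaver import (
    ModelConfig,
    OrbWeaverNet,
    SimulationConfig,
    build_filter_bank,
    simulate_caqtl_panel,
    simulate_dataset,
    simulate_pwms,
    split_dataset,
)
from orbweaver.model import train


@pytest.fixture(scope="session")
def small_sim():
    """A small motif-planted benchmark: 7 TFs, 150 loci per category."""
    cfg = SimulationConfig(loci_per_category=250, seed=3)
    pwms = simulate_pwms(cfg)
    dataset = simulate_dataset(cfg, pwms)
    bank = build_filter_bank(pwms)
    return {"config": cfg, "pwms": pwms, "dataset": dataset, "bank": bank}


@pytest.fixture(scope="session")
def small_net(small_sim):
    """A quickly trained network over the small benchmark (for mechanism
    tests; accuracy-level checks use the full-scale fixture)."""
    net = OrbWeaverNet(small_sim["bank"], ModelConfig(seed=1, epochs=12))
    train_set, test_set = split_dataset(small_sim["dataset"].loci, 0.2, 1)
    train(net, train_set)
    return {"net": net, "train": train_set, "test": test_set, **small_sim}


@pytest.fixture(scope="session")
def full_run():
    """Full-scale end-to-end run: ~14,000 training / 2,000 held-out loci,
    plus a 200 caQTL + 200 decoy panel scored with the trained model."""
    cfg = SimulationConfig(loci_per_category=2285, seed=3)
    pwms = simulate_pwms(cfg)
    dataset = simulate_dataset(cfg, pwms)
    bank = build_filter_bank(pwms)
    net = OrbWeaverNet(bank, ModelConfig(seed=1, epochs=12))
    train_set, test_set = split_dataset(dataset.loci, 2000 / len(dataset.loci), 1)
    train(net, train_set)
    panel = simulate_caqtl_panel(cfg, pwms)
    return {
        "config": cfg,
        "pwms": pwms,
        "dataset": dataset,
        "bank": bank,
        "net": net,
        "train": train_set,
        "test": test_set,
        "panel": panel,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
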