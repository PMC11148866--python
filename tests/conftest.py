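import numpy as np
import pytest

from monoseize import (
    ChannelSubsetPolicy,
    ModelConfig,
    RunConfig,
    SynthConfig,
    build_model,
    generate_case,
    run_case,
    train_model,
)
from monoseize.preprocess import SegmentSet


def make_separable_segments(n_per_class: int = 200, n_channels: int = 1,
                            seed: int = 0) -> SegmentSet:
    """High-amplitude 5 Hz bursts vs low-amplitude noise: trivially
    separable by amplitude, used to exercise the training loop."""
    rng = np.random.default_rng(seed)
    t = np.arange(1024) / 256.0
    burst = 50.0 * np.sin(2 * np.pi * 5.0 * t)
    ictal = burst[None, None, :] + rng.normal(0, 5, (n_per_class, n_channels, 1024))
    inter = rng.normal(0, 5, (n_per_class, n_channels, 1024))
    windows = np.concatenate([ictal, inter]).astype(np.float32)
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return SegmentSet(
        windows=windows,
        labels=labels,
        window_starts=np.arange(2 * n_per_class) * 4.0,
        source_ids=np.array(["sep"] * (2 * n_per_class), dtype=object),
        fs=256.0,
    )


def small_model_config(**overrides) -> ModelConfig:
    defaults = dict(max_epochs=8, early_stop_patience=3, epoch_batches=20,
                    batch_size=16, seed=0)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def separable_segments() -> SegmentSet:
    return make_separable_segments()


@pytest.fixture(scope="session")
def trained_toy_model(separable_segments):
    """A quick model trained to separate the toy classes; reused by
    inference-side tests."""
    segs = separable_segments
    idx = np.arange(len(segs))
    train = segs.subset(np.r_[idx[:150], idx[200:350]])
    val = segs.subset(np.r_[idx[150:175], idx[350:375]])
    cfg = small_model_config(max_epochs=5)
    model = build_model(cfg, 1)
    return train_model(model, train, val, cfg)


# ---------------------------------------------------------------------------
# Shared end-to-end runs on the standard synthetic case (0.25-h files,
# 2 of 4 files with seizures).  Session-scoped: several acceptance checks
# read different aspects of the same runs.
# ---------------------------------------------------------------------------

E2E_SEEDS = (101, 102, 103, 104, 105)
MISMATCHED_CHANNEL = "Fp1-F3"  # shares no electrode with the default P8-O2


def _e2e_run_config(seed: int) -> RunConfig:
    return RunConfig(
        model=ModelConfig(max_epochs=10, early_stop_patience=3,
                          epoch_batches=30, batch_size=16, seed=seed),
        seed=seed,
    )


@pytest.fixture(scope="session")
def e2e_case_results():
    """run_case on 5 seeded synthetic cases with the ground-truth single
    channel and a mismatched one; returns {seed: {"gt": ..., "mis": ...}}."""
    out = {}
    for seed in E2E_SEEDS:
        case = generate_case(SynthConfig(seed=seed))
        files = list(zip(case.recordings, case.annotations))
        cfg = _e2e_run_config(seed)
        gt = run_case(
            files, ChannelSubsetPolicy("single", case.ground_truth_channel), cfg
        )
        mis = run_case(
            files, ChannelSubsetPolicy("single", MISMATCHED_CHANNEL), cfg
        )
        out[seed] = {"gt": gt, "mis": mis, "case": case}
    return out
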