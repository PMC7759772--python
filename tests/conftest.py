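import numpy as np
import pytest

import surgmon as sm


@pytest.fixture(scope="session")
def tiny_config():
    """Small, low-resolution phantom configuration for fast unit tests."""
    return sm.PhantomConfig(n_videos=4, frames_per_video=30,
                            cls_resolution=(160, 90), seg_resolution=(64, 32),
                            problem_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def tiny_videos(tiny_config):
    return [sm.generate_video(tiny_config, i) for i in range(tiny_config.n_videos)]


@pytest.fixture(scope="session")
def tiny_dataset_dir(tiny_videos, tmp_path_factory):
    out = tmp_path_factory.mktemp("phantom_ds")
    manifest = sm.write_dataset(tiny_videos, out,
                                splits={"train": [0, 1], "val": [2], "test": [3]})
    return manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom20(tmp_path_factory):
    """The 20-video phantom study set (120 s per video at 1 FPS)."""
    cfg = sm.PhantomConfig(seed=7)
    seqs = sm.generate_dataset(cfg)
    out = tmp_path_factory.mktemp("phantom20")
    return sm.write_dataset(seqs, out)


@pytest.fixture(scope="session")
def trained_phase_small(phantom20, tmp_path_factory):
    cfg = sm.TrainConfig.for_task("phase", small=True, max_epochs=10, seed=0,
                                  target_metric=0.9)
    return sm.train(phantom20, cfg, tmp_path_factory.mktemp("run_phase"))


@pytest.fixture(scope="session")
def trained_problem_small(phantom20, tmp_path_factory):
    cfg = sm.TrainConfig.for_task("problem", small=True, max_epochs=10, seed=0,
                                  target_metric=0.9)
    return sm.train(phantom20, cfg, tmp_path_factory.mktemp("run_problem"))


@pytest.fixture(scope="session")
def trained_seg_small(phantom20, tmp_path_factory):
    cfg = sm.TrainConfig.for_task("segmentation", small=True, max_epochs=10,
                                  seed=0, target_metric=0.8)
    return sm.train(phantom20, cfg, tmp_path_factory.mktemp("run_seg"))
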