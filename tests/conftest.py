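"""Shared fixtures: deterministic RNGs and session-scoped simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ivscan.pipeline import DetectionParams, detect_files
from ivscan.synthetic import (GeneratorConfig, default_segment_ids, read_truth,
                              simulate_dataset)

SMALL_CENSUS = {"hypothetical": 6}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small parasitized dataset: 2x50 kb host, 6 segments, 6 events."""
    cfg = GeneratorConfig(seed=7, n_host_chroms=2, host_chrom_bp=50_000,
                          n_segments=6, segment_len_range=(1500, 3000),
                          sites_per_segment=2, coverage=30, error_rate=0.0)
    out = tmp_path_factory.mktemp("small_sim")
    paths = simulate_dataset(cfg, out, census=SMALL_CENSUS)
    return cfg, paths


@pytest.fixture(scope="session")
def small_detect(small_sim):
    cfg, paths = small_sim
    result = detect_files(paths["host"], paths["viral"],
                          r1=paths["r1"], r2=paths["r2"])
    return cfg, paths, result


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The survey-scale dataset: 5x200 kb host, 62 segments, three integrated
    segments with one of them at five host sites, 30x, error-free reads."""
    cfg = GeneratorConfig(seed=1, error_rate=0.0,
                          integrated_segment_ids=("D22", "E3", "F2"),
                          sites_per_segment={"D22": 1, "E3": 1, "F2": 5})
    out = tmp_path_factory.mktemp("default_sim")
    paths = simulate_dataset(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def default_detect(default_sim):
    cfg, paths = default_sim
    result = detect_files(paths["host"], paths["viral"],
                          r1=paths["r1"], r2=paths["r2"])
    return cfg, paths, read_truth(paths["truth"]), result


@pytest.fixture(scope="session")
def many_events_sim(tmp_path_factory):
    """Over 200 integration events (41 segments x 5 sites), error-free."""
    cfg = GeneratorConfig(seed=1, error_rate=0.0,
                          integrated_segment_ids=tuple(default_segment_ids(62)[:41]),
                          sites_per_segment=5)
    out = tmp_path_factory.mktemp("many_events")
    paths = simulate_dataset(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def many_events_detect(many_events_sim):
    cfg, paths = many_events_sim
    result = detect_files(paths["host"], paths["viral"],
                          r1=paths["r1"], r2=paths["r2"])
    return cfg, paths, read_truth(paths["truth"]), result
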