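"""Shared fixtures: small raw-CSV fixtures and pre-computed simulation runs."""

from __future__ import annotations

import numpy as np
import pytest

import facesync as fs


@pytest.fixture(scope="session")
def raw_fixture_dir(tmp_path_factory):
    """Small raw Trace-dialect CSV fixture (3 subjects, 30 s, 20% drops)."""
    out = tmp_path_factory.mktemp("rawcsv")
    fs.simulate_raw_trace_csv(
        n_subjects=3, duration=30.0, mean_rate=5.0, drop_fraction=0.2,
        seed=11, out_path=out,
    )
    return out


@pytest.fixture(scope="session")
def processed_set(raw_fixture_dir):
    """Fully preprocessed recording set from the raw fixture."""
    raws = fs.read_trace_folder(raw_fixture_dir)
    cfg = fs.PreprocConfig(target_rate=5.0)
    return fs.preprocess_group(raws, cfg)


@pytest.fixture(scope="session")
def landmark_sim():
    """One run of the simulated landmark synchrony study (seed 0)."""
    return fs.simulate_landmark_study(fs.CorrcaSimSpec(seed=0))


@pytest.fixture(scope="session")
def landmark_features(landmark_sim):
    """Vector-norm scalarised feature tensor from the landmark simulation."""
    data, truth = landmark_sim
    centred = data - data.mean(axis=3, keepdims=True)
    feats = np.linalg.norm(centred, axis=2)  # (N, 68, T)
    return fs.FeatureMatrix(
        data=feats,
        feature_labels=list(range(1, 69)),
        subject_ids=list(range(1, feats.shape[0] + 1)),
        rate=5.0,
        mode="vector_norm",
    )


@pytest.fixture(scope="session")
def landmark_fit(landmark_features):
    """CorrCA fit (3 components) of the landmark-simulation features."""
    return fs.corrca_fit(
        landmark_features, fs.CorrCAConfig(gamma=0.1, n_components=3)
    )


@pytest.fixture(scope="session")
def susy_sim_result():
    """One run of the simulated head-movement study with SUSY applied."""
    X, truth = fs.simulate_head_movement_study(fs.SusySimSpec(seed=0))
    cfg = fs.SusyConfig(
        segment_seconds=5.0, maxlag_seconds=0.0, rate=1.0,
        n_surrogates=50, seed=0,
    )
    return fs.susy_group(X, "", cfg), truth
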