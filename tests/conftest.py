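from dataclasses import replace

import numpy as np
import pytest

from swaylab.preprocess import StabilogramPreprocessor, design_lowpass
from swaylab.recording import StabilogramRecording, SubjectMeta


@pytest.fixture(scope="session")
def filter_design():
    return design_lowpass(50.0)


@pytest.fixture(scope="session")
def preprocessor():
    probe = StabilogramRecording(fs=50.0, cpf_x=np.zeros(2), cpf_y=np.zeros(2))
    return StabilogramPreprocessor().fit(probe)


@pytest.fixture(scope="session")
def cohort_features(preprocessor):
    """Feature table of a scaled-down synthetic cohort calibrated to the
    published per-sex, per-age-group means (24 subjects per group, eyes
    closed). Shared by the directional-fidelity and classification tests."""
    from swaylab.features import SwayFeatureExtractor
    from swaylab.simulate import generate_cohort, load_table2_spec

    spec = load_table2_spec()
    spec.groups = [replace(g, n=24) for g in spec.groups]
    recs, meta = generate_cohort(
        spec,
        master_seed=2026,
        calibrate=True,
        calib_kwargs={"n_replicates": 8, "max_iter": 6},
        conditions=("eyes_closed",),
    )
    df = SwayFeatureExtractor().transform(preprocessor.transform(recs))
    df["age_group"] = meta["age_group"].to_numpy()
    return df


def make_recording(
    cpf_x=None,
    cpf_y=None,
    moment_x=None,
    moment_y=None,
    weight=None,
    fs=50.0,
    n=1500,
    mass=70.0,
    sex="female",
    preprocessed=False,
):
    """Build a recording from arrays, filling absent channels with zeros."""
    if cpf_x is None:
        cpf_x = np.zeros(n)
    n = len(cpf_x)
    if cpf_y is None:
        cpf_y = np.zeros(n)
    meta = SubjectMeta(subject_id="t", sex=sex, age=72, mass=mass)
    return StabilogramRecording(
        fs=fs,
        cpf_x=cpf_x,
        cpf_y=cpf_y,
        moment_x=np.zeros(n) if moment_x is None else moment_x,
        moment_y=np.zeros(n) if moment_y is None else moment_y,
        weight=np.full(n, mass * 9.81) if weight is None else weight,
        meta=meta,
        preprocessed=preprocessed,
    )
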