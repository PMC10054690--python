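import numpy as np
import pytest

import readerstudy as rs


@pytest.fixture(scope="session")
def fixture_study():
    """One deterministic synthetic study with the emulated design."""
    return rs.adhesion_study_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_scores(fixture_study):
    """Session-1 score matrix of the fixture study."""
    return rs.slice_scores(
        fixture_study.annotations,
        fixture_study.slices,
        fixture_study.observers,
        session=1,
    )


@pytest.fixture(scope="session")
def fixture_labels(fixture_study, fixture_scores):
    profiles = {p.observer_id: p for p in fixture_study.profiles}
    return rs.binarize_scores(fixture_scores, profiles)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def homogeneous_config(
    n_obs=15,
    discrimination=1.0,
    noise_sd=1.0,
    threshold=40,
    seed=0,
    n_patients=10,
    fixed_layout=True,
    slices_per_patient=(5, 7),
):
    """A study of identical (exchangeable) readers, study-sized by default."""
    specs = tuple(
        rs.ObserverSpec(
            observer_id=f"r{i:02d}",
            years_experience=5,
            cine_cases=30,
            adhesion_cases=5,
            clinical_threshold_pct=threshold,
            discrimination=discrimination,
            noise_sd=noise_sd,
        )
        for i in range(n_obs)
    )
    kwargs = dict(observer_specs=specs, seed=seed, n_patients=n_patients)
    if fixed_layout:
        kwargs.update(
            n_patients=10,
            slice_layout=(6,) * 9 + (7,),
            positive_layout=(4, 3, 3, 3, 2, 2, 2, 0, 0, 0),
        )
    else:
        kwargs.update(slices_per_patient=slices_per_patient)
    return rs.SimulationConfig(**kwargs)


def binarized_study_labels(config):
    """Simulate a study and return its binarized session-1 label array."""
    study = rs.simulate_study(config)
    scores = rs.slice_scores(
        study.annotations, study.slices, study.observers, session=1
    )
    profiles = {p.observer_id: p for p in study.profiles}
    return rs.binarize_scores(scores, profiles).values()
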