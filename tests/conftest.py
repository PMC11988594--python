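import numpy as np
import pytest

from kelptrace import (Cnn1DClassifier, CohortConfig, SplitSpec,
                       apply_scaler, evaluate, fit_scaler, generate_cohort,
                       load_reference_table, screen_features,
                       stratified_split)


@pytest.fixture(scope="session")
def ref_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def seed1_cohort(ref_table):
    return generate_cohort(ref_table, CohortConfig(seed=1))


@pytest.fixture(scope="session")
def seed1_run(ref_table, seed1_cohort):
    """One full seed-1 experiment, shared across tests.

    Stage seeds follow the pipeline convention (cohort=seed, split=seed+1,
    train=seed+2).
    """
    report, reduced = screen_features(seed1_cohort, alpha=0.05)
    train, test = stratified_split(reduced, SplitSpec(seed=2))
    scaler = fit_scaler(train)
    Xtr = apply_scaler(scaler, train)
    Xte = apply_scaler(scaler, test)
    clf = Cnn1DClassifier(random_state=3).fit(Xtr, train.labels)
    ev = evaluate(test.labels, clf.predict_proba(Xte))
    return {
        "report": report, "reduced": reduced, "train": train, "test": test,
        "scaler": scaler, "Xtr": Xtr, "Xte": Xte, "clf": clf, "eval": ev,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
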