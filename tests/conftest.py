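"""Shared fixtures: one small simulated cohort reused across the suite."""

import pandas as pd
import pytest

from storkmig import behaviour, segmentation
from storkmig.synthetic import SimConfig, simulate_cohort, simulate_labelled_bursts


@pytest.fixture(scope="session")
def cohort():
    """Small cohort (6 birds) with acceleration and weather, fixed seed."""
    cfg = SimConfig(seed=11, n_adults=2, n_juveniles=4)
    tracks, accel, grid, truth = simulate_cohort(cfg)
    return {"cfg": cfg, "tracks": tracks, "accel": accel, "grid": grid, "truth": truth}


@pytest.fixture(scope="session")
def segmented(cohort):
    events, daily = segmentation.segment_cohort(cohort["tracks"])
    return {"events": events, "daily": daily}


@pytest.fixture(scope="session")
def classifiers(cohort):
    """Per-logger random forests trained on labelled synthetic bursts."""
    out = {}
    for lt in cohort["cfg"].logger_types:
        bursts, labels = simulate_labelled_bursts(250, lt, seed=5, config=cohort["cfg"])
        feats = pd.DataFrame(
            [behaviour.extract_burst_features(b) for b in bursts],
            columns=behaviour.FEATURE_NAMES)
        clf, _ = behaviour.train_behaviour_classifier(feats, labels, lt, seed=5)
        out[lt] = clf
    return out


@pytest.fixture(scope="session")
def classified(cohort, classifiers):
    return behaviour.classify_fixes(cohort["tracks"], cohort["accel"], classifiers)
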