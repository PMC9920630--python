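import numpy as np
import pytest

import edaffect as ea


@pytest.fixture(scope="session")
def small_corpus_table():
    """A small labeled feature table from generator segments.

    10 segments per quadrant of 60 s at the 8 Hz native rate, default
    profiles — large enough for stratified 5-fold CV, small enough for
    fast model tests.
    """
    profiles = ea.default_profiles()
    segments = []
    seed = 100
    for quad in ea.QUADRANT_ORDER:
        for i in range(10):
            session, _ = ea.generate_segment(profiles[quad], duration=60.0, rate=8.0, seed=seed)
            seed += 1
            segments.append(
                ea.LabeledSegment(label=quad, session=session, source_session=f"fix{seed}", song_index=i)
            )
    return ea.build_feature_table(segments)


@pytest.fixture(scope="session")
def small_normalized_table(small_corpus_table):
    return ea.normalize(small_corpus_table)


@pytest.fixture
def constant_session():
    """A 60 s, 8 Hz session with perfectly constant resistance."""
    n = 480
    t = np.arange(n) * 125.0
    r = np.full(n, 500000.0)
    return ea.RawSession(t, r, session_id="const", nominal_rate=8.0)


def make_signal(values, rate=2.0):
    return ea.EDASignal(np.asarray(values, dtype=float), rate=rate)
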