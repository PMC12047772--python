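"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tachometry import (
    BehaviorModelParams,
    DesignSpec,
    TrialTable,
    apply_exclusions,
    generate_design,
    simulate_experiment,
)


def loess_oracle(x, y, span, degree, weights=None):
    """Brute-force tricube weighted least squares, one lstsq per point.

    Deliberately independent of the package's batched implementation:
    k-nearest-neighbour windows via a stable sort on (distance, index),
    explicit Vandermonde design, numpy lstsq.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = int(np.ceil(span * n))
    out = np.empty(n)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        idx = np.lexsort((np.arange(n), d))[:k]
        dmax = d[idx].max()
        if dmax == 0:
            dmax = 1.0
        u = (x[idx] - x0) / dmax
        w = (1 - np.abs(u) ** 3) ** 3
        if weights is not None:
            w = w * np.asarray(weights, float)[idx]
        sw = np.sqrt(w)
        X = np.vander(u, degree + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def make_trials(
    rpt,
    correct,
    congruency=None,
    participant=None,
    experiment="spatial_stroop",
):
    """Build a minimal analyzable TrialTable from rPT/correctness vectors.

    Gap is fixed at 0 so rt_ms == rpt_ms; response/correct sides are wired
    so the derived ``correct`` column equals the requested one.
    """
    rpt = np.asarray(rpt, dtype=int)
    n = len(rpt)
    correct = np.asarray(correct, dtype=bool)
    if congruency is None:
        congruency = np.where(np.arange(n) % 2 == 0, "congruent", "incongruent")
    else:
        congruency = np.asarray(congruency, dtype=object)
    if participant is None:
        participant = np.full(n, "P01", dtype=object)
    df = pd.DataFrame({
        "participant_id": participant,
        "experiment": experiment,
        "session": 1,
        "block": 1,
        "trial_index": np.arange(1, n + 1),
        "is_practice": False,
        "fixation_ms": 400,
        "gap_ms": 0,
        "congruency": congruency,
        "stim_desc": "synthetic",
        "correct_side": "left",
        "response_side": np.where(correct, "left", "right"),
        "rt_ms": rpt,
    })
    return TrialTable(df)


@pytest.fixture(scope="session")
def default_params():
    return BehaviorModelParams()


@pytest.fixture(scope="session")
def small_experiment(default_params):
    """One participant, one session (1188 main trials), default model."""
    spec = DesignSpec(task="spatial_stroop", n_participants=1, n_sessions=1,
                      seed=101)
    table = simulate_experiment(generate_design(spec), default_params, seed=102)
    analyzed, report = apply_exclusions(table)
    return analyzed, report


@pytest.fixture(scope="session")
def full_experiment(default_params):
    """Five participants at full scale (5 x 5940 trials), default model."""
    spec = DesignSpec(task="spatial_stroop", n_participants=5, seed=7)
    table = simulate_experiment(generate_design(spec), default_params, seed=11)
    analyzed, _ = apply_exclusions(table)
    return analyzed
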