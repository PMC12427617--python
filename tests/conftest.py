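"""Shared fixtures: tiny hand-written corpora and truth-table builders."""

from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lingdist as ld

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture()
def tiny_corpus_files(tmp_path):
    """Two clients, three assessments each over six weeks, a few messages."""
    messages = pd.DataFrame(
        {
            "message_id": [f"m{i}" for i in range(8)],
            "client_id": ["cA"] * 4 + ["cB"] * 4,
            "therapist_id": ["t1"] * 4 + ["t2"] * 4,
            "author_role": ["client", "client", "therapist", "client"] * 2,
            "timestamp": ["2020-01-01", "2020-01-10", "2020-01-25",
                          "2020-02-10"] * 2,
            "text": ["I am here", "We slept and they played", "How are you",
                     "She walked home"] * 2,
        }
    )
    assessments = pd.DataFrame(
        {
            "client_id": ["cA"] * 3 + ["cB"] * 3,
            "date": ["2020-01-22", "2020-02-12", "2020-03-04"] * 2,
            "phq8": [10, 8, 6, 20, 18, 12],
            "gad7": [7, 6, 5, 15, 14, 10],
        }
    )
    mpath = tmp_path / "messages.csv"
    apath = tmp_path / "assessments.csv"
    messages.to_csv(mpath, index=False)
    assessments.to_csv(apath, index=False)
    return mpath, apath


@pytest.fixture(scope="session")
def small_corpus():
    """One modest synthetic corpus with its truth, reused across tests."""
    params = ld.SimParams(n_clients=40, messages_per_window=6,
                          messages_per_window_therapist=4, seed=11)
    corpus, truth = ld.generate_corpus(params)
    return params, corpus, truth


def truth_table(truth, score_col="d_ik"):
    """Regression table taken directly from the latent truth windows."""
    w = truth.windows
    return pd.DataFrame(
        {
            "client_id": w["client_id"],
            "window_index": w["window_index"],
            "time": w["tau"],
            "internalizing": w["internalizing"],
            "score": w[score_col],
        }
    )


def make_truth_params(**overrides):
    """Continuous-outcome settings used by the estimator studies."""
    base = dict(
        n_clients=200, messages_per_window=1, messages_per_window_therapist=1,
        assessments_per_client=4, mu_d=0.3, sigma_between=0.08,
        sigma_within=0.1, gamma_time=0.3, beta_within=-5.0,
        beta_between=-12.0, c_prime=-1.5, beta0=20.0, sigma_intercept=4.0,
        sigma_symptom=3.0, jitter_days=0, round_symptoms=False, seed=0,
    )
    base.update(overrides)
    return ld.SimParams(**base)


def boundary_examples():
    """The six bundled floor/ceiling worked-example messages."""
    payload = json.loads(
        resources.files("lingdist.data")
        .joinpath("boundary_examples.json")
        .read_text(encoding="utf-8")
    )
    return payload["examples"]
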