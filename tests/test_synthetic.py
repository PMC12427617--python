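"""Generator: determinism, degenerate cases, oracle recovery, fractions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lingdist as ld
from lingdist.corpus import apply_inclusion_rule

from conftest import make_truth_params


def test_identical_seed_identical_corpus():
    p = ld.SimParams(n_clients=15, messages_per_window=4,
                     messages_per_window_therapist=3, seed=5)
    c1, t1 = ld.generate_corpus(p)
    c2, t2 = ld.generate_corpus(p)
    assert c1.messages.to_csv(index=False) == c2.messages.to_csv(index=False)
    assert c1.assessments.to_csv(index=False) == \
        c2.assessments.to_csv(index=False)
    assert t1.windows.to_csv(index=False) == t2.windows.to_csv(index=False)

    c3, _ = ld.generate_corpus(dataclasses.replace(p, seed=6))
    assert c3.messages.to_csv(index=False) != c1.messages.to_csv(index=False)


def test_degenerate_variance_gives_constant_windows():
    p = ld.SimParams(n_clients=5, sigma_within=0.0, gamma_time=0.0,
                     messages_per_window=2, messages_per_window_therapist=1,
                     seed=1)
    _, truth = ld.generate_corpus(p)
    per_client = truth.windows.groupby("client_id")["d_ik"].nunique()
    assert (per_client == 1).all()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ld.SimParams(n_clients=0)
    with pytest.raises(ValueError):
        ld.SimParams(p_no_verbs=0.7, p_no_pronouns=0.6)
    with pytest.raises(ValueError):
        ld.SimParams(sigma_between=-0.1)
    with pytest.raises(ValueError):
        ld.SimParams(assessments_per_client=2)
    with pytest.raises(ValueError):
        ld.SimParams(jitter_days=11, assessment_spacing_days=21)


def test_all_generated_clients_pass_inclusion():
    p = ld.SimParams(n_clients=30, assessments_per_client=3,
                     messages_per_window=2, messages_per_window_therapist=1,
                     jitter_days=3, seed=9)
    corpus, _ = ld.generate_corpus(p)
    _, excluded = apply_inclusion_rule(corpus.assessments)
    assert excluded == []
    assert (corpus.assessments["phq8"].between(0, 24)).all()
    assert (corpus.assessments["gad7"].between(0, 21)).all()


def test_ols_oracle_recovers_generating_coefficients():
    """OLS of simulated symptoms on the true within/between components
    recovers beta_within and beta_between (independent oracle)."""
    # sigma_symptom chosen so the OLS standard error (~0.013) makes the
    # 0.06 band a >4-SE check rather than a coin flip
    p = make_truth_params(n_clients=500, beta_within=-0.4, beta_between=-0.4,
                          sigma_symptom=0.05, sigma_intercept=0.0,
                          c_prime=0.0, gamma_time=0.0, beta0=1.0, seed=21)
    _, truth = ld.generate_corpus(p)
    w = truth.windows
    d_i = w.groupby("client_id")["d_ik"].transform("mean")
    within = (w["d_ik"] - d_i).to_numpy()
    between = (d_i - d_i.mean()).to_numpy()
    X = np.column_stack([np.ones(len(w)), within, between])
    coef, *_ = np.linalg.lstsq(X, w["symptom_continuous"].to_numpy(),
                               rcond=None)
    assert coef[1] == pytest.approx(-0.4, abs=0.06)
    assert coef[2] == pytest.approx(-0.4, abs=0.06)


def test_undefined_fractions_match_parameters():
    rng = np.random.default_rng(2)
    n = 6000
    texts = [ld.generate_message_text(0.5, rng) for _ in range(n)]
    verb_free = np.mean([ld.tag_tokens(t).past + ld.tag_tokens(t).present
                         + ld.tag_tokens(t).future == 0 for t in texts])
    from lingdist.wordcount import PERSONAL_CATEGORIES, tag_tokens
    pron_free = np.mean([
        sum(getattr(tag_tokens(t), c) for c in PERSONAL_CATEGORIES) == 0
        for t in texts])
    # ~3 binomial SDs around the generating fractions
    assert verb_free == pytest.approx(0.071, abs=0.010)
    assert pron_free == pytest.approx(0.094, abs=0.012)


def test_mean_wordcount_tracks_latent():
    rng = np.random.default_rng(3)
    scores = []
    for _ in range(10_000):
        v = ld.wc_self_distance(ld.generate_message_text(0.5, rng, 0.0, 0.0))
        scores.append(v)
    assert np.mean(scores) == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize(
    "a,b,c,expected",
    [
        (0.5, -0.4, -0.1, 200.0 / 3.0),  # (-0.2)/(-0.3) x 100
        (0.5, -0.4, 0.0, 100.0),
        (0.5, 0.0, -0.1, 0.0),
    ],
)
def test_theoretical_effects(a, b, c, expected):
    p = ld.SimParams(gamma_time=a, beta_within=b, c_prime=c)
    out = ld.theoretical_effects(p)
    assert out["proportion_mediated"] == pytest.approx(expected)
    assert out["proportion_mediated_defined"]


def test_theoretical_effects_flags_undefined_denominator():
    p = ld.SimParams(gamma_time=0.5, beta_within=-0.4, c_prime=0.2)
    out = ld.theoretical_effects(p)
    assert not out["proportion_mediated_defined"]
    assert np.isnan(out["proportion_mediated"])


def test_clip_rates_reported(small_corpus):
    _, _, truth = small_corpus
    assert 0.0 <= truth.clip_rate_latent <= 1.0
    assert 0.0 <= truth.clip_rate_symptom <= 1.0


def test_poisson_message_counts():
    p = ld.SimParams(n_clients=20, messages_per_window=5,
                     messages_per_window_therapist=2, poisson_messages=True,
                     seed=4)
    corpus, _ = ld.generate_corpus(p)
    counts = corpus.messages[corpus.messages.author_role == "client"] \
        .groupby("client_id").size()
    assert counts.var() > 0  # fixed counts would all be equal
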