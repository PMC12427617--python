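"""Prompted-LLM scoring: expected-score formula, prompts, mock backend."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import lingdist as ld
from lingdist.llm import LABELS, MESSAGE_PLACEHOLDER, expected_score


@pytest.mark.parametrize(
    "logits,expected",
    [
        ([0, 0, 0, 0, 0], 3.0),                      # uniform
        ([7, 7, 7, 7, 7], 3.0),                      # uniform, shifted
        ([50, 0, 0, 0, 0], 1.0),                     # one-hot limit at A
        ([0, 0, 0, 0, 50], 5.0),                     # one-hot limit at E
        ([math.log(1), math.log(2), math.log(3), math.log(2), math.log(1)],
         3.0),                                       # weights (1,2,3,2,1)/9
        ([0.0, 0.0, 0.0, 0.0, math.log(6)], 4.0),    # weights (.1,.1,.1,.1,.6)
    ],
)
def test_expected_score_values(logits, expected):
    assert expected_score(np.array(logits, dtype=float)) == pytest.approx(
        expected, abs=1e-9)


@given(st.lists(st.floats(-30, 30), min_size=5, max_size=5),
       st.floats(-100, 100))
@settings(deadline=None, max_examples=100)
def test_expected_score_shift_invariance_and_range(logits, shift):
    base = expected_score(np.array(logits))
    shifted = expected_score(np.array(logits) + shift)
    assert shifted == pytest.approx(base, abs=1e-9)
    assert 1.0 <= base <= 5.0


def test_expected_score_monotone_in_mass_transfer():
    """Moving probability mass from a lower to a higher label raises it."""
    lo = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    for j in range(1, 5):
        hi = np.zeros(5)
        hi[j] = 1.0
        assert expected_score(hi) > expected_score(lo)
        lo = hi


def test_expected_score_rejects_bad_input():
    with pytest.raises(ValueError):
        expected_score(np.array([np.inf, 0, 0, 0, 0]))
    with pytest.raises(ValueError):
        expected_score(np.zeros(4))


def test_templates_load_and_validate():
    for construct in ("self_distance", "other_distance"):
        tpl = ld.PromptTemplate.load(construct)
        assert len(tpl.labels) == 5 and tpl.labels == LABELS
        assert MESSAGE_PLACEHOLDER in tpl.instruction_text
    with pytest.raises(ValueError):
        ld.PromptTemplate.load("empathy")


def test_build_prompt_truncation_and_role_warning(caplog):
    tpl = ld.PromptTemplate.load("self_distance")
    empty = ld.build_prompt(tpl, "")
    assert empty == tpl.instruction_text.replace(MESSAGE_PLACEHOLDER, "")

    long_msg = " ".join(f"w{i}" for i in range(1500))
    prompt = ld.build_prompt(tpl, long_msg)
    head, _, tail = tpl.instruction_text.partition(MESSAGE_PLACEHOLDER)
    payload = prompt[len(head):len(prompt) - len(tail)]
    assert len(payload.split()) == 1000
    assert payload.split()[-1] == "w999"

    other = ld.PromptTemplate.load("other_distance")
    with caplog.at_level(logging.WARNING, logger="lingdist.llm"):
        ld.build_prompt(other, "hello", author_role="client")
    assert any("client" in rec.message for rec in caplog.records)


def test_mock_backend_limits():
    mock = ld.MockBackend({"m0": 0.5}, sharpness=4.0)
    logits = mock.label_logits("", message_id="m0").values
    assert np.allclose(logits, logits[::-1])  # symmetric about label C
    assert expected_score(logits) == pytest.approx(3.0)

    flat = ld.MockBackend({"m0": 0.9}, sharpness=0.0)
    assert expected_score(flat.label_logits("", message_id="m0")) == \
        pytest.approx(3.0)

    sharp = ld.MockBackend({"m0": 0.0}, sharpness=200.0)
    assert expected_score(sharp.label_logits("", message_id="m0")) == \
        pytest.approx(1.0, abs=1e-6)
    with pytest.raises(KeyError):
        sharp.label_logits("", message_id="unknown")


def test_score_messages_full_path(small_corpus):
    """Batch scores equal the formula applied to the mock's logits, are
    order-invariant, and rank-track the generating latents."""
    _, corpus, truth = small_corpus
    tpl = ld.PromptTemplate.load("self_distance")
    mock = ld.MockBackend(truth, sharpness=6.0)
    msgs = corpus.messages[corpus.messages["author_role"] == "client"]

    scores = ld.score_messages(mock, tpl, msgs)
    assert scores["defined"].all()
    latents = truth.messages.set_index("message_id")["latent"]
    for mid, value in zip(scores["message_id"].head(50),
                          scores["value"].head(50)):
        direct = expected_score(mock.label_logits("", message_id=mid))
        assert value == direct

    shuffled = ld.score_messages(
        mock, tpl, msgs.sample(frac=1.0, random_state=1))
    merged = scores.merge(shuffled, on="message_id")
    assert np.allclose(merged["value_x"], merged["value_y"])

    rho = spearmanr(scores["value"],
                    latents.loc[scores["message_id"]].to_numpy()).statistic
    assert rho > 0.9


def test_backend_failure_marks_undefined(small_corpus, caplog):
    _, corpus, truth = small_corpus
    tpl = ld.PromptTemplate.load("self_distance")
    latents = truth.message_latents()
    some = corpus.messages.head(10)
    broken = {k: v for k, v in latents.items()
              if k != some["message_id"].iloc[3]}
    mock = ld.MockBackend(broken, sharpness=4.0)
    with caplog.at_level(logging.WARNING, logger="lingdist.llm"):
        scores = ld.score_messages(mock, tpl, some)
    assert scores["defined"].sum() == 9
    assert not scores["defined"].iloc[3]
    assert np.isnan(scores["value"].iloc[3])
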