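"""Windowing and within/between decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lingdist as ld


def _two_assessment_corpus(tmp_path, message_days):
    messages = pd.DataFrame(
        {
            "message_id": [f"m{i}" for i in range(len(message_days))],
            "client_id": "c1",
            "therapist_id": "t1",
            "author_role": "client",
            "timestamp": [
                (pd.Timestamp("2020-01-01")
                 + pd.Timedelta(days=d - 1)).strftime("%Y-%m-%d")
                for d in message_days
            ],
            "text": "I am here",
        }
    )
    assessments = pd.DataFrame(
        {"client_id": "c1",
         "date": ["2020-01-22", "2020-02-12", "2020-03-04"],
         "phq8": [5, 4, 3], "gad7": [5, 4, 3]}
    )
    mpath, apath = tmp_path / "m.csv", tmp_path / "a.csv"
    messages.to_csv(mpath, index=False)
    assessments.to_csv(apath, index=False)
    return ld.read_corpus(mpath, apath)


def test_window_boundary_convention(tmp_path, caplog):
    # assessments on days 21 / 42 / 63 after the first message (Jan 1)
    corpus = _two_assessment_corpus(tmp_path, [1, 22, 23, 70])
    # day 70 = 2020-03-10, after the last assessment on 2020-03-04
    with caplog.at_level("INFO", logger="lingdist.longitudinal"):
        win = ld.assign_windows(corpus)
    mapping = dict(zip(win["message_id"], win["window_index"]))
    assert mapping["m0"] == 1   # day 0 of treatment
    assert mapping["m1"] == 1   # on the assessment day -> closing window
    assert mapping["m2"] == 2   # the day after -> next window
    assert "m3" not in mapping  # after the last assessment
    assert any("unmapped" in rec.message for rec in caplog.records)


def test_three_assessments_three_windows(small_corpus):
    params, corpus, _ = small_corpus
    win = ld.assign_windows(corpus)
    per_client = win.groupby("client_id")["window_index"].nunique()
    assert (per_client <= params.assessments_per_client).all()
    # every mapped message is mapped exactly once
    assert win["message_id"].is_unique


def test_window_means_unweighted(tmp_path):
    corpus = _two_assessment_corpus(tmp_path, [1, 2])
    corpus.messages.loc[0, "text"] = "I sleep"                    # 5 words max
    corpus.messages.loc[1, "text"] = " ".join(["They slept."] * 250)
    scores = ld.score_messages_wc(corpus.messages)
    assert scores["value"].tolist() == [0.0, 1.0]
    table = ld.build_table(corpus, scores, "wc_self")
    assert table.loc[0, "score"] == pytest.approx(0.5)  # not length-weighted
    assert table.loc[0, "n_messages_used"] == 2


def test_window_mean_simple_average(tmp_path):
    corpus = _two_assessment_corpus(tmp_path, [1, 2])
    scores = pd.DataFrame(
        {"message_id": ["m0", "m1"], "method": "wc_self",
         "value": [0.2, 0.4], "defined": True}
    )
    table = ld.build_table(corpus, scores, "wc_self")
    assert table.loc[0, "score"] == pytest.approx(0.3)


def test_all_undefined_window_dropped(tmp_path, caplog):
    corpus = _two_assessment_corpus(tmp_path, [1, 2, 30])
    scores = pd.DataFrame(
        {"message_id": ["m0", "m1", "m2"], "method": "wc_self",
         "value": [np.nan, np.nan, 0.8], "defined": [False, False, True]}
    )
    with caplog.at_level("INFO", logger="lingdist.longitudinal"):
        table = ld.build_table(corpus, scores, "wc_self")
    assert table["window_index"].tolist() == [2]
    assert any("dropped" in rec.message for rec in caplog.records)


def test_decompose_hand_examples():
    t1 = pd.DataFrame({"client_id": "c1", "score": [1.0, 2.0, 3.0]})
    d1 = ld.decompose(t1)
    assert d1["score_within"].tolist() == [-1.0, 0.0, 1.0]
    assert (d1["score_between"] == 0.0).all()

    t2 = pd.DataFrame({"client_id": ["a", "a", "b", "b"],
                       "score": [1.0, 3.0, 3.0, 5.0]})
    d2 = ld.decompose(t2)
    assert sorted(d2["score_between"].unique()) == [-1.0, 1.0]

    t3 = pd.DataFrame({"client_id": ["a", "a", "b"], "score": 2.0})
    d3 = ld.decompose(t3)
    assert (d3["score_within"] == 0.0).all()
    assert (d3["score_between"] == 0.0).all()


@given(st.lists(st.tuples(st.integers(0, 5),
                          st.floats(-10, 10, allow_nan=False)),
                min_size=2, max_size=40))
@settings(deadline=None, max_examples=60)
def test_decompose_identities(rows):
    table = pd.DataFrame(rows, columns=["client_id", "score"])
    out = ld.decompose(table)
    grand = out.attrs["score_grand_mean"]
    # per-person within sums vanish
    sums = out.groupby("client_id")["score_within"].sum()
    assert np.allclose(sums, 0.0, atol=1e-9)
    # between constant within person
    assert (out.groupby("client_id")["score_between"].nunique() == 1).all()
    # exact reconstruction
    recon = grand + out["score_between"] + out["score_within"]
    assert np.allclose(recon, out["score"], atol=1e-9)


def test_therapist_tables_cluster_by_client(small_corpus):
    _, corpus, truth = small_corpus
    tpl = ld.PromptTemplate.load("other_distance")
    mock = ld.MockBackend(truth, sharpness=6.0)
    tmsgs = corpus.messages[corpus.messages["author_role"] == "therapist"]
    scores = ld.score_messages(mock, tpl, tmsgs)
    table = ld.build_table(corpus, scores, "llm_other", role="therapist")
    assert table["client_id"].nunique() > 1
    assert "therapist_id" in table.columns
    # therapist messages only: windows align with the client assessments
    assert set(table.columns) >= {"internalizing", "days_in_treatment",
                                  "time", "score"}
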