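"""Corpus I/O: round trips, validation, inclusion rule, dyad derivation."""

import numpy as np
import pandas as pd
import pytest

import lingdist as ld
from lingdist.corpus import (CorpusFormatError, ValidationError,
                             apply_inclusion_rule)


def test_read_corpus_round_trip(tiny_corpus_files, tmp_path):
    corpus = ld.read_corpus(*tiny_corpus_files)
    assert len(corpus.dyads) == 2
    assert corpus.n_excluded_clients == 0
    assert (corpus.assessments["internalizing"]
            == corpus.assessments["phq8"] + corpus.assessments["gad7"]).all()

    mpath, apath = ld.write_corpus(corpus, tmp_path / "out")
    again = ld.read_corpus(mpath, apath)
    assert again.messages["text"].equals(corpus.messages["text"])
    assert again.assessments["internalizing"].equals(
        corpus.assessments["internalizing"])
    assert again.dyads.equals(corpus.dyads)


def test_days_in_treatment_from_first_message(tiny_corpus_files):
    corpus = ld.read_corpus(*tiny_corpus_files)
    row = corpus.assessments.iloc[0]
    assert row["days_in_treatment"] == 21  # 2020-01-01 -> 2020-01-22


def test_short_history_client_excluded(tiny_corpus_files, caplog):
    mpath, apath = tiny_corpus_files
    a = pd.read_csv(apath)
    a = a[~((a.client_id == "cB") & (a.date > "2020-02-01"))]  # 2 left for cB
    a.to_csv(apath, index=False)
    with caplog.at_level("INFO", logger="lingdist.corpus"):
        corpus = ld.read_corpus(mpath, apath)
    assert corpus.n_excluded_clients == 1
    assert corpus.client_ids == ["cA"]
    assert not (corpus.messages["client_id"] == "cB").any()
    assert any("excluded 1" in rec.message for rec in caplog.records)


def test_six_week_span_required(tiny_corpus_files):
    mpath, apath = tiny_corpus_files
    a = pd.read_csv(apath)
    # compress cB's three assessments into five weeks
    a.loc[a.client_id == "cB", "date"] = ["2020-01-22", "2020-02-05",
                                          "2020-02-25"]
    a.to_csv(apath, index=False)
    corpus = ld.read_corpus(mpath, apath)
    assert corpus.client_ids == ["cA"]


def test_inclusion_rule_idempotent(tiny_corpus_files):
    corpus = ld.read_corpus(*tiny_corpus_files)
    once, excluded = apply_inclusion_rule(corpus.assessments)
    twice, excluded2 = apply_inclusion_rule(once)
    assert excluded2 == []
    assert once.equals(twice)


def test_out_of_range_symptoms_rejected(tiny_corpus_files):
    mpath, apath = tiny_corpus_files
    a = pd.read_csv(apath)
    a.loc[0, "phq8"] = 25
    a.to_csv(apath, index=False)
    with pytest.raises(ValidationError, match="phq8"):
        ld.read_corpus(mpath, apath)


def test_missing_column_and_bad_date(tiny_corpus_files):
    mpath, apath = tiny_corpus_files
    a = pd.read_csv(apath)
    a.drop(columns=["gad7"]).to_csv(apath, index=False)
    with pytest.raises(CorpusFormatError, match="gad7"):
        ld.read_corpus(mpath, apath)
    a.loc[2, "date"] = "not-a-date"
    a.to_csv(apath, index=False)
    with pytest.raises(CorpusFormatError, match="line"):
        ld.read_corpus(mpath, apath)


def test_jsonl_messages_supported(tiny_corpus_files, tmp_path):
    mpath, apath = tiny_corpus_files
    df = pd.read_csv(mpath)
    jpath = tmp_path / "messages.jsonl"
    df.to_json(jpath, orient="records", lines=True)
    corpus = ld.read_corpus(jpath, apath)
    assert len(corpus.messages) == len(df)


def test_primary_therapist_most_messages_then_earliest(tmp_path):
    messages = pd.DataFrame(
        {
            "message_id": [f"m{i}" for i in range(7)],
            "client_id": ["c1"] * 7,
            "therapist_id": ["tA", "tA", "tB", "tB", "tB", "tC", "tC"],
            "author_role": ["client"] * 7,
            "timestamp": ["2020-01-05", "2020-01-06", "2020-01-01",
                          "2020-01-02", "2020-01-03", "2020-01-04",
                          "2020-01-07"],
            "text": ["hi"] * 7,
        }
    )
    assessments = pd.DataFrame(
        {"client_id": ["c1"] * 3,
         "date": ["2020-01-22", "2020-02-12", "2020-03-04"],
         "phq8": [5, 5, 5], "gad7": [5, 5, 5]}
    )
    mpath, apath = tmp_path / "m.csv", tmp_path / "a.csv"
    messages.to_csv(mpath, index=False)
    assessments.to_csv(apath, index=False)
    corpus = ld.read_corpus(mpath, apath)
    assert corpus.dyads.loc[0, "therapist_id"] == "tB"  # 3 msgs beats 2
    assert corpus.dyads.loc[0, "first_message_date"] == pd.Timestamp(
        "2020-01-01")

    # tie between tA (2) and tC (2) after removing a tB message twice
    messages2 = messages[messages.message_id != "m4"].copy()
    messages2 = messages2[messages2.message_id != "m3"]
    messages2.to_csv(mpath, index=False)
    corpus2 = ld.read_corpus(mpath, apath)
    # tB now has 1; tA and tC have 2 each; tC texted first (01-04 > tA 01-05?)
    assert corpus2.dyads.loc[0, "therapist_id"] == "tC"


def test_score_table_round_trip(small_corpus, tmp_path):
    _, corpus, _ = small_corpus
    scores = ld.score_messages_wc(corpus.messages.head(100))
    path = tmp_path / "scores.csv"
    ld.write_scores(corpus, scores, path)
    again = ld.read_scores(path)
    assert len(again) == len(scores)
    pd.testing.assert_series_equal(again["value"], scores["value"],
                                   check_exact=False)
    assert again["defined"].equals(scores["defined"])


def test_score_table_integrity(small_corpus, tmp_path):
    _, corpus, _ = small_corpus
    empty = pd.DataFrame(columns=["message_id", "method", "value", "defined"])
    path = ld.write_scores(corpus, empty, tmp_path / "empty.csv")
    assert len(ld.read_scores(path)) == 0

    bad = pd.DataFrame({"message_id": ["nope"], "method": ["wc_self"],
                        "value": [0.5], "defined": [True]})
    with pytest.raises(ValidationError, match="unknown message_id"):
        ld.write_scores(corpus, bad, tmp_path / "bad.csv")


def test_load_config(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("simulate:\n  n_clients: 12\n  seed: 3\n", encoding="utf-8")
    loaded = ld.load_config(cfg)
    assert loaded["simulate"]["n_clients"] == 12
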