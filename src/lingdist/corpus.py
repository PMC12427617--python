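"""Data model and file I/O for message/assessment corpora.

A corpus couples three tables:

* ``messages`` — one row per text message (``message_id``, ``client_id``,
  ``therapist_id``, ``author_role`` in {client, therapist}, ``timestamp`` at
  day resolution, ``text``);
* ``assessments`` — one row per symptom observation (``client_id``, ``date``,
  ``phq8`` 0-24, ``gad7`` 0-21, derived ``internalizing`` 0-45 and
  ``days_in_treatment``);
* ``dyads`` — one row per client with their primary therapist and the
  dyad's first-message date.

Internalizing symptoms are the sum of the PHQ-8 depression and GAD-7 anxiety
questionnaires.  ``days_in_treatment`` counts days since the first message
with the primary therapist.  Clients enter analysis only if they completed at
least three assessments spanning at least six weeks; readers apply this
inclusion rule and log how many clients it removes.  The primary therapist is
the therapist with the most messages to the client (ties broken by earliest
first message) — multi-therapist handling is a convention of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "CorpusFormatError",
    "ValidationError",
    "read_corpus",
    "write_corpus",
    "read_scores",
    "write_scores",
    "load_config",
    "MIN_ASSESSMENTS",
    "MIN_SPAN_DAYS",
]

MESSAGE_COLUMNS = ("message_id", "client_id", "therapist_id", "author_role",
                   "timestamp", "text")
ASSESSMENT_COLUMNS = ("client_id", "date", "phq8", "gad7")
SCORE_COLUMNS = ("message_id", "method", "value", "defined")
ROLES = ("client", "therapist")
METHODS = ("wc_self", "llm_self", "llm_other")

#: inclusion rule: at least this many assessments ...
MIN_ASSESSMENTS = 3
#: ... spanning at least this many days (six weeks)
MIN_SPAN_DAYS = 42


class CorpusFormatError(ValueError):
    """A file does not have the expected columns or encoding."""


class ValidationError(ValueError):
    """Row contents violate a domain invariant."""


@dataclass
class Corpus:
    """Validated messages + assessments + derived dyads."""

    messages: pd.DataFrame
    assessments: pd.DataFrame
    dyads: pd.DataFrame
    n_excluded_clients: int = 0

    @property
    def client_ids(self) -> list:
        return list(self.dyads["client_id"])


def _require_columns(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CorpusFormatError(
            f"{what} file {path}: missing column(s) {missing}"
        )


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise CorpusFormatError(
            f"{what}: unparsable date {series[bad.idxmax()]!r} near line {line}"
        )
    return parsed.dt.normalize()


def _read_table(path, columns, what) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        df = pd.read_json(path, lines=True, dtype=False)
    else:
        df = pd.read_csv(path, dtype={"text": str}, keep_default_na=False,
                         na_values=[""])
    _require_columns(df, columns, what, path)
    return df


def _derive_dyads(messages: pd.DataFrame) -> pd.DataFrame:
    """Primary therapist per client: most messages, earliest tie-break."""
    stats = (
        messages.groupby(["client_id", "therapist_id"], sort=True)
        .agg(n=("message_id", "size"), first=("timestamp", "min"))
        .reset_index()
        .sort_values(["client_id", "n", "first"],
                     ascending=[True, False, True], kind="stable")
    )
    primary = stats.drop_duplicates("client_id", keep="first")
    first_any = messages.groupby("client_id")["timestamp"].min()
    dyads = primary[["client_id", "therapist_id"]].copy()
    dyads["first_message_date"] = dyads["client_id"].map(first_any).values
    return dyads.reset_index(drop=True)


def validate_assessments(assessments: pd.DataFrame) -> None:
    for col, lo, hi in (("phq8", 0, 24), ("gad7", 0, 21)):
        vals = pd.to_numeric(assessments[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric {col} value")
        if ((vals < lo) | (vals > hi)).any():
            bad = assessments.loc[(vals < lo) | (vals > hi), col].iloc[0]
            raise ValidationError(f"{col}={bad} outside [{lo}, {hi}]")


def apply_inclusion_rule(assessments: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Keep clients with >= 3 assessments spanning >= 42 days.

    Returns the filtered table and the list of excluded client ids.  The
    filter is idempotent: applying it twice changes nothing.
    """
    g = assessments.groupby("client_id")["date"]
    span = (g.max() - g.min()).dt.days
    count = g.size()
    ok = (count >= MIN_ASSESSMENTS) & (span >= MIN_SPAN_DAYS)
    excluded = sorted(ok.index[~ok])
    kept = assessments[assessments["client_id"].map(ok)].reset_index(drop=True)
    return kept, excluded


def read_corpus(messages_path, assessments_path) -> Corpus:
    """Read, validate, and link a messages file and an assessments file.

    Derives dyads, ``internalizing`` (= phq8 + gad7) and
    ``days_in_treatment`` (days since the dyad's first message), and applies
    the inclusion rule, logging the number of excluded clients.
    """
    messages = _read_table(messages_path, MESSAGE_COLUMNS, "messages")
    assessments = _read_table(assessments_path, ASSESSMENT_COLUMNS,
                              "assessments")

    bad_roles = set(messages["author_role"]) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown author_role value(s): {bad_roles}")
    messages = messages.copy()
    messages["timestamp"] = _parse_dates(messages["timestamp"], "messages")
    messages["text"] = messages["text"].fillna("").astype(str)

    validate_assessments(assessments)
    assessments = assessments.copy()
    assessments["date"] = _parse_dates(assessments["date"], "assessments")
    assessments["phq8"] = assessments["phq8"].astype(int)
    assessments["gad7"] = assessments["gad7"].astype(int)
    assessments["internalizing"] = assessments["phq8"] + assessments["gad7"]

    dyads = _derive_dyads(messages)

    # referential integrity: every assessed client must have messages
    known = set(dyads["client_id"])
    orphan = set(assessments["client_id"]) - known
    if orphan:
        raise ValidationError(
            f"assessments reference clients without messages: {sorted(orphan)[:5]}"
        )

    assessments, excluded = apply_inclusion_rule(assessments)
    # clients whose assessments all vanished are excluded entirely
    excluded = sorted(set(excluded) | (known - set(assessments["client_id"])))
    if excluded:
        logger.info(
            "inclusion rule (>=%d assessments over >=%d days) excluded %d client(s)",
            MIN_ASSESSMENTS, MIN_SPAN_DAYS, len(excluded),
        )
        keep = ~messages["client_id"].isin(excluded)
        messages = messages[keep].reset_index(drop=True)
        dyads = dyads[~dyads["client_id"].isin(excluded)].reset_index(drop=True)

    first = dyads.set_index("client_id")["first_message_date"]
    assessments["days_in_treatment"] = (
        (assessments["date"] - assessments["client_id"].map(first)).dt.days
    )
    if (assessments["days_in_treatment"] < 0).any():
        raise ValidationError("assessment precedes the dyad's first message")
    assessments = assessments.sort_values(["client_id", "date"],
                                          kind="stable").reset_index(drop=True)
    return Corpus(messages=messages, assessments=assessments, dyads=dyads,
                  n_excluded_clients=len(excluded))


def write_corpus(corpus: Corpus, out_dir) -> tuple[Path, Path]:
    """Write ``messages.csv`` and ``assessments.csv`` under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / "messages.csv"
    apath = out_dir / "assessments.csv"
    m = corpus.messages.copy()
    m["timestamp"] = m["timestamp"].dt.strftime("%Y-%m-%d")
    m.to_csv(mpath, index=False)
    a = corpus.assessments[list(ASSESSMENT_COLUMNS)].copy()
    a["date"] = a["date"].dt.strftime("%Y-%m-%d")
    a.to_csv(apath, index=False)
    return mpath, apath


def write_scores(corpus: Corpus, scores: pd.DataFrame, path) -> Path:
    """Write a score table (one row per message x method) as CSV.

    Every score must reference a message present in the corpus; a dangling
    ``message_id`` is an integrity error.
    """
    _require_columns(scores, SCORE_COLUMNS, "scores", path)
    known = set(corpus.messages["message_id"])
    dangling = set(scores["message_id"]) - known
    if dangling:
        raise ValidationError(
            f"scores reference unknown message_id(s): {sorted(dangling)[:5]}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores[list(SCORE_COLUMNS)].to_csv(path, index=False)
    return path


def read_scores(path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    df = _read_table(path, SCORE_COLUMNS, "scores")
    df["defined"] = df["defined"].astype(bool)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = set(df["method"]) - set(METHODS)
    if bad:
        raise ValidationError(f"unknown score method(s): {bad}")
    if (df["defined"] & df["value"].isna()).any():
        raise ValidationError("defined score without a value")
    return df


def load_config(path) -> dict:
    """Load a nested key-value configuration file (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
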