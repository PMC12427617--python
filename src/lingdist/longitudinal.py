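"""Windowing, per-window averaging, and within/between-person decomposition.

Message-level distance scores become one regression row per client per
assessment: window ``k`` is the half-open interval from assessment ``k-1``
(exclusive) to assessment ``k`` (inclusive), with window 1 opening at the
dyad's first-message date; scores are averaged over the window's messages
without weighting by length, using defined scores only.  Each observation
carries the assessment's internalizing score and days in treatment.

For modelling, a window-level predictor is split into a between-person part
(the person's mean, grand-mean centered, where the grand mean is the
unweighted mean of person means) and a within-person part (the observation
minus the person's mean); the two parts plus the grand mean reconstruct the
observation exactly, and the within parts sum to zero for every person.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = ["assign_windows", "window_means", "build_table", "decompose",
            "DEFAULT_TIME_UNIT_DAYS"]

#: assessments arrive roughly every three weeks; `time` expresses
#: days-in-treatment in units of this interval
DEFAULT_TIME_UNIT_DAYS = 21.0


def assign_windows(corpus: Corpus, role: str = "client") -> pd.DataFrame:
    """Map each message by *role* to its client's assessment window.

    Returns columns ``message_id``, ``client_id``, ``window_index`` (1-based)
    for messages falling in some window; messages after a client's last
    assessment are unmapped (their count is logged).
    """
    if role not in ("client", "therapist"):
        raise ValueError(f"unknown role: {role!r}")
    msgs = corpus.messages[corpus.messages["author_role"] == role]
    first = corpus.dyads.set_index("client_id")["first_message_date"]

    rows = []
    n_after = 0
    by_client = corpus.assessments.sort_values(["client_id", "date"]).groupby(
        "client_id"
    )["date"]
    bounds = {cid: dates.to_numpy() for cid, dates in by_client}
    for cid, grp in msgs.groupby("client_id", sort=True):
        dates = bounds.get(cid)
        if dates is None:
            continue
        ts = grp["timestamp"].to_numpy()
        # window k = (a_{k-1}, a_k]; searchsorted with side='left' puts a
        # message on an assessment day into the window that day closes
        idx = np.searchsorted(dates, ts, side="left")
        in_range = idx < len(dates)
        n_after += int((~in_range).sum())
        start_ok = ts >= np.datetime64(first[cid])
        keep = in_range & start_ok
        for mid, k in zip(grp.loc[keep, "message_id"], idx[keep] + 1):
            rows.append((mid, cid, int(k)))
    if n_after:
        logger.info("%d message(s) after the last assessment left unmapped",
                    n_after)
    return pd.DataFrame(rows, columns=["message_id", "client_id",
                                       "window_index"])


def window_means(
    scores: pd.DataFrame,
    windows: pd.DataFrame,
    corpus: Corpus,
    method: str,
    time_unit_days: float = DEFAULT_TIME_UNIT_DAYS,
) -> pd.DataFrame:
    """Average defined scores per (client, window) and attach assessments.

    Undefined message scores are excluded; a window with no defined score is
    dropped from the table (logged).  ``time`` is days in treatment divided
    by *time_unit_days*.
    """
    sc = scores[scores["method"] == method]
    merged = windows.merge(sc[["message_id", "value", "defined"]],
                           on="message_id", how="left")
    merged["defined"] = merged["defined"].fillna(False).astype(bool)
    grp = merged.groupby(["client_id", "window_index"], sort=True)
    agg = grp.agg(
        score=("value", lambda v: v[merged.loc[v.index, "defined"]].mean()),
        n_messages_used=("defined", "sum"),
    ).reset_index()

    assess = corpus.assessments.sort_values(["client_id", "date"]).copy()
    assess["window_index"] = assess.groupby("client_id").cumcount() + 1
    table = agg.merge(
        assess[["client_id", "window_index", "internalizing",
                "days_in_treatment"]],
        on=["client_id", "window_index"], how="inner",
    )
    n_drop = int(table["score"].isna().sum())
    if n_drop:
        logger.info("%d window(s) without defined scores dropped", n_drop)
    table = table[table["score"].notna()].reset_index(drop=True)
    table["time"] = table["days_in_treatment"] / float(time_unit_days)
    table["n_messages_used"] = table["n_messages_used"].astype(int)
    return table


def build_table(
    corpus: Corpus,
    scores: pd.DataFrame,
    method: str,
    role: str = "client",
    time_unit_days: float = DEFAULT_TIME_UNIT_DAYS,
) -> pd.DataFrame:
    """Windowed regression table for one scoring method and author role.

    For therapist analyses the client's assessment windows are kept and
    therapist-authored messages are averaged; rows remain clustered by
    client (therapist identity is attached for bootstrap resampling).
    """
    windows = assign_windows(corpus, role=role)
    table = window_means(scores, windows, corpus, method,
                         time_unit_days=time_unit_days)
    tmap = corpus.dyads.set_index("client_id")["therapist_id"]
    table["therapist_id"] = table["client_id"].map(tmap)
    return table


def decompose(table: pd.DataFrame, col: str = "score",
              group: str = "client_id") -> pd.DataFrame:
    """Add ``{col}_within`` and ``{col}_between`` columns.

    between = person mean − grand mean of person means (unweighted);
    within = observation − person mean.  grand mean + between + within
    reconstructs the observation exactly.
    """
    out = table.copy()
    person_mean = out.groupby(group)[col].transform("mean")
    grand = out.groupby(group)[col].mean().mean()
    out[f"{col}_between"] = person_mean - grand
    out[f"{col}_within"] = out[col] - person_mean
    out.attrs[f"{col}_grand_mean"] = float(grand)
    return out
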