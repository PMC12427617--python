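"""Dictionary/rule-based word-count measure of linguistic distancing.

Linguistic distancing is the degree to which language frames an experience
as removed from the self and the present moment.  The word-count composite
operationalizes it as the mean of two sub-measures computed from closed-class
word counts:

* **temporal distance** — the proportion of tensed verbs that are not in the
  present tense: ``(past + future) / (past + future + present)``;
* **social distance** — the proportion of personal pronouns that are not
  first-person singular: ``(second + first_plural + third_singular +
  third_plural) / (all five personal-pronoun categories)``.

Messages without any tensed verb have no temporal distance, and messages
without any personal pronoun have no social distance; the composite is
undefined whenever either part is, and such messages are excluded from all
downstream analyses so that every scoring method sees the same message set.

The pronoun dictionary is enumerated exhaustively below.  Tense tagging is
rule-based: an irregular-verb lookup table plus the ``-ed`` suffix mark past
tense; ``will``/``shall``/``'ll``/``going to`` mark future; finite base and
``-s`` forms of lexicon verbs, the present forms of *be*/*have*/*do*, and the
contracted auxiliaries ``'s``/``'re``/``'m``/``'ve`` mark present.
Infinitival ``to VERB``, bare participles, and participles that follow a
*be*/*have* auxiliary carry no tense of their own and are not counted.  The
verb lexicon is deliberately curated: words whose ``-ed`` form is
predominantly adjectival (e.g. *detached*, *puzzled*) and noun-heavy
homographs (e.g. *experience*, *shoot*, *matter*) are omitted, because for a
context-free counter the cost of a false verb is higher than the cost of a
missed one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

__all__ = [
    "TokenCounts",
    "tokenize",
    "tag_tokens",
    "temporal_distance",
    "social_distance",
    "wc_self_distance",
    "display_score",
    "score_messages_wc",
]

DISPLAY_SCALE = 10.0

# ---------------------------------------------------------------------------
# Pronoun dictionary
# ---------------------------------------------------------------------------

PRONOUNS: dict[str, str] = {}
for _w in ("i", "me", "my", "mine", "myself"):
    PRONOUNS[_w] = "pron_first_singular"
for _w in ("we", "us", "our", "ours", "ourselves"):
    PRONOUNS[_w] = "pron_first_plural"
for _w in ("you", "your", "yours", "yourself", "yourselves"):
    PRONOUNS[_w] = "pron_second"
for _w in ("he", "she", "him", "her", "his", "hers", "himself", "herself"):
    PRONOUNS[_w] = "pron_third_singular"
for _w in ("they", "them", "their", "theirs", "themselves"):
    PRONOUNS[_w] = "pron_third_plural"
# Impersonal pronouns are tallied but excluded from the social-distance
# denominator (the measure contrasts self-reference with reference to other
# *people*).
for _w in ("it", "its", "itself", "this", "that", "these", "those", "one"):
    PRONOUNS[_w] = "pron_impersonal"

PERSONAL_CATEGORIES = (
    "pron_first_singular",
    "pron_first_plural",
    "pron_second",
    "pron_third_singular",
    "pron_third_plural",
)

# ---------------------------------------------------------------------------
# Verb lexicon
# ---------------------------------------------------------------------------

# Base forms tagged present when finite (also via -s / -es / -ies inflection).
VERB_BASES = frozenset(
    """
    afford agree arrive ask become begin believe bring build buy call carry
    catch choose clean come cook decide drink drive eat enjoy fall feel find
    finish forget get give go grow happen hear help hold hope join keep know
    learn leave let listen live look lose love make mean meet move need pay
    play prefer put remember run say see seem sell send sing sit sleep speak
    spend stand start stay stop struggle take talk teach tell thank think try
    turn understand visit wait walk want watch wear win wish wonder work
    worry write
    """.split()
)

# Irregular past-tense forms (past == participle forms appear here and are
# treated as participles only when an auxiliary precedes them).
IRREGULAR_PAST: dict[str, str] = {
    "was": "be", "were": "be", "had": "have", "did": "do",
    "became": "become", "began": "begin", "bought": "buy", "brought": "bring",
    "built": "build", "came": "come", "caught": "catch", "chose": "choose",
    "drank": "drink", "drove": "drive", "ate": "eat", "fell": "fall",
    "felt": "feel", "found": "find", "forgot": "forget", "got": "get",
    "gave": "give", "went": "go", "grew": "grow", "heard": "hear",
    "held": "hold", "kept": "keep", "knew": "know", "left": "leave",
    "lost": "lose", "made": "make", "meant": "mean", "met": "meet",
    "paid": "pay", "ran": "run", "said": "say", "saw": "see", "sold": "sell",
    "sent": "send", "sang": "sing", "sat": "sit", "slept": "sleep",
    "spoke": "speak", "spent": "spend", "stood": "stand", "took": "take",
    "taught": "teach", "told": "tell", "thought": "think", "wore": "wear",
    "won": "win", "wrote": "write", "understood": "understand",
}

# Participle-only forms: never tensed on their own.
PARTICIPLES = frozenset(
    """
    be been being begun broken chosen done drunk driven eaten fallen
    forgotten given gone gotten grown known seen spoken sung taken worn
    written
    """.split()
)

# Present forms of the auxiliaries / copula.
PRESENT_SPECIAL = frozenset(("am", "is", "are", "have", "has", "do", "does"))

# Auxiliaries after which a past/participle form is part of a compound verb
# phrase whose tense the auxiliary already carries ("are puzzled",
# "have played").
AUX_BEFORE_PARTICIPLE = frozenset(
    ("am", "is", "are", "was", "were", "be", "been", "being",
     "have", "has", "had", "'s", "'m", "'re", "'ve", "'d")
)

MODALS = frozenset(("can", "could", "may", "might", "must", "should", "would"))

# Hosts whose clitic 's is read as a contracted present auxiliary (is/has);
# elsewhere 's is possessive and carries no tense.
CLITIC_S_HOSTS = frozenset(
    ("it", "he", "she", "that", "this", "there", "here", "what", "who",
     "where", "one", "everything", "nothing", "something", "someone",
     "everyone", "nobody", "everybody", "somebody")
)

# Contractions that the tokenizer keeps whole.
NEGATED_FORMS: dict[str, str] = {
    "isn't": "present", "aren't": "present", "ain't": "present",
    "don't": "present", "doesn't": "present", "hasn't": "present",
    "haven't": "present", "wasn't": "past", "weren't": "past",
    "didn't": "past", "hadn't": "past", "won't": "future", "shan't": "future",
}

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")
_CLITICS = ("'ll", "'ve", "'re", "'m", "'s", "'d")

REDACTION_MARKER = "[-]"


@dataclass
class TokenCounts:
    """Verb-tense and pronoun-category counts for one message."""

    past: int = 0
    present: int = 0
    future: int = 0
    pron_first_singular: int = 0
    pron_first_plural: int = 0
    pron_second: int = 0
    pron_third_singular: int = 0
    pron_third_plural: int = 0
    pron_impersonal: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics, keeping internal apostrophes.

    Curly apostrophes are normalized to straight ones; contracted
    auxiliaries (``'s``, ``'re``, ``'m``, ``'ve``, ``'ll``, ``'d``) are split
    off as separate tokens; the redaction marker ``[-]`` contains no word
    characters and disappears.
    """
    text = text.replace("’", "'").replace("‘", "'").lower()
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        if tok in NEGATED_FORMS or tok in PRONOUNS:
            out.append(tok)
            continue
        split = False
        for cl in _CLITICS:
            if tok.endswith(cl) and len(tok) > len(cl):
                out.extend((tok[: -len(cl)], cl))
                split = True
                break
        if not split:
            out.append(tok)
    return out


def _base_lookup(token: str) -> str | None:
    """Return the lexicon base form for a finite base/-s token, else None."""
    if token in VERB_BASES:
        return token
    if token.endswith("ies") and token[:-3] + "y" in VERB_BASES:
        return token[:-3] + "y"
    if token.endswith("es") and token[:-2] in VERB_BASES:
        return token[:-2]
    if token.endswith("s") and token[:-1] in VERB_BASES:
        return token[:-1]
    return None


def _past_lookup(token: str) -> str | None:
    """Return the base form if *token* is a past-tense form, else None."""
    if token in IRREGULAR_PAST:
        return IRREGULAR_PAST[token]
    if token.endswith("ed"):
        stem = token[:-2]
        for cand in (stem, stem + "e", stem[:-1] if stem and stem[-1:] * 2 == stem[-2:] else None):
            if cand and cand in VERB_BASES:
                return cand
    return None


def _is_verbform(token: str) -> bool:
    return (
        token in PRESENT_SPECIAL
        or token in PARTICIPLES
        or token in IRREGULAR_PAST
        or _base_lookup(token) is not None
        or _past_lookup(token) is not None
        or (token.endswith("ing") and (token[:-3] in VERB_BASES
                                       or token[:-3] + "e" in VERB_BASES))
    )


_BE_PRESENT = frozenset(("am", "is", "are", "'m", "'s", "'re"))
_FUTURE_MARK = "\x00future"


def _mark_going_to(tokens: list[str]) -> list[str]:
    """Rewrite the ``going to VERB`` periphrasis as a single future marker.

    ``[be-form,] going to VERB`` counts one future tense; the be-form and the
    bare verb are consumed so nothing is double-counted.
    """
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        j = i
        if tok in _BE_PRESENT and i + 1 < n and tokens[i + 1] == "going":
            j = i + 1
        if (
            tokens[j] == "going"
            and j + 2 < n
            and tokens[j + 1] == "to"
            and _is_verbform(tokens[j + 2])
        ):
            if j > i and tok == "'s" and (not out or out[-1] not in CLITIC_S_HOSTS):
                # possessive 's cannot head the periphrasis
                out.append(tok)
                i += 1
                continue
            out.append(_FUTURE_MARK)
            i = j + 3
            continue
        out.append(tok)
        i += 1
    return out


def tag_tokens(text: str) -> TokenCounts:
    """Count verb tenses and pronoun categories in *text*.

    Deterministic and purely local: the same text always yields the same
    counts.  Empty or word-free text yields all zeros.
    """
    counts = TokenCounts()
    tokens = _mark_going_to(tokenize(text))
    # When True, the next verb form encountered is untensed (after "to",
    # "will", a modal, or a negated auxiliary whose tense was already
    # counted).  Any intervening non-verb token cancels it.
    skip_next_verb = False
    prev = ""
    for tok in tokens:
        cat = PRONOUNS.get(tok)
        if cat is not None:
            setattr(counts, cat, getattr(counts, cat) + 1)
            # a pronoun separates an auxiliary from any later verb
            skip_next_verb = False
            prev = tok
            continue
        if tok in NEGATED_FORMS:
            tense = NEGATED_FORMS[tok]
            setattr(counts, tense, getattr(counts, tense) + 1)
            skip_next_verb = True  # "didn't go": tense already counted
            prev = tok
            continue
        if tok in ("will", "shall", "'ll") or tok == _FUTURE_MARK:
            counts.future += 1
            skip_next_verb = True
            prev = tok
            continue
        if tok == "to":
            # infinitival "to VERB" carries no tense
            skip_next_verb = True
            prev = tok
            continue
        if tok in MODALS or tok == "'d":
            # modal constructions ("could go", "I'd like") are not assigned
            # a tense by these rules
            skip_next_verb = True
            prev = tok
            continue

        if tok.endswith("ing") or tok in PARTICIPLES:
            # bare participles and -ing forms carry no tense of their own
            prev = tok
            continue

        if tok in PRESENT_SPECIAL:
            if skip_next_verb:  # "to be", "will have"
                skip_next_verb = False
            else:
                counts.present += 1
            prev = tok
            continue
        if tok in ("'s", "'m", "'re", "'ve"):
            if tok == "'s" and prev not in CLITIC_S_HOSTS:
                prev = tok
                continue  # possessive
            if skip_next_verb:
                skip_next_verb = False
            else:
                counts.present += 1
            prev = tok
            continue

        past_base = _past_lookup(tok)
        if past_base is not None:
            if skip_next_verb:
                skip_next_verb = False
            elif prev in AUX_BEFORE_PARTICIPLE:
                pass  # compound verb phrase: auxiliary already carried tense
            else:
                counts.past += 1
            prev = tok
            continue

        base = _base_lookup(tok)
        if base is not None:
            if skip_next_verb:
                skip_next_verb = False
            else:
                counts.present += 1
            prev = tok
            continue

        skip_next_verb = False
        prev = tok
    return counts


def temporal_distance(counts: TokenCounts) -> float | None:
    """``(past + future) / (past + future + present)``; None without verbs."""
    denom = counts.past + counts.future + counts.present
    if denom == 0:
        return None
    return (counts.past + counts.future) / denom


def social_distance(
    counts: TokenCounts, include_impersonal: bool = False
) -> float | None:
    """Share of pronouns that are not first-person singular; None without any.

    By default the denominator is the five personal-pronoun categories;
    ``include_impersonal=True`` adds impersonal pronouns to the denominator
    only (they are never distancing in the numerator sense).
    """
    numer = (
        counts.pron_second
        + counts.pron_first_plural
        + counts.pron_third_singular
        + counts.pron_third_plural
    )
    denom = sum(getattr(counts, c) for c in PERSONAL_CATEGORIES)
    if include_impersonal:
        denom += counts.pron_impersonal
    if denom == 0:
        return None
    return numer / denom


def wc_self_distance(text: str, include_impersonal: bool = False) -> float | None:
    """Composite word-count self-distance on [0, 1], or None if undefined.

    The composite is the unweighted mean of temporal and social distance and
    is undefined when either component is (verb-free or pronoun-free
    messages), so that all scoring methods can be compared on an identical
    message set.
    """
    counts = tag_tokens(text)
    t = temporal_distance(counts)
    s = social_distance(counts, include_impersonal=include_impersonal)
    if t is None or s is None:
        return None
    return (t + s) / 2.0


def display_score(text: str) -> float | None:
    """Composite score on the 0-10 display scale (value x 10), or None."""
    value = wc_self_distance(text)
    return None if value is None else DISPLAY_SCALE * value


def score_messages_wc(messages, include_impersonal: bool = False):
    """Score a message table with the word-count composite.

    Parameters
    ----------
    messages : pandas.DataFrame
        Must carry ``message_id`` and ``text`` columns.

    Returns
    -------
    pandas.DataFrame
        One row per message: ``message_id``, ``method`` (``wc_self``),
        ``value`` (NaN when undefined) and ``defined``.
    """
    import pandas as pd

    ids, values, defined = [], [], []
    for mid, text in zip(messages["message_id"], messages["text"]):
        v = wc_self_distance("" if text is None else str(text),
                             include_impersonal=include_impersonal)
        ids.append(mid)
        values.append(float("nan") if v is None else v)
        defined.append(v is not None)
    return pd.DataFrame(
        {"message_id": ids, "method": "wc_self", "value": values,
         "defined": defined}
    )
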