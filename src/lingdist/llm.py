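"""Prompted-LLM construct scoring via constrained five-label readout.

A construct (self-distance, or other-distance for therapist messages) is
described in an instruction prompt ending in a five-level scale labelled
A-E.  A scoring backend returns the model's next-token logits for the five
label tokens; these are softmax-normalized (restricted to the five labels)
and combined into an expected score

    score = sum_i i * softmax(logit_i),   i = 1..5, 1 <-> A,

a deterministic value in [1, 5] that replaces stochastic sampling.

The instruction texts shipped under ``prompts/`` are synthetic re-creations
written from the construct definitions in the distancing literature (the
construct is defined to the model in plain language; the code treats the
instruction as opaque).  Backends are pluggable; the bundled
:class:`MockBackend` reads a synthetic message's hidden generating latent
and emits sharply peaked logits around it, enabling full-pipeline tests
without any model weights.  No backend may perform network calls: scoring is
local by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Protocol

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "MESSAGE_PLACEHOLDER",
    "PromptTemplate",
    "LabelLogits",
    "ScoringBackend",
    "MockBackend",
    "build_prompt",
    "expected_score",
    "score_messages",
]

LABELS = ("A", "B", "C", "D", "E")
MESSAGE_PLACEHOLDER = "<<MESSAGE>>"
CONSTRUCTS = ("self_distance", "other_distance")
#: messages are truncated to this many tokens before prompting
MAX_MESSAGE_TOKENS = 1000


@dataclass(frozen=True)
class PromptTemplate:
    """Instruction text for one construct, with the ordered A-E label set."""

    construct: str
    instruction_text: str
    labels: tuple[str, ...] = LABELS

    def __post_init__(self):
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct: {self.construct!r}")
        if len(self.labels) != 5:
            raise ValueError("exactly five labels are required")
        if MESSAGE_PLACEHOLDER not in self.instruction_text:
            raise ValueError(
                f"instruction text lacks the {MESSAGE_PLACEHOLDER} placeholder"
            )

    @classmethod
    def load(cls, construct: str) -> "PromptTemplate":
        """Load the packaged instruction file for *construct*."""
        if construct not in CONSTRUCTS:
            raise ValueError(f"unknown construct: {construct!r}")
        text = (
            resources.files("lingdist.prompts")
            .joinpath(f"{construct}.txt")
            .read_text(encoding="utf-8")
        )
        return cls(construct=construct, instruction_text=text)


@dataclass
class LabelLogits:
    """Unnormalized next-token scores for the five labels."""

    values: np.ndarray  # shape (5,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (5,):
            raise ValueError("five logits are required")


class ScoringBackend(Protocol):
    """A component producing label logits for a fully built prompt.

    Backends must be deterministic for a fixed prompt (no sampling).  The
    optional ``message_id`` lets oracle backends (such as the mock) identify
    the message; real model adapters ignore it.
    """

    def label_logits(self, prompt: str, message_id=None) -> LabelLogits: ...


def build_prompt(
    template: PromptTemplate,
    message_text: str,
    author_role: str | None = None,
    max_message_tokens: int = MAX_MESSAGE_TOKENS,
) -> str:
    """Insert *message_text* (truncated) into the instruction template.

    Truncation keeps the first ``max_message_tokens`` whitespace tokens of
    the message; the instruction is never truncated.  Other-distance is a
    therapist-message construct: applying it to client text is allowed but
    logged as a warning.
    """
    if template.construct == "other_distance" and author_role == "client":
        logger.warning(
            "other_distance prompt applied to a client-authored message; "
            "the construct is defined for therapist messages"
        )
    tokens = message_text.split()
    if len(tokens) > max_message_tokens:
        message_text = " ".join(tokens[:max_message_tokens])
    return template.instruction_text.replace(MESSAGE_PLACEHOLDER, message_text)


def expected_score(logits: LabelLogits | np.ndarray) -> float:
    """Expected label rank under the softmax over the five label logits.

    Computed in double precision with max-subtraction stabilization; the
    result lies in [1, 5], attaining an endpoint only in a one-hot limit.
    """
    values = logits.values if isinstance(logits, LabelLogits) else np.asarray(
        logits, dtype=float
    )
    if values.shape != (5,):
        raise ValueError("five logits are required")
    if not np.all(np.isfinite(values)):
        raise ValueError("logits must be finite")
    z = values - values.max()
    p = np.exp(z)
    p /= p.sum()
    return float(np.dot(np.arange(1.0, 6.0), p))


class MockBackend:
    """Oracle backend that peaks at the label bin holding the true latent.

    For a message generated at hidden latent ``d`` in [0, 1] the backend
    emits ``logit_i = -sharpness * (i - (1 + 4 d))**2`` for ``i = 1..5``:
    the logits peak at the scale position the latent maps to under the
    affine [0,1] -> [1,5] correspondence, with peak width controlled by
    ``sharpness``.  ``sharpness=0`` yields uniform logits (score 3.0 for
    every message); large sharpness approaches a one-hot readout.
    """

    def __init__(self, truth, sharpness: float = 4.0):
        if sharpness < 0:
            raise ValueError("sharpness must be non-negative")
        self.sharpness = float(sharpness)
        # accept a LatentTruth or any mapping message_id -> latent
        if hasattr(truth, "message_latents"):
            self._latents = dict(truth.message_latents())
        else:
            self._latents = dict(truth)

    def label_logits(self, prompt: str, message_id=None) -> LabelLogits:
        if message_id is None or message_id not in self._latents:
            raise KeyError(f"message {message_id!r} not in latent truth")
        d = float(np.clip(self._latents[message_id], 0.0, 1.0))
        centre = 1.0 + 4.0 * d
        i = np.arange(1.0, 6.0)
        return LabelLogits(-self.sharpness * (i - centre) ** 2)


def score_messages(
    backend: ScoringBackend,
    template: PromptTemplate,
    messages: pd.DataFrame,
) -> pd.DataFrame:
    """Score each message with the prompted-construct expected score.

    Returns one row per message (``message_id``, ``method``, ``value``,
    ``defined``) where ``method`` is ``llm_self`` or ``llm_other``.  A
    backend failure on a message marks that score undefined, logs the
    failure, and continues; values do not depend on batch order.
    """
    method = "llm_self" if template.construct == "self_distance" else "llm_other"
    ids, values, defined = [], [], []
    roles = (
        messages["author_role"]
        if "author_role" in messages.columns
        else [None] * len(messages)
    )
    n_failed = 0
    for mid, text, role in zip(messages["message_id"], messages["text"], roles):
        ids.append(mid)
        try:
            prompt = build_prompt(template, "" if text is None else str(text), role)
            value = expected_score(backend.label_logits(prompt, message_id=mid))
        except Exception as exc:  # noqa: BLE001 - per-message isolation
            n_failed += 1
            logger.warning("backend failed on message %r: %s", mid, exc)
            values.append(float("nan"))
            defined.append(False)
            continue
        values.append(value)
        defined.append(True)
    if n_failed:
        logger.warning("%d of %d messages failed scoring", n_failed, len(ids))
    return pd.DataFrame(
        {"message_id": ids, "method": method, "value": values, "defined": defined}
    )
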