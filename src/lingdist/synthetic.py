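"""Synthetic therapy-corpus generator with known ground-truth effect structure.

The generator emulates the longitudinal design every downstream stage
assumes: clients in dyads with therapists, at least three symptom
assessments spaced roughly three weeks apart, streams of short messages in
each between-assessment window, and internalizing symptoms (PHQ-8 + GAD-7,
0-45) linearly coupled to the within- and between-person components of a
latent "distancing" trait:

    d_i   ~ Normal(mu_d, sigma_between^2)                (person mean)
    d_ik  = d_i + gamma_time * tau_ik + Normal(0, sigma_within^2)
    Y_ik  = beta0 + beta_within * (d_ik - d_i)
                  + beta_between * (d_i - mu_d)
                  + c_prime * tau_ik + u_i + Normal(0, sigma_symptom^2)

where ``tau_ik`` is time in treatment as a fraction of the planned course
(``assessment_spacing_days * assessments_per_client`` days) and ``u_i`` is a
person-level symptom intercept.  Symptoms are rounded and clipped to the
0-45 questionnaire range by default (the clip rate is reported so recovery
studies can avoid heavy-censoring regimes).

Message text is slot-template ("SUBJ VERB OBJ") prose from a closed
vocabulary in which the probability of a non-first-singular subject pronoun
and the probability of a past-tense verb both equal the window's latent
``d_ik`` (clipped to [0, 1]) — so the word-count composite of a message is an
unbiased draw around the latent, and equals it exactly at the endpoints.  A
controllable fraction of messages is verb-free (default 7.1%) or
pronoun-free (default 9.4%), making the composite undefined for them.
Therapist message streams follow an analogous, independent latent
("other-distance encouragement") with the same time trend.  Templates carry
controlled grammatical signal only; no attempt is made at clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .corpus import Corpus

__all__ = [
    "SimParams",
    "LatentTruth",
    "generate_corpus",
    "generate_message_text",
    "theoretical_effects",
    "expected_standardized_effects",
]

# ---------------------------------------------------------------------------
# Template vocabulary.  Every verb is regular (-s present, -ed past, will +
# base future); objects are noun phrases that the word-count lexicon can
# never mistake for verbs.
# ---------------------------------------------------------------------------

VERBS = ("walk", "call", "help", "talk", "visit", "watch", "clean", "cook",
         "play", "ask", "listen", "wait", "finish", "start", "enjoy")
OBJECTS = ("near the park", "with the neighbors", "in the kitchen",
           "about the weekend", "after dinner", "at the library",
           "during the afternoon", "by the lake", "for a while",
           "before breakfast", "around the block", "at the office")
SUBJ_IMMERSED = "i"
SUBJ_DISTANCED = ("we", "you", "he", "she", "they")
VERB_FREE_FRAGMENTS = (
    "my goodness, such a lovely day!",
    "oh my, what a week!",
    "my word, quite the morning!",
)
PRONOUN_FREE_FRAGMENTS = (
    "the meeting went well.",
    "the weather turned cold.",
    "the garden looked lovely.",
)


@dataclass(frozen=True)
class SimParams:
    """Generative settings; defaults mirror the emulated study design.

    ``clients_per_therapist`` defaults to the corpus ratio of roughly 2.7
    clients per therapist; assessments default to every 21 days;
    ``p_no_verbs``/``p_no_pronouns`` default to the observed 7.1% / 9.4%
    undefined-message fractions.  ``gamma_time`` is latent drift per full
    planned treatment course; ``beta_*`` and ``c_prime`` are in symptom
    points per latent unit and per course, respectively.
    """

    n_clients: int = 300
    clients_per_therapist: float = 2.7
    assessments_per_client: int = 4
    assessment_spacing_days: int = 21
    messages_per_window: int = 30
    messages_per_window_therapist: int = 18
    mu_d: float = 0.35
    sigma_between: float = 0.10
    sigma_within: float = 0.07
    gamma_time: float = 0.25
    beta_within: float = -5.0
    beta_between: float = -15.0
    c_prime: float = -2.0
    beta0: float = 18.0
    sigma_intercept: float = 6.0
    sigma_symptom: float = 3.0
    p_no_verbs: float = 0.071
    p_no_pronouns: float = 0.094
    seed: int = 0
    jitter_days: int = 3
    poisson_messages: bool = False
    round_symptoms: bool = True

    def __post_init__(self):
        if self.n_clients < 1:
            raise ValueError("n_clients must be >= 1")
        if self.clients_per_therapist <= 0:
            raise ValueError("clients_per_therapist must be positive")
        if self.assessments_per_client < 3:
            raise ValueError("at least three assessments are required")
        for name in ("sigma_between", "sigma_within", "sigma_symptom",
                     "sigma_intercept"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_no_verbs", "p_no_pronouns"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_no_verbs + self.p_no_pronouns > 1.0:
            raise ValueError("p_no_verbs + p_no_pronouns must be <= 1")
        if self.messages_per_window < 1:
            raise ValueError("messages_per_window must be >= 1")
        if self.jitter_days < 0 or self.jitter_days * 2 >= self.assessment_spacing_days:
            raise ValueError("jitter_days must be < half the spacing")


@dataclass
class LatentTruth:
    """Ground truth behind a generated corpus (reproducible from the seed)."""

    params: SimParams
    clients: pd.DataFrame   # client_id, therapist_id, d_i, o_i, u_i
    windows: pd.DataFrame   # client_id, window_index, day, tau, d_ik, o_ik,
                            # symptom_continuous, internalizing
    messages: pd.DataFrame  # message_id, client_id, window_index, role, latent
    clip_rate_latent: float = 0.0
    clip_rate_symptom: float = 0.0

    def message_latents(self) -> dict:
        return dict(zip(self.messages["message_id"], self.messages["latent"]))


def generate_message_text(
    latent_distance: float,
    rng: np.random.Generator,
    p_no_verbs: float = 0.071,
    p_no_pronouns: float = 0.094,
) -> str:
    """One template message at the given latent distancing level.

    With probability ``p_no_verbs`` a verb-free fragment is emitted, with
    ``p_no_pronouns`` a pronoun-free one; otherwise a "SUBJ VERB OBJ"
    sentence whose subject is non-first-singular with probability
    ``latent_distance`` and whose verb is past-tense with the same
    probability.
    """
    if not 0.0 <= latent_distance <= 1.0:
        raise ValueError("latent_distance must lie in [0, 1]")
    u = rng.random()
    if u < p_no_verbs:
        return VERB_FREE_FRAGMENTS[rng.integers(len(VERB_FREE_FRAGMENTS))]
    if u < p_no_verbs + p_no_pronouns:
        return PRONOUN_FREE_FRAGMENTS[rng.integers(len(PRONOUN_FREE_FRAGMENTS))]
    distanced_subj = rng.random() < latent_distance
    past = rng.random() < latent_distance
    verb = VERBS[rng.integers(len(VERBS))]
    obj = OBJECTS[rng.integers(len(OBJECTS))]
    if distanced_subj:
        subj = SUBJ_DISTANCED[rng.integers(len(SUBJ_DISTANCED))]
    else:
        subj = SUBJ_IMMERSED
    if past:
        vform = verb + "d" if verb.endswith("e") else verb + "ed"
    elif subj in ("he", "she"):
        vform = verb + "es" if verb.endswith(("sh", "ch", "s")) else verb + "s"
    else:
        vform = verb
    return f"{subj} {vform} {obj}."


def _assessment_days(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Planned assessment days for one client; first and last unjittered.

    Keeping the endpoints exact guarantees every generated client passes the
    three-assessments/six-weeks inclusion rule.
    """
    m = params.assessments_per_client
    days = params.assessment_spacing_days * np.arange(1, m + 1)
    if params.jitter_days > 0 and m > 2:
        jit = rng.integers(-params.jitter_days, params.jitter_days + 1,
                           size=m - 2)
        days = days.copy()
        days[1:-1] += jit
    return days


def generate_corpus(params: SimParams) -> tuple[Corpus, LatentTruth]:
    """Generate a full corpus plus its latent ground truth.

    Identical ``params`` (including the seed) give identical corpora across
    runs and platforms; all stochastic choices flow through one seeded
    integer-based generator.
    """
    rng = np.random.default_rng(params.seed)
    m = params.assessments_per_client
    course_days = params.assessment_spacing_days * m
    base_date = pd.Timestamp(datetime(2017, 1, 1))

    n_therapists = max(1, round(params.n_clients / params.clients_per_therapist))
    client_ids = [f"c{i:05d}" for i in range(params.n_clients)]
    therapist_ids = [f"t{i:04d}" for i in range(n_therapists)]
    assignment = [therapist_ids[i % n_therapists] for i in range(params.n_clients)]

    d_i = rng.normal(params.mu_d, params.sigma_between, params.n_clients)
    o_i = rng.normal(params.mu_d, params.sigma_between, params.n_clients)
    u_i = rng.normal(0.0, params.sigma_intercept, params.n_clients)

    clients = pd.DataFrame(
        {"client_id": client_ids, "therapist_id": assignment,
         "d_i": d_i, "o_i": o_i, "u_i": u_i}
    )

    msg_rows, win_rows, assess_rows, truth_msg_rows = [], [], [], []
    n_lat, n_lat_clipped = 0, 0
    n_sym, n_sym_clipped = 0, 0
    msg_counter = 0

    for ci, cid in enumerate(client_ids):
        tid = assignment[ci]
        days = _assessment_days(params, rng)
        taus = days / course_days
        w_c = rng.normal(0.0, params.sigma_within, m)
        w_t = rng.normal(0.0, params.sigma_within, m)
        eps = rng.normal(0.0, params.sigma_symptom, m)
        prev_day = 0
        for k in range(m):
            d_ik = d_i[ci] + params.gamma_time * taus[k] + w_c[k]
            o_ik = o_i[ci] + params.gamma_time * taus[k] + w_t[k]
            y = (params.beta0
                 + params.beta_within * (d_ik - d_i[ci])
                 + params.beta_between * (d_i[ci] - params.mu_d)
                 + params.c_prime * taus[k]
                 + u_i[ci] + eps[k])
            n_sym += 1
            if params.round_symptoms:
                internalizing = int(np.clip(round(y), 0, 45))
                if y < -0.5 or y > 45.5:
                    n_sym_clipped += 1
            else:
                internalizing = y
            win_rows.append((cid, k + 1, int(days[k]), float(taus[k]),
                             float(d_ik), float(o_ik), float(y), internalizing))
            phq8 = int(np.clip(round(internalizing * 24.0 / 45.0), 0, 24)) \
                if params.round_symptoms else None
            assess_rows.append((cid, base_date + pd.Timedelta(days=int(days[k])),
                                internalizing, phq8))

            for role, latent_raw, n_msgs in (
                ("client", d_ik, params.messages_per_window),
                ("therapist", o_ik, params.messages_per_window_therapist),
            ):
                if params.poisson_messages:
                    count = int(rng.poisson(n_msgs))
                else:
                    count = n_msgs
                if count == 0:
                    continue
                latent = float(np.clip(latent_raw, 0.0, 1.0))
                n_lat += 1
                if latent != latent_raw:
                    n_lat_clipped += 1
                lo = prev_day + 1 if k > 0 else 0
                mdays = np.sort(rng.integers(lo, days[k] + 1, size=count))
                if k == 0 and role == "client":
                    mdays[0] = 0  # anchor the dyad's first-message date
                for md in mdays:
                    mid = f"m{msg_counter:07d}"
                    msg_counter += 1
                    text = generate_message_text(
                        latent, rng, params.p_no_verbs, params.p_no_pronouns
                    )
                    msg_rows.append((mid, cid, tid, role,
                                     base_date + pd.Timedelta(days=int(md)),
                                     text))
                    truth_msg_rows.append((mid, cid, k + 1, role, latent))
            prev_day = int(days[k])

    messages = pd.DataFrame(
        msg_rows, columns=["message_id", "client_id", "therapist_id",
                           "author_role", "timestamp", "text"]
    )
    windows = pd.DataFrame(
        win_rows, columns=["client_id", "window_index", "day", "tau", "d_ik",
                           "o_ik", "symptom_continuous", "internalizing"]
    )
    if params.round_symptoms:
        assessments = pd.DataFrame(
            assess_rows, columns=["client_id", "date", "internalizing", "phq8"]
        )
        assessments["gad7"] = assessments["internalizing"] - assessments["phq8"]
    else:
        # continuous-output mode keeps the linear outcome for estimator
        # studies; such corpora are in-memory objects (the questionnaire
        # split is not meaningful and the tables are not written to disk)
        assessments = pd.DataFrame(
            assess_rows, columns=["client_id", "date", "internalizing", "phq8"]
        )
        assessments["phq8"] = 0.0
        assessments["gad7"] = assessments["internalizing"]

    first = messages.groupby("client_id")["timestamp"].min()
    dyads = clients[["client_id", "therapist_id"]].copy()
    dyads["first_message_date"] = dyads["client_id"].map(first).values
    assessments["days_in_treatment"] = (
        assessments["date"] - assessments["client_id"].map(first)
    ).dt.days

    corpus = Corpus(messages=messages,
                    assessments=assessments[
                        ["client_id", "date", "phq8", "gad7", "internalizing",
                         "days_in_treatment"]],
                    dyads=dyads)
    truth_messages = pd.DataFrame(
        truth_msg_rows,
        columns=["message_id", "client_id", "window_index", "role", "latent"],
    )
    truth = LatentTruth(
        params=params, clients=clients, windows=windows,
        messages=truth_messages,
        clip_rate_latent=n_lat_clipped / max(n_lat, 1),
        clip_rate_symptom=n_sym_clipped / max(n_sym, 1),
    )
    return corpus, truth


def theoretical_effects(params: SimParams) -> dict:
    """Ground-truth coefficients and the implied proportion mediated.

    With time as predictor and latent distancing as mediator, the a path is
    the latent time slope ``gamma_time``, the b path is ``beta_within``, and
    the direct effect is ``c_prime``; proportion mediated is
    ``100 * a*b / (a*b + c')``, undefined when the denominator vanishes.
    """
    a = params.gamma_time
    b = params.beta_within
    denom = a * b + params.c_prime
    out = {
        "beta_within": params.beta_within,
        "beta_between": params.beta_between,
        "a": a,
        "b": b,
        "c_prime": params.c_prime,
        "indirect": a * b,
    }
    if abs(denom) < 1e-12:
        out["proportion_mediated"] = float("nan")
        out["proportion_mediated_defined"] = False
    else:
        out["proportion_mediated"] = 100.0 * a * b / denom
        out["proportion_mediated_defined"] = True
    return out


def _mean_inverse_truncated_binomial(n: int, q: float) -> float:
    """E[1/K | K >= 1] for K ~ Binomial(n, q)."""
    from scipy.stats import binom

    ks = np.arange(1, n + 1)
    pmf = binom.pmf(ks, n, q)
    tot = pmf.sum()
    if tot <= 0:
        return np.inf
    return float((pmf / tot / ks).sum())


def expected_standardized_effects(params: SimParams) -> dict:
    """Large-sample standardized within/between coefficients for the
    word-count pipeline.

    Accounts for the three gaps between the latent truth and what the
    pipeline observes: (1) binomial measurement noise of the per-window
    word-count mean (a message's composite is the mean of two Bernoulli
    draws at the window latent, averaged over the window's defined
    messages), which attenuates both coefficients; (2) the latent time
    trend, which inflates within-person predictor variance and, because the
    symptoms model omits time, confounds the within coefficient; (3)
    rounding of symptoms, which adds variance 1/12 to the outcome.
    Exact only without assessment-date jitter and with negligible clipping.
    """
    p = params
    m = p.assessments_per_client
    taus = p.assessment_spacing_days * np.arange(1, m + 1) / (
        p.assessment_spacing_days * m
    )
    v_tau = float(np.mean((taus - taus.mean()) ** 2))
    q_defined = 1.0 - p.p_no_verbs - p.p_no_pronouns
    e_inv_n = _mean_inverse_truncated_binomial(p.messages_per_window, q_defined)
    mu_k = p.mu_d + p.gamma_time * taus
    var_d = p.sigma_between ** 2 + p.sigma_within ** 2
    e_d_oneminus = float(np.mean(mu_k * (1 - mu_k)) - var_d)
    v_meas = e_d_oneminus * e_inv_n / 2.0  # per-window measurement variance

    r = 1.0 / 12.0 if p.round_symptoms else 0.0
    f = (m - 1) / m

    var_lat_w = p.gamma_time ** 2 * v_tau + p.sigma_within ** 2 * f
    var_x_w = var_lat_w + v_meas * f
    cov_w = p.beta_within * var_lat_w + p.c_prime * p.gamma_time * v_tau
    b_w = cov_w / var_x_w
    var_y_w = (p.beta_within ** 2 * p.sigma_within ** 2 * f
               + (p.beta_within * p.gamma_time + p.c_prime) ** 2 * v_tau
               + (p.sigma_symptom ** 2 + r) * f)
    beta_w_std = b_w * np.sqrt(var_x_w / var_y_w)

    var_x_b = p.sigma_between ** 2 + (p.sigma_within ** 2 + v_meas) / m
    cov_b = (p.beta_between * p.sigma_between ** 2
             + p.beta_within * p.sigma_within ** 2 / m)
    b_b = cov_b / var_x_b
    var_y_b = (p.beta_between ** 2 * p.sigma_between ** 2
               + p.beta_within ** 2 * p.sigma_within ** 2 / m
               + p.sigma_intercept ** 2
               + (p.sigma_symptom ** 2 + r) / m)
    beta_b_std = b_b * np.sqrt(var_x_b / var_y_b)

    return {
        "beta_within_raw": b_w,
        "beta_between_raw": b_b,
        "beta_within_std": float(beta_w_std),
        "beta_between_std": float(beta_b_std),
        "measurement_variance": v_meas,
    }
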