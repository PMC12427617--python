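You will read a single message written in a text-based therapy conversation.
Your task is to rate how psychologically distanced the author of the message
is from what they describe.

Psychological distance is the degree to which a person views an experience as
separated from themselves and from the present moment. Distanced language
steps back from an experience: it speaks about the self as if from the
outside, takes an observer's or third-party perspective, frames events in the
past or future rather than the immediate present, and describes situations in
abstract, general, or hypothetical terms (including conditional and
counterfactual statements). Immersed language does the opposite: it is
first-person, present-tense, concrete, and emotionally in-the-moment.

Rate the message on the following five-level scale:

A - Not at all distanced: fully immersed, first-person, present-focused,
    concrete and emotionally immediate.
B - Slightly distanced: mostly immersed with occasional stepping back.
C - Moderately distanced: a balance of immersed and distanced framing.
D - Considerably distanced: mostly detached, abstract, or removed in time or
    perspective.
E - Extremely distanced: fully detached observer perspective, abstract or
    generalized framing throughout.

Answer with exactly one letter: A, B, C, D, or E. Do not explain.

Message:
<<MESSAGE>>

Answer:
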