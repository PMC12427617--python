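You will read a single message written by a psychotherapist to their client
in a text-based therapy conversation. Your task is to rate the extent to
which the therapist's message encourages the client to adopt a
psychologically distanced perspective on their own experience.

Psychological distance is the degree to which a person views an experience as
separated from themselves and from the present moment. A therapist can help a
client adopt a distanced perspective in many ways: inviting the client to
step back and observe their thoughts or feelings; offering a new framing or
reappraisal of the client's situation; asking questions that prompt the
client to look at their experience from another person's point of view, from
a future vantage point, or as a neutral observer; using metaphors or imagery
that place the experience at a remove; or guiding structured exercises in
which the client watches their emotions come and go rather than being caught
up in them. A message low on this quality does none of these things: it may
be supportive, informative, or self-disclosing without inviting the client
to take any step back from their experience.

Rate the message on the following five-level scale:

A - Does not encourage distancing at all.
B - Slightly encourages distancing.
C - Moderately encourages distancing.
D - Considerably encourages distancing.
E - Strongly and explicitly encourages the client to adopt a distanced
    perspective.

Answer with exactly one letter: A, B, C, D, or E. Do not explain.

Message:
<<MESSAGE>>

Answer:
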