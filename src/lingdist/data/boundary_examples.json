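{
  "description": "Paraphrased client-message worked examples at the floor and ceiling of the word-count composite: the first three score 0.00 and the last three 10.0 on the 0-10 display scale.",
  "examples": [
    {
      "name": "floor-1",
      "text": "No matter how the job turns out, it’s just a tool, not a goal. It’s primarily about finances and being able to afford things, rather than being part of my identity."
    },
    {
      "name": "floor-2",
      "text": "Every now and then, I feel oddly detached, as though I’m witnessing my own life from a distance, fully aware it’s me but feeling as if I’m on the outside looking in."
    },
    {
      "name": "floor-3",
      "text": "My lawyer and accountant are puzzled by this situation. This process is typically a standard part of any transaction."
    },
    {
      "name": "ceiling-1",
      "text": "[-] spent the day at the gym and then joined Mom and her parents for a film shoot! It was such an awesome experience!"
    },
    {
      "name": "ceiling-2",
      "text": "On Saturday, we slept in, went to yoga, and played cards—it was such a blast! Overall, it turned out to be a fantastic weekend. Haha!"
    },
    {
      "name": "ceiling-3",
      "text": "We had a fantastic time at a concert tonight! The performances were outstanding, and it was so enjoyable to share the evening together."
    }
  ]
}
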