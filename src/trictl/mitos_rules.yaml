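# MITOS staging: a functional domain counts as compromised when its trigger
# holds on the ALSFRS-R question scores. Stage = number of compromised
# domains (0-4); 5 denotes death. Kept as data so clinical corrections need
# no code change.
movement:
  any_of:
    - {question: Q8, max: 1}   # walking
    - {question: Q6, max: 1}   # dressing / self-care
swallowing:
  any_of:
    - {question: Q3, max: 1}
communicating:
  all_of:
    - {question: Q1, max: 1}   # speech
    - {question: Q4, max: 1}   # handwriting
breathing:
  any_of:
    - {question: Q10, max: 1}  # dyspnea
    - {question: Q12, max: 2}  # respiratory insufficiency
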