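task: concept-medication
preamble: |
  You are reviewing a single constructed concept extracted from an intensive
  care unit electronic health record. Each concept names its source table and
  the descriptive values recorded there.

  Definitions of the medications of interest:
  {definitions}

  Constructed concept to review:
  {payload}
cot_questions:
  - "Q1: Does the concept name a drug, and from which source table?"
  - "Q2: Is the drug a rapid sequence intubation agent, a neuromuscular blocking agent, or a continuous sedative infusion?"
  - "Q3: Is the drug instead used for an indication unrelated to airway management, such as cardiovascular or metabolic care?"
final_question: "FINAL ANSWER (YES or NO):"
answer_vocabulary: ["YES", "NO"]
placeholders:
  definitions: >-
    Medications of interest are those used for pre-intubation,
    intra-intubation, or post-intubation care: rapid sequence intubation
    agents (e.g., etomidate, ketamine, succinylcholine), neuromuscular
    blocking agents (e.g., rocuronium, vecuronium, cisatracurium), and
    continuous sedative infusions (e.g., propofol, fentanyl, midazolam,
    dexmedetomidine).
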