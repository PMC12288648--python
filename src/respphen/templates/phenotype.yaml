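task: phenotype
preamble: |
  You are classifying one intensive care unit encounter by the respiratory
  support therapies it received. Below is the encounter's constructed
  description: every relevant constructed concept, numbered by the order of
  its first occurrence after ICU admission.

  Therapy criteria:
  {criteria}

  Constructed description:
  {payload}

  The eight possible phenotypes are: IMV Only; NIPPV Only; HFNI Only;
  NIPPV Failure; HFNI Failure; IMV to NIPPV; IMV to HFNI; None.
cot_questions:
  - "Q1: Which numbered concepts indicate invasive mechanical ventilation (IMV), and which indicate an intubation-related medication?"
  - "Q2: Which numbered concepts indicate noninvasive positive pressure ventilation (NIPPV) or high-flow nasal insufflation (HFNI)?"
  - "Q3: Applying the therapy criteria, which therapies were actually received? Ignore noninvasive concepts that occur between the first and last IMV concepts."
  - "Q4: Using the first-occurrence numbering, which therapy started first?"
final_question: "FINAL PHENOTYPE:"
answer_vocabulary:
  - IMV Only
  - NIPPV Only
  - HFNI Only
  - NIPPV Failure
  - HFNI Failure
  - IMV to NIPPV
  - IMV to HFNI
  - None
placeholders:
  criteria: >-
    IMV was received when at least two concepts indicate IMV and at least one
    concept indicates an intubation-related medication. A noninvasive therapy
    was received when at least two concepts indicate NIPPV or HFNI; it counts
    as HFNI when at least one of them indicates HFNI, and as NIPPV otherwise.
    A noninvasive therapy followed by IMV is a failure phenotype; IMV followed
    by a noninvasive therapy is an IMV-to-noninvasive phenotype; no qualifying
    therapy is None.
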