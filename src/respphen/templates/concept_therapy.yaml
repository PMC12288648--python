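task: concept-therapy
preamble: |
  You are reviewing a single constructed concept extracted from an intensive
  care unit electronic health record. Each concept names its source table and
  the descriptive values recorded there.

  Definitions of the respiratory support therapies of interest:
  {definitions}

  Constructed concept to review:
  {payload}
cot_questions:
  - "Q1: Which source table does this concept come from, and what kind of documentation does that table usually hold?"
  - "Q2: Does the concept describe equipment, a device, a setting, or a procedure used to support breathing?"
  - "Q3: If it does, which of invasive mechanical ventilation (IMV), noninvasive positive pressure ventilation (NIPPV), or high-flow nasal insufflation (HFNI) does it indicate?"
  - "Q4: Could the concept instead describe routine monitoring or care unrelated to any of the three therapies?"
final_question: "FINAL ANSWER (YES or NO):"
answer_vocabulary: ["YES", "NO"]
placeholders:
  definitions: >-
    IMV is ventilation delivered through an endotracheal or tracheostomy tube
    by a mechanical ventilator. NIPPV is positive-pressure ventilation
    delivered through a tight-fitting mask, such as BiPAP or CPAP. HFNI is
    heated, humidified oxygen delivered at high flow rates through nasal
    cannulae, such as "Hi Flow NC" devices.
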