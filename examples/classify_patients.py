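"""Classify individual questionnaires with the default rule table.

Builds three patients — the three published worked assignments — plus a
screen-negative one, and prints what the algorithm returns for each.
"""

from edscreen import ScoffResponse, classify, default_rule_table

table = default_rule_table()

patients = [
    # (label, answers (sick, control, one_stone, fat, food), BMI)
    ("weight loss + feels fat, BMI 16.5", (0, 0, 1, 1, 0), 16.5),
    ("vomits + loss of control, BMI 21", (1, 1, 0, 0, 0), 21.0),
    ("loss of control + food dominates, BMI 34", (0, 1, 0, 0, 1), 34.0),
    ("only one positive answer, BMI 22", (0, 1, 0, 0, 0), 22.0),
]

for label, bits, bmi in patients:
    result = classify(ScoffResponse.from_pattern(bits), bmi, table)
    category = result.category.value if result.category else "none (screen negative)"
    print(f"{label:45s} -> {result.bmi_class.label:12s} {category}")

print()
print("RD = restrictive, BD = bulimic, HD = hyperphagic, OED = other eating")
print("disorder. Fewer than 2 positive answers is a negative screen and gets")
print("no category; everyone else gets the rule-table cell for their answer")
print("pattern and BMI class.")
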