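"""Build the paper-based lexical-decision schedule and inspect its structure.

Prints the schedule counts (total stimuli, reference items, analyzable
items) and demonstrates the nonword construction rule: vowels are replaced
by different vowels, consonants stay in place, "u" after "q" is kept, and
umlauts become plain vowels.
"""

import numpy as np

from pendiff import ExperimentDesign, build_design, make_nonword

rng = np.random.default_rng(0)
design = ExperimentDesign()  # 67 sessions x 3 pages x 11 items
schedule = build_design(design, rng)

n_ref = sum(s.is_reference for s in schedule)
print(f"stimuli scheduled : {len(schedule)}")   # 2211
print(f"reference items   : {n_ref}")           # 201 (first item of each page)
print(f"analyzable items  : {len(schedule) - n_ref}")  # 2010

print("\nfirst page of session 1:")
for s in schedule[:5]:
    ref = " (reference)" if s.is_reference else ""
    print(f"  slot {s.slot}: {s.text:8s} {s.condition}{ref}")

print("\nnonword rule examples:")
for word in ["Miete", "Quark", "Földe", "Krnst"]:
    print(f"  {word} -> {make_nonword(word, rng)}")
# The reference item anchors the page's timing: it never receives a response
# time, every later item's RT runs from the previous item's pen-up.
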