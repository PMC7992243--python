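"""Recover integer confusion tables from published summary percentages.

A validation study reports only four one-decimal percentages per cohort
of 50.  Exhaustive enumeration of all integer 2x2 tables summing to 50
shows which tables could have produced them — and whether the printed
narrative (counts of false negatives/positives) is arithmetically
consistent with the printed metrics.
"""

from ardscreen import diagnostics, reconstruct_tables

# derivation-style: narrative fixes 2 false negatives and 0 false
# positives; sensitivity 91.3% then pins the table uniquely
tables = reconstruct_tables(50, fixed={"fn": 2, "fp": 0},
                            targets={"sensitivity": 91.3})
print("derivation-style (fn=2, fp=0, sens 91.3):", tables)
print("  metrics:", diagnostics(tables[0]).as_dict())

# validation-style: the four percentages alone identify one table
targets = {"sensitivity": 94.4, "specificity": 96.9, "ppv": 94.4, "npv": 96.9}
tables = reconstruct_tables(50, targets=targets)
print("\nvalidation-style (metrics only):", tables)

# a narrative of "2 patients, both false negatives" cannot coexist with
# specificity 96.9% (< 100% forces at least one false positive):
inconsistent = reconstruct_tables(50, fixed={"fn": 2, "fp": 0},
                                  targets={"sensitivity": 94.4, "specificity": 96.9})
print("\ntables with fn=2, fp=0 AND specificity 96.9:", inconsistent)
print("(empty: those constraints are mutually inconsistent)")
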