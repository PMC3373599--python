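"""Condition labels shared across the package.

A search target is unique in color (C), orientation (O), motion direction
(M), or redundantly in two of these (CO, MO, CM).  Each double-feature
condition is modelled as a race between the two corresponding single-feature
racers plus one conjunctive racer.
"""

CONDITIONS = ("C", "O", "M", "CO", "MO", "CM")
SINGLE_CONDITIONS = ("C", "O", "M")
DOUBLE_CONDITIONS = ("CO", "MO", "CM")

#: single-feature racers participating in each double-feature race
RACE_SINGLES = {"CO": ("C", "O"), "MO": ("M", "O"), "CM": ("C", "M")}
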