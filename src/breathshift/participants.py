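"""Study-participant table for the two-cohort cold-pressor breath study.

Discovery cohort: 19 healthy adults (Basel, Switzerland); validation cohort:
21 healthy adults (Guangzhou, China).  Ages are in years at enrollment.
"""

from __future__ import annotations

import pandas as pd

_DISCOVERY = [
    ("male", 21.7), ("female", 27.9), ("female", 26.4), ("male", 40.1),
    ("male", 22.4), ("female", 22.8), ("female", 55.4), ("female", 28.5),
    ("male", 20.5), ("male", 27.5), ("male", 27.0), ("female", 22.4),
    ("female", 22.9), ("female", 24.7), ("female", 27.1), ("male", 18.7),
    ("female", 23.5), ("female", 47.7), ("female", 39.7),
]

_VALIDATION = [
    ("male", 31.0), ("male", 24.2), ("female", 24.0), ("female", 30.7),
    ("female", 29.1), ("male", 23.9), ("female", 25.3), ("male", 23.4),
    ("male", 27.3), ("female", 23.9), ("male", 31.2), ("male", 23.9),
    ("male", 23.8), ("male", 26.7), ("male", 24.4), ("male", 23.3),
    ("female", 24.6), ("female", 28.7), ("female", 22.1), ("female", 24.2),
    ("male", 28.5),
]


def load_participants() -> pd.DataFrame:
    """Participant demographics: columns ``cohort``, ``sex``, ``age_years``."""
    rows = [("discovery", s, a) for s, a in _DISCOVERY] + [
        ("validation", s, a) for s, a in _VALIDATION
    ]
    return pd.DataFrame(rows, columns=["cohort", "sex", "age_years"])


def sex_contingency_table(participants: pd.DataFrame) -> list[list[int]]:
    """2x2 male/female counts per cohort, rows = cohorts."""
    out = []
    for cohort in ("discovery", "validation"):
        sub = participants[participants["cohort"] == cohort]
        out.append([int((sub["sex"] == "male").sum()), int((sub["sex"] == "female").sum())])
    return out
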