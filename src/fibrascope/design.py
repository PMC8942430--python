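"""Crossover-design bookkeeping.

The trial design is a 2-arm, 2-period crossover: every subject consumes both
the multi-fiber (MF) and the control (CTL) bread for one period each, in the
order given by their randomized sequence, with profiled visits before and
after each period.  Visit labels follow the study convention: V2/V4 bracket
period 1 and V5/V7 bracket period 2; V2 and V5 are pre-intervention, V4 and
V7 post-intervention.
"""

from __future__ import annotations

import pandas as pd

from .errors import ReferenceError_

MULTI_FIBER = "multi_fiber"
CONTROL = "control"
BREADS = (MULTI_FIBER, CONTROL)

SEQ_MF_FIRST = "MF-then-CTL"
SEQ_CTL_FIRST = "CTL-then-MF"

VISITS = ("V2", "V4", "V5", "V7")
VISIT_PERIOD = {"V2": 1, "V4": 1, "V5": 2, "V7": 2}
VISIT_PHASE = {"V2": "pre", "V4": "post", "V5": "pre", "V7": "post"}

DESIGN_COLUMNS = ["sample_id", "subject_id", "sequence", "visit", "period", "phase", "bread"]


def bread_for(sequence: str, period: int) -> str:
    """Bread consumed by a subject of the given sequence in the given period."""
    if sequence == SEQ_MF_FIRST:
        return MULTI_FIBER if period == 1 else CONTROL
    if sequence == SEQ_CTL_FIRST:
        return CONTROL if period == 1 else MULTI_FIBER
    raise ReferenceError_(f"unknown sequence: {sequence!r}")


def build_design(subject_sequences: dict[str, str]) -> pd.DataFrame:
    """Expand subject→sequence assignments into one row per profiled visit.

    Returns a DataFrame with columns ``sample_id, subject_id, sequence,
    visit, period, phase, bread``; ``sample_id`` is ``{subject}_{visit}``.
    """
    rows = []
    for subject, seq in subject_sequences.items():
        for visit in VISITS:
            period = VISIT_PERIOD[visit]
            rows.append({
                "sample_id": f"{subject}_{visit}",
                "subject_id": subject,
                "sequence": seq,
                "visit": visit,
                "period": period,
                "phase": VISIT_PHASE[visit],
                "bread": bread_for(seq, period),
            })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def arm_samples(design: pd.DataFrame, bread: str) -> pd.DataFrame:
    """Rows of `design` belonging to one bread arm, with a ``phase`` column."""
    if bread not in BREADS:
        raise ReferenceError_(f"unknown bread: {bread!r}")
    return design[design["bread"] == bread]


def paired_samples(design: pd.DataFrame, bread: str) -> pd.DataFrame:
    """Subjects × {pre, post} sample_id table for one bread arm.

    Subjects missing either visit are dropped.
    """
    arm = arm_samples(design, bread)
    wide = arm.pivot(index="subject_id", columns="phase", values="sample_id")
    return wide.dropna()[["pre", "post"]]
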