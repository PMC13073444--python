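"""Triage label space.

The three-class urgency scale used throughout the package. The integer
values fix the class order (GREEN, YELLOW, RED) everywhere: confusion
matrix axes, logit/count vectors, and tie-breaking all rely on it.
"""

from __future__ import annotations

from enum import IntEnum


class TriageLabel(IntEnum):
    """Clinical urgency of one report segment, in increasing order.

    GREEN
        No clinically significant abnormality (normal findings or an
        explicit statement of absence).
    YELLOW
        Non-urgent pathological finding — benign or indeterminate lesions
        needing follow-up or clinical correlation.
    RED
        Urgent or potentially urgent finding (hematoma, abscess,
        suspected malignancy, escalation language) needing prompt
        further evaluation.
    """

    GREEN = 0
    YELLOW = 1
    RED = 2

    @classmethod
    def parse(cls, value: "int | str | TriageLabel") -> "TriageLabel":
        """Coerce an int index or a (case-insensitive) name to a label."""
        if isinstance(value, TriageLabel):
            return value
        if isinstance(value, str):
            try:
                return cls[value.strip().upper()]
            except KeyError:
                raise ValueError(f"unknown triage label: {value!r}") from None
        return cls(int(value))


#: Class names in canonical order; index == TriageLabel value.
CLASS_NAMES: tuple[str, str, str] = ("GREEN", "YELLOW", "RED")

#: Number of triage classes.
N_CLASSES = 3
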