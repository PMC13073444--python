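"""Leakage-controlled train/validation/test partitioning.

Two strategies are provided. The *group* (patient-level) split assigns
whole patients to partitions so no patient's reports straddle a
partition boundary — the leakage control needed when near-identical
templates recur within a patient. The *stratified* split preserves the
class mix per partition (to within one segment per class) and is
appropriate when every segment belongs to a distinct patient.

Partition sizes follow a fixed rounding convention: the test size is the
ceiling of its fraction, the train size the floor of its own, and
validation takes the remainder. For n = 394 with fractions 80/10/10 this
yields 315/39/40.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import SegmentCorpus

__all__ = [
    "SplitAssignment",
    "derive_patient_id",
    "partition_sizes",
    "group_split",
    "stratified_split",
    "verify_disjoint",
    "PARTITIONS",
]

PARTITIONS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class SplitAssignment:
    """segment_id -> partition mapping plus the generating recipe."""

    assignment: dict[str, str]
    strategy: str
    seed: int
    fractions: tuple[float, float, float]

    def partition(self, corpus: SegmentCorpus, name: str) -> SegmentCorpus:
        """Materialize one partition as a sub-corpus (corpus order kept)."""
        if name not in PARTITIONS:
            raise ValueError(f"unknown partition {name!r}")
        segs = [s for s in corpus.segments if self.assignment[s.segment_id] == name]
        return SegmentCorpus(segments=segs, dedup_policy=corpus.dedup_policy)

    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in PARTITIONS}
        for p in self.assignment.values():
            out[p] += 1
        return out

    def to_frame(self, corpus: SegmentCorpus) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in corpus.segments],
                "patient_id": [s.patient_id for s in corpus.segments],
                "partition": [self.assignment[s.segment_id] for s in corpus.segments],
            }
        )


def derive_patient_id(filename: str) -> str:
    """Leading numeric token of a report filename's basename.

    Report files are named with the patient number first (e.g.
    ``12345_report.pdf`` -> ``"12345"``). Raises ValueError when the
    basename does not start with a digit.
    """
    if not filename:
        raise ValueError("empty filename")
    base = Path(filename).name
    m = re.match(r"\d+", base)
    if m is None:
        raise ValueError(f"no leading numeric token in filename {base!r}")
    return m.group(0)


def _check_fractions(fractions: Sequence[float]) -> tuple[float, float, float]:
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three positive reals summing to 1: {fr}")
    return fr  # type: ignore[return-value]


def partition_sizes(
    n: int, fractions: Sequence[float] = DEFAULT_FRACTIONS
) -> tuple[int, int, int]:
    """(n_train, n_val, n_test) under the ceil-test / floor-train rule."""
    f_train, f_val, f_test = _check_fractions(fractions)
    if n < 3:
        raise ValueError(f"need at least 3 segments, got {n}")
    n_test = math.ceil(f_test * n)
    n_train = math.floor(f_train * n)
    n_val = n - n_train - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError(f"infeasible sizes for n={n}, fractions={fractions}")
    return n_train, n_val, n_test


def group_split(
    corpus: SegmentCorpus,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 42,
) -> SplitAssignment:
    """Patient-level split: whole patients shuffled into partitions.

    Patients are shuffled with a seeded generator and assigned whole,
    filling test first, then validation, then train, against the target
    sizes of :func:`partition_sizes`. Realized sizes can overshoot a
    target by at most (largest group - 1). Group disjointness holds by
    construction.
    """
    fr = _check_fractions(fractions)
    groups: dict[str, list[str]] = {}
    for s in corpus.segments:
        if not s.patient_id:
            raise ValueError(f"segment {s.segment_id!r} lacks a patient_id")
        groups.setdefault(s.patient_id, []).append(s.segment_id)
    if len(groups) < 3:
        raise ValueError(f"need at least 3 patient groups, got {len(groups)}")
    n = len(corpus.segments)
    n_train, n_val, n_test = partition_sizes(n, fr)
    rng = np.random.default_rng(seed)
    pids = sorted(groups)
    order = rng.permutation(len(pids))
    assignment: dict[str, str] = {}
    filled = {"test": 0, "validation": 0}
    for idx in order:
        members = groups[pids[idx]]
        if filled["test"] < n_test:
            part = "test"
        elif filled["validation"] < n_val:
            part = "validation"
        else:
            part = "train"
        if part in filled:
            filled[part] += len(members)
        for sid in members:
            assignment[sid] = part
    return SplitAssignment(assignment=assignment, strategy="group_shuffle",
                           seed=seed, fractions=fr)


def _apportion(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n into (train, val, test).

    Ties and leftover units favor test, then validation, mirroring the
    global ceil-test convention.
    """
    quotas = [f * n for f in fractions]
    base = [math.floor(q) for q in quotas]
    remainder = n - sum(base)
    # order: remainder desc, then test > validation > train
    priority = sorted(
        range(3), key=lambda i: (-(quotas[i] - base[i]), -i)
    )
    for i in priority[:remainder]:
        base[i] += 1
    return tuple(base)  # type: ignore[return-value]


def stratified_split(
    corpus: SegmentCorpus,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 42,
) -> SplitAssignment:
    """Class-preserving split; requires every segment to be labeled.

    Each class is apportioned independently by largest remainder, so
    per-partition class proportions deviate from the corpus proportions
    by at most one segment per class. Raises when a class has fewer
    segments than partitions.
    """
    fr = _check_fractions(fractions)
    by_class: dict[int, list[str]] = {}
    for s in corpus.segments:
        if s.label is None:
            raise ValueError(f"segment {s.segment_id!r} is unlabeled")
        by_class.setdefault(int(s.label), []).append(s.segment_id)
    if len(by_class) < 2:
        raise ValueError("degenerate corpus: fewer than two classes present")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for c in sorted(by_class):
        sids = by_class[c]
        if len(sids) < len(PARTITIONS):
            raise ValueError(
                f"class {c} has {len(sids)} segments, fewer than "
                f"{len(PARTITIONS)} partitions"
            )
        tr, va, te = _apportion(len(sids), fr)
        order = rng.permutation(len(sids))
        shuffled = [sids[i] for i in order]
        for sid in shuffled[:tr]:
            assignment[sid] = "train"
        for sid in shuffled[tr : tr + va]:
            assignment[sid] = "validation"
        for sid in shuffled[tr + va :]:
            assignment[sid] = "test"
    return SplitAssignment(assignment=assignment, strategy="stratified",
                           seed=seed, fractions=fr)


def verify_disjoint(assignment: SplitAssignment, corpus: SegmentCorpus) -> bool:
    """True iff no patient occurs in more than one partition.

    Raises when the assignment does not cover the corpus exactly.
    """
    missing = [
        s.segment_id for s in corpus.segments
        if s.segment_id not in assignment.assignment
    ]
    if missing:
        raise ValueError(f"assignment missing segments: {missing[:5]}")
    seen: dict[str, str] = {}
    for s in corpus.segments:
        part = assignment.assignment[s.segment_id]
        prev = seen.setdefault(s.patient_id, part)
        if prev != part:
            return False
    return True
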