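"""Keyword late fusion and the deterministic regex override layer.

Late fusion adds a scaled keyword hit-count vector to the classifier
logits before the arg-max decision: z_fused = z + alpha * K, where K_c
counts occurrences of class-c lexicon phrases in the simplified text and
alpha >= 0 is tuned on the validation split by macro-F1.

The rule layer applies after the (possibly fused) prediction:

* *negative shield* — patterns for explicitly negative examinations
  (e.g. "kitle izlenmedi") force GREEN and block escalation;
* *red force* — patterns for high-risk concepts or escalation language
  (e.g. "hematom", "mrg onerilir") force RED.

When both fire, the negative shield takes precedence: an explicitly
negative report must never be escalated by a stray high-risk token.

The clinician dictionary behind the published system is not public;
seed lists here contain only phrases that are standard negative/high-risk
ultrasound vocabulary, and full inventories load from plain-text files
(one phrase or pattern per line under [GREEN]/[YELLOW]/[RED] or
[NEGATIVE]/[RED_FORCE] section headers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, field_validator

from .classify import predict_label
from .ingest import SegmentCorpus
from .labels import N_CLASSES, TriageLabel
from .text import normalize_text, simplify

__all__ = [
    "KeywordLexicon",
    "FusionConfig",
    "RulePatternSet",
    "compile_lexicon",
    "keyword_counts",
    "fuse",
    "tune_alpha",
    "apply_rules",
    "count_rule_changes",
    "load_phrase_file",
    "load_pattern_file",
    "SEED_PHRASES",
    "SEED_PATTERNS",
    "DEFAULT_ALPHA_GRID",
]

#: Seed phrase lists per class (normalized at compile time).
SEED_PHRASES: dict[str, list[str]] = {
    "GREEN": ["kitle izlenmedi", "lezyon saptanmadı"],
    "YELLOW": ["ganglion", "kist"],
    "RED": ["hematom", "apse", "MRG önerilir"],
}

#: Seed regex patterns for the rule layer (matched on simplified text).
SEED_PATTERNS: dict[str, list[str]] = {
    "NEGATIVE": [r"kitle izlenmedi", r"lezyon saptanmadi"],
    "RED_FORCE": [r"hematom", r"apse", r"mrg onerilir"],
}

#: Default fusion-weight grid: 0 to 3 in steps of 0.25, including 0.
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    round(0.25 * i, 2) for i in range(13)
)


@dataclass(frozen=True)
class KeywordLexicon:
    """Compiled, priority-resolved phrase lists (GREEN, YELLOW, RED).

    Phrases are normalized and simplified; the three lists are pairwise
    disjoint after compilation.
    """

    phrases: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]

    def is_empty(self) -> bool:
        return not any(self.phrases)


class FusionConfig(BaseModel):
    """Fusion weight and the candidate grid used for tuning."""

    alpha: float = 0.0
    grid: tuple[float, ...] = DEFAULT_ALPHA_GRID

    @field_validator("alpha")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("alpha must be >= 0")
        return v

    @field_validator("grid")
    @classmethod
    def _grid_ok(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or 0.0 not in v:
            raise ValueError("alpha grid must be non-empty and include 0")
        return v


def compile_lexicon(
    green: Sequence[str], yellow: Sequence[str], red: Sequence[str]
) -> KeywordLexicon:
    """Normalize, simplify, deduplicate and priority-resolve phrase lists.

    A phrase present in several input lists is retained only in the
    highest-priority one (RED > YELLOW > GREEN), so contradictory
    matches cannot occur. Empty phrases are rejected.
    """
    cleaned: list[list[str]] = []
    for raw_list in (green, yellow, red):
        out, seen = [], set()
        for p in raw_list:
            s = simplify(normalize_text(p))
            if not s:
                raise ValueError(f"empty phrase in lexicon input: {p!r}")
            if s not in seen:
                seen.add(s)
                out.append(s)
        cleaned.append(out)
    red_set = set(cleaned[2])
    yellow = [p for p in cleaned[1] if p not in red_set]
    yellow_set = set(yellow)
    green = [p for p in cleaned[0] if p not in red_set and p not in yellow_set]
    return KeywordLexicon(phrases=(tuple(green), tuple(yellow), tuple(cleaned[2])))


def _count_class(simplified: str, phrases: Sequence[str]) -> int:
    """Non-overlapping, leftmost, longest-first phrase occurrences."""
    if not phrases:
        return 0
    ordered = sorted(phrases, key=len, reverse=True)
    i, count = 0, 0
    n = len(simplified)
    while i < n:
        for ph in ordered:
            if simplified.startswith(ph, i):
                count += 1
                i += len(ph)
                break
        else:
            i += 1
    return count


def keyword_counts(text: str, lexicon: KeywordLexicon) -> np.ndarray:
    """Hit-count vector K = (K_GREEN, K_YELLOW, K_RED) for one text."""
    s = simplify(normalize_text(text))
    return np.array(
        [_count_class(s, lexicon.phrases[c]) for c in range(N_CLASSES)],
        dtype=float,
    )


def keyword_count_matrix(texts: Sequence[str], lexicon: KeywordLexicon) -> np.ndarray:
    return np.vstack([keyword_counts(t, lexicon) for t in texts])


def fuse(z: np.ndarray, K: np.ndarray, alpha: float) -> np.ndarray:
    """Fused logits z + alpha * K (elementwise; alpha=0 is the identity)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    z = np.asarray(z, dtype=float)
    K = np.asarray(K, dtype=float)
    if not (np.isfinite(z).all() and np.isfinite(K).all()):
        raise ValueError("fuse requires finite inputs")
    return z + alpha * K


def tune_alpha(
    backend,
    lexicon: KeywordLexicon,
    validation: SegmentCorpus,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
) -> float:
    """Grid-search the fusion weight by validation macro-F1.

    Ties break toward the smallest alpha, preferring the unfused model;
    in particular an empty lexicon always yields alpha = 0.
    """
    from .metrics import confusion_matrix, macro_f1

    if not list(grid):
        raise ValueError("empty alpha grid")
    if len(validation) == 0:
        raise ValueError("empty validation corpus")
    y_true = [int(l) for l in validation.labels()]
    Z = np.atleast_2d(backend.predict_logits(validation.texts()))
    K = keyword_count_matrix(validation.texts(), lexicon)
    best_alpha, best_f1 = None, -1.0
    for alpha in sorted(float(a) for a in grid):
        preds = [int(predict_label(row)) for row in fuse(Z, K, alpha)]
        f1 = macro_f1(confusion_matrix(y_true, preds))
        if f1 > best_f1 + 1e-12:
            best_alpha, best_f1 = alpha, f1
    return best_alpha


# ---------------------------------------------------------------------------
# Regex rule layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RulePatternSet:
    """Compiled negative-shield and red-force pattern inventories."""

    negative: tuple["re.Pattern[str]", ...] = ()
    red_force: tuple["re.Pattern[str]", ...] = ()

    @classmethod
    def from_lists(
        cls,
        negative: Sequence[str] = (),
        red_force: Sequence[str] = (),
    ) -> "RulePatternSet":
        return cls(
            negative=tuple(re.compile(p) for p in negative),
            red_force=tuple(re.compile(p) for p in red_force),
        )

    @classmethod
    def seed(cls) -> "RulePatternSet":
        return cls.from_lists(SEED_PATTERNS["NEGATIVE"], SEED_PATTERNS["RED_FORCE"])

    def is_empty(self) -> bool:
        return not (self.negative or self.red_force)


def apply_rules(
    base_pred: TriageLabel, text: str, patterns: RulePatternSet
) -> tuple[TriageLabel, bool]:
    """Deterministic override of one prediction.

    Negative shield -> GREEN; else red force -> RED; else unchanged.
    Matching runs on the simplified text; returns (final, changed).
    """
    s = simplify(normalize_text(text))
    if any(p.search(s) for p in patterns.negative):
        final = TriageLabel.GREEN
    elif any(p.search(s) for p in patterns.red_force):
        final = TriageLabel.RED
    else:
        final = TriageLabel.parse(base_pred)
    return final, final != TriageLabel.parse(base_pred)


def count_rule_changes(
    base_preds: Sequence[TriageLabel], final_preds: Sequence[TriageLabel]
) -> int:
    """Number of predictions altered by the rule layer."""
    if len(base_preds) != len(final_preds):
        raise ValueError("prediction sequences differ in length")
    return sum(int(a) != int(b) for a, b in zip(base_preds, final_preds))


# ---------------------------------------------------------------------------
# Plain-text inventories
# ---------------------------------------------------------------------------

def _parse_sectioned(path: str | Path, sections: Sequence[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {s: [] for s in sections}
    current: Optional[str] = None
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = re.fullmatch(r"\[([A-Z_]+)\]", stripped)
        if m:
            if m.group(1) not in out:
                raise ValueError(f"{path}:{lineno}: unknown section {stripped}")
            current = m.group(1)
            continue
        if current is None:
            raise ValueError(f"{path}:{lineno}: entry before any section header")
        out[current].append(stripped)
    return out


def load_phrase_file(path: str | Path) -> KeywordLexicon:
    """Compile a lexicon from a [GREEN]/[YELLOW]/[RED] sectioned file."""
    sec = _parse_sectioned(path, ("GREEN", "YELLOW", "RED"))
    return compile_lexicon(sec["GREEN"], sec["YELLOW"], sec["RED"])


def load_pattern_file(path: str | Path) -> RulePatternSet:
    """Compile rule patterns from a [NEGATIVE]/[RED_FORCE] sectioned file."""
    sec = _parse_sectioned(path, ("NEGATIVE", "RED_FORCE"))
    return RulePatternSet.from_lists(sec["NEGATIVE"], sec["RED_FORCE"])


def seed_lexicon() -> KeywordLexicon:
    """The built-in seed lexicon, compiled."""
    return compile_lexicon(
        SEED_PHRASES["GREEN"], SEED_PHRASES["YELLOW"], SEED_PHRASES["RED"]
    )
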