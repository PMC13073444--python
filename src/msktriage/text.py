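"""Unicode normalization and the simplified search view.

Two text representations are used throughout the pipeline:

* the *normalized* text — NFKC-normalized, whitespace-collapsed — which is
  the canonical form stored for each report segment and used for
  deduplication by exact identity;
* the *simplified* view — additionally case-folded and diacritic-folded —
  used only for pattern matching (section anchors, keyword lexicon, regex
  rules), so that spelling variants such as "Yüzeyel/Yüzeysel Doku" or
  "USG/Ultrasonografi" can be matched with a single ASCII pattern family.

Because matching happens on the simplified view while extracted spans must
refer to the raw text, :func:`build_simplified_view` also returns a
character-level index map from simplified offsets back to raw offsets, so
match boundaries project onto the original text without index drift.
"""

from __future__ import annotations

import unicodedata

__all__ = ["normalize_text", "simplify", "build_simplified_view", "fold_char"]

# Turkish-specific folds applied before the generic accent-stripping
# fallback. The dotted/dotless i pair must not go through casefold()
# (which maps İ to "i" + combining dot) before the table lookup.
_TURKISH_FOLD = {
    "ç": "c", "Ç": "c",
    "ğ": "g", "Ğ": "g",
    "ı": "i", "I": "i",
    "İ": "i", "i": "i",
    "ö": "o", "Ö": "o",
    "ş": "s", "Ş": "s",
    "ü": "u", "Ü": "u",
    "â": "a", "Â": "a",
    "î": "i", "Î": "i",
    "û": "u", "Û": "u",
}


def normalize_text(raw: str) -> str:
    """Canonical segment text: NFKC + whitespace standardization.

    Runs of any Unicode whitespace (line breaks, tabs, non-breaking
    spaces) collapse to a single ASCII space and leading/trailing
    whitespace is removed. Idempotent; empty input yields "".
    """
    return " ".join(unicodedata.normalize("NFKC", raw).split())


def fold_char(ch: str) -> str:
    """Fold one character for the simplified view.

    Turkish diacritics map through an explicit table; everything else is
    case-folded and stripped of combining marks via NFKD. May expand to
    several characters (e.g. "ß" -> "ss") or to none (bare combining
    marks).
    """
    mapped = _TURKISH_FOLD.get(ch)
    if mapped is not None:
        return mapped
    out = []
    for low in ch.casefold():
        for dec in unicodedata.normalize("NFKD", low):
            if unicodedata.combining(dec):
                continue
            out.append(_TURKISH_FOLD.get(dec, dec))
    return "".join(out)


def build_simplified_view(raw: str) -> tuple[str, list[int]]:
    """Build the simplified search view and its simplified->raw index map.

    Returns ``(simplified, index_map)`` where ``index_map[k]`` is the raw
    offset of the character that produced ``simplified[k]``. Offsets are
    non-decreasing; whitespace runs collapse to one space mapped to the
    first whitespace character of the run; leading and trailing
    whitespace is dropped. For raw text that is already lower-ASCII with
    single interior spaces the view is the identity.

    Projecting a simplified span ``[a, b)`` back to raw coordinates as
    ``(index_map[a], index_map[b - 1] + 1)`` yields a raw span whose own
    simplification reproduces the matched substring, provided the span
    boundaries fall on raw character boundaries (always true for spans
    produced by matching whole simplified characters).
    """
    chars: list[str] = []
    imap: list[int] = []
    pending_ws: int | None = None
    for i, ch in enumerate(raw):
        if ch.isspace():
            if chars and pending_ws is None:
                pending_ws = i
            continue
        if pending_ws is not None:
            chars.append(" ")
            imap.append(pending_ws)
            pending_ws = None
        for fc in fold_char(ch):
            chars.append(fc)
            imap.append(i)
    return "".join(chars), imap


def simplify(text: str) -> str:
    """Simplified view without the index map (for pattern compilation)."""
    return build_simplified_view(text)[0]
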