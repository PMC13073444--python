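"""Corpus ingestion: documents -> clean, deduplicated, labeled segments.

One document is one examination report. Each document yields at most one
*report segment*: the free-text findings content located between the main
result heading, a recognized modality sub-header, and the earliest
terminator line (separator / technical note / clinician signature).
Matching runs on the simplified view (see :mod:`msktriage.text`) and
boundaries are projected back through the index map, so anchors written
with Turkish diacritics or spelling variants are all recognized.

Deduplication groups segments by identical normalized text and resolves
label conflicts under one of three policies; ``conservative_yellow`` is
the default triage-safe choice (an identical text annotated both YELLOW
and RED is retained as YELLOW).
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .labels import TriageLabel
from .text import build_simplified_view, normalize_text, simplify

__all__ = [
    "ReportDocument",
    "ReportSegment",
    "SegmentCorpus",
    "DedupSummary",
    "ExtractionConfig",
    "IngestError",
    "extract_segment",
    "deduplicate",
    "read_documents",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_corpus_csv",
    "DEDUP_POLICIES",
]

DEDUP_POLICIES = ("conservative_yellow", "majority_vote", "drop_conflicts", "none")


class IngestError(ValueError):
    """Raised for malformed documents or invalid ingestion configuration."""


@dataclass(frozen=True)
class ReportDocument:
    """One examination report: raw page-wise concatenated text."""

    doc_id: str
    source_filename: str
    raw_text: str
    patient_id: str = ""


@dataclass(frozen=True)
class ReportSegment:
    """One normalized findings segment extracted from a document.

    ``raw_span`` is a 0-based half-open character interval into the
    document's raw text; ``normalize_text(raw_text[start:end]) == text``
    holds for every extracted segment.
    """

    segment_id: str
    doc_id: str
    patient_id: str
    text: str
    label: Optional[TriageLabel] = None
    raw_span: tuple[int, int] = (0, 0)


@dataclass
class DedupSummary:
    """Accounting for one deduplication pass.

    ``n_input == n_retained + n_merged + n_dropped`` always holds:
    merged counts the non-representative members of kept groups, dropped
    counts members of groups removed entirely by the policy.
    """

    policy: str
    n_input: int = 0
    n_retained: int = 0
    n_merged: int = 0
    n_dropped: int = 0
    n_unlabeled: int = 0
    n_conflict_groups: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class SegmentCorpus:
    """An ordered collection of segments plus the dedup policy applied."""

    segments: list[ReportSegment]
    dedup_policy: str = "none"
    summary: Optional[DedupSummary] = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[ReportSegment]:
        return iter(self.segments)

    def texts(self) -> list[str]:
        return [s.text for s in self.segments]

    def labels(self) -> list[TriageLabel]:
        missing = [s.segment_id for s in self.segments if s.label is None]
        if missing:
            raise IngestError(f"unlabeled segments: {missing[:5]}")
        return [s.label for s in self.segments]  # type: ignore[misc]


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionConfig:
    """Anchors for the rule-based segment extractor.

    All entries are matched on the simplified view; list them in plain
    ASCII lowercase. The defaults cover the report anatomy of superficial
    soft-tissue ultrasound reports: a main result heading, a modality
    sub-header with spelling variants, and three terminator families.
    """

    main_heading: str = "tetkik sonucu"
    subheader_bodies: tuple[str, ...] = ("yuzeysel doku", "yuzeyel doku")
    modality_variants: tuple[str, ...] = (
        "ultrasonografisi",
        "ultrasonografi",
        "ultrason",
        "usg",
        "u/s",
        "u.s.",
        "us",
        "u",
        "s",
    )
    technical_note_prefixes: tuple[str, ...] = ("ultrason cihazindan kaynaklanan",)
    signature_titles: tuple[str, ...] = ("uzm. dr.", "prof. dr.", "doc. dr.")
    # a separator line is >=3 repeats of one punctuation character
    separator_pattern: str = r"([-=_*])\1{2,}"

    def subheader_regex(self) -> "re.Pattern[str]":
        bodies = "|".join(re.escape(b) for b in self.subheader_bodies)
        variants = sorted(self.modality_variants, key=len, reverse=True)
        mods = "|".join(re.escape(v) for v in variants)
        return re.compile(rf"({bodies})(\s(?:{mods})\b\.?)?\s?:?")


DEFAULT_EXTRACTION = ExtractionConfig()


def _iter_lines(raw: str) -> Iterator[tuple[int, str]]:
    """Yield (start_offset, line_without_newline) for each raw line."""
    start = 0
    for m in re.finditer(r"\n", raw):
        yield start, raw[start : m.start()]
        start = m.end()
    if start <= len(raw):
        yield start, raw[start:]


def _terminator_start(
    raw: str, from_offset: int, config: ExtractionConfig
) -> int:
    """Raw offset of the earliest terminator line at/after ``from_offset``."""
    sep = re.compile(config.separator_pattern)
    for start, line in _iter_lines(raw):
        if start < from_offset:
            continue
        stripped = line.strip()
        if not stripped:
            continue
        if sep.fullmatch(stripped):
            return start
        sline = simplify(line)
        if any(sline.startswith(p) for p in config.technical_note_prefixes):
            return start
        if any(t in sline for t in config.signature_titles):
            return start
    return len(raw)


def extract_segment(
    doc: ReportDocument, config: ExtractionConfig = DEFAULT_EXTRACTION
) -> Optional[ReportSegment]:
    """Extract the findings segment of one document, or None.

    Returns None when the main heading or a recognized modality
    sub-header is absent (or when nothing but terminators follows them).
    Deterministic: a pure function of ``doc.raw_text`` and the config.
    """
    if not doc.raw_text or not doc.raw_text.strip():
        raise IngestError(f"document {doc.doc_id!r}: empty raw_text")
    simplified, imap = build_simplified_view(doc.raw_text)
    head = simplified.find(config.main_heading)
    if head < 0:
        return None
    m = config.subheader_regex().search(simplified, head + len(config.main_heading))
    if m is None:
        return None
    # raw offset just past the last raw character of the sub-header match
    raw_begin = imap[m.end() - 1] + 1
    raw_end = _terminator_start(doc.raw_text, raw_begin, config)
    if raw_end < raw_begin:
        return None
    text = normalize_text(doc.raw_text[raw_begin:raw_end])
    if not text:
        return None
    return ReportSegment(
        segment_id=f"{doc.doc_id}:seg0",
        doc_id=doc.doc_id,
        patient_id=doc.patient_id,
        text=text,
        label=None,
        raw_span=(raw_begin, raw_end),
    )


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _resolve_conflict_conservative(
    labels: set[TriageLabel], key_preview: str, warnings: list[str]
) -> TriageLabel:
    if TriageLabel.YELLOW in labels:
        return TriageLabel.YELLOW
    resolved = max(labels)  # most urgent present (GREEN-vs-RED -> RED)
    warnings.append(
        "conflict group without YELLOW resolved to "
        f"{resolved.name} ({key_preview!r})"
    )
    return resolved


def deduplicate(
    segments: Iterable[ReportSegment], policy: str = "conservative_yellow"
) -> SegmentCorpus:
    """Collapse identical normalized texts to one representative each.

    Policies for groups whose labels disagree:

    * ``conservative_yellow`` — keep YELLOW (the triage-safe middle
      call); a conflict with no YELLOW resolves to the most urgent label
      present and logs a warning in the summary.
    * ``majority_vote`` — keep the unique modal label; groups without a
      unique mode are dropped entirely.
    * ``drop_conflicts`` — drop every group whose labels disagree.
    * ``none`` — no deduplication; segments pass through unchanged.

    The representative is the member with the lexicographically smallest
    (doc_id, segment_id), for reproducibility. Unlabeled segments carry
    no vote and are counted in ``summary.n_unlabeled``.
    """
    segs = list(segments)
    if policy not in DEDUP_POLICIES:
        raise IngestError(f"unknown dedup policy: {policy!r}")
    summary = DedupSummary(policy=policy, n_input=len(segs))
    if policy == "none":
        summary.n_retained = len(segs)
        summary.n_unlabeled = sum(1 for s in segs if s.label is None)
        return SegmentCorpus(segments=segs, dedup_policy=policy, summary=summary)

    groups: dict[str, list[ReportSegment]] = {}
    for s in segs:
        groups.setdefault(s.text, []).append(s)

    kept: list[ReportSegment] = []
    for text, members in groups.items():
        rep = min(members, key=lambda s: (s.doc_id, s.segment_id))
        votes = [s.label for s in members if s.label is not None]
        distinct = set(votes)
        preview = text[:40]
        if not votes:
            summary.n_unlabeled += 1
            label: Optional[TriageLabel] = None
        elif len(distinct) == 1:
            label = votes[0]
        else:
            summary.n_conflict_groups += 1
            if policy == "conservative_yellow":
                label = _resolve_conflict_conservative(
                    distinct, preview, summary.warnings
                )
            elif policy == "majority_vote":
                counts = Counter(votes).most_common()
                if len(counts) > 1 and counts[0][1] == counts[1][1]:
                    summary.n_dropped += len(members)
                    continue
                label = counts[0][0]
            else:  # drop_conflicts
                summary.n_dropped += len(members)
                continue
        kept.append(dataclasses.replace(rep, label=label))
        summary.n_merged += len(members) - 1
    summary.n_retained = len(kept)
    return SegmentCorpus(segments=kept, dedup_policy=policy, summary=summary)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_pdf_text(path: Path) -> str:
    try:
        import pdfplumber  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise IngestError(
            f"{path.name}: PDF ingestion requires the optional 'pdfplumber' "
            "dependency (pip install msktriage[pdf]); provide .txt documents "
            "otherwise"
        ) from exc
    with pdfplumber.open(path) as pdf:  # pragma: no cover - optional dependency
        return "\n".join(page.extract_text() or "" for page in pdf.pages)


def read_documents(directory: str | Path) -> list[ReportDocument]:
    """Read one document per .txt (or .pdf) file in a directory.

    Page texts of PDFs are concatenated with newlines. The patient
    identifier is the leading numeric token of the filename when present
    (see :func:`msktriage.splitting.derive_patient_id`), else "".
    """
    from .splitting import derive_patient_id

    directory = Path(directory)
    docs: list[ReportDocument] = []
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() == ".txt":
            raw = path.read_text(encoding="utf-8")
        elif path.suffix.lower() == ".pdf":
            raw = _read_pdf_text(path)
        else:
            continue
        if not raw.strip():
            raise IngestError(f"document {path.name!r}: empty raw_text")
        try:
            pid = derive_patient_id(path.name)
        except ValueError:
            pid = ""
        docs.append(
            ReportDocument(
                doc_id=path.stem, source_filename=path.name, raw_text=raw,
                patient_id=pid,
            )
        )
    return docs


def _segment_record(s: ReportSegment) -> dict:
    return {
        "segment_id": s.segment_id,
        "doc_id": s.doc_id,
        "patient_id": s.patient_id,
        "text": s.text,
        "label": None if s.label is None else s.label.name,
        "raw_span": list(s.raw_span),
    }


def write_corpus_jsonl(corpus: SegmentCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.segments:
            fh.write(json.dumps(_segment_record(s), ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: str | Path) -> SegmentCorpus:
    segments = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            segments.append(
                ReportSegment(
                    segment_id=rec["segment_id"],
                    doc_id=rec["doc_id"],
                    patient_id=rec.get("patient_id", ""),
                    text=rec["text"],
                    label=None
                    if rec.get("label") is None
                    else TriageLabel.parse(rec["label"]),
                    raw_span=tuple(rec.get("raw_span", (0, 0))),
                )
            )
    return SegmentCorpus(segments=segments)


def write_corpus_csv(corpus: SegmentCorpus, path: str | Path) -> None:
    pd.DataFrame([_segment_record(s) for s in corpus.segments]).to_csv(
        path, index=False
    )
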