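"""Synthetic ultrasound-report corpora with known ground truth.

The real report corpus behind this pipeline is hospital data and is not
distributable, so every stage is exercised on generated corpora that
reproduce the structural and statistical properties the pipeline
assumes:

* document anatomy — a findings paragraph embedded between a main
  result heading, a modality sub-header (spelling variants, Turkish
  diacritics, mixed case), and a terminator line (separator, technical
  note, or clinician signature), with filenames carrying a leading
  numeric patient token;
* a three-class label mix defaulting to 19/63/18% (GREEN/YELLOW/RED),
  the distribution of routine orthopedic outpatient practice where
  benign or indeterminate findings dominate;
* injected exact-duplicate texts, a configurable fraction of which carry
  conflicting labels, so deduplication policies have known-truth
  outcomes;
* a vocabulary-overlap dial: at 0 the three class phrase banks share no
  content words and the corpus is linearly separable; raising it makes
  segments borrow sentences from the adjacent urgency class, emulating
  the borderline language that drives real GREEN/YELLOW and YELLOW/RED
  confusions.

Two language packs exist: ``turkish_seed`` writes short Turkish findings
built from standard ultrasound vocabulary; ``ascii_abstract`` uses
abstract tokens, demonstrating the pipeline is language-agnostic.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .ingest import (DEFAULT_EXTRACTION, ExtractionConfig, ReportDocument,
                     ReportSegment, extract_segment, write_corpus_jsonl,
                     SegmentCorpus)
from .labels import N_CLASSES, TriageLabel
from .text import normalize_text, simplify

__all__ = [
    "SyntheticCorpusConfig",
    "GeneratedCorpus",
    "DuplicateGroup",
    "generate_corpus",
    "render_document",
    "PHRASE_BANKS",
]

# Class-conditional sentence banks. Within the turkish_seed pack the
# content-word sets of the three classes are disjoint under the
# simplified fold (asserted in the test suite), so a corpus generated
# with vocabulary_overlap=0 is separable by construction.
_TURKISH_BANKS: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]] = (
    (  # GREEN: explicit absence / normal findings
        "Kitle izlenmedi.",
        "Belirgin lezyon saptanmadı.",
        "Patolojik bulguya rastlanmadı.",
        "Normal sonografik görünüm mevcuttur.",
        "Cilt altı dokular olağan değerlendirildi.",
        "Klinik takip yeterlidir.",
    ),
    (  # YELLOW: benign / indeterminate lesions, follow-up language
        "Ganglion kisti ile uyumlu anekoik yapı.",
        "Basit kistik formasyon dikkati çekti.",
        "Minimal peritendinöz ödem gözlendi.",
        "Tendon kalınlaşmasına ait eko farkı seçilmektedir.",
        "Benign karakterde nodüler alan, takibi önerilmektedir.",
        "Küçük boyutlu lipom düşünülebilir.",
    ),
    (  # RED: hematoma / abscess / suspicious mass / escalation
        "Hematom lehine heterojen koleksiyon.",
        "Apse formasyonuna işaret eden şüpheli bulgular.",
        "Malignite kuşkusu taşıyan solid kitlesel oluşum.",
        "Acil MRG önerilir.",
        "Parsiyel rüptür düşündürmektedir.",
        "İvedi ileri tetkik gereklidir.",
    ),
)

_ABSTRACT_BANKS: tuple[tuple[str, ...], ...] = tuple(
    tuple(
        " ".join(f"{pref}{w:02d}" for w in range(5 * k, 5 * k + 4)) + "."
        for k in range(6)
    )
    for pref in ("grn", "yel", "red")
)

PHRASE_BANKS = {"turkish_seed": _TURKISH_BANKS, "ascii_abstract": _ABSTRACT_BANKS}

# measurement sentence appended to every segment; its structural tokens
# are shared across classes and carry no class signal
_MEASURE = {"turkish_seed": "Boyutu {} mm olarak ölçülmüştür.",
            "ascii_abstract": "value {} units."}

_SUBHEADERS = (
    "Yüzeysel Doku USG",
    "Yüzeyel Doku USG:",
    "Yüzeysel Doku US",
    "YÜZEYEL DOKU ULTRASONOGRAFİ",
    "Yüzeysel Doku Ultrason",
)
_HEADINGS = ("TETKİK SONUCU", "TETKİK SONUCU:", "Tetkik Sonucu")
_TECH_NOTE = ("Ultrason cihazından kaynaklanan artefaktlar nedeniyle "
              "değerlendirme sınırlı olabilir.")
_SIGNATURES = ("Uzm. Dr. A. Yılmaz", "Prof. Dr. B. Demirel", "Doç. Dr. C. Aksoy")


class SyntheticCorpusConfig(BaseModel):
    """Study conditions for one generated corpus."""

    n_reports: int = Field(398, ge=10)
    class_proportions: tuple[float, float, float] = (0.19, 0.63, 0.18)
    duplicate_rate: float = Field(0.01, ge=0, lt=1)
    conflict_rate: float = Field(0.5, ge=0, le=1)
    vocabulary_overlap: float = Field(0.2, ge=0, le=1)
    patient_repeat_rate: float = Field(0.0, ge=0, lt=1)
    seed: int = 42
    language_pack: Literal["turkish_seed", "ascii_abstract"] = "turkish_seed"

    @model_validator(mode="after")
    def _feasible(self) -> "SyntheticCorpusConfig":
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.conflict_rate > 0 and self.duplicate_rate == 0:
            raise ValueError(
                "conflicting duplicates requested with duplicate_rate 0"
            )
        return self


@dataclass(frozen=True)
class DuplicateGroup:
    """One duplicated text: indices into the document list, plus labels."""

    original_index: int
    duplicate_indices: tuple[int, ...]
    labels: tuple[TriageLabel, ...]  # original first, then duplicates
    conflicting: bool


@dataclass
class GeneratedCorpus:
    """Generator output with full ground truth."""

    documents: list[ReportDocument]
    segments: list[ReportSegment]  # labeled truth, one per document
    duplicate_groups: list[DuplicateGroup]
    config: SyntheticCorpusConfig

    def truth_corpus(self) -> SegmentCorpus:
        return SegmentCorpus(segments=list(self.segments), dedup_policy="none")

    def n_unique_texts(self) -> int:
        return len({s.text for s in self.segments})

    def write(self, directory: str | Path) -> None:
        """Persist as a directory of .txt documents plus truth JSONL."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for doc in self.documents:
            (directory / doc.source_filename).write_text(
                doc.raw_text, encoding="utf-8"
            )
        write_corpus_jsonl(self.truth_corpus(), directory / "truth.jsonl")


def _apportion_classes(n: int, proportions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n segments over the classes."""
    quotas = [p * n for p in proportions]
    base = [int(np.floor(q)) for q in quotas]
    order = sorted(range(N_CLASSES), key=lambda c: -(quotas[c] - base[c]))
    for c in order[: n - sum(base)]:
        base[c] += 1
    return base


def _segment_sentences(
    label: int, rng: np.random.Generator, pack: str, overlap: float
) -> str:
    banks = PHRASE_BANKS[pack]
    n_sent = int(rng.integers(1, 4))  # 1-3 finding sentences
    sentences = []
    for _ in range(n_sent):
        source = label
        if overlap > 0 and rng.random() < overlap:
            neighbours = [c for c in (label - 1, label + 1) if 0 <= c < N_CLASSES]
            source = int(rng.choice(neighbours))
        bank = banks[source]
        sentences.append(bank[int(rng.integers(0, len(bank)))])
    size = f"{int(rng.integers(2, 95))}.{int(rng.integers(0, 10))}"
    sentences.append(_MEASURE[pack].format(size))
    return " ".join(sentences)


_SEP_RE = re.compile(r"([-=_*])\1{2,}")


def _contains_terminator(
    text: str, config: ExtractionConfig = DEFAULT_EXTRACTION
) -> bool:
    s = simplify(text)
    if any(p in s for p in config.technical_note_prefixes):
        return True
    if any(t in s for t in config.signature_titles):
        return True
    return any(_SEP_RE.fullmatch(tok) for tok in text.split())


def render_document(segment_text: str, layout_seed: int) -> str:
    """Wrap a findings text in a full raw report document.

    Deterministic in ``(segment_text, layout_seed)``. The layout places
    the text between the result heading plus a randomly chosen
    sub-header variant and a randomly chosen terminator, so that
    extraction recovers exactly ``normalize_text(segment_text)``.
    Raises when the findings text itself would match a terminator (the
    segment would be truncated).
    """
    if not segment_text.strip():
        raise ValueError("empty segment text")
    if _contains_terminator(segment_text):
        raise ValueError("segment text contains a terminator line")
    rng = np.random.default_rng(layout_seed)

    def pick(seq):
        return seq[int(rng.integers(0, len(seq)))]

    lines: list[str] = []
    if rng.random() < 0.7:
        lines += ["RADYOLOJİ RAPORU", f"Protokol No: {int(rng.integers(1e5, 1e6))}"]
    lines.append(pick(_HEADINGS))
    lines.append(pick(_SUBHEADERS))
    # body: single line or word-wrapped
    words = segment_text.split()
    if rng.random() < 0.5:
        lines.append(" ".join(words))
    else:
        width = int(rng.integers(40, 70))
        line: list[str] = []
        for w in words:
            if line and len(" ".join(line + [w])) > width:
                lines.append(" ".join(line))
                line = [w]
            else:
                line.append(w)
        if line:
            lines.append(" ".join(line))
    term = int(rng.integers(0, 3))
    if term == 0:
        lines.append(pick(("-", "=", "*")) * int(rng.integers(5, 25)))
    elif term == 1:
        lines.append(_TECH_NOTE)
        lines.append(pick(_SIGNATURES))
    else:
        lines.append(pick(_SIGNATURES))
    if rng.random() < 0.3:
        lines.append(f"Onay No: {int(rng.integers(1e4, 1e5))}")
    return "\n".join(lines) + "\n"


def generate_corpus(config: SyntheticCorpusConfig) -> GeneratedCorpus:
    """Generate documents plus labeled truth segments.

    Per-class counts over all ``n_reports`` slots follow largest-
    remainder apportionment of ``class_proportions`` (exact when no
    conflicting duplicate rewrites a label). ``duplicate_rate * n``
    reports reuse an earlier text verbatim; ``conflict_rate`` of those
    duplicate groups keep a deliberately discordant label, the rest
    inherit the original's label.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    counts = _apportion_classes(n, config.class_proportions)
    labels = [c for c in range(N_CLASSES) for _ in range(counts[c])]
    labels = [labels[i] for i in rng.permutation(n)]

    n_dup = int(round(config.duplicate_rate * n))
    dup_positions = sorted(
        int(i) for i in rng.choice(np.arange(1, n), size=n_dup, replace=False)
    ) if n_dup else []
    dup_set = set(dup_positions)
    original_positions = [i for i in range(n) if i not in dup_set]

    # original texts, unique by construction (retry on collision)
    texts: dict[int, str] = {}
    seen: set[str] = set()
    for i in original_positions:
        for _attempt in range(200):
            t = _segment_sentences(
                labels[i], rng, config.language_pack, config.vocabulary_overlap
            )
            key = normalize_text(t)
            if key not in seen:
                seen.add(key)
                texts[i] = t
                break
        else:  # pragma: no cover - would need a tiny phrase space
            raise RuntimeError("could not generate a unique segment text")

    # duplicates copy an earlier original; group by original index
    groups: dict[int, list[int]] = {}
    for i in dup_positions:
        earlier = [j for j in original_positions if j < i]
        j = int(earlier[int(rng.integers(0, len(earlier)))])
        texts[i] = texts[j]
        groups.setdefault(j, []).append(i)

    group_keys = sorted(groups)
    n_conflict = int(round(config.conflict_rate * len(group_keys)))
    conflict_keys = set(
        int(k) for k in rng.choice(group_keys, size=n_conflict, replace=False)
    ) if group_keys else set()
    duplicate_groups: list[DuplicateGroup] = []
    for j in group_keys:
        conflicting = j in conflict_keys
        for i in groups[j]:
            if conflicting:
                if labels[i] == labels[j]:
                    others = [c for c in range(N_CLASSES) if c != labels[j]]
                    labels[i] = int(rng.choice(others))
            else:
                labels[i] = labels[j]
        duplicate_groups.append(
            DuplicateGroup(
                original_index=j,
                duplicate_indices=tuple(groups[j]),
                labels=tuple(
                    TriageLabel(labels[k]) for k in [j, *groups[j]]
                ),
                conflicting=conflicting,
            )
        )

    # patient ids: unique numeric tokens, optionally reused
    documents: list[ReportDocument] = []
    segments: list[ReportSegment] = []
    used_pids: list[str] = []
    for i in range(n):
        if used_pids and rng.random() < config.patient_repeat_rate:
            pid = used_pids[int(rng.integers(0, len(used_pids)))]
        else:
            pid = str(100000 + int(rng.integers(0, 900000)))
            while pid in used_pids:
                pid = str(100000 + int(rng.integers(0, 900000)))
            used_pids.append(pid)
        filename = f"{pid}_USG_{i:04d}.txt"
        raw = render_document(texts[i], layout_seed=int(rng.integers(0, 2**31)))
        doc = ReportDocument(
            doc_id=Path(filename).stem,
            source_filename=filename,
            raw_text=raw,
            patient_id=pid,
        )
        seg = extract_segment(doc)
        if seg is None or seg.text != normalize_text(texts[i]):  # pragma: no cover
            raise RuntimeError(f"render/extract round-trip failed for doc {i}")
        documents.append(doc)
        segments.append(dataclasses.replace(seg, label=TriageLabel(labels[i])))
    return GeneratedCorpus(
        documents=documents,
        segments=segments,
        duplicate_groups=duplicate_groups,
        config=config,
    )
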