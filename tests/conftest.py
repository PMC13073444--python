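import pytest

from msktriage.ingest import ReportDocument, ReportSegment
from msktriage.labels import TriageLabel


def make_segment(i, text, label=None, patient=None):
    return ReportSegment(
        segment_id=f"s{i:03d}",
        doc_id=f"d{i:03d}",
        patient_id=patient or f"p{i:03d}",
        text=text,
        label=None if label is None else TriageLabel.parse(label),
        raw_span=(0, len(text)),
    )


def build_split_corpus(group_sizes):
    """Corpus with one patient per group, labels cycling over classes."""
    from msktriage.ingest import SegmentCorpus

    segs = []
    i = 0
    for g, size in enumerate(group_sizes):
        for _ in range(int(size)):
            segs.append(
                make_segment(i, f"text {i}", i % 3, patient=f"{g:04d}")
            )
            i += 1
    return SegmentCorpus(segments=segs)


@pytest.fixture
def report_doc():
    def _make(body, doc_id="doc1"):
        return ReportDocument(
            doc_id=doc_id, source_filename=f"{doc_id}.txt", raw_text=body,
            patient_id="123",
        )

    return _make
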