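# Methods

## Problem and unit of analysis

The unit of analysis is a *report segment*: the free-text findings (or
conclusion) paragraph of one superficial soft-tissue ultrasound
examination. One document corresponds to one examination and yields at
most one segment. Labels form an ordinal three-class urgency scale
GREEN < YELLOW < RED; the integer encoding (0, 1, 2) fixes the axis
order of every vector and matrix in the package.

## Text representations

Two deterministic views of every text are maintained:

* **normalized** — Unicode NFKC plus whitespace standardization (runs
  of any whitespace → one space, trimmed). This is the canonical stored
  form and the identity used for deduplication. The operation is
  idempotent.
* **simplified** — additionally case-folded and diacritic-folded
  (ü→u, ı/İ/I→i, ş→s, ç→c, ö→o, ğ→g; other characters casefold + NFKD
  mark stripping). Only pattern matching (anchors, keywords, regex
  rules) uses this view. `build_simplified_view` also emits a
  per-character index map back to raw offsets; folding may expand a
  character (ß→ss), so the map is non-decreasing rather than injective.
  Simplified match spans project to raw spans as
  `(imap[a], imap[b-1]+1)`, which re-simplify to the matched substring
  whenever span ends align with raw character boundaries — always the
  case for spans produced by matching whole simplified characters.

## Extraction

A rule-based, pure function of the raw text. The main heading
("tetkik sonucu" on the simplified view) must precede a modality
sub-header matching `(yuzeysel|yuzeyel) doku` plus an optional modality
token (ultrasonografi(si)/ultrason/usg/us/u/s/u.s., longest-first with
a word boundary). The segment starts immediately after the sub-header
and ends at the earliest terminator line:

* a *separator*: a line that is ≥3 repeats of one of `- = _ *`
  (configurable regex);
* a *technical note*: simplified line starting with a configured prefix
  (seed: "ultrason cihazindan kaynaklanan");
* a *signature*: simplified line containing a clinician title (seed:
  "uzm. dr.", "prof. dr.", "doc. dr.").

All anchor inventories are configurable (`ExtractionConfig`) because
the variant spellings in real archives are open-ended. Absent anchors
yield no segment; empty documents raise an error naming the document.
Coordinates are 0-based half-open throughout, and
`normalize_text(raw[span]) == segment.text` holds for every extraction.

## Deduplication

Segments group by identical normalized text; one representative per
group is kept — the member with the smallest (doc_id, segment_id), a
deterministic choice. Label-conflict policies:

* `conservative_yellow` (default): conflicts resolve to YELLOW, the
  triage-safe middle call. A conflict with no YELLOW member (GREEN vs
  RED) is not covered by that rule; we resolve to the most urgent label
  present and record a warning, preferring over-triage to silent
  under-triage.
* `majority_vote`: unique modal label; groups with a tied vote are
  dropped entirely.
* `drop_conflicts`: any disagreeing group is dropped.
* `none`: explicit pass-through for raw corpora.

The summary satisfies retained + merged + dropped = input, and every
policy is idempotent. Unlabeled segments carry no vote and are counted
separately.

## Splitting and leakage control

Patient identifiers are the leading digit run of the report filename.
Partition sizes follow a fixed convention: n_test = ceil(f_test·n),
n_train = floor(f_train·n), validation takes the remainder — chosen so
80/10/10 of 394 gives 315/39/40. The group split shuffles patients with
a seeded generator (seed default 42) and assigns whole groups, filling
test, then validation, then train; overshoot is bounded by
(largest group − 1) and patient disjointness holds by construction and
is re-verified. The stratified split apportions each class independently
by largest remainder (leftovers favor test, then validation), so
per-partition class shares deviate from the corpus shares by at most
one segment per class; it requires ≥3 segments per class.

## Classifier backends

The backend contract: fitted backends expose `predict_logits(text) →
(z_G, z_Y, z_R)`; probabilities are softmax(z) (shift-invariant, stable
via the usual max subtraction); predictions are the arg-max with exact
ties broken toward the more urgent class — a deliberate triage-safety
choice that also makes tie behavior testable. Class weights are
w_c = n/(3·n_c) (inverse frequency, mean ≈ 1), reducing to unweighted
loss on balanced data.

`sparse_linear` (mandatory, self-contained): TF-IDF features (word
1–2-grams, sublinear tf, simplified-fold preprocessing so diacritic
variants share features) into multinomial logistic regression
(L2, C = 10, lbfgs, the class weights above). C = 10 keeps the
regularizer from flattening the small-corpus decision function; the fit
is deterministic given the seed.

`transformer` (optional): fine-tunes a pretrained encoder with AdamW
(lr 2e-5, weight decay 0.01), linear schedule with 10% warm-up, batch
sizes 16/32 (train/eval), inputs truncated to 256 tokens, at most 6
epochs, keeping the checkpoint with the best validation macro-F1. Only
the transformer truncates input; the sparse baseline sees full text.
The backend raises a clear error when the optional dependencies are
absent; its weights are not part of this package.

## Keyword fusion

The lexicon holds one phrase list per class; compilation normalizes,
simplifies, deduplicates, and resolves cross-list overlaps with
priority RED > YELLOW > GREEN, so the compiled lists are pairwise
disjoint. Hit counting is substring-based on the simplified text:
within a class, phrases are tried longest-first at each position and
matches are non-overlapping, leftmost-first ("hit counts" admits
several conventions; this one is deterministic and order-free).
Fused logits are z + α·K. The fusion weight is grid-searched over
{0, 0.25, …, 3.0} (the stated range 0–3; the 0.25 step is our choice)
by validation macro-F1, ties toward the smallest α so the unfused model
is preferred; an empty lexicon therefore always selects α = 0.

## Regex override layer

Patterns match the simplified text. Decision rule: any negative-shield
match → GREEN; else any red-force match → RED; else the base prediction
stands. Shield precedence prevents escalating an explicitly negative
report that happens to contain a high-risk token. The layer is a pure,
idempotent function of (base prediction, simplified text, patterns),
and the number of changed predictions is reported as the rule
intervention intensity. Seed inventories contain only standard
negative/high-risk ultrasound phrases ("kitle izlenmedi", "lezyon
saptanmadi" / "hematom", "apse", "mrg onerilir"); full inventories load
from sectioned plain-text files. Context gating for escalation phrases
such as "MRG önerilir" (e.g. suppressing routine-recommendation uses)
is deliberately not modeled: no principled definition of the intended
contexts is available, so the phrase acts as a plain pattern that users
can refine via lookarounds in their pattern files.

## Evaluation

All metrics derive from the 3×3 confusion matrix; 0/0 ratios are 0
(never NaN), including inside bootstrap resamples, which are never
discarded. Macro aggregates are unweighted class means; weighted-F1
weights by support; accuracy equals support-weighted recall (asserted
as a property). Uncertainty uses the percentile bootstrap (resample
pairs with replacement, 2.5th/97.5th percentiles; BCa was judged
unnecessary at these sample sizes and would obscure the simple
resampling semantics). The paired bootstrap resamples the same indices
for both models; its `p_like` — the fraction of resamples where the
difference is ≤ 0 — is descriptive, not a significance test, and no
significance labels are emitted. Display rounding: two decimals for
rates, one for percentages.

Worked-fixture note: the external-evaluation confusion matrix used in
the tests yields YELLOW F1 ≈ 0.87, RED F1 ≈ 0.727 and macro-F1 ≈ 0.77;
summary tables elsewhere quoting 0.85/0.72/0.76 for those cells are
internally inconsistent with that matrix, and this package always
reports matrix-derived values.

## Synthetic corpora

The generator emulates what the pipeline assumes about real report
archives: document anatomy (heading, sub-header variants with Turkish
diacritics and mixed case, 1–3-sentence findings, terminator variants,
occasional preamble/trailer lines), filenames with leading numeric
patient tokens, a 19/63/18% GREEN/YELLOW/RED mix apportioned by largest
remainder, ~1% verbatim duplicate texts (half of duplicate groups given
deliberately conflicting labels), and optional multi-report patients.
Class-conditional sentence banks are word-disjoint under the simplified
fold (asserted in tests), so `vocabulary_overlap = 0` yields a linearly
separable corpus; raising it makes segments borrow sentences from the
adjacent urgency class, emulating borderline language. A measurement
sentence with a randomized size guarantees text uniqueness among
non-duplicates; its structural tokens are class-neutral. Default
overlap is 0.2 — enough shared vocabulary that the baseline makes
realistic GREEN/YELLOW and YELLOW/RED confusions rather than saturating.

What the generator does *not* emulate: real reporting-style diversity
across radiologists, misspellings and OCR noise, near-duplicates that
differ by a token (duplication is exact by design, matching the
dedup-by-identity contract), seasonal or indication-driven label drift,
and genuinely ambiguous borderline cases where the true label is
contested. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under controlled difficulty, not clinical
performance on hospital data.

Every generated document is round-tripped through the real extractor at
generation time, so generator output is guaranteed consistent with the
ingestion contract. Findings texts that would themselves match a
terminator are rejected rather than silently truncated.

## Orchestration and reproducibility

`ExperimentConfig` is one declarative (YAML-able) object; variants A–D
toggle fusion and rules. Four independent seeds (generation, split,
training, bootstrap) default to 42; all randomness flows through
per-stage `numpy` generators, no global state. Stage failures propagate
with the stage name and a config hash; metrics JSON is key-sorted so
identical configs reproduce byte-identical artifacts.

## Problem sizes

The test suite and the acceptance script run the pipeline at the study
scale it is designed for: corpora of 100–398 documents, 1000-document
extraction fidelity sweeps, B = 1000 bootstrap resamples, and a
500-replication coverage study of the bootstrap interval at n = 200.
The full suite completes in well under a minute of CPU plus ~15 s for
the acceptance script.

## Known limitations

* Deduplication is exact-text only; near-duplicates survive it.
* The extractor assumes line-oriented reports with the documented
  anchor families; archives with different section conventions need a
  custom `ExtractionConfig`.
* The sparse baseline has no notion of negation scope beyond what
  n-grams capture; the negative shield is the only explicit negation
  mechanism.
* Bootstrap intervals at n = 40 are wide and percentile intervals can
  undercover slightly for extreme proportions; interpret comparisons
  via the paired bootstrap, not interval overlap.
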