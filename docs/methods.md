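# Methods

This note documents the models and procedures implemented in `relmine`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The package structures dietary-health knowledge scattered across
scientific abstracts into typed triples: a FOOD or CHEMICAL entity
*causes* or *treats* a DISEASE, or a FOOD *contains* a CHEMICAL. Three
pipeline configurations (`foodis`, `chemdis`, `foodchem`) share one
template — segment, recognize and link entities, filter sentences by
rhetorical role, enumerate and mask candidate pairs, vote, aggregate —
and differ only in the pair schema and the ensemble serving it. The unit
of evidence is the sentence; the unit of output is the aggregated
relation record with all of its supporting sentences.

## Sentence segmentation

Segmentation is a deterministic rule splitter: a run of `.!?` (plus
closing quotes/brackets) followed by whitespace or end of text closes a
sentence, unless the preceding token is in a short abbreviation list
(`e.g`, `i.e`, `et al`, `fig`, …) or the period sits inside a token
(decimal numbers, formulas). Unit symbols such as `mg` are deliberately
*not* in the list: "Levels were 3.5 mg. Intake rose." is two sentences.
Offsets are 0-based half-open into the abstract, so
`abstract[char_start:char_end] == text` always holds and segmentation is
losslessly invertible — this invariant is property-tested over arbitrary
text. The trade-off versus a learned segmenter is occasional over- or
under-splitting on exotic prose; the gain is bit-for-bit reproducibility
with no model download. Structured abstracts are flattened by joining
sections with single spaces and dropping labels, since the downstream
stages treat an abstract as flat text.

## Lexicon construction and dictionary NER/NEL

The food lexicon is built in two steps from pipe-delimited RRF-dialect
tables: concept ids carrying the semantic type label (default `"Food"`)
are collected from the MRSTY-like table, then every English name of
those concepts is collected from the MRCONSO-like table. Column
positions are configurable and default to the UMLS layout (MRSTY: CUI 0,
type name 3; MRCONSO: CUI 0, language 1, string 14); a trailing pipe is
tolerated. Surface normalization is case-folding plus internal
whitespace collapse — no stemming and no plural folding, keeping the
matcher fully auditable. One consequence worth stating: inflected
mentions ("walnuts" vs lexicon "walnut") do not match.

Matching is a token-indexed multi-pattern scan: tokens are alphanumeric
runs, surfaces are indexed by first token, and a candidate must align
token-for-token with its normalized raw span equal to the lexicon
surface (so "fish  oil" matches "fish oil", but "saltwater" never
matches "salt" and "fish-oil" is not folded). Overlaps are resolved
leftmost-longest — the standard gazetteer convention. When one surface
maps to several concepts the smallest concept id wins, a deterministic
tie-break. The scanner is verified against a brute-force
try-every-surface-at-every-position oracle on randomized fixtures.
Because every surface carries its concept id, recognition *is* linking;
candidates without an identifier are never emitted.

Disease and chemical recognition is a contract
(`EntityRecognizer`): implementations declare their entity class and
linking target and must return offset-valid mentions, which the caller
re-validates. The bundled fallback is the same dictionary engine loaded
with a different lexicon; model-based recognizers (e.g. BiLSTM-CRF
taggers) plug in without touching the pipeline.

## Role filtering, candidate pairs, masking

Abstract sentences stating an objective, hypothesis, or method are
unreliable evidence (a stated hypothesis may be false), so relations are
only mined from FACT/ANALYSIS sentences. The bundled role classifier is
a cue-phrase heuristic (configurable `ROLE<TAB>phrase` file; priority
OBJECTIVE → HYPOTHESIS → METHOD; empty → OTHER; default FACT). This is
deliberately simple and biased toward FACT: false FACT labels admit
noise that the ensemble can still discard, while false METHOD labels
would silently lose evidence.

Candidate pairs are the full cross-product of the schema's two mention
classes within one sentence, excluding overlapping spans; orientation is
fixed by the schema regardless of textual order. Cross-sentence pairs
are not generated. Masking replaces exactly the two pair mentions with
`@FOOD$` / `@CHEMICAL$` / `@DISEASE$` (right-to-left so offsets stay
valid); third-party entities in the sentence are left intact so each
pair's masked text is independent of which other pairs exist.

## Ensemble voting

Each relation classifier is a binary predictor over masked text
(`RelationClassifier` contract, deterministic given the text). The
cause/treat scheme uses two banks of `n_models = 4`: relation *r* is
assigned iff at least `min_for = 3` of its own bank are positive and at
most `max_against = 1` of the opposing bank are positive; otherwise the
pair is discarded. Since `min_for > max_against`, the CAUSE and TREAT
conditions are mutually exclusive — asserted exhaustively over all 2^8
vote vectors, where the rule yields 25 CAUSE, 25 TREAT and 206 DISCARD
outcomes ((C(4,3)+C(4,4))·(C(4,0)+C(4,1)) = 5·5 per relation). The
contains scheme is a simple majority: `min_for = 2` of 3. Thresholds and
bank sizes are parameterized for simulation studies; the defaults are
the reference configuration. Discarding is per-pair: other pairs in the
same sentence are unaffected.

The default ensemble member is a deterministic cue-phrase pattern
classifier, so the full pipeline runs with no trained weights; a
transformer-backed classifier honoring the contract is a drop-in
replacement. Classifier order is fixed by configuration order so vote
vectors are reproducible; every pair's votes and outcome go to a TSV
audit log.

Under per-model flip probability *p* on a true-CAUSE pair, the
assignment rate has the closed form
P(Bin(4, 1−p) ≥ 3) · P(Bin(4, p) ≤ 1); at p = 0.2 both factors equal
0.8192, giving ≈ 0.671. The Monte-Carlo simulation
(`simulate_noisy_ensemble`, n = 2000 by default) reproduces this within
three binomial standard errors, and the closed form itself is
cross-checked in tests against an exhaustive probability-weighted
enumeration of all 256 vote vectors.

## Aggregation and the knowledge graph

Sentence relations merge on (concept_id_a, concept_id_b, relation) —
identifiers, never surface strings — so synonyms of one concept fall
into one record whose synonym sets are the union of observed surfaces.
Supporting sentences deduplicate by (doc_id, sentence_index) within a
record and are ordered by address; output is sorted by key, making
aggregation order-invariant (tested by shuffling). The representative
name is the most frequent observed surface, ties broken
lexicographically.

The graph keeps one node per concept id and one directed edge per record
key (food/chemical → disease; food → chemical), with evidence references
and support counts as edge attributes. Contradictory evidence — the same
pair with both CAUSE and TREAT — is retained as parallel edges;
adjudication belongs to domain experts, not the builder. Node display
names come from the contributing record with the most support (ties
lexicographic). Exports (GraphML, nodes/edges TSV, JSONL) serialize
collection attributes as ";"-joined strings and re-import to an
isomorphic graph; merging corpora is simply union of record sets before
building.

## Evaluation

Precision of a group of extracted relations is the mean of expert binary
correctness indicators; an empty indicator set is an *error*, not zero.
Display truncates (floors) to two decimals — 2/3 renders as 0.66 — while
internal values keep full precision; a 1e-9 guard stops exact hundredths
from flooring down through float error. Experts annotate only within
their expertise, so coverage (fraction of extracted keys annotated) is
always reported; annotations referencing unknown keys go to a
reconciliation list rather than being dropped or crashing the run.
Indicators from different annotators are never merged by majority:
the report carries per-annotator precision, their unweighted mean
("averaged"), and the pooled-indicator mean, which generally differ.
Precision-by-support buckets records by supporting-sentence count;
unannotated records count toward `n_extracted` but not precision, and
the annotation-count-weighted mean of bucket precisions equals the
pooled precision (a tested identity).

## Synthetic data: what it emulates, and what it does not

The generator emulates the pipeline's full input surface: RRF lexicon
tables (all three classes present so the semantic-type filter does real
work, plus non-English rows), abstracts, and annotation files. Entity
names are nonsense syllable words with class-specific suffixes —
disjoint across classes by construction and absent from all fixed
template text (scanned in tests). Each abstract holds an optional
role-cue distractor (rate 0.5), one to three fact sentences instantiating
planted triples, and optional entity-free filler (rate 0.4). Triples are
drawn from a pool of 8 per relation kind, so relations recur across the
200 default documents and multi-support records arise; template slots
are filled with uniformly chosen synonyms, exercising synonym-union
aggregation. One `random.Random` seeded by the spec's mandatory integer
seed drives everything; regeneration is byte-identical.

With noise-free classifiers, end-to-end extraction equals the planted
ground truth exactly — including supporting-sentence addresses — and
planting only in hypothesis-wrapped sentences yields zero records (the
role filter works). These are *consistency* results: templated sentences
always contain a recognizable cue and exactly two entities. Passing them
shows the plumbing is lossless and the voting/aggregation logic exact;
it says nothing about recall on real prose, where entity variation,
partial matches, negation, and quantity language ("low-sodium diet")
dominate the error budget. Annotation generation draws correctness with
probability min(1, base + slope·(support−1)) (defaults 0.6, 0.2), giving
a known, monotone precision-versus-support profile for testing the
evaluator — not a model of real expert behavior.

## Numerical and design choices

- Tie-breaks are everywhere deterministic: lexicographic on names and
  ids, configuration order for classifiers, address order for sentences.
- Degenerate inputs: empty abstracts yield zero sentences; an empty
  lexicon or empty corpus runs cleanly to empty outputs; an empty
  semantic-type filter result is a warning, not an error.
- Default problem sizes (200-document corpora, n = 2000 vote
  simulations) were chosen as the smallest sizes at which multi-support
  aggregation genuinely occurs and the Monte-Carlo check has sub-percent
  standard error.
- The noisy classifier derives flips from a hash of (seed, relation,
  text): deterministic per text, independent across seeds, no shared
  state between ensemble members.
- Pipeline runs are reproducible: identical config and seed produce
  byte-identical JSONL/TSV outputs, and the manifest records a config
  hash plus stage counts satisfying
  `pairs_generated = pairs_discarded + sentence_relations`.

## Known limitations

- No morphological folding in the matcher (plurals and inflections
  miss); no abbreviation expansion; no nested entities.
- The cue-phrase role classifier and pattern relation classifiers are
  baselines; quantitative performance on real corpora depends entirely
  on the plugged-in recognizers and classifiers.
- Relations are sentence-scoped: no coreference, no cross-sentence
  evidence.
- The knowledge graph performs no reconciliation beyond exact concept-id
  equality, and no reasoning over the linked knowledge bases.
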