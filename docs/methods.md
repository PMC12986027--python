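# Methods

`cappm` implements conformance-aware predictive process monitoring for early
clinical deterioration: it predicts, from the first k events of an ongoing
care pathway, whether the case will later reach a deterioration-defining
activity, and it does so with features that quantify *how care is being
delivered* (deviations from a discovered reference pathway) in addition to
what was measured.

## Data model and labelling

An event log is a set of cases; each case is a time-ordered trace of events
(case id, activity, UTC timestamp, optional numeric attributes such as
laboratory values). Timestamps are normalized to UTC and events sorted within
each case; ties keep original record order. A case is labelled deteriorated
(y=1) iff its trace contains an activity from the deterioration set, by
default `{Admission IC, Release D}` (intensive-care admission or the severe
discharge code). The index and time of the first such event are recorded; the
label is a case property and is inherited by every prefix. The deterioration
set is configurable because discharge-code semantics are institution-specific.

Missing numeric values are median-imputed, with medians computed on training
rows only and reapplied to held-out rows at prediction time.

## Prefixes and splitting

Prefixes of fixed lengths k ∈ {3, 5, 10} model early, intermediate and more
advanced stages of a pathway. Two exclusion rules prevent outcome leakage: a
prefix containing any deterioration-defining event is dropped, and for
deteriorated cases only prefixes ending strictly before the first such event
are retained. Cases shorter than the smallest k, and positives that
deteriorate before any usable prefix, contribute nothing (they are counted
and logged). Train/test splitting is at *case* level (all prefixes of a case
on one side), stratified by outcome, seeded; the default test fraction is
0.3. Evaluation is at prefix level, with the (case_id, k) pair as row
identity.

## Reference model discovery

The reference pathway is discovered from the complete log (including
deterioration events) by an inductive-miner-style recursion: the
directly-follows graph of the current sub-log is searched for cuts in the
fixed order exclusive-choice, sequence, parallel, loop; sub-logs are split
accordingly and mined recursively. Base cases map empty traces to silent
leaves and a single repeated activity to a self-loop; when no cut applies the
recursion falls through to a flower model (loop over an exclusive choice of
the alphabet). Partition ties are broken alphabetically so discovery is
deterministic. The resulting process tree is translated compositionally into
a safe workflow Petri net (sequence = place chaining; choice = shared
entry/exit places; parallel = silent fork/join; loop = silent entry/exit with
redo back-edges). The construction guarantees that every discovery-log trace
replays at zero alignment cost; the test suite certifies this on generated
logs. No infrequent-behaviour filtering is applied by default (an optional
variant-frequency filter exists but forfeits the fitness guarantee).

## Alignments and conformance features

For each prefix an optimal alignment against the reference net is computed by
uniform-cost search over the synchronous product, with unit costs (visible
model move 1, log move 1, synchronous and silent moves 0) and ties preferring
synchronous moves. Two goal semantics are exposed:

* `complete` (default): the model must reach its final marking, so steps the
  pathway has not yet performed are charged as model moves. This measures
  "distance from a finished compliant pathway" and is what the pipeline uses.
* `prefix`: the prefix must be consumed with the model left in a marking from
  which the final marking is reachable; completion is free. This is the
  semantically correct reading for incomplete traces and is provided and
  tested, including the monotonicity of cost along a case's prefix chain.

Per prefix the feature set records raw cost, `log1p(cost) = ln(1 + cost)`
(variance-stabilizing for heavy-tailed costs), and the counts of synchronous,
visible-model and log moves. Per case, two trend features are broadcast to
all its prefixes: `align_cost_slope`, the least-squares slope of log1p cost
against k over the case's available prefixes (0 for a single prefix), and
`align_cost_delta`, last minus first log1p cost. k was chosen as the trend
regressor (rather than wall-clock time) because prefix length is the
monitoring grid on which costs are sampled.

Declarative response constraints complement alignments: for an
activation→response pair (a, b), the violation ratio of a prefix is the
fraction of a-occurrences not followed by any later b within the prefix (0
when a never occurs). Defaults cover the entry protocol and sepsis bundle:
(ER Registration → ER Triage), (ER Triage → ER Sepsis Triage),
(ER Sepsis Triage → IV Antibiotics), (ER Sepsis Triage → LacticAcid); the
pair list is configurable.

## Feature groups and assembly

* behavioral: event count n, distinct-activity count, revisit ratio
  `R = 1 − n_distinct/n` (in [0, 1), 0 iff all activities distinct), binary
  indicators for a watch list of key steps. Deterioration-defining activities
  are excluded from the watch list — they cannot occur in retained prefixes,
  and the assembler additionally refuses any column embedding one.
* temporal: elapsed hours `(t_k − t_1)/3600`, mean inter-event gap, hours
  since the last event (0 in offline evaluation, where "now" is the last
  event's time).
* clinical: mean/min/max/last of each numeric attribute within the prefix.
* pathway cluster: each case is described by the structure of its *longest
  retained prefix* (length, activity presence indicators, selected activity
  counts), z-scored and clustered by K-means with k = 3 (10 restarts, fixed
  seed), fitted without outcome labels; the cluster id joins every prefix of
  the case as a categorical feature. Using the longest retained prefix for
  both classes keeps the structural window comparable between positives
  (truncated before deterioration) and negatives; a length-matched sampling
  alternative was considered and rejected for determinism.

The baseline matrix contains behavioral + temporal + clinical columns only;
the full matrix adds conformance, trend, declare and cluster groups. A column
manifest maps every column to its group, and baseline columns are bit-for-bit
identical between the two matrices.

## Models and evaluation

Five tree-based classifiers (decision tree, random forest, gradient boosting,
extra trees, AdaBoost) are trained with library defaults and fixed seeds —
hyperparameter search is deliberately out of scope, and class imbalance is
handled by metric choice rather than resampling. Metrics: AUROC (trapezoidal,
equal to the tie-corrected pairwise-concordance statistic, certified against
a brute-force oracle in the tests), AUPRC (average precision; the no-skill
reference equals prevalence), Brier score (mean squared error of
probabilities), equal-width 10-bin reliability tables (empty bins kept and
flagged), and a confusion matrix at threshold 0.5 with `p >= threshold`
counting as positive.

Feature attributions are additive tree-path contributions: walking each
sample's decision path, the change in node value at a split is credited to
the split feature. Contributions per row sum exactly to the prediction minus
the ensemble base value — in probability space for the single tree and the
bagged forests, in decision-function (log-odds) space for gradient boosting.
AdaBoost's weighted vote admits no such per-path decomposition here and is
rejected with an error.

The early-warning window is, per deteriorated case, the time from the end of
its longest retained prefix to its first deterioration event (positive by
construction); the median and interquartile range summarize how far ahead of
escalation predictions are made.

## Synthetic study logs

The generator emulates an emergency-department sepsis-style log: entry
sequence (ER Registration → ER Triage → ER Sepsis Triage), repeated
laboratory loops (CRP, Leucocytes, LacticAcid with lognormal values at
plausible magnitudes), optional IV Liquid → IV Antibiotics, ward-admission
loops, occasional ER returns and one final admission/release outcome.
Defaults are 1050 cases at 12.3% deterioration prevalence, with lab-loop
volume set so per-case occurrence counts of the laboratory activities match
the real log's scale (≈3 CRP, ≈3 Leucocytes, ≈1.4 LacticAcid per case; mean
trace length ≈14). Inter-event gaps are exponential (base scale 1 h) with a
strictly positive floor so timestamps strictly increase.

Deviation–outcome coupling is per-channel and applies to deteriorating cases
only: pathway coupling (triage order violations, antibiotics deferred past
ward admission, extra laboratory repeats, an off-model activity insertion)
and clinical/temporal coupling (lognormal location shift of lab values,
inter-event slowdown). Moderate values on both channels are the default —
real deterioration expresses through both. Named constructors give the two
experimental regimes: `conformance_only` (pathway coupling only; the baseline
feature set is blind to order violations by construction, since presence
indicators and timing distributions are unchanged) and `uncoupled` (all
weights zero; the two classes are generated identically except for the final
outcome activity). A small `early_ic_fraction` places the ICU admission right
after entry to exercise the prefix-exclusion logic.

What passing the simulation experiments shows — and what it does not: the
uplift experiment demonstrates that the conformance/declarative channel
recovers deviation-coupled risk that static features cannot see, and the
zero-coupling null shows the pipeline manufactures no signal from the
labelling or prefix machinery itself. The generator is not a physiological
simulator; absolute metric values on synthetic logs do not transfer to real
hospital data, where coupling strength, noise and censoring differ.

## Numerical and design notes

* Alignment search state is (trace position, marking); markings are token
  count tuples, and identical activity sequences share one cached alignment.
* Reachability of the final marking (prefix mode) is memoized per net with
  negative-component caching.
* The trend slope uses `numpy.polyfit` degree 1; a single prefix yields slope
  0 rather than NaN.
* Degenerate inputs: single-event prefixes have mean gap 0; empty calibration
  bins report NaN (None in JSON) rather than being dropped; an all-missing
  numeric column aborts imputation with the column named.
* Problem sizes used by the tests and the acceptance script (1050-case main
  run; five seeds × 1000 cases per simulation arm; 600-case attribution runs)
  were chosen to give stable estimates at interactive runtimes.
* Known limitations: the miner is the plain variant (no infrequent-behaviour
  handling by default), only response constraints are implemented from the
  declarative family, AdaBoost probabilities are used uncalibrated, and
  case-level aggregation of prefix predictions is a diagnostic only.
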