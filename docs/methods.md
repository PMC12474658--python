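# Methods

This note documents the models and procedures implemented in `laolink`,
the parameter defaults and why they were chosen, the numerical details,
and the limits of what the synthetic test conditions can show.

## Text canonicalization

All free-text comparisons operate on canonical forms produced by
`normalize_text`: Unicode NFC (Lao combining marks admit several byte
orders, so equality must not depend on the input encoder), removal of
control characters and of **all** whitespace (Lao is written without
spaces; romanizations space names inconsistently), upper-casing of Latin
letters, and an ordered substitution table (`CharMap`). The bundled
default table rewrites Lao digit forms to ASCII digits, expands the
ligatures ໜ → ຫນ and ໝ → ຫມ, and folds the decomposed vowel sequence
◌ໍ + າ into the precomposed ◌ຳ. The table is data (a two-column CSV), not
code, and is validated at load time to be idempotent (which also excludes
rewrite cycles), so normalization applied twice equals normalization
applied once — a property the test suite checks on random Lao/ASCII
strings.

An optional *phonetic-merge* layer additionally maps the confusable
short/long vowel pair ◌ຸ → ◌ູ and strips the four tone marks, collapsing
tonal spelling variants of one name (ສຸກສັນ / ສູກສັນ, both read
"Souksan") to a single form. It is off by default: merging is a recall /
precision trade the operator should make deliberately.

Placeholder names ("Eanoi"/ແອນ້ອຍ and the honorific stand-ins "Mr.",
"Miss") are flagged during normalization. By default they compare as
ordinary values — which is what real registries do, and why temporary
names are a known source of spurious matches; an opt-in switch demotes
them to missing so they compare as "not available".

Sex is mapped onto {male, female, unknown}; dates accept ISO 8601 and
day-first dd/mm/yyyy and are stored internally as dates; contact numbers
are checked against the Lao phone format (optional +856 or leading 0,
6–12 digits) and flagged — never dropped — on failure. A contact value
longer than 50 characters is rejected at read time.

## Deterministic matching

Blocking: exact agreement on (DOB, sex, village). Records missing any key
join no block; their count is logged. Within a block, each pair is
compared on (child's name, father's name, mother's name); each field is
MATCH (both present, canonical forms equal), NONMATCH (both present,
unequal) or NOT_AVAILABLE (either side missing).

The decision table over the 27 state triples defaults to the majority
rule **link iff #MATCH > #NONMATCH**. This closed form reproduces exactly
the 21 reviewer criteria established for this registry class (10 match,
11 non-match rows); the 6 triples absent from that published list all
have zero MATCH states and fall to FALSE under the same rule. The table
is overridable row-by-row from CSV. A `strict_all_fields` mode demands
exact agreement on all three fields (the "all fields exact" variant that
is also described for such pipelines); the table semantics are the
default because they are the fully specified artifact. Accepted links are
closed transitively (clusters up to size 5 occur in the data this
emulates).

## Probabilistic matching (Fellegi–Sunter)

Blocking: exact (DOB, village) as a composite key — the conjunctive
reading, consistent with how review candidates are constructed; a
`blocking_mode="union"` option instead pools pairs blocked on each key
alone (and then also compares DOB as a field, since pairs may disagree on
it).

Comparison vectors: name, father's name and mother's name at four levels
(exact / JW ≥ 0.88 / JW ≥ 0.70 / other) plus sex (exact / other); either
side missing gives a NOT_AVAILABLE code. The Jaro–Winkler cut-offs are
the conventional defaults of probabilistic-linkage tooling, exposed as
configuration — the studies this emulates do not print theirs.

Jaro–Winkler is implemented from scratch over Unicode code points (Lao
included): Jaro similarity (common characters within the half-length
window, transpositions halved and floored) plus the Winkler bonus with
scaling 0.1 and prefix capped at 4, applied unconditionally. The test
suite checks it against an independently written from-definition
implementation on 1,000 random Lao/ASCII string pairs at 1e-12.

Parameters: per field *i* and level *l*, m_il = P(level | match) and
u_il = P(level | non-match); prior match probability λ.

- λ is estimated as (deterministic-proxy match pairs among candidates /
  assumed proxy recall) / candidate pairs, clamped to (1e-6, 1−1e-6).
  The assumed recall defaults to 0.7 (the value such pipelines select
  after sweeping 0.65–0.95; the sweep is available via the CLI).
- EM: two-class latent-variable EM under conditional independence.
  NOT_AVAILABLE levels are excluded from the field likelihood
  (missing-at-random). Initialization: m puts 0.9 mass on the exact level
  (rest uniform); u starts at the observed level frequencies over all
  candidate pairs (Laplace-smoothed). Convergence: |Δ log-likelihood| <
  1e-6 or 100 iterations; the observed-data log-likelihood is recorded
  each iteration and is non-decreasing. λ is held fixed at the proxy
  estimate by default (the workflow of prior-from-deterministic-rules
  tooling); `update_lambda=True` lets EM re-estimate it.
- Clamping: after each M-step every probability is clipped into
  [1e-6, 1−1e-6] and the excess is returned to the largest entry, so each
  per-field distribution still sums to exactly 1. This keeps all weights
  finite without breaking the simplex constraint.
- Identifiability: EM refuses to run on fewer than two distinct
  comparison vectors. Note that a *single* compared field makes the
  two-class categorical mixture unidentifiable regardless of sample size;
  parameter-recovery checks therefore use three fields.

Scoring: w(γ) = Σ log₂(m/u) over non-missing fields (missing fields
contribute 0); posterior = λ·2^w / (λ·2^w + 1−λ); pairs with posterior ≥
0.5 (configurable) are linked and closed transitively. Output order is
deterministic (descending posterior, then ascending id pair).

## Hybrid matching

Deterministic first. The FS parameters (m, u, λ) are estimated on the
full candidate set — they describe the registry's distribution — but only
probabilistic links whose **both** endpoints lie outside deterministic
multi-record clusters are unioned in, so the probabilistic stage never
reprocesses settled records. (Estimating λ on the residual alone would be
self-defeating: the deterministic proxy finds no matches there by
construction, collapsing the prior.) This guarantees the hybrid
linked-record set is a superset of the deterministic one, hence hybrid
record-level recall ≥ deterministic recall, on every input.

Each probabilistic link is audited against the decision table within its
(DOB, sex, village) evidence: a link is flagged when the table says FALSE
with at least one outright NONMATCH among the name fields, or when the
pair disagrees on sex (the table presumes sex equality). The default is a
non-destructive audit — flags are reported in the trace, links kept —
because validation in the pipelines this emulates evidently removed
little (their hybrid true-positive count slightly *exceeds* the
probabilistic one). A `strict_audit` mode removes flagged links before
closure.

## Evaluation

The unit is the record: positive = member of a multi-record cluster.
This convention is forced by how such studies report confusion matrices
(four counts summing to the registry size per method). tp/fp/fn/tn follow
from comparing predicted and gold positives; precision, recall and F1 use
the zero-division-to-zero rule; printed-percent comparisons round half
away from zero. Pair-level counts are available as a clearly labelled
secondary report.

PR curves sweep a per-record score (for probabilistic/hybrid, the maximum
posterior over incident candidate pairs; records without candidates score
0). For the deterministic method, which has no natural score, the
suggested stand-in is the number of agreeing name fields (0–3) within the
block. AUC is the trapezoid over (recall, precision) sorted by recall,
with an anchor at recall 0 carrying the strictest threshold's precision; a
single-point sweep degenerates to the rectangle precision × recall.

## Synthetic registry generator

The generator emits a registry with a known truth partition under the
study conditions the pipeline targets:

| parameter | default | basis |
|---|---|---|
| records | 20,433 | registry size emulated |
| duplicated-record fraction | 0.1562 | share of records in duplicate clusters |
| cluster sizes 2/3/4/5 | 0.869/0.114/0.014/0.003 | of multi-record clusters |
| family-name completeness | 0.32 | field-completeness profile |
| contact completeness | 0.13 | field-completeness profile |
| placeholder rates | 0.024 (Eanoi), 110/20,433 (Mr.), 80/20,433 (Miss) | name-frequency profile |
| DOB pool | 3 years | plausible pediatric cohort span |
| villages | 100 | produces a realistic blocking-collision rate |
| Lao-script name share | 0.3 | mixed-script entry practice |
| twin rate | 0.02 per duplicate cluster | twins as a known failure mode |

Duplicate records derive from a base record through corruption operators:
a name typo with probability 0.40 and a typo on each parent name with
probability 0.20 (for Lao script: confusable-vowel swap, tone-mark
toggle, or adjacent transposition; for Latin: romanization-variant
substitution or transposition), a DOB entry error (±1–30 days) with
probability 0.02 and a wrong village with probability 0.01 — the two
block-breaking errors that bound attainable recall. These rates are the
package's own choice of a realistic noise level: heavy enough that exact
rules visibly lose duplicates (two or more corrupted fields sink the
majority rule), light enough that single-field typos stay within
Jaro–Winkler ≥ 0.70 of the original. Placeholder names are assigned
record-wise at the configured rates; when a placeholder lands inside a
duplicate cluster it models the temporary-to-permanent name transition
(the truth link is kept, and the cluster is annotated). Twins are emitted
as *distinct* truth entities sharing DOB, village, parents and family
name, with the same sex half the time.

All randomness flows from a single `numpy` generator seeded by one
integer; a configuration and seed reproduce byte-identical output.

A simulated gold-standard review (`emit_gold_review`) applies the
decision table to every blocked candidate pair and gives each of three
simulated reviewers independent decision-flip noise; the consensus keeps
links all three accept, so the consensus match count never exceeds any
single reviewer's — the ordering observed in real multi-reviewer gold
standards.

**What the synthetic conditions do not show.** The generator reproduces
the *marginals* the analysis depends on (duplicate structure,
missingness, placeholder frequency, spelling-noise classes), not the full
messiness of a real registry: name pools are small and clean, corruption
is independent across fields, missingness is missing-at-random, and
villages are uniform. Matcher metrics on synthetic data are therefore
systematically optimistic relative to real registry data — on the default
conditions the deterministic/probabilistic recall gap (≈0.80 vs ≈0.97) is
qualitatively, not numerically, the gap reported on real Lao registry
data (0.67 vs 0.90). Passing tests validate the algorithms and their
relative ordering, not absolute field performance.

## Problem sizes used in the test suite

Unit and property tests run on hand-built fixtures and registries of
200–2,000 records; EM parameter recovery uses 20,000 simulated comparison
vectors; the end-to-end ordering and generator-calibration checks run one
full-size registry (n = 20,433). The acceptance script uses the full-size
registry only; a complete run takes well under a minute on one CPU.

## Known limitations

- Conditional-independence FS only: no term-frequency adjustment (a
  frequent placeholder name is as match-informative as a rare name) and
  no modelling of correlated fields.
- λ estimation inflates the deterministic proxy count by an *assumed*
  recall; when candidate pairs are few (small blocks, small n) the
  estimate can saturate at the clamp boundary and degrade precision —
  visible on registries of a few thousand records.
- The deterministic PR-curve score (agreeing-field count) is a documented
  stand-in; rule-based matchers have no canonical score to sweep.
- Transitive closure can chain clusters through borderline links; no
  cluster-splitting post-process is applied.
- No transliteration between Lao script and Latin, and no Lao phonetic
  encoding (a Lao Soundex analogue): a record written in Lao script will
  not fuzzily match its romanization.
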