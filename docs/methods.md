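# Methods

## The descriptor model

An experimental action is reproducible only if the values of its essential
descriptors are recorded.  The catalog encodes, per action, which of the
eleven descriptor kinds (biochemical entity, equipment, temperature,
period, volume, speed, concentration, condition, goal, protocol method,
time point) are essential and which optional.  Well-attested assignments:
*store* requires temperature, period, biochemical entity, condition and
equipment; *incubate* requires biochemical entity, condition, temperature
and period, with equipment, protocol method and goal optional; temperature
is optional for *filter* and *resuspend* because those actions default to
ambient or carried-over temperature unless stated otherwise.  For all
other actions the catalog applies an editorial default: the biochemical
entity is essential (an action without a participant cannot be repeated),
quantity descriptors are optional unless the action's definition names one
(*dilute* → concentration essential).  Each descriptor kind carries a
fixed semantic relation (`is-participant-of`, `is-quality-of`,
`is-proposition`) and value class (entity reference, quantity, text);
time point is assigned `is-proposition` with a quantity value by analogy
with period.

The bundled catalog has 87 actions partitioned by provenance (33 legacy /
51 added in this revision / 3 imported from OBI, one of the three a
flagged placeholder pending curation).  Accessions `EXACT2_000049`
(incubate) and `EXACT2_000089` (adjust) are fixed; others are sequential.
External-term imports are recorded as complete MIREOT triples (source
ontology URI, term URI, target superclass URI); the bundled list covers
the well-attested PATO/IAO/BFO/OBI imports only.

## Translation pipeline

1. **Normalize** — line endings to LF, `µ`→`μ`, `° C`/`℃`→`°C`,
   horizontal whitespace collapsed.  Idempotent, pure.
2. **Expand abbreviations** — whole-token, case-sensitive ("ON" never
   fires inside "CONICAL"; lowercase "on" is not the abbreviation).  The
   substitution log stores spans into the expanded text so the original
   is reconstructible (tested by property).
3. **Split sentences** — `.`/`!`/`?` before whitespace, plus newlines;
   periods inside decimals and after a small non-breaking-token list
   ("e.g.", "Fig.") are not boundaries.
4. **Identify actions** — protocols use an imperative register, so no
   statistical tagger is needed: candidates are the sentence-initial
   token (after skipping a small adverb list) and tokens following
   "and"/"then"/comma.  A hand-rolled inflection stripper (-s/-ed/-ing
   with un-doubling and e-restoration) generates lemma variants that are
   matched against the catalog lexicon (labels + synonyms).  A sentence
   with several matched verbs yields that many step copies; a sentence
   with none is kept verbatim as a note on the nearest step.
5. **Fill slots** — number+unit pairs are typed by the unit clue table
   (`data/units.yaml`; the clue inventory is a versioned file precisely so
   it can be extended).  Entities and equipment are linked by longest,
   non-overlapping, case-insensitive match against the lab config, which
   carries their external IDs.  Conditions are captured verbatim after
   "under"/"with <gerund>"/"in the presence of"; goals after "in order
   to" or a clause-final "to <verb>" (rejected when the next word is a
   determiner, so "transfer to the flask" is not a goal); goal-clause
   verbs are never promoted to actions.  Default tokens ("overnight",
   "room temperature") resolve through the lab defaults table with
   provenance `default`, and only when no explicit value of that kind was
   extracted.
6. **Carry-forward (optional)** — a step missing its essential
   biochemical entity may inherit the nearest preceding step's entity,
   flagged `inferred` and requiring explicit user confirmation before the
   protocol can count as complete.  This inference is off by default in
   `translate_protocol`: the base pipeline reports what the text itself
   fails to specify, which is the honest input to the user dialogue; the
   flag enables it.

Numerical choices: offsets are 0-based half-open everywhere; quantity
magnitudes are floats compared exactly (values are parsed, never
computed); when several mentions of one kind occur in a sentence copy, a
concentration introduced by the cue "concentration of" outranks bare or
entity-adjacent mentions ("…with 0.1% BSA solution at a concentration of
100 μg/mL" yields 100 μg/mL), and remaining ties go to the mention nearest
the action verb, the rest being preserved as notes.  Unknown unit symbols
keep their value with an empty ontology ID and a logged warning (rpm and
×g have no Units Ontology accession).  The whole pipeline is
deterministic: identical input bytes give identical output.

## Completeness and the Petri-net view

`check_completeness` reports, per step, missing essential kinds,
inferred-but-unconfirmed essentials, and quantity values without an
ontology unit ID; status is `complete` iff the first two lists are empty
for every step.  Unmatched sentences persist as notes and do not block
completeness.  User answers are monotone: they may supersede inferred or
default values but never remove extracted ones.

`compile_net` maps step *i* to transition *T_i* on a linear sequencing
chain and each essential kind to a condition place joined by a *pair* of
self-loop arcs — the condition is read, not consumed, so a satisfied
condition persists across firings (token conservation is asserted in
tests over every run).  All emitted arc weights are 1; the data model
permits weights ≥ 1 for hand-built nets.  Optional descriptors are
omitted entirely rather than emitted as unmarked-but-ignorable places:
only essentials gate firing.  Compilation targets linear protocols;
branching workflows can be expressed in the net data model but are not
emitted by the compiler.  The equivalence property — the simulation
completes iff the validator says complete — is checked over 100 random
synthetic protocols with randomly deleted essential values, alongside the
firing-order invariant (fired sequence equals step order).

## Synthetic data

No annotated protocol corpus is redistributable, so evaluation uses a
seeded generator whose sentences come from the template
`<Verb> the <entity> [at T°C | at RT] [for n min | for n h | overnight]
[in the <equipment>] [under sterile conditions] [in order to <goal>].`
Slot probabilities (0.7 temperature, 0.7 period, 0.4 equipment, 0.3
condition, 0.3 goal) keep most sentences partially specified, as real
protocols are.  Verbs are drawn from the catalog actions whose essential
set is exactly {biochemical entity}, so generated protocols are complete
by construction and incompleteness for the workflow study is induced by
deleting values after translation.  Default tokens (RT, overnight)
exercise the abbreviation + defaults path; an adversarial mode appends
out-of-grammar sentences (negations, unknown verbs) that must land in
the unmatched list.

The grammar is intentionally inside the clue-table coverage, so perfect
recovery (action recall = precision = descriptor-value accuracy = 1.0
over 200 seeds) demonstrates pipeline self-consistency — that the rules
implement their own specification exactly — not performance on free-form
prose.  Real protocols contain passives, ellipsis, cross-references and
tables that this generator deliberately does not emulate; coverage on
them is bounded by the catalog lexicon and the clue inventory, both of
which are data files meant to grow under curation
(`record_update_suggestions` emits exactly those curation records).

## Known limitations

- No negation handling ("do not smoke" is preserved as a note, never
  structured) and no command/if-then control flow; sequencing is linear.
- Entity linking is exact-match against the lab dictionary; no fuzzy
  matching or live PubChem/ChEBI lookups.
- The goal/condition cues are a small fixed lexicon; clause-final "to
  <verb>" capture can misfire on unusual word orders.
- Catalog membership beyond the well-attested verbs, and the default
  essential/optional assignments, are editorial choices documented in the
  catalog file itself.
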