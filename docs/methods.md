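# Methods

## Matching model

A record carries first name, last name and date of birth.  Matching is
the classical weighted-sum model: per-field similarities are combined
as sim(x,y) = Σ wᵢ·sim(xᵢ,yᵢ) / Σ wᵢ with wᵢ = log₂((1−eᵢ)/fᵢ), where
fᵢ is the field's mean value frequency and eᵢ its error rate.  The
bundled default (f, e) pairs are the stock values of a German cancer
registry evaluation:

| field         | f         | e     | w     |
|---------------|-----------|-------|-------|
| first name    | 0.000235  | 0.010 | 12.04 |
| last name     | 0.0000271 | 0.008 | 15.16 |
| birth day     | 0.0333    | 0.005 | 4.90  |
| birth month   | 0.0833    | 0.002 | 3.58  |
| birth year    | 0.0286    | 0.004 | 5.12  |
| date of birth | 0.00007   | 0.005 | 13.80 |

(The last-name weight is the exact value of the formula; the commonly
printed 15.15 appears to be a rounding artifact.)  Plaintext mode uses
day/month/year as three separate equality-compared fields; encoded mode
uses the joint date-of-birth filter with weight 13.8.

Similarities: q-gram Dice (q=2, multiset semantics, unpadded) for
plaintext strings; Dice over AND-cardinality for bit vectors; 0/1
equality for numeric components.  Classification against t₁ ≥ t₂ gives
match / possible match / non-match; only the best-scoring candidate is
classified, ties broken toward the earliest-inserted patient.  Default
thresholds: plaintext 0.9, Bloom 0.95 (clean data); 0.8 / 0.85 are the
recommended settings for noisier corpora.  With t₁ = t₂ (default) the
possible class is empty; possible matches, when configured, are stored
as new patients with a flag rather than queued for review.

**Missing values.** A field absent on either side is excluded from both
numerator and denominator, so incomplete records are compared on their
shared fields.  This is what makes a duplicate with a dropped last name
linkable at all (its similarity would otherwise be capped at ≈ 0.63,
below every threshold).  The conservative alternative — similarity 0
with the weight kept in the denominator — is available as
`MatchingConfig(count_missing_weight=True)`.

**Compound names.** Names are split on whitespace and hyphens; each
component gets its own similarity (and in encoded mode its own Bloom
filter).  The field similarity is the mean over the shorter side's
components of the best counterpart on the longer side, each longer-side
component used at most once (greedy, descending).  "PINKETT SMITH" vs
"PINKETT" scores 1: a dropped or added component does not penalize.
The flip side is that a person named "Hans Peter Koch" will also score
1 against a different "Hans Koch" — precision relies on the date of
birth separating such pairs.

## Bloom filter encoding

Name components are padded with q−1 framing characters, split into
bigrams and hashed into one bit vector per component: positions
pᵢ(e) = (H1(e) + i·H2(e)) mod m for i < k, with H1/H2 from a keyed
BLAKE2b digest of the feature under the shared secret (double hashing,
per-field salt).  All data holders with the same `EncodingConfig` are
bit-compatible.  Serialization is little-endian within bytes (bit i =
bit i mod 8 of byte ⌊i/8⌋), base64-encoded, m alongside.

Defaults: names m = 512, k = 10; DOB m = 256, k = 24.  The three date
components enter one joint filter as whole-value tagged features (D07,
M05, Y1990), not as digit q-grams: digits share century/decade/pad
grams across almost all dates, which would give unrelated dates Dice
0.5+ and destroy precision, whereas whole-value features reproduce the
stepwise equality semantics of the plaintext comparison (0, 1/3, 2/3, 1
before noise).

The k values balance three constraints that pull against each other:
mean fill (1-bit share) in [0.15, 0.35], expected Dice of unrelated
filters below 0.2, and bit-vector Dice within ±0.15 of q-gram Dice on
average.  The Dice noise floor of two unrelated filters approximately
equals the fill rate, so name fill must sit near 0.17 (measured corpus
mean fill ≈ 0.17, mean |ΔDice| ≈ 0.14).  Raising k toward 25% fill
increases error tolerance slightly but inflates the similarity of
unrelated records.

## Blocking

Soundex (plaintext): standard American Soundex of every first-name and
last-name component, one key per component.  A leading-letter error
("Zarah"/"Sarah") defeats the key — inherent to the method.

Hamming-LSH (encoded): a key samples Ψ bit positions; two filters with
agreement fraction s collide with probability ≈ s^Ψ, so Λ keys trade
recall against block size.  FieldLSH (default Λᵢ = 1 key per field,
Ψ = 36) draws each key from one field's filter and emits one instance
per compound component: one error-free field suffices for candidacy,
giving larger blocks and slightly better recall.  RecordLSH (Λ = 9,
Ψᵢ = 8 bits from each of the three fields) yields smaller blocks and
better precision/runtime at scale; missing fields contribute a sentinel
segment, compound fields their first component (keys must be fixed
length).

Calibration: after the first 1000 stored records (configurable), the
per-position 1-frequencies are measured, positions ranked by
|freq − 0.5|, the worst half pruned (ρ = 0.5), keys re-drawn from the
survivors and **all stored patients re-keyed** — without re-keying,
candidate retrieval against pre-calibration records would silently
break.  Position draws derive from a single seed; runs are
reproducible.

Candidate retrieval is database-side: keys live in an indexed SQLite
table (method, key index, key value, patient), and a query returns
exactly the stored patients sharing ≥ 1 key.  Without blocking, every
stored patient is a candidate.

## Engine

Insert workflow: validate (calendar rules; findings, not exceptions) →
normalize (uppercase, umlaut transcription ä→AE/ö→OE/ü→UE/ß→SS,
diacritic stripping, compound split) or encode → retrieve candidates →
score → classify best → assign PID (existing on match, else a fresh
12-character alphanumeric id, uniqueness-checked against the persisted
set) → persist record and keys.  Matching is exact but vectorized:
per field, all stored component values live in packed-bit matrices
(q-gram multisets are expanded to (gram, occurrence) indicator bits, so
popcount-AND equals multiset intersection exactly), and one insert
scores every candidate with a few popcount passes.  A 10k-record
end-to-end run without blocking takes ~30 s on one CPU; with LSH
blocking ~7 s.

## Synthetic data

`generate_dataset` emulates the incremental evaluation protocol: subset
A (70%) is loaded first, subset B (30%) is inserted one by one; 50% of
B duplicates a distinct A record.  Corruption is stratified by exact
counts, default 70% clean / 20% one / 10% two erroneous fields (the
"dirty" preset: 60/20/15/5 including three-field errors).  Error types:
keyboard typos (insert/delete/substitute/transpose), OCR confusions
(I↔L, W→VV, M→RN, …), German phonetic variants (PH↔F, C↔K, EI→AI, …),
missing values, compound add/drop and component swap; date corruptions
stay within the real calendar so the record remains insertable.

Names come from bundled pools: ~470 real given names (German classic,
modern, and common migrant-community names) and ~400 surnames (real
inventory plus toponymic place+ER/MANN formations), with Zipf-like rank
weights (exponent 0.5 / 0.3).  Same-name collision rates are ~4·10⁻³
(first) and ~3·10⁻³ (last) — far above a real census (~10⁻⁴), because a
bundled pool cannot reach census breadth.  Consequences: generated
datasets are *harder* than real ones for precision and block sizes, so
a green quality test here is conservative in those respects; but the
pools contain no extremely rare names, so weight estimation from
realized frequencies is not exercised (weights are fixed defaults).
Earlier drafts built surnames as stem×suffix families, which produced
unrealistic clusters of near-identical frequent surnames and was the
dominant false-positive source; the bundled inventory avoids this.

What a green run does not establish: behavior on real-world field
distributions (addresses, insurance numbers are out of scope), fill
rates for non-Latin scripts, robustness to adversarial encodings, or
cryptographic hardness of the Bloom encoding (no hardening schemes —
balancing, salting, xor-folding — are implemented).

## Evaluation

Quality is pairwise over the incremental protocol: each insert that
returns an existing PID predicts one pair; it is a true positive iff
the query's ground-truth partner carries that PID (a wrong-PID match
counts as both FP and FN).  Precision with no predictions is reported
as 0 and flagged.  Reduction ratio is computed per insert against the
store size at that moment and averaged; inserts into an empty store are
skipped.  Timings are recorded inside the engine (retrieval, matching,
persistence), excluding driver I/O.

## Numerical and design choices

- Bit-position convention: 0-based from the left of the serialized
  vector; the position-7 hash of 11011001 returns 1.
- Dice with an empty side (empty gram set, zero-cardinality filter) is
  0; two zero-cardinality filters also score 0.
- Tie-breaks: best-match prefers the earliest-inserted candidate;
  greedy compound assignment breaks ties by component order.
- Per-field salts in the hash keep identical grams in first and last
  name from mapping to identical positions.
- The year window for validation is 1850–2100 (proleptic Gregorian).
- PID: 12 characters from a 34-symbol alphabet (no I/O), ~60 bits;
  collision-checked against all previously issued PIDs, so uniqueness
  is unconditional.

## Known limitations

- Field set is fixed to name + date of birth; no address or insurance
  number fields, no per-value frequency weights.
- The possible-match band has no review workflow; records are persisted
  immediately.
- RecordLSH candidate counts retain a small linear component in store
  size (~2–6·10⁻⁴ per stored record): sparse filters bound per-bit
  agreement away from 1/2, so random Ψ-bit collisions cannot be fully
  pruned away.  FieldLSH block sizes scale with name-frequency mass.
- A cluster that grows through a chain of pairwise matches can drift:
  each new member is compared to stored records independently; no
  cluster-level consolidation is performed.  When a query matches
  multiple stored patients with different PIDs, the best match wins and
  a conflict warning is logged.
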