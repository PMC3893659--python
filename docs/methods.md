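# Methods

## Problem and stance

`bibdedup` links article records returned by several bibliographic databases
for the same query and flags pairs that denote the same publication. The
design stance is recall-first *for the search task*: because users screening
references for a systematic review must not lose a distinct article, the
matcher only merges when the evidence is strong, and accepts missing some
true duplicates (conflicting page numbers, wrong-year entries) as the price.
Output is the pair list itself — clustering or record fusion is left to the
caller (a union–find over the pairs gives clusters directly).

## Normalization

Every record is canonicalized once before any comparison:

* **Tokens.** Free text (journal, title) is lowercased, split on whitespace
  and all punctuation (hyphens, periods, commas included), and filtered
  against a stop-word list. The default list —
  `of, the, and, a, an, in, on, for, to, with, de, la, le` — covers the
  journal-title connectives that differ between full and abbreviated styles;
  it is overridable in `MatchConfig` and on the CLI. Diacritics are *not*
  folded: the character-level matcher compares literal codepoints and an
  accented character simply costs one mismatch, which is exactly the
  behaviour wanted for encoding variants.
* **Pages.** `112–8`-style truncated end pages are expanded with the leading
  digits of the start page (`112–8` → `112–118`); a single numeric page is
  both start and end; non-numeric paging (article numbers such as `e100044`)
  is kept verbatim with no end page. The operation is idempotent.
* **Identifiers.** PMIDs reduce to digits (pulled from an explicit `PMID`
  field or from a `PUBMED<digits>` record key), DOIs are lowercased with
  `doi:`/resolver prefixes stripped, ISSN/EISSN lose hyphens. Print and
  electronic ISSNs are never cross-compared: they are different numbers for
  the same journal.
* **Authors.** Each name reduces to `[surname, first-initial]`. Databases
  disagree on name order and initial punctuation, and no reliable order
  marker exists in the exports, so the surname is taken to be the longest
  alphabetic token (ties: first token) and middle initials are dropped. This
  is a heuristic; it erases the variation observed between real exports
  (`Smalheiser, NR.` vs `Smalheiser N.R.`) but will mis-split multi-word
  surnames with particles (`van der Berg`) — a known limitation.

## Matching

Both matching layers use the longest common subsequence with the similarity
`LCS / MIN_LEN`. At the character level this scores encoding variants
(`Hello` vs `Hḗllo` → 4/5). At the token level, token equality is
"one is a prefix of the other, or character similarity ≥ threshold", which
resolves per-token abbreviations the way acronym matchers do. One threshold
(default **0.8**) serves both levels; the comparison is inclusive (≥). The
division by the *shorter* length is what lets a truncated author list or an
abbreviated journal fully match its complete form; the risk of short
sequences matching spuriously is bounded by the rule structure (text
similarity alone never decides — rule 6 also needs the paging group, rule 7
needs title and authors too).

Raising the threshold can only shrink the duplicate set (a monotonicity the
test suite asserts over 0.7/0.8/0.9); 0.8 is the default because 0.7 starts
admitting unrelated text and 0.9 rejects legitimate encoding variants like
the 4/5 example above.

## Rules and engine

The per-pair procedure tries, in order: identifier denial (PMID, DOI,
ISSN/EISSN conflicts), identifier match (PMID, DOI), journal + paging group
(volume and start page equal, issue equal or missing on one side), and
journal + title + authors + non-conflicting pages. Missing values never
decide in either direction: a denial rule needs both sides present, a match
rule never fires on two nulls. Rule 6 deliberately requires volume
agreement — start page alone would merge distinct same-page articles across
volumes — and rule 7 tolerates a missing page but rejects a conflicting one.

The engine blocks by year, seeds each block's accumulator with the PubMed
records, folds the other sources in a fixed order (pubmed, embase, cinahl,
psycinfo, cochrane, then anything else, for determinism), and emits a pair
for *every* accumulated record an incoming record matches — so an article
indexed twice in one database yields two pairs against the same retained
PubMed copy. A record that matched anything stays out of the accumulator;
one that matched nothing joins it. Missing-year records are compared against
the full accumulated pool at the end. Wrong-year records are out of reach by
construction: blocking is what makes the join affordable, and the wrong-year
case is rare enough that chasing it would cost more than it returns.

Instrumentation counts record comparisons and evaluated text-sequence
comparisons; the four modes (`plain`, `denial`, `approx`, `approx_denial`)
toggle approximate matching and denial rules independently. On consistent
identifiers the denial rules are provably outcome-neutral (they only deny
pairs no match rule would accept) — the suite checks this equality — while
cutting text comparisons by roughly the fraction of pairs with identifiers
present on both sides.

## Synthetic corpus

Real multi-database result sets are licensed and cannot ship, so the test
bed is generated. Base articles get pronounceable random words (journal
names drawn from a pool of about one journal per eight articles, some with a
`Journal of …` shape), 1–5 authors, years in a narrow 2006–2010 band so that
year blocks genuinely fill, and consistent PMID/DOI/ISSN identifiers. An
article is indexed in a second database with probability `overlap_rate`
(default 0.4, a free choice in the plausible range for overlapping
biomedical databases); the reference copy goes to the first source
(preferring PubMed, the dominant pairing in practice), a perturbed variant
to the second, and the id pair is recorded as ground truth.

Perturbations mirror the observed cross-database variation classes:
per-token prefix abbreviation of journal names, page-range truncation,
author-initial re-punctuation, dropped trailing authors, one diacritic in a
title word, missing PMID/DOI, and (rarely) a missing or wrong year. Default
probabilities: abbreviation / page truncation / initials 0.3, author drop
0.05, missing PMID 0.2, missing DOI 0.3, diacritics 0.1, missing year 0.001
(about one per thousand records in real exports) and wrong year 0.001. Only
the missing-year rate is anchored to a reported figure; the others are
chosen to exercise each class in a corpus of a few hundred articles.
`modeled_profile()` is the same with wrong-year off — i.e. only variation
the matcher is designed to absorb — and `clean_profile()` zeroes everything.

What the generator does *not* model, and what passing tests therefore do not
show: non-prefix abbreviations (`Jnl`), supplement designations migrating
between journal and volume fields, entirely different page numbers for the
same article, real journal-name distributions, multilingual titles, or
conference-abstract/full-paper near-duplicates. On such inputs the matcher
is designed to miss rather than mis-merge, but the synthetic precision of
1.0 should not be read as a field-data guarantee.

Two structural choices keep evaluation crisp. Overlapping articles are
emitted in exactly **two** sources: with the accumulator semantics above, k
copies of one article produce k−1 pairs, so pairwise overlap makes
"ground-truth pair" and "discoverable pair" coincide and lets the engine be
compared for set equality against a brute-force all-pairs oracle. And the
diacritic perturbation is applied only to title words of ≥5 characters, so a
single accent keeps the word above the 0.8 character-similarity threshold —
matching the variation class the matcher models, where accents alter a
character or two of a word, not most of a short word.

## Numerical and degenerate-input choices

* Similarities are exact rational arithmetic in floating point
  (`int / int`); no tolerance is needed at the 0.8 comparison except that it
  is inclusive.
* Empty words/sequences raise `ValueError` in the similarity primitives;
  the field-level predicates translate "empty" into "missing, no match"
  before ever calling them.
* The BibTeX reader accepts straight quotes, typographic quotes and braces,
  skips malformed entries with a logged warning and offset (never aborting a
  batch), and preserves unknown fields verbatim for lossless round-trips.
* LCS tie-breaking is irrelevant: only the length is used, never a
  particular alignment.
* Problem sizes in the test suite (corpora of 160–340 articles, brute-force
  oracles on ≤500 records and ≤6-token sequences) are chosen so the whole
  suite completes in well under a minute while still covering multi-block,
  multi-source, missing-year and perturbed regimes.

## Known limitations

* Wrong-year duplicates are never found (by design; measured and documented
  by the suite rather than hidden).
* Within-source duplicates are only found via the accumulator — two copies
  inside one database match each other only if neither matched an earlier
  record.
* Author normalization mishandles particle surnames; journal matching has no
  authority file, so non-prefix abbreviations fail the prefix rule and fall
  back to character similarity, which may or may not clear the threshold.
* Pair output depends on source processing order in the sense that the
  retained copy is the PubMed-preferred accumulated one; the order is fixed,
  so results are deterministic.
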