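# Methods

## The validation model

A search filter is treated as a binary classifier over a fully screened
reference set. Given the gold-standard partition of a corpus into relevant
and irrelevant records, running a filter yields the 2×2 table
(a, b, c, d) = (relevant retrieved, irrelevant retrieved, relevant missed,
irrelevant excluded), from which sensitivity a/(a+c), specificity d/(b+d),
precision a/(a+b), NNR 1/precision, and accuracy (a+d)/(a+b+c+d) follow.
The model assumes *complete* screening: every record in the evaluation
corpus carries exactly one label. Evaluating against an incompletely
screened corpus is a hard error, not a silent restriction, because all five
statistics are defined only over the reference set.

Two conventions are interpretations rather than fixed by the validation
literature and are documented as such:

- **Accuracy** is computed as (a+d)/N, the standard classification accuracy;
  hedge studies name the metric more often than they print its formula.
- **Standard deviations** in single-term summaries use the sample convention
  (n−1 denominator) and are reported as undefined for a single term.

When a filter retrieves nothing (a+b = 0), precision and NNR are **undefined
markers**, never 0 or ∞; summaries take NNR ranges over terms with a defined
NNR only.

## Ovid filter semantics

The parser accepts the dialect used by published hedges: field-tagged atoms
(`.tw` text word, `.sh` subject heading), multi-word phrases, trailing-token
truncation `*`, and OR/AND/NOT with precedence NOT > AND > OR. Choices where
Ovid's behaviour is configurable or undocumented:

- **Tokenisation** case-folds and splits on every non-alphanumeric
  character. Hyphens split, so `pre-hospital.tw` (tokens `pre hospital`) and
  `prehospital.tw` are distinct terms — which is exactly why published
  filters carry both spellings.
- **`.tw` scope** is title + abstract; the record model carries no author
  keywords.
- **`.sh`** is an *unexploded* exact heading match with `/qualifier`
  suffixes stripped, compared token-wise so punctuation differences do not
  matter. MeSH-tree explosion would require shipping the MeSH hierarchy and
  is out of scope; `match_term` is the single switch point if explosion is
  ever added.
- **Truncation** is a prefix match (zero or more extra characters) on the
  final token only; mid-word wildcards are a parse error.
- OR/AND nodes are n-ary and self-flattening, which makes the canonical
  serialisation round-trip structurally exact (`parse(serialize(e)) == e`)
  without redundant parentheses.

## Greedy filter development

Published hedges were historically built by hand, adding and subtracting
terms from trial OR-combinations. The builder formalises that loop as
deterministic greedy forward selection with backward pruning. Because the
output is a pure OR-filter, retrieval grows monotonically with each added
term: sensitivity can only rise and specificity can only fall. The two
objectives are therefore constrained mirror images, and a single rule covers
both:

1. From the empty filter, repeatedly add the candidate that most improves
   the objective metric; ties break by greater improvement of the
   non-objective metric, then fewer retrieved records, then term text.
2. An addition is also acceptable while the non-objective metric is below
   its **floor** and the addition raises it. This branch is what drives the
   specificity-maximising variant: its objective starts at 1.0 and can only
   fall, so the builder instead crawls toward the sensitivity floor choosing
   the additions that cost the least specificity.
3. A candidate that would push an above-floor non-objective below the floor
   is never taken.
4. After each addition, any chosen term whose removal does not reduce the
   objective and strictly raises the non-objective is subtracted (redundant
   terms whose retrieval set became covered by later additions).
5. Stop at no acceptable addition or at `max_terms`. If the run ends with
   the floor unmet — or every candidate is rejected by the floor outright —
   the result is an explicit infeasibility, never a silent empty filter.

Objectives compare raw proportions, not display-rounded values, to avoid tie
artefacts. The builder is fully deterministic; `DevelopmentConfig.seed`
exists for API stability but no stochastic tie-shuffling is implemented.
Greedy selection is not optimal in general, so `exhaustive_or_search`
enumerates all OR-subsets of small pools (≤ 8 terms, subsets capped at 4 by
default) and `audit_against_exhaustive` records the objective gap in the
result's notes; the CLI runs the audit automatically for small pools.
Only pure-OR filters are emitted: the published filters contain no AND/NOT,
and the evaluation machinery handles them independently of the builder.

## Published-row reconstruction

The corpus the published figures were measured on is not deposited, so the
printed rows are audited for *internal* consistency instead of re-measured:
`reconstruct_table(R, I, sens, spec)` sets a = round(R·sens),
d = round(I·spec) (half-up rounding) with R = 431, I = 1671, and the NNR is
recomputed from the rebuilt table. A reported NNR printed as a whole number
is compared at integer precision — the sensitivity-maximising row's
reconstruction gives 2.01, consistent with the quoted "NNR of 2" — while
non-integer reported NNRs are compared at two decimals. Under this rule the
two paramedic rows pass and the prehospital row fails (reconstruction ≈ 2.38
against a printed 2.44); the audit flags the discrepancy and deliberately
does not resolve it.

## Synthetic corpora

No labelled reference set is publicly available, so the pipeline is
validated on generated corpora whose statistical structure is known exactly.
Each record gets filler titles/abstracts/headings, and each profiled term is
inserted **independently** per record with probability `p_relevant` or
`p_irrelevant` according to the record's class, at a placement drawn from
the profile's weights (subject-heading terms go only to the MeSH field,
text-word terms never do). This gives closed-form oracles:

- single-term expected sensitivity = `p_relevant`, expected specificity =
  `1 − p_irrelevant`;
- for terms with disjoint token patterns, OR-sensitivity = 1 − Π(1 − pᵢ).

The filler vocabulary is built prefix-disjoint from every profile-term token
(including truncation suffixes), so a term matches a record **iff** it was
inserted and the oracles are exact rather than approximate. Prevalence is
exact by construction — class sizes are counts, not draws — and generation
is byte-reproducible from the mandatory seed.

Defaults mirror the validation study's reference-set structure: 431 relevant
+ 1671 irrelevant records (20.5 % prevalence) and a 16-term candidate pool
whose occurrence rates put single terms in the regime hedge studies observe
(mostly low sensitivity, specificity near 1, NNR of a few), with two
hyphen-variant spellings of the same concept. Journals and years are drawn
from the six emergency-care journals and four index years the reference set
sampled.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: natural-language text (term occurrences are
independent insertions, with no co-occurrence structure, synonymy or topical
correlation; a correlation hook exists in the design but defaults off),
journal/year stratification effects, indexing variability in MeSH
assignment, and screening disagreement structure. Results on synthetic
corpora validate the *machinery* (parsing, matching, counting, optimisation),
not the published filters' field performance.

## Numerical conventions and degenerate inputs

- Display rounding: percentages to 1 dp, NNR to 2 dp, matching the precision
  of published tables; all stored values are unrounded.
- `reconstruct_table` rounds half-up (`floor(x + 0.5)`), so
  `performance(reconstruct_table(R, I, s, p))` recovers s and p to within
  1/(2R) and 1/(2I).
- Duplicate detection in retrieval-set preparation: record id first, then
  case-folded punctuation-stripped title + year, keeping the first
  occurrence. "No abstract" means empty or whitespace-only; no minimum
  length is imposed.
- A reviewer labelling one record twice with different values is an error;
  ids screened by only one reviewer are reported, never guessed.
- Problem sizes: the test suite and the acceptance script run the synthetic
  pipeline at the study-sized 2102-record corpus, Monte-Carlo checks at
  n = 10,000 records, monotonicity sweeps over 100 seeded 60-record corpora,
  and exhaustive development audits on 8-term pools with ≤ 4-term subsets.

## Known limitations

- `.sh` matching is unexploded; filters relying on MeSH explosion would
  score differently.
- The greedy builder explores pure OR-combinations only; AND/NOT structures
  can be evaluated but not constructed.
- The prehospital filter's query string is published elsewhere and is not
  redistributed; only its reported performance row is packaged, so parser
  round-trip checks cover the two paramedic strings.
- Confidence intervals and significance tests for filter performance are not
  implemented; published hedge validations of this design report none.
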