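# hedgekit

Toolkit for developing and validating Boolean literature **search filters**
(hedges) against gold-standard-labelled corpora of bibliographic records.

Search filters are pre-built Boolean query strings that restrict database
retrieval to a field — here, the paramedic literature, for which no MeSH term
exists. A filter is validated like a diagnostic test: every record of a
hand-screened reference set is labelled relevant or irrelevant, the filter is
run over the set, and the resulting 2×2 contingency table

|                | relevant | irrelevant |
|----------------|----------|------------|
| retrieved      | a        | b          |
| not retrieved  | c        | d          |

yields

- **sensitivity** = a/(a+c) — the share of relevant records retrieved,
- **specificity** = d/(b+d) — the share of irrelevant records correctly excluded,
- **precision** = a/(a+b) and **NNR** = 1/precision — the *number needed to
  read*: how many retrieved records must be screened to find one relevant,
- **accuracy** = (a+d)/(a+b+c+d).

hedgekit covers the whole second-generation development cycle:

- `hedgekit.records` — MEDLINE tagged-format reading/writing (via
  `Bio.Medline`), retrieval-set preparation (duplicate and abstract-less
  exclusion), and dual-screening bookkeeping (reconciliation of two
  independent label passes plus third-reviewer adjudication).
- `hedgekit.filterlang` — an Ovid-syntax parser/serialiser for field-tagged
  terms (`paramedic*.tw`, `Ambulances.sh`, truncation, OR/AND/NOT,
  parentheses) and their evaluation against records.
- `hedgekit.metrics` — contingency tables, performance reports, table
  reconstruction from printed figures, single-term summaries.
- `hedgekit.development` — single-term analysis and greedy add/subtract
  construction of OR-filters, with sensitivity- or specificity-maximising
  objectives and an exhaustive small-pool audit.
- `hedgekit.synthetic` — labelled MEDLINE-like corpus generation with exact
  closed-form performance oracles.
- `hedgekit.published` — the two published paramedic filters as verbatim Ovid
  strings with their reported performance, plus an internal-consistency audit.

## Worked example

Generate a labelled synthetic corpus, score a published filter against it and
audit the published performance rows:

```sh
$ hedgekit generate --spec spec.json --out-prefix syn
wrote syn.medline.txt (300 records, 60 relevant) and syn.labels.csv [seed=5]

$ hedgekit evaluate --filter paramedic_specificity \
    --corpus syn.medline.txt --labels syn.labels.csv
paramedic_specificity: sensitivity 88.3%, specificity 87.9%, precision 0.646, NNR 1.55, accuracy 88.0%

$ hedgekit check-published
paramedic_sensitivity: reconstructed table a=424 b=429 c=7 d=1242; NNR 2.01 vs reported 2.00: consistent
paramedic_specificity: reconstructed table a=408 b=196 c=23 d=1475; NNR 1.48 vs reported 1.48: consistent
prehospital: reconstructed table a=420 b=578 c=11 d=1093; NNR 2.38 vs reported 2.44: INCONSISTENT
flagged as internally inconsistent: prehospital
```

The first command writes a 300-record corpus (60 relevant, 20% prevalence) in
which three profiled terms occur with known class-conditional probabilities.
The second runs the specificity-maximising paramedic filter over it: 88.3% of
relevant records are retrieved, 87.9% of irrelevant ones excluded, and on
average 1.55 retrieved records must be read per relevant find.
`check-published` rebuilds each published filter's 2×2 table from the
reference-set class sizes (431 relevant / 1671 irrelevant) and the printed
rates: the two paramedic rows are internally consistent, while the older
prehospital filter's printed NNR of 2.44 disagrees with its reconstruction
(≈2.38) and is flagged rather than reproduced.

The same machinery is available as a library:

```python
import hedgekit as hk

corpus, gold = hk.generate_corpus(hk.default_corpus_spec(seed=42))
expr = hk.parse_filter("paramedic*.tw OR ems.tw OR Ambulances.sh")
report = hk.evaluate_performance(expr, corpus, gold)
print(report.format_row())
# {'sensitivity': '64.7%', 'specificity': '92.2%', 'precision': '0.680',
#  'nnr': '1.47', 'accuracy': '86.5%'}
```

Greedy filter development (`hedgekit develop`, `hk.greedy_develop`) starts
from an empty filter and OR-adds the candidate term that most improves the
objective metric, pruning redundant terms after each step, until no addition
helps, the other metric would fall below a configurable floor, or a term cap
is reached.

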