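# pathcurate

Curator-in-the-loop pathway annotation for a query gene.

Manually curated pathway knowledgebases (Reactome being the prototype) add
genes to pathways by reading PubMed-indexed literature — accurate but slow.
`pathcurate` implements the computational side of an LLM-assisted curation
workflow: given a query gene, it predicts which existing pathways the gene
likely belongs to from protein-interaction evidence, triages candidate
literature against those pathways with a two-way relevance score, generates
grounded text summaries for curator review through a pluggable LLM
provider, and validates generated annotations against curated ones with a
permutation-background semantic-similarity statistic. Everything runs
offline: file-backed stores replace database servers, and deterministic
mock providers replace remote embedding/LLM APIs (real providers plug in
behind the same contracts).

## The method

**Pathway prediction.** For a query gene with interaction partners, each
candidate pathway (one with an entity-level view containing reactions) is
tested for over-representation of the partners in its gene set with an
upper-tail binomial test. With *N* annotated genes overall, a pathway of
*m* annotated genes, *k* partners that are annotated genes, and *x* of them
inside the pathway,

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ x), X ~ Binomial(k, m/N),

computed by exact log-space pmf summation. P-values are Benjamini–Hochberg
adjusted over the tested family, ranked by (p, pathway id), truncated to
the top *k* pathways and filtered at an FDR threshold. Interactions come
from IntAct (PSI-MI TAB 2.7), BioGRID (TAB3), or a functional-interaction
(FI) TSV scored by a random-forest model; experimentally supported PPIs can
optionally be filtered by FI score.

**Literature triage.** Candidate abstracts (local JSON-lines store keyed by
PMID, searched with the facet queries "*GENE* interactions / reactions /
pathways") are scored against each predicted pathway's *context text* — the
pathway summary concatenated with the reaction-role descriptions of the
overlapping partners. Score one is the mean cosine similarity between the
context embedding and the abstract's chunk embeddings (token windows with
overlap); score two is an LLM-judge relevance rating on a 0–5 scale. A
match must pass both thresholds; passing matches rank by cosine, then
judge score.

**Grounded summarization.** Fixed prompt templates generate a per-match
summary, a condensed overview citing sources as `[PMID: n]`, and (for genes
already in the knowledgebase) an annotation overview citing
`[Pathway name]`. Every bracketed citation is checked lexically against the
sources actually supplied in the prompt context; anything else lands in a
grounding report.

**Validation.** For genes whose curated annotations appeared between two
releases, the generated summary is compared to the curated one by cosine
similarity of whole-text embeddings; matched similarities are tested
against a background of mismatched (different-gene) pairs with a two-sided
Mann–Whitney U test.

## Worked example

Generate a synthetic world with a planted signal — a query gene `QRYG1`
whose partners concentrate in one pathway and whose "relevant" abstracts
share that pathway's vocabulary — then run the pipeline:

```
$ pathcurate fixtures --out fx
$ pathcurate predict --kb fx/knowledgebase.json --abstracts fx/abstracts.jsonl \
    --intact fx/interactions.mitab --gene QRYG1 --out-markdown report.md
```

`report.md` then contains:

```
# Annotation report: QRYG1

Status: OK

## Predicted pathways

| pathway | p-value | FDR | overlap | evidence PMIDs |
|---|---|---|---|---|
| Synthetic pathway 0 (PW000) | 4.6e-05 | 0.000184 | P0G0, P0G1, P0G11, ... | 900001, 900002, ... |

## Summary

Mock summary of the supplied context. Sources: [PMID: 100001], [PMID: 100002], ...
```

Reading: the planted pathway `PW000` is recovered with binomial
p = 4.6e-05 (FDR 1.8e-04); ten of the query gene's partners overlap its
gene set; the PMIDs in the last column are the papers supporting those
interactions in the PPI file; the condensed summary cites exactly the five
abstracts that passed both relevance thresholds (the five planted
"relevant" ones — the five off-topic distractors score near zero and are
filtered out). Exit code is 0 on success, 2 for structured empty results
(e.g. a gene with no interaction partners).

The other subcommands: `pathcurate summarize` (overview of a gene's
existing annotations), `pathcurate extract-pdf` (arrow-format relationship
extraction from a full-text document), `pathcurate validate`
(matched-vs-permuted similarity test on a TSV of text pairs).

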