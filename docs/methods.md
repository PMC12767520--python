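# Methods

## Scope and data model

`pathcurate` operates on a flat JSON snapshot of a pathway knowledgebase
rather than a live graph database: each pathway carries its identifier,
display name, annotated gene set, free-text summary, per-gene reaction-role
texts, and two hierarchy flags (`has_entity_level_view`,
`contains_reactions`). Only pathways with both flags true are enrichment
candidates; this is the hierarchy control that keeps high-level container
pathways out of the tested family. Gene symbols are case-sensitive exact
strings and no synonym resolution is attempted — conflating or splitting
synonyms is a real failure mode of symbol-keyed curation and should surface,
not be papered over.

## Pathway enrichment

The binomial parameterization treats the query gene's annotated interaction
partners as trials: k = |partners ∩ annotated genes|, success probability
q = m/N where m is the pathway's annotated gene-set size and N the total
annotated genes, and the p-value is the upper tail P(X ≥ x) at the observed
overlap x. Partners not annotated anywhere carry no information about
pathway membership and are excluded from the trials. The tail is summed in
log space (gammaln + logsumexp); direct pmf summation underflows once tail
masses pass ~1e-300, and the log-space sum agrees with direct summation to
< 1e-12 relative error everywhere both are representable.

Benjamini–Hochberg adjustment (via `statsmodels.stats.multitest`) is
applied over exactly the pathways tested (x ≥ 1): untested pathways have no
p-value and do not belong to the family. Adjustment happens *before*
top-k truncation, so the reported FDR of a pathway does not depend on how
many results the caller asked to see. Ties in p-value break by pathway id
for deterministic output.

Defaults: `top_pathways=10`, `max_fdr=0.05`. These mirror the adjustable
thresholds of an interactive configuration panel; they are package
defaults, not empirically fitted values.

## Interaction parsing

Three dialects are read: PSI-MI TAB 2.7 (gene symbols from the alias
columns' `gene name` entries, PMIDs from the publication-identifier column,
taxid 9606 required for both interactors), BioGRID TAB3 (named header
columns), and a functional-interaction TSV (`gene_a`, `gene_b`, `score`).
Pairs are canonicalized lexicographically, self-edges dropped, duplicates
merged with PMIDs unioned and the maximum score kept. MITAB confidence
columns are deliberately ignored: PPIs are filtered by FI score (an
orthogonal predictor), not by source-database confidence. UniProt-to-symbol
mapping uses only the file's own alias columns — no external mapping
service, so parsing is fully offline.

## Relevance scoring

The reference text for a (pathway, query gene) pair is the pathway summary
concatenated with the reaction-role texts of the overlapping partners, in
sorted-symbol order with a fixed `"\n"` separator (the roles have no
inherent order; determinism is required for reproducible scores).

Abstracts are chunked into token windows (default 256 tokens — the sequence
capacity of a typical small sentence-embedding model — with overlap 10,
whitespace tokenization when no model tokenizer is configured) and the
score is the mean cosine between the context embedding and the chunk
embeddings. The context is embedded whole because context texts are short;
the abstract side is chunked so long abstracts are not truncated away. A
zero-norm embedding scores 0, never NaN. The judge provider rates the
abstract against the same context on a declared integer scale; 0–5 is the
package's declared scale. A match passes only if both scores meet their
thresholds (defaults `min_cosine=0.2`, `min_judge=1`), and passing matches
order by cosine desc, judge desc, pmid asc, pathway id asc.

### Offline providers

The mock embedder is a hashed bag-of-words: lowercase alphanumeric tokens,
crc32 into 64 buckets, count, L2-normalize. crc32 rather than Python's
built-in `hash` because the latter is salted per process and would break
cross-run determinism. The mock judge is token-set Jaccard rescaled to the
judge scale. The mock LLM echoes a digest of the context block it was
handed, citing every source marked `PMID: n:` or `Pathway: name` — so any
ungrounded citation under the mock indicates a context-assembly bug, and
fault-injection providers exercise the grounding check itself. These mocks
are lexical; real embedding models score paraphrases that share no tokens,
so planted-signal results under the mocks bound what vocabulary overlap can
do, not what a semantic model would do.

## Summarization and grounding

The four prompt templates are fixed text with `{placeholder}` substitution
(byte-exact, no reflowing). Context conventions: pair summaries mark the
abstract with its PMID; condensed summaries assemble `PMID: n: text`
paragraphs in rank order; annotated-gene summaries list
`Pathway: name` blocks. The grounding check is lexical — bracketed citation
tokens (`[PMID: n]`, `[Pathway name]`) must appear among the supplied
sources; semantic hallucination detection is out of scope. All matches
passing thresholds feed condensation (configurable). Word budgets default
to 200 (pair), 300 (condensed), 300 (annotated). Provider responses can be
cached keyed by prompt hash, making remote providers reproducible.

## Full-text extraction

Input is pre-extracted plain text (PDF-to-text is an adapter concern, kept
out of the core so fixtures stay text-only). Chunks are ranked by their
maximum cosine against the three facet queries and the top 12 (default) are
batched into a single extraction prompt. Output lines matching the arrow
grammar `GENE - type -> object` with the correct subject gene are parsed;
every other non-blank line is preserved in a raw remainder rather than
dropped, because context notes (cellular component, experimental system)
arrive as free text.

## Validation statistic

Each validation gene contributes one matched cosine (predicted vs curated
summary, whole-text embeddings — two complete texts of similar length, so
no chunking) and the background is built from mismatched (different-gene)
pairs. The test is a two-sided Mann–Whitney U (midranks for ties; exact
enumeration when both samples are tie-free and |x|·|y| ≤ 10⁴, otherwise the
tie- and continuity-corrected normal approximation, via
`scipy.stats.mannwhitneyu`).

**Background size.** The default background is a *sample* of n mismatched
pairs, not the full n(n−1) enumeration. Every background cosine reuses
texts that also produce the matched cosines; enumerating all ordered
mismatches multiplies that dependence while the rank test assumes
independent observations. In simulation under the null generator (all texts
drawn from one shared vocabulary; 200 seeds, n=50) the full background's
p-values are visibly non-uniform (KS vs uniform p ≈ 0.002, conservative),
while a size-n sampled background is calibrated (KS p ≈ 0.6, rejection rate
3.5% at α = 0.05). Full enumeration remains available
(`mode="all_mismatched"`) for descriptive histograms, where the richer
background distribution is what one wants to draw.

## Synthetic fixtures

The generators emulate the structure the pipeline consumes, not the
statistics of real corpora. Relevance signal is vocabulary disjointness:
pathway i owns tokens `pw{i}tok{j}`, off-topic text uses a reserved pool,
and validation genes own private vocabularies in planted mode or share one
pool in null mode. Defaults: 5 pathways × 12 genes, 40 unannotated
background genes, 30-token pathway vocabularies, 20 partners at 0.8
enrichment toward the target pathway, 5 relevant + 5 irrelevant abstracts
(~40 tokens each), FI scores uniform in [0.5, 1] — sizes chosen as a small
but non-degenerate desk-scale world in which one pathway's signal must
compete against four distractor pathways and a background gene pool.
Irrelevant abstracts do mention the query gene (off-topic papers about the
gene are the realistic distractor and keep retrieval non-trivial); their
remaining vocabulary is disjoint from every pathway. Each generator seeds
its own RNG from the config seed plus a fixed offset, so fixture components
are independent of call order and byte-identical across runs.

What passing tests show — and don't: under bag-of-words mocks, disjoint
vocabularies make planted signal nearly separable, so recovery rates near
100% demonstrate the pipeline's plumbing, ranking, thresholds, and
statistics, not embedding quality on real prose. Real-world behavior
depends on the embedding model and LLM behind the provider contracts.

## Known limitations

- Symbol-keyed throughout: synonym pairs are treated as distinct genes.
- The grounding check is lexical citation membership; a provider citing a
  correct source for a wrong claim passes it.
- Single-gene queries only; no pathway-topology-aware enrichment, no
  hypergeometric alternative, no network propagation.
- The mock search provider ranks by substring match count — adequate for a
  local store, not a substitute for a real literature search engine.
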