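"""Grounded summary generation through a pluggable LLM provider.

Three summary kinds are produced for a query gene:

* **pair summaries** — one per passing (abstract, pathway) match,
  explaining how the paper supports annotating the gene in that pathway;
* a **condensed summary** — the pair summaries merged into one overview,
  citing sources as ``[PMID: n]``;
* an **annotated-gene summary** — for genes already in the knowledgebase,
  an overview of their existing pathway annotations citing
  ``[Pathway name]``.

Every generation is grounded: the context handed to the provider marks its
sources (``PMID: n:`` paragraph prefixes, ``Pathway: name`` lines), and the
output's bracketed citations are checked lexically against exactly those
sources.  Citations with no supplied source land in the grounding report —
the first-line hallucination guard.  The offline mock provider cites
precisely the sources it is given, so a non-empty grounding report under
the mock always indicates a context-assembly bug.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Protocol, Sequence

from .knowledge_model import Knowledgebase, PathwayRecord, pathway_context_text
from .literature import AbstractRecord
from .prompts import TEMPLATES, TemplateId, render_prompt
from .relevance import ScoredMatch

DEFAULT_PAIR_WORDS = 200
DEFAULT_CONDENSED_WORDS = 300
DEFAULT_ANNOTATED_WORDS = 300

#: Bracketed citation tokens: [PMID: 123] or [Some Pathway Name]
_CITATION_RE = re.compile(r"\[([^\[\]]+)\]")
_PMID_CITATION_RE = re.compile(r"^PMID:\s*(\d+)$")
#: Context-source markers the mock provider echoes.
_CONTEXT_PMID_RE = re.compile(r"PMID:\s*(\d+):")
_CONTEXT_PATHWAY_RE = re.compile(r"(?m)(?:^|context: )Pathway: (.+)$")


class SummaryStatus(str, Enum):
    OK = "OK"
    NOT_ANNOTATED = "NOT_ANNOTATED"


@dataclass(frozen=True)
class Citations:
    pmids: frozenset[str]
    pathway_names: frozenset[str]


def extract_citations(text: str) -> Citations:
    """Parse bracketed citation tokens by the fixed grammar.

    ``[PMID: n]`` tokens are PMID citations; any other bracketed token is
    treated as a pathway-name citation.
    """
    pmids: set[str] = set()
    names: set[str] = set()
    for token in _CITATION_RE.findall(text):
        m = _PMID_CITATION_RE.match(token.strip())
        if m:
            pmids.add(m.group(1))
        else:
            names.add(token.strip())
    return Citations(pmids=frozenset(pmids), pathway_names=frozenset(names))


@dataclass(frozen=True)
class SummaryOutput:
    text: str
    cited_pmids: frozenset[str] = frozenset()
    cited_pathway_names: frozenset[str] = frozenset()
    grounding_report: frozenset[str] = frozenset()
    status: SummaryStatus = SummaryStatus.OK


class LLMProvider(Protocol):
    def complete(self, prompt: str) -> str:
        ...


class MockLLMProvider:
    """Deterministic offline provider.

    Echoes a digest of the context block it was handed: it cites every
    source marked ``PMID: n:`` (note the trailing colon — the bare
    ``[PMID: 123456]`` example inside the condensed template's own
    instructions is not a source) and every ``Pathway: name`` line.
    Identical prompts yield identical outputs.
    """

    def complete(self, prompt: str) -> str:
        if not prompt:
            raise ValueError("prompt must be non-empty")
        pmids = sorted(set(_CONTEXT_PMID_RE.findall(prompt)), key=lambda p: (len(p), p))
        names = sorted(set(_CONTEXT_PATHWAY_RE.findall(prompt)))
        parts = ["Mock summary of the supplied context."]
        if pmids:
            parts.append("Sources: " + ", ".join(f"[PMID: {p}]" for p in pmids) + ".")
        if names:
            parts.append("Pathways: " + ", ".join(f"[{n}]" for n in names) + ".")
        return " ".join(parts)


class CachingProvider:
    """Wrap a provider with a prompt-hash cache (optionally file-backed).

    Makes remote providers reproducible and cheap on re-runs; a no-op
    speedup for the mock.
    """

    def __init__(self, inner: LLMProvider, cache_path: str | Path | None = None):
        self._inner = inner
        self._cache_path = Path(cache_path) if cache_path else None
        self._cache: dict[str, str] = {}
        if self._cache_path and self._cache_path.exists():
            self._cache = json.loads(self._cache_path.read_text(encoding="utf-8"))

    def complete(self, prompt: str) -> str:
        key = hashlib.sha256(prompt.encode("utf-8")).hexdigest()
        if key not in self._cache:
            self._cache[key] = self._inner.complete(prompt)
            if self._cache_path:
                self._cache_path.write_text(
                    json.dumps(self._cache, ensure_ascii=False, indent=1),
                    encoding="utf-8",
                )
        return self._cache[key]


def _grounding_report(
    citations: Citations,
    allowed_pmids: frozenset[str] = frozenset(),
    allowed_names: frozenset[str] = frozenset(),
) -> frozenset[str]:
    bad_pmids = {f"PMID: {p}" for p in citations.pmids - allowed_pmids}
    bad_names = set(citations.pathway_names - allowed_names)
    return frozenset(bad_pmids | bad_names)


def summarize_pair(
    query_gene: str,
    match: ScoredMatch,
    abstract: AbstractRecord,
    pathway: PathwayRecord,
    partners: set[str] | frozenset[str],
    provider: LLMProvider,
    total_words: int = DEFAULT_PAIR_WORDS,
) -> SummaryOutput:
    """Summarize one passing (abstract, pathway) match for curator review.

    The abstract is marked with its PMID so the provider can cite it;
    interacting genes are passed in sorted order; the pathway text is the
    same context text the relevance scores were computed against.  Any
    cited PMID other than the abstract's own is flagged as ungrounded.
    """
    if not match.passed:
        raise ValueError("summarize_pair requires a match that passed thresholds")
    prompt = render_prompt(
        TEMPLATES[TemplateId.PAIR_SUMMARY],
        {
            "total_words": str(total_words),
            "pathway": pathway.name,
            "query_gene": query_gene,
            "interacting_genes": ", ".join(sorted(partners)),
            "pathway_text": pathway_context_text(pathway, set(partners)),
            "abstract_text": f"PMID: {abstract.pmid}: {abstract.title} {abstract.abstract_text}",
        },
    )
    text = provider.complete(prompt)
    citations = extract_citations(text)
    return SummaryOutput(
        text=text,
        cited_pmids=citations.pmids,
        cited_pathway_names=citations.pathway_names,
        grounding_report=_grounding_report(
            citations,
            allowed_pmids=frozenset({abstract.pmid}),
            allowed_names=frozenset({pathway.name}),
        ),
    )


def condense_summaries(
    pair_summaries: Sequence[tuple[str, str]],
    query_gene: str,
    interacting_genes: Sequence[str],
    provider: LLMProvider,
    total_words: int = DEFAULT_CONDENSED_WORDS,
) -> SummaryOutput:
    """Condense rank-ordered pair summaries into one overview.

    ``pair_summaries`` is a list of (pmid, summary text) in rank order; the
    context is assembled as ``PMID: n: text`` paragraphs so the provider
    can cite each source.  Citations outside the supplied PMID set are
    flagged.
    """
    if not pair_summaries:
        raise ValueError("need at least one pair summary to condense")
    context = "\n\n".join(f"PMID: {pmid}: {text}" for pmid, text in pair_summaries)
    prompt = render_prompt(
        TEMPLATES[TemplateId.CONDENSED_SUMMARY],
        {
            "total_words": str(total_words),
            "query_gene": query_gene,
            "interacting_genes": ", ".join(interacting_genes),
            "context": context,
        },
    )
    text = provider.complete(prompt)
    citations = extract_citations(text)
    return SummaryOutput(
        text=text,
        cited_pmids=citations.pmids,
        cited_pathway_names=citations.pathway_names,
        grounding_report=_grounding_report(
            citations, allowed_pmids=frozenset(p for p, _ in pair_summaries)
        ),
    )


def summarize_annotated_gene(
    kb: Knowledgebase,
    gene: str,
    provider: LLMProvider,
    total_words: int = DEFAULT_ANNOTATED_WORDS,
) -> SummaryOutput:
    """Overview of a gene's existing annotations across the knowledgebase.

    Context lists, per pathway containing the gene, the pathway name, its
    summary, and the gene's reaction-role text.  Genes absent from the
    knowledgebase return a distinct NOT_ANNOTATED status without any
    provider call.
    """
    containing = [p for p in kb.pathways if gene in p.gene_set]
    if not containing:
        return SummaryOutput(text="", status=SummaryStatus.NOT_ANNOTATED)
    blocks = []
    for p in containing:
        block = f"Pathway: {p.name}\n{p.summary_text}"
        role = p.gene_roles.get(gene)
        if role:
            block += f"\nRole of {gene}: {role}"
        blocks.append(block)
    prompt = render_prompt(
        TEMPLATES[TemplateId.ANNOTATED_PATHWAYS],
        {
            "total_words": str(total_words),
            "gene": gene,
            "annotated_pathways_text": "\n\n".join(blocks),
        },
    )
    text = provider.complete(prompt)
    citations = extract_citations(text)
    return SummaryOutput(
        text=text,
        cited_pmids=citations.pmids,
        cited_pathway_names=citations.pathway_names,
        grounding_report=_grounding_report(
            citations, allowed_names=frozenset(p.name for p in containing)
        ),
    )
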