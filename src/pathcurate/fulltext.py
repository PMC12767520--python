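"""Full-text relationship extraction: retrieve gene-relevant chunks, parse arrows.

Abstracts rarely carry the mechanistic detail reaction-based curation
needs, so full-text documents (pre-extracted plain text; PDF-to-text is an
optional adapter upstream) are chunked, the chunks most relevant to the
query gene's interactions/reactions/pathways are retrieved by cosine
similarity, and a provider extracts typed functional relationships in an
arrow format::

    GENE - relationship_type -> object

Lines matching that grammar become :class:`ExtractedRelationship`; anything
else the provider emits (context notes, malformed lines, relationships with
the wrong subject gene) is preserved verbatim in a raw remainder — never
silently dropped, since those lines often hold the cellular-component or
experimental-system context a curator wants to see.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .literature import build_queries
from .prompts import TEMPLATES, TemplateId, render_prompt
from .relevance import EmbedProvider, TextChunk, cosine
from .summarization import LLMProvider

#: Number of top chunks retrieved per document.
DEFAULT_TOP_CHUNKS = 12

_ARROW_RE = re.compile(r"^\s*(\S+)\s+-\s+(.+?)\s+->\s+(.+?)\s*$")


@dataclass(frozen=True)
class ExtractedRelationship:
    """One parsed arrow line: subject gene, verb phrase, object."""

    subject_gene: str
    relationship_type: str
    object: str


@dataclass(frozen=True)
class ExtractionResult:
    relationships: tuple[ExtractedRelationship, ...]
    raw_remainder: tuple[str, ...]


def retrieve_relevant_chunks(
    doc_chunks: list[TextChunk],
    query_gene: str,
    embedder: EmbedProvider,
    k: int = DEFAULT_TOP_CHUNKS,
) -> list[TextChunk]:
    """Top-k chunks by similarity to the gene's facet queries.

    Each chunk is scored by its maximum cosine similarity against the three
    facet query strings ("<gene> interactions/reactions/pathways"); ties
    break by ascending start_index so retrieval is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not doc_chunks:
        return []
    queries = build_queries(query_gene)
    vectors = embedder.embed(queries + [c.text for c in doc_chunks])
    query_vecs = vectors[: len(queries)]
    scored = []
    for chunk, vec in zip(doc_chunks, vectors[len(queries) :]):
        score = max(cosine(q, vec) for q in query_vecs)
        scored.append((-score, chunk.start_index, chunk))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [chunk for _, _, chunk in scored[:k]]


def parse_relationship_lines(lines: list[str], query_gene: str) -> ExtractionResult:
    """Parse provider output lines by the arrow grammar.

    A line parses iff it matches ``SUBJECT - type -> object`` *and* the
    subject equals the query gene; every other non-blank line lands in the
    raw remainder.
    """
    rels: list[ExtractedRelationship] = []
    remainder: list[str] = []
    for line in lines:
        if not line.strip():
            continue
        m = _ARROW_RE.match(line)
        if m and m.group(1) == query_gene:
            rels.append(
                ExtractedRelationship(
                    subject_gene=m.group(1),
                    relationship_type=m.group(2).strip(),
                    object=m.group(3).strip(),
                )
            )
        else:
            remainder.append(line.rstrip("\n"))
    return ExtractionResult(tuple(rels), tuple(remainder))


def serialize_relationships(rels: tuple[ExtractedRelationship, ...]) -> list[str]:
    """Normalized arrow lines (inverse of parsing, up to whitespace)."""
    return [f"{r.subject_gene} - {r.relationship_type} -> {r.object}" for r in rels]


def extract_relationships(
    chunks: list[TextChunk],
    query_gene: str,
    provider: LLMProvider,
) -> ExtractionResult:
    """Run the extraction prompt over the retrieved chunks, parse the output.

    All chunks are batched into a single prompt (one provider call per
    document), separated by blank lines in document order.
    """
    if not chunks:
        raise ValueError("need at least one chunk to extract from")
    document = "\n\n".join(c.text for c in chunks)
    prompt = render_prompt(
        TEMPLATES[TemplateId.RELATIONSHIP_EXTRACTION],
        {"query_gene": query_gene, "document": document},
    )
    output = provider.complete(prompt)
    return parse_relationship_lines(output.splitlines(), query_gene)


class MockExtractionProvider:
    """Offline extraction provider for end-to-end runs.

    Emits one arrow line per co-mention: any token in the document that
    looks like a gene symbol (uppercase alphanumeric, >=2 chars, not the
    query gene) appearing in the same chunk paragraph as the query gene
    becomes ``<query> - co-occurs with -> <token>``.  Deterministic;
    paragraphs without the query gene contribute a remainder note.
    """

    _SYMBOL_RE = re.compile(r"\b[A-Z][A-Z0-9]{1,9}\b")

    def complete(self, prompt: str) -> str:
        if not prompt:
            raise ValueError("prompt must be non-empty")
        gene_m = re.search(r"(?m)^query_gene: (.+)$", prompt)
        doc_m = re.search(r"(?ms)^document: (.+)\Z", prompt)
        if not gene_m or not doc_m:
            return "No relationships found."
        gene = gene_m.group(1).strip()
        lines: list[str] = []
        for para in doc_m.group(1).split("\n\n"):
            symbols = [s for s in dict.fromkeys(self._SYMBOL_RE.findall(para)) if s != gene]
            if gene in para:
                for sym in symbols:
                    lines.append(f"{gene} - co-occurs with -> {sym}")
            elif symbols:
                lines.append(f"Note: paragraph mentions {symbols[0]} without {gene}.")
        return "\n".join(lines) if lines else "No relationships found."
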