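"""The four prompt templates driving the curation workflow, verbatim.

These templates are carried byte-exactly (including typographic quotes and
placeholder names); rendering is literal substitution, never reflowing, so
that provider behavior is reproducible and the grounding conventions the
templates state (e.g. citing sources "[PMID: 123456]") stay in force.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class TemplateId(str, Enum):
    ANNOTATED_PATHWAYS = "ANNOTATED_PATHWAYS"
    PAIR_SUMMARY = "PAIR_SUMMARY"
    CONDENSED_SUMMARY = "CONDENSED_SUMMARY"
    RELATIONSHIP_EXTRACTION = "RELATIONSHIP_EXTRACTION"


@dataclass(frozen=True)
class PromptTemplate:
    template_id: TemplateId
    text: str
    required_placeholders: frozenset[str]


ANNOTATED_PATHWAYS_TEXT = """\
The gene below has been annotated in multiple pathways described in the context text below in Reactome. Write a summary having about {total_words} words with focus on the molecular functions of the gene in these pathways. Use the context text only for the summary and don’t speculate anything that is not in the text. Make sure to cite the pathway names in the format like this [Pathway_Name] for each sentence. The pathway names are provided in the context. Write a summary sentence at the end to summarize all results.
gene: {gene}
context: {annotated_pathways_text}"""

PAIR_SUMMARY_TEXT = """\
The text in the abstract section is excerpts of scientific papers’ abstracts collected from PubMed and best matched with pathway text below. Write a summary of the abstract text with about {total_words} words to highlight the query_gene and its interaction with interacting_genes, so that Reactome curators can create reactions based on the original papers. The generated text should be based on the abstract text below only, providing evidence showing the possible functions of the query gene in the pathway, {pathway}. Don’t speculate and don’t mention interacting genes if you cannot see them in the abstract text. Don’t just list interacting genes if there is no information.
query_gene: {query_gene}
interacting_genes: {interacting_genes}
pathway_text: {pathway_text}
abstract: {abstract_text}"""

CONDENSED_SUMMARY_TEXT = """\
Write a summary based only on the context to summarize the functions of the query gene with about {total_words} words. Highlight the query gene and its interactions with genes in the interacting_genes list. If you cannot see any genes listed in the interacting genes in the context, it is fine not mentioning them. Don’t speculate! Make sure to cite the original context sources, which are provided at the start of each paragraph before “: “, using a format like this [PMID: 123456]. Don’t just list interacting genes if there is no information.
query_gene: {query_gene}
interacting_genes: {interacting_genes}
context: {context} """

RELATIONSHIP_EXTRACTION_TEXT = """\
Extract functional relationships between the query gene specified below and other genes, proteins, or biological concepts from the following document. Output the relationships in the following format: {query_gene} - relationship_type -> other gene or protein or biological concept. If you can find the cellular component, tissue or cell type, or other experimental system related to the extracted relationships, make sure to list them.
query_gene: {query_gene}
document: {document}"""

TEMPLATES: dict[TemplateId, PromptTemplate] = {
    TemplateId.ANNOTATED_PATHWAYS: PromptTemplate(
        TemplateId.ANNOTATED_PATHWAYS,
        ANNOTATED_PATHWAYS_TEXT,
        frozenset({"total_words", "gene", "annotated_pathways_text"}),
    ),
    TemplateId.PAIR_SUMMARY: PromptTemplate(
        TemplateId.PAIR_SUMMARY,
        PAIR_SUMMARY_TEXT,
        frozenset(
            {"total_words", "pathway", "query_gene", "interacting_genes", "pathway_text", "abstract_text"}
        ),
    ),
    TemplateId.CONDENSED_SUMMARY: PromptTemplate(
        TemplateId.CONDENSED_SUMMARY,
        CONDENSED_SUMMARY_TEXT,
        frozenset({"total_words", "query_gene", "interacting_genes", "context"}),
    ),
    TemplateId.RELATIONSHIP_EXTRACTION: PromptTemplate(
        TemplateId.RELATIONSHIP_EXTRACTION,
        RELATIONSHIP_EXTRACTION_TEXT,
        frozenset({"query_gene", "document"}),
    ),
}

_PLACEHOLDER_RE = re.compile(r"\{([a-z_]+)\}")


def render_prompt(template: PromptTemplate, bindings: dict[str, str]) -> str:
    """Byte-exact substitution of ``{placeholder}`` markers.

    Every required placeholder must be bound (error names the first missing
    one); after substitution no ``{name}`` marker may remain.  Substitution
    replaces *all* occurrences of a placeholder — the extraction template
    intentionally names the query gene both in its format instruction and
    in its input block.
    """
    missing = sorted(template.required_placeholders - set(bindings))
    if missing:
        raise KeyError(missing[0])
    text = template.text
    for name in sorted(template.required_placeholders):
        text = text.replace("{" + name + "}", str(bindings[name]))
    residual = _PLACEHOLDER_RE.search(text)
    if residual:
        raise ValueError(f"unbound placeholder remains: {residual.group(1)}")
    return text
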