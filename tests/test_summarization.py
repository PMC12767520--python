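"""Prompt fidelity, rendering, citation grammar, and grounding checks."""

from pathlib import Path

import pytest

from pathcurate.knowledge_model import Knowledgebase, PathwayRecord
from pathcurate.literature import AbstractRecord
from pathcurate.prompts import TEMPLATES, TemplateId, render_prompt
from pathcurate.relevance import ScoredMatch
from pathcurate.summarization import (
    MockLLMProvider,
    CachingProvider,
    SummaryStatus,
    condense_summaries,
    extract_citations,
    summarize_annotated_gene,
    summarize_pair,
)

PROMPT_DIR = Path(__file__).parent / "data" / "prompts"

TEMPLATE_FILES = {
    TemplateId.ANNOTATED_PATHWAYS: "annotated_pathways.txt",
    TemplateId.PAIR_SUMMARY: "pair_summary.txt",
    TemplateId.CONDENSED_SUMMARY: "condensed_summary.txt",
    TemplateId.RELATIONSHIP_EXTRACTION: "relationship_extraction.txt",
}


class TestTemplateFidelity:
    @pytest.mark.parametrize("tid", list(TemplateId))
    def test_template_byte_identical_to_reference_copy(self, tid):
        reference = (PROMPT_DIR / TEMPLATE_FILES[tid]).read_text(encoding="utf-8")
        assert TEMPLATES[tid].text == reference

    def test_pair_summary_keeps_curator_instruction(self):
        rendered = render_prompt(
            TEMPLATES[TemplateId.PAIR_SUMMARY],
            {
                "total_words": "200",
                "pathway": "Pathway X",
                "query_gene": "TANC1",
                "interacting_genes": "A, B",
                "pathway_text": "ptext",
                "abstract_text": "atext",
            },
        )
        assert "so that Reactome curators can create reactions" in rendered


class TestRendering:
    BINDINGS = {
        "total_words": "200",
        "pathway": "P",
        "query_gene": "G1",
        "interacting_genes": "A",
        "pathway_text": "pt",
        "abstract_text": "at",
    }

    def test_missing_binding_names_placeholder(self):
        bindings = dict(self.BINDINGS)
        del bindings["query_gene"]
        with pytest.raises(KeyError, match="query_gene"):
            render_prompt(TEMPLATES[TemplateId.PAIR_SUMMARY], bindings)

    def test_double_render_deterministic(self):
        t = TEMPLATES[TemplateId.PAIR_SUMMARY]
        assert render_prompt(t, self.BINDINGS) == render_prompt(t, self.BINDINGS)

    def test_no_residual_placeholders(self):
        import re

        for tid, bindings in [
            (TemplateId.PAIR_SUMMARY, self.BINDINGS),
            (TemplateId.RELATIONSHIP_EXTRACTION, {"query_gene": "G", "document": "d"}),
        ]:
            rendered = render_prompt(TEMPLATES[tid], bindings)
            assert re.search(r"\{[a-z_]+\}", rendered) is None

    def test_extraction_template_substitutes_gene_in_format_line(self):
        rendered = render_prompt(
            TEMPLATES[TemplateId.RELATIONSHIP_EXTRACTION],
            {"query_gene": "TANC1", "document": "doc text"},
        )
        assert "format: TANC1 - relationship_type ->" in rendered


class TestCitationGrammar:
    def test_pmid_citation_extraction(self):
        c = extract_citations("evidence [PMID: 123456] and more")
        assert c.pmids == {"123456"} and c.pathway_names == frozenset()

    def test_pathway_name_citation(self):
        c = extract_citations("works in [Signaling by X] here")
        assert c.pathway_names == {"Signaling by X"}

    def test_mixed_and_repeated(self):
        c = extract_citations("[PMID: 7] text [Alpha Path] text [PMID: 7]")
        assert c.pmids == {"7"} and c.pathway_names == {"Alpha Path"}


class _FaultyProvider:
    """Fault injection: cites a PMID that was never supplied."""

    def complete(self, prompt: str) -> str:
        return "Bogus claim [PMID: 999999] and [Invented Pathway]."


def _kb2():
    return Knowledgebase(
        release_label="t",
        pathways=(
            PathwayRecord(pathway_id="P1", name="Alpha signaling",
                          gene_set=frozenset({"G1", "A"}), summary_text="alpha summary",
                          gene_roles={"G1": "G1 phosphorylates A"}),
            PathwayRecord(pathway_id="P2", name="Beta transport",
                          gene_set=frozenset({"G1", "B"}), summary_text="beta summary"),
        ),
    )


def _passing_match(pmid="101", pid="P1"):
    return ScoredMatch(pmid=pmid, pathway_id=pid, cosine_score=0.9, judge_score=5, passed=True)


def _abstract(pmid="101"):
    return AbstractRecord(pmid=pmid, title="t", abstract_text="G1 binds A in alpha")


class TestMockProvider:
    def test_cites_context_pmids(self, llm):
        out = llm.complete("instructions...\ncontext: PMID: 7: some pair summary")
        assert "[PMID: 7]" in out

    def test_empty_prompt_error(self, llm):
        with pytest.raises(ValueError):
            llm.complete("")

    def test_deterministic(self, llm):
        p = "context: PMID: 3: text\n\nPMID: 4: text"
        assert llm.complete(p) == llm.complete(p)

    def test_instruction_example_pmid_not_cited(self, llm):
        # the condensed template itself contains "[PMID: 123456]" as an example
        out = llm.complete("cite like [PMID: 123456].\ncontext: PMID: 9: real source")
        assert "123456" not in out and "[PMID: 9]" in out

    def test_caching_provider_transparent(self, tmp_path):
        calls = []

        class Counting:
            def complete(self, prompt):
                calls.append(prompt)
                return "out"

        cached = CachingProvider(Counting(), tmp_path / "cache.json")
        assert cached.complete("p") == cached.complete("p") == "out"
        assert len(calls) == 1


class TestSummarizePair:
    def test_mock_grounding_clean(self, llm):
        pw = _kb2().get("P1")
        out = summarize_pair("G1", _passing_match(), _abstract(), pw, {"A"}, llm)
        assert out.grounding_report == frozenset()
        assert out.cited_pmids == {"101"}

    def test_foreign_pmid_flagged(self):
        pw = _kb2().get("P1")
        out = summarize_pair("G1", _passing_match(), _abstract(), pw, {"A"}, _FaultyProvider())
        assert "PMID: 999999" in out.grounding_report
        assert "Invented Pathway" in out.grounding_report

    def test_unpassed_match_rejected(self, llm):
        m = ScoredMatch(pmid="1", pathway_id="P1", cosine_score=0.9, judge_score=5, passed=False)
        with pytest.raises(ValueError):
            summarize_pair("G1", m, _abstract("1"), _kb2().get("P1"), {"A"}, llm)

    def test_interacting_genes_sorted_in_prompt(self):
        captured = {}

        class Capture:
            def complete(self, prompt):
                captured["prompt"] = prompt
                return "ok"

        summarize_pair("G1", _passing_match(), _abstract(), _kb2().get("P1"),
                       {"Z", "A", "M"}, Capture())
        assert "interacting_genes: A, M, Z" in captured["prompt"]


class TestCondense:
    def test_single_summary_cites_exactly_that_pmid(self, llm):
        out = condense_summaries([("77", "pair text")], "G1", ["A"], llm)
        assert out.cited_pmids == {"77"}
        assert out.grounding_report == frozenset()

    def test_three_summaries_three_source_paragraphs(self):
        captured = {}

        class Capture:
            def complete(self, prompt):
                captured["prompt"] = prompt
                return "ok"

        condense_summaries([("1", "a"), ("2", "b"), ("3", "c")], "G1", [], Capture())
        context_block = captured["prompt"].split("context: ", 1)[1]
        assert context_block.count("PMID: ") == 3

    def test_requires_at_least_one(self, llm):
        with pytest.raises(ValueError):
            condense_summaries([], "G1", [], llm)

    def test_foreign_citation_flagged(self):
        out = condense_summaries([("77", "text")], "G1", [], _FaultyProvider())
        assert "PMID: 999999" in out.grounding_report


class TestAnnotatedGene:
    def test_absent_gene_no_provider_call(self):
        class Exploding:
            def complete(self, prompt):
                raise AssertionError("provider must not be called")

        out = summarize_annotated_gene(_kb2(), "NOPE", Exploding())
        assert out.status is SummaryStatus.NOT_ANNOTATED

    def test_context_names_both_pathways(self):
        captured = {}

        class Capture:
            def complete(self, prompt):
                captured["prompt"] = prompt
                return "ok"

        summarize_annotated_gene(_kb2(), "G1", Capture())
        assert "Pathway: Alpha signaling" in captured["prompt"]
        assert "Pathway: Beta transport" in captured["prompt"]
        assert "G1 phosphorylates A" in captured["prompt"]

    def test_mock_cites_only_supplied_names(self, llm):
        out = summarize_annotated_gene(_kb2(), "G1", llm)
        assert out.status is SummaryStatus.OK
        assert out.cited_pathway_names <= {"Alpha signaling", "Beta transport"}
        assert out.grounding_report == frozenset()
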