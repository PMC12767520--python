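"""End-to-end orchestration: gene in, structured annotation report out.

The pipeline chains the stages: predict candidate pathways from the query
gene's interaction partners, retrieve candidate abstracts from the local
store, score every (abstract, pathway) pair two ways (embedding cosine +
judge), generate grounded pair summaries and a condensed overview, and
attach the interaction-evidence PMIDs per pathway.  Every stage logs a
structured line (stage, counts, thresholds), and the report embeds the
exact configuration that produced it, so each number in the report is
traceable and re-runs with the mock providers are bit-identical.

Empty results are statuses, not crashes: a gene with no partners, no
annotated partners, no pathway overlap, no retrievable abstracts, or no
match passing both thresholds each gets a distinct code.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field

from . import relevance
from .interactions import InteractionSet, partners_of
from .knowledge_model import Knowledgebase, pathway_context_text
from .literature import AbstractStore, MockSearchProvider, build_queries, fetch_abstracts, union_search
from .pathway_prediction import (
    DEFAULT_MAX_FDR,
    DEFAULT_TOP_PATHWAYS,
    PredictionStatus,
    predict_interacting_pathways,
)
from .relevance import (
    DEFAULT_CHUNK_TOKENS,
    DEFAULT_JUDGE_SCALE,
    DEFAULT_MIN_COSINE,
    DEFAULT_MIN_JUDGE,
    DEFAULT_OVERLAP_TOKENS,
    HashedBagOfWordsEmbedder,
    MockJudgeProvider,
    ScoredMatch,
    rank_matches,
    score_abstract_pathway,
)
from .summarization import (
    DEFAULT_ANNOTATED_WORDS,
    DEFAULT_CONDENSED_WORDS,
    DEFAULT_PAIR_WORDS,
    MockLLMProvider,
    SummaryStatus,
    condense_summaries,
    summarize_annotated_gene,
    summarize_pair,
)


class PipelineStatus(str, Enum):
    OK = "OK"
    NO_PARTNERS = "NO_PARTNERS"
    NO_ANNOTATED_PARTNERS = "NO_ANNOTATED_PARTNERS"
    NO_OVERLAP = "NO_OVERLAP"
    NO_PASSING_PATHWAYS = "NO_PASSING_PATHWAYS"
    NO_ABSTRACTS = "NO_ABSTRACTS"
    NO_PASSING_MATCHES = "NO_PASSING_MATCHES"


_PREDICTION_TO_PIPELINE = {
    PredictionStatus.NO_PARTNERS: PipelineStatus.NO_PARTNERS,
    PredictionStatus.NO_ANNOTATED_PARTNERS: PipelineStatus.NO_ANNOTATED_PARTNERS,
    PredictionStatus.NO_OVERLAP: PipelineStatus.NO_OVERLAP,
    PredictionStatus.NO_PASSING_PATHWAYS: PipelineStatus.NO_PASSING_PATHWAYS,
}


class PipelineConfig(BaseModel):
    """All tunables of a run; serialized into the report for provenance."""

    model_config = ConfigDict(frozen=True)

    use_fi_filter: bool = False
    min_fi_score: float = Field(default=0.9, ge=0.0, le=1.0)
    top_abstracts: int = Field(default=10, ge=1)
    top_pathways: int = Field(default=DEFAULT_TOP_PATHWAYS, ge=1)
    max_fdr: float = Field(default=DEFAULT_MAX_FDR, gt=0.0, le=1.0)
    min_cosine: float = DEFAULT_MIN_COSINE
    min_judge: float = DEFAULT_MIN_JUDGE
    chunk_tokens: int = DEFAULT_CHUNK_TOKENS
    overlap_tokens: int = DEFAULT_OVERLAP_TOKENS
    judge_scale: int = DEFAULT_JUDGE_SCALE
    pair_words: int = DEFAULT_PAIR_WORDS
    condensed_words: int = DEFAULT_CONDENSED_WORDS
    annotated_words: int = DEFAULT_ANNOTATED_WORDS
    embed_provider: str = "mock"
    judge_provider: str = "mock"
    llm_provider: str = "mock"
    seed: int = 0


class PredictedPathwayReport(BaseModel):
    pathway_id: str
    name: str
    overlap_genes: list[str]
    x: int
    k: int
    m: int
    N: int
    p_value: float
    fdr: float
    evidence_pmids: list[str]


class MatchReport(BaseModel):
    pmid: str
    pathway_id: str
    cosine_score: float
    judge_score: float
    rank: int


class SummaryReport(BaseModel):
    text: str
    cited_pmids: list[str]
    cited_pathway_names: list[str]
    ungrounded_citations: list[str]


class PairSummaryReport(SummaryReport):
    pmid: str
    pathway_id: str


class AnnotationReport(BaseModel):
    """The pipeline's complete, JSON-serializable output for one query gene."""

    query_gene: str
    status: PipelineStatus
    config: PipelineConfig
    annotated_summary: SummaryReport | None = None
    predicted_pathways: list[PredictedPathwayReport] = []
    matches: list[MatchReport] = []
    pair_summaries: list[PairSummaryReport] = []
    condensed_summary: SummaryReport | None = None
    log: list[str] = []

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    def to_markdown(self) -> str:
        lines = [f"# Annotation report: {self.query_gene}", "", f"Status: {self.status.value}", ""]
        if self.annotated_summary:
            lines += ["## Existing annotation summary", "", self.annotated_summary.text, ""]
        if self.predicted_pathways:
            lines += ["## Predicted pathways", ""]
            lines.append("| pathway | p-value | FDR | overlap | evidence PMIDs |")
            lines.append("|---|---|---|---|---|")
            for p in self.predicted_pathways:
                lines.append(
                    f"| {p.name} ({p.pathway_id}) | {p.p_value:.3g} | {p.fdr:.3g} | "
                    f"{', '.join(p.overlap_genes)} | {', '.join(p.evidence_pmids)} |"
                )
            lines.append("")
        if self.condensed_summary:
            lines += ["## Summary", "", self.condensed_summary.text, ""]
        if self.pair_summaries:
            lines += ["## Details", ""]
            for ps in self.pair_summaries:
                lines += [f"### PMID {ps.pmid} — {ps.pathway_id}", "", ps.text, ""]
        return "\n".join(lines)


def _summary_report(s) -> SummaryReport:
    return SummaryReport(
        text=s.text,
        cited_pmids=sorted(s.cited_pmids),
        cited_pathway_names=sorted(s.cited_pathway_names),
        ungrounded_citations=sorted(s.grounding_report),
    )


def _make_providers(config: PipelineConfig):
    if config.embed_provider != "mock":
        raise ValueError(f"unknown embed provider {config.embed_provider!r}")
    if config.judge_provider != "mock":
        raise ValueError(f"unknown judge provider {config.judge_provider!r}")
    if config.llm_provider != "mock":
        raise ValueError(f"unknown llm provider {config.llm_provider!r}")
    return (
        HashedBagOfWordsEmbedder(),
        MockJudgeProvider(scale=config.judge_scale),
        MockLLMProvider(),
    )


def run_pipeline(
    kb: Knowledgebase,
    interactions: InteractionSet,
    store: AbstractStore,
    query_gene: str,
    config: PipelineConfig | None = None,
    embedder=None,
    judge=None,
    llm=None,
    search_provider=None,
) -> AnnotationReport:
    """Run every stage for one query gene and assemble the report.

    Providers default to the offline mocks named in the config; explicit
    provider objects override it (the hook for real embedding/judge/LLM
    backends).
    """
    config = config or PipelineConfig()
    log: list[str] = []
    mock_embedder, mock_judge, mock_llm = _make_providers(config)
    embedder = embedder or mock_embedder
    judge = judge or mock_judge
    llm = llm or mock_llm
    search_provider = search_provider or MockSearchProvider(store)

    report = AnnotationReport(query_gene=query_gene, status=PipelineStatus.OK, config=config)

    # Stage 0: overview of any existing annotation
    annotated = summarize_annotated_gene(kb, query_gene, llm, config.annotated_words)
    if annotated.status == SummaryStatus.OK:
        report.annotated_summary = _summary_report(annotated)
        log.append(f"annotated_summary: gene={query_gene} pathways_cited={len(annotated.cited_pathway_names)}")
    else:
        log.append(f"annotated_summary: gene={query_gene} status=NOT_ANNOTATED")

    # Stage 1: pathway prediction from interaction partners
    prediction = predict_interacting_pathways(
        kb, interactions, query_gene, config.top_pathways, config.max_fdr
    )
    log.append(
        f"predict: status={prediction.status.value} pathways={len(prediction.pathways)} "
        f"top_pathways={config.top_pathways} max_fdr={config.max_fdr}"
    )
    if prediction.status != PredictionStatus.OK:
        report.status = _PREDICTION_TO_PIPELINE[prediction.status]
        report.log = log
        return report

    partner_edges = partners_of(interactions, query_gene)
    edge_by_partner = {g: e for g, e in partner_edges}
    for ep in prediction.pathways:
        evidence = sorted(
            {p for g in ep.overlap_genes for p in edge_by_partner[g].pmids},
            key=lambda s: (len(s), s),
        )
        report.predicted_pathways.append(
            PredictedPathwayReport(
                pathway_id=ep.pathway_id,
                name=ep.name,
                overlap_genes=sorted(ep.overlap_genes),
                x=ep.x,
                k=ep.k,
                m=ep.m,
                N=ep.N,
                p_value=ep.p_value,
                fdr=ep.fdr,
                evidence_pmids=evidence,
            )
        )

    # Stage 2: literature retrieval
    queries = build_queries(query_gene)
    pmids = union_search(search_provider, queries, config.top_abstracts)
    fetched = fetch_abstracts(store, pmids, config.top_abstracts) if pmids else None
    n_found = len(fetched.records) if fetched else 0
    log.append(f"retrieve: queries={len(queries)} pmids={len(pmids)} fetched={n_found}")
    if not fetched or not fetched.records:
        report.status = PipelineStatus.NO_ABSTRACTS
        report.log = log
        return report

    # Stage 3: two-way relevance scoring of every (abstract, pathway) pair
    enriched_by_id = {ep.pathway_id: ep for ep in prediction.pathways}
    contexts = {
        ep.pathway_id: pathway_context_text(kb.get(ep.pathway_id), set(ep.overlap_genes))
        for ep in prediction.pathways
    }
    raw_matches: list[ScoredMatch] = []
    for rec in fetched.records:
        for pid, context in contexts.items():
            cos = score_abstract_pathway(
                rec.abstract_text,
                context,
                embedder,
                config.chunk_tokens,
                config.overlap_tokens,
                source_id=rec.pmid,
            )
            j = judge.judge(rec.abstract_text, context, query_gene)
            raw_matches.append(
                ScoredMatch(pmid=rec.pmid, pathway_id=pid, cosine_score=cos, judge_score=j)
            )
    ranked = rank_matches(raw_matches, config.min_cosine, config.min_judge)
    log.append(
        f"score: pairs={len(raw_matches)} passed={len(ranked)} "
        f"min_cosine={config.min_cosine} min_judge={config.min_judge}"
    )
    report.matches = [
        MatchReport(
            pmid=m.pmid,
            pathway_id=m.pathway_id,
            cosine_score=round(m.cosine_score, 4),
            judge_score=round(m.judge_score, 4),
            rank=i + 1,
        )
        for i, m in enumerate(ranked)
    ]
    if not ranked:
        report.status = PipelineStatus.NO_PASSING_MATCHES
        report.log = log
        return report

    # Stage 4: grounded summaries
    all_overlap = sorted({g for ep in prediction.pathways for g in ep.overlap_genes})
    pair_texts: list[tuple[str, str]] = []
    for m in ranked:
        ep = enriched_by_id[m.pathway_id]
        rec = store.get(m.pmid)
        assert rec is not None
        s = summarize_pair(
            query_gene, m, rec, kb.get(m.pathway_id), ep.overlap_genes, llm, config.pair_words
        )
        report.pair_summaries.append(
            PairSummaryReport(
                pmid=m.pmid,
                pathway_id=m.pathway_id,
                text=s.text,
                cited_pmids=sorted(s.cited_pmids),
                cited_pathway_names=sorted(s.cited_pathway_names),
                ungrounded_citations=sorted(s.grounding_report),
            )
        )
        pair_texts.append((m.pmid, s.text))
    condensed = condense_summaries(pair_texts, query_gene, all_overlap, llm, config.condensed_words)
    report.condensed_summary = _summary_report(condensed)
    log.append(
        f"summarize: pair_summaries={len(pair_texts)} "
        f"ungrounded={sum(len(p.ungrounded_citations) for p in report.pair_summaries)}"
    )
    report.log = log
    return report


def exit_code_for(status: PipelineStatus) -> int:
    """0 for success, 2 for structured empty results."""
    return 0 if status == PipelineStatus.OK else 2
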