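"""Deterministic synthetic fixtures with controllable relevance signal.

Everything the pipeline consumes — knowledgebase snapshots, interaction
files in all three dialects, abstract corpora, full-text documents, and
validation text pairs — can be generated here with a seed, so the entire
test surface runs offline and reproducibly.

The relevance mechanism is vocabulary disjointness: each pathway owns a
disjoint token vocabulary used for its summary, role texts, and "relevant"
abstracts, while "irrelevant" abstracts draw from a reserved off-topic
vocabulary.  Because the offline embedder is a bag-of-words, disjoint
vocabularies give near-orthogonal embeddings — planted signal is therefore
sharp under the mock providers, sharper than real embeddings on real text
would be.

Each ``make_*`` function seeds its own RNG from the config seed, so fixture
components are independent of call order; the same config always yields
byte-identical artifacts.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .interactions import InteractionSet, Source
from .knowledge_model import Knowledgebase, PathwayRecord, save_knowledgebase
from .literature import AbstractRecord, AbstractStore
from .validation import GeneTextPair

QUERY_GENE = "QRYG1"
PMID_BASE = 100_001


class FixtureConfig(BaseModel):
    """Knobs for the synthetic world; defaults are the standard test conditions."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_pathways: int = Field(default=5, ge=0)
    genes_per_pathway: int = Field(default=12, ge=1)
    n_background_genes: int = Field(default=40, ge=0)
    vocab_size_per_pathway: int = Field(default=30, ge=4)
    n_relevant_abstracts: int = Field(default=5, ge=0)
    n_irrelevant_abstracts: int = Field(default=5, ge=0)
    n_partners: int = Field(default=20, ge=1)
    partner_enrichment: float = Field(default=0.8, ge=0.0, le=1.0)
    signal: str = Field(default="planted", pattern="^(planted|null)$")

    # text lengths (tokens) for generated pieces
    summary_words: int = 12
    role_words: int = 6
    abstract_words: int = 40
    validation_words: int = 30
    validation_vocab_per_gene: int = 8
    validation_shared_pool: int = 50


def pathway_vocab(i: int, size: int) -> list[str]:
    """Disjoint per-pathway token vocabulary."""
    return [f"pw{i}tok{j}" for j in range(size)]


def offtopic_vocab(size: int) -> list[str]:
    """Reserved vocabulary never used by any pathway."""
    return [f"offtok{j}" for j in range(size)]


def _sample_words(rng: np.random.Generator, vocab: list[str], n: int) -> list[str]:
    return [vocab[k] for k in rng.integers(0, len(vocab), size=n)]


def make_knowledgebase(cfg: FixtureConfig) -> Knowledgebase:
    """Pathways with disjoint gene sets and disjoint core vocabularies.

    Pathway ``i`` owns genes ``P{i}G{j}``; its summary and per-gene role
    texts are drawn from its private vocabulary.  Eligibility flags are true
    by default (tests flip them per-record where needed).
    """
    rng = np.random.default_rng(cfg.seed)
    pathways = []
    for i in range(cfg.n_pathways):
        vocab = pathway_vocab(i, cfg.vocab_size_per_pathway)
        genes = frozenset(f"P{i}G{j}" for j in range(cfg.genes_per_pathway))
        summary = " ".join(_sample_words(rng, vocab, cfg.summary_words))
        roles = {
            g: f"{g} " + " ".join(_sample_words(rng, vocab, cfg.role_words))
            for g in sorted(genes)
        }
        pathways.append(
            PathwayRecord(
                pathway_id=f"PW{i:03d}",
                name=f"Synthetic pathway {i}",
                gene_set=genes,
                summary_text=summary,
                gene_roles=roles,
            )
        )
    return Knowledgebase(release_label=f"synthetic-seed{cfg.seed}", pathways=tuple(pathways))


def background_genes(cfg: FixtureConfig) -> list[str]:
    """Interactor genes annotated in no pathway."""
    return [f"BG{j}" for j in range(cfg.n_background_genes)]


def make_interactions(
    cfg: FixtureConfig,
    kb: Knowledgebase,
    query_gene: str = QUERY_GENE,
    target_pathway: str | None = None,
) -> InteractionSet:
    """A star of FI edges around the query gene with planted enrichment.

    Each of ``n_partners`` partners is drawn from the target pathway's gene
    set with probability ``partner_enrichment``, otherwise uniformly from
    the other annotated genes plus the unannotated background pool.  FI
    scores are uniform in [0.5, 1]; each edge carries one sequential PMID.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if target_pathway is None and len(kb) > 0:
        target_pathway = kb.pathways[0].pathway_id
    target_genes = sorted(kb.get(target_pathway).gene_set) if target_pathway else []
    other_pool = sorted(
        (kb.annotated_genes - set(target_genes)) | set(background_genes(cfg))
    )
    partners: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(partners) < cfg.n_partners and attempts < 100 * cfg.n_partners:
        attempts += 1
        if target_genes and rng.random() < cfg.partner_enrichment:
            g = target_genes[rng.integers(0, len(target_genes))]
        elif other_pool:
            g = other_pool[rng.integers(0, len(other_pool))]
        else:
            break
        if g != query_gene and g not in seen:
            seen.add(g)
            partners.append(g)
    s = InteractionSet()
    for idx, g in enumerate(partners):
        score = float(0.5 + 0.5 * rng.random())
        s.add(
            query_gene,
            g,
            Source.REACTOME_FI,
            score=round(score, 4),
            pmids=frozenset({str(900_001 + idx)}),
        )
    s.report.rows_read = len(partners)
    s.report.edges_kept = len(s)
    return s


def make_abstract_corpus(
    cfg: FixtureConfig,
    kb: Knowledgebase,
    query_gene: str = QUERY_GENE,
    target_pathway: str | None = None,
) -> tuple[AbstractStore, list[str], list[str]]:
    """Abstract store with planted relevance; returns (store, relevant, irrelevant) PMIDs.

    Relevant abstracts mix the target pathway's vocabulary with the query
    gene symbol; irrelevant ones mention the gene too (so retrieval finds
    them — off-topic papers about the gene are the realistic distractor)
    but otherwise use the reserved off-topic vocabulary.  PMIDs are
    sequential from a fixed base.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if target_pathway is None and len(kb) > 0:
        target_pathway = kb.pathways[0].pathway_id
    target_idx = int(target_pathway[2:]) if target_pathway else 0
    rel_vocab = pathway_vocab(target_idx, cfg.vocab_size_per_pathway)
    irr_vocab = offtopic_vocab(cfg.vocab_size_per_pathway)
    facets = ["interactions", "reactions", "pathways"]
    store = AbstractStore()
    relevant: list[str] = []
    irrelevant: list[str] = []
    pmid = PMID_BASE
    for i in range(cfg.n_relevant_abstracts):
        words = _sample_words(rng, rel_vocab, cfg.abstract_words)
        text = f"{query_gene} {facets[i % 3]} " + " ".join(words)
        store.add(
            AbstractRecord(
                pmid=str(pmid),
                title=f"Study of {query_gene} {facets[i % 3]}",
                abstract_text=text,
                year=2020 + (i % 5),
            )
        )
        relevant.append(str(pmid))
        pmid += 1
    for i in range(cfg.n_irrelevant_abstracts):
        words = _sample_words(rng, irr_vocab, cfg.abstract_words)
        text = f"{query_gene} {facets[i % 3]} " + " ".join(words)
        store.add(
            AbstractRecord(
                pmid=str(pmid),
                title=f"Unrelated report mentioning {query_gene}",
                abstract_text=text,
                year=2020 + (i % 5),
            )
        )
        irrelevant.append(str(pmid))
        pmid += 1
    return store, relevant, irrelevant


def make_fulltext_document(
    cfg: FixtureConfig,
    kb: Knowledgebase,
    query_gene: str = QUERY_GENE,
    target_pathway: str | None = None,
    n_relevant_paragraphs: int = 4,
    n_offtopic_paragraphs: int = 4,
) -> str:
    """Plain-text document: paragraphs co-mentioning the gene with pathway
    genes, interleaved with off-topic paragraphs."""
    rng = np.random.default_rng(cfg.seed + 3)
    if target_pathway is None and len(kb) > 0:
        target_pathway = kb.pathways[0].pathway_id
    target_idx = int(target_pathway[2:]) if target_pathway else 0
    rel_vocab = pathway_vocab(target_idx, cfg.vocab_size_per_pathway)
    irr_vocab = offtopic_vocab(cfg.vocab_size_per_pathway)
    genes = sorted(kb.get(target_pathway).gene_set) if target_pathway else []
    paras: list[str] = []
    for i in range(n_relevant_paragraphs):
        partner = genes[i % len(genes)] if genes else "NONE1"
        words = _sample_words(rng, rel_vocab, 25)
        paras.append(
            f"{query_gene} interactions with {partner} were observed. " + " ".join(words)
        )
    for _ in range(n_offtopic_paragraphs):
        words = _sample_words(rng, irr_vocab, 25)
        paras.append("Unrelated observations. " + " ".join(words))
    return "\n\n".join(paras)


def make_validation_pairs(cfg: FixtureConfig, n_genes: int) -> list[GeneTextPair]:
    """Gene text pairs with planted or null similarity structure.

    ``planted``: each gene owns a private vocabulary; its predicted and
    curated texts are drawn from it, so matched cosines are high and
    mismatched ones near zero.  ``null``: every text is drawn from one
    shared pool, so matched and mismatched cosines are identically
    distributed — the calibration case.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    pairs: list[GeneTextPair] = []
    shared = [f"pool{j}" for j in range(cfg.validation_shared_pool)]
    for g in range(n_genes):
        if cfg.signal == "planted":
            vocab = [f"gene{g}w{j}" for j in range(cfg.validation_vocab_per_gene)]
        else:
            vocab = shared
        predicted = " ".join(_sample_words(rng, vocab, cfg.validation_words))
        curated = " ".join(_sample_words(rng, vocab, cfg.validation_words))
        pairs.append(GeneTextPair(gene=f"VG{g}", predicted_text=predicted, curated_text=curated))
    return pairs


# ---------------------------------------------------------------------------
# File writers: emit every dialect the parsers read
# ---------------------------------------------------------------------------


def write_psimitab(s: InteractionSet, path: str | Path) -> None:
    """Serialize edges as minimal PSI-MI TAB 2.7 rows (15 columns)."""
    lines = []
    for e in s.edges.values():
        pub = "|".join(f"pubmed:{p}" for p in sorted(e.pmids)) or "-"
        row = [
            f"uniprotkb:{e.gene_a}ACC",
            f"uniprotkb:{e.gene_b}ACC",
            "-",
            "-",
            f"uniprotkb:{e.gene_a}(gene name)",
            f"uniprotkb:{e.gene_b}(gene name)",
            'psi-mi:"MI:0018"(two hybrid)',
            "author et al. (2020)",
            pub,
            "taxid:9606(human)",
            "taxid:9606(human)",
            'psi-mi:"MI:0915"(physical association)',
            'psi-mi:"MI:0469"(IntAct)',
            f"intact:EBI-{zlib.crc32(f'{e.gene_a}|{e.gene_b}'.encode()) % 10_000_000}",
            "-",
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_biogrid_tab3(s: InteractionSet, path: str | Path) -> None:
    """Serialize edges as a minimal BioGRID TAB3 file."""
    header = "\t".join(
        [
            "#BioGRID Interaction ID",
            "Official Symbol Interactor A",
            "Official Symbol Interactor B",
            "Publication Source",
            "Organism ID Interactor A",
            "Organism ID Interactor B",
        ]
    )
    lines = [header]
    for i, e in enumerate(s.edges.values(), start=1):
        pub = "|".join(f"PUBMED:{p}" for p in sorted(e.pmids)) or "-"
        lines.append(
            "\t".join([str(i), e.gene_a, e.gene_b, pub, "9606", "9606"])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fi_tsv(s: InteractionSet, path: str | Path) -> None:
    """Serialize edges as a functional-interaction TSV."""
    lines = ["gene_a\tgene_b\tscore"]
    for e in s.edges.values():
        score = e.score if e.score is not None else 1.0
        lines.append(f"{e.gene_a}\t{e.gene_b}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_validation_pairs_tsv(pairs: list[GeneTextPair], path: str | Path) -> None:
    lines = ["gene\tpredicted_text\tcurated_text"]
    for p in pairs:
        lines.append(f"{p.gene}\t{p.predicted_text}\t{p.curated_text}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_dir(cfg: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a complete fixture set; returns {artifact: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb = make_knowledgebase(cfg)
    interactions = make_interactions(cfg, kb)
    store, _, _ = make_abstract_corpus(cfg, kb)
    pairs = make_validation_pairs(cfg, n_genes=20)
    doc = make_fulltext_document(cfg, kb)
    paths = {
        "knowledgebase": out / "knowledgebase.json",
        "intact": out / "interactions.mitab",
        "biogrid": out / "interactions.tab3.txt",
        "fi": out / "interactions.fi.tsv",
        "abstracts": out / "abstracts.jsonl",
        "validation_pairs": out / "validation_pairs.tsv",
        "fulltext": out / "fulltext.txt",
    }
    save_knowledgebase(kb, paths["knowledgebase"])
    write_psimitab(interactions, paths["intact"])
    write_biogrid_tab3(interactions, paths["biogrid"])
    write_fi_tsv(interactions, paths["fi"])
    store.save_jsonl(paths["abstracts"])
    write_validation_pairs_tsv(pairs, paths["validation_pairs"])
    paths["fulltext"].write_text(doc, encoding="utf-8")
    return paths
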