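"""Abstract-to-pathway relevance: chunking, embedding, cosine and judge scores.

Relevance between an abstract and a candidate pathway is measured two ways
and both must pass:

1. **Embedding cosine** — the abstract is split into overlapping token
   chunks, each chunk embedded, and the score is the mean cosine similarity
   between the pathway-context embedding and the chunk embeddings.  The
   pathway side is embedded as a single vector (context texts are short);
   the abstract side is chunked so long abstracts are not penalized by
   sequence-length truncation.
2. **LLM judge** — a provider scores the abstract's relevance to the
   pathway context on a declared integer scale (0..5 by default).

Matches are then ranked lexicographically: cosine first, judge second.

Both providers have deterministic offline mocks so the full pipeline is
testable with no model downloads: the mock embedder is a hashed
bag-of-words (crc32 into 64 buckets, L2-normalized) and the mock judge a
token-set Jaccard rescaled to the judge scale.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_TOKENS = 256
DEFAULT_OVERLAP_TOKENS = 10
DEFAULT_JUDGE_SCALE = 5
DEFAULT_MIN_COSINE = 0.2
DEFAULT_MIN_JUDGE = 1

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")
_WS_TOKEN_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class TextChunk:
    source_id: str
    text: str
    start_index: int


@dataclass(frozen=True)
class ScoredMatch:
    """An (abstract, pathway) pair with both relevance scores."""

    pmid: str
    pathway_id: str
    cosine_score: float
    judge_score: float
    passed: bool = False


def chunk_text(
    text: str,
    chunk_tokens: int = DEFAULT_CHUNK_TOKENS,
    overlap_tokens: int = DEFAULT_OVERLAP_TOKENS,
    source_id: str = "",
) -> list[TextChunk]:
    """Sliding token-window chunks with overlap, character offsets recorded.

    Tokenization is whitespace-based (the fallback when no model tokenizer
    is configured).  Windows start every ``chunk_tokens - overlap_tokens``
    tokens; the final window may be shorter.  Chunk text is the original
    substring spanning its tokens, so offsets remain valid in the source.
    """
    if not (chunk_tokens > overlap_tokens >= 0):
        raise ValueError("require chunk_tokens > overlap_tokens >= 0")
    spans = [(m.start(), m.end()) for m in _WS_TOKEN_RE.finditer(text)]
    if not spans:
        return []
    stride = chunk_tokens - overlap_tokens
    chunks: list[TextChunk] = []
    for start_tok in range(0, len(spans), stride):
        window = spans[start_tok : start_tok + chunk_tokens]
        lo, hi = window[0][0], window[-1][1]
        chunks.append(TextChunk(source_id=source_id, text=text[lo:hi], start_index=lo))
    return chunks


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens (the mock providers' tokenizer)."""
    return _TOKEN_RE.findall(text.lower())


class EmbedProvider(Protocol):
    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """(len(texts), dimension) array of embedding vectors."""
        ...


class HashedBagOfWordsEmbedder:
    """Deterministic offline embedder: crc32-hashed token counts, L2-normalized.

    Texts with no alphanumeric tokens embed to the zero vector.  Because the
    representation is lexical, disjoint vocabularies give (near-)orthogonal
    vectors — the property the synthetic fixtures exploit to plant relevance
    signal.  Hash collisions across 64 buckets can introduce small spurious
    similarity between unrelated texts; scores are exactly 1.0 only for
    identical bags of words.
    """

    def __init__(self, dimension: int = 64):
        self.dimension = dimension

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension))
        for row, text in enumerate(texts):
            for tok in tokenize(text):
                out[row, zlib.crc32(tok.encode("utf-8")) % self.dimension] += 1.0
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
        return out


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity; defined as 0 when either vector has zero norm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def score_abstract_pathway(
    abstract_text: str,
    context_text: str,
    embedder: EmbedProvider,
    chunk_tokens: int = DEFAULT_CHUNK_TOKENS,
    overlap_tokens: int = DEFAULT_OVERLAP_TOKENS,
    source_id: str = "",
) -> float:
    """Mean cosine between the pathway-context vector and abstract chunks."""
    if not context_text:
        raise ValueError("context_text must be non-empty")
    chunks = chunk_text(abstract_text, chunk_tokens, overlap_tokens, source_id)
    if not chunks:
        logger.warning("abstract %s has no chunks; scoring 0", source_id or "<anon>")
        return 0.0
    vectors = embedder.embed([context_text] + [c.text for c in chunks])
    ctx = vectors[0]
    return float(np.mean([cosine(ctx, v) for v in vectors[1:]]))


class JudgeProvider(Protocol):
    scale: int

    def judge(self, abstract_text: str, pathway_context: str, query_gene: str) -> float:
        """Relevance score on the declared integer scale [0, scale]."""
        ...


class MockJudgeProvider:
    """Deterministic offline judge: token-set Jaccard rescaled to [0, scale].

    Identical token sets score the full scale; disjoint sets score 0.
    """

    def __init__(self, scale: int = DEFAULT_JUDGE_SCALE):
        self.scale = scale

    def judge(self, abstract_text: str, pathway_context: str, query_gene: str) -> float:
        a = set(tokenize(abstract_text))
        b = set(tokenize(pathway_context))
        if not a and not b:
            return float(self.scale)
        union = a | b
        if not union:
            return 0.0
        jaccard = len(a & b) / len(union)
        return float(round(jaccard * self.scale))


def rank_matches(
    matches: Sequence[ScoredMatch],
    min_cosine: float = DEFAULT_MIN_COSINE,
    min_judge: float = DEFAULT_MIN_JUDGE,
) -> list[ScoredMatch]:
    """Threshold on both scores, then rank lexicographically.

    A match passes only if cosine_score >= min_cosine AND judge_score >=
    min_judge (the two-way filter).  Passing matches are sorted descending
    by cosine, then descending judge, then ascending pmid and pathway_id
    for determinism.
    """
    passed = [
        ScoredMatch(m.pmid, m.pathway_id, m.cosine_score, m.judge_score, True)
        for m in matches
        if m.cosine_score >= min_cosine and m.judge_score >= min_judge
    ]

    def _pmid_key(pmid: str) -> tuple[int, str]:
        return (0, pmid.zfill(20)) if pmid.isdigit() else (1, pmid)

    passed.sort(
        key=lambda m: (-m.cosine_score, -m.judge_score, _pmid_key(m.pmid), m.pathway_id)
    )
    return passed
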