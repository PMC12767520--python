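"""Interacting-pathway prediction by binomial enrichment of partners.

Given a query gene and its interaction partners, each candidate pathway is
tested for over-representation of those partners in its gene set.  With
``N`` annotated genes in the knowledgebase, a pathway of ``m`` annotated
genes, and ``k`` partners that are annotated genes, the number of partners
landing in the pathway under the null is Binomial(k, q) with q = m/N; the
reported p-value is the upper tail P(X >= x) at the observed overlap x.
Benjamini–Hochberg step-up adjustment is applied over the family of
pathways actually tested (those with x >= 1), then results are ranked by
(p-value, pathway_id), truncated to the top-k, and filtered by FDR.

Only partners that are themselves annotated genes count as trials:
unannotated partners carry no information about pathway membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .interactions import InteractionSet, partners_of
from .knowledge_model import Knowledgebase, PathwayRecord, eligible_pathways

DEFAULT_TOP_PATHWAYS = 10
DEFAULT_MAX_FDR = 0.05


class PredictionStatus(str, Enum):
    OK = "OK"
    NO_PARTNERS = "NO_PARTNERS"
    NO_ANNOTATED_PARTNERS = "NO_ANNOTATED_PARTNERS"
    NO_OVERLAP = "NO_OVERLAP"
    NO_PASSING_PATHWAYS = "NO_PASSING_PATHWAYS"


@dataclass(frozen=True)
class EnrichedPathway:
    """One candidate pathway with its enrichment evidence.

    x = overlap count, k = annotated partners (trials), m = pathway gene-set
    size restricted to annotated genes, N = annotated genes in the
    knowledgebase.
    """

    pathway_id: str
    name: str
    overlap_genes: frozenset[str]
    x: int
    k: int
    m: int
    N: int
    p_value: float
    fdr: float


@dataclass(frozen=True)
class PredictionResult:
    status: PredictionStatus
    pathways: tuple[EnrichedPathway, ...]


def binomial_tail(x: int, k: int, q: float) -> float:
    """Upper-tail binomial probability P(X >= x), X ~ Binomial(k, q).

    Exact log-space summation of the pmf terms x..k (stable for small tail
    masses, where naive summation underflows).
    """
    if not (0 <= x <= k):
        raise ValueError(f"require 0 <= x <= k, got x={x}, k={k}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"require q in [0,1], got {q}")
    if x == 0:
        return 1.0
    if q == 0.0:
        return 0.0
    if q == 1.0:
        return 1.0
    i = np.arange(x, k + 1)
    log_terms = (
        gammaln(k + 1)
        - gammaln(i + 1)
        - gammaln(k - i + 1)
        + i * math.log(q)
        + (k - i) * math.log1p(-q)
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, order-aligned with input."""
    if not p_values:
        return []
    arr = np.asarray(p_values, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in adjusted]


def enrich_partners(
    kb: Knowledgebase, partner_genes: set[str]
) -> list[EnrichedPathway]:
    """Score every eligible pathway against a partner set; no truncation.

    Returns pathways with x >= 1 sorted ascending by (p_value, pathway_id),
    with BH FDR computed over exactly this tested family.
    """
    annotated = kb.annotated_genes
    N = len(annotated)
    k_partners = partner_genes & annotated
    k = len(k_partners)
    rows: list[tuple[PathwayRecord, frozenset[str], int, int, float]] = []
    if k == 0 or N == 0:
        return []
    for p in eligible_pathways(kb):
        members = p.gene_set & annotated
        m = len(members)
        if m == 0:
            continue
        overlap = frozenset(k_partners & members)
        x = len(overlap)
        if x == 0:
            continue
        pval = binomial_tail(x, k, m / N)
        rows.append((p, overlap, x, m, pval))
    if not rows:
        return []
    fdrs = bh_adjust([r[4] for r in rows])
    out = [
        EnrichedPathway(
            pathway_id=p.pathway_id,
            name=p.name,
            overlap_genes=overlap,
            x=x,
            k=k,
            m=m,
            N=N,
            p_value=pval,
            fdr=fdr,
        )
        for (p, overlap, x, m, pval), fdr in zip(rows, fdrs)
    ]
    out.sort(key=lambda e: (e.p_value, e.pathway_id))
    return out


def predict_interacting_pathways(
    kb: Knowledgebase,
    interactions: InteractionSet,
    query_gene: str,
    top_pathways: int = DEFAULT_TOP_PATHWAYS,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> PredictionResult:
    """Rank candidate pathways for a query gene from its interaction partners.

    BH adjustment is applied over all tested pathways *before* top-k
    truncation; the truncated list is then filtered to fdr <= max_fdr.
    Distinct empty-result statuses separate "gene has no partners at all"
    from "partners exist but none are annotated" from "no pathway overlap".
    """
    if top_pathways < 1:
        raise ValueError("top_pathways must be >= 1")
    if not (0.0 < max_fdr <= 1.0):
        raise ValueError("max_fdr must be in (0, 1]")
    partner_genes = {g for g, _ in partners_of(interactions, query_gene)}
    if not partner_genes:
        return PredictionResult(PredictionStatus.NO_PARTNERS, ())
    annotated_partners = partner_genes & kb.annotated_genes
    if not annotated_partners:
        return PredictionResult(PredictionStatus.NO_ANNOTATED_PARTNERS, ())
    ranked = enrich_partners(kb, partner_genes)
    if not ranked:
        return PredictionResult(PredictionStatus.NO_OVERLAP, ())
    kept = tuple(e for e in ranked[:top_pathways] if e.fdr <= max_fdr)
    if not kept:
        return PredictionResult(PredictionStatus.NO_PASSING_PATHWAYS, ())
    return PredictionResult(PredictionStatus.OK, kept)
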