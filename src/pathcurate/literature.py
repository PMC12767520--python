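"""PMID-keyed abstract store, query construction, and abstract retrieval.

The store is a JSON-lines file, one record per line
(``{"pmid", "title", "abstract", "year"}``), indexed in memory by PMID.  A
local store exists because remote literature APIs are rate-limited; the
contract that matters downstream is only "abstract lookup by PMID".

Search is a provider contract: the offline mock ranks store records by
substring-match count so the whole pipeline runs with zero network access;
a remote provider can be slotted in behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

from lxml import etree

#: The three literature facets a curation query covers for a gene.
QUERY_FACETS = ("interactions", "reactions", "pathways")


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    abstract_text: str
    year: int | None = None


@dataclass(frozen=True)
class LiteratureQuery:
    """A gene's literature query: one search string per facet."""

    query_gene: str
    facets: tuple[str, ...] = QUERY_FACETS

    def strings(self) -> list[str]:
        if not self.query_gene:
            raise ValueError("gene symbol must be non-empty")
        return [f"{self.query_gene} {facet}" for facet in self.facets]


class AbstractStore:
    """In-memory PMID -> AbstractRecord index backed by a JSON-lines file."""

    def __init__(self, records: list[AbstractRecord] | None = None):
        self._by_pmid: dict[str, AbstractRecord] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: AbstractRecord) -> None:
        if rec.pmid in self._by_pmid:
            raise ValueError(f"duplicate pmid {rec.pmid}")
        if not rec.abstract_text:
            raise ValueError(f"pmid {rec.pmid}: empty abstract_text")
        self._by_pmid[rec.pmid] = rec

    def get(self, pmid: str) -> AbstractRecord | None:
        return self._by_pmid.get(pmid)

    def __len__(self) -> int:
        return len(self._by_pmid)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._by_pmid

    def records(self) -> list[AbstractRecord]:
        return list(self._by_pmid.values())

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "AbstractStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    raw = json.loads(line)
                    store.add(
                        AbstractRecord(
                            pmid=str(raw["pmid"]),
                            title=raw.get("title", ""),
                            abstract_text=raw["abstract"],
                            year=raw.get("year"),
                        )
                    )
                except (KeyError, ValueError, json.JSONDecodeError) as exc:
                    raise ValueError(f"{path}:{lineno}: invalid record: {exc}") from exc
        return store

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self._by_pmid.values():
                fh.write(
                    json.dumps(
                        {
                            "pmid": rec.pmid,
                            "title": rec.title,
                            "abstract": rec.abstract_text,
                            "year": rec.year,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )

    @classmethod
    def load_pubmed_xml(cls, path: str | Path) -> "AbstractStore":
        """Read MedlineCitation records from a PubMed XML export."""
        store = cls()
        tree = etree.parse(str(path))
        for cit in tree.iter("MedlineCitation"):
            pmid = cit.findtext("PMID")
            article = cit.find("Article")
            if pmid is None or article is None:
                continue
            title = article.findtext("ArticleTitle") or ""
            abstract = " ".join(
                (t.text or "") for t in article.iterfind("Abstract/AbstractText")
            ).strip()
            year_text = article.findtext("Journal/JournalIssue/PubDate/Year")
            if not abstract:
                continue
            store.add(
                AbstractRecord(
                    pmid=pmid,
                    title=title,
                    abstract_text=abstract,
                    year=int(year_text) if year_text else None,
                )
            )
        return store


def build_queries(gene: str) -> list[str]:
    """The three facet query strings for a gene, in fixed order.

    For gene TANC1 these are "TANC1 interactions", "TANC1 reactions",
    "TANC1 pathways" — the facets that surface papers usable for
    reaction-based pathway annotation.
    """
    return LiteratureQuery(query_gene=gene).strings()


@dataclass(frozen=True)
class FetchResult:
    records: list[AbstractRecord]
    missing: list[str]


def fetch_abstracts(store: AbstractStore, pmids: list[str], top_n: int) -> FetchResult:
    """First ``top_n`` store hits among ``pmids``, preserving input order.

    PMIDs absent from the store are reported in ``missing``, never fatal —
    a local store necessarily lags the live index.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    records: list[AbstractRecord] = []
    missing: list[str] = []
    for pmid in pmids:
        rec = store.get(pmid)
        if rec is None:
            missing.append(pmid)
        elif len(records) < top_n:
            records.append(rec)
    return FetchResult(records=records, missing=missing)


class SearchProvider(Protocol):
    def search(self, query: str, max_results: int) -> list[str]:
        """Ordered PMIDs for a query string."""
        ...


class MockSearchProvider:
    """Offline search over a local store.

    Ranks records by the number of query terms occurring (case-insensitive
    substring) in title+abstract, ties broken by ascending PMID (numeric
    where possible).  Records matching no term are excluded.
    """

    def __init__(self, store: AbstractStore):
        self._store = store

    def search(self, query: str, max_results: int) -> list[str]:
        terms = [t.lower() for t in query.split() if t]
        if not terms:
            return []
        scored: list[tuple[int, tuple[int, str], str]] = []
        for rec in self._store.records():
            haystack = f"{rec.title} {rec.abstract_text}".lower()
            count = sum(1 for t in terms if t in haystack)
            if count > 0:
                pmid_key = (0, rec.pmid.zfill(20)) if rec.pmid.isdigit() else (1, rec.pmid)
                scored.append((-count, pmid_key, rec.pmid))
        scored.sort()
        return [pmid for _, _, pmid in scored[:max_results]]


def union_search(
    provider: SearchProvider, queries: list[str], max_results_per_query: int
) -> list[str]:
    """Union of per-facet search results, preserving first-seen order."""
    seen: dict[str, None] = {}
    for q in queries:
        for pmid in provider.search(q, max_results_per_query):
            seen.setdefault(pmid)
    return list(seen)
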