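"""Pathway-knowledgebase snapshot: data model, JSON reader/writer, context text.

The knowledgebase is a flat JSON snapshot of a curated pathway resource
(pathways, their annotated gene sets, free-text summaries, and per-gene
reaction-role texts).  A graph database is an access detail of the live
resource; a snapshot keeps the pipeline self-contained and testable.

Gene symbols are case-sensitive exact strings throughout.  Synonym
resolution is deliberately not attempted: treating a synonym as a distinct
gene is a known failure mode of symbol-keyed curation pipelines and must be
visible, not papered over.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Separator used when concatenating a pathway summary with partner role texts.
CONTEXT_SEPARATOR = "\n"


class PathwayRecord(BaseModel):
    """A single pathway: gene set, summary text, and per-gene reaction roles.

    ``has_entity_level_view`` and ``contains_reactions`` are the two
    hierarchy flags that make a pathway eligible as an annotation candidate:
    only pathways with entity-level views containing reactions are
    considered, which keeps enrichment away from high-level container
    pathways.
    """

    model_config = ConfigDict(frozen=True)

    pathway_id: str
    name: str
    gene_set: frozenset[str]
    summary_text: str
    gene_roles: dict[str, str] = {}
    has_entity_level_view: bool = True
    contains_reactions: bool = True

    @field_validator("pathway_id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("pathway_id must be non-empty")
        return v

    @model_validator(mode="after")
    def _roles_subset_of_genes(self) -> "PathwayRecord":
        extra = set(self.gene_roles) - set(self.gene_set)
        if extra:
            raise ValueError(
                f"pathway {self.pathway_id!r}: gene_roles keys not in gene_set: "
                f"{sorted(extra)}"
            )
        return self


class Knowledgebase(BaseModel):
    """A release snapshot: pathway records plus the union of annotated genes."""

    model_config = ConfigDict(frozen=True)

    release_label: str
    pathways: tuple[PathwayRecord, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "Knowledgebase":
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway_id(s): {dupes}")
        return self

    @property
    def annotated_genes(self) -> frozenset[str]:
        """Union of all pathway gene sets."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.gene_set
        return frozenset(out)

    def get(self, pathway_id: str) -> PathwayRecord:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def __iter__(self) -> Iterator[PathwayRecord]:  # type: ignore[override]
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


def load_knowledgebase(path: str | Path) -> Knowledgebase:
    """Load a knowledgebase snapshot from its JSON file.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    (naming the offending record) for schema violations.  Malformed records
    are rejected, never silently dropped.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or "pathways" not in raw:
        raise ValueError(f"{path}: not a knowledgebase snapshot (missing 'pathways')")
    records = []
    for i, rec in enumerate(raw["pathways"]):
        try:
            records.append(
                PathwayRecord(
                    pathway_id=rec["pathway_id"],
                    name=rec["name"],
                    gene_set=frozenset(rec["gene_set"]),
                    summary_text=rec["summary_text"],
                    gene_roles=rec.get("gene_roles", {}),
                    has_entity_level_view=rec.get("has_entity_level_view", True),
                    contains_reactions=rec.get("contains_reactions", True),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            ident = rec.get("pathway_id", f"<record #{i}>") if isinstance(rec, dict) else f"<record #{i}>"
            raise ValueError(f"{path}: invalid pathway record {ident}: {exc}") from exc
    return Knowledgebase(release_label=raw.get("release_label", ""), pathways=tuple(records))


def save_knowledgebase(kb: Knowledgebase, path: str | Path) -> None:
    """Write a snapshot as canonical JSON (sorted keys/sets, stable bytes)."""
    payload = {
        "release_label": kb.release_label,
        "pathways": [
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "gene_set": sorted(p.gene_set),
                "summary_text": p.summary_text,
                "gene_roles": {g: p.gene_roles[g] for g in sorted(p.gene_roles)},
                "has_entity_level_view": p.has_entity_level_view,
                "contains_reactions": p.contains_reactions,
            }
            for p in kb.pathways
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def eligible_pathways(kb: Knowledgebase) -> list[PathwayRecord]:
    """Pathways eligible as annotation candidates.

    A pathway qualifies iff it has an entity-level view AND contains
    reactions; this is the hierarchy control that excludes abstract
    container pathways from enrichment.  Order-stable (input order).
    """
    return [p for p in kb.pathways if p.has_entity_level_view and p.contains_reactions]


def pathway_context_text(pathway: PathwayRecord, partners: set[str] | frozenset[str]) -> str:
    """Reference text for relevance scoring of one pathway against abstracts.

    Concatenates the pathway summary with the reaction-role descriptions of
    the query gene's interaction partners annotated in this pathway, in
    sorted-symbol order (deterministic; the roles have no inherent order).
    Partners with no role entry contribute nothing.
    """
    parts = [pathway.summary_text]
    for gene in sorted(partners):
        role = pathway.gene_roles.get(gene)
        if role:
            parts.append(role)
    return CONTEXT_SEPARATOR.join(parts)
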