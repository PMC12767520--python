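"""Protein interaction parsing, FI-score filtering, and partner lookup.

Two kinds of pairwise evidence are consumed:

* **PPIs** — experimentally supported protein–protein interactions curated
  in IntAct (PSI-MI TAB 2.7) and BioGRID (TAB3).  Every PPI row carries the
  PubMed identifiers of the papers reporting it; those PMIDs become the
  literature evidence attached to predicted pathways downstream.
* **FIs** — functional interactions predicted by a random-forest model over
  pairwise gene/protein relationship features.  FI edges carry the model
  score in [0,1] and may lack direct experimental support, which is why the
  pipeline can optionally *filter* PPIs by FI score rather than trust either
  source alone.

Only human–human rows are kept (taxid 9606 where the format states it).
Pairs are stored canonically (lexicographic order), self-edges are dropped,
and duplicate pairs are merged with PMIDs unioned and the maximum score
retained.  Confidence columns in MITAB are ignored: PPIs are filtered with
FI scores, not source-database scores.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)

HUMAN_TAXID = "9606"


class Source(str, Enum):
    INTACT = "INTACT"
    BIOGRID = "BIOGRID"
    REACTOME_FI = "REACTOME_FI"


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected interaction between two distinct genes.

    The pair is canonical: ``gene_a < gene_b`` lexicographically.
    ``score`` is the FI random-forest score for FI edges and ``None`` for
    PPI edges; ``pmids`` are the supporting PubMed identifiers (possibly
    empty for FI edges).
    """

    gene_a: str
    gene_b: str
    source: Source
    score: float | None = None
    pmids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge not allowed: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError("edge pair must be canonical (gene_a < gene_b)")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class ParseReport:
    """Row accounting for a parser run: read / kept / skipped."""

    rows_read: int = 0
    edges_kept: int = 0
    rows_skipped: int = 0


@dataclass
class InteractionSet:
    """Canonical edge collection with a gene -> incident-edge index."""

    edges: dict[tuple[str, str], InteractionEdge] = field(default_factory=dict)
    report: ParseReport = field(default_factory=ParseReport)

    def add(
        self,
        gene_a: str,
        gene_b: str,
        source: Source,
        score: float | None = None,
        pmids: frozenset[str] = frozenset(),
    ) -> bool:
        """Add an edge, merging with any existing edge for the same pair.

        Returns False (no-op) for self-edges.  On merge, PMIDs are unioned
        and the maximum score retained; the first-seen source wins.
        """
        if gene_a == gene_b:
            return False
        a, b = _canonical(gene_a, gene_b)
        existing = self.edges.get((a, b))
        if existing is None:
            self.edges[(a, b)] = InteractionEdge(a, b, source, score, frozenset(pmids))
        else:
            merged_score = existing.score
            if score is not None:
                merged_score = score if merged_score is None else max(merged_score, score)
            self.edges[(a, b)] = InteractionEdge(
                a, b, existing.source, merged_score, existing.pmids | pmids
            )
        return True

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canonical(*pair) in self.edges

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def union(self, other: "InteractionSet") -> "InteractionSet":
        """Merge two interaction sets (e.g. IntAct + BioGRID PPIs)."""
        merged = InteractionSet()
        for s in (self, other):
            for e in s.edges.values():
                merged.add(e.gene_a, e.gene_b, e.source, e.score, e.pmids)
        merged.report = ParseReport(
            rows_read=self.report.rows_read + other.report.rows_read,
            edges_kept=len(merged),
            rows_skipped=self.report.rows_skipped + other.report.rows_skipped,
        )
        return merged


def partners_of(s: InteractionSet, gene: str) -> set[tuple[str, InteractionEdge]]:
    """All (partner, edge) pairs incident to ``gene``; empty if absent."""
    out: set[tuple[str, InteractionEdge]] = set()
    for (a, b), edge in s.edges.items():
        if a == gene:
            out.add((b, edge))
        elif b == gene:
            out.add((a, edge))
    return out


# ---------------------------------------------------------------------------
# PSI-MI TAB 2.7 (IntAct)
# ---------------------------------------------------------------------------

_GENE_NAME_RE = re.compile(r"^[^:]+:([^(]+)\(gene name\)$")
_PUBMED_RE = re.compile(r"pubmed:(\d+)", re.IGNORECASE)
_TAXID_RE = re.compile(r"taxid:(-?\d+)")


def _mitab_gene_symbol(*fields: str) -> str | None:
    """First alias annotated with MI type 'gene name' across the given fields."""
    for f in fields:
        if f == "-":
            continue
        for part in f.split("|"):
            m = _GENE_NAME_RE.match(part.strip())
            if m:
                sym = m.group(1).strip().strip('"')
                if sym:
                    return sym
    return None


def _mitab_is_human(taxfield: str) -> bool:
    m = _TAXID_RE.search(taxfield)
    return bool(m and m.group(1) == HUMAN_TAXID)


def parse_psimitab(path: str | Path) -> InteractionSet:
    """Parse a PSI-MI TAB 2.7 file into an InteractionSet of PPI edges.

    Gene symbols come from the alt-ID/alias columns (entries of alias type
    ``gene name``); PMIDs from the publication-identifier column; only rows
    where both interactors are human (taxid 9606) are kept.  Rows without a
    resolvable symbol for both interactors are skipped and counted, never
    fatal.
    """
    out = InteractionSet()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise ValueError(
                    f"{path}: not PSI-MI TAB 2.7 (row has {len(cols)} columns, need >=15)"
                )
            out.report.rows_read += 1
            if not (_mitab_is_human(cols[9]) and _mitab_is_human(cols[10])):
                out.report.rows_skipped += 1
                continue
            sym_a = _mitab_gene_symbol(cols[2], cols[4])
            sym_b = _mitab_gene_symbol(cols[3], cols[5])
            if sym_a is None or sym_b is None:
                out.report.rows_skipped += 1
                logger.debug("MITAB row without gene symbols skipped: %s", cols[0])
                continue
            pmids = frozenset(_PUBMED_RE.findall(cols[8]))
            if not out.add(sym_a, sym_b, Source.INTACT, pmids=pmids):
                out.report.rows_skipped += 1
    out.report.edges_kept = len(out)
    return out


# ---------------------------------------------------------------------------
# BioGRID TAB3
# ---------------------------------------------------------------------------

_TAB3_SYM_A = "Official Symbol Interactor A"
_TAB3_SYM_B = "Official Symbol Interactor B"
_TAB3_PUB = "Publication Source"
_TAB3_ORG_A = "Organism ID Interactor A"
_TAB3_ORG_B = "Organism ID Interactor B"


def parse_biogrid_tab3(path: str | Path) -> InteractionSet:
    """Parse a BioGRID TAB3 file (named header columns) into PPI edges."""
    out = InteractionSet()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        # BioGRID prefixes the first header cell with '#'
        reader.fieldnames = [f.lstrip("#") for f in reader.fieldnames]
        required = {_TAB3_SYM_A, _TAB3_SYM_B}
        if not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: not BioGRID TAB3 (missing {sorted(required)})")
        for row in reader:
            out.report.rows_read += 1
            org_a = row.get(_TAB3_ORG_A, HUMAN_TAXID)
            org_b = row.get(_TAB3_ORG_B, HUMAN_TAXID)
            if org_a != HUMAN_TAXID or org_b != HUMAN_TAXID:
                out.report.rows_skipped += 1
                continue
            sym_a = (row.get(_TAB3_SYM_A) or "").strip()
            sym_b = (row.get(_TAB3_SYM_B) or "").strip()
            if not sym_a or not sym_b or sym_a == "-" or sym_b == "-":
                out.report.rows_skipped += 1
                continue
            pmids = frozenset(_PUBMED_RE.findall(row.get(_TAB3_PUB, "") or ""))
            if not out.add(sym_a, sym_b, Source.BIOGRID, pmids=pmids):
                out.report.rows_skipped += 1
    out.report.edges_kept = len(out)
    return out


# ---------------------------------------------------------------------------
# Functional-interaction TSV
# ---------------------------------------------------------------------------


def parse_reactome_fi(path: str | Path) -> InteractionSet:
    """Parse a functional-interaction TSV (header: gene_a, gene_b, score).

    FI edges carry the random-forest prediction score; a score outside
    [0,1] is a validation error.
    """
    out = InteractionSet()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"gene_a", "gene_b", "score"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: not an FI TSV (need header gene_a, gene_b, score)")
        for row in reader:
            out.report.rows_read += 1
            score = float(row["score"])
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{path}: FI score {score} outside [0,1] for pair "
                    f"({row['gene_a']}, {row['gene_b']})"
                )
            if not out.add(row["gene_a"], row["gene_b"], Source.REACTOME_FI, score=score):
                out.report.rows_skipped += 1
    out.report.edges_kept = len(out)
    return out


def filter_ppis_by_fi(
    ppis: InteractionSet, fis: InteractionSet, min_fi_score: float
) -> InteractionSet:
    """Keep only PPI edges whose pair has an FI with score >= min_fi_score.

    The FI filter restricts experimentally supported interactions to those
    the functional-interaction model also considers likely, trading recall
    for precision.  PMIDs are preserved from the PPI edge.  Monotone:
    raising ``min_fi_score`` never adds edges.
    """
    if not (0.0 <= min_fi_score <= 1.0):
        raise ValueError(f"min_fi_score {min_fi_score} outside [0,1]")
    out = InteractionSet()
    for pair, edge in ppis.edges.items():
        fi = fis.edges.get(pair)
        if fi is not None and fi.score is not None and fi.score >= min_fi_score:
            out.add(edge.gene_a, edge.gene_b, edge.source, edge.score, edge.pmids)
    out.report = ParseReport(
        rows_read=len(ppis), edges_kept=len(out), rows_skipped=len(ppis) - len(out)
    )
    return out
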