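"""Regulatory-gap analysis for prioritized NHP categories.

Trends and final wild cards are matched against a table of regulatory
documents (guidelines, standards, reflection papers), each tagged with the
signature pattern of the NHP type it addresses.  A prioritized item with no
specifically applicable document is flagged as insufficiently regulated.

Matching semantics: a document applies to a query when every non-wildcard
position of its pattern intersects the query's code set (strict mode).  For
*flagging*, multifunctional products use the stricter full-coverage
predicate by default: a document must admit every code of every multivalued
position, since guidance covering only one component function of a
multifunctional product is not specific guidance for the product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .classification import (
    ClassificationError,
    ClassificationSignature,
    SignaturePattern,
    as_pattern,
    format_signature,
)
from .enrichment import WildCardResult
from .novelty import QuartileSelection
from .signal_store import SignalDatabase

__all__ = [
    "RegulatoryDocument",
    "GapEntry",
    "GapReport",
    "read_regdb",
    "load_packaged_regdb",
    "applicable_documents",
    "gap_report",
]

REGDB_COLUMNS = ("source", "status", "name", "nhp_pattern")
KNOWN_SOURCES = ("ASTM", "ISO", "EMA", "FDA", "European Commission", "OECD", "other")


@dataclass(frozen=True)
class RegulatoryDocument:
    """One guideline/standard with the NHP signature pattern it addresses."""

    source: str
    status: str
    name: str
    nhp_pattern: SignaturePattern

    @property
    def pattern_text(self) -> str:
        return str(self.nhp_pattern)


def _parse_doc(row: Dict[str, str], rownum: int) -> RegulatoryDocument:
    for col in REGDB_COLUMNS:
        if col not in row:
            raise ValueError(f"regulatory table row {rownum}: missing column '{col}'")
    try:
        pattern = as_pattern(str(row["nhp_pattern"]))
    except ClassificationError as exc:
        raise ValueError(
            f"regulatory table row {rownum}: unparsable pattern "
            f"{row['nhp_pattern']!r}: {exc}"
        ) from exc
    return RegulatoryDocument(
        source=str(row["source"]).strip(),
        status=str(row["status"]).strip(),
        name=str(row["name"]).strip(),
        nhp_pattern=pattern,
    )


def read_regdb(path: Union[str, Path]) -> List[RegulatoryDocument]:
    """Read a regulatory-document table from CSV, validating every pattern."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        _parse_doc(rec, i + 1) for i, rec in enumerate(frame.to_dict(orient="records"))
    ]


def load_packaged_regdb() -> List[RegulatoryDocument]:
    """The packaged nine-document table of regulatory references specifically
    applicable to NHPs with a galenic function."""
    ref = resources.files("nanoforesight.data").joinpath("regulatory_documents.csv")
    with resources.as_file(ref) as path:
        return read_regdb(path)


def applicable_documents(
    query: Union[str, ClassificationSignature, SignaturePattern],
    regdb: Sequence[RegulatoryDocument],
    lenient: bool = False,
    full_coverage: bool = False,
) -> List[RegulatoryDocument]:
    """Documents whose NHP pattern matches the query signature or pattern.

    ``lenient`` lets the undefined code 0 on either side match anything in
    its position; ``full_coverage`` requires the document pattern to admit
    every code of every query position (multifunctional specificity).
    """
    pattern = as_pattern(query)
    out = []
    for doc in regdb:
        if full_coverage:
            hit = doc.nhp_pattern.covers(pattern)
        else:
            hit = doc.nhp_pattern.matches(pattern, lenient=lenient)
        if hit:
            out.append(doc)
    return out


@dataclass(frozen=True)
class GapEntry:
    """Regulatory coverage of one prioritized item."""

    label: str
    kind: str  # "trend" | "wildcard"
    query: str
    matches: Tuple[RegulatoryDocument, ...]
    insufficient: bool

    @property
    def match_count(self) -> int:
        return len(self.matches)


@dataclass
class GapReport:
    """Gap analysis over all prioritized items, sorted by match count."""

    entries: List[GapEntry] = field(default_factory=list)

    def insufficient(self) -> List[GapEntry]:
        return [e for e in self.entries if e.insufficient]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": e.label,
                "kind": e.kind,
                "query": e.query,
                "match_count": e.match_count,
                "matched_documents": "; ".join(d.name for d in e.matches),
                "insufficient": e.insufficient,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=["label", "kind", "query", "match_count",
                     "matched_documents", "insufficient"],
        )


def _modal_signature(db: SignalDatabase, dsc) -> Optional[str]:
    # most frequent signature among selected signals carrying the DSC;
    # ties by canonical string for determinism
    counts: Dict[str, int] = {}
    for sig in db.selected():
        if dsc in sig.dscs and sig.signature is not None:
            key = format_signature(sig.signature)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return None
    return min(counts, key=lambda k: (-counts[k], k))


def gap_report(
    trends: QuartileSelection,
    final_wildcards: Sequence[WildCardResult],
    regdb: Sequence[RegulatoryDocument],
    db: Optional[SignalDatabase] = None,
    lenient: bool = False,
    flag_full_coverage: bool = True,
) -> GapReport:
    """Match prioritized items against the regulatory table and flag gaps.

    Each trend DSC is queried by the modal classification signature of the
    signals carrying it (requires ``db``; absent signatures skip the trend);
    each final wild card is queried by its own signature.  An item is
    flagged *insufficient* when no document matches it under the flagging
    predicate — full coverage of every (possibly multivalued) position by
    default, plain strict matching when ``flag_full_coverage=False``.
    Entries are sorted by match count ascending, then label.
    """
    entries: List[GapEntry] = []

    def add(label: str, kind: str, query: str) -> None:
        matched = tuple(applicable_documents(query, regdb, lenient=lenient))
        flag_matches = applicable_documents(
            query, regdb, lenient=lenient, full_coverage=flag_full_coverage
        )
        entries.append(
            GapEntry(
                label=label,
                kind=kind,
                query=query,
                matches=matched,
                insufficient=len(flag_matches) == 0,
            )
        )

    for dsc in trends.trends:
        query = _modal_signature(db, dsc) if db is not None else None
        if query is None:
            continue
        add(str(dsc), "trend", query)
    for result in final_wildcards:
        sig = result.signal.signature
        if sig is None:
            continue
        add(result.signal.signal_id, "wildcard", format_signature(sig))

    entries.sort(key=lambda e: (e.match_count, e.label))
    return GapReport(entries=entries)
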