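"""Data model and I/O for the detected-signal database.

A *detected signal* is one record returned by a horizon-scanning query of a
literature, patent or clinical-trial source, classified with an NHP
signature and one or more design solution codes (DSCs), and marked either
``selected`` (relevant, feeds the novelty pipeline) or ``discarded`` (kept
only for scan-tally reporting, with the reason recorded).

The on-disk schema is a flat CSV (or JSON array) with the fixed header
``signal_id, source, scan_period, status, discard_reason, signature, dscs,
source_ref``; the ``dscs`` field joins DSC strings with semicolons.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .classification import (
    ClassificationError,
    ClassificationSignature,
    DesignSolutionCode,
    format_signature,
    parse_dsc,
    parse_signature,
)

__all__ = [
    "SOURCES",
    "STATUSES",
    "SchemaError",
    "DetectedSignal",
    "SignalDatabase",
    "read_signals",
    "write_signals",
    "tally",
    "source_breakdown",
]

SOURCES = ("scopus", "epo", "clinicaltrials")
STATUSES = ("selected", "discarded")

CSV_COLUMNS = (
    "signal_id",
    "source",
    "scan_period",
    "status",
    "discard_reason",
    "signature",
    "dscs",
    "source_ref",
)


class SchemaError(ValueError):
    """A signal table row violates the schema; carries row and field."""

    def __init__(self, message: str, row: Optional[int] = None,
                 field_name: Optional[str] = None):
        where = []
        if row is not None:
            where.append(f"row {row}")
        if field_name is not None:
            where.append(f"field '{field_name}'")
        prefix = " (".join([", ".join(where)]) if where else ""
        super().__init__(f"{', '.join(where)}: {message}" if where else message)
        self.row = row
        self.field_name = field_name


@dataclass(frozen=True)
class DetectedSignal:
    """One scanned record: source, period, classification and selection."""

    signal_id: str
    source: str
    scan_period: str
    status: str
    signature: Optional[ClassificationSignature] = None
    dscs: Tuple[DesignSolutionCode, ...] = ()
    discard_reason: str = ""
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.signal_id:
            raise SchemaError("empty signal_id", field_name="signal_id")
        if self.source not in SOURCES:
            raise SchemaError(
                f"unknown source {self.source!r} (legal: {list(SOURCES)})",
                field_name="source",
            )
        if self.status not in STATUSES:
            raise SchemaError(
                f"unknown status {self.status!r} (legal: {list(STATUSES)})",
                field_name="status",
            )
        if self.status == "selected":
            if self.signature is None:
                raise SchemaError(
                    "selected signal lacks a classification signature",
                    field_name="signature",
                )
            if not self.dscs:
                raise SchemaError(
                    "selected signal carries no DSC", field_name="dscs"
                )
        else:
            if not self.discard_reason:
                raise SchemaError(
                    "discarded signal lacks a discard_reason",
                    field_name="discard_reason",
                )
        if len(set(self.dscs)) != len(self.dscs):
            raise SchemaError("duplicate DSCs on one signal", field_name="dscs")

    @property
    def is_selected(self) -> bool:
        return self.status == "selected"

    @property
    def dsc_set(self) -> frozenset:
        """The signal's DSC combination (the unit wild-card scoring uses)."""
        return frozenset(self.dscs)


@dataclass
class SignalDatabase:
    """An in-memory signal database with provenance metadata."""

    signals: List[DetectedSignal] = field(default_factory=list)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.signal_id for s in self.signals]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise SchemaError(f"duplicate signal_id(s): {sorted(dupes)[:5]}")

    def selected(self) -> List[DetectedSignal]:
        return [s for s in self.signals if s.is_selected]

    def __len__(self) -> int:
        return len(self.signals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalDatabase):
            return NotImplemented
        return self.signals == other.signals and self.provenance == other.provenance


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _signal_to_row(sig: DetectedSignal) -> Dict[str, str]:
    return {
        "signal_id": sig.signal_id,
        "source": sig.source,
        "scan_period": sig.scan_period,
        "status": sig.status,
        "discard_reason": sig.discard_reason,
        "signature": format_signature(sig.signature) if sig.signature else "",
        "dscs": ";".join(str(d) for d in sig.dscs),
        "source_ref": sig.source_ref,
    }


def _row_to_signal(row: Dict[str, str], rownum: int) -> DetectedSignal:
    def get(key: str) -> str:
        value = row.get(key)
        if value is None:
            raise SchemaError(f"missing column '{key}'", row=rownum, field_name=key)
        return str(value).strip()

    sig_text = get("signature")
    dsc_text = get("dscs")
    try:
        signature = parse_signature(sig_text) if sig_text else None
    except ClassificationError as exc:
        raise SchemaError(str(exc), row=rownum, field_name="signature") from exc
    try:
        dscs = tuple(
            parse_dsc(tok) for tok in dsc_text.split(";") if tok.strip()
        )
    except ClassificationError as exc:
        raise SchemaError(str(exc), row=rownum, field_name="dscs") from exc
    try:
        return DetectedSignal(
            signal_id=get("signal_id"),
            source=get("source"),
            scan_period=get("scan_period"),
            status=get("status"),
            signature=signature,
            dscs=dscs,
            discard_reason=get("discard_reason"),
            source_ref=get("source_ref"),
        )
    except SchemaError as exc:
        raise SchemaError(str(exc), row=rownum) from exc


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format='csv'|'json'")


def read_signals(path: Union[str, Path], format: Optional[str] = None) -> SignalDatabase:
    """Read a signal database from CSV or JSON, validating every row.

    Raises :class:`SchemaError` naming the offending row (1-based, excluding
    the header for CSV) and field on the first violation.
    """
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = frame.to_dict(orient="records")
    elif fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            records = payload.get("signals", [])
            provenance = payload.get("provenance", {})
        else:
            records, provenance = payload, {}
        db_signals = [
            _row_to_signal(rec, i + 1) for i, rec in enumerate(records)
        ]
        return SignalDatabase(signals=db_signals, provenance=dict(provenance))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    signals = [_row_to_signal(rec, i + 1) for i, rec in enumerate(records)]
    return SignalDatabase(signals=signals)


def write_signals(
    db: SignalDatabase, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a signal database to CSV or JSON (lossless round-trip)."""
    fmt = _infer_format(path, format)
    rows = [_signal_to_row(s) for s in db.signals]
    if fmt == "csv":
        frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        frame.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"provenance": db.provenance, "signals": rows},
                fh,
                indent=1,
                ensure_ascii=False,
            )
            fh.write("\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# --------------------------------------------------------------------------
# scan tallies
# --------------------------------------------------------------------------

def tally(db: SignalDatabase) -> pd.DataFrame:
    """Per-(source, scan period) scan tallies.

    Returns a DataFrame indexed by ``(source, scan_period)`` with columns
    ``TR`` (total results), ``S`` (selected) and ``NS`` (not selected);
    ``TR = S + NS`` on every row.  Order of signals is irrelevant.
    """
    counts: Counter = Counter()
    for sig in db.signals:
        counts[(sig.source, sig.scan_period, sig.status)] += 1
    keys = sorted({(src, per) for (src, per, _st) in counts})
    rows = []
    for src, per in keys:
        s = counts[(src, per, "selected")]
        ns = counts[(src, per, "discarded")]
        rows.append({"source": src, "scan_period": per, "TR": s + ns, "S": s, "NS": ns})
    frame = pd.DataFrame(rows, columns=["source", "scan_period", "TR", "S", "NS"])
    if not frame.empty:
        frame = frame.set_index(["source", "scan_period"])
    else:
        frame = frame.set_index(["source", "scan_period"])
    return frame


def source_totals(db: SignalDatabase) -> Dict[str, Dict[str, int]]:
    """Per-source grand totals of the scan tallies (summed over periods)."""
    frame = tally(db)
    out: Dict[str, Dict[str, int]] = {}
    if frame.empty:
        return out
    grouped = frame.groupby(level="source").sum()
    for src, row in grouped.iterrows():
        out[str(src)] = {"TR": int(row["TR"]), "S": int(row["S"]), "NS": int(row["NS"])}
    return out


def source_breakdown(
    db: SignalDatabase, dsc: Union[DesignSolutionCode, str]
) -> Dict[str, int]:
    """Counts of selected signals carrying ``dsc``, per source.

    The counts sum to the DSC's frequency in the spectrum built from ``db``.
    """
    if isinstance(dsc, str):
        dsc = parse_dsc(dsc)
    out = {src: 0 for src in SOURCES}
    for sig in db.selected():
        if dsc in sig.dscs:
            out[sig.source] += 1
    return out
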