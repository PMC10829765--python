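"""Frequency spectrum, novelty scoring and quartile prioritization.

Novelty of a design solution follows the design-creativity metric of Shah
and co-workers: with ``C`` the frequency of a design solution and ``T`` the
total number of detected signals,

    S = (T - C) / T * 10

so a solution shared by every signal scores 0 and a unique one approaches
10.  Ordering design solutions by descending frequency and accumulating
their counts gives the cumulative spectrum; the first quartile (Q1) of the
cumulative signal-count axis delimits *trends* (weak signals) at the
high-frequency end, and the third quartile (Q3) delimits *tentative wild
cards* in the rare tail.

``T`` is the number of selected signals, not the number of distinct DSCs: a
multifunctional signal increments each of its DSCs' counts but contributes
once to ``T``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .classification import DesignSolutionCode, parse_dsc
from .signal_store import DetectedSignal, SignalDatabase

__all__ = [
    "FrequencySpectrum",
    "QuartileSelection",
    "DegenerateSpectrumWarning",
    "round_half_up",
    "build_spectrum",
    "novelty_score",
    "cumulative_table",
    "select_weak_signals",
    "select_tentative_wildcards",
    "quartile_selection",
    "tentative_wildcard_signals",
]


class DegenerateSpectrumWarning(UserWarning):
    """The Q1 and Q3 crossings coincide; trend and wild-card sets overlap."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (display convention, decimal point)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencySpectrum:
    """DSC frequency spectrum: entries sorted by descending count.

    ``total`` is T, the number of selected signals.  Ties in count are broken
    by the DSC's canonical string ascending, so ordering is deterministic.
    Because signals may be multifunctional, the summed counts may exceed T.
    """

    entries: Tuple[Tuple[DesignSolutionCode, int], ...]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("spectrum total T must be positive")
        prev = None
        for dsc, count in self.entries:
            if count <= 0:
                raise ValueError(f"non-positive count for {dsc}")
            key = (-count, str(dsc))
            if prev is not None and key < prev:
                raise ValueError("spectrum entries not in canonical order")
            prev = key

    @property
    def counts(self) -> Tuple[int, ...]:
        return tuple(c for _d, c in self.entries)

    def count_of(self, dsc: Union[DesignSolutionCode, str]) -> int:
        if isinstance(dsc, str):
            dsc = parse_dsc(dsc)
        for d, c in self.entries:
            if d == dsc:
                return c
        return 0

    @classmethod
    def from_counts(
        cls,
        counts: Iterable[Tuple[Union[DesignSolutionCode, str], int]],
        total: int,
    ) -> "FrequencySpectrum":
        """Build a spectrum from (dsc, count) pairs, sorting canonically."""
        parsed = [
            (parse_dsc(d) if isinstance(d, str) else d, int(c)) for d, c in counts
        ]
        parsed.sort(key=lambda e: (-e[1], str(e[0])))
        return cls(entries=tuple(parsed), total=total)


def build_spectrum(db: SignalDatabase) -> FrequencySpectrum:
    """Count DSC occurrences over the selected signals of ``db``.

    Each selected signal contributes 1 to the count of each of its DSCs;
    T is the number of selected signals.
    """
    selected = db.selected()
    if not selected:
        raise ValueError("database holds no selected signal")
    counter: Counter = Counter()
    for sig in selected:
        for dsc in sig.dscs:
            counter[dsc] += 1
    return FrequencySpectrum.from_counts(counter.items(), total=len(selected))


def novelty_score(count: int, total: int) -> float:
    """The novelty score (T - C) / T * 10 at full precision.

    ``count`` is the design solution's frequency C with 1 <= C <= T; higher
    scores mean rarer solutions.  Use :func:`round_half_up` for the 2-decimal
    display convention.
    """
    if total <= 0:
        raise ValueError("total T must be positive")
    if count < 1 or count > total:
        raise ValueError(f"frequency C={count} outside [1, T={total}]")
    return (total - count) / total * 10.0


def cumulative_table(spectrum: FrequencySpectrum) -> pd.DataFrame:
    """The descending-frequency cumulative table of a spectrum.

    Columns: ``dsc``, ``count``, ``novelty_score`` (2-decimal display),
    ``cumulative_count`` and ``cumulative_percent`` (of the summed counts;
    non-decreasing, ending at 100).
    """
    rows = []
    running = 0
    grand = sum(spectrum.counts)
    for dsc, count in spectrum.entries:
        running += count
        rows.append(
            {
                "dsc": str(dsc),
                "count": count,
                "novelty_score": round_half_up(novelty_score(count, spectrum.total)),
                "cumulative_count": running,
                "cumulative_percent": running / grand * 100.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dsc", "count", "novelty_score", "cumulative_count",
                 "cumulative_percent"],
    )


@dataclass
class QuartileSelection:
    """Outcome of Q1/Q3 prioritization on a frequency spectrum."""

    q1_fraction: float = 0.25
    q3_fraction: float = 0.75
    trends: List[DesignSolutionCode] = field(default_factory=list)
    tentative_wildcards: List[DesignSolutionCode] = field(default_factory=list)
    trend_signal_count: int = 0
    tentative_wildcard_signal_count: int = 0
    degenerate: bool = False


def select_weak_signals(
    spectrum: FrequencySpectrum, q1_fraction: float = 0.25
) -> QuartileSelection:
    """Select trend DSCs (weak signals) at the Q1 cumulative threshold.

    Walking the cumulative table in descending-frequency order, a DSC is a
    trend iff the cumulative count before it is below ``q1_fraction * T`` —
    the DSC whose count interval crosses Q1 is included.
    """
    threshold = q1_fraction * spectrum.total
    sel = QuartileSelection(q1_fraction=q1_fraction)
    before = 0
    for dsc, count in spectrum.entries:
        if before < threshold:
            sel.trends.append(dsc)
            sel.trend_signal_count += count
        else:
            break
        before += count
    return sel


def select_tentative_wildcards(
    spectrum: FrequencySpectrum, q3_fraction: float = 0.75
) -> QuartileSelection:
    """Select tentative wild-card DSCs at the Q3 cumulative threshold.

    Mirror of the trend rule: a DSC is a tentative wild card iff the
    cumulative count through it exceeds ``q3_fraction * T`` — its interval
    crosses or lies beyond Q3.  The reported signal count is the summed
    frequency of the selected DSCs (on a singleton-tail spectrum this equals
    the number of signals in the tail).
    """
    threshold = q3_fraction * spectrum.total
    sel = QuartileSelection(q3_fraction=q3_fraction)
    through = 0
    for dsc, count in spectrum.entries:
        through += count
        if through > threshold:
            sel.tentative_wildcards.append(dsc)
            sel.tentative_wildcard_signal_count += count
    return sel


def quartile_selection(
    spectrum: FrequencySpectrum,
    q1_fraction: float = 0.25,
    q3_fraction: float = 0.75,
) -> QuartileSelection:
    """Joint Q1/Q3 selection with degeneracy handling.

    On spectra whose Q1 and Q3 crossings fall on the same DSC the two sets
    would overlap; such DSCs are reported as trends only, the selection is
    flagged degenerate and a :class:`DegenerateSpectrumWarning` is emitted.
    """
    low = select_weak_signals(spectrum, q1_fraction)
    high = select_tentative_wildcards(spectrum, q3_fraction)
    sel = QuartileSelection(
        q1_fraction=q1_fraction,
        q3_fraction=q3_fraction,
        trends=list(low.trends),
        trend_signal_count=low.trend_signal_count,
    )
    trend_set = set(low.trends)
    overlap = [d for d in high.tentative_wildcards if d in trend_set]
    if overlap:
        sel.degenerate = True
        warnings.warn(
            f"Q1 and Q3 crossings overlap on {len(overlap)} DSC(s); "
            "trend and wild-card sets are not separable on this spectrum",
            DegenerateSpectrumWarning,
            stacklevel=2,
        )
    for dsc, count in spectrum.entries:
        if dsc in trend_set:
            continue
        if dsc in high.tentative_wildcards:
            sel.tentative_wildcards.append(dsc)
            sel.tentative_wildcard_signal_count += count
    return sel


def tentative_wildcard_signals(
    db: SignalDatabase, selection: QuartileSelection
) -> List[DetectedSignal]:
    """Selected signals carrying at least one tentative-wild-card DSC and no
    trend DSC — the tentative wild-card signal set."""
    wc = set(selection.tentative_wildcards)
    tr = set(selection.trends)
    out = []
    for sig in db.selected():
        dscs = set(sig.dscs)
        if dscs & wc and not dscs & tr:
            out.append(sig)
    return out
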