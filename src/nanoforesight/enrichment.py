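"""Correction-factor enrichment and final wild-card selection.

Tentative wild cards cluster at near-maximal novelty scores (a rare DSC
combination scores close to 10 whatever its substance), so raw novelty
cannot rank them.  Each tentative wild-card signal is therefore assessed
against four criteria, each contributing a multiplicative correction
factor:

* **Z — unspecific codes.**  Any DSC with reserved identifier Y/Z: factor 0
  (the signal is removed; nothing can be concluded from unspecific codes);
  otherwise 1.
* **N — multifunctionality.**  Number of DSCs defining the signal: 1 -> 1,
  2 -> 3/2, more than 2 -> 2 (multicomposite/multifunctional products are
  enriched).
* **S — trend overlap.**  Number of the signal's DSCs that equal a trend
  (weak-signal) DSC: 0 -> 2, 1 -> 2/3, more than 1 -> 1/2 (sharing design
  solutions with a trend is penalised).
* **C — trend NHP overlap.**  Whether the signal's classification signature
  equals that of some trend signal: yes -> 1, no -> 2.

The corrected score is the signal's raw novelty score times the product of
the four factors.  The raw score of a multi-DSC signal is the novelty of
its DSC *combination*: C is the number of selected signals with exactly
that DSC set, so a one-off combination among T = 836 signals scores 9.99.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Union

from .classification import ClassificationSignature, DesignSolutionCode, format_signature
from .novelty import QuartileSelection, novelty_score, round_half_up, tentative_wildcard_signals
from .signal_store import DetectedSignal, SignalDatabase

__all__ = [
    "CorrectionAssessment",
    "WildCardResult",
    "assess_correction",
    "combination_frequencies",
    "corrected_scores",
    "select_final_wildcards",
]

# Criterion factor tables (answer -> factor), exactly as printed in the
# correction-factor table of the method.
N_FACTORS: Dict[int, Fraction] = {1: Fraction(1), 2: Fraction(3, 2)}
N_FACTOR_MANY = Fraction(2)  # > 2 DSCs
S_FACTORS: Dict[int, Fraction] = {0: Fraction(2), 1: Fraction(2, 3)}
S_FACTOR_MANY = Fraction(1, 2)  # > 1 shared DSCs
C_FACTOR_SHARED = Fraction(1)
C_FACTOR_NOVEL = Fraction(2)


@dataclass(frozen=True)
class CorrectionAssessment:
    """The four criterion answers and their combined multiplicative factor."""

    has_unspecific_dsc: bool
    n_dscs: int
    n_dscs_shared_with_trends: int
    nhp_among_weak_signals: bool
    combined_factor: Fraction
    corrected_score: float


def _criterion_factors(
    has_unspecific: bool, n_dscs: int, n_shared: int, nhp_shared: bool
) -> Fraction:
    z = Fraction(0) if has_unspecific else Fraction(1)
    n = N_FACTORS.get(n_dscs, N_FACTOR_MANY)
    s = S_FACTORS.get(n_shared, S_FACTOR_MANY)
    c = C_FACTOR_SHARED if nhp_shared else C_FACTOR_NOVEL
    return z * n * s * c


def assess_correction(
    signal: DetectedSignal,
    trends: Iterable[Union[DesignSolutionCode, str]],
    trend_nhps: Iterable[Union[ClassificationSignature, str]],
    raw_score: float,
    nhp_predicate: Optional[
        Callable[[ClassificationSignature, Set[str]], bool]
    ] = None,
) -> CorrectionAssessment:
    """Evaluate the four correction criteria for one tentative wild card.

    ``trends`` are the trend (weak-signal) DSCs and ``trend_nhps`` the
    classification signatures observed among trend signals.  The default
    NHP-overlap predicate is canonical-string equality of signatures; pass
    ``nhp_predicate(signature, trend_signature_strings)`` to change it.
    """
    trend_dscs = {str(d) for d in trends}
    trend_sigs = {
        s if isinstance(s, str) else format_signature(s) for s in trend_nhps
    }
    has_unspecific = any(d.is_unspecific for d in signal.dscs)
    n_dscs = len(signal.dscs)
    n_shared = sum(1 for d in signal.dscs if str(d) in trend_dscs)
    if nhp_predicate is None:
        nhp_shared = (
            signal.signature is not None
            and format_signature(signal.signature) in trend_sigs
        )
    else:
        nhp_shared = bool(nhp_predicate(signal.signature, trend_sigs))
    factor = _criterion_factors(has_unspecific, n_dscs, n_shared, nhp_shared)
    return CorrectionAssessment(
        has_unspecific_dsc=has_unspecific,
        n_dscs=n_dscs,
        n_dscs_shared_with_trends=n_shared,
        nhp_among_weak_signals=nhp_shared,
        combined_factor=factor,
        corrected_score=raw_score * float(factor),
    )


@dataclass(frozen=True)
class WildCardResult:
    """One enriched tentative wild card, ready for ranking."""

    signal: DetectedSignal
    raw_score: float
    assessment: CorrectionAssessment
    rank: int = 0

    @property
    def corrected_score(self) -> float:
        return self.assessment.corrected_score

    @property
    def display_raw(self) -> float:
        return round_half_up(self.raw_score)

    @property
    def display_corrected(self) -> float:
        return round_half_up(self.corrected_score)


def combination_frequencies(db: SignalDatabase) -> Counter:
    """Frequency of each exact DSC combination among selected signals."""
    counter: Counter = Counter()
    for sig in db.selected():
        counter[sig.dsc_set] += 1
    return counter


def trend_signatures(
    db: SignalDatabase, selection: QuartileSelection
) -> Set[str]:
    """Canonical signature strings observed on signals carrying a trend DSC."""
    trend_set = set(selection.trends)
    out: Set[str] = set()
    for sig in db.selected():
        if set(sig.dscs) & trend_set and sig.signature is not None:
            out.add(format_signature(sig.signature))
    return out


def corrected_scores(
    db: SignalDatabase,
    selection: QuartileSelection,
    wildcard_signals: Optional[Sequence[DetectedSignal]] = None,
    nhp_predicate: Optional[Callable] = None,
) -> List[WildCardResult]:
    """Score and rank the tentative wild-card signals of a database.

    Raw scores use combination frequencies against the spectrum total T;
    zero-factor signals (unspecific DSCs) are removed before ranking.
    Results are sorted by corrected score descending, ties by signal_id.
    """
    if wildcard_signals is None:
        wildcard_signals = tentative_wildcard_signals(db, selection)
    total = len(db.selected())
    combo_freq = combination_frequencies(db)
    trend_sigs = trend_signatures(db, selection)
    results: List[WildCardResult] = []
    for sig in wildcard_signals:
        raw = novelty_score(combo_freq[sig.dsc_set], total)
        assessment = assess_correction(
            sig, selection.trends, trend_sigs, raw, nhp_predicate=nhp_predicate
        )
        if assessment.combined_factor == 0:
            continue
        results.append(WildCardResult(signal=sig, raw_score=raw, assessment=assessment))
    results.sort(key=lambda r: (-r.corrected_score, r.signal.signal_id))
    return [
        WildCardResult(r.signal, r.raw_score, r.assessment, rank=i + 1)
        for i, r in enumerate(results)
    ]


def select_final_wildcards(
    results: Sequence[WildCardResult],
    mode: str = "max-cluster",
    k: Optional[int] = None,
) -> List[WildCardResult]:
    """Pick the final wild cards from ranked, enriched results.

    ``max-cluster`` (default) returns every signal attaining the maximal
    corrected score — after enrichment the corrected-score distribution
    segregates and the top cluster is the wild-card set.  ``top-k`` returns
    the ``k`` best by rank.
    """
    if not results:
        raise ValueError("no enriched wild-card results to select from")
    if mode == "max-cluster":
        best = max(r.corrected_score for r in results)
        return [r for r in results if r.corrected_score == best]
    if mode == "top-k":
        if k is None or k < 1:
            raise ValueError("top-k mode requires k >= 1")
        return list(results[:k])
    raise ValueError(f"unknown selection mode {mode!r}")
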