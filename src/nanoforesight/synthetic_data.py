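"""Synthetic signal databases with the structure the analysis assumes.

The generator emulates the classified-signal layer of a horizon scan of
nanotechnology-enabled health products: three source strata (literature,
patent register, clinical-trial registry) scanned over three periods, a
top-heavy DSC frequency spectrum (a few high-frequency design solutions
over a long singleton-rich tail), a handful of multifunctional triple-DSC
products in the rare tail, and a sprinkling of unspecific (Y/Z) codes.

Defaults reproduce the study conditions: per-(source, period) selected and
discarded counts exactly as the scan-results table (selected totals 102
literature + 524 patents + 210 trials = 836), planted trend DSCs with
counts 95/61/61, and five planted triple-DSC wild cards with unique DSC
combinations and one multivalued signature position each.  Everything else
— tail identity and shape, signatures, source placement — is drawn from a
seeded generator; varying the seed changes only the tail, never the
planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assessment import KNOWN_SOURCES, RegulatoryDocument, load_packaged_regdb
from .classification import SignaturePattern, as_pattern, parse_dsc, parse_signature
from .signal_store import SOURCES, DetectedSignal, SignalDatabase

__all__ = ["GeneratorConfig", "generate", "generate_regdb", "DEFAULT_SCAN_COUNTS"]

# (source, period) -> (selected, not selected); the scan-results study
# conditions.  Selected totals: 102 + 524 + 210 = 836.
DEFAULT_SCAN_COUNTS: Dict[Tuple[str, str], Tuple[int, int]] = {
    ("scopus", "1"): (57, 169),
    ("scopus", "2"): (25, 32),
    ("scopus", "3"): (20, 27),
    ("epo", "1"): (309, 86),
    ("epo", "2"): (99, 27),
    ("epo", "3"): (116, 22),
    ("clinicaltrials", "1"): (193, 166),
    ("clinicaltrials", "2"): (9, 14),
    ("clinicaltrials", "3"): (8, 15),
}

DEFAULT_PLANTED_TRENDS: Tuple[Tuple[str, int], ...] = (
    ("B.T.2.3", 95),
    ("E.T.2.1", 61),
    ("C.T.2.3", 61),
)

# signature pools per trend DSC: (signature, weight); the modal signatures
# mirror the dominant classification codes reported for each trend.
DEFAULT_TREND_SIGNATURES: Dict[str, Tuple[Tuple[str, float], ...]] = {
    "B.T.2.3": (("2.3.2.1", 0.70), ("2.3.2.0", 0.15), ("2.3.2.2", 0.15)),
    "E.T.2.1": (
        ("2.1.1.0", 0.40), ("2.1.2.0", 0.25), ("2.1.3.0", 0.15),
        ("2.1.0.0", 0.10), ("2.1.1.1", 0.05), ("2.1.1.2", 0.05),
    ),
    "C.T.2.3": (("2.3.3s.1", 0.80), ("2.3.3.1", 0.20)),
}

# dental nanomaterials skew towards clinical-trial registries
DEFAULT_TREND_SOURCE_BIAS: Dict[str, Dict[str, float]] = {
    "E.T.2.1": {"scopus": 0.15, "epo": 0.15, "clinicaltrials": 0.70},
}

# five multifunctional wild cards: unique triple-DSC combinations sharing no
# DSC with the trends, each with exactly one multivalued signature position.
DEFAULT_PLANTED_WILDCARDS: Tuple[Tuple[Tuple[str, str, str], str], ...] = (
    (("F.T.2.1", "A.T.2.2", "P.T.2.3"), "2.(1.2.3).1.1"),
    (("K.T.1.1", "F.T.2.1", "E.T.2.2"), "1.1.(2.3).1"),
    (("B.T.1.1", "G.T.2.1", "L.T.2.3"), "1.1.(1.2).1"),
    (("B.T.1.1", "H.T.1.1", "G.T.2.1"), "(1.2).1.1.1"),
    (("R.T.2.1", "B.T.2.2", "L.T.2.3"), "2.(1.2.3).1.1"),
)

DEFAULT_DISCARD_REASONS: Tuple[str, ...] = (
    "not describing a NHP in particular",
    "not available",
    "outside the selected timeframe",
    "not at the nano-scale",
    "duplicated",
    "no medical purpose",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic signal database.

    ``tail_exponent`` and ``singleton_fraction`` shape the Zipf-like tail:
    tail DSC frequencies decay as rank**-exponent from ``max_tail_count``
    down to a singleton floor, and ``singleton_fraction`` of the remaining
    tail signals get unique one-off DSCs on top of that.
    """

    scan_counts: Dict[Tuple[str, str], Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SCAN_COUNTS)
    )
    planted_trends: Tuple[Tuple[str, int], ...] = DEFAULT_PLANTED_TRENDS
    trend_signatures: Dict[str, Tuple[Tuple[str, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_TREND_SIGNATURES)
    )
    trend_source_bias: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_TREND_SOURCE_BIAS)
    )
    planted_wildcards: Tuple[Tuple[Tuple[str, ...], str], ...] = (
        DEFAULT_PLANTED_WILDCARDS
    )
    tail_exponent: float = 0.6
    singleton_fraction: float = 0.15
    max_tail_count: int = 45
    unspecific_rate: float = 0.05
    seed: int = 1

    @property
    def n_signals(self) -> int:
        """Number of selected signals (the spectrum total T)."""
        return sum(s for s, _ns in self.scan_counts.values())

    @property
    def n_multifunctional(self) -> int:
        return len(self.planted_wildcards)

    def validate(self) -> None:
        planted = sum(c for _d, c in self.planted_trends)
        if planted + self.n_multifunctional > self.n_signals:
            raise ValueError(
                f"planted counts ({planted} trend + {self.n_multifunctional} "
                f"wild-card signals) exceed n_signals = {self.n_signals}"
            )
        for _dsc, count in self.planted_trends:
            if count <= 0:
                raise ValueError("planted trend counts must be positive")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if not 0 <= self.unspecific_rate <= 1:
            raise ValueError("unspecific_rate must be in [0, 1]")
        if self.max_tail_count < 1:
            raise ValueError("max_tail_count must be >= 1")
        combos = [frozenset(c) for c, _s in self.planted_wildcards]
        if len(set(combos)) != len(combos):
            raise ValueError("planted wild-card DSC combinations must be unique")
        trend_dscs = {d for d, _c in self.planted_trends}
        for combo, _sig in self.planted_wildcards:
            if trend_dscs & set(combo):
                raise ValueError(
                    "planted wild cards must not share DSCs with planted trends"
                )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _letters(index: int) -> str:
    # AA, AB, ... two-letter-plus ids: cannot collide with the single-letter
    # planted vocabulary or the reserved Y/Z identifiers
    out = ""
    index, rem = divmod(index, 26)
    out = chr(ord("A") + rem)
    while True:
        index, rem = divmod(index, 26)
        out = chr(ord("A") + rem) + out
        if index == 0:
            break
    return out if len(out) > 1 else "A" + out


def _random_dsc(rng: np.random.Generator, sid: str) -> str:
    mode = int(rng.integers(1, 3))
    purpose = int(rng.integers(1, 4))
    return f"{sid}.T.{mode}.{purpose}"


def _random_signature(rng: np.random.Generator, dsc_text: str) -> str:
    # signature consistent with the DSC's mode and purpose digits
    _sid, _q, mode, purpose = dsc_text.split(".")
    comp = int(rng.integers(0, 4))
    comp_text = f"{comp}s" if comp == 3 and rng.random() < 0.5 else str(comp)
    fab = int(rng.integers(0, 3))
    return f"{mode}.{purpose}.{comp_text}.{fab}"


def _zipf_tail_counts(
    n: int, exponent: float, max_count: int
) -> List[int]:
    # rank-r count = max_count * r**-exponent, floored at 1 and clipped to
    # the remaining mass; yields a short head and a long singleton tail
    counts: List[int] = []
    r = 1
    remaining = n
    while remaining > 0:
        c = int(round(max_count * r ** (-exponent)))
        c = max(1, min(c, max_count, remaining))
        counts.append(c)
        remaining -= c
        r += 1
    return counts


def _weighted_choice(
    rng: np.random.Generator, items: Sequence[str], weights: Sequence[float]
) -> str:
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    return str(items[int(rng.choice(len(items), p=p))])


def generate(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> SignalDatabase:
    """Generate a signal database under the configured study conditions.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    Planted trend DSCs appear with exactly their configured counts; planted
    wild cards keep unique DSC combinations disjoint from the trends; the
    remaining selected signals carry one tail DSC each, drawn from the
    Zipf-like law with a singleton floor plus unspecific Y/Z codes at the
    configured rate.  Discarded rows fill the per-(source, period) tallies.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- selected payloads: (dsc strings, signature string, source bias)
    payloads: List[Tuple[Tuple[str, ...], str, Optional[Dict[str, float]]]] = []
    for dsc_text, count in config.planted_trends:
        pool = config.trend_signatures.get(dsc_text)
        bias = config.trend_source_bias.get(dsc_text)
        for _ in range(count):
            if pool:
                sigs = [s for s, _w in pool]
                weights = [w for _s, w in pool]
                sig_text = _weighted_choice(rng, sigs, weights)
            else:
                sig_text = _random_signature(rng, dsc_text)
            payloads.append(((dsc_text,), sig_text, bias))
    for combo, sig_text in config.planted_wildcards:
        payloads.append((tuple(combo), sig_text, None))

    n_tail = config.n_signals - len(payloads)
    n_unspecific = int(rng.binomial(n_tail, config.unspecific_rate)) if n_tail else 0
    n_rest = n_tail - n_unspecific
    n_singleton = int(round(config.singleton_fraction * n_rest))
    n_zipf = n_rest - n_singleton

    next_id = 0
    for c in _zipf_tail_counts(n_zipf, config.tail_exponent, config.max_tail_count):
        dsc_text = _random_dsc(rng, _letters(next_id))
        next_id += 1
        for _ in range(c):
            payloads.append(
                ((dsc_text,), _random_signature(rng, dsc_text), None)
            )
    for _ in range(n_singleton):
        dsc_text = _random_dsc(rng, _letters(next_id))
        next_id += 1
        payloads.append(((dsc_text,), _random_signature(rng, dsc_text), None))
    for _ in range(n_unspecific):
        sid = "Y" if rng.random() < 0.5 else "Z"
        dsc_text = _random_dsc(rng, sid)
        payloads.append(((dsc_text,), _random_signature(rng, dsc_text), None))

    # --- source/period placement, honouring per-cell selected counts
    cells = sorted(config.scan_counts)
    capacity = {cell: config.scan_counts[cell][0] for cell in cells}
    assignment: List[Optional[Tuple[str, str]]] = [None] * len(payloads)
    biased = [i for i, (_d, _s, b) in enumerate(payloads) if b]
    for i in biased:
        bias = payloads[i][2] or {}
        srcs = [s for s in SOURCES if any(capacity[c] > 0 for c in cells if c[0] == s)]
        weights = [bias.get(s, 1e-9) for s in srcs]
        if sum(weights) <= 0:
            weights = [1.0] * len(srcs)
        src = _weighted_choice(rng, srcs, weights)
        options = [c for c in cells if c[0] == src and capacity[c] > 0]
        cell = options[int(rng.choice(len(options),
                                      p=np.array([capacity[c] for c in options],
                                                 dtype=float)
                                      / sum(capacity[c] for c in options)))]
        capacity[cell] -= 1
        assignment[i] = cell
    slots: List[Tuple[str, str]] = []
    for cell in cells:
        slots.extend([cell] * capacity[cell])
    order = rng.permutation(len(slots))
    unbiased = [i for i in range(len(payloads)) if assignment[i] is None]
    for slot_idx, i in zip(order, unbiased):
        assignment[i] = slots[int(slot_idx)]

    # --- materialize signals in a seeded shuffled order
    signals: List[DetectedSignal] = []
    perm = rng.permutation(len(payloads))
    width = max(4, len(str(len(payloads))))
    for serial, idx in enumerate(perm, start=1):
        dscs, sig_text, _bias = payloads[int(idx)]
        src, per = assignment[int(idx)]  # type: ignore[misc]
        signals.append(
            DetectedSignal(
                signal_id=f"S{serial:0{width}d}",
                source=src,
                scan_period=per,
                status="selected",
                signature=parse_signature(sig_text),
                dscs=tuple(parse_dsc(d) for d in dscs),
            )
        )

    serial = 0
    for cell in cells:
        _s, ns = config.scan_counts[cell]
        for _ in range(ns):
            serial += 1
            reason = DEFAULT_DISCARD_REASONS[
                int(rng.integers(0, len(DEFAULT_DISCARD_REASONS)))
            ]
            signals.append(
                DetectedSignal(
                    signal_id=f"D{serial:0{width}d}",
                    source=cell[0],
                    scan_period=cell[1],
                    status="discarded",
                    discard_reason=reason,
                )
            )

    return SignalDatabase(
        signals=signals,
        provenance={
            "generator": "nanoforesight.synthetic_data",
            "seed": str(config.seed if seed is None else seed),
        },
    )


def generate_regdb(
    n_extra: int = 0, seed: Optional[int] = None
) -> List[RegulatoryDocument]:
    """The packaged regulatory-document table, optionally augmented with
    random synthetic documents over the signature-pattern alphabet."""
    docs = load_packaged_regdb()
    if n_extra <= 0:
        return docs
    rng = np.random.default_rng(seed)
    alphabets = (("1", "2"), ("1", "2", "3"), ("0", "1", "2", "3", "3s"),
                 ("0", "1", "2"))
    statuses = ("Under development", "Current version", "Final")
    for k in range(n_extra):
        positions = []
        for alphabet in alphabets:
            if rng.random() < 0.3:
                positions.append("n")
            else:
                positions.append(str(alphabet[int(rng.integers(0, len(alphabet)))]))
        docs.append(
            RegulatoryDocument(
                source=str(KNOWN_SOURCES[int(rng.integers(0, len(KNOWN_SOURCES)))]),
                status=str(statuses[int(rng.integers(0, len(statuses)))]),
                name=f"Synthetic regulatory document {k + 1}",
                nhp_pattern=as_pattern(".".join(positions)),
            )
        )
    return docs
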