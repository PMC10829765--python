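"""Grammar, validation and matching for NHP classification codes.

Nanotechnology-enabled health products (NHPs) are indexed by two controlled
vocabularies:

* a **classification signature** — a four-position code giving the product's
  primary mode of action, medical purpose, chemical composition and
  nanofabrication approach, e.g. ``"2.3.2.1"``.  A position may hold several
  codes (a *multifunctional* product), rendered with parentheses:
  ``"2.(1.2.3).1.1"``.  Composition codes may carry an ``s`` suffix marking
  self-assembly in physiological medium, e.g. ``"2.3.3s.1"``.

* a **design solution code (DSC)** — the attribute by which a product solves
  one of six design problems, e.g. ``"B.T.2.3"`` (a molecular building block
  nanocarrier).  Its last two tokens repeat the mode-of-action and purpose
  digits of the signature vocabulary.

Patterns over signatures use the literal ``n`` as a per-position wildcard
(``"2.3.n.n"``); the code ``0`` means *undefined* and is an ordinary code,
not a wildcard.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from fractions import Fraction  # noqa: F401  (re-exported convenience)
from importlib import resources
from typing import Callable, FrozenSet, Iterable, Optional, Sequence, Tuple, Union

__all__ = [
    "ClassificationError",
    "CompositionCode",
    "ClassificationSignature",
    "SignaturePattern",
    "DesignSolutionCode",
    "DesignProblemCategory",
    "DESIGN_PROBLEMS",
    "parse_signature",
    "format_signature",
    "parse_pattern",
    "matches_pattern",
    "parse_dsc",
    "design_problem",
    "load_dsc_dictionary",
]


class ClassificationError(ValueError):
    """Raised when a signature, pattern or DSC string is malformed."""


# position index -> (name, legal digit alphabet, allows "s" flag)
_POSITIONS: Tuple[Tuple[str, FrozenSet[int], bool], ...] = (
    ("mode_of_action", frozenset({1, 2}), False),
    ("medical_purpose", frozenset({1, 2, 3}), False),
    ("chemical_composition", frozenset({0, 1, 2, 3}), True),
    ("nanofabrication", frozenset({0, 1, 2}), False),
)


@dataclass(frozen=True, order=True)
class CompositionCode:
    """A chemical-composition code with its optional self-assembling flag."""

    code: int
    self_assembling: bool = False

    def __str__(self) -> str:
        return f"{self.code}s" if self.self_assembling else str(self.code)


Code = Union[int, CompositionCode]


def _format_code(code: Code) -> str:
    return str(code)


def _format_position(codes: FrozenSet[Code]) -> str:
    parts = [_format_code(c) for c in sorted(codes, key=lambda c: (str(c)))]
    if len(parts) == 1:
        return parts[0]
    return "(" + ".".join(parts) + ")"


@dataclass(frozen=True)
class ClassificationSignature:
    """Validated four-position NHP classification signature.

    Each position is a non-empty frozenset of codes from its legal alphabet;
    composition codes are :class:`CompositionCode` values, the other three
    positions plain ints.
    """

    mode_of_action: FrozenSet[int]
    medical_purpose: FrozenSet[int]
    chemical_composition: FrozenSet[CompositionCode]
    nanofabrication: FrozenSet[int]

    def __post_init__(self) -> None:
        for (name, alphabet, flagged), codes in zip(_POSITIONS, self.positions()):
            if not codes:
                raise ClassificationError(f"position '{name}' holds no code")
            for code in codes:
                digit = code.code if isinstance(code, CompositionCode) else code
                if isinstance(code, CompositionCode) and not flagged:
                    raise ClassificationError(
                        f"position '{name}' does not admit an 's' flag"
                    )
                if digit not in alphabet:
                    raise ClassificationError(
                        f"illegal code {digit} in position '{name}' "
                        f"(legal: {sorted(alphabet)})"
                    )

    def positions(self) -> Tuple[FrozenSet[Code], ...]:
        return (
            self.mode_of_action,
            self.medical_purpose,
            self.chemical_composition,
            self.nanofabrication,
        )

    @property
    def is_multifunctional(self) -> bool:
        """True if any position holds more than one code."""
        return any(len(p) > 1 for p in self.positions())

    def __str__(self) -> str:
        return format_signature(self)


@dataclass(frozen=True)
class SignaturePattern:
    """A signature with per-position wildcards, e.g. ``"2.3.n.n"``.

    ``None`` in a position means the wildcard ``n``; otherwise the position is
    a frozenset of codes exactly as in :class:`ClassificationSignature`.
    """

    positions: Tuple[Optional[FrozenSet[Code]], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 4:
            raise ClassificationError(
                f"pattern has {len(self.positions)} positions, expected 4"
            )

    def __str__(self) -> str:
        return ".".join(
            "n" if p is None else _format_position(p) for p in self.positions
        )

    # --- matching -----------------------------------------------------

    def matches(
        self, other: Union["SignaturePattern", ClassificationSignature, str],
        lenient: bool = False,
    ) -> bool:
        """Position-wise compatibility with a signature (or another pattern).

        A wildcard position matches anything; two concrete positions match iff
        their code sets intersect.  With ``lenient=True`` the undefined code 0
        on either side also matches (composition flags are never relaxed).
        """
        other_pat = as_pattern(other)
        for mine, theirs in zip(self.positions, other_pat.positions):
            if mine is None or theirs is None:
                continue
            if mine & theirs:
                continue
            if lenient and (_has_zero(mine) or _has_zero(theirs)):
                continue
            return False
        return True

    def covers(
        self, sig: Union[ClassificationSignature, "SignaturePattern", str]
    ) -> bool:
        """True iff every code of every query position is admitted here.

        Stricter than :meth:`matches`: a multifunctional query position is
        covered only when this pattern's position is a wildcard or a superset
        of the full code set.
        """
        query = as_pattern(sig)
        for mine, theirs in zip(self.positions, query.positions):
            if mine is None:
                continue
            if theirs is None or not (theirs <= mine):
                return False
        return True


def _has_zero(codes: FrozenSet[Code]) -> bool:
    return any(
        (c.code if isinstance(c, CompositionCode) else c) == 0 for c in codes
    )


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_ATOM_RE = re.compile(r"^(\d)(s?)$")


def _split_positions(text: str, what: str) -> list[str]:
    # split on top-level dots only; parenthesised groups keep their dots
    out: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
            current.append(ch)
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ClassificationError(f"unbalanced parentheses in {what} {text!r}")
            current.append(ch)
        elif ch == "." and depth == 0:
            out.append("".join(current))
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise ClassificationError(f"unbalanced parentheses in {what} {text!r}")
    out.append("".join(current))
    return out


def _parse_atom(
    atom: str, index: int, allow_wildcard: bool
) -> Union[None, Code]:
    name, alphabet, flagged = _POSITIONS[index]
    if allow_wildcard and atom == "n":
        return None
    m = _ATOM_RE.match(atom)
    if not m:
        raise ClassificationError(
            f"malformed code {atom!r} in position '{name}'"
        )
    digit = int(m.group(1))
    has_flag = m.group(2) == "s"
    if digit not in alphabet:
        raise ClassificationError(
            f"illegal code {digit} in position '{name}' (legal: {sorted(alphabet)})"
        )
    if has_flag and not flagged:
        raise ClassificationError(
            f"position '{name}' does not admit an 's' flag"
        )
    if flagged:
        return CompositionCode(digit, has_flag)
    return digit


def _parse_position(
    token: str, index: int, allow_wildcard: bool
) -> Optional[FrozenSet[Code]]:
    name = _POSITIONS[index][0]
    if not token:
        raise ClassificationError(f"empty position '{name}'")
    if token.startswith("("):
        if not token.endswith(")"):
            raise ClassificationError(
                f"unbalanced parentheses in position '{name}': {token!r}"
            )
        atoms = token[1:-1].split(".")
        if len(atoms) < 2:
            raise ClassificationError(
                f"parenthesised position '{name}' must hold at least two codes"
            )
    else:
        atoms = [token]
    codes = []
    wildcard = False
    for atom in atoms:
        parsed = _parse_atom(atom, index, allow_wildcard)
        if parsed is None:
            wildcard = True
        else:
            codes.append(parsed)
    if wildcard:
        if codes:
            raise ClassificationError(
                f"position '{name}' mixes 'n' with concrete codes"
            )
        return None
    return frozenset(codes)


def _normalize(text: str) -> str:
    # tolerate stray whitespace inside positions, e.g. "2.3.3 s.1"
    return re.sub(r"\s+", "", text)


def parse_signature(text: str) -> ClassificationSignature:
    """Parse a classification signature string like ``"2.(1.2.3).1.1"``.

    Whitespace inside positions is discarded, so ``"2.3.3 s.1"`` and
    ``"2.3.3s.1"`` parse identically.
    """
    if not text or not text.strip():
        raise ClassificationError("empty signature string")
    tokens = _split_positions(_normalize(text), "signature")
    if len(tokens) != 4:
        raise ClassificationError(
            f"signature {text!r} has {len(tokens)} positions, expected 4"
        )
    parsed = [
        _parse_position(tok, i, allow_wildcard=False) for i, tok in enumerate(tokens)
    ]
    return ClassificationSignature(*parsed)  # type: ignore[arg-type]


def format_signature(sig: ClassificationSignature) -> str:
    """Canonical string form: dot-separated, multivalued positions in
    parentheses with codes ascending, ``s`` flags appended without space."""
    return ".".join(_format_position(p) for p in sig.positions())


def parse_pattern(text: str) -> SignaturePattern:
    """Parse a signature pattern; ``n`` is the per-position wildcard."""
    if not text or not text.strip():
        raise ClassificationError("empty pattern string")
    tokens = _split_positions(_normalize(text), "pattern")
    if len(tokens) != 4:
        raise ClassificationError(
            f"pattern {text!r} has {len(tokens)} positions, expected 4"
        )
    return SignaturePattern(
        tuple(_parse_position(tok, i, allow_wildcard=True) for i, tok in enumerate(tokens))
    )


def as_pattern(
    value: Union[str, ClassificationSignature, SignaturePattern]
) -> SignaturePattern:
    """Coerce a signature, pattern or string to a :class:`SignaturePattern`."""
    if isinstance(value, SignaturePattern):
        return value
    if isinstance(value, ClassificationSignature):
        return SignaturePattern(value.positions())
    return parse_pattern(value)


def matches_pattern(
    sig: Union[ClassificationSignature, str],
    pattern: Union[SignaturePattern, str],
    lenient: bool = False,
) -> bool:
    """True iff every non-wildcard pattern position intersects the signature's
    corresponding code set.  ``0`` (undefined) is a literal code unless
    ``lenient`` is set, in which case it matches anything in its position."""
    if isinstance(sig, str):
        sig = parse_signature(sig)
    return as_pattern(pattern).matches(sig, lenient=lenient)


# --------------------------------------------------------------------------
# design solution codes
# --------------------------------------------------------------------------

_DSC_RE = re.compile(r"^([A-Za-z]+)\.([A-Za-z])\.(\d)\.(\d)$")
_UNSPECIFIC_IDS = frozenset({"Y", "Z"})


@dataclass(frozen=True, order=True)
class DesignSolutionCode:
    """A design solution code such as ``"B.T.2.3"``.

    The identifier names the design solution (one or more letters; ``Y`` and
    ``Z`` are reserved for unspecific solutions), the single-letter effect
    qualifier distinguishes treating from prophylactic effects, and the two
    digits repeat the mode-of-action and medical-purpose codes of the
    signature vocabulary.
    """

    solution_id: str
    effect_qualifier: str
    mode_of_action: int
    medical_purpose: int
    descriptor: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.solution_id.isalpha():
            raise ClassificationError(
                f"solution id {self.solution_id!r} must be letters only"
            )
        if len(self.effect_qualifier) != 1 or not self.effect_qualifier.isalpha():
            raise ClassificationError(
                f"effect qualifier {self.effect_qualifier!r} must be one letter"
            )
        if self.mode_of_action not in (1, 2):
            raise ClassificationError(
                f"illegal mode of action {self.mode_of_action} in DSC (legal: [1, 2])"
            )
        if self.medical_purpose not in (1, 2, 3):
            raise ClassificationError(
                f"illegal medical purpose {self.medical_purpose} in DSC "
                "(legal: [1, 2, 3])"
            )

    @property
    def is_unspecific(self) -> bool:
        """Reserved identifiers Y/Z mark solutions too vague to analyse."""
        return self.solution_id.upper() in _UNSPECIFIC_IDS

    def __str__(self) -> str:
        return (
            f"{self.solution_id}.{self.effect_qualifier}"
            f".{self.mode_of_action}.{self.medical_purpose}"
        )


def parse_dsc(text: str, descriptor: Optional[str] = None) -> DesignSolutionCode:
    """Parse a DSC string like ``"B.T.2.3"``."""
    if not text or not text.strip():
        raise ClassificationError("empty DSC string")
    m = _DSC_RE.match(_normalize(text))
    if not m:
        raise ClassificationError(
            f"malformed DSC {text!r}: expected '<letters>.<letter>.<digit>.<digit>'"
        )
    return DesignSolutionCode(
        solution_id=m.group(1),
        effect_qualifier=m.group(2),
        mode_of_action=int(m.group(3)),
        medical_purpose=int(m.group(4)),
        descriptor=descriptor,
    )


# --------------------------------------------------------------------------
# design problems
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class DesignProblemCategory:
    """One of the six design problems an NHP attribute may address."""

    mode_of_action: int
    purpose_label: str

    def __str__(self) -> str:
        action = (
            "pharmacological/immunological/metabolic"
            if self.mode_of_action == 1
            else "non-pharmacological/immunological/metabolic"
        )
        return f"{action} action, {self.purpose_label} effect"


#: The canonical six design-problem categories.
DESIGN_PROBLEMS: Tuple[DesignProblemCategory, ...] = (
    DesignProblemCategory(1, "therapeutic/treating"),
    DesignProblemCategory(1, "therapeutic/prophylactic"),
    DesignProblemCategory(2, "therapeutic"),
    DesignProblemCategory(2, "non-IVD diagnostic"),
    DesignProblemCategory(2, "IVD diagnostic"),
    DesignProblemCategory(2, "galenic"),
)

#: Effect qualifier carrying the treating/prophylactic split for mode-1
#: therapeutic DSCs.  Only "T" (treating) is attested in the source
#: vocabulary; the prophylactic letter is configurable.
TREATING_QUALIFIER = "T"
PROPHYLACTIC_QUALIFIER = "P"

# Data-driven category map: (mode, purpose, qualifier-or-None) -> purpose
# label.  qualifier None is the fallback for the (mode, purpose) cell.
_DEFAULT_CATEGORY_TABLE: dict = {
    (1, 1, TREATING_QUALIFIER): "therapeutic/treating",
    (1, 1, PROPHYLACTIC_QUALIFIER): "therapeutic/prophylactic",
    (1, 1, None): "therapeutic/treating",
    (2, 1, None): "therapeutic",
    (1, 2, None): "non-IVD diagnostic",
    (2, 2, None): "non-IVD diagnostic",
    (1, 3, None): "galenic",
    (2, 3, None): "galenic",
}

#: DSC-level overrides for splits the digits cannot encode (e.g. in vitro
#: diagnostics).  Maps canonical DSC string -> purpose label.
_DEFAULT_DSC_OVERRIDES: dict = {}


def design_problem(
    dsc: Union[DesignSolutionCode, str],
    category_table: Optional[dict] = None,
    dsc_overrides: Optional[dict] = None,
) -> DesignProblemCategory:
    """Map a DSC to its design-problem category.

    The mapping is data-driven: ``category_table`` keys are
    ``(mode, purpose, qualifier)`` with ``qualifier=None`` as the cell
    fallback, and ``dsc_overrides`` maps canonical DSC strings to purpose
    labels (used e.g. to mark individual diagnostic solutions as in vitro).
    Total on every parseable DSC, including unspecific (Y/Z) codes.
    """
    if isinstance(dsc, str):
        dsc = parse_dsc(dsc)
    table = category_table if category_table is not None else _DEFAULT_CATEGORY_TABLE
    overrides = (
        dsc_overrides if dsc_overrides is not None else _DEFAULT_DSC_OVERRIDES
    )
    label = overrides.get(str(dsc))
    if label is None:
        label = table.get((dsc.mode_of_action, dsc.medical_purpose, dsc.effect_qualifier))
    if label is None:
        label = table.get((dsc.mode_of_action, dsc.medical_purpose, None))
    if label is None:
        raise ClassificationError(
            f"no design-problem category for DSC {dsc} "
            f"(mode {dsc.mode_of_action}, purpose {dsc.medical_purpose})"
        )
    return DesignProblemCategory(dsc.mode_of_action, label)


# --------------------------------------------------------------------------
# packaged DSC dictionary
# --------------------------------------------------------------------------

def load_dsc_dictionary() -> dict:
    """Load the packaged DSC dictionary.

    Returns a mapping from canonical DSC string to a
    ``{"descriptor": ..., "definition": ...}`` dict covering every design
    solution named in the packaged trend and wild-card vocabularies.
    """
    out: dict = {}
    ref = resources.files("nanoforesight.data").joinpath("dsc_dictionary.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            code = str(parse_dsc(row["dsc_code"]))
            out[code] = {
                "descriptor": row["descriptor"],
                "definition": row["definition"],
            }
    return out
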