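"""Signature/DSC grammar: parsing, formatting, pattern matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoforesight.classification import (
    ClassificationError,
    CompositionCode,
    DESIGN_PROBLEMS,
    design_problem,
    format_signature,
    load_dsc_dictionary,
    matches_pattern,
    parse_dsc,
    parse_pattern,
    parse_signature,
)

# ---------------------------------------------------------------------------
# hypothesis strategies for valid codes


def _position_strategy(alphabet, flagged):
    if flagged:
        atoms = st.tuples(st.sampled_from(sorted(alphabet)), st.booleans()).map(
            lambda t: CompositionCode(*t)
        )
    else:
        atoms = st.sampled_from(sorted(alphabet))
    return st.frozensets(atoms, min_size=1, max_size=len(alphabet))


valid_signatures = st.builds(
    lambda m, p, c, f: ".".join(
        "(" + ".".join(sorted(map(str, pos))) + ")" if len(pos) > 1 else str(next(iter(pos)))
        for pos in (m, p, c, f)
    ),
    _position_strategy({1, 2}, False),
    _position_strategy({1, 2, 3}, False),
    _position_strategy({0, 1, 2, 3}, True),
    _position_strategy({0, 1, 2}, False),
)

valid_dscs = st.builds(
    lambda sid, q, m, p: f"{sid}.{q}.{m}.{p}",
    st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=1, max_size=3),
    st.sampled_from("TP"),
    st.sampled_from([1, 2]),
    st.sampled_from([1, 2, 3]),
)


# ---------------------------------------------------------------------------
# signatures


@pytest.mark.parametrize(
    "text, mode, purpose, comp, fab",
    [
        ("2.3.2.1", {2}, {3}, {CompositionCode(2)}, {1}),
        (
            "2.(1.2.3).1.1",
            {2},
            {1, 2, 3},
            {CompositionCode(1)},
            {1},
        ),
        ("2.3.3 s.1", {2}, {3}, {CompositionCode(3, True)}, {1}),
        ("(1.2).1.1.1", {1, 2}, {1}, {CompositionCode(1)}, {1}),
    ],
)
def test_parse_signature_positions(text, mode, purpose, comp, fab):
    sig = parse_signature(text)
    assert sig.mode_of_action == frozenset(mode)
    assert sig.medical_purpose == frozenset(purpose)
    assert sig.chemical_composition == frozenset(comp)
    assert sig.nanofabrication == frozenset(fab)


def test_whitespace_normalization():
    assert parse_signature("2.3.3 s.1") == parse_signature("2.3.3s.1")
    assert format_signature(parse_signature("2.3.3 s.1")) == "2.3.3s.1"


def test_multivalued_formatting():
    assert format_signature(parse_signature("(1.2).1.1.1")) == "(1.2).1.1.1"
    assert format_signature(parse_signature("(2.1).1.1.1")) == "(1.2).1.1.1"


@pytest.mark.parametrize(
    "bad",
    [
        "2.3.2",  # arity
        "2.3.2.1.1",  # arity
        "4.3.2.1",  # illegal mode
        "2.5.2.1",  # illegal purpose
        "2.3.(2.1.1",  # unbalanced parens
        "2s.3.2.1",  # s flag outside composition
        "",
        "2.3..1",
    ],
)
def test_parse_signature_rejects_malformed(bad):
    with pytest.raises(ClassificationError):
        parse_signature(bad)


def test_error_names_offending_position():
    with pytest.raises(ClassificationError, match="medical_purpose"):
        parse_signature("2.5.2.1")


@settings(max_examples=200, deadline=None)
@given(valid_signatures)
def test_signature_round_trip(text):
    sig = parse_signature(text)
    assert parse_signature(format_signature(sig)) == sig


# ---------------------------------------------------------------------------
# pattern matching


@pytest.mark.parametrize(
    "sig, pattern, expected",
    [
        ("2.3.2.1", "2.3.n.n", True),
        ("2.(1.2.3).1.1", "n.2.n.n", True),
        ("2.3.1.0", "2.3.3s.n", False),
        ("2.3.3s.1", "2.3.3s.1", True),
        # "0" is a literal undefined code, not a wildcard
        ("2.3.0.1", "2.3.2.1", False),
        ("2.1.1.0", "2.1.1.1", False),
    ],
)
def test_matches_pattern(sig, pattern, expected):
    assert matches_pattern(sig, pattern) is expected


def test_lenient_matching_relaxes_zero():
    assert matches_pattern("2.3.0.1", "2.3.2.1", lenient=True)
    assert matches_pattern("2.1.1.0", "2.1.1.1", lenient=True)
    assert not matches_pattern("1.3.2.1", "2.3.2.1", lenient=True)


def test_malformed_pattern_rejected():
    with pytest.raises(ClassificationError):
        parse_pattern("2.3.x.n")
    with pytest.raises(ClassificationError):
        parse_pattern("2.3.n")


@settings(max_examples=200, deadline=None)
@given(valid_signatures)
def test_pattern_self_and_universal_match(text):
    sig = parse_signature(text)
    assert matches_pattern(sig, format_signature(sig))
    assert matches_pattern(sig, "n.n.n.n")


# ---------------------------------------------------------------------------
# design solution codes


def test_parse_dsc_fields():
    dsc = parse_dsc("B.T.2.3")
    assert dsc.solution_id == "B"
    assert dsc.effect_qualifier == "T"
    assert dsc.mode_of_action == 2
    assert dsc.medical_purpose == 3
    assert not dsc.is_unspecific
    assert str(dsc) == "B.T.2.3"


def test_unspecific_dscs():
    assert parse_dsc("Z.T.2.1").is_unspecific
    assert parse_dsc("Y.T.1.1").is_unspecific
    assert not parse_dsc("YY.T.1.1").is_unspecific


@pytest.mark.parametrize("bad", ["B.T.2", "B.2.3", "B.T.3.3", "B.T.2.4", "1.T.2.3", ""])
def test_parse_dsc_rejects_malformed(bad):
    with pytest.raises(ClassificationError):
        parse_dsc(bad)


@settings(max_examples=200, deadline=None)
@given(valid_dscs)
def test_dsc_round_trip(text):
    assert str(parse_dsc(text)) == text


# ---------------------------------------------------------------------------
# design problems


def test_six_canonical_categories():
    assert len(DESIGN_PROBLEMS) == 6
    assert len(set(DESIGN_PROBLEMS)) == 6


def test_design_problem_grid():
    # the printed (mode, purpose, qualifier) grid yields exactly the six
    # canonical categories, the treating/prophylactic split carried by the
    # effect qualifier and the IVD split by DSC-level override
    got = {
        design_problem("K.T.1.1"),  # pharmacological treating
        design_problem("K.P.1.1"),  # pharmacological prophylactic
        design_problem("E.T.2.1"),  # non-pharm therapeutic
        design_problem("A.T.2.2"),  # non-pharm non-IVD diagnostic
        design_problem("A.T.2.2", dsc_overrides={"A.T.2.2": "IVD diagnostic"}),
        design_problem("B.T.2.3"),  # non-pharm galenic
    }
    assert got == set(DESIGN_PROBLEMS)


def test_design_problem_galenic_example():
    cat = design_problem(parse_dsc("B.T.2.3"))
    assert cat.mode_of_action == 2
    assert cat.purpose_label == "galenic"


@settings(max_examples=200, deadline=None)
@given(valid_dscs)
def test_design_problem_total(text):
    cat = design_problem(text)
    assert cat.mode_of_action == parse_dsc(text).mode_of_action


# ---------------------------------------------------------------------------
# packaged dictionary


def test_dsc_dictionary_covers_planted_vocabulary():
    d = load_dsc_dictionary()
    assert d["B.T.2.3"]["descriptor"] == "Molecular building block nanocarrier"
    assert d["E.T.2.1"]["descriptor"] == "Dental filling/replacement material"
    for code in ("C.T.2.3", "F.T.2.1", "K.T.1.1", "L.T.2.3"):
        assert code in d
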