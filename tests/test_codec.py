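"""Scaffold-code validation, serialization, distances and the move grammar."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iridograph import (
    ScaffoldCode,
    apply_move,
    format_code,
    generalized_distance,
    iridoid_grammar,
    list_moves,
    parse_code,
    validate_code,
)
from iridograph.codec import (
    CodeStructureError,
    ReactionMove,
    manhattan_complex,
)

CFG = iridoid_grammar()

CATALPOL = "1,0+1/4i,0+1/4i,0,1,0+3/4i,0+3/4i,0,1,3"
AUCUBIN = "1,0+1/4i,0+1/4i,0,1,0,0,0,1,3"
BARTSIOSIDE = "1,0+1/4i,0+1/4i,0,0,0,0,0,1,3"


def code(text):
    return parse_code(text, CFG)


def random_valid_codes(n, seed=0):
    """Deterministic sample of valid codes by random walks from saturation."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        c = ScaffoldCode.saturated(CFG)
        for _ in range(int(rng.integers(0, 12))):
            moves = list_moves(c, CFG)
            if not moves:
                break
            c = apply_move(c, moves[int(rng.integers(len(moves)))], CFG)
        out.append(c)
    return out


class TestValidation:
    def test_catalpol_code_is_valid(self):
        # C3=C4 double bond, C7-C8 epoxide, decarboxylated C11, three hydroxyls
        ok, violations = validate_code(code(CATALPOL), CFG)
        assert ok and violations == []

    def test_fully_saturated_scaffold_is_valid(self):
        ok, _ = validate_code(ScaffoldCode.saturated(CFG), CFG)
        assert ok

    def test_unpaired_double_bond_flag_is_rejected(self):
        # i/4 on C3 only: no adjacent partner carries the flag
        c = ScaffoldCode((0,) * 10, (0, 1, 0, 0, 0, 0, 0, 0, 0, 0))
        ok, violations = validate_code(c, CFG)
        assert not ok
        assert any(v.rule == "flag-pairing" for v in violations)

    def test_state_above_valence_cap_is_rejected(self):
        c = ScaffoldCode((0, 3, 0, 0, 0, 0, 0, 0, 0, 0), (0,) * 10)
        ok, violations = validate_code(c, CFG)
        assert not ok
        assert violations[0].position == "C3"
        assert violations[0].rule == "oxidation-state-range"

    def test_flagged_carbon_oxidation_cap(self):
        # double-bond carbons must stay saturated in the published grammar
        flags = [0] * 10
        flags[1] = flags[2] = 1  # C3=C4
        reals = [0] * 10
        reals[1] = 1
        ok, violations = validate_code(ScaffoldCode(tuple(reals), tuple(flags)), CFG)
        assert not ok
        assert any(v.rule == "flag-valence" for v in violations)

    def test_malformed_position_set_is_a_structural_error(self):
        with pytest.raises(CodeStructureError):
            validate_code(ScaffoldCode((0,) * 9, (0,) * 9), CFG)


class TestSerialization:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_format_parse_roundtrip(self, seed):
        for c in random_valid_codes(4, seed=seed):
            assert parse_code(format_code(c), CFG) == c

    def test_bad_token_is_strict(self):
        with pytest.raises(CodeStructureError, match="C3"):
            parse_code("0,x,0,0,0,0,0,0,0,0", CFG)

    def test_token_grammar_writes_quarters(self):
        assert format_code(code(CATALPOL)) == CATALPOL


class TestDistance:
    def test_identical_codes_have_zero_distance(self):
        c = code(CATALPOL)
        assert generalized_distance(c, c, CFG) == 0.0

    def test_single_hydroxylation_is_distance_one(self):
        assert generalized_distance(code(BARTSIOSIDE), code(AUCUBIN), CFG) == 1.0

    def test_literal_desaturation_arithmetic_is_half(self):
        # direct complex arithmetic: two i/4 steps sum to 0.5 ...
        a = ScaffoldCode.saturated(CFG)
        flags = [0] * 10
        flags[1] = flags[2] = 1
        b = ScaffoldCode((0,) * 10, tuple(flags))
        assert manhattan_complex(a, b) == pytest.approx(0.5)
        # ... and the calibrated metric scores the move as one reaction
        assert generalized_distance(a, b, CFG) == pytest.approx(1.0)

    def test_distance_is_symmetric(self):
        codes = random_valid_codes(20, seed=7)
        for a, b in itertools.combinations(codes, 2):
            assert generalized_distance(a, b, CFG) == pytest.approx(
                generalized_distance(b, a, CFG)
            )

    def test_every_move_changes_distance_by_exactly_one(self):
        for c in random_valid_codes(300, seed=11):
            for mv in list_moves(c, CFG):
                product = apply_move(c, mv, CFG)
                assert generalized_distance(c, product, CFG) == pytest.approx(1.0)


class TestMoves:
    def test_c11_direct_oxidation_step(self):
        # aldehyde (1) -> carboxylic acid (2) in one step
        reals = [0] * 10
        reals[9] = 1
        c = ScaffoldCode(tuple(reals), (0,) * 10)
        mv = next(
            m for m in list_moves(c, CFG)
            if m.kind == "c11_direct_oxidation" and m.carbons == (9,)
        )
        out = apply_move(c, mv, CFG)
        assert out.reals[9] == 2

    def test_hydroxylation_changes_only_one_carbon(self):
        c = ScaffoldCode.saturated(CFG)
        mv = next(m for m in list_moves(c, CFG) if m.carbons == (0,))
        out = apply_move(c, mv, CFG)
        assert out.reals[0] == 1
        assert out.reals[1:] == c.reals[1:]
        assert out.flags == c.flags

    def test_inapplicable_move_is_rejected_with_reason(self):
        c = ScaffoldCode.saturated(CFG)
        bogus = ReactionMove("decarboxylation", (1,), (1 + 0j,))
        with pytest.raises(ValueError):
            apply_move(c, bogus, CFG)

    def test_list_moves_matches_brute_force_scan(self):
        """Moves listed are exactly the (kind, carbons) whose application
        yields a valid code one calibrated unit away."""
        ox_kinds = {
            "hydroxylation",
            "alcohol_to_aldehyde",
            "aldehyde_to_acid",
            "decarboxylation",
            "c11_direct_oxidation",
        }
        for c in random_valid_codes(30, seed=3):
            listed = {
                ("ox" if m.kind in ox_kinds else m.kind, m.carbons)
                for m in list_moves(c, CFG)
            }
            brute = set()
            # oxidation attempts on every carbon
            for i in range(10):
                cand = ScaffoldCode(
                    tuple(r + (1 if j == i else 0) for j, r in enumerate(c.reals)),
                    c.flags,
                )
                ok, _ = validate_code(cand, CFG)
                if ok:
                    brute.add(("ox", (i,)))
            # flag attempts on every bond
            for a, b in CFG.bonds:
                for q in (1, 3):
                    flags = list(c.flags)
                    if flags[a] or flags[b]:
                        continue
                    flags[a] = flags[b] = q
                    cand = ScaffoldCode(c.reals, tuple(flags))
                    ok, _ = validate_code(cand, CFG)
                    if ok:
                        kind = "desaturation" if q == 1 else "epoxidation"
                        key = (min(a, b), max(a, b))
                        pair = (a, b) if a < b else (b, a)
                        brute.add((kind, pair))
                # double bond -> epoxide
                flags = list(c.flags)
                if flags[a] == 1 and flags[b] == 1:
                    flags[a] = flags[b] = 3
                    cand = ScaffoldCode(c.reals, tuple(flags))
                    ok, _ = validate_code(cand, CFG)
                    if ok:
                        pair = (a, b) if a < b else (b, a)
                        brute.add(("epoxidation", pair))
            normalized = {
                (k, tuple(sorted(cs))) for k, cs in listed
            }
            assert normalized == {
                (k, tuple(sorted(cs))) for k, cs in brute
            }

    def test_saturated_code_has_the_most_forward_oxidations(self):
        zero = ScaffoldCode.saturated(CFG)
        n_zero = len(list_moves(zero, CFG))
        # a maximally oxidized code: every carbon at its cap
        top = ScaffoldCode(tuple(CFG.max_real), (0,) * 10)
        n_top = len(list_moves(top, CFG))
        assert n_top < n_zero
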