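"""Unit and property tests for the integer fuzzy-controller datapath."""

import pytest
from hypothesis import given, settings, strategies as st

from fuzzyfes.flc import (DEFAULT_MEMBERSHIPS, DEFAULT_SINGLETONS, RULE_OUTPUT,
                          FuzzyConfigError, MembershipVector, TriangleParams,
                          ZeroFiringError, default_flc_config, defuzzify,
                          flc_step, flc_step_float, fuzzify, infer_rules,
                          reset_defuzzy, scale_to_digital,
                          triangular_membership)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [
    (-20, 0),      # bottom anchor of the digital scale
    (0, 127),      # centre anchor
    (20, 255),     # top anchor
    (-4, 102),     # floor((16*255)/40)
    (66, 255),     # clamped to +20 before scaling
    (-100, 0),     # clamped to -20
])
def test_scale_to_digital_anchors(x, expected):
    assert scale_to_digital(x) == expected


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=-1000, max_value=1000))
def test_scaling_is_idempotent_under_clamping(x):
    clamped = min(max(x, -20), 20)
    assert scale_to_digital(x) == scale_to_digital(clamped)
    assert 0 <= scale_to_digital(x) <= 255


# ---------------------------------------------------------------------------
# triangular membership
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,tri,expected", [
    (63, (0, 63, 127), 255),     # peak value
    (0, (0, 63, 127), 0),        # left boundary
    (127, (0, 63, 127), 0),      # right boundary
    (102, (0, 63, 127), 99),     # falling edge floor(255*25/64)
    (32, (0, 63, 127), 129),     # rising edge floor(255*32/63)
    (255, (191, 255, 255), 255), # right shoulder at top of scale
    (0, (0, 0, 63), 255),        # left shoulder at bottom of scale
])
def test_triangular_membership_values(x, tri, expected):
    assert triangular_membership(x, TriangleParams(*tri)) == expected


def test_degenerate_triangle_is_a_single_point():
    t = TriangleParams(100, 100, 100)
    assert triangular_membership(100, t) == 255
    assert all(triangular_membership(x, t) == 0
               for x in (0, 99, 101, 255))


def test_unsorted_breakpoints_rejected():
    with pytest.raises(FuzzyConfigError):
        triangular_membership(0, TriangleParams(10, 5, 20))


# ---------------------------------------------------------------------------
# fuzzification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [
    (127, (0, 0, 255, 0, 0)),
    (255, (0, 0, 0, 0, 255)),
    (0, (255, 0, 0, 0, 0)),
    (102, (0, 99, 155, 0, 0)),
])
def test_fuzzify_examples(x, expected):
    assert fuzzify(x) == MembershipVector(*expected)


def test_partition_of_unity_over_full_scale():
    """The five memberships always sum to 254 or 255 (floor loss <= 1)."""
    for x in range(256):
        vec = fuzzify(x)
        assert sum(vec) in (254, 255), f"x={x}: {vec}"
        assert max(vec) >= 127


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _vec(**kw):
    base = dict(nb=0, ns=0, ze=0, ps=0, pb=0)
    base.update(kw)
    return MembershipVector(**base)


@pytest.mark.parametrize("e,de,expected_nonzero", [
    (_vec(ze=255), _vec(ze=255), {13: 255}),
    (_vec(pb=255), _vec(ns=99, ze=155), {10: 99, 15: 155}),
    (_vec(nb=255), _vec(nb=255), {1: 255}),
])
def test_infer_rules_min_selection(e, de, expected_nonzero):
    strengths = infer_rules(e, de)
    found = {i + 1: s for i, s in enumerate(strengths) if s}
    assert found == expected_nonzero


# ---------------------------------------------------------------------------
# defuzzification
# ---------------------------------------------------------------------------

def test_defuzzify_single_rule_returns_its_singleton_scaled():
    strengths = [0] * 25
    strengths[12] = 255  # rule 13: (ZE, ZE) -> ME
    res = defuzzify(strengths, DEFAULT_SINGLETONS[70])
    assert res.defuzzy == 38
    assert res.pulse == 380
    assert res.fired_rules == ((13, 255),)


def test_defuzzify_weighted_floor():
    strengths = [0] * 25
    strengths[9] = 99    # rule 10 -> BG (42)
    strengths[14] = 155  # rule 15 -> VB (45)
    res = defuzzify(strengths, DEFAULT_SINGLETONS[70])
    assert res.defuzzy == (99 * 42 + 155 * 45) // 254 == 43
    assert res.pulse == 430


def test_defuzzify_uniform_strengths_uses_label_multiplicities():
    # 6 VS, 4 SM, 5 ME, 4 BG, 6 VB in the rule grid -> floor(798/25)
    res = defuzzify([7] * 25, DEFAULT_SINGLETONS[70])
    assert res.defuzzy == 31


def test_defuzzify_rejects_all_zero_strengths():
    with pytest.raises(ZeroFiringError):
        defuzzify([0] * 25, DEFAULT_SINGLETONS[70])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=0, max_value=255), min_size=25,
                max_size=25).filter(lambda s: any(s)),
       st.sampled_from([70, 40, 30]))
def test_defuzzify_output_bounded_by_singletons(strengths, ref):
    table = DEFAULT_SINGLETONS[ref]
    res = defuzzify(strengths, table)
    assert table.vs <= res.defuzzy <= table.vb
    assert res.pulse == res.defuzzy * 10


# ---------------------------------------------------------------------------
# full controller steps
# ---------------------------------------------------------------------------

def test_worked_register_example():
    """ref 70, act 4, raw previous error 70: the documented RTL walk-through."""
    res, new_prev = flc_step(70, 4, 70)
    assert (70 - 4, new_prev) == (66, 66)
    assert res.defuzzy == 43
    assert res.pulse == 430


@pytest.mark.parametrize("ref,act,prev,expected", [
    (70, 0, 0, 45),    # saturated positive error and change
    (70, 90, -20, 15), # saturated sweep end: NB error, ZE change
    (40, 0, 0, 30),
    (40, 90, -50, 10),
    (30, 0, 0, 26),
    (30, 90, -60, 10),
])
def test_flc_step_saturated_anchors(ref, act, prev, expected):
    res, _ = flc_step(ref, act, prev)
    assert res.defuzzy == expected


@pytest.mark.parametrize("ref,expected", [(70, 38), (40, 22), (30, 16)])
def test_power_on_output_is_me_singleton(ref, expected):
    assert reset_defuzzy(ref).defuzzy == expected


def test_unknown_reference_angle_rejected():
    with pytest.raises(FuzzyConfigError):
        flc_step(55, 0, 0)


def test_float_pipeline_worked_example():
    val, new_prev = flc_step_float(70, 4.0, 70.0)
    assert val == pytest.approx(43.8)
    assert new_prev == pytest.approx(66.0)


def test_float_pipeline_single_rule_exact():
    val, _ = flc_step_float(70, 0.0, 0.0)
    assert val == 45.0


def test_monotone_in_error_at_zero_change():
    """With dE pinned at its ZE peak, output is non-decreasing in E."""
    de = fuzzify(127)
    prev = None
    for e_scaled in range(256):
        res = defuzzify(infer_rules(fuzzify(e_scaled), de),
                        DEFAULT_SINGLETONS[70])
        if prev is not None:
            assert res.defuzzy >= prev
        prev = res.defuzzy


def test_integer_tracks_float_oracle_within_two_units():
    """Quantization never moves the output by more than 2 defuzzy units."""
    table = DEFAULT_SINGLETONS[70]
    worst = 0.0
    for err in range(-25, 26):
        for derr in range(-25, 26):
            prev = err - derr
            act = 70 - err
            res, _ = flc_step(70, act, prev)
            fval, _ = flc_step_float(70, float(act), float(prev))
            worst = max(worst, abs(res.defuzzy - fval))
    assert worst <= 2.0


# Independent oracle: literal transcription of the published rule grid,
# sharing no code with the datapath under test.
_BF_LABELS = ("nb", "ns", "ze", "ps", "pb")
_BF_TRIS = {"nb": (0, 0, 63), "ns": (0, 63, 127), "ze": (63, 127, 191),
            "ps": (127, 191, 255), "pb": (191, 255, 255)}
_BF_GRID = {  # (dE label, E label) -> output label
    ("nb", "nb"): "vs", ("nb", "ns"): "vs", ("nb", "ze"): "vs",
    ("nb", "ps"): "sm", ("nb", "pb"): "me",
    ("ns", "nb"): "vs", ("ns", "ns"): "vs", ("ns", "ze"): "sm",
    ("ns", "ps"): "me", ("ns", "pb"): "bg",
    ("ze", "nb"): "vs", ("ze", "ns"): "sm", ("ze", "ze"): "me",
    ("ze", "ps"): "bg", ("ze", "pb"): "vb",
    ("ps", "nb"): "sm", ("ps", "ns"): "me", ("ps", "ze"): "bg",
    ("ps", "ps"): "vb", ("ps", "pb"): "vb",
    ("pb", "nb"): "me", ("pb", "ns"): "bg", ("pb", "ze"): "vb",
    ("pb", "ps"): "vb", ("pb", "pb"): "vb",
}


def _bf_mu(x, a, b, c):
    if x == b:
        return 255
    if x <= a or x >= c:
        return 0
    if x < b:
        return (255 * (x - a)) // (b - a)
    return (255 * (c - x)) // (c - b)


def test_exhaustive_agreement_with_literal_rule_table():
    """Datapath equals a naive rule-grid loop on all 256x256 input pairs."""
    table = DEFAULT_SINGLETONS[70]
    vecs = [fuzzify(x) for x in range(256)]
    bf_mu = {lab: [_bf_mu(x, *_BF_TRIS[lab]) for x in range(256)]
             for lab in _BF_LABELS}
    cells = [(bf_mu[de_lab], bf_mu[e_lab],
              getattr(table, _BF_GRID[(de_lab, e_lab)]))
             for de_lab in _BF_LABELS for e_lab in _BF_LABELS]
    for e_scaled in range(256):
        e = vecs[e_scaled]
        for de_scaled in range(256):
            res = defuzzify(infer_rules(e, vecs[de_scaled]), table)
            num = den = 0
            for de_col, e_col, c in cells:
                s = min(de_col[de_scaled], e_col[e_scaled])
                num += s * c
                den += s
            assert res.defuzzy == num // den, (e_scaled, de_scaled)


def test_default_tables_match_design_constants():
    """Guard against accidental drift of the shipped controller constants."""
    assert DEFAULT_MEMBERSHIPS == (
        TriangleParams(0, 0, 63), TriangleParams(0, 63, 127),
        TriangleParams(63, 127, 191), TriangleParams(127, 191, 255),
        TriangleParams(191, 255, 255))
    assert DEFAULT_SINGLETONS[70].as_tuple() == (15, 20, 38, 42, 45)
    assert DEFAULT_SINGLETONS[40].as_tuple() == (10, 14, 22, 24, 30)
    assert DEFAULT_SINGLETONS[30].as_tuple() == (10, 12, 16, 18, 26)
    assert len(RULE_OUTPUT) == 25
    assert RULE_OUTPUT.count("vs") == 6 and RULE_OUTPUT.count("vb") == 6
    assert default_flc_config().pulse_multiplier == 10
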