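"""Integer Takagi-Sugeno fuzzy controller datapath.

This module mirrors, bit for bit, the arithmetic of a fixed-point fuzzy
logic controller as it would be synthesized in digital logic: crisp errors
in degrees are clamped to the +/-20 deg fuzzy domain, mapped onto an 8-bit
scale, fuzzified through five triangular membership functions whose degrees
are themselves 8-bit integers (255 == full membership), pushed through a
25-rule min-inference grid, and defuzzified as a floored weighted average of
singleton positions (zero-order Sugeno / centre-of-gravity with singleton
consequents).  All divisions are floor divisions applied once at the end of
each rational expression; this is what makes the pipeline reproduce the
register-level worked examples exactly.

A parallel real-valued pipeline (:func:`flc_step_float`) computes the same
controller in continuous arithmetic on the degree domain.  It plays the role
of the original floating-point control model and is used as the
quantization oracle: the integer output never deviates from it by more than
a couple of defuzzy units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Sequence, Tuple

__all__ = [
    "TriangleParams",
    "MembershipVector",
    "SingletonTable",
    "FlcConfig",
    "DefuzzyResult",
    "FuzzyConfigError",
    "ZeroFiringError",
    "IN_LABELS",
    "OUT_LABELS",
    "RULE_OUTPUT",
    "DEFAULT_MEMBERSHIPS",
    "DEFAULT_SINGLETONS",
    "default_flc_config",
    "scale_to_digital",
    "triangular_membership",
    "fuzzify",
    "infer_rules",
    "defuzzify",
    "flc_step",
    "flc_step_float",
    "reset_defuzzy",
]


class FuzzyConfigError(ValueError):
    """Raised for an unknown reference angle or malformed controller config."""


class ZeroFiringError(ArithmeticError):
    """No rule fired (all strengths zero): invalid membership configuration."""


#: Linguistic labels of the five input sets, in scale order.
IN_LABELS: Tuple[str, ...] = ("nb", "ns", "ze", "ps", "pb")

#: Linguistic labels of the five output singletons, in magnitude order.
OUT_LABELS: Tuple[str, ...] = ("vs", "sm", "me", "bg", "vb")

#: 25-rule consequent grid, row-major over (change-in-error row, error column),
#: rows and columns both ordered NB, NS, ZE, PS, PB.  Rule i (1-based) is
#: RULE_OUTPUT[i-1].  This grid is a fixed design constant, not user data.
RULE_OUTPUT: Tuple[str, ...] = (
    "vs", "vs", "vs", "sm", "me",   # dE = NB
    "vs", "vs", "sm", "me", "bg",   # dE = NS
    "vs", "sm", "me", "bg", "vb",   # dE = ZE
    "sm", "me", "bg", "vb", "vb",   # dE = PS
    "me", "bg", "vb", "vb", "vb",   # dE = PB
)


class TriangleParams(NamedTuple):
    """Breakpoints of a triangular membership function on the 0-255 scale.

    Shoulders are encoded by collapsing a breakpoint: ``a == b`` is a left
    shoulder (full membership at the bottom of the scale), ``b == c`` a right
    shoulder.
    """

    a: int
    b: int
    c: int


class MembershipVector(NamedTuple):
    """8-bit membership degrees of one crisp input in the five fuzzy sets."""

    nb: int
    ns: int
    ze: int
    ps: int
    pb: int


#: Digital breakpoints of the five input sets.  NB and PB are shoulders so
#: that fully clamped inputs (scale 0 / 255) carry full membership.
DEFAULT_MEMBERSHIPS: Tuple[TriangleParams, ...] = (
    TriangleParams(0, 0, 63),       # NB
    TriangleParams(0, 63, 127),     # NS
    TriangleParams(63, 127, 191),   # ZE
    TriangleParams(127, 191, 255),  # PS
    TriangleParams(191, 255, 255),  # PB
)


@dataclass(frozen=True)
class SingletonTable:
    """Output singleton positions (defuzzy units) for one reference angle."""

    vs: int
    sm: int
    me: int
    bg: int
    vb: int
    reference_angle: int

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v1 > v2 for v1, v2 in zip(vals, vals[1:])):
            raise FuzzyConfigError(
                f"singletons must be non-decreasing, got {vals}")
        if not all(10 <= v <= 50 for v in vals):
            raise FuzzyConfigError(
                f"singletons must lie in [10, 50], got {vals}")

    def as_tuple(self) -> Tuple[int, int, int, int, int]:
        return (self.vs, self.sm, self.me, self.bg, self.vb)

    def __getitem__(self, label: str) -> int:
        return getattr(self, label)


#: Tuned singleton tables per reference angle (defuzzy units).
DEFAULT_SINGLETONS: Dict[int, SingletonTable] = {
    70: SingletonTable(15, 20, 38, 42, 45, reference_angle=70),
    40: SingletonTable(10, 14, 22, 24, 30, reference_angle=40),
    30: SingletonTable(10, 12, 16, 18, 26, reference_angle=30),
}


@dataclass(frozen=True)
class FlcConfig:
    """Complete parameterization of the fuzzy controller datapath."""

    memberships: Tuple[TriangleParams, ...] = DEFAULT_MEMBERSHIPS
    rules: Tuple[str, ...] = RULE_OUTPUT
    singletons: Mapping[int, SingletonTable] = field(
        default_factory=lambda: dict(DEFAULT_SINGLETONS))
    pulse_multiplier: int = 10
    clamp_deg: int = 20

    def __post_init__(self) -> None:
        if len(self.memberships) != 5:
            raise FuzzyConfigError("exactly five input membership sets required")
        if len(self.rules) != 25 or any(r not in OUT_LABELS for r in self.rules):
            raise FuzzyConfigError("rule map must hold 25 output labels")
        if self.pulse_multiplier <= 0:
            raise FuzzyConfigError("pulse multiplier must be positive")

    def singleton_table(self, ref: int) -> SingletonTable:
        try:
            return self.singletons[ref]
        except KeyError:
            raise FuzzyConfigError(
                f"no singleton table for reference angle {ref!r}; "
                f"known angles: {sorted(self.singletons)}") from None


def default_flc_config() -> FlcConfig:
    """The shipped controller constants (membership, rules, singletons)."""
    return FlcConfig()


@dataclass(frozen=True)
class DefuzzyResult:
    """Crisp controller output: defuzzy value, pulse width and fired rules."""

    defuzzy: int
    pulse: int
    fired_rules: Tuple[Tuple[int, int], ...]  # (1-based rule index, strength)


# ---------------------------------------------------------------------------
# scaling and fuzzification
# ---------------------------------------------------------------------------

def scale_to_digital(x: int, clamp: int = 20) -> int:
    """Clamp a crisp error (degrees) to ``+/-clamp`` and map it to 0-255.

    The mapping is ``floor(((x + clamp) * 255) / (2 * clamp))``; with the
    default clamp the anchors are -20 -> 0, 0 -> 127, 20 -> 255.
    """
    if x < -clamp:
        x = -clamp
    elif x > clamp:
        x = clamp
    return ((x + clamp) * 255) // (2 * clamp)


def triangular_membership(x: int, t: TriangleParams) -> int:
    """8-bit triangular membership degree of scale value ``x`` in set ``t``.

    255 at the peak ``x == b``; the rising edge is
    ``floor(255 * (x - a) / (b - a))`` and the falling edge
    ``floor(255 * (c - x) / (c - b))``, each floored once at the end.
    Collapsed breakpoints encode shoulders; a fully degenerate triangle
    (a == b == c) is 255 at its single point and 0 elsewhere.
    """
    a, b, c = t
    if not a <= b <= c:
        raise FuzzyConfigError(f"breakpoints must satisfy a <= b <= c, got {t}")
    if x == b:
        return 255
    if x <= a or x >= c:
        return 0
    if x < b:
        return (255 * (x - a)) // (b - a)
    return (255 * (c - x)) // (c - b)


def fuzzify(x: int, mfs: Sequence[TriangleParams] = DEFAULT_MEMBERSHIPS,
            ) -> MembershipVector:
    """Membership degrees of one scaled input in all five fuzzy sets."""
    return MembershipVector(*(triangular_membership(x, t) for t in mfs))


# ---------------------------------------------------------------------------
# inference and defuzzification
# ---------------------------------------------------------------------------

def infer_rules(e: MembershipVector, de: MembershipVector,
                rules: Sequence[str] = RULE_OUTPUT) -> Tuple[int, ...]:
    """Min-inference strengths of the 25 rules (AND of the two antecedents).

    Rule ``5*row + col + 1`` pairs change-in-error set ``row`` with error set
    ``col`` (both in NB..PB order); ``rules`` only names the consequents and
    is accepted here so callers can carry one rule map around.
    """
    del rules  # consequents are applied in defuzzify
    return tuple(
        de_val if de_val <= e_val else e_val
        for de_val in de
        for e_val in e
    )


def defuzzify(strengths: Sequence[int], table: SingletonTable,
              rules: Sequence[str] = RULE_OUTPUT,
              pulse_multiplier: int = 10) -> DefuzzyResult:
    """Floored weighted average of singleton positions over the 25 rules.

    ``defuzzy = floor(sum(strength_i * c_i) / sum(strength_i))`` where c_i is
    the singleton assigned to rule i by the consequent grid.
    """
    if len(strengths) != 25:
        raise FuzzyConfigError("exactly 25 rule strengths required")
    num = 0
    den = 0
    fired: List[Tuple[int, int]] = []
    for i, (s, label) in enumerate(zip(strengths, rules), start=1):
        if s:
            num += s * table[label]
            den += s
            fired.append((i, s))
    if den == 0:
        raise ZeroFiringError(
            "all rule strengths are zero; the membership configuration does "
            "not cover this input")
    defuzzy = num // den
    return DefuzzyResult(defuzzy=defuzzy, pulse=defuzzy * pulse_multiplier,
                         fired_rules=tuple(fired))


# ---------------------------------------------------------------------------
# one controller step
# ---------------------------------------------------------------------------

def flc_step(ref: int, act: int, prev_err: int,
             config: FlcConfig | None = None) -> Tuple[DefuzzyResult, int]:
    """One integer controller evaluation.

    Computes ``err = ref - act`` and ``derr = err - prev_err`` (both raw,
    un-clamped), scales and fuzzifies each, runs min-inference and
    defuzzification against the singleton table selected by ``ref``, and
    returns the result together with the new previous-error register value
    (the raw ``err``).  Clamping to the fuzzy domain happens only inside the
    scaler, never in the stored register — the register-level traces this
    models store the raw error.
    """
    config = config or default_flc_config()
    table = config.singleton_table(ref)
    err = ref - act
    derr = err - prev_err
    e = fuzzify(scale_to_digital(err, config.clamp_deg), config.memberships)
    de = fuzzify(scale_to_digital(derr, config.clamp_deg), config.memberships)
    strengths = infer_rules(e, de, config.rules)
    result = defuzzify(strengths, table, config.rules,
                       config.pulse_multiplier)
    return result, err


def reset_defuzzy(ref: int, config: FlcConfig | None = None) -> DefuzzyResult:
    """Power-on output: error and change-in-error registers both zero.

    With zeroed registers only the (ZE, ZE) rule fires at full strength, so
    the first registered defuzzy output equals the ME singleton of the
    selected table.
    """
    config = config or default_flc_config()
    table = config.singleton_table(ref)
    e = fuzzify(scale_to_digital(0, config.clamp_deg), config.memberships)
    strengths = infer_rules(e, e, config.rules)
    return defuzzify(strengths, table, config.rules, config.pulse_multiplier)


# ---------------------------------------------------------------------------
# real-valued reference pipeline
# ---------------------------------------------------------------------------

def _triangle_float(x: float, a: float, b: float, c: float) -> float:
    if x == b:
        return 1.0
    if x <= a or x >= c:
        return 0.0
    if x < b:
        return (x - a) / (b - a)
    return (c - x) / (c - b)


def _fuzzify_float(x: float, clamp: float) -> Tuple[float, ...]:
    # Same five sets as the digital pipeline, expressed on the degree domain:
    # NB/PB shoulders at the clamp bounds, half-clamp spacing.
    h = clamp / 2.0
    if x < -clamp:
        x = -clamp
    elif x > clamp:
        x = clamp
    tris = ((-clamp, -clamp, -h), (-clamp, -h, 0.0), (-h, 0.0, h),
            (0.0, h, clamp), (h, clamp, clamp))
    return tuple(_triangle_float(x, *t) for t in tris)


def flc_step_float(ref: float, act: float, prev_err: float,
                   config: FlcConfig | None = None) -> Tuple[float, float]:
    """One controller evaluation in real arithmetic (the modelling oracle).

    Identical structure to :func:`flc_step` — same clamp, same sets, same
    rule grid, same singleton tables — but memberships are real numbers in
    [0, 1] and the weighted average is not floored.  Returns the real-valued
    defuzzy output and the new previous-error register (the raw error).
    """
    config = config or default_flc_config()
    table = config.singleton_table(int(ref))
    err = ref - act
    derr = err - prev_err
    e = _fuzzify_float(err, config.clamp_deg)
    de = _fuzzify_float(derr, config.clamp_deg)
    num = 0.0
    den = 0.0
    idx = 0
    for de_val in de:
        for e_val in e:
            s = de_val if de_val <= e_val else e_val
            if s:
                num += s * table[config.rules[idx]]
                den += s
            idx += 1
    if den == 0.0:
        raise ZeroFiringError("all rule strengths are zero")
    return num / den, err
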