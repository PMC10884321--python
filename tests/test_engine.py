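"""Scoring engine: worked examples, invariants, and a brute-force oracle."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from caindex import (
    ATTRIBUTE_KINDS,
    AttributeKind,
    ComponentSet,
    DeviationMode,
    DeviationRule,
    ObservationFrequency,
    SpeciesProfile,
    StructureCount,
    StructureState,
    WeightScheme,
    cai,
    component_deviation,
    count_penalty,
    frequency,
    group_gcai,
    paf,
    variant_frequency_penalty,
)

# ---------------------------------------------------------------------------
# elementary operations: worked examples
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r_v, n, expected",
    [(16, 16, 1.0), (12, 16, 0.75), (0, 16, 0.0)],
)
def test_relative_frequency(r_v, n, expected):
    assert frequency(ObservationFrequency(r_v, n)) == expected


def test_relative_frequency_undefined_for_zero_n():
    with pytest.raises(ZeroDivisionError):
        frequency(ObservationFrequency(0, 0))


@pytest.mark.parametrize(
    "kc, ko, expected",
    [
        (1, 3, 0.5),        # one origin structure vs three: 1 - 1/4*2
        (4, 4, 1.0),
        (4, 6.5, 0.375),    # range midpoint: 1 - 1/4*2.5
        (1, 6, 0.0),        # floored at zero
        (4, 0, 0.0),        # absent structure credits nothing
        (0, 0, 1.0),
    ],
)
def test_count_penalty(kc, ko, expected):
    assert count_penalty(kc, ko) == pytest.approx(expected, abs=1e-12)


def test_count_penalty_rejects_negative():
    with pytest.raises(ValueError):
        count_penalty(-1, 2)


@pytest.mark.parametrize(
    "f, expected",
    [(Fraction(1, 4), Fraction(13, 16)), (0.0, 1.0), (Fraction(1, 16), Fraction(61, 64))],
)
def test_variant_frequency_penalty(f, expected):
    assert variant_frequency_penalty(float(f)) == pytest.approx(float(expected), abs=1e-15)


def test_variant_frequency_penalty_rejects_out_of_range():
    with pytest.raises(ValueError):
        variant_frequency_penalty(1.5)


@pytest.mark.parametrize(
    "control, other, expected",
    [
        (["palmar aponeurosis"], ["palmar aponeurosis"], 0.0),
        # two added components: a quarter unit each
        (["palmar aponeurosis"], ["palmar aponeurosis", "annular ligament", "pisiform"], 0.5),
        # no shared component: a completely different state scores the cap
        (["trapezium", "trapezium-metacarpal capsule"], ["a", "b", "c", "d"], 1.0),
        (["anterior side of metacarpal i", "base of mcp joint"], ["lateral side of metacarpal i"], 1.0),
    ],
)
def test_component_deviation(control, other, expected):
    got = component_deviation(ComponentSet(control), ComponentSet(other))
    assert got == pytest.approx(expected, abs=1e-12)


def test_component_deviation_missing_only_mode():
    rule = DeviationRule(mode=DeviationMode.MISSING_ONLY)
    c = ComponentSet(["a", "b", "c"])
    o = ComponentSet(["a", "b", "x", "y"])  # one missing, two added
    assert component_deviation(c, o, rule) == 0.25
    assert component_deviation(c, o) == 0.75  # symmetric difference counts both


def test_paf_weighted_average():
    w = WeightScheme()
    zero = {k: 0.0 for k in ATTRIBUTE_KINDS}
    assert paf(zero, w) == 1.0
    devs = dict(zero)
    devs[AttributeKind.COUNT] = 0.25
    assert paf(devs, w) == pytest.approx(8.75 / 9)
    assert paf({k: 1.0 for k in ATTRIBUTE_KINDS}, w) == 0.0
    with pytest.raises(ValueError):
        paf({AttributeKind.COUNT: 0.0}, w)


# ---------------------------------------------------------------------------
# random profile pairs for property tests
# ---------------------------------------------------------------------------

_LABELS = [f"component {i}" for i in range(8)]


@st.composite
def state_pairs(draw):
    """A (control, other) pair of states for the same structure."""
    def one(arches_default=None, absent_ok=False):
        comps = lambda: ComponentSet(draw(st.sets(st.sampled_from(_LABELS), min_size=1, max_size=4)))
        count = draw(st.integers(min_value=0 if absent_ok else 1, max_value=8))
        if count == 0:
            return StructureState(
                structure_name="s", group="central",
                innervation=ComponentSet(), origin=ComponentSet(),
                insertion=ComponentSet(), supply=ComponentSet(),
                palmar_arches=arches_default or draw(st.sampled_from([1, 2])),
                count=StructureCount.point(0),
                frequency=ObservationFrequency(1, 1),
            )
        return StructureState(
            structure_name="s", group="central",
            innervation=comps(), origin=comps(), insertion=comps(), supply=comps(),
            palmar_arches=arches_default or draw(st.sampled_from([1, 2])),
            count=StructureCount.point(count),
            frequency=ObservationFrequency(1, 1),
            variant_frequency=draw(
                st.one_of(st.none(), st.floats(min_value=0, max_value=1, allow_nan=False))
            ),
        )

    control = one()
    other = one(absent_ok=True)
    return control, other


def _profile(name, state):
    return SpeciesProfile.from_states(name, [state])


KEY = ("central", "s")


@given(state_pairs())
@settings(max_examples=150, derandomize=True, deadline=None)
def test_cai_bounds_and_identity(pair):
    control, other = pair
    res = cai(_profile("c", control), _profile("o", other), KEY)
    assert 0 <= res.cai <= 1
    assert res.cai == pytest.approx(abs(res.paf_control - res.paf_other), abs=1e-12)
    self_res = cai(_profile("c", control), _profile("c2", control), KEY)
    assert self_res.cai == 0.0
    gr = group_gcai(_profile("c", control), _profile("c2", control), "central")
    assert gr.gcai_mean == 0.0 and gr.gcai_formula == 0.0


@given(state_pairs(), st.floats(min_value=0.1, max_value=50))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_weight_scaling_invariance(pair, scale):
    control, other = pair
    w1 = WeightScheme()
    w2 = WeightScheme({k: scale * v for k, v in w1.weights.items()})
    r1 = cai(_profile("c", control), _profile("o", other), KEY, weights=w1)
    r2 = cai(_profile("c", control), _profile("o", other), KEY, weights=w2)
    assert r1.cai == pytest.approx(r2.cai, abs=1e-12)


@given(
    st.sets(st.sampled_from(_LABELS[:4]), min_size=1, max_size=4),
    st.sets(st.sampled_from(_LABELS[:6]), min_size=1, max_size=6),
    st.integers(min_value=0, max_value=3),
)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_monotonicity_in_differing_components(c_set, o_set, extra):
    """Adding differing components never decreases the deviation (until the cap)."""
    control = ComponentSet(c_set)
    other = ComponentSet(o_set)
    grown = ComponentSet(sorted(other) + [f"novel {i}" for i in range(extra)])
    assert component_deviation(control, grown) >= component_deviation(control, other) - 1e-12


# ---------------------------------------------------------------------------
# brute-force oracle: an independent recomputation from first principles
# ---------------------------------------------------------------------------


def _oracle_cai(control: StructureState, other: StructureState) -> Fraction:
    """Enumerate deviations directly with exact Fraction arithmetic."""
    W = {"inn": 3, "ori": 2, "ins": 2, "vas": 1, "cnt": 1}
    if other.count.effective == 0 and control.count.effective > 0:
        return Fraction(1)
    if control.count.effective == 0 and other.count.effective == 0:
        return Fraction(0)

    def set_dev(a, b):
        if set(a) == set(b):
            return Fraction(0)
        if not (set(a) & set(b)):
            return Fraction(1)
        n_diff = sum(1 for x in set(a) ^ set(b))
        return min(Fraction(1), Fraction(n_diff, 4))

    f_eff = abs((other.variant_frequency or 0.0) - (control.variant_frequency or 0.0))
    if f_eff > 0:
        # credited frequency 1 - 3/4 f, carried at 3-decimal working precision
        from decimal import Decimal, ROUND_HALF_UP

        credited = Fraction(
            str(Decimal(repr(1 - 0.75 * f_eff)).quantize(
                Decimal("0.001"), rounding=ROUND_HALF_UP))
        )
        var_dev = 1 - credited
        d_inn = var_dev
        d_ori = var_dev
        d_cnt = var_dev
    else:
        d_inn = set_dev(control.innervation, other.innervation)
        d_ori = set_dev(control.origin, other.origin)
        diff = abs(
            Fraction(control.count.low + control.count.high, 2)
            - Fraction(other.count.low + other.count.high, 2)
        )
        d_cnt = 1 - max(Fraction(0), 1 - Fraction(1, 4) * diff)
    d_ins = set_dev(control.insertion, other.insertion)
    d_vas = Fraction(0) if control.palmar_arches == other.palmar_arches else Fraction(1, 2)
    total = (
        W["inn"] * d_inn + W["ori"] * d_ori + W["ins"] * d_ins
        + W["vas"] * d_vas + W["cnt"] * d_cnt
    )
    return total / Fraction(sum(W.values()))


@given(state_pairs())
@settings(max_examples=200, derandomize=True, deadline=None)
def test_cai_matches_brute_force_oracle(pair):
    control, other = pair
    res = cai(_profile("c", control), _profile("o", other), KEY)
    assert res.cai == pytest.approx(float(_oracle_cai(control, other)), abs=1e-9)


def test_cai_errors_when_structure_missing():
    c, o = ("central", "s"), None
    st1 = SpeciesProfile.from_states("c", [])
    with pytest.raises(KeyError):
        cai(st1, st1, c)
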