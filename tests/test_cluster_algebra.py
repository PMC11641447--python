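"""Operator algebra: branching coefficients, marginals and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterdamage import (
    ClusterGeometry,
    EventProbabilities,
    LesionSpectrum,
    LesionState,
    ParameterError,
    RadicalFates,
    apply_A_step,
    apply_B_step,
    apply_C_step,
    damage_probabilities,
    dsb_bd_colocation,
    resolve_composition,
)
from clusterdamage.cluster_algebra import (
    EMPTY_STATE,
    PRINTED_Q0_TABLE,
    lesion_spectrum,
    marginals,
)

Q0, Q1 = 0.6, 0.2  # constant-q0 symbolic values used throughout

S = LesionState  # brevity in expected-state tables


class TestClusterGeometry:
    def test_printed_ladder_conservation(self, geometry):
        for j in PRINTED_Q0_TABLE:
            assert geometry.q0(j) + 2 * geometry.q1(j) == pytest.approx(1.0)

    def test_first_break_always_isolated(self, geometry):
        assert geometry.q0(1) == 1.0

    def test_ladder_non_increasing_and_extrapolates_to_zero(self, geometry):
        values = [geometry.q0(k) for k in range(2, 12)]
        assert all(b <= a for a, b in zip(values, values[1:]))
        assert geometry.q0(8) == 0.0  # linear extrapolation clipped

    def test_increasing_table_rejected(self):
        with pytest.raises(ParameterError):
            ClusterGeometry(q0_table={2: 0.5, 3: 0.9})


class TestRadicalFates:
    def test_printed_values_from_interaction_split(self):
        f = RadicalFates.from_interaction_split()
        assert f.r1 == pytest.approx(0.13)
        assert f.r2 == pytest.approx(0.52)
        assert f.r3 == pytest.approx(0.35)

    def test_sum_constraint_enforced(self):
        with pytest.raises(ParameterError):
            RadicalFates(0.5, 0.5, 0.5)


class TestOperatorSteps:
    def test_a_on_single_ssb_three_branches(self, constant_geometry):
        spec = LesionSpectrum({S(ssb_iso=1): 1.0})
        out = apply_A_step(spec, constant_geometry, k=2)
        assert out[S(ssb_iso=2)] == pytest.approx(Q0)
        assert out[S(dsb_s=1)] == pytest.approx(Q1)
        assert out[S(ssb_plus=1)] == pytest.approx(Q1)

    def test_a_on_simple_dsb(self, constant_geometry):
        out = apply_A_step(LesionSpectrum({S(dsb_s=1): 1.0}),
                           constant_geometry, k=3)
        assert out[S(dsb_s=1, ssb_iso=1)] == pytest.approx(Q0)
        assert out[S(dsb_plus=1)] == pytest.approx(2 * Q1)

    def test_a_on_complex_ssb(self, constant_geometry):
        out = apply_A_step(LesionSpectrum({S(ssb_plus=1): 1.0}),
                           constant_geometry, k=3)
        assert out[S(ssb_plus=1, ssb_iso=1)] == pytest.approx(Q0)
        assert out[S(ssb_pp=1)] == pytest.approx(Q1)
        assert out[S(dsb_plus=1)] == pytest.approx(Q1)

    def test_a_attachment_splits_equally_over_lesions(self, constant_geometry):
        # mixed operand SSB(+) x SSB(S): four attachment branches at q1/2
        out = apply_A_step(
            LesionSpectrum({S(ssb_plus=1, ssb_iso=1): 1.0}),
            constant_geometry, k=4,
        )
        assert out[S(ssb_plus=1, ssb_iso=2)] == pytest.approx(Q0)
        assert out[S(ssb_pp=1, ssb_iso=1)] == pytest.approx(Q1 / 2)
        assert out[S(dsb_plus=1, ssb_iso=1)] == pytest.approx(Q1 / 2)
        assert out[S(ssb_plus=1, dsb_s=1)] == pytest.approx(Q1 / 2)
        assert out[S(ssb_plus=2)] == pytest.approx(Q1 / 2)

    def test_a_on_empty_state_always_isolated(self):
        geom = ClusterGeometry.constant(1.0)
        out = apply_A_step(LesionSpectrum({EMPTY_STATE: 1.0}), geom, k=1)
        assert out[S(ssb_iso=1)] == pytest.approx(1.0)

    def test_b_first_order(self, constant_geometry, fates):
        out = apply_B_step(LesionSpectrum({EMPTY_STATE: 1.0}),
                           constant_geometry, fates, k=1)
        assert out[S(ssb_iso=1)] == pytest.approx(fates.r1)
        assert out[S(bd=1)] == pytest.approx(fates.r2)
        assert out[EMPTY_STATE] == pytest.approx(fates.r3)

    def test_b_degenerate_fates_never_break(self, constant_geometry):
        f = RadicalFates(r1=0.0, r2=0.6, r3=0.4)
        spec = LesionSpectrum({EMPTY_STATE: 1.0})
        for k in range(1, 4):
            spec = apply_B_step(spec, constant_geometry, f, k=k)
        assert all(s.min_breaks == 0 for s in spec)

    def test_c_step_increments_bd(self):
        spec = LesionSpectrum({EMPTY_STATE: 1.0})
        out = apply_C_step(apply_C_step(spec))
        assert out[S(bd=2)] == pytest.approx(1.0)


class TestResolveComposition:
    def test_second_order_A(self, constant_geometry, fates):
        out = resolve_composition((2, 0, 0, 0), constant_geometry, fates)
        assert out[S(ssb_iso=2)] == pytest.approx(Q0)
        assert out[S(dsb_s=1)] == pytest.approx(Q1)
        assert out[S(ssb_plus=1)] == pytest.approx(Q1)

    def test_third_order_A_five_branches(self, constant_geometry, fates):
        out = resolve_composition((3, 0, 0, 0), constant_geometry, fates)
        expected = {
            S(ssb_iso=3): Q0**2,
            S(ssb_iso=1, dsb_s=1): 2 * Q0 * Q1,
            S(ssb_iso=1, ssb_plus=1): 2 * Q0 * Q1,
            S(dsb_plus=1): 3 * Q1**2,
            S(ssb_pp=1): Q1**2,
        }
        assert len(out) == 5
        for state, value in expected.items():
            assert out[state] == pytest.approx(value)

    def test_fourth_order_A_full_tier_structure(self, constant_geometry, fates):
        out = resolve_composition((4, 0, 0, 0), constant_geometry, fates)
        expected = {
            S(ssb_iso=4): Q0**3,
            S(ssb_iso=2, dsb_s=1): 3 * Q0**2 * Q1,
            S(ssb_iso=2, ssb_plus=1): 3 * Q0**2 * Q1,
            S(ssb_iso=1, dsb_plus=1): 6 * Q0 * Q1**2,
            S(ssb_iso=1, ssb_pp=1): 2 * Q0 * Q1**2,
            S(ssb_plus=1, dsb_s=1): 2 * Q0 * Q1**2,
            S(dsb_s=2): Q0 * Q1**2,
            S(ssb_plus=2): Q0 * Q1**2,
            S(dsb_pp=1): 7 * Q1**3,
            S(ssb_ppp=1): Q1**3,
        }
        for state, value in expected.items():
            assert out[state] == pytest.approx(value)

    def test_second_order_B_branches(self, constant_geometry, fates):
        r1, r2, r3 = fates.r1, fates.r2, fates.r3
        out = resolve_composition((0, 2, 0, 0), constant_geometry, fates)
        expected = {
            S(ssb_iso=2): r1**2 * Q0,
            S(dsb_s=1): r1**2 * Q1,
            S(ssb_plus=1): r1**2 * Q1,
            S(ssb_iso=1, bd=1): 2 * r1 * r2,
            S(bd=2): r2**2,
            S(ssb_iso=1): 2 * r1 * r3,
            S(bd=1): 2 * r2 * r3,
            EMPTY_STATE: r3**2,
        }
        for state, value in expected.items():
            assert out[state] == pytest.approx(value)

    def test_d_events_inert(self, geometry, fates):
        for j_d in (1, 5, 12):
            out = resolve_composition((0, 0, 0, j_d), geometry, fates)
            assert out[EMPTY_STATE] == pytest.approx(1.0)

    def test_c_events_shift_bd(self, geometry, fates):
        out = resolve_composition((0, 0, 3, 0), geometry, fates)
        assert out[S(bd=3)] == pytest.approx(1.0)

    def test_heterogeneous_order_via_operator_chain(self, geometry, fates):
        # applying A then B then C step-by-step matches the direct resolution
        chain = LesionSpectrum({EMPTY_STATE: 1.0})
        chain = apply_A_step(chain, geometry)
        chain = apply_B_step(chain, geometry, fates)
        chain = apply_C_step(chain)
        direct = resolve_composition((1, 1, 1, 0), geometry, fates)
        assert chain.total_variation(direct) < 1e-12

    @given(
        j_a=st.integers(0, 4),
        j_b=st.integers(0, 4),
        j_c=st.integers(0, 2),
        q0=st.floats(0.0, 1.0),
        raw=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        mode=st.sampled_from(["exact", "paper_approx"]),
    )
    @settings(max_examples=120, deadline=None)
    def test_every_resolved_spectrum_is_normalized(self, j_a, j_b, j_c, q0,
                                                   raw, mode):
        geom = ClusterGeometry.constant(q0)
        total = sum(raw)
        f = RadicalFates(*(x / total for x in raw))
        out = resolve_composition((j_a, j_b, j_c, 0), geom, f, mode=mode)
        assert out.total() == pytest.approx(1.0, abs=1e-10)

    def test_break_count_conserved_in_pure_A(self, geometry, fates):
        for j in range(1, 7):
            out = resolve_composition((j, 0, 0, 0), geometry, fates)
            assert all(s.min_breaks <= j for s in out)
            # without the grouped >=4 classes the bound is tight
            for s in out:
                if s.ssb_ppp == 0 and s.dsb_pp == 0:
                    assert s.min_breaks == j


class TestModes:
    def test_modes_agree_at_low_order(self, geometry, fates, events):
        for j in range(5):
            exact = lesion_spectrum(j, events, geometry, fates, "exact")
            approx = lesion_spectrum(j, events, geometry, fates, "paper_approx")
            assert exact.total_variation(approx) < 0.01

    def test_bad_mode_rejected(self, geometry, fates):
        with pytest.raises(ParameterError):
            resolve_composition((1, 0, 0, 0), geometry, fates, mode="bogus")

    def test_high_order_approx_saturates_in_complex_dsb(self, geometry, fates):
        m = marginals(resolve_composition((12, 0, 0, 0), geometry, fates,
                                          mode="paper_approx"))
        assert m["p_dsb_pp"] > 0.9


class TestDamageProbabilities:
    def test_no_events_no_damage(self, geometry, fates, events):
        m = damage_probabilities(0, events, geometry, fates)
        for key in ("p_ssb_s1", "p_dsb_any", "p_bd_any", "e_ssb_breaks", "e_bd"):
            assert m[key] == 0.0

    def test_first_order_marginals(self, geometry, fates, events):
        m = damage_probabilities(1, events, geometry, fates)
        assert m["p_ssb_s1"] == pytest.approx(
            events.p_a + events.p_b * fates.r1)
        assert m["p_bd_1"] == pytest.approx(events.p_c + events.p_b * fates.r2)

    def test_expected_bd_is_linear(self, geometry, fates, events):
        # each event contributes p_c + p_b*r2 base damages on average
        for j in (1, 3, 7, 12):
            m = damage_probabilities(j, events, geometry, fates)
            assert m["e_bd"] == pytest.approx(
                j * (events.p_c + events.p_b * fates.r2), abs=1e-9)

    def test_complex_dsb_fraction_monotone(self, geometry, fates, events):
        fracs = [
            damage_probabilities(j, events, geometry, fates)["frac_complex_dsb"]
            for j in range(2, 16)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestColocation:
    def test_no_bd_channels_makes_variants_coincide(self, geometry):
        f = RadicalFates(r1=0.13, r2=0.0, r3=0.87)
        p = EventProbabilities(0.25, 0.25, 0.0, 0.5)
        out = dsb_bd_colocation(6, p, geometry, f)
        assert out["p_dsb_no_bd"] == pytest.approx(out["p_dsb"], abs=1e-12)
        assert out["p_dsb_no_radical_bd"] == pytest.approx(out["p_dsb"], abs=1e-10)

    def test_r2_to_r3_swap_cannot_change_dsb(self, geometry, fates, events):
        # neither branch produces strand breaks, so folding r2 into r3
        # leaves every break marginal unchanged
        out = dsb_bd_colocation(8, events, geometry, fates)
        assert out["p_dsb_r2_to_r3"] == pytest.approx(out["p_dsb"], abs=1e-10)

    def test_dsb_without_bd_vanishes_at_high_multiplicity(
            self, geometry, fates, events):
        out = dsb_bd_colocation(12, events, geometry, fates)
        assert out["p_dsb_no_bd"] < 0.05 * out["p_dsb"]
        assert out["p_dsb_no_radical_bd"] < out["p_dsb"]
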