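import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stcmix import (
    Direction,
    LogisticCRC,
    MixtureComponent,
    MixtureDesign,
    ca_curve,
    ca_ecx,
    equitoxic_design,
    equitoxic_fractions,
    ia_curve,
    ia_ecx,
    ia_effect,
    ll4_effect,
    ll4_inverse,
    substitution_design,
)
from stcmix.exceptions import DesignError, MixedDirectionError, ParameterError


def std_crc(b, e, direction=Direction.HYPERACTIVITY):
    return LogisticCRC(slope_b=b, inflection_e=e, direction=direction)


def design_of(*triples, label=""):
    comps = tuple(
        MixtureComponent(name, frac, std_crc(b, e)) for name, frac, b, e in triples
    )
    return MixtureDesign(comps, label=label)


class TestEquitoxicFractions:
    @pytest.mark.parametrize(
        "ec50s, expected",
        [
            ((1.95, 0.44), (0.816, 0.184)),
            ((0.09, 46.0), (0.002, 0.998)),
        ],
    )
    def test_published_ratios(self, ec50s, expected):
        fracs = equitoxic_fractions(ec50s)
        assert fracs == pytest.approx(expected, abs=5e-4)

    def test_symmetry(self):
        assert equitoxic_fractions((3.0, 3.0, 3.0)) == pytest.approx([1 / 3] * 3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            equitoxic_fractions((1.0, 0.0))

    @given(st.lists(st.floats(0.01, 1000.0), min_size=2, max_size=6))
    def test_sum_to_one_and_proportional(self, ec50s):
        fracs = equitoxic_fractions(ec50s)
        assert fracs.sum() == pytest.approx(1.0)
        ratio = fracs / np.asarray(ec50s)
        assert ratio == pytest.approx(np.full(len(ec50s), ratio[0]))


class TestConcentrationAddition:
    def test_binary_equitoxic_prediction(self, hyper_pair_design):
        assert ca_ecx(50.0, hyper_pair_design) == pytest.approx(1.195, abs=1e-9)

    def test_single_component_collapses_to_its_ec50(self):
        d = MixtureDesign((MixtureComponent("a", 1.0, std_crc(1.3, 1.95)),))
        assert ca_ecx(50.0, d) == pytest.approx(1.95)

    def test_nontrivial_level_against_tabulated_inverse_oracle(self):
        """Eq-solving check: brute-force solve sum p_i * x / ECx_i = 1 on a
        dense tabulation of the component inverses."""
        d = design_of(("hex", 0.65, 1.8, 3.63), ("chl", 0.35, 1.3, 1.95))
        level = 30.0
        ec_hex = ll4_inverse(30.0, std_crc(1.8, 3.63))
        ec_chl = ll4_inverse(30.0, std_crc(1.3, 1.95))
        grid = np.linspace(1e-4, 10, 2_000_001)
        tu = 0.65 * grid / ec_hex + 0.35 * grid / ec_chl
        oracle = grid[np.argmin(np.abs(tu - 1.0))]
        assert ca_ecx(level, d) == pytest.approx(oracle, abs=1e-5)

    def test_equitoxic_closed_form_oracle(self, ternary_design):
        ec50s = [c.ec50 for c in ternary_design.components]
        assert ca_ecx(50.0, ternary_design) == pytest.approx(np.mean(ec50s), rel=1e-12)

    def test_ternary_prediction_matches_published_value(self, ternary_design):
        assert ca_ecx(50.0, ternary_design) == pytest.approx(2.0, abs=0.01)

    def test_curve_monotone_and_self_dilution_identity(self):
        a = std_crc(1.3, 1.95)
        d = MixtureDesign(
            (
                MixtureComponent("a1", 0.5, a),
                MixtureComponent("a2", 0.5, a),
            )
        )
        curve = ca_curve(d, np.arange(10.0, 95.0, 5.0))
        assert np.all(np.diff(curve.concentrations) > 0)
        # equitoxic mixture of identical components is the component itself
        single = ll4_inverse(curve.effects, a)
        assert curve.concentrations == pytest.approx(single, rel=1e-10)

    def test_mixed_directions_rejected(self, substances):
        d = equitoxic_design(
            [(n, substances[n].crc()) for n in ("chlorpyrifos", "abamectin")]
        )
        with pytest.raises(MixedDirectionError, match="antagonism"):
            ca_ecx(50.0, d)

    def test_unstandardized_curve_warns(self):
        raw = LogisticCRC(slope_b=1.7, inflection_e=2.0, ceiling_d=82.0)
        d = MixtureDesign(
            (
                MixtureComponent("raw", 0.5, raw),
                MixtureComponent("std", 0.5, std_crc(1.3, 1.95)),
            )
        )
        with pytest.warns(RuntimeWarning, match="standardize"):
            ca_ecx(50.0, d)


class TestIndependentAction:
    def test_zero_concentration_zero_effect(self, hyper_pair_design):
        assert ia_effect(0.0, hyper_pair_design) == pytest.approx(0.0)

    def test_single_component_collapses(self):
        crc = std_crc(1.3, 1.95)
        d = MixtureDesign((MixtureComponent("a", 1.0, crc),))
        for c in (0.5, 1.95, 7.0):
            assert ia_effect(c, d) == pytest.approx(ll4_effect(c, crc))

    def test_two_thirty_percent_components_combine_to_51(self):
        # each component at 30% fractional effect: 1 - 0.7^2 = 0.51
        crc = std_crc(1.0, 1.0)
        d = MixtureDesign(
            (MixtureComponent("a", 0.5, crc), MixtureComponent("b", 0.5, crc))
        )
        total = 2.0 * ll4_inverse(30.0, crc)  # each sees its 30% concentration
        assert ia_effect(total, d) == pytest.approx(51.0, rel=1e-12)

    def test_bounded_and_nondecreasing(self, ternary_design):
        grid = np.geomspace(1e-3, 1e3, 300)
        vals = np.array([ia_effect(c, ternary_design) for c in grid])
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] <= 100.0

    def test_ecx_agrees_with_brute_force_scan(self, ternary_design):
        grid = np.geomspace(1e-3, 1e3, 100_000)
        vals = ia_effect(grid, ternary_design)
        for level in (20.0, 50.0, 80.0):
            scan = grid[np.argmin(np.abs(vals - level))]
            assert ia_ecx(level, ternary_design) == pytest.approx(scan, rel=1e-3)

    def test_ternary_ec50_close_to_published(self, ternary_design):
        assert ia_ecx(50.0, ternary_design) == pytest.approx(2.19, rel=0.05)

    def test_curve_monotone(self, hyper_b_design):
        curve = ia_curve(hyper_b_design, np.arange(5.0, 100.0, 5.0))
        assert np.all(np.diff(curve.concentrations) > 0)

    def test_mixed_directions_rejected(self, substances):
        d = equitoxic_design(
            [(n, substances[n].crc()) for n in ("hexaconazole", "propafenone")]
        )
        with pytest.raises(MixedDirectionError):
            ia_ecx(50.0, d)


class TestPermutationInvariance:
    @given(perm=st.permutations([0, 1, 2]))
    def test_component_order_never_matters(self, perm, ternary_design):
        comps = ternary_design.components
        d2 = MixtureDesign(tuple(comps[i] for i in perm))
        assert ca_ecx(37.0, d2) == pytest.approx(ca_ecx(37.0, ternary_design), rel=1e-12)
        assert ia_ecx(37.0, d2) == pytest.approx(ia_ecx(37.0, ternary_design), rel=1e-9)


class TestSubstitution:
    def test_share_rule_reproduces_published_triple(self, hyper_pair_design, substances):
        """Replacing half of chlorpyrifos' toxic units with hexaconazole at
        fixed molar share reproduces the published substituted ratios
        0.184 : 0.286 : 0.53."""
        new = substitution_design(
            hyper_pair_design,
            "chlorpyrifos",
            ("hexaconazole", substances["hexaconazole"].crc()),
            portion=0.5,
        )
        fr = new.fractions_by_name()
        assert fr["chlorpyrifos-oxon"] == pytest.approx(0.184, abs=5e-4)
        assert fr["chlorpyrifos"] == pytest.approx(0.286, abs=1e-3)
        assert fr["hexaconazole"] == pytest.approx(0.53, abs=1e-3)

    def test_share_rule_reproduces_second_published_triple(self, hyper_b_design, substances):
        new = substitution_design(
            hyper_b_design,
            "chlorpyrifos",
            ("chlorpyrifos-oxon", substances["chlorpyrifos-oxon"].crc()),
            portion=0.5,
        )
        fr = new.fractions_by_name()
        assert fr["hexaconazole"] == pytest.approx(0.65, abs=1e-3)
        assert fr["chlorpyrifos"] == pytest.approx(0.286, abs=1e-3)
        assert fr["chlorpyrifos-oxon"] == pytest.approx(0.064, abs=1e-3)

    def test_full_replacement_with_identical_curve_is_noop(self, hyper_pair_design):
        crc = hyper_pair_design.component("chlorpyrifos").crc
        new = substitution_design(
            hyper_pair_design, "chlorpyrifos", ("chlorpyrifos", crc), portion=1.0
        )
        assert new.fractions_by_name() == pytest.approx(
            hyper_pair_design.fractions_by_name()
        )
        assert ca_ecx(50.0, new) == pytest.approx(ca_ecx(50.0, hyper_pair_design))

    def test_toxic_unit_mode_preserves_parent_scale_ca_ec50(
        self, hyper_pair_design, substances
    ):
        new = substitution_design(
            hyper_pair_design,
            "chlorpyrifos",
            ("hexaconazole", substances["hexaconazole"].crc()),
            portion=0.5,
            conserve="toxic_units",
        )
        assert sum(new.fractions_by_name().values()) == pytest.approx(1.0)
        assert ca_ecx(50.0, new) / new.parent_scale == pytest.approx(
            ca_ecx(50.0, hyper_pair_design), abs=1e-9
        )

    @given(
        portion=st.floats(0.05, 1.0),
        e_new=st.floats(0.05, 50.0),
        b_new=st.floats(0.3, 4.0),
    )
    def test_toxic_unit_identity_for_arbitrary_substitutes(
        self, portion, e_new, b_new, ternary_design
    ):
        new = substitution_design(
            ternary_design,
            "hexaconazole",
            ("x", std_crc(b_new, e_new)),
            portion=portion,
            conserve="toxic_units",
        )
        assert ca_ecx(50.0, new) / new.parent_scale == pytest.approx(
            ca_ecx(50.0, ternary_design), abs=1e-9
        )

    def test_unknown_component_rejected(self, hyper_pair_design):
        with pytest.raises(DesignError):
            substitution_design(
                hyper_pair_design, "nonesuch", ("x", std_crc(1.0, 1.0))
            )


class TestDesignValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(DesignError):
            design_of(("a", 0.5, 1.0, 1.0), ("b", 0.4, 1.0, 1.0))

    def test_duplicate_names_rejected(self):
        with pytest.raises(DesignError):
            design_of(("a", 0.5, 1.0, 1.0), ("a", 0.5, 1.0, 1.0))
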