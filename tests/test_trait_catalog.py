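"""Trait profiles: validation, flexible-trait evaluation, averaging,
ablation type sets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nobsim.trait_catalog import (
    FunctionalTypeSet,
    TraitValidationError,
    average_traits,
    build_type_set,
    default_type_set,
    evaluate_k_m_o2,
    evaluate_mu_max,
    load_trait_config,
    save_trait_config,
)

from .conftest import make_profile


class TestDefaultConfig:
    def test_reference_set_names(self, typeset):
        assert typeset.names == (
            "Nitrospira",
            "Nitrobacter_chemolitho",
            "Nitrobacter_mixo",
        )
        assert typeset.n_types == 3

    def test_only_mixotroph_oxidizes_oc(self, typeset):
        assert typeset["Nitrospira"].v_max_oc == 0
        assert typeset["Nitrobacter_chemolitho"].v_max_oc == 0
        assert typeset["Nitrobacter_mixo"].v_max_oc > 0

    def test_k_r_contrast(self, typeset):
        """Nitrospira is the low half-saturation, slow-growing K
        strategist; both Nitrobacter types have much higher K_m and
        specific activity."""
        spira = typeset["Nitrospira"]
        for other in ("Nitrobacter_chemolitho", "Nitrobacter_mixo"):
            assert typeset[other].k_m_no2 > 10 * spira.k_m_no2
        chemo = typeset["Nitrobacter_chemolitho"]
        assert chemo.mu_max > 2 * spira.mu_max
        assert chemo.v_max_no2 > 10 * spira.v_max_no2

    def test_round_trip(self, typeset, tmp_path):
        out = tmp_path / "traits.yaml"
        save_trait_config(typeset, out)
        again = load_trait_config(out)
        assert again.profiles == typeset.profiles


class TestValidation:
    def test_negative_half_saturation_rejected(self):
        with pytest.raises(TraitValidationError, match="k_m_no2"):
            make_profile(k_m_no2=-1.0)

    @pytest.mark.parametrize("y", [0.0, 1.5, -0.1])
    def test_yield_outside_unit_interval_rejected(self, y):
        with pytest.raises(TraitValidationError, match="growth_yield"):
            make_profile(growth_yield=y)

    def test_zero_mortality_rejected(self):
        with pytest.raises(TraitValidationError, match="mortality"):
            make_profile(mortality=0.0)

    def test_unordered_anchors_rejected(self):
        with pytest.raises(TraitValidationError, match="strictly increasing"):
            make_profile(
                strategy="r_mixotroph",
                v_max_oc=100.0,
                flexible_mu_max=((1e-3, 1e-5), (1e-4, 2e-5)),
            )

    def test_non_mixotroph_with_flexible_traits_rejected(self):
        with pytest.raises(TraitValidationError, match="non-mixotroph"):
            make_profile(flexible_mu_max=((0.0, 1e-5), (1e-3, 2e-5)))

    def test_config_error_names_offending_key(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            "profiles:\n- name: x\n  strategy: K_chemolithotroph\n"
        )
        with pytest.raises(Exception, match="missing key"):
            load_trait_config(bad)


class TestFlexibleTraits:
    """The mixotroph's published physiological anchors and their
    interpolation."""

    def test_mu_max_anchors(self, typeset):
        mixo = typeset["Nitrobacter_mixo"]
        assert evaluate_mu_max(mixo, 0.0) == pytest.approx(6.9e-6)
        assert evaluate_mu_max(mixo, 5e-3) == pytest.approx(27.8e-6)
        # constant extrapolation past the last anchor
        assert evaluate_mu_max(mixo, 1.0) == pytest.approx(27.8e-6)

    def test_mu_max_midpoint_interpolation(self, typeset):
        mixo = typeset["Nitrobacter_mixo"]
        assert evaluate_mu_max(mixo, 2.5e-3) == pytest.approx(1.735e-5)

    def test_k_m_o2_anchors(self, typeset):
        mixo = typeset["Nitrobacter_mixo"]
        assert evaluate_k_m_o2(mixo, 1e-4) == pytest.approx(25.1)
        assert evaluate_k_m_o2(mixo, 6.25e-3) == pytest.approx(125.0)
        assert evaluate_k_m_o2(mixo, 2e-2) == pytest.approx(125.0)

    def test_non_flexible_profile_returns_constant(self, typeset):
        spira = typeset["Nitrospira"]
        for o2 in (0.0, 1e-4, 1e-2):
            assert evaluate_k_m_o2(spira, o2) == spira.k_m_o2

    def test_negative_concentration_rejected(self, typeset):
        mixo = typeset["Nitrobacter_mixo"]
        with pytest.raises(ValueError):
            evaluate_mu_max(mixo, -1e-6)
        with pytest.raises(ValueError):
            evaluate_k_m_o2(mixo, -1e-6)

    @given(
        anchors=st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False),
                st.floats(1e-7, 1e-4, allow_nan=False),
            ),
            min_size=2,
            max_size=5,
            unique_by=lambda a: a[0],
        ),
        xs=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_when_anchors_monotone(self, anchors, xs):
        """Evaluation is nondecreasing in the environmental argument
        whenever the anchor values are nondecreasing in their abscissae."""
        anchors = sorted(anchors)
        ys = sorted(y for _, y in anchors)
        anchors = tuple((x, y) for (x, _), y in zip(anchors, ys))
        p = make_profile(
            strategy="r_mixotroph", v_max_oc=10.0, flexible_mu_max=anchors
        )
        values = [evaluate_mu_max(p, x) for x in sorted(xs)]
        assert all(b >= a - 1e-30 for a, b in zip(values, values[1:]))


class TestAveraging:
    def test_average_of_identical_profiles_is_identity(self, typeset):
        mixo = typeset["Nitrobacter_mixo"]
        avg = average_traits([mixo, mixo, mixo], name=mixo.name)
        for f in (
            "v_max_no2",
            "k_m_no2",
            "k_m_o2",
            "v_max_oc",
            "mu_max",
            "growth_yield",
            "mortality",
        ):
            assert getattr(avg, f) == pytest.approx(getattr(mixo, f))
        assert avg.flexible_mu_max == mixo.flexible_mu_max

    def test_scalar_mean(self):
        a = make_profile(name="a", k_m_no2=10.0)
        b = make_profile(name="b", k_m_no2=500.0)
        assert average_traits([a, b], "m").k_m_no2 == pytest.approx(255.0)

    def test_flexible_mean_contains_constant_contribution(self, typeset):
        """Averaging a flexible and a constant profile evaluates the
        constant one at every anchor abscissa."""
        chemo = typeset["Nitrobacter_chemolitho"]
        mixo = typeset["Nitrobacter_mixo"]
        avg = average_traits([chemo, mixo], "two")
        assert evaluate_mu_max(avg, 0.0) == pytest.approx(
            (chemo.mu_max + 6.9e-6) / 2
        )
        assert evaluate_mu_max(avg, 5e-3) == pytest.approx(
            (chemo.mu_max + 27.8e-6) / 2
        )

    def test_single_profile_rejected(self, typeset):
        with pytest.raises(ValueError):
            average_traits([typeset["Nitrospira"]], "solo")


class TestBuildTypeSet:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_counts(self, n):
        assert build_type_set(n).n_types == n

    def test_reference_prefix_shared_between_3_and_4(self):
        assert (
            build_type_set(4).profiles[:3] == build_type_set(3).profiles
        )

    def test_two_type_set_is_genus_level(self, typeset):
        two = build_type_set(2)
        assert two.names == ("Nitrospira", "Nitrobacter_avg")
        expected = average_traits(
            [typeset["Nitrobacter_chemolitho"], typeset["Nitrobacter_mixo"]],
            "Nitrobacter_avg",
        )
        assert two["Nitrobacter_avg"] == expected

    def test_one_type_set_is_mean_of_all_three(self, typeset):
        one = build_type_set(1)
        expected = average_traits(typeset.profiles, "NOB_avg")
        assert one.profiles[0] == expected

    def test_added_nitrospira_mixotroph_is_weakly_flexible(self):
        extra = build_type_set(4)["Nitrospira_mixo"]
        base = build_type_set(3)["Nitrospira"]
        high = evaluate_mu_max(extra, 5e-3)
        assert base.mu_max < high <= 1.5 * base.mu_max

    @pytest.mark.parametrize("n", [0, 5, -1])
    def test_invalid_counts_rejected(self, n):
        with pytest.raises(ValueError):
            build_type_set(n)
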