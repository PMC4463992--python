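import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_simple
from shellsim.similarity import (
    DEFAULT_LAYER_SCHEME,
    LayerProfile,
    LayerScheme,
    ParameterSimilarityVector,
    count_atoms,
    count_residue_types,
    count_residues,
    density_similarity,
    element_fraction,
    element_position_similarity,
    layer_profile,
    layer_weights,
    overall_similarity,
    parameter_vector,
    per_layer_similarity,
    rank_reference_proteins,
    scalar_similarity,
)
from shellsim.synthetic_data import (
    StructureSpec,
    make_structure,
    perturb_structure,
    place_marker,
    table1_weights,
    table4_fixture,
)

from _oracles import brute_force_layer_similarity, brute_force_layer_weights, brute_force_shell_counts


def profile_of(counts, scheme=DEFAULT_LAYER_SCHEME):
    return LayerProfile(counts=tuple(counts), scheme=scheme)


class TestLayerProfile:
    def test_small_radii_all_in_first_shell(self):
        p = layer_profile([1.0, 2.0, 3.0])
        assert p.counts == (3, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_boundary_radius_goes_to_outer_shell(self):
        # half-open [lo, hi): a radius exactly on a breakpoint belongs above it
        assert layer_profile([10.0]).counts[1] == 1
        assert layer_profile([100.0]).counts[9] == 1

    def test_matches_interval_membership_oracle(self, rng):
        radii = rng.uniform(0, 120, size=1000)
        p = layer_profile(radii)
        assert list(p.counts) == brute_force_shell_counts(
            radii.tolist(), DEFAULT_LAYER_SCHEME.breakpoints
        )
        assert p.total == 1000

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            layer_profile([-0.1])


class TestPerLayerSimilarity:
    def test_identical_profiles_score_one(self):
        p = profile_of([3, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        np.testing.assert_array_equal(per_layer_similarity(p, p), np.ones(10))

    @pytest.mark.parametrize(
        "l1,l2,expected",
        [(10, 5, 0.5), (10, 25, -0.5), (0, 0, 1.0), (0, 7, 0.0)],
    )
    def test_shellwise_formula_and_empty_shell_rule(self, l1, l2, expected):
        p1 = profile_of([l1] + [0] * 9)
        p2 = profile_of([l2] + [0] * 9)
        assert per_layer_similarity(p1, p2)[0] == pytest.approx(expected)

    def test_scheme_mismatch_rejected(self, two_shell_scheme):
        p1 = profile_of([1, 1], two_shell_scheme)
        p2 = profile_of([1] * 10)
        with pytest.raises(ValueError, match="scheme"):
            per_layer_similarity(p1, p2)


class TestLayerWeights:
    def test_identical_profiles_weight_by_fraction(self):
        p = profile_of([10, 30, 60, 0, 0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(
            layer_weights(p, p), [0.1, 0.3, 0.6, 0, 0, 0, 0, 0, 0, 0]
        )

    def test_random_pair_matches_oracle_and_sums_to_one(self, rng):
        for _ in range(20):
            c1 = rng.integers(0, 50, size=10)
            c2 = rng.integers(0, 50, size=10)
            c1[0] += 1  # keep totals positive
            c2[0] += 1
            p1, p2 = profile_of(c1.tolist()), profile_of(c2.tolist())
            w = layer_weights(p1, p2)
            np.testing.assert_allclose(
                w, brute_force_layer_weights(c1.tolist(), c2.tolist()), rtol=1e-12
            )
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestDensitySimilarity:
    def test_self_similarity_is_exactly_one(self, default_structure):
        st, _ = default_structure
        assert density_similarity(st, st) == pytest.approx(1.0, abs=1e-12)

    def test_two_shell_toy_case_hand_computed(self, two_shell_scheme):
        st1, _ = make_structure(
            StructureSpec(n_atoms=10, shell_fractions=(0.5, 0.5), seed=1), two_shell_scheme
        )
        st2, _ = make_structure(
            StructureSpec(n_atoms=15, shell_fractions=(1 / 3, 2 / 3), seed=2), two_shell_scheme
        )
        # profiles [5,5] vs [5,10]: weights (5/12, 7/12), sims (1, 0) -> 5/12
        assert density_similarity(st1, st2, two_shell_scheme) == pytest.approx(5 / 12)

    def test_perturbation_lowers_score(self, default_structure):
        st, _ = default_structure
        moved = perturb_structure(st, relocation_fraction=0.1, seed=5)
        assert density_similarity(st, moved) < 1.0


class TestScalarSimilarity:
    @pytest.mark.parametrize(
        "n1,n2,expected", [(100, 100, 1.0), (100, 150, 0.5), (100, 250, -0.5)]
    )
    def test_relative_difference_unclamped(self, n1, n2, expected):
        assert scalar_similarity(n1, n2) == pytest.approx(expected)

    def test_query_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            scalar_similarity(0, 5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n1=st.floats(min_value=1e-3, max_value=1e6),
        n2=st.floats(min_value=0, max_value=1e6),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, n1, n2, k):
        assert scalar_similarity(k * n1, k * n2) == pytest.approx(
            scalar_similarity(n1, n2), rel=1e-9, abs=1e-9
        )


class TestCountsAndFractions:
    def test_single_glycine(self):
        stc = make_simple([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert (count_atoms(stc), count_residues(stc), count_residue_types(stc)) == (3, 1, 1)

    def test_two_residues(self):
        stc = make_simple(
            np.arange(24).reshape(8, 3),
            residue_ids=[1, 1, 1, 1, 2, 2, 2, 2],
            residue_names=["ALA"] * 4 + ["GLY"] * 4,
        )
        assert (count_atoms(stc), count_residues(stc), count_residue_types(stc)) == (8, 2, 2)

    def test_nonstandard_residues_ignored_in_type_count(self):
        stc = make_simple([[0, 0, 0], [1, 0, 0]], residue_ids=[1, 2],
                          residue_names=["ALA", "XYZ"])
        assert count_residue_types(stc) == 1

    def test_synthetic_composition_matches_generator_truth(self, default_structure):
        stc, truth = default_structure
        assert count_atoms(stc) == sum(truth["element_counts"].values())
        assert count_residues(stc) == truth["n_residues"]
        for elem, n in truth["element_counts"].items():
            assert element_fraction(stc, elem) == pytest.approx(n / len(stc))

    def test_element_fraction_simple_cases(self):
        all_c = make_simple([[0, 0, 0], [1, 0, 0]])
        assert element_fraction(all_c, "C") == 1.0
        half_n = make_simple(np.arange(12).reshape(4, 3), elements=["C", "C", "N", "N"])
        assert element_fraction(half_n, "N") == 0.5


def _structure_with_sulfur_at(radius, seed=0):
    """400-atom carbon/nitrogen/oxygen cloud plus one S atom at the given radius."""
    spec = StructureSpec(
        n_atoms=400,
        composition={"C": 0.7, "N": 0.15, "O": 0.15},
        shell_fractions=(0.12, 0.12, 0.12, 0.12, 0.12, 0.08, 0.08, 0.08, 0.08, 0.08),
        seed=seed,
    )
    stc, _ = make_structure(spec)
    shell = int(DEFAULT_LAYER_SCHEME.shell_indices([radius])[0])
    return place_marker(stc, "S", shell)


class TestElementPositionSimilarity:
    def test_same_shell_scores_full(self):
        a = _structure_with_sulfur_at(25.0, seed=1)
        b = _structure_with_sulfur_at(27.0, seed=2)
        assert element_position_similarity(a, b, "S") == 1.0

    def test_adjacent_shells_score_point_eight(self):
        a = _structure_with_sulfur_at(25.0, seed=1)
        b = _structure_with_sulfur_at(35.0, seed=2)
        assert element_position_similarity(a, b, "S") == 0.8

    def test_distant_shells_score_zero(self):
        a = _structure_with_sulfur_at(5.0, seed=1)
        b = _structure_with_sulfur_at(45.0, seed=2)
        assert element_position_similarity(a, b, "S") == 0.0

    def test_absent_in_both_scores_full_absent_in_one_scores_zero(self):
        a = _structure_with_sulfur_at(25.0, seed=1)
        b = _structure_with_sulfur_at(27.0, seed=2)
        # neither structure carries phosphorus
        assert element_position_similarity(a, b, "P") == 1.0
        no_s, _ = make_structure(
            StructureSpec(n_atoms=100, composition={"C": 1.0}, seed=3)
        )
        assert element_position_similarity(a, no_s, "S") == 0.0

    def test_multiple_atoms_use_best_match(self):
        base, _ = make_structure(
            StructureSpec(n_atoms=400, composition={"C": 1.0},
                          shell_fractions=(0.1,) * 10, seed=4)
        )
        a = place_marker(place_marker(base, "S", 0), "S", 6)
        b = place_marker(base, "S", 6)
        assert element_position_similarity(a, b, "S") == 1.0

    def test_only_p_and_s_allowed(self, default_structure):
        stc, _ = default_structure
        with pytest.raises(ValueError, match="P and S"):
            element_position_similarity(stc, stc, "C")


class TestParameterVectorAndOverall:
    def test_self_comparison_is_all_ones(self, default_structure, weights):
        stc, _ = default_structure
        v = parameter_vector(stc, stc)
        np.testing.assert_allclose(v.as_array(), np.ones(9), atol=1e-12)
        assert overall_similarity(v, weights) == pytest.approx(
            weights.as_array().sum()
        )

    def test_weight_sum_is_the_printed_total(self, weights):
        # sum of the nine packaged weights by independent scalar addition
        total = 0.3183 + 0.0343 + 0.0204 + 0.0603 + 0.0653 + 0.1062 + 0.1002 + 0.1477 + 0.1480
        assert total == pytest.approx(1.0007)
        ones = ParameterSimilarityVector(*([1.0] * 9))
        assert overall_similarity(ones, weights) == pytest.approx(1.0007)

    def test_zero_vector_scores_zero(self, weights):
        zeros = ParameterSimilarityVector(*([0.0] * 9))
        assert overall_similarity(zeros, weights) == 0.0

    def test_published_top_row_recomputes_to_its_dot_product(self, weights):
        row = next(r for r in table4_fixture() if r.name == "S100A11")
        # independent arithmetic: explicit sum of the nine products
        expected = sum(
            q * s for q, s in zip(weights.as_array().tolist(), row.vector.as_array().tolist())
        )
        assert expected == pytest.approx(0.83284468)
        assert overall_similarity(row.vector, weights) == pytest.approx(expected)
        # the published overall column disagrees with its own printed rows
        assert row.printed_overall == 0.8102

    def test_random_pair_matches_elementwise_recomputation(self, rng):
        s1, _ = make_structure(StructureSpec(n_atoms=700, seed=21))
        s2, _ = make_structure(StructureSpec(n_atoms=900, seed=22))
        v = parameter_vector(s1, s2)
        assert v.s2 == pytest.approx(1 - abs(len(s1) - len(s2)) / len(s1))
        assert v.s5 == pytest.approx(
            1 - abs(element_fraction(s1, "C") - element_fraction(s2, "C")) / element_fraction(s1, "C")
        )
        assert v.s1 == pytest.approx(density_similarity(s1, s2))
        assert v.s8 in (0.0, 0.8, 1.0) and v.s9 in (0.0, 0.8, 1.0)


class TestRanking:
    def test_published_rows_rank_the_reported_root_first(self, weights):
        rows = [(r.name, r.vector) for r in table4_fixture()]
        ranked = rank_reference_proteins(rows, weights)
        assert ranked[0][0] == "S100A11"
        assert len(ranked) == 17
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_input_order_is_irrelevant(self, weights, rng):
        rows = [(r.name, r.vector) for r in table4_fixture()]
        shuffled = list(rows)
        rng.shuffle(shuffled)
        assert rank_reference_proteins(rows, weights) == rank_reference_proteins(
            shuffled, weights
        )

    def test_single_row(self, weights):
        rows = [(r.name, r.vector) for r in table4_fixture()[:1]]
        assert rank_reference_proteins(rows, weights)[0][0] == rows[0][0]


class TestSchemeValidation:
    def test_default_scheme_shape(self):
        assert DEFAULT_LAYER_SCHEME.n_shells == 10
        assert DEFAULT_LAYER_SCHEME.breakpoints == (10, 20, 30, 40, 50, 60, 70, 80, 100)

    def test_non_increasing_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            LayerScheme((10.0, 10.0))
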