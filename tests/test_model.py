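"""Core model: tuple spaces, assessment domains, opinion filters, validation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpnhse.model import (
    OPINIONS,
    AttributeSpec,
    Expert,
    NeutrosophicTriplet,
    SubAttributeValueSet,
    build_assessment_domain,
    build_tuple_space,
    collapse_opinions,
    restrict_by_opinion,
    validate,
)
from fpnhse.paperdata import example_expert_set
from fpnhse.synth import GeneratorConfig, generate_case


def _sets(sizes):
    return [
        SubAttributeValueSet(f"a{k}", tuple(f"a{k}.{j}" for j in range(n)))
        for k, n in enumerate(sizes)
    ]


class TestTupleSpace:
    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ((2, 3, 2, 2, 1, 3, 4, 4, 3), 3456),  # the Cleveland attribute sets
            ((1,), 1),
            ((2, 3), 6),
        ],
    )
    def test_cardinality_is_product_of_set_sizes(self, sizes, expected):
        space = build_tuple_space(_sets(sizes))
        assert len(space) == expected

    def test_enumeration_matches_nested_loops_and_is_deterministic(self):
        sets = _sets((2, 3))
        space = build_tuple_space(sets)
        brute = [
            (x, y) for x in sets[0].values for y in sets[1].values
        ]  # independent nested-loop enumeration
        assert [t.components for t in space.tuples] == brute
        again = build_tuple_space(sets)
        assert space.tuples == again.tuples

    @given(
        st.lists(st.integers(min_value=1, max_value=10), min_size=1, max_size=4)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cardinality_property(self, sizes):
        space = build_tuple_space(_sets(sizes))
        expected = 1
        for n in sizes:
            expected *= n
        assert len(space) == expected
        assert len(set(space.tuples)) == len(space)  # all tuples distinct

    def test_empty_value_set_names_the_attribute(self):
        with pytest.raises(ValueError, match="bad_attr"):
            SubAttributeValueSet("bad_attr", ())
        with pytest.raises(ValueError):
            build_tuple_space([])


class TestAssessmentDomain:
    @pytest.mark.parametrize(
        "nt, ne, no, expected", [(8, 4, 2, 64), (1, 1, 1, 1), (3, 2, 2, 12)]
    )
    def test_domain_size(self, nt, ne, no, expected):
        space = build_tuple_space(_sets((nt,)))
        experts = [Expert(f"E{k}") for k in range(ne)]
        domain = build_assessment_domain(space.tuples, experts, OPINIONS[:no])
        assert len(domain) == expected
        # matches independent nested-loop enumeration
        brute = [
            (t, e.id, o)
            for t in space.tuples
            for e in experts
            for o in OPINIONS[:no]
        ]
        assert domain == brute

    def test_empty_collection_rejected(self):
        space = build_tuple_space(_sets((2,)))
        with pytest.raises(ValueError):
            build_assessment_domain(space.tuples, [], OPINIONS)


class TestOpinionRestriction:
    def test_example_set_agree_side_keeps_two_of_four(self):
        s = example_expert_set()
        agree = restrict_by_opinion(s, 1)
        assert len(agree.approximations) == 2
        assert all(k[2] == 1 for k in agree.approximations)
        assert agree.degrees == s.degrees
        assert agree.tuple_space is s.tuple_space

    def test_restriction_is_identity_when_all_match(self):
        s = example_expert_set()
        agree = restrict_by_opinion(s, 1)
        assert restrict_by_opinion(agree, 1).approximations == agree.approximations

    def test_restrictions_partition_the_keys(self):
        s = generate_case(GeneratorConfig(seed=7)).expert_set
        k0 = set(restrict_by_opinion(s, 0).approximations)
        k1 = set(restrict_by_opinion(s, 1).approximations)
        assert k0 | k1 == set(s.approximations)
        assert not (k0 & k1)
        # count also matches a direct filter over all keys
        assert len(k1) == sum(1 for k in s.approximations if k[2] == 1)


class TestValidate:
    def test_example_set_is_valid(self):
        assert validate(example_expert_set()) == []

    def test_out_of_range_triplet_reported_at_its_key(self):
        s = example_expert_set()
        key = next(iter(s.approximations))
        alt = next(iter(s.approximations[key]))
        s.approximations[key][alt] = NeutrosophicTriplet(1.2, 0.0, 0.0)
        report = validate(s)
        assert len(report) == 1
        assert "1.2" in report[0].message
        assert repr(alt) in report[0].location

    def test_corrupting_k_entries_yields_k_violations(self):
        s = generate_case(GeneratorConfig(seed=3)).expert_set
        keys = list(s.approximations)[:5]
        for k in keys:
            alt = next(iter(s.approximations[k]))
            s.approximations[k][alt] = NeutrosophicTriplet(-0.5, 0.2, 0.2)
        assert len(validate(s)) == len(keys)

    def test_missing_degree_flagged(self):
        s = example_expert_set()
        tup = next(iter(s.degrees))
        del s.degrees[tup]
        assert any("chi" in v.message for v in validate(s))


class TestAttributeSpec:
    def test_selected_values_must_be_prescribed(self):
        with pytest.raises(ValueError, match="selected"):
            AttributeSpec("cp", "discrete", (1, 2, 3, 4), selected_values=(5,))

    def test_range_needs_min_below_max(self):
        with pytest.raises(ValueError):
            AttributeSpec("bp", "range", (200, 90))


class TestCollapseOpinions:
    def test_reducer_prefers_agree_entries_and_covers_grid(self):
        s = generate_case(GeneratorConfig(n_patients=3, n_tuples=2, n_experts=2,
                                          seed=11)).expert_set
        pat, exp = collapse_opinions(s)
        assert len(pat) == 3 * 2
        assert len(exp) == 2 * 2
        # agree-only entries determine the expert matrix cell
        tup = s.tuple_space.tuples[0]
        eid = s.experts[0].id
        agree = s.approximations[(tup, eid, 1)]
        mean_t = sum(v.t for v in agree.values()) / len(agree)
        assert exp[(tup, eid)].t == pytest.approx(mean_t)
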