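from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ystrped.counting import (
    COMPLEX,
    DELETION,
    DUPLICATION,
    SINGLE_STEP,
    MutationEvent,
    compare_pair,
    count_locus,
    count_multi_copy,
    count_single_copy,
    filter_pairs,
)
from ystrped.model import Allele, LocusSpec, NULL_ALLELE
from ystrped.simulate import SimConfig, simulate_pairs

from _oracles import min_mutation_cost
from conftest import make_pair

DYS390 = LocusSpec("DYS390", 1)
DYS385 = LocusSpec("DYS385", 2)


def kinds(events):
    return sorted(e.kind for e in events)


class TestSingleCopy:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Allele(10), Allele(12), [SINGLE_STEP, SINGLE_STEP]),
            (Allele(13), Allele(13), []),
            (Allele(20), NULL_ALLELE, [DELETION]),
            (NULL_ALLELE, NULL_ALLELE, []),
            (Allele(16), Allele(16, 2), [COMPLEX]),
            (Allele(14), Allele(16, 2), [COMPLEX]),
        ],
    )
    def test_event_rules(self, a, b, expected):
        assert kinds(count_single_copy(DYS390, a, b)) == sorted(expected)
        assert kinds(count_single_copy(DYS390, b, a)) == sorted(expected)

    def test_multi_step_decomposed_into_unit_steps(self):
        events = count_single_copy(DYS390, Allele(10), Allele(15))
        assert len(events) == 5
        assert all(e.kind == SINGLE_STEP and e.steps == 1 for e in events)


class TestMultiCopy:
    @pytest.mark.parametrize(
        "A,B,expected",
        [
            # inherited duplication: both men carry it, zero events
            ((15, 17), (15, 17), []),
            ((36, 38), (36, 39), [SINGLE_STEP]),
            # identity-shift matching beats crossed matching
            ((35, 37), (36, 38), [SINGLE_STEP, SINGLE_STEP]),
            # copy-number change is one event when steps cannot explain it;
            # a copy missing below the expected two is labelled a deletion
            ((15,), (15, 22), [DELETION]),
            # homoallelic reading wins ties: {15} may hide {15,15}
            ((15,), (15, 15), []),
            ((15,), (14, 15), [SINGLE_STEP]),
        ],
    )
    def test_parsimony_assignments(self, A, B, expected):
        A = tuple(Allele(x) for x in A)
        B = tuple(Allele(x) for x in B)
        assert kinds(count_multi_copy(DYS385, A, B)) == sorted(expected)
        assert kinds(count_multi_copy(DYS385, B, A)) == sorted(expected)

    def test_homoallelic_tie_prefers_no_event(self):
        # {16} vs {15,16}: deletion (cost 1) vs homoallelic {16,16} (cost 1)
        # -> tie broken toward fewer copy events, one single step remains
        events = count_multi_copy(DYS385, (Allele(16),), (Allele(15), Allele(16)))
        assert kinds(events) == [SINGLE_STEP]

    def test_null_states(self):
        assert count_multi_copy(DYS385, (NULL_ALLELE,), (NULL_ALLELE,)) == []
        events = count_multi_copy(DYS385, (NULL_ALLELE,), (Allele(36), Allele(38)))
        assert kinds(events) == [DELETION]

    def test_more_than_four_copies_rejected(self):
        A = tuple(Allele(30 + i) for i in range(5))
        with pytest.raises(ValueError, match="copies"):
            count_multi_copy(DYS385, A, (Allele(30),))

    def test_duplication_at_nominally_single_copy_locus(self):
        # extra copy above the expected single copy is a duplication
        events = count_locus(
            LocusSpec("DYS19", 1), (Allele(15),), (Allele(15), Allele(17))
        )
        assert kinds(events) == [DUPLICATION]


@st.composite
def allele_multisets(draw, max_size=3):
    size = draw(st.integers(1, max_size))
    alleles = st.builds(
        Allele,
        whole=st.integers(10, 16),
        frac=st.sampled_from([0, 2]),
    )
    return tuple(sorted(draw(st.tuples(*[alleles] * size))))


class TestParsimonyProperties:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(A=allele_multisets(), B=allele_multisets())
    def test_symmetry_and_oracle_cost(self, A, B):
        """d(A,B) = d(B,A) as event multisets, and the total equals the
        independent recursive minimum-mutation search."""
        ab = count_multi_copy(DYS385, A, B)
        ba = count_multi_copy(DYS385, B, A)
        assert kinds(ab) == kinds(ba)
        assert len(ab) == min_mutation_cost(A, B, expected=2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(A=allele_multisets())
    def test_identity(self, A):
        assert count_multi_copy(DYS385, A, A) == []

    def test_event_type_accounting(self, panel):
        pair = make_pair(
            panel,
            overrides1={"DYS627": "20", "DYS385": "13,17", "DYS448": "20"},
            overrides2={"DYS627": "22", "DYS385": "13,17,18", "DYS448": "NEG"},
        )
        comp = compare_pair(pair, panel)
        by_kind = {k: sum(1 for e in comp.events if e.kind == k)
                   for k in (SINGLE_STEP, DUPLICATION, DELETION, COMPLEX)}
        assert comp.total_mutations == sum(by_kind.values()) == 4
        assert comp.loci_discordant == {"DYS627", "DYS385", "DYS448"}


class TestComparePair:
    def test_identical_haplotypes_no_events(self, panel):
        comp = compare_pair(make_pair(panel), panel)
        assert comp.events == () and comp.loci_discordant == frozenset()

    def test_single_locus_difference(self, panel):
        pair = make_pair(panel, overrides1={"DYS627": "20"}, overrides2={"DYS627": "21"})
        comp = compare_pair(pair, panel)
        assert comp.total_mutations == 1
        assert comp.loci_discordant == {"DYS627"}

    def test_symmetric_in_pair_order(self, panel):
        p = make_pair(panel, overrides1={"DYS627": "20", "DYS19": "15,17"},
                      overrides2={"DYS627": "23", "DYS19": "15"})
        q = make_pair(panel, overrides1=None, overrides2=None)
        flipped = type(p)(p.family_id, p.hap2, p.hap1, p.meioses)
        assert kinds(compare_pair(p, panel).events) == kinds(
            compare_pair(flipped, panel).events
        )
        assert compare_pair(q, panel).events == ()

    def test_parsimony_lower_bound_on_simulation(self, panel):
        """With single-step truth only, the inferred count at a locus can
        never exceed the simulated event count (net drift argument)."""
        config = SimConfig(
            panel=tuple(panel), n_pairs=60, meioses={8: 1.0}, p_dupdel=0.0
        )
        result = simulate_pairs(config, seed=7)
        for pair in result.pairs:
            comp = compare_pair(pair, panel)
            for spec in panel:
                inferred = len(comp.events_at(spec.name))
                assert inferred <= result.truth.count(pair.family_id, spec.name)


class TestFilterPairs:
    @pytest.mark.parametrize("n_events,kept", [(0, True), (15, True), (16, False)])
    def test_boundary_semantics(self, panel, n_events, kept):
        pair = make_pair(
            panel, overrides1={"DYS627": "20"}, overrides2={"DYS627": str(20 + n_events)}
        )
        comp = compare_pair(pair, panel)
        assert comp.total_mutations == n_events
        kept_list, excluded = filter_pairs([comp])
        assert (comp in kept_list) is kept
        assert (comp in excluded) is not kept
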