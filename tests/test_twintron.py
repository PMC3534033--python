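"""Twintron component alignment, classification and nested decomposition."""
import numpy as np
import pytest

from plastintron.annotation_io import IntronRecord, StructuralError
from plastintron.synthetic_data import (build_twintron_cohort,
                                        generate_intron_sequence)
from plastintron.twintron import (Thresholds, TwintronReference,
                                  classify_site, component_align,
                                  decompose_nested, excise, shares_twintron)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(11)
    external = generate_intron_sequence("group_II", 320, rng)
    internals = (
        (generate_intron_sequence("group_III", 90, rng), 80),
        (generate_intron_sequence("group_III", 110, rng), 200),
    )
    return TwintronReference(site_id="rps3.Egra.1", external=external,
                             internals=internals)


class TestComponentAlign:
    def test_external_only_target_supports_external_not_internals(
            self, reference):
        ev = component_align(reference.external, reference)
        assert ev.external.coverage == 1.0
        assert ev.external.identity == 1.0
        assert all(c.coverage < 0.5 for c in ev.internals)

    def test_full_reference_supports_every_component(self, reference):
        ev = component_align(reference.full_sequence, reference)
        assert ev.full_span.coverage == ev.full_span.identity == 1.0
        assert ev.external.coverage == 1.0
        assert all(c.coverage == c.identity == 1.0 for c in ev.internals)

    def test_shuffled_target_identity_sits_in_permutation_null(
            self, reference):
        # identity of a composition-preserving shuffled target should not
        # stand out from its own permutation null (z < 3)
        rng = np.random.default_rng(3)
        target = list(reference.full_sequence)
        rng.shuffle(target)
        obs = component_align("".join(target), reference).external.identity
        null = []
        for _ in range(100):
            rng.shuffle(target)
            null.append(
                component_align("".join(target), reference).external.identity
            )
        z = abs(obs - np.mean(null)) / (np.std(null) + 1e-12)
        assert z < 3

    def test_empty_inputs_rejected(self, reference):
        with pytest.raises(ValueError):
            component_align("", reference)
        with pytest.raises(ValueError):
            TwintronReference(site_id="x", external="",
                              internals=((("ACGT"), 1),))


class TestClassification:
    def test_self_consistency_complete(self, reference):
        ev = component_align(reference.full_sequence, reference)
        st = classify_site(ev)
        assert st.status == "complete_twintron"
        assert st.supported_internals == (1, 2)

    def test_partial_keeps_second_internal(self, reference):
        ev = component_align(reference.with_internals([1]), reference)
        st = classify_site(ev)
        assert st.status == "partial_twintron"
        assert st.supported_internals == (2,)

    def test_external_only_status(self, reference):
        ev = component_align(reference.with_internals([]), reference)
        assert classify_site(ev).status == "external_only"

    def test_unrelated_sequence(self, reference):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGT"), 300))
        st = classify_site(component_align(junk, reference))
        assert st.status == "unrelated"

    def test_deleting_internals_only_demotes(self, reference):
        rank = {"complete_twintron": 3, "partial_twintron": 2,
                "external_only": 1}
        keeps = [[0, 1], [1], []]
        statuses = [
            classify_site(
                component_align(reference.with_internals(k), reference)
            ).status
            for k in keeps
        ]
        values = [rank[s] for s in statuses]
        assert values == sorted(values, reverse=True)

    def test_surplus_triggers_motif_report(self, reference):
        # an unrecognized extra intron leaves an unexplained length surplus
        rng = np.random.default_rng(9)
        extra = generate_intron_sequence("group_III", 100, rng)
        ext = reference.external
        target = ext[:150] + extra + ext[150:]
        ev = component_align(target, reference)
        st = classify_site(ev, ref=reference, target=target)
        assert st.status == "external_only"
        assert st.surplus_nt > 60
        assert st.surplus_motif_report is not None

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(coverage=1.5)

    def test_cohort_reproduces_published_composition(self):
        cohort = build_twintron_cohort(seed=0)
        statuses = []
        for sid, target, ref, built in cohort.entries:
            ev = component_align(target, ref)
            statuses.append(classify_site(ev, ref=ref, target=target))
        sharing = sum(shares_twintron(s) for s in statuses)
        external_only = sum(
            1 for s in statuses if s.status == "external_only")
        assert sharing == 6
        assert external_only == 6


class TestDecomposition:
    def test_single_child_two_step_plan(self):
        parent = IntronRecord("g", 1, (0, 100), "A" * 100)
        parent.children.append(IntronRecord("g", 0, (40, 60), "A" * 20))
        plan = decompose_nested(parent)
        assert len(plan) == 2 and plan[-1] is parent

    def test_three_level_nesting_innermost_first(self):
        inner = IntronRecord("g", 0, (45, 55), "A" * 10)
        mid = IntronRecord("g", 0, (40, 70), "A" * 30, children=[inner])
        outer = IntronRecord("g", 1, (0, 100), "A" * 100, children=[mid])
        plan = decompose_nested(outer)
        assert [p.interval for p in plan] == [(45, 55), (40, 70), (0, 100)]

    def test_overlapping_children_rejected(self):
        outer = IntronRecord("g", 1, (0, 100), "A" * 100)
        outer.children = [
            IntronRecord("g", 0, (10, 50), "A" * 40),
            IntronRecord("g", 0, (40, 80), "A" * 40),
        ]
        with pytest.raises(StructuralError):
            decompose_nested(outer)

    def test_excision_reconstitutes_fragmented_orf(self):
        # an ORF split across the external intron is contiguous once the
        # internal introns are excised (the maturase arrangement)
        rng = np.random.default_rng(2)
        orf = "ATG" + "".join(rng.choice(list("ACGT"), 120)) + "TAA"
        i1 = generate_intron_sequence("group_III", 80, rng)
        i2 = generate_intron_sequence("group_III", 70, rng)
        ext = "GTGCG" + orf[:60] + orf[60:] + "ACTG" * 5
        seq = ("GTGCG" + orf[:60] + i1 + orf[60:100] + i2 + orf[100:]
               + "ACTG" * 5)
        parent = IntronRecord("psbC", 1, (0, len(seq)), seq)
        a = 5 + 60
        b = a + len(i1) + 40
        parent.children = [
            IntronRecord("psbC", 0, (a, a + len(i1)), i1),
            IntronRecord("psbC", 0, (b, b + len(i2)), i2),
        ]
        mature = excise(parent)
        assert orf in mature
        assert mature == ext
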