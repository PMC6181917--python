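"""AS event detection, canonicalization, and region assignment."""

import random

import pytest

from splicescape.as_events import (
    assign_region,
    detect_events,
    event_catalog,
    region_type_matrix,
    type_counts,
)
from splicescape.annotation_model import partition_regions

from conftest import make_gene, make_transcript


def _events(gene, etype=None):
    evs = detect_events(gene)
    return [e for e in evs if etype is None or e.event_type == etype]


class TestSkippedExon:
    def test_definition_and_junction_sets(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300), (400, 500)]),
                make_transcript("b", [(0, 100), (400, 500)]),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["SE"]
        e = evs[0]
        assert e.anchors == (100, 200, 300, 400)
        assert e.inclusion_junctions == frozenset({(100, 200), (300, 400)})
        assert e.exclusion_junctions == frozenset({(100, 400)})


class TestRetainedIntron:
    def test_definition(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)]),
                make_transcript("b", [(0, 300)]),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["RI"]
        e = evs[0]
        assert e.anchors == (0, 100, 200, 300)
        assert e.inclusion_junctions == frozenset()
        assert e.exclusion_junctions == frozenset({(100, 200)})
        assert e.defining_span == (100, 200)

    def test_outer_bounds_must_match(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)]),
                make_transcript("b", [(10, 300)]),  # different left bound
            ]
        )
        assert _events(g, "RI") == []


class TestAlternativeSpliceSites:
    def test_plus_strand_alternative_donor_is_a5ss(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)]),
                make_transcript("b", [(0, 120), (200, 300)]),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["A5SS"]
        e = evs[0]
        assert e.anchors == (200, 100, 120)
        assert e.inclusion_junctions == frozenset({(120, 200)})
        assert e.exclusion_junctions == frozenset({(100, 200)})

    def test_same_exons_on_minus_strand_is_a3ss(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)], strand="-"),
                make_transcript("b", [(0, 120), (200, 300)], strand="-"),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["A3SS"]

    def test_plus_strand_alternative_acceptor_is_a3ss(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)]),
                make_transcript("b", [(0, 100), (230, 300)]),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["A3SS"]
        assert evs[0].anchors == (100, 200, 230)


class TestMutuallyExclusiveExons:
    def test_definition(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (150, 180), (400, 500)]),
                make_transcript("b", [(0, 100), (250, 300), (400, 500)]),
            ]
        )
        evs = detect_events(g)
        assert [e.event_type for e in evs] == ["MXE"]
        e = evs[0]
        assert e.anchors == (100, 150, 180, 250, 300, 400)
        assert e.inclusion_junctions == frozenset({(100, 150), (180, 400)})
        assert e.exclusion_junctions == frozenset({(100, 250), (300, 400)})

    def test_overlapping_middle_exons_are_not_mxe(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (150, 250), (400, 500)]),
                make_transcript("b", [(0, 100), (200, 300), (400, 500)]),
            ]
        )
        assert _events(g, "MXE") == []


class TestDegenerate:
    def test_duplicate_isoforms_give_no_events(self):
        g = make_gene(
            [
                make_transcript("a", [(0, 100), (200, 300)]),
                make_transcript("b", [(0, 100), (200, 300)]),
            ]
        )
        assert detect_events(g) == []

    def test_single_isoform_gives_no_events(self):
        g = make_gene([make_transcript("a", [(0, 100), (200, 300)])])
        assert detect_events(g) == []

    def test_empty_catalog(self):
        events, table = event_catalog([])
        assert events == [] and table.empty


def test_detection_invariant_to_isoform_ordering(sim_small):
    _, ann, _ = sim_small
    rng = random.Random(0)
    for g in ann.genes:
        ref = [e.key for e in detect_events(g)]
        shuffled = make_gene(
            rng.sample(g.transcripts, k=len(g.transcripts)), gene_id=g.gene_id
        )
        assert [e.key for e in detect_events(shuffled)] == ref


def test_event_key_invariant_to_pair_order():
    a = make_transcript("a", [(0, 100), (200, 300), (400, 500)])
    b = make_transcript("b", [(0, 100), (400, 500)])
    k1 = detect_events(make_gene([a, b]))[0].key
    k2 = detect_events(make_gene([b, a]))[0].key
    assert k1 == k2


class TestRegionAssignment:
    def _partition(self, strand="+"):
        t = make_transcript("rep", [(0, 1000)], strand=strand, cds_span=(150, 450))
        return partition_regions(t)

    def _se(self, span):
        g = make_gene(
            [
                make_transcript("a", [(0, 50), span, (600, 700)]),
                make_transcript("b", [(0, 50), (600, 700)]),
            ]
        )
        return detect_events(g)[0]

    def test_event_inside_cds(self):
        e = assign_region(self._se((200, 300)), self._partition())
        assert e.region == "CDS"

    def test_ri_inside_five_prime_utr(self):
        g = make_gene(
            [
                make_transcript("a", [(60, 100), (120, 140)]),
                make_transcript("b", [(60, 140)]),
            ]
        )
        (e,) = detect_events(g)
        rep = partition_regions(
            make_transcript("rep", [(0, 1000)], cds_span=(210, 800))
        )
        assert assign_region(e, rep).region == "5UTR"

    def test_majority_overlap_wins_on_straddle(self):
        # spans CDS/3UTR 60%/40% -> CDS
        e = assign_region(self._se((330, 530)), self._partition())
        assert e.region == "CDS"

    def test_tie_goes_to_more_five_prime_region(self):
        e = assign_region(self._se((400, 500)), self._partition())
        assert e.region == "CDS"  # 50 nt in CDS, 50 nt in 3'UTR

    def test_no_partition_is_unpartitioned(self):
        e = assign_region(self._se((200, 300)), None)
        assert e.region == "unpartitioned"


def test_simulated_catalog_matches_planted_events_exactly(sim_small):
    """Noise-free precision and recall of 1.0 against the planted truth."""
    _, ann, _ = sim_small
    planted = {(p.event.event_type, p.event.chrom, p.event.anchors) for p in ann.planted}
    detected = set()
    for g in ann.genes:
        for e in detect_events(g):
            detected.add((e.event_type, e.chrom, e.anchors))
            assert e.inclusion_junctions.isdisjoint(e.exclusion_junctions)
    assert detected == planted


def test_planted_type_proportions_recovered_within_multinomial_error():
    from splicescape.synthetic_data import SimulationConfig, simulate_annotation

    cfg = SimulationConfig(n_genes=1200, rng_seed=5)
    ann = simulate_annotation(cfg)
    events = [e for g in ann.genes for e in detect_events(g)]
    tc = type_counts(events).set_index("event_type")
    n = len(events)
    assert n >= 1000
    for etype, p in cfg.as_type_proportions.items():
        se = (p * (1 - p) / n) ** 0.5
        assert abs(tc.loc[etype, "count"] / n - p) <= 3 * se + 1e-12


def test_catalog_counts_and_region_matrix_are_consistent(sim_small):
    _, ann, _ = sim_small
    events, table = event_catalog(ann.genes)
    tc = type_counts(events)
    assert tc["count"].sum() == len(events)
    assert abs(tc["percent"].sum() - 100.0) < 0.05
    mat = region_type_matrix(events)
    assert mat.to_numpy().sum() == len(events)
    assert {e.gene_id for e in events} <= {
        g.gene_id for g in ann.genes if len(g.transcripts) >= 2
    }
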