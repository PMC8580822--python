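"""Frequency bookkeeping, thresholds, conservation and determinant roles."""

import pytest

from gpcrstates.fixture_factory import EnsembleSpec, make_alignment, make_contact_ensemble
from gpcrstates.state_contacts import (
    ClassThresholds, aggregate_segment_network, classify_positions,
    compute_pair_frequencies, conservation_filter, cross_class_overlap,
    filter_state_specific, intersegment_edge_count,
)
from gpcrstates.structure_model import GenericPosition


def ensemble(pairs, n_inactive=4, n_active=4, gpcr_class="A", dropout=(),
             **kw):
    spec = EnsembleSpec(gpcr_class=gpcr_class, n_inactive=n_inactive,
                        n_active=n_active, pairs=tuple(pairs),
                        dropout=tuple(dropout), **kw)
    return make_contact_ensemble(spec)


class TestPairFrequencies:
    def test_all_or_nothing_pair(self):
        inact, act = ensemble(
            [(("1x50", "2x50"), 100.0, 0.0, ("A", "A"))],
            n_inactive=4, n_active=2)
        rec = compute_pair_frequencies(inact, act, "A")[0]
        assert rec.freq_inactive == 100.0
        assert rec.freq_active == 0.0
        assert rec.diff == 100.0
        assert (rec.n_inactive_obs, rec.n_active_obs) == (4, 2)

    def test_dropout_shrinks_denominator(self):
        """A position unresolved in two of four inactive templates leaves
        a denominator of 2; forming the contact in both remaining
        templates gives 100%."""
        inact, act = ensemble(
            [(("3x50", "6x37"), 100.0, 0.0, ("R", "A"))],
            dropout=[("3x50", "inactive", 0), ("3x50", "inactive", 1)])
        rec = compute_pair_frequencies(inact, act, "A")[0]
        assert rec.n_inactive_obs == 2
        assert rec.k_inactive == 2
        assert rec.freq_inactive == 100.0

    def test_two_thirds_frequency_exact(self):
        # resolved in 3 of 4 templates, formed in 2 -> 66.7%
        inact, act = ensemble(
            [(("3x50", "6x37"), 200.0 / 3.0, 0.0, ("R", "A"))],
            dropout=[("3x50", "inactive", 3)])
        rec = compute_pair_frequencies(inact, act, "A")[0]
        assert rec.n_inactive_obs == 3 and rec.k_inactive == 2
        assert rec.freq_inactive == pytest.approx(66.6667, abs=1e-3)

    def test_all_templates_denominator_mode(self):
        inact, act = ensemble(
            [(("3x50", "6x37"), 100.0, 0.0, ("R", "A"))],
            dropout=[("3x50", "inactive", 0), ("3x50", "inactive", 1)])
        rec = compute_pair_frequencies(inact, act, "A",
                                       denominator="all")[0]
        assert rec.n_inactive_obs == 4
        assert rec.freq_inactive == 50.0

    def test_programmed_frequencies_recovered_exactly(self):
        pairs = [(("1x49", "7x50"), 90.0, 10.0, ("N", "P")),
                 (("3x50", "6x37"), 75.0, 25.0, ("R", "A")),
                 (("5x58", "6x40"), 20.0, 95.0, ("Y", "L"))]
        inact, act = ensemble(pairs, n_inactive=20, n_active=20)
        recs = {tuple(str(p) for p in r.pair): r
                for r in compute_pair_frequencies(inact, act, "A")}
        for (pa, pb), fi, fa, _ in pairs:
            r = recs[(pa, pb)]
            assert r.freq_inactive == fi
            assert r.freq_active == fa

    def test_template_order_permutation_invariance(self):
        pairs = [(("1x49", "7x50"), 75.0, 25.0, ("N", "P"))]
        inact, act = ensemble(pairs)
        a = compute_pair_frequencies(inact, act, "A")
        b = compute_pair_frequencies(list(reversed(inact)),
                                     list(reversed(act)), "A")
        assert [(r.pair, r.diff) for r in a] == [(r.pair, r.diff) for r in b]

    def test_empty_state_rejected(self):
        inact, act = ensemble([(("1x50", "2x50"), 100.0, 0.0, ("A", "A"))])
        with pytest.raises(ValueError):
            compute_pair_frequencies(inact, [], "A")


class TestStateSpecificFilter:
    def _records(self, diffs, gpcr_class="A"):
        pairs = []
        for i, (fi, fa) in enumerate(diffs):
            pairs.append(((f"1x{30 + i}", f"2x{30 + i}"), fi, fa, ("A", "A")))
        inact, act = ensemble(pairs, n_inactive=10, n_active=10,
                              gpcr_class=gpcr_class)
        return compute_pair_frequencies(inact, act, gpcr_class)

    def test_boundary_inclusive_at_class_threshold(self):
        recs = self._records([(40.0, 0.0), (100.0, 60.0)])
        kept = filter_state_specific(recs)
        assert len(kept) == 2
        assert all(r.label == "inactivating" for r in kept)

    def test_just_below_threshold_dropped(self):
        # 39.9 points is not constructible at n=10; 30 vs 0 gives 30 < 40
        recs = self._records([(30.0, 0.0)])
        assert filter_state_specific(recs) == []

    def test_activating_label_for_negative_diff(self):
        recs = self._records([(0.0, 100.0)], gpcr_class="F")
        kept = filter_state_specific(recs)
        assert kept[0].label == "activating"
        assert kept[0].diff == -100.0

    def test_programmed_count_above_threshold(self):
        recs = self._records([(100.0, 0.0), (90.0, 10.0), (80.0, 30.0),
                              (70.0, 30.0), (60.0, 20.0),
                              (30.0, 0.0), (20.0, 10.0), (50.0, 40.0)])
        assert len(filter_state_specific(recs)) == 5

    def test_sorted_by_absolute_difference(self):
        recs = self._records([(50.0, 0.0), (100.0, 0.0), (0.0, 70.0)])
        kept = filter_state_specific(recs)
        assert [abs(r.diff) for r in kept] == [100.0, 70.0, 50.0]

    def test_unknown_class_rejected(self):
        recs = self._records([(100.0, 0.0)])
        bad = ClassThresholds(by_class=(("A", 40.0),))
        recs2 = [r.__class__(**{**r.__dict__, "gpcr_class": "Z"})
                 for r in recs]
        with pytest.raises(KeyError):
            filter_state_specific(recs2, bad)


class TestConservationFilter:
    def _specific(self, aa_pair=("R", "A")):
        inact, act = ensemble(
            [(("3x50", "6x37"), 100.0, 0.0, aa_pair)])
        return filter_state_specific(
            compute_pair_frequencies(inact, act, "A"))

    def test_fully_conserved_kept_with_fraction_one(self):
        recs = self._specific()
        aln = make_alignment([f"R{i}" for i in range(10)],
                             {"3x50": "R", "6x37": "A"})
        kept = conservation_filter(recs, aln)
        assert kept[0].conservation_fraction == 1.0

    @pytest.mark.parametrize("n_match,kept", [(3, True), (2, False)])
    def test_boundary_three_of_ten(self, n_match, kept):
        """30% conservation is inclusive: 3 of 10 receptors keep a
        record, 2 of 10 drop it."""
        recs = self._specific()
        aln = make_alignment(
            [f"R{i}" for i in range(10)],
            {"3x50": [("R", n_match), ("K", 10 - n_match)],
             "6x37": "A"})
        out = conservation_filter(recs, aln)
        assert bool(out) is kept
        if kept:
            assert out[0].conservation_fraction == pytest.approx(0.3)

    def test_missing_position_counts_as_nonmatching(self):
        recs = self._specific()
        aln = make_alignment([f"R{i}" for i in range(10)], {"3x50": "R"})
        assert conservation_filter(recs, aln) == []

    def test_empty_alignment_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            conservation_filter(self._specific(), pd.DataFrame())


class TestClassifyPositions:
    def _map(self, pair_specs, gpcr_class="A"):
        inact, act = ensemble(pair_specs, n_inactive=10, n_active=10,
                              gpcr_class=gpcr_class)
        recs = filter_state_specific(
            compute_pair_frequencies(inact, act, gpcr_class))
        return classify_positions(recs)

    def test_single_inactivating_contact_gives_inactivator(self):
        m = self._map([(("1x49", "7x50"), 80.0, 0.0, ("N", "P"))])
        assert m.roles()[GenericPosition(1, 49)] == "inactivator"
        assert m.roles()[GenericPosition(7, 50)] == "inactivator"

    def test_switch_needs_contacts_in_both_states(self):
        m = self._map([(("7x53", "3x46"), 70.0, 0.0, ("Y", "I")),
                       (("7x53", "8x50"), 0.0, 60.0, ("Y", "F"))])
        roles = m.roles()
        assert roles[GenericPosition(7, 53)] == "switch"
        assert roles[GenericPosition(3, 46)] == "inactivator"
        assert roles[GenericPosition(8, 50)] == "activator"

    def test_role_partition_is_total(self):
        m = self._map([(("1x49", "7x50"), 90.0, 10.0, ("N", "P")),
                       (("3x50", "6x37"), 100.0, 0.0, ("R", "A")),
                       (("5x58", "6x40"), 0.0, 90.0, ("Y", "L")),
                       (("7x53", "3x46"), 70.0, 0.0, ("Y", "I")),
                       (("7x53", "8x50"), 0.0, 60.0, ("Y", "F"))])
        counts = m.count_by_role()
        assert sum(counts.values()) == len(m.positions)
        for p in m.positions:
            labels = {r.label for r in p.contacts}
            assert (p.role == "switch") == (
                labels == {"inactivating", "activating"})

    def test_consensus_amino_acid_from_alignment(self):
        inact, act = ensemble([(("3x50", "6x37"), 100.0, 0.0, ("R", "A"))])
        recs = filter_state_specific(
            compute_pair_frequencies(inact, act, "A"))
        aln = make_alignment([f"R{i}" for i in range(10)],
                             {"3x50": [("R", 7), ("K", 3)], "6x37": "A"})
        m = classify_positions(recs, aln)
        p = m.by_position()[GenericPosition(3, 50)]
        assert p.consensus_aa == "R"
        assert p.consensus_conservation == pytest.approx(0.7)


class TestCrossClassOverlap:
    def _map_for(self, gpcr_class, pairs):
        inact, act = ensemble(pairs, gpcr_class=gpcr_class,
                              n_inactive=10, n_active=10)
        thr = ClassThresholds(by_class=(("A", 40.0), ("B1", 67.0),
                                        ("C", 75.0), ("F", 100.0)))
        recs = filter_state_specific(
            compute_pair_frequencies(inact, act, gpcr_class), thr)
        return classify_positions(recs)

    def test_disjoint_maps_all_unique(self):
        a = self._map_for("A", [(("1x50", "2x50"), 80.0, 0.0, ("A", "A"))])
        f = self._map_for("F", [(("6x48", "7x43"), 100.0, 0.0, ("W", "A"))])
        out = cross_class_overlap([a, f])
        assert out["shared_by"][1] == out["n_positions"] == 4
        assert out["shared_by"][2] == 0

    def test_programmed_sharing_counts(self):
        a = self._map_for("A", [(("3x50", "6x48"), 80.0, 0.0, ("R", "W"))])
        c = self._map_for("C", [(("3x50", "6x48"), 100.0, 0.0, ("R", "W"))])
        out = cross_class_overlap([a, c])
        assert out["shared_by"][2] == 2
        assert set(out["positions_by_share"][2]) == {"3x50", "6x48"}
        assert out["same_role_shared"]["inactivator"] == 2

    def test_needs_two_maps(self):
        a = self._map_for("A", [(("3x50", "6x48"), 80.0, 0.0, ("R", "W"))])
        with pytest.raises(ValueError):
            cross_class_overlap([a])


class TestSegmentNetwork:
    def _records(self, pair_specs, gpcr_class="A"):
        inact, act = ensemble(pair_specs, n_inactive=10, n_active=10,
                              gpcr_class=gpcr_class)
        return filter_state_specific(
            compute_pair_frequencies(inact, act, gpcr_class))

    def test_all_inactivating_fraction_100(self):
        net = aggregate_segment_network(self._records(
            [(("1x50", "2x50"), 80.0, 0.0, ("A", "A")),
             (("3x50", "6x37"), 90.0, 0.0, ("R", "A"))]))
        assert net.inactivating_fraction == 100.0

    def test_edge_counts_match_underlying_pairs(self):
        recs = self._records(
            [(("3x50", "6x37"), 90.0, 0.0, ("R", "A")),
             (("3x46", "6x40"), 80.0, 10.0, ("I", "L")),
             (("3x44", "6x41"), 0.0, 70.0, ("A", "A")),
             (("5x58", "6x40"), 0.0, 60.0, ("Y", "L"))])
        net = aggregate_segment_network(recs)
        assert net.edges[("TM3", "TM6")] == {"n_inactivating": 2,
                                             "n_activating": 1}
        assert net.edges[("TM5", "TM6")] == {"n_inactivating": 0,
                                             "n_activating": 1}
        assert intersegment_edge_count(net, "TM6") == 4
        assert intersegment_edge_count(net, "TM5") == 1

    def test_segment_switch_flag(self):
        recs = self._records(
            [(("3x50", "6x37"), 90.0, 0.0, ("R", "A")),
             (("3x44", "6x41"), 0.0, 70.0, ("A", "A"))])
        net = aggregate_segment_network(recs)
        assert net.segment_switch["TM3"] is True
        assert net.segment_switch["TM6"] is True

    def test_intersegment_fraction_excludes_intrahelical(self):
        recs = self._records(
            [(("6x37", "6x41"), 90.0, 0.0, ("A", "A")),      # intrahelical
             (("3x50", "6x37"), 80.0, 0.0, ("R", "A")),
             (("5x58", "6x40"), 0.0, 60.0, ("Y", "L"))])
        net = aggregate_segment_network(recs)
        assert net.inactivating_fraction == pytest.approx(200.0 / 3)
        assert net.inactivating_fraction_intersegment == pytest.approx(50.0)
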