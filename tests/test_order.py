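"""Travel distances, order assignment, strand fractions and heatmaps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adaptscan.mapping import ProtospacerHit
from adaptscan.order import (
    OrderedHit,
    five_three_split,
    heatmap,
    order_hits,
    strand_fraction_by_order,
    terminal_position_stat,
    travel_distance,
    travel_table,
)
from adaptscan.reference import ReferenceSet, Replicon


def make_hit(rid, start, end, strand):
    return ProtospacerHit(
        spacer_seq="N", replicon_id=rid, start=start, end=end, strand=strand,
        flank5="NNNNN", flank3="NNNNN", pam="NN", target_class="plasmid",
    )


@pytest.fixture(scope="module")
def circular_1000():
    rep = Replicon("p1", "A" * 1000, "circular", "plasmid")
    return ReferenceSet(replicons={"p1": rep}, loci={}, seed_sites=[])


class TestTravelDistance:
    def test_five_prime_on_plus_is_positive(self, circular_1000):
        frm = make_hit("p1", 484, 516, "-")  # midpoint 500
        to = make_hit("p1", 384, 416, "+")  # midpoint 400
        # oracle: arcs are 100 and 900; shortest is 100; 400 is 5' of 500 on +
        assert travel_distance(frm, to, circular_1000) == 100

    def test_same_position_minus_strand_flips_sign(self, circular_1000):
        frm = make_hit("p1", 484, 516, "-")
        to = make_hit("p1", 384, 416, "-")
        assert travel_distance(frm, to, circular_1000) == -100

    def test_identical_anchors_zero(self, circular_1000):
        a = make_hit("p1", 100, 132, "+")
        b = make_hit("p1", 100, 132, "-")
        assert travel_distance(a, b, circular_1000) == 0

    def test_cross_replicon_excluded(self, circular_1000):
        refset = ReferenceSet(
            replicons={
                "p1": circular_1000.replicons["p1"],
                "c1": Replicon("c1", "A" * 500, "linear", "chromosome"),
            },
            loci={},
            seed_sites=[],
        )
        assert travel_distance(make_hit("p1", 0, 32, "+"), make_hit("c1", 0, 32, "+"), refset) is None

    def test_antipodal_tie_excluded(self, circular_1000):
        a = make_hit("p1", 0, 32, "+")
        b = make_hit("p1", 500, 532, "+")
        assert travel_distance(a, b, circular_1000) is None

    def test_antisymmetry_on_shared_strand(self, circular_1000):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s1, s2 = rng.integers(0, 960, size=2)
            strand = rng.choice(["+", "-"])
            a = make_hit("p1", int(s1), int(s1) + 32, strand)
            b = make_hit("p1", int(s2), int(s2) + 32, strand)
            d_ab = travel_distance(a, b, circular_1000)
            d_ba = travel_distance(b, a, circular_1000)
            if d_ab is None:
                assert d_ba is None
            else:
                assert d_ab == -d_ba

    def test_shortest_arc_bound_exhaustive_small_L(self):
        rep = Replicon("p1", "A" * 20, "circular", "plasmid")
        refset = ReferenceSet(replicons={"p1": rep}, loci={}, seed_sites=[])
        for i in range(20):
            for j in range(20):
                a = make_hit("p1", i, i + 2, "+")
                b = make_hit("p1", j, j + 2, "+")
                d = travel_distance(a, b, refset)
                if d is not None:
                    assert abs(d) <= 10


class TestOrderHits:
    def _arrays(self):
        from adaptscan.extract import ArrayRecord

        return [
            ArrayRecord(
                array_id="a1", sample_id="s", locus_id="CRISPR1",
                spacers=("X" * 32, "Y" * 32, "P" * 32),
                read_count=3, new_spacer_indices=(0, 1),
            )
        ]

    def test_ps_numbering_most_leader_distal_is_one(self, circular_1000):
        hx, hy = make_hit("p1", 0, 32, "+"), make_hit("p1", 100, 132, "+")
        mapping = {"X" * 32: [hx], "Y" * 32: [hy]}
        ordered = order_hits(self._arrays(), mapping)
        by_k = {oh.k: oh for oh in ordered}
        assert by_k[1].hit == hy  # y, leader-distal, earliest
        assert by_k[2].hit == hx

    def test_unmapped_spacer_keeps_k(self, circular_1000):
        mapping = {"X" * 32: [make_hit("p1", 0, 32, "+")], "Y" * 32: []}
        ordered = order_hits(self._arrays(), mapping)
        by_k = {oh.k: oh for oh in ordered}
        assert by_k[1].hit is None and by_k[2].hit is not None

    def test_anomalous_arrays_excluded(self, circular_1000):
        recs = self._arrays()
        recs[0] = dataclasses.replace(recs[0], anomalous=True)
        assert order_hits(recs, {}) == []


class TestHeatmapAndFractions:
    def _ordered(self):
        hits = {
            1: make_hit("p1", 380, 412, "+"),
            2: make_hit("p1", 280, 312, "-"),
        }
        return [
            OrderedHit("a1", k, h, read_count=2) for k, h in hits.items()
        ]

    def test_histogram_weight_conservation(self, circular_1000):
        pps = make_hit("p1", 484, 516, "-")
        H, xe, ye = heatmap(self._ordered(), (("PPS", 1), (1, 2)), pps, circular_1000)
        assert H.sum() == 2  # one contributing array with read_count 2

    def test_swapping_axes_transposes(self, circular_1000):
        pps = make_hit("p1", 484, 516, "-")
        H1, _, _ = heatmap(self._ordered(), (("PPS", 1), (1, 2)), pps, circular_1000)
        H2, _, _ = heatmap(self._ordered(), ((1, 2), ("PPS", 1)), pps, circular_1000)
        assert np.array_equal(H1, H2.T)

    def test_empty_selection_empty_histogram(self, circular_1000):
        pps = make_hit("p1", 484, 516, "-")
        H, _, _ = heatmap([], (("PPS", 1), (1, 2)), pps, circular_1000)
        assert H.sum() == 0

    def test_strand_fractions_sum_to_one(self, circular_1000):
        pps = make_hit("p1", 484, 516, "-")
        df = strand_fraction_by_order(self._ordered(), pps, ks=(1, 2))
        assert np.allclose(
            df["primed_strand_fraction"] + df["nonprimed_strand_fraction"], 1.0
        )

    def test_five_three_split_cells_sum_to_one(self, circular_1000):
        pps = make_hit("p1", 484, 516, "-")
        split = five_three_split([(oh.hit, oh.read_count) for oh in self._ordered()], pps, circular_1000)
        assert np.isclose(split.to_numpy().sum(), 1.0)

    def test_five_three_split_forced_quadrant(self, refset):
        """All mass lands in (non-primed, 5') when the simulator is forced there."""
        from adaptscan.simulate import SimConfig, simulate_population

        config = SimConfig(
            n_cells=300, seed=41, quadrant_weights=(1.0, 0.0, 0.0, 0.0),
            feedback_mean=0.0, chrom_event_rate=0.0,
            slip_dist={}, p_flip_given_small_slip=0.0,
        )
        truth = simulate_population(refset, config)
        pps = refset.priming_site()
        hits = [
            (make_hit(e.replicon_id, e.start, e.end, e.strand), 1) for e in truth.events
        ]
        split = five_three_split(hits, pps, refset)
        assert split.loc["nonprimed", "five_prime"] == pytest.approx(1.0)


class TestTerminalPosition:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["array_id", "position", "is_new", "target_class", "read_count"],
        )

    def test_forced_terminal(self):
        table = self._table(
            [
                ("a1", 0, True, "chromosome", 2),
                ("a1", 1, True, "plasmid", 2),
                ("a2", 0, True, "chromosome", 1),
            ]
        )
        out = terminal_position_stat(table)
        assert out["terminal_fraction"] == 1.0 and out["n_arrays"] == 2

    def test_no_chromosomal_spacers(self):
        table = self._table([("a1", 0, True, "plasmid", 1)])
        out = terminal_position_stat(table)
        assert out["n_arrays"] == 0 and np.isnan(out["terminal_fraction"])

    def test_nonterminal_chromosomal_lowers_fraction(self):
        table = self._table(
            [
                ("a1", 0, True, "plasmid", 1),
                ("a1", 1, True, "chromosome", 1),
                ("a2", 0, True, "chromosome", 1),
            ]
        )
        out = terminal_position_stat(table)
        assert out["terminal_fraction"] == 0.5
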