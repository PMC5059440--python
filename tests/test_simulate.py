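"""Generative model: site sampling, capture errors, population simulation."""

import numpy as np
import pandas as pd
import pytest

from adaptscan._seq import revcomp
from adaptscan.mapping import map_spacer
from adaptscan.pam import call_flip
from adaptscan.reference import ReferenceSet, Replicon, SeedSite, fetch, seed_site_pam
from adaptscan.simulate import (
    SimConfig,
    _SiteIndex,
    apply_capture_errors,
    default_reference,
    emit_amplicons,
    sample_naive_site,
    sample_seeded_site,
    simulate_population,
    write_fastq,
)


def _refset_single_gg():
    # exactly one GG (plus strand) and no CC, far from the edges
    seq = "AT" * 40 + "GG" + "TA" * 40
    rep = Replicon("p1", seq, "circular", "plasmid")
    return ReferenceSet(replicons={"p1": rep}, loci={}, seed_sites=[])


class TestSampleNaiveSite:
    def test_degenerate_single_site(self):
        refset = _refset_single_gg()
        rng = np.random.default_rng(0)
        for _ in range(10):
            site = sample_naive_site(refset, rng, "p1")
            assert (site.anchor, site.strand) == (80, "+")

    def test_hotspot_profile_doubles_frequency(self, refset):
        rng = np.random.default_rng(1)
        rep = refset.replicons["plasmid"]
        L = len(rep)
        weights = np.ones(L)
        interval = slice(1000, 3000)
        weights[interval] = 2.0
        index = _SiteIndex(refset)
        n = 10_000
        draws = np.array(
            [sample_naive_site(refset, rng, "plasmid", weights=weights, index=index).anchor
             for _ in range(n)]
        )
        in_interval = ((draws >= 1000) & (draws < 3000)).mean()
        # closed-form expectation from the weighted site counts
        anchors = np.concatenate([index.anchors("plasmid", "+"), index.anchors("plasmid", "-")])
        w = np.where((anchors >= 1000) & (anchors < 3000), 2.0, 1.0)
        expect = w[(anchors >= 1000) & (anchors < 3000)].sum() / w.sum()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(in_interval - expect) <= 3 * se

    def test_bias_off_matches_background_composition(self, refset):
        rng = np.random.default_rng(2)
        index = _SiteIndex(refset)
        # exhaustive background: adjacent-base composition over all GG sites
        adj = np.concatenate(
            [index.adjacent_bases("plasmid", "+"), index.adjacent_bases("plasmid", "-")]
        )
        background_at = np.isin(adj, ["A", "T"]).mean()
        n = 4000
        draws_at = 0
        for _ in range(n):
            site = sample_naive_site(refset, rng, "plasmid", at_start_bias=1.0, index=index)
            strand_adj = index.adjacent_bases("plasmid", site.strand)
            anchors = index.anchors("plasmid", site.strand)
            draws_at += strand_adj[np.flatnonzero(anchors == site.anchor)[0]] in "AT"
        se = np.sqrt(background_at * (1 - background_at) / n)
        assert abs(draws_at / n - background_at) <= 3 * se

    def test_no_gg_sites_errors(self):
        rep = Replicon("p1", "AT" * 50, "circular", "plasmid")
        refset = ReferenceSet(replicons={"p1": rep}, loci={}, seed_sites=[])
        with pytest.raises(ValueError):
            sample_naive_site(refset, np.random.default_rng(0), "p1")


class TestSampleSeededSite:
    def test_forced_displaced_five_prime_quadrant(self, refset):
        config = SimConfig(quadrant_weights=(1.0, 0.0, 0.0, 0.0), seed=0)
        rng = np.random.default_rng(3)
        pps = refset.priming_site()  # minus strand
        L = len(refset.replicons["plasmid"])
        pps_mid = (pps.start + pps.end) / 2
        index = _SiteIndex(refset)
        for _ in range(300):
            site = sample_seeded_site(pps, config, rng, refset, index)
            assert site.strand == "+"  # displaced = opposite the seed
            mid = (site.anchor - 16) % L
            disp = ((mid - pps_mid) % L)
            disp = disp if disp < L / 2 else disp - L
            assert disp < 0  # 5' on the plus strand = lower coordinate, short arc

    def test_tiny_translocation_mean_selects_nearest(self, refset):
        config = SimConfig(
            quadrant_weights=(1.0, 0.0, 0.0, 0.0), translocation_mean=1e-9,
            at_start_bias=1.0, seed=0,
        )
        rng = np.random.default_rng(4)
        pps = refset.priming_site()
        index = _SiteIndex(refset)
        L = len(refset.replicons["plasmid"])
        pps_mid = (pps.start + pps.end) / 2
        mids = index.midpoints("plasmid", "+")
        delta = np.mod((mids - pps_mid) * -1, L)
        nearest = index.anchors("plasmid", "+")[np.argmin(np.where(delta > 0, delta, np.inf))]
        for _ in range(20):
            assert sample_seeded_site(pps, config, rng, refset, index).anchor == nearest

    def test_default_quadrant_weights_recovered(self, refset):
        config = SimConfig(seed=0)
        rng = np.random.default_rng(5)
        pps = refset.priming_site()
        index = _SiteIndex(refset)
        L = len(refset.replicons["plasmid"])
        pps_mid = (pps.start + pps.end) / 2
        n = 10_000
        hit_q0 = 0
        for _ in range(n):
            site = sample_seeded_site(pps, config, rng, refset, index)
            mid = ((site.anchor - 16) if site.strand == "+" else (site.anchor + 18)) % L
            disp = (mid - pps_mid) % L
            disp = disp if disp < L / 2 else disp - L
            five_p = (site.strand == "+") == (disp < 0)
            hit_q0 += (site.strand != pps.strand) and five_p
        p = config.quadrant_weights[0]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hit_q0 / n - p) <= 3 * se


class TestApplyCaptureErrors:
    def _site(self, refset):
        return sample_naive_site(refset, np.random.default_rng(0), "plasmid")

    def test_error_free_limit(self, refset):
        config = SimConfig(slip_dist={}, p_flip_given_small_slip=0.0, p_len_other=0.0)
        rng = np.random.default_rng(6)
        rep = refset.replicons["plasmid"]
        for _ in range(50):
            ev = apply_capture_errors(self._site(refset), config, rng, refset)
            assert len(ev.spacer_seq) in (32, 33)
            # GG immediately 3' of the protospacer on its strand
            if ev.strand == "+":
                pam = fetch(rep, ev.end % len(rep), ev.end % len(rep) + 2, "+")
            else:
                pam = fetch(rep, ev.start - 2, ev.start, "-")
            assert pam == "GG"

    def test_minus_one_slip_puts_g_at_3prime_end(self, refset):
        rng = np.random.default_rng(7)
        config = SimConfig()
        for _ in range(30):
            ev = apply_capture_errors(self._site(refset), config, rng, refset, slip=-1, flipped=False)
            assert ev.spacer_seq[-1] == "G"

    def test_flip_leaves_cc_5prime_of_mapped_protospacer(self, refset):
        rng = np.random.default_rng(8)
        config = SimConfig()
        n_checked = 0
        for _ in range(30):
            ev = apply_capture_errors(self._site(refset), config, rng, refset, slip=0, flipped=True)
            hits = map_spacer(ev.spacer_seq, refset)
            if len(hits) != 1:
                continue
            h = hits[0]
            assert h.flank5[-2:] == "CC"
            assert call_flip(h.spacer_seq, h.flank5)
            n_checked += 1
        assert n_checked > 20


class TestSimulatePopulation:
    def test_no_sources_no_events(self, refset):
        config = SimConfig(n_cells=200, naive_rate=0, priming_rate=0, chrom_event_rate=0)
        assert simulate_population(refset, config).events == []

    def test_forced_single_primed_event_per_cell(self, refset):
        config = SimConfig(
            n_cells=100, priming_rate=1.0, feedback_mean=0.0, chrom_event_rate=0.0
        )
        truth = simulate_population(refset, config)
        cells = truth.cells()
        assert len(cells) == 100
        for chain in cells.values():
            assert len(chain) == 1 and chain[0].mechanism == "primed"

    def test_strand_alternation_through_feedback(self, refset):
        """PS+1 mostly displaced; PS+2, seeded from PS+1, flips back."""
        config = SimConfig(n_cells=4000, seed=13, chrom_event_rate=0.0)
        truth = simulate_population(refset, config)
        tf = truth.as_frame()
        pps = refset.priming_site()
        k1 = tf[tf["k"] == 1]
        k2 = tf[tf["k"] == 2]
        q0 = (k1["strand"] != pps.strand).mean()
        p = sum(config.quadrant_weights[:2])  # displaced quadrants
        se = np.sqrt(p * (1 - p) / len(k1))
        assert abs(q0 - p) <= 3 * se
        assert (k2["strand"] == pps.strand).mean() > 0.5

    def test_canonical_chromosomal_events_are_terminal(self, refset):
        config = SimConfig(n_cells=3000, seed=17, chrom_event_rate=0.2)
        truth = simulate_population(refset, config)
        for chain in truth.cells().values():
            for i, ev in enumerate(chain):
                if ev.mechanism == "chromosomal" and ev.slip_offset == 0 and not ev.flipped:
                    assert i == len(chain) - 1

    def test_determinism_byte_identical(self, refset, tmp_path):
        outs = []
        for run in range(2):
            config = SimConfig(n_cells=150, seed=23)
            truth = simulate_population(refset, config)
            reads = emit_amplicons(truth, refset, config)
            path = tmp_path / f"run{run}.fastq"
            write_fastq(reads, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]


class TestEmitAmplicons:
    def test_last_acquired_is_leader_proximal(self, refset):
        config = SimConfig(n_cells=400, seed=29, feedback_mean=1.0, chrom_event_rate=0.0)
        truth = simulate_population(refset, config)
        reads = dict(emit_amplicons(truth, refset, config))
        multi = next(
            (c, chain) for c, chain in truth.cells().items() if len(chain) >= 2
        )
        cell, chain = multi
        locus = refset.loci[chain[0].locus_id]
        seq = reads[f"cell{cell}_{chain[0].locus_id}"]
        if locus.repeat_seq not in seq:
            seq = revcomp(seq)
        body = seq.split(locus.repeat_seq)
        spacers = [s for s in body[1:] if 20 <= len(s) <= 45]
        # leader-proximal first: highest k first, then down to k=1, then pre-existing
        expected = [e.spacer_seq for e in sorted(chain, key=lambda e: -e.k)]
        assert spacers[: len(expected)] == expected
        assert spacers[len(expected)] == locus.preexisting_spacers[0]

    def test_read_count_equals_cell_locus_pairs(self, refset):
        config = SimConfig(n_cells=500, seed=31)
        truth = simulate_population(refset, config)
        reads = emit_amplicons(truth, refset, config)
        pairs = {(e.cell_id, e.locus_id) for e in truth.events}
        assert len(reads) == len(pairs)

    def test_error_free_round_trip(self, refset):
        from adaptscan.extract import extract_array, orient_read

        config = SimConfig(n_cells=300, seed=37)
        truth = simulate_population(refset, config)
        reads = emit_amplicons(truth, refset, config)
        by_cell = truth.cells()
        for rid, seq in reads:
            cell = truth.read_map[rid]
            locus_id = rid.split("_", 1)[1]
            locus = refset.loci[locus_id]
            oriented, _, ok = orient_read(seq, locus.repeat_seq)
            assert ok
            spacers, malformed = extract_array(oriented, locus.repeat_seq)
            chain = [e for e in by_cell[cell] if e.locus_id == locus_id]
            expected = [e.spacer_seq for e in sorted(chain, key=lambda e: -e.k)]
            expected.append(locus.preexisting_spacers[0])
            assert list(spacers) == expected
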