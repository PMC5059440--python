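"""Generative simulator of type I-F spacer acquisition.

The model: adaptation starts rarely from scratch (naive capture at a GG
PAM anywhere on the plasmid) or, far more often, from an escape-PAM
priming protospacer (PPS). The adaptation complex loads on the displaced
(non-primed) strand of the seeding R-loop and translocates 3'->5',
scanning successive GG sites and capturing a ~32 nt protospacer 5' of a
chosen GG. Every newly integrated spacer whose target has a consensus PAM
is itself interference-proficient and seeds the next capture the same way
— a positive feedback loop in which each event is seeded by the
immediately preceding one, not by the original PPS. Capture is error
prone: the effective PAM window can slip by up to +/-3 nt (minus slips
produce over-long spacers) and the captured duplex can be integrated
flipped, leaving a CC-type motif 5' of the mapped protospacer. Rare
chromosomal captures are terminal for the cell when their PAM is
canonical (self-targeting is lethal), but escape-PAM chromosomal events
let the chain continue.

Slip categories are defined observationally: a slip of ``s`` means the
nearest GG to the emitted protospacer's canonical PAM window sits at
offset ``s``. The simulator therefore samples capture sites conditional
on the drawn category being readable from the emitted sequence context,
so the configured slip distribution is exactly the distribution an
analysis of the emitted reads estimates.
"""

from __future__ import annotations

import dataclasses
import io
from bisect import bisect_left
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .pam import slip_offset_from_context
from .reference import (
    CrisprLocus,
    ReferenceSet,
    Replicon,
    SeedSite,
    fetch,
    fetch_padded,
    scan_motif_sites,
    seed_site_pam,
)

PROTOSPACER_LEN = 32

# quadrant order: (displaced-5', displaced-3', target-5', target-3')
QUADRANTS = (
    ("displaced", "5p"),
    ("displaced", "3p"),
    ("target", "5p"),
    ("target", "3p"),
)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the acquisition model.

    Defaults describe a wild-type priming experiment: ~92% canonical GG
    capture, 32 nt spacers with a ~10% 33 nt minority, locus shares of
    roughly 70/28/2%, first captures biased 5' of the seed on the
    displaced strand (62.5%), and priming >=500-fold more active than
    naive acquisition.
    """

    n_cells: int = 10_000
    locus_weights: dict[str, float] | None = None  # None -> ReferenceSet weights
    p_len33: float = 0.10
    p_len_other: float = 0.005
    other_lengths: tuple[int, ...] = (30, 31, 34, 35)
    minus_slip_lengths: tuple[int, ...] = (33, 34, 35, 36)
    slip_dist: dict[int, float] = dataclasses.field(
        default_factory=lambda: {1: 0.030, -1: 0.025, 2: 0.008, -2: 0.008, 3: 0.005, -3: 0.004}
    )
    p_flip_given_small_slip: float = 0.002
    p_flip_given_big_slip: float = 0.05
    naive_rate: float = 0.001
    priming_rate: float = 0.75
    quadrant_weights: tuple[float, float, float, float] = (0.625, 0.10, 0.15, 0.125)
    translocation_mean: float = 400.0
    feedback_mean: float = 1.5
    feedback_max: int = 6
    chrom_event_rate: float = 0.0005
    at_start_bias: float = 2.0
    locus_per_event: bool = False
    read_error_rate: float = 0.0
    p_reverse_read: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_len33,
            self.p_len_other,
            self.p_flip_given_small_slip,
            self.p_flip_given_big_slip,
            self.naive_rate,
            self.priming_rate,
            self.chrom_event_rate,
            self.read_error_rate,
            self.p_reverse_read,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_len33 + self.p_len_other > 1:
            raise ValueError("length probabilities exceed 1")
        for s, p in self.slip_dist.items():
            if s == 0 or not -3 <= s <= 3:
                raise ValueError(f"slip offsets must be in -3..-1, 1..3; got {s}")
            if not 0 <= p <= 1:
                raise ValueError("slip probabilities must lie in [0, 1]")
        if sum(self.slip_dist.values()) > 1:
            raise ValueError("slip distribution mass exceeds 1")
        if abs(sum(self.quadrant_weights) - 1) > 1e-9:
            raise ValueError("quadrant weights must sum to 1")
        if self.locus_weights is not None:
            if abs(sum(self.locus_weights.values()) - 1) > 1e-9:
                raise ValueError("locus weights must sum to 1")
        if self.translocation_mean <= 0:
            raise ValueError("translocation_mean must be positive")
        if self.at_start_bias < 0:
            raise ValueError("at_start_bias must be non-negative")

    @property
    def p_canonical(self) -> float:
        return 1.0 - sum(self.slip_dist.values())


@dataclasses.dataclass(frozen=True)
class ProtoSite:
    """A candidate capture site: a GG anchor on one strand of a replicon.

    ``anchor`` is the plus-strand coordinate of the GG footprint start
    (for a minus-strand site, the position of the CC on the plus strand).
    """

    replicon_id: str
    anchor: int
    strand: str


@dataclasses.dataclass(frozen=True)
class AcquisitionEvent:
    """One spacer integration, as recorded in the truth log.

    ``start``/``end``/``strand`` give the capture-strand protospacer
    interval (plus-strand coordinates; ``end`` may exceed the replicon
    length for origin-spanning captures). For flipped events the emitted
    spacer is the reverse complement of this interval's sequence, so an
    exact mapper places it on the opposite strand.
    """

    cell_id: int
    k: int
    locus_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    mechanism: str  # {naive, primed, targeted, chromosomal}
    slip_offset: int
    flipped: bool
    spacer_seq: str


@dataclasses.dataclass
class AcquisitionTruth:
    """Ground-truth event log plus the read -> cell map filled at emission."""

    events: list[AcquisitionEvent]
    read_map: dict[str, int] = dataclasses.field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        cols = [
            "cell_id", "k", "locus_id", "replicon_id", "start", "end",
            "strand", "mechanism", "slip_offset", "flipped", "spacer_seq",
        ]
        return pd.DataFrame([dataclasses.asdict(e) for e in self.events], columns=cols)

    def cells(self) -> dict[int, list[AcquisitionEvent]]:
        out: dict[int, list[AcquisitionEvent]] = {}
        for e in self.events:
            out.setdefault(e.cell_id, []).append(e)
        return out


class _SiteIndex:
    """Per-replicon sorted GG anchors and midpoint coordinates per strand."""

    def __init__(self, refset: ReferenceSet):
        self.refset = refset
        self._anchors: dict[tuple[str, str], np.ndarray] = {}
        self._mids: dict[tuple[str, str], np.ndarray] = {}
        self._adj: dict[tuple[str, str], np.ndarray] = {}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        for rep in refset.replicons.values():
            L = len(rep)
            for strand in "+-":
                anchors = np.array(scan_motif_sites(rep, "GG", strand), dtype=np.int64)
                if strand == "+":
                    mids = anchors - PROTOSPACER_LEN // 2
                    adj = np.array([rep.seq[(a - 1) % L] for a in anchors])
                else:
                    mids = anchors + 2 + PROTOSPACER_LEN // 2
                    adj = np.array([comp[rep.seq[(a + 2) % L]] for a in anchors])
                mids = np.mod(mids, L)
                order = np.argsort(mids, kind="stable")
                self._anchors[(rep.id, strand)] = anchors[order]
                self._mids[(rep.id, strand)] = mids[order]
                self._adj[(rep.id, strand)] = (
                    adj[order] if len(anchors) else np.array([], dtype="<U1")
                )

    def anchors(self, replicon_id: str, strand: str) -> np.ndarray:
        return self._anchors[(replicon_id, strand)]

    def midpoints(self, replicon_id: str, strand: str) -> np.ndarray:
        return self._mids[(replicon_id, strand)]

    def adjacent_bases(self, replicon_id: str, strand: str) -> np.ndarray:
        """3'-terminal protospacer base captured at each anchor (site strand)."""
        return self._adj[(replicon_id, strand)]


def _pam_adjacent_base(rep: Replicon, site: ProtoSite) -> str:
    """The base captured at the protospacer's 3' end (immediately 5' of the GG)."""
    if site.strand == "+":
        return fetch_padded(rep, site.anchor - 1, site.anchor, "+")
    return fetch_padded(rep, site.anchor + 2, site.anchor + 3, "-")


def sample_naive_site(
    refset: ReferenceSet,
    rng: np.random.Generator,
    replicon_id: str | None = None,
    weights: np.ndarray | None = None,
    at_start_bias: float = 1.0,
    index: _SiteIndex | None = None,
) -> ProtoSite:
    """Sample a naive capture site: a GG anchor on either strand.

    ``weights`` is an optional per-position hotspot profile over the
    replicon (uniform by default). ``at_start_bias`` multiplies the weight
    of sites whose captured 3'-terminal protospacer base (the base
    immediately 5' of the GG on the site strand) is A or T.
    """
    if replicon_id is None:
        plasmids = refset.replicons_by_role("plasmid")
        if not plasmids:
            raise ValueError("reference set has no plasmid replicon")
        replicon_id = plasmids[0].id
    rep = refset.replicons[replicon_id]
    index = index or _SiteIndex(refset)
    anchors_p = index.anchors(replicon_id, "+")
    anchors_m = index.anchors(replicon_id, "-")
    n_p, n_m = len(anchors_p), len(anchors_m)
    if n_p + n_m == 0:
        raise ValueError(f"no GG sites on replicon {replicon_id!r}")
    anchors = np.concatenate([anchors_p, anchors_m])
    strands = np.array(["+"] * n_p + ["-"] * n_m)
    w = np.ones(len(anchors))
    if weights is not None:
        w *= np.asarray(weights, dtype=float)[anchors]
    if at_start_bias != 1.0:
        adj = np.concatenate(
            [index.adjacent_bases(replicon_id, "+"), index.adjacent_bases(replicon_id, "-")]
        )
        w *= np.where(np.isin(adj, ["A", "T"]), at_start_bias, 1.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("site weights sum to zero")
    i = rng.choice(len(anchors), p=w / total)
    return ProtoSite(replicon_id, int(anchors[i]), str(strands[i]))


def _seed_frame(seed) -> tuple[str, int, int, str]:
    """Normalise a SeedSite or previous AcquisitionEvent to (replicon, start, end, strand)."""
    return seed.replicon_id, seed.start, seed.end, seed.strand


def sample_seeded_site(
    seed,
    config: SimConfig,
    rng: np.random.Generator,
    refset: ReferenceSet,
    index: _SiteIndex | None = None,
) -> ProtoSite:
    """Sample a capture site seeded by an existing target (priming/targeted).

    One of four quadrants is drawn by ``quadrant_weights``: the new site
    lies on the displaced strand (opposite the seed protospacer's strand)
    or the target strand, and 5' or 3' of the seed as read on the NEW
    protospacer's strand. The complex then hops successive GG sites away
    from the seed midpoint, capturing after a geometric translocation
    distance with mean ``translocation_mean`` nt (shortest arc on circular
    replicons; a walk off a linear replicon end resamples the quadrant).
    """
    rid, s_start, s_end, s_strand = _seed_frame(seed)
    rep = refset.replicons[rid]
    index = index or _SiteIndex(refset)
    L = len(rep)
    seed_mid = ((s_start + s_end) / 2.0) % L
    at_bias = config.at_start_bias

    for _ in range(1000):
        q = rng.choice(4, p=np.asarray(config.quadrant_weights))
        strand_kind, side = QUADRANTS[q]
        new_strand = (
            ("-" if s_strand == "+" else "+") if strand_kind == "displaced" else s_strand
        )
        # 5' on + strand is decreasing coordinate; on - strand increasing.
        direction = -1 if (new_strand == "+") == (side == "5p") else 1
        mids = index.midpoints(rid, new_strand)
        anchors = index.anchors(rid, new_strand)
        adj = index.adjacent_bases(rid, new_strand)
        if len(mids) == 0:
            continue
        if rep.topology == "circular":
            delta = np.mod((mids - seed_mid) * direction, L)
            ok = (delta > 0) & (delta < L / 2)  # shortest-arc quadrant; antipode excluded
        else:
            delta = (mids - seed_mid) * direction
            ok = delta > 0
        if not ok.any():
            continue  # walk off a linear end (or empty direction): resample quadrant
        cand_delta = delta[ok]
        cand_anchor = anchors[ok]
        cand_adj = adj[ok]
        order = np.argsort(cand_delta, kind="stable")
        cand_anchor = cand_anchor[order]
        cand_adj = cand_adj[order]
        # Per-site Bernoulli capture: geometric in hops, with the base
        # rate calibrated so the mean travel is ~translocation_mean nt,
        # and the A/T 3'-end preference modulating each site locally.
        w = np.where(np.isin(cand_adj, ("A", "T")), at_bias, 1.0)
        adj_all = index.adjacent_bases(rid, new_strand)
        frac_at = float(np.isin(adj_all, ("A", "T")).mean())
        w_mean = frac_at * at_bias + (1.0 - frac_at)
        spacing = L / max(1, len(mids))
        p = np.minimum(1.0, (spacing / config.translocation_mean) * w / w_mean)
        capture = rng.random(len(p)) < p
        if capture.any():
            i = int(np.argmax(capture))
            return ProtoSite(rid, int(cand_anchor[i]), new_strand)
        # walked the whole arc without capturing: resample the quadrant
    raise RuntimeError("seeded site sampling failed to converge")


def _draw_length(config: SimConfig, slip: int, rng: np.random.Generator) -> int:
    if slip < 0:
        return int(rng.choice(config.minus_slip_lengths))
    u = rng.random()
    if u < config.p_len33:
        return 33
    if u < config.p_len33 + config.p_len_other:
        return int(rng.choice(config.other_lengths))
    return 32


def _draw_slip_flip(config: SimConfig, rng: np.random.Generator) -> tuple[int, bool]:
    offsets = list(config.slip_dist)
    probs = [config.slip_dist[s] for s in offsets]
    u = rng.random()
    acc, slip = 0.0, 0
    for s, p in zip(offsets, probs):
        acc += p
        if u < acc:
            slip = s
            break
    p_flip = (
        config.p_flip_given_big_slip if abs(slip) >= 2 else config.p_flip_given_small_slip
    )
    return slip, rng.random() < p_flip


def protospacer_interval(site: ProtoSite, slip: int, length: int, L: int) -> tuple[int, int]:
    """Capture-strand interval [start, end) for a site, slip and length.

    A positive slip moves the effective PAM distal (3' of the canonical
    window); a negative slip moves it proximal, extending the protospacer
    into the GG itself. ``end`` may exceed L (origin wrap).
    """
    if site.strand == "+":
        end = site.anchor - slip
        start = end - length
    else:
        start = site.anchor + 2 + slip
        end = start + length
    start_mod = start % L
    return start_mod, start_mod + length


def apply_capture_errors(
    site: ProtoSite,
    config: SimConfig,
    rng: np.random.Generator,
    refset: ReferenceSet,
    slip: int | None = None,
    flipped: bool | None = None,
    length: int | None = None,
) -> AcquisitionEvent:
    """Realise a capture at a GG-anchored site, applying slip/flip/length errors.

    ``slip``/``flipped``/``length`` may be forced for testing; otherwise
    they are drawn from the configured distributions. Cell/order/locus
    fields are filled by the population simulator and default to 0/"".
    """
    rep = refset.replicons[site.replicon_id]
    if slip is None or flipped is None:
        s, f = _draw_slip_flip(config, rng)
        slip = s if slip is None else slip
        flipped = f if flipped is None else flipped
    if length is None:
        length = _draw_length(config, slip, rng)
    start, end = protospacer_interval(site, slip, length, len(rep))
    captured = fetch(rep, start, end, site.strand)
    spacer = revcomp(captured) if flipped else captured
    return AcquisitionEvent(
        cell_id=0,
        k=0,
        locus_id="",
        replicon_id=site.replicon_id,
        start=start,
        end=end,
        strand=site.strand,
        mechanism="naive",
        slip_offset=slip,
        flipped=flipped,
        spacer_seq=spacer,
    )


def _observable_slip(event: AcquisitionEvent, refset: ReferenceSet) -> int | None:
    """Slip offset an exact-mapping analysis would call on the capture strand."""
    rep = refset.replicons[event.replicon_id]
    captured = fetch(rep, event.start, event.end, event.strand)
    tail3 = captured[-3:]
    if event.strand == "+":
        e = event.end % len(rep)
        flank3 = fetch_padded(rep, e, e + 5, "+")
    else:
        flank3 = fetch_padded(rep, event.start - 5, event.start, "-")
    return slip_offset_from_context(tail3, flank3)


def _make_event(
    sampler: Callable[[], ProtoSite],
    config: SimConfig,
    rng: np.random.Generator,
    refset: ReferenceSet,
    mechanism: str,
    max_tries: int = 200,
) -> AcquisitionEvent:
    """Draw an event whose emitted context reads back as its drawn slip.

    The slip category and flip flag are drawn once; capture sites are then
    resampled until the context is compatible (so the emitted population
    follows ``slip_dist`` exactly). Flipped captures skip the check: their
    slip is unobservable after reorientation, matching the analysis-side
    exclusion of flip candidates from slip statistics.
    """
    slip, flipped = _draw_slip_flip(config, rng)
    length = _draw_length(config, slip, rng)
    event = None
    for _ in range(max_tries):
        site = sampler()
        event = apply_capture_errors(
            site, config, rng, refset, slip=slip, flipped=flipped, length=length
        )
        if flipped or _observable_slip(event, refset) == slip:
            break
    return dataclasses.replace(event, mechanism=mechanism)


def _draw_feedback_count(config: SimConfig, rng: np.random.Generator) -> int:
    """Number of additional targeted events: truncated geometric, mean ~feedback_mean."""
    if config.feedback_mean <= 0:
        return 0
    p = 1.0 / (1.0 + config.feedback_mean)
    n = int(rng.geometric(p)) - 1  # support 0,1,2,...
    return min(n, config.feedback_max)


def simulate_population(refset: ReferenceSet, config: SimConfig) -> AcquisitionTruth:
    """Simulate spacer acquisition across a population of cells.

    Per cell: with ``priming_rate`` (given a priming/targeted seed site in
    the reference) a chain starts at the seed; otherwise with
    ``naive_rate`` a chain starts at a naive plasmid site. Every
    subsequent event is seeded by the immediately preceding event
    (targeted feedback); the chain length follows ``feedback_mean``. With
    ``chrom_event_rate`` a chromosomal capture is appended; if its PAM is
    canonical the cell acquires nothing further (self-targeting is
    terminal), otherwise targeted feedback from the last plasmid event may
    continue.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    index = _SiteIndex(refset)
    locus_ids = list(refset.loci)
    lw = config.locus_weights or refset.locus_weights
    locus_p = np.array([lw[l] for l in locus_ids], dtype=float)
    locus_p = locus_p / locus_p.sum()

    seed_site = refset.priming_site() or refset.targeted_site()
    chromosomes = refset.replicons_by_role("chromosome")
    plasmids = refset.replicons_by_role("plasmid")

    events: list[AcquisitionEvent] = []
    for cell in range(config.n_cells):
        chain: list[AcquisitionEvent] = []
        primed = seed_site is not None and rng.random() < config.priming_rate
        naive = not primed and plasmids and rng.random() < config.naive_rate
        if primed:
            first_mech = "primed" if seed_site.kind == "priming" else "targeted"
            sampler = lambda: sample_seeded_site(seed_site, config, rng, refset, index)
            chain.append(_make_event(sampler, config, rng, refset, first_mech))
        elif naive:
            sampler = lambda: sample_naive_site(
                refset, rng, plasmids[0].id, at_start_bias=config.at_start_bias, index=index
            )
            chain.append(_make_event(sampler, config, rng, refset, "naive"))

        if chain:
            for _ in range(_draw_feedback_count(config, rng)):
                prev = chain[-1]
                sampler = lambda: sample_seeded_site(prev, config, rng, refset, index)
                chain.append(_make_event(sampler, config, rng, refset, "targeted"))

        if chromosomes and rng.random() < config.chrom_event_rate:
            chrom = chromosomes[0]
            sampler = lambda: sample_naive_site(
                refset, rng, chrom.id, at_start_bias=config.at_start_bias, index=index
            )
            chrom_event = _make_event(sampler, config, rng, refset, "chromosomal")
            chain.append(chrom_event)
            escaped = chrom_event.slip_offset != 0 or chrom_event.flipped
            if escaped and len(chain) > 1:
                for _ in range(_draw_feedback_count(config, rng)):
                    prev = next(e for e in reversed(chain) if e.mechanism != "chromosomal")
                    sampler = lambda: sample_seeded_site(prev, config, rng, refset, index)
                    chain.append(_make_event(sampler, config, rng, refset, "targeted"))

        # One array receives the whole chain by default, so array order
        # equals acquisition order; per-event assignment spreads a chain
        # across loci, diluting order statistics (available as an option).
        cell_locus = locus_ids[rng.choice(len(locus_ids), p=locus_p)] if chain else None
        for k, ev in enumerate(chain, start=1):
            if config.locus_per_event:
                locus = locus_ids[rng.choice(len(locus_ids), p=locus_p)]
            else:
                locus = cell_locus
            events.append(
                dataclasses.replace(ev, cell_id=cell, k=k, locus_id=locus)
            )
    return AcquisitionTruth(events=events)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def emit_amplicons(
    truth: AcquisitionTruth,
    refset: ReferenceSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Emit one merged amplicon read per (cell, locus) with >=1 new spacer.

    Read layout, 5'->3' on the leader strand: locus barcode, leader tail,
    then (repeat + spacer) for each new spacer with the LAST-acquired
    event leader-proximal, then repeat + first pre-existing spacer +
    repeat + the 3' primer tag (annealing in the second pre-existing
    spacer). Reads are emitted in a random orientation with probability
    ``p_reverse_read`` and with optional per-base substitution noise.
    Returns (read_id, sequence) pairs and fills ``truth.read_map``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    reads: list[tuple[str, str]] = []
    for cell_id, chain in truth.cells().items():
        by_locus: dict[str, list[AcquisitionEvent]] = {}
        for ev in chain:
            by_locus.setdefault(ev.locus_id, []).append(ev)
        for locus_id, evs in by_locus.items():
            locus = refset.loci[locus_id]
            parts = [locus.leader_barcode, locus.leader_tail]
            for ev in sorted(evs, key=lambda e: e.k, reverse=True):
                parts.append(locus.repeat_seq)
                parts.append(ev.spacer_seq)
            parts.append(locus.repeat_seq)
            if locus.preexisting_spacers:
                parts.append(locus.preexisting_spacers[0])
                parts.append(locus.repeat_seq)
            parts.append(locus.primer3_tag)
            seq = _mutate("".join(parts), config.read_error_rate, rng)
            if rng.random() < config.p_reverse_read:
                seq = revcomp(seq)
            read_id = f"cell{cell_id}_{locus_id}"
            reads.append((read_id, seq))
            truth.read_map[read_id] = cell_id
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: AcquisitionTruth, path) -> None:
    truth.as_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Default synthetic reference


_REPEAT = "GTTCACTGCCGTGTAGGCAGCTAAGAAA"  # 28 nt, type I-F style repeat

_LOCUS_META = {
    "CRISPR1": {"barcode": "ACGTCA", "weight": 0.70},
    "CRISPR2": {"barcode": "GTACAG", "weight": 0.28},
    "CRISPR3": {"barcode": "TCAGTC", "weight": 0.02},
}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def default_reference(
    seed: int = 0,
    plasmid_len: int = 8_000,
    chrom_len: int = 40_000,
    seed_kind: str = "priming",
) -> ReferenceSet:
    """Build the default synthetic reference: one plasmid, one chromosome.

    The plasmid is circular with a 32 nt seed protospacer on the minus
    strand; its PAM is forced to the escape dinucleotide TG for
    ``seed_kind='priming'`` and to the consensus GG for
    ``seed_kind='targeted'``. ``seed_kind='naive'`` omits the seed site
    entirely. Three CRISPR loci share a repeat and carry two pre-existing
    spacers each.
    """
    rng = np.random.default_rng(seed)
    plasmid_seq = list(_random_dna(rng, plasmid_len))
    pps_start, pps_end = plasmid_len // 2, plasmid_len // 2 + 32
    if seed_kind in ("priming", "targeted"):
        pam = "TG" if seed_kind == "priming" else "GG"
        # minus-strand PAM sits immediately below the interval on the plus strand
        plasmid_seq[pps_start - 2 : pps_start] = revcomp(pam)
    plasmid = Replicon("plasmid", "".join(plasmid_seq), "circular", "plasmid")
    chrom = Replicon("chromosome", _random_dna(rng, chrom_len), "circular", "chromosome")

    loci = {}
    for lid, meta in _LOCUS_META.items():
        pre = tuple(_random_dna(rng, 32) for _ in range(2))
        loci[lid] = CrisprLocus(
            id=lid,
            repeat_seq=_REPEAT,
            leader_barcode=meta["barcode"],
            preexisting_spacers=pre,
            incorporation_weight=meta["weight"],
            leader_tail=_random_dna(rng, 15),
            primer3_tag=pre[1][:12],
        )

    seeds = []
    if seed_kind in ("priming", "targeted"):
        seeds.append(
            SeedSite(
                replicon_id="plasmid",
                start=pps_start,
                end=pps_end,
                strand="-",
                pam=seed_site_pam(plasmid, pps_start, pps_end, "-"),
                kind=seed_kind,
            )
        )
    return ReferenceSet(
        replicons={"plasmid": plasmid, "chromosome": chrom},
        loci=loci,
        seed_sites=seeds,
    )
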