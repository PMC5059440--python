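"""Reference replicons, CRISPR locus definitions and seed (priming) sites.

Coordinates are 0-based, half-open on the plus strand throughout the
package. Circular replicons allow intervals with ``end > len(seq)``, which
wrap across the origin; negative coordinates are never used. A
protospacer's strand is the strand whose 5'->3' sequence is identical to
the spacer stored in the array, and its PAM is the dinucleotide
immediately 3' of the protospacer on that strand.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

from ._seq import is_dna, revcomp


@dataclasses.dataclass(frozen=True)
class Replicon:
    """A named reference sequence with topology and biological role."""

    id: str
    seq: str
    topology: str = "circular"  # {"circular", "linear"}
    role: str = "plasmid"  # {"plasmid", "chromosome"}

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        if not is_dna(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"replicon {self.id!r}: non-DNA characters {bad}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        if self.role not in ("plasmid", "chromosome"):
            raise ValueError(f"replicon {self.id!r}: bad role {self.role!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class CrisprLocus:
    """One CRISPR array: repeat, leader-side primer barcode, pre-existing spacers.

    ``preexisting_spacers`` are ordered leader-proximal first, matching the
    order in which they appear in an amplicon read. ``incorporation_weight``
    is the locus' share of new integrations (weights are normalised over
    loci when a ReferenceSet is assembled).
    """

    id: str
    repeat_seq: str
    leader_barcode: str
    preexisting_spacers: tuple[str, ...]
    incorporation_weight: float = 1.0
    leader_tail: str = ""
    primer3_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeat_seq", self.repeat_seq.upper())
        object.__setattr__(
            self, "preexisting_spacers", tuple(s.upper() for s in self.preexisting_spacers)
        )
        if len(self.repeat_seq) < 20:
            raise ValueError(f"locus {self.id!r}: repeat shorter than 20 nt")
        if self.incorporation_weight < 0:
            raise ValueError(f"locus {self.id!r}: negative incorporation weight")


@dataclasses.dataclass(frozen=True)
class SeedSite:
    """A protospacer that seeds adaptation (priming or interference-driven).

    ``pam`` is read from the reference immediately 3' of the interval on the
    protospacer strand at load time. ``kind`` distinguishes an escape-PAM
    priming protospacer from an interference-proficient (consensus-PAM)
    target.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    pam: str = ""
    kind: str = "priming"  # {"priming", "targeted"}

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"seed site strand must be + or -, got {self.strand!r}")
        if self.kind not in ("priming", "targeted"):
            raise ValueError(f"bad seed site kind {self.kind!r}")
        if self.end - self.start not in (32, 33):
            raise ValueError(
                f"seed site length {self.end - self.start} nt; expected 32 or 33"
            )


def fetch(replicon: Replicon, start: int, end: int, strand: str = "+") -> str:
    """Extract ``[start, end)`` from a replicon, circular-aware.

    On circular replicons ``end`` may exceed the sequence length and wraps
    across the origin; ``strand == '-'`` returns the reverse complement of
    the plus-strand extraction.
    """
    L = len(replicon)
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    if not 0 <= start < L and not (start == end == 0):
        raise ValueError(f"start {start} outside [0, {L})")
    if replicon.topology == "linear":
        if end > L:
            raise ValueError(
                f"interval [{start}, {end}) exceeds linear replicon {replicon.id!r} (L={L})"
            )
        s = replicon.seq[start:end]
    else:
        if end - start > L:
            raise ValueError(f"interval longer than replicon (L={L})")
        if end <= L:
            s = replicon.seq[start:end]
        else:
            s = replicon.seq[start:] + replicon.seq[: end - L]
    return revcomp(s) if strand == "-" else s


def fetch_padded(replicon: Replicon, start: int, end: int, strand: str = "+") -> str:
    """Like :func:`fetch` but tolerant of out-of-range flank coordinates.

    Circular replicons normalise ``start`` modulo L; linear replicons pad
    positions outside ``[0, L)`` with ``N``. Used to read fixed-width flanks
    next to protospacers at replicon edges.
    """
    L = len(replicon)
    if replicon.topology == "circular":
        shift = start % L
        return fetch(replicon, shift, shift + (end - start), strand)
    left_pad = max(0, -start)
    right_pad = max(0, end - L)
    s = "N" * left_pad + replicon.seq[max(0, start) : min(L, end)] + "N" * right_pad
    return revcomp(s) if strand == "-" else s


def scan_motif_sites(replicon: Replicon, motif: str, strand: str = "+") -> list[int]:
    """All start positions (plus-strand coordinates) of a motif, overlaps included.

    A minus-strand occurrence at position ``p`` means the minus-strand read
    of ``[p, p + len(motif))`` equals the motif, i.e. the plus strand
    carries its reverse complement there. Circular occurrences spanning the
    origin are included; N never matches.
    """
    motif = motif.upper()
    if not set(motif) <= set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    target = motif if strand == "+" else revcomp(motif)
    L = len(replicon)
    haystack = replicon.seq
    if replicon.topology == "circular" and len(motif) > 1:
        haystack = haystack + replicon.seq[: len(motif) - 1]
    positions = []
    i = haystack.find(target)
    while i != -1:
        if i < L:
            positions.append(i)
        i = haystack.find(target, i + 1)
    return positions


@dataclasses.dataclass
class ReferenceSet:
    """Replicons plus CRISPR locus definitions and seed sites."""

    replicons: dict[str, Replicon]
    loci: dict[str, CrisprLocus]
    seed_sites: list[SeedSite]

    def __post_init__(self) -> None:
        total = sum(l.incorporation_weight for l in self.loci.values())
        if self.loci and total <= 0:
            raise ValueError("locus incorporation weights sum to zero")
        if self.loci:
            self.loci = {
                lid: dataclasses.replace(l, incorporation_weight=l.incorporation_weight / total)
                for lid, l in self.loci.items()
            }
        for site in self.seed_sites:
            if site.replicon_id not in self.replicons:
                raise ValueError(f"seed site references unknown replicon {site.replicon_id!r}")

    @property
    def locus_weights(self) -> dict[str, float]:
        return {lid: l.incorporation_weight for lid, l in self.loci.items()}

    def replicons_by_role(self, role: str) -> list[Replicon]:
        return [r for r in self.replicons.values() if r.role == role]

    def priming_site(self) -> SeedSite | None:
        for s in self.seed_sites:
            if s.kind == "priming":
                return s
        return None

    def targeted_site(self) -> SeedSite | None:
        for s in self.seed_sites:
            if s.kind == "targeted":
                return s
        return None


def seed_site_pam(replicon: Replicon, start: int, end: int, strand: str) -> str:
    """Dinucleotide immediately 3' of a protospacer on its own strand."""
    if strand == "+":
        return fetch_padded(replicon, end, end + 2, "+")
    return fetch_padded(replicon, start - 2, start, "-")


def _resolve_seed(entry: Mapping, replicons: dict[str, Replicon]) -> SeedSite:
    rid = entry["replicon"]
    if rid not in replicons:
        raise ValueError(f"seed site references unknown replicon {rid!r}")
    rep = replicons[rid]
    start, end = int(entry["start"]), int(entry["end"])
    L = len(rep)
    if start > end:
        if rep.topology != "circular":
            raise ValueError("start > end only valid on circular replicons (origin wrap)")
        end += L
    if not 0 <= start < L:
        raise ValueError(f"seed site start {start} outside replicon {rid!r}")
    if rep.topology == "linear" and end > L:
        raise ValueError(f"seed site end {end} beyond linear replicon {rid!r} (L={L})")
    strand = entry["strand"]
    pam = seed_site_pam(rep, start, end, strand)
    return SeedSite(
        replicon_id=rid,
        start=start,
        end=end,
        strand=strand,
        pam=pam,
        kind=entry.get("kind", "priming"),
    )


def load_references(fasta_source, locus_config) -> ReferenceSet:
    """Assemble a ReferenceSet from a FASTA file and a locus/seed config.

    Parameters
    ----------
    fasta_source : path or file-like
        Multi-record FASTA with one record per replicon.
    locus_config : mapping or path
        Mapping (or path to a YAML file) with keys ``replicons``
        (id -> topology/role), ``loci`` (repeat, barcode, pre-existing
        spacers, weight) and optional ``seed_sites``.
    """
    if isinstance(locus_config, (str, Path)):
        with open(locus_config) as fh:
            locus_config = yaml.safe_load(fh)

    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_source, "fasta")}
    replicons: dict[str, Replicon] = {}
    for rid, meta in locus_config.get("replicons", {}).items():
        if rid not in records:
            raise ValueError(f"config names replicon {rid!r} absent from FASTA")
        replicons[rid] = Replicon(
            id=rid,
            seq=records[rid],
            topology=meta.get("topology", "circular"),
            role=meta.get("role", "plasmid"),
        )

    loci: dict[str, CrisprLocus] = {}
    for lid, meta in locus_config.get("loci", {}).items():
        loci[lid] = CrisprLocus(
            id=lid,
            repeat_seq=meta["repeat"],
            leader_barcode=meta["barcode"].upper(),
            preexisting_spacers=tuple(meta.get("preexisting_spacers", ())),
            incorporation_weight=float(meta.get("weight", 1.0)),
            leader_tail=meta.get("leader_tail", "").upper(),
            primer3_tag=meta.get("primer3_tag", "").upper(),
        )

    seeds = [_resolve_seed(e, replicons) for e in locus_config.get("seed_sites", [])]
    return ReferenceSet(replicons=replicons, loci=loci, seed_sites=seeds)
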