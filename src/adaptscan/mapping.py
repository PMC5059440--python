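"""Exact protospacer mapping with strand, flank and PAM annotation.

Spacers are located by exact string search on both strands of every
replicon, circular-aware (matches spanning the origin are found by
searching a doubled sequence). Flanks are always read from the reference
on the protospacer strand, 5 nt to each side — wide enough to cover the
+/-3 nt slip window with context. A spacer hitting no replicon is
'unknown'; one hitting several locations is returned in full but flagged
'ambiguous' and excluded from positional statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from ._seq import revcomp
from .reference import ReferenceSet, Replicon, fetch_padded


@dataclasses.dataclass(frozen=True)
class ProtospacerHit:
    """A spacer's mapped location with strand-aware flanks and PAM."""

    spacer_seq: str
    replicon_id: str
    start: int  # 0-based half-open, plus-strand coordinates
    end: int  # may exceed replicon length for origin-spanning hits
    strand: str
    flank5: str
    flank3: str
    pam: str
    target_class: str  # {plasmid, chromosome, unknown, ambiguous}

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def coord_key(self) -> tuple[str, int, int, str]:
        return (self.replicon_id, self.start, self.end, self.strand)


def _search_plus(rep: Replicon, query: str) -> list[int]:
    """Plus-strand start positions of exact matches, origin wrap included."""
    L = len(rep)
    haystack = rep.seq
    if rep.topology == "circular" and len(query) > 1:
        haystack = haystack + rep.seq[: len(query) - 1]
    out = []
    i = haystack.find(query)
    while i != -1:
        if i < L:
            out.append(i)
        i = haystack.find(query, i + 1)
    return out


def _make_hit(rep: Replicon, spacer: str, start: int, strand: str, target_class: str) -> ProtospacerHit:
    end = start + len(spacer)
    if strand == "+":
        flank5 = fetch_padded(rep, start - 5, start, "+")
        flank3 = fetch_padded(rep, end, end + 5, "+")
    else:
        flank5 = fetch_padded(rep, end, end + 5, "-")
        flank3 = fetch_padded(rep, start - 5, start, "-")
    return ProtospacerHit(
        spacer_seq=spacer,
        replicon_id=rep.id,
        start=start,
        end=end,
        strand=strand,
        flank5=flank5,
        flank3=flank3,
        pam=flank3[:2],
        target_class=target_class,
    )


def map_spacer(spacer: str, refset: ReferenceSet) -> list[ProtospacerHit]:
    """All exact occurrences of a spacer on both strands of all replicons.

    Zero hits yield an empty list (the spacer is 'unknown'); multiple hits
    are all returned with ``target_class='ambiguous'``.
    """
    spacer = spacer.upper()
    hits: list[ProtospacerHit] = []
    for rep in refset.replicons.values():
        for start in _search_plus(rep, spacer):
            hits.append(_make_hit(rep, spacer, start, "+", rep.role))
        for start in _search_plus(rep, revcomp(spacer)):
            hits.append(_make_hit(rep, spacer, start, "-", rep.role))
    if len(hits) > 1:
        hits = [dataclasses.replace(h, target_class="ambiguous") for h in hits]
    return hits


def unique_protospacer_count(hits: Iterable[ProtospacerHit]) -> int:
    """Distinct (replicon, start, end, strand) tuples; read counts ignored."""
    return len({h.coord_key() for h in hits})


def classify_targets(per_spacer_hits: dict[str, list[ProtospacerHit]]) -> pd.Series:
    """Per-spacer target class: plasmid, chromosome, unknown or ambiguous.

    A spacer hitting replicons of more than one role — or more than one
    location — is ambiguous and excluded from plasmid/chromosome tallies.
    """
    classes = {}
    for spacer, hits in per_spacer_hits.items():
        if not hits:
            classes[spacer] = "unknown"
        elif len(hits) == 1:
            classes[spacer] = hits[0].target_class
        else:
            classes[spacer] = "ambiguous"
    return pd.Series(classes, dtype=object)


def build_spacer_table(
    arrays,
    refset: ReferenceSet,
    mapping: dict[str, list[ProtospacerHit]] | None = None,
) -> pd.DataFrame:
    """Per-spacer annotation table: one row per spacer occurrence per array.

    Columns cover the array context (array id, locus, position, S-number,
    read count) and, for uniquely mapped spacers, the protospacer location,
    strand, flanks and PAM. Unmapped spacers keep their order index with
    null location fields.
    """
    from .extract import s_number

    if mapping is None:
        all_spacers = {s for rec in arrays for s in rec.spacers}
        mapping = {s: map_spacer(s, refset) for s in all_spacers}

    rows = []
    for rec in arrays:
        for pos, spacer in enumerate(rec.spacers):
            is_new = pos in rec.new_spacer_indices
            hits = mapping.get(spacer, [])
            if not hits:
                cls = "unknown"
            elif len(hits) > 1:
                cls = "ambiguous"
            else:
                cls = hits[0].target_class
            hit = hits[0] if len(hits) == 1 else None
            rows.append(
                {
                    "array_id": rec.array_id,
                    "sample_id": rec.sample_id,
                    "locus_id": rec.locus_id,
                    "read_count": rec.read_count,
                    "position": pos,
                    "is_new": is_new,
                    "s_number": s_number(rec, pos) if (is_new and not rec.anomalous) else None,
                    "anomalous": rec.anomalous,
                    "spacer_seq": spacer,
                    "spacer_len": len(spacer),
                    "target_class": cls,
                    "replicon_id": hit.replicon_id if hit else None,
                    "start": hit.start if hit else None,
                    "end": hit.end if hit else None,
                    "strand": hit.strand if hit else None,
                    "flank5": hit.flank5 if hit else None,
                    "flank3": hit.flank3 if hit else None,
                    "pam": hit.pam if hit else None,
                }
            )
    table = pd.DataFrame(rows)
    for col in ("position", "start", "end", "spacer_len", "s_number"):
        if col in table:
            table[col] = table[col].astype("Int64")
    return table


def hits_to_bed(hits: Sequence[ProtospacerHit], weights: Sequence[int] | None = None) -> pd.DataFrame:
    """BED-like protospacer track: replicon, start, end, name, score, strand."""
    if weights is None:
        weights = [1] * len(hits)
    return pd.DataFrame(
        {
            "chrom": [h.replicon_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [h.spacer_seq for h in hits],
            "score": list(weights),
            "strand": [h.strand for h in hits],
        }
    )
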