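"""End-to-end driver: reads -> arrays -> mapped, annotated spacer table."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .extract import ArrayRecord, ExtractionStats, demultiplex, extract_arrays
from .mapping import ProtospacerHit, build_spacer_table, map_spacer
from .pam import annotate_calls
from .reference import ReferenceSet


@dataclasses.dataclass
class PipelineResult:
    arrays: list[ArrayRecord]
    spacer_table: pd.DataFrame
    mapping: dict[str, list[ProtospacerHit]]
    stats: dict[str, ExtractionStats]
    reads_in: int
    reads_rejected: int


def barcode_table_from_loci(refset: ReferenceSet, sample_id: str = "sample") -> dict:
    """(sample, locus) -> (5' barcode, 3' primer tag) from locus definitions."""
    return {
        (sample_id, lid): (locus.leader_barcode, locus.primer3_tag)
        for lid, locus in refset.loci.items()
    }


def run_pipeline(
    reads: Sequence[tuple[str, str]],
    refset: ReferenceSet,
    sample_id: str = "sample",
    max_mismatch: int = 3,
) -> PipelineResult:
    """Demultiplex, orient, dereplicate, extract and map a read set.

    Reads are assigned to loci by exact terminal tags, oriented with the
    locus repeat, dereplicated at 100% identity, split into spacers, and
    every spacer is exact-mapped against the reference. The returned
    spacer table carries one row per spacer per array with location,
    flank and PAM-call annotation.
    """
    table = barcode_table_from_loci(refset, sample_id)
    assigned, rejected = demultiplex(reads, table)
    arrays: list[ArrayRecord] = []
    stats: dict[str, ExtractionStats] = {}
    for (sample, lid), locus_reads in assigned.items():
        recs, st = extract_arrays(
            locus_reads, refset.loci[lid], sample_id=sample, max_mismatch=max_mismatch
        )
        arrays.extend(recs)
        stats[lid] = st

    all_spacers = {s for rec in arrays for s in rec.spacers}
    mapping = {s: map_spacer(s, refset) for s in sorted(all_spacers)}
    spacer_table = build_spacer_table(arrays, refset, mapping)
    if len(spacer_table):
        mapped = spacer_table["flank3"].notna()
        if mapped.any():
            annotated = annotate_calls(spacer_table.loc[mapped])
            for col in ("pam_category", "slip_offset", "other", "flip_candidate"):
                spacer_table[col] = annotated[col]
    return PipelineResult(
        arrays=arrays,
        spacer_table=spacer_table,
        mapping=mapping,
        stats=stats,
        reads_in=len(reads),
        reads_rejected=rejected,
    )


def locus_spacer_counts(spacer_table: pd.DataFrame, new_only: bool = True) -> dict[str, int]:
    """Read-weighted spacer counts per locus (new spacers by default)."""
    t = spacer_table.loc[spacer_table["is_new"]] if new_only else spacer_table
    return t.groupby("locus_id")["read_count"].sum().astype(int).to_dict()


def target_class_counts(spacer_table: pd.DataFrame, new_only: bool = True) -> dict[str, int]:
    """Read-weighted spacer counts per target class (new spacers by default)."""
    t = spacer_table.loc[spacer_table["is_new"]] if new_only else spacer_table
    return t.groupby("target_class")["read_count"].sum().astype(int).to_dict()
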