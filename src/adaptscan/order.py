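"""Acquisition-order statistics: PS+k, strand bias, signed travel distances.

The k-th spacer acquired by an array is S+k (S+1 earliest, most
leader-distal among the new spacers); its mapped protospacer is PS+k. A
"travel" between two protospacers is the shortest-arc separation of
their anchors, signed positive when the second protospacer lies in the
5' direction evaluated on the second protospacer's strand (on the plus
strand 5' means decreasing coordinate; on the minus strand increasing).
Heatmaps and fractions are weighted by dereplicated read counts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import ProtospacerHit
from .reference import ReferenceSet


@dataclasses.dataclass(frozen=True)
class OrderedHit:
    """A mapped protospacer with its acquisition order within an array.

    ``hit`` is None for spacers that held an order index but could not be
    mapped uniquely; they keep their k so later orders are not renumbered,
    and are skipped by positional statistics.
    """

    array_id: str
    k: int
    hit: ProtospacerHit | None
    read_count: int


def order_hits(arrays, mapping: dict[str, list[ProtospacerHit]]) -> list[OrderedHit]:
    """PS+k assignment for every new spacer of every non-anomalous array."""
    from .extract import s_number

    out: list[OrderedHit] = []
    for rec in arrays:
        if rec.anomalous:
            continue
        for pos in rec.new_spacer_indices:
            hits = mapping.get(rec.spacers[pos], [])
            hit = hits[0] if len(hits) == 1 else None
            out.append(
                OrderedHit(
                    array_id=rec.array_id,
                    k=s_number(rec, pos),
                    hit=hit,
                    read_count=rec.read_count,
                )
            )
    return out


def _anchor(site, anchor: str) -> float:
    """Anchor coordinate of a hit/seed: protospacer midpoint or 3' (PAM-proximal) end."""
    if anchor == "midpoint":
        return (site.start + site.end) / 2.0
    if anchor == "three_prime":
        return float(site.end if site.strand == "+" else site.start)
    raise ValueError(f"unknown anchor {anchor!r}")


def travel_distance(
    from_site,
    to_site,
    refset: ReferenceSet,
    anchor: str = "midpoint",
) -> float | None:
    """Signed shortest-arc distance from one protospacer to another, in nt.

    Positive means ``to_site`` lies 5' of ``from_site`` on ``to_site``'s
    strand. Returns None for cross-replicon pairs and for exact antipodal
    ties on circular replicons (side undefined).
    """
    if from_site.replicon_id != to_site.replicon_id:
        return None
    rep = refset.replicons[from_site.replicon_id]
    L = len(rep)
    a_from = _anchor(from_site, anchor) % L
    a_to = _anchor(to_site, anchor) % L
    if rep.topology == "circular":
        delta = (a_to - a_from) % L
        if delta == 0:
            return 0.0
        if delta == L / 2:
            return None  # antipodal tie: both arcs equal
        disp = delta if delta < L / 2 else delta - L  # signed shortest arc
    else:
        disp = a_to - a_from
    # 5' on + strand is decreasing coordinate, so a negative displacement is
    # a positive (5'-ward) travel on the plus strand, and vice versa.
    return -disp if to_site.strand == "+" else disp


def _by_array(ordered: Iterable[OrderedHit]) -> dict[str, dict[int, OrderedHit]]:
    out: dict[str, dict[int, OrderedHit]] = {}
    for oh in ordered:
        out.setdefault(oh.array_id, {})[oh.k] = oh
    return out


def _resolve(token, arr: dict[int, OrderedHit], pps):
    """A pair_spec endpoint: 'PPS' (the seed site) or an integer order k."""
    if token == "PPS":
        return pps
    oh = arr.get(int(token))
    return oh.hit if oh else None


def travel_table(
    ordered: Iterable[OrderedHit],
    pair_spec: tuple[tuple, tuple],
    pps,
    refset: ReferenceSet,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Per-array signed distances for two travels, e.g. ((PPS,1), (1,2)).

    Each pair is (from, to) with endpoints 'PPS' or an order index k.
    Arrays missing any referenced endpoint, cross-replicon pairs and
    antipodal ties are dropped. Columns: d1, d2, weight.
    """
    rows = []
    for arr in _by_array(ordered).values():
        weight = next(iter(arr.values())).read_count
        ds = []
        for frm, to in pair_spec:
            a = _resolve(frm, arr, pps)
            b = _resolve(to, arr, pps)
            d = travel_distance(a, b, refset, anchor) if a is not None and b is not None else None
            if d is None:
                break
            ds.append(d)
        else:
            rows.append({"d1": ds[0], "d2": ds[1], "weight": weight})
    return pd.DataFrame(rows, columns=["d1", "d2", "weight"])


def heatmap(
    ordered: Iterable[OrderedHit],
    pair_spec: tuple[tuple, tuple],
    pps,
    refset: ReferenceSet,
    bin_width: int = 100,
    anchor: str = "midpoint",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read-weighted 2D histogram of two signed travel distances.

    Returns (H, x_edges, y_edges) with the first travel on the x axis.
    """
    tab = travel_table(ordered, pair_spec, pps, refset, anchor)
    rid = pps.replicon_id if hasattr(pps, "replicon_id") else None
    if rid is not None and refset.replicons[rid].topology == "circular":
        half = len(refset.replicons[rid]) / 2
    else:
        half = max(tab[["d1", "d2"]].abs().max().max(), bin_width) if len(tab) else bin_width
    lim = float(np.ceil(half / bin_width) * bin_width)
    edges = np.arange(-lim, lim + bin_width, bin_width, dtype=float)
    if len(tab) == 0:
        return np.zeros((len(edges) - 1, len(edges) - 1)), edges, edges
    H, xe, ye = np.histogram2d(
        tab["d1"], tab["d2"], bins=[edges, edges], weights=tab["weight"].astype(float)
    )
    return H, xe, ye


def strand_fraction_by_order(
    ordered: Iterable[OrderedHit],
    pps,
    ks: Sequence[int] = (1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Read-weighted fraction of PS+k on the primed (PPS) strand, per k."""
    rows = []
    for k in ks:
        num = den = 0.0
        for oh in ordered:
            if oh.k != k or oh.hit is None:
                continue
            if oh.hit.replicon_id != pps.replicon_id:
                continue
            den += oh.read_count
            if oh.hit.strand == pps.strand:
                num += oh.read_count
        rows.append(
            {
                "k": k,
                "weight": den,
                "primed_strand_fraction": num / den if den else np.nan,
                "nonprimed_strand_fraction": 1 - num / den if den else np.nan,
            }
        )
    return pd.DataFrame(rows)


def five_three_split(
    hits_weights: Iterable[tuple[ProtospacerHit, int]],
    pps,
    refset: ReferenceSet,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Proportion of protospacers 5' vs 3' of the PPS on each strand.

    Rows: 'nonprimed' (displaced, opposite the PPS strand) and 'primed';
    columns: 'five_prime', 'three_prime'. Read-weighted; the four cells
    sum to 1. Antipodal ties and zero distances are excluded.
    """
    cells = {(s, d): 0.0 for s in ("nonprimed", "primed") for d in ("five_prime", "three_prime")}
    for hit, w in hits_weights:
        if hit is None or hit.replicon_id != pps.replicon_id:
            continue
        d = travel_distance(pps, hit, refset, anchor)
        if d is None or d == 0:
            continue
        srow = "primed" if hit.strand == pps.strand else "nonprimed"
        scol = "five_prime" if d > 0 else "three_prime"
        cells[(srow, scol)] += w
    total = sum(cells.values())
    frame = pd.DataFrame(
        [
            {
                "strand": s,
                "five_prime": cells[(s, "five_prime")],
                "three_prime": cells[(s, "three_prime")],
            }
            for s in ("nonprimed", "primed")
        ]
    ).set_index("strand")
    return frame / total if total else frame


def terminal_position_stat(spacer_table: pd.DataFrame) -> dict:
    """How often the chromosomal spacer is the last (leader-proximal) acquisition.

    Operates on the per-spacer annotation table. Considers arrays with at
    least one new chromosomal spacer; a chromosomal spacer is terminal
    when it sits at array position 0 (leader-proximal). Returns the
    read-weighted terminal fraction, the number of qualifying arrays and
    how many carry more than one chromosomal spacer.
    """
    new = spacer_table.loc[spacer_table["is_new"]]
    out = {"n_arrays": 0, "terminal_fraction": np.nan, "multi_chromosomal_arrays": 0}
    num = den = 0.0
    for _, grp in new.groupby("array_id"):
        chrom = grp.loc[grp["target_class"] == "chromosome"]
        if chrom.empty:
            continue
        out["n_arrays"] += 1
        if len(chrom) > 1:
            out["multi_chromosomal_arrays"] += 1
        w = float(grp["read_count"].iloc[0])
        den += w
        if (chrom["position"] == 0).any():
            num += w
    if den:
        out["terminal_fraction"] = num / den
    return out
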