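"""Summary tables, density tracks, composition, rarefaction and QC.

Percentages in summary tables are computed against the grand total and
rounded half-away-from-zero to two decimals. Density tracks use a sliding
binning window (default 150 nt, 10 nt step) that wraps on circular
replicons.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import Replicon, scan_motif_sites


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, total: float, ndigits: int = 2) -> float:
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)


def summary_table(
    locus_counts: Mapping[str, int],
    class_counts: Mapping[str, int],
    grand_total: int | None = None,
) -> pd.DataFrame:
    """Per-experiment summary: spacer counts and percentages by locus and target.

    All percentages are taken against one grand total — by default the sum
    of the target-class section (which includes 'unknown'); the locus
    section is reported against the same denominator, matching how such
    summary tables are conventionally printed. All-zero input yields an
    empty table.
    """
    if grand_total is None:
        grand_total = sum(class_counts.values()) or sum(locus_counts.values())
    if grand_total == 0:
        return pd.DataFrame(columns=["section", "name", "count", "percent"])
    rows = []
    for section, counts in (("locus", locus_counts), ("target", class_counts)):
        if not counts:
            continue
        for name, n in counts.items():
            rows.append(
                {
                    "section": section,
                    "name": name,
                    "count": int(n),
                    "percent": percentage(n, grand_total),
                }
            )
        rows.append(
            {
                "section": section,
                "name": "total",
                "count": int(sum(counts.values())),
                "percent": percentage(sum(counts.values()), grand_total),
            }
        )
    return pd.DataFrame(rows, columns=["section", "name", "count", "percent"])


def efficiency_ratio(count_a: float, count_b: float) -> float:
    """Spacer-count ratio between two experiments (e.g. primed vs naive)."""
    if count_b == 0:
        return float("inf")
    return count_a / count_b


def read_accounting(total_pairs: int, merged: int, barcode_ok: int) -> dict[str, int]:
    """Merge/demultiplex accounting: whole-percent pass rates."""
    return {
        "merged_pct": int(round_half_up(100.0 * merged / total_pairs, 0)),
        "barcode_pct": int(round_half_up(100.0 * barcode_ok / merged, 0)),
    }


@dataclasses.dataclass
class DensityTrack:
    """Per-window read-weighted protospacer counts along one replicon."""

    replicon_id: str
    strand: str | None
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    background: np.ndarray | None = None


def _window_counts(
    anchors: Sequence[float],
    weights: Sequence[float],
    L: int,
    circular: bool,
    window: int,
    step: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.ceil(L / step))
    starts = np.arange(n, dtype=np.int64) * step
    values = np.zeros(n, dtype=float)
    for m, w in zip(anchors, weights):
        if circular:
            d = np.mod(m - starts, L)
            mask = d < window
        else:
            d = m - starts
            mask = (d >= 0) & (d < window)
        values[mask] += w
    return starts, values


def density_track(
    hits_weights: Iterable[tuple],
    replicon: Replicon,
    window: int = 150,
    step: int = 10,
    strand: str | None = None,
    anchor: str = "midpoint",
    background_motif: str | None = None,
) -> DensityTrack:
    """Sliding-window density of protospacer hits on one replicon.

    ``hits_weights`` yields (hit, weight) pairs; hits on other replicons
    (or the other strand, when ``strand`` is given) are ignored. A hit is
    counted in every window containing its midpoint anchor. When
    ``background_motif`` is set (e.g. ``'GG'``), a PAM-site density with
    the same windowing is attached as the background.
    """
    L = len(replicon)
    window = min(window, L)
    circular = replicon.topology == "circular"
    anchors, weights = [], []
    for hit, w in hits_weights:
        if hit.replicon_id != replicon.id:
            continue
        if strand is not None and hit.strand != strand:
            continue
        if anchor == "midpoint":
            a = ((hit.start + hit.end) / 2.0) % L
        else:
            a = float(hit.end if hit.strand == "+" else hit.start) % L
        anchors.append(a)
        weights.append(float(w))
    starts, values = _window_counts(anchors, weights, L, circular, window, step)
    background = None
    if background_motif:
        bg_strands = [strand] if strand else ["+", "-"]
        bg_pos = []
        for s in bg_strands:
            bg_pos.extend(scan_motif_sites(replicon, background_motif, s))
        _, background = _window_counts(
            bg_pos, np.ones(len(bg_pos)), L, circular, window, step
        )
    return DensityTrack(
        replicon_id=replicon.id,
        strand=strand,
        window=window,
        step=step,
        starts=starts,
        values=values,
        background=background,
    )


def composition_deviation(spacers: Sequence[str], length: int = 32) -> pd.DataFrame:
    """Per-position base-frequency deviation from the uniform 25%.

    Only spacers of the stated length are used. Returns a 4 x length frame
    (rows A/C/G/T) of observed percent minus 25; overrepresentation is
    positive and each column sums to zero.
    """
    kept = [s for s in spacers if len(s) == length]
    if not kept:
        raise ValueError(f"no spacers of length {length}")
    arr = np.array([list(s) for s in kept])
    out = pd.DataFrame(index=list("ACGT"), columns=range(1, length + 1), dtype=float)
    n = len(kept)
    for j in range(length):
        col = arr[:, j]
        for base in "ACGT":
            out.loc[base, j + 1] = 100.0 * np.count_nonzero(col == base) / n - 25.0
    return out


def rarefaction(
    items: Sequence,
    depths: Sequence[int],
    rng: np.random.Generator,
    n_subsamples: int = 10,
) -> pd.DataFrame:
    """Unique-item saturation curves by subsampling without replacement.

    ``items`` is the read-level multiset (one entry per read, e.g.
    protospacer coordinate keys or array identities). For each depth the
    mean and s.d. of the unique count over ``n_subsamples`` draws is
    reported; depths beyond the multiset size are capped.
    """
    pool = np.asarray(items, dtype=object)
    N = len(pool)
    rows = []
    for depth in depths:
        d = min(int(depth), N)
        uniques = []
        for _ in range(n_subsamples):
            idx = rng.choice(N, size=d, replace=False)
            uniques.append(len(set(pool[idx])))
        rows.append(
            {
                "depth": d,
                "mean_unique": float(np.mean(uniques)),
                "sd_unique": float(np.std(uniques, ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def hotspot_detection(
    track: DensityTrack, min_fold: float = 5.0, min_windows: int = 3
) -> list[dict]:
    """Maximal runs of consecutive windows above a fold of the track baseline.

    The baseline is the median over windows with nonzero coverage (a plain
    median degenerates to zero on sparse chromosome tracks). Runs of at
    least ``min_windows`` windows with value >= min_fold * baseline are
    merged (wrapping across the origin on circular tracks) and reported
    with their peak window.
    """
    values = track.values
    nonzero = values[values > 0]
    if len(nonzero) == 0:
        return []
    baseline = float(np.median(nonzero))
    mask = values >= min_fold * baseline
    if not mask.any():
        return []
    n = len(values)
    runs = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append([i, j])  # [first, last+1) window indices
            i = j
        else:
            i += 1
    # circular wrap: merge a run ending at n with one starting at 0
    wrapped = False
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n:
        first = runs.pop(0)
        runs[-1][1] = n + first[1]
        wrapped = True
    out = []
    for a, b in runs:
        if b - a < min_windows:
            continue
        idx = np.array([k % n for k in range(a, b)])
        peak = int(idx[np.argmax(values[idx])])
        out.append(
            {
                "start": int(track.starts[a % n]),
                "end": int((b - 1) % n * track.step + track.window),
                "n_windows": b - a,
                "peak_window_start": int(track.starts[peak]),
                "peak_value": float(values[peak]),
                "wraps_origin": wrapped and b > n,
            }
        )
    return out


def replicate_qc(spacer_table: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Flag samples where one S+1 spacer dominates the read-weighted arrays.

    A sample enriched for a single founder clone shows one S+1 spacer
    carrying a large share of its reads; shares strictly greater than the
    threshold are flagged.
    """
    s1 = spacer_table.loc[spacer_table["s_number"] == 1]
    rows = []
    for sample, grp in s1.groupby("sample_id"):
        shares = grp.groupby("spacer_seq")["read_count"].sum()
        top = float(shares.max()) / float(shares.sum()) if shares.sum() else 0.0
        rows.append(
            {
                "sample_id": sample,
                "top_s1_share": top,
                "flagged": bool(top > threshold),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "top_s1_share", "flagged"])
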