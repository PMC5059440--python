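"""PAM-error taxonomy: slip-offset calling, flip detection, cross-tabs.

The canonical type I-F PAM is the GG dinucleotide immediately 3' of the
protospacer (positions +1/+2 on the protospacer strand). "Slipping" is a
misregistration of the capture machinery in which the nearest GG lies up
to 3 nt away from that window: positive offsets are distal (further into
the 3' flank), negative offsets are proximal and overlap the
protospacer's 3' end. "Flipping" is integration of the captured duplex in
reverse orientation, which leaves a complementary CC-type motif near the
5' end of the mapped protospacer; flip candidates are excluded from slip
statistics because their apparent PAM is uninformative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

SLIP_RADIUS = 3


def classify_pam(pam: str) -> str:
    """Classify a PAM dinucleotide as GG, GN, NG or NN (N = any base but G).

    Non-ACGT characters count as N.
    """
    if len(pam) != 2:
        raise ValueError(f"PAM must be 2 nt, got {pam!r}")
    a = "G" if pam[0] == "G" else "N"
    b = "G" if pam[1] == "G" else "N"
    return a + b


def slip_offset_from_context(tail3: str, flank3: str, radius: int = SLIP_RADIUS) -> int | None:
    """Smallest-|s| offset at which GG occurs in the shifted PAM window.

    ``tail3`` is the protospacer's last 3 bases and ``flank3`` the 5 bases
    immediately 3' of it, both on the protospacer strand. The window at
    offset ``s`` covers positions ``s..s+1`` relative to the canonical PAM
    start; ties between -s and +s resolve to +s. Returns None when no GG
    lies within the radius ("other").
    """
    context = tail3 + flank3
    boundary = len(tail3)  # index of the canonical PAM start within context
    for mag in range(radius + 1):
        for s in ((mag,) if mag == 0 else (mag, -mag)):
            i = boundary + s
            if 0 <= i and i + 2 <= len(context) and context[i : i + 2] == "GG":
                return s
    return None


@dataclasses.dataclass(frozen=True)
class SlipFlipCall:
    """Per-protospacer PAM-error call: category, slip offset, flip candidacy."""

    pam_category: str  # {GG, GN, NG, NN}
    slip_offset: int | None  # None when 'other'
    flip_candidate: bool
    other: bool  # no GG within +/- SLIP_RADIUS of the canonical window
    non_acgt: bool = False


def call_slip(spacer_seq: str, flank3: str, radius: int = SLIP_RADIUS) -> tuple[str, int | None, bool]:
    """Call (pam_category, slip_offset, other) for one mapped protospacer."""
    pam = flank3[:2]
    non_acgt = not set(pam) <= set("ACGT")
    category = "NN" if non_acgt else classify_pam(pam)
    offset = slip_offset_from_context(spacer_seq[-3:], flank3, radius)
    return category, offset, offset is None


def call_flip(spacer_seq: str, flank5: str) -> bool:
    """Flip candidacy: a CC with its start within 3 nt of the 5' boundary.

    ``flank5`` is the 5 bases immediately 5' of the protospacer on its
    strand. CC start offsets -3..+1 relative to the protospacer's first
    base are tested, i.e. the CC lies within 3 nt on either side of the
    5' end.
    """
    context = flank5 + spacer_seq[:3]
    boundary = len(flank5)
    for o in range(-SLIP_RADIUS, 2):
        i = boundary + o
        if 0 <= i and i + 2 <= len(context) and context[i : i + 2] == "CC":
            return True
    return False


def call_slip_flip(spacer_seq: str, flank5: str, flank3: str) -> SlipFlipCall:
    """Full per-protospacer call; flip candidates are flagged for exclusion."""
    category, offset, other = call_slip(spacer_seq, flank3)
    flip = call_flip(spacer_seq, flank5)
    return SlipFlipCall(
        pam_category=category,
        slip_offset=offset,
        flip_candidate=flip,
        other=other,
        non_acgt=not set(flank3[:2]) <= set("ACGT"),
    )


def annotate_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Add PAM-call columns to a per-spacer annotation table.

    Expects columns ``spacer_seq``, ``flank5``, ``flank3`` (mapped hits
    only). Adds ``pam_category``, ``slip_offset`` (nullable), ``other``
    and ``flip_candidate``.
    """
    calls = [
        call_slip_flip(s, f5, f3)
        for s, f5, f3 in zip(table["spacer_seq"], table["flank5"], table["flank3"])
    ]
    out = table.copy()
    out["pam_category"] = [c.pam_category for c in calls]
    out["slip_offset"] = pd.array([c.slip_offset for c in calls], dtype="Int64")
    out["other"] = [c.other for c in calls]
    out["flip_candidate"] = [c.flip_candidate for c in calls]
    return out


def _weights(calls: pd.DataFrame) -> pd.Series:
    """Dereplicated read counts when present, else unit weights."""
    if "read_count" in calls:
        return calls["read_count"].astype(float)
    return pd.Series(1.0, index=calls.index)


def slip_frequencies(calls: pd.DataFrame) -> pd.Series:
    """Read-weighted slip-category frequencies among non-flip-candidate hits.

    Index: -3..3 plus 'other'; values are fractions of the retained hits.
    """
    kept = calls.loc[~calls["flip_candidate"].astype(bool)]
    w = _weights(kept)
    n = float(w.sum())
    freqs = {}
    for s in range(-SLIP_RADIUS, SLIP_RADIUS + 1):
        freqs[s] = float(w[kept["slip_offset"] == s].sum()) / n if n else np.nan
    freqs["other"] = float(w[kept["other"].astype(bool)].sum()) / n if n else np.nan
    return pd.Series(freqs)


def crosstab_slip_length(calls: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Spacer length x slip category read-weighted counts, flips excluded.

    Returns the contingency table (rows: length, columns: slip offset or
    'other') and the fraction of non-32-nt spacers whose PAM is canonical
    (slip 0) — the headline 'aberrant lengths map to canonical PAMs'
    statistic.
    """
    kept = calls.loc[~calls["flip_candidate"].astype(bool)].copy()
    kept["length"] = kept["spacer_seq"].str.len()
    kept["slip_cat"] = kept["slip_offset"].astype(object).where(
        ~kept["other"].astype(bool), "other"
    )
    kept["weight"] = _weights(kept)
    tab = kept.pivot_table(
        index="length", columns="slip_cat", values="weight", aggfunc="sum", fill_value=0
    )
    aberrant = kept.loc[kept["length"] != 32]
    if len(aberrant):
        frac = float(
            aberrant.loc[aberrant["slip_offset"] == 0, "weight"].sum()
            / aberrant["weight"].sum()
        )
    else:
        frac = np.nan
    return tab, frac


def gstretch_usage(calls: pd.DataFrame, refset) -> pd.DataFrame:
    """5'-most vs other GG-window usage within reference G-runs.

    For each canonical-PAM (slip 0, non-flip-candidate) hit whose GG lies
    in a maximal G-run of length >= 3 on the protospacer strand, record
    whether the used window is the 5'-most GG of the run. Returns per
    run-length counts and the 5' usage fraction.
    """
    from .reference import fetch_padded

    rows = []
    kept = calls.loc[(~calls["flip_candidate"].astype(bool)) & (calls["slip_offset"] == 0)]
    kept_w = _weights(kept)
    for (_, hit), w in zip(kept.iterrows(), kept_w):
        rep = refset.replicons[hit["replicon_id"]]
        start, end, strand = int(hit["start"]), int(hit["end"]), hit["strand"]
        # read the PAM neighbourhood on the protospacer strand: 1 protospacer
        # base, then up to 6 flank bases
        if strand == "+":
            ctx = fetch_padded(rep, end - 1, end + 6, "+")
        else:
            ctx = fetch_padded(rep, start - 6, start + 1, "-")
        # ctx[1:3] is the canonical GG; extend the G-run around it
        left = 1
        while left > 0 and ctx[left - 1] == "G":
            left -= 1
        right = 3
        while right < len(ctx) and ctx[right] == "G":
            right += 1
        run_len = right - left
        if run_len >= 3:
            rows.append({"run_length": run_len, "five_prime_gg": left == 1, "weight": w})
    if not rows:
        return pd.DataFrame(columns=["run_length", "n", "five_prime_fraction"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("run_length")
        .apply(
            lambda g: pd.Series(
                {
                    "n": g["weight"].sum(),
                    "five_prime_fraction": (g["five_prime_gg"] * g["weight"]).sum()
                    / g["weight"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return out
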