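# Methods

## Coordinates, strands and PAMs

All coordinates are 0-based, half-open, on the plus strand. Circular
replicons represent origin-spanning intervals as `end > L` (never with
negative coordinates); reports that print coordinates use 1-based
inclusive values. A protospacer's strand is the strand whose 5′→3′
sequence equals the spacer stored in the array. The canonical type I-F
PAM is the GG dinucleotide occupying positions +1/+2 immediately 3′ of
the protospacer on the protospacer strand; for a minus-strand protospacer
this is the two plus-strand bases just below `start`, read on the minus
strand.

## The acquisition model

Each simulated cell is an independent realisation of the following
process.

**Chain initiation.** With probability `priming_rate` (default 0.75,
requires a seed site in the reference) a chain starts at the priming
protospacer — an escape-PAM (TG) target of a pre-existing spacer. With
probability `naive_rate` (default 0.001) a chain starts instead at a
naive capture site anywhere on the plasmid. The two defaults encode the
central empirical asymmetry of the system: priming is several hundred
fold more active than naive acquisition.

**Seeded capture.** A seeded capture (priming or targeted) chooses one of
four quadrants relative to its seed with weights `quadrant_weights`
(default 0.625 / 0.10 / 0.15 / 0.125 for displaced-5′, displaced-3′,
target-5′, target-3′). "Displaced" is the strand opposite the seed's
protospacer strand — the strand the adaptation complex is recruited to in
the R-loop — and 5′/3′ are evaluated on the *new* protospacer's strand
(5′ = decreasing coordinate on +, increasing on −), using the shortest
arc on circular replicons (exact antipodes are resampled). The complex
then walks successive GG sites away from the seed midpoint in the chosen
direction and captures at each site with a per-site Bernoulli
probability: the base rate is calibrated so the mean travel distance is
`translocation_mean` nt (default 400, giving a geometric hop kernel over
GG sites), and each site's probability is multiplied by `at_start_bias`
(default 2.0) when the base captured at the protospacer's 3′ end — the
base immediately 5′ of the GG — is A or T. This single local preference
produces the characteristic 5′-GG usage bias inside G-stretches, because
the 3′-most GG of a run always places a G at the protospacer's 3′ end.
Two rejected designs are worth recording: drawing a travel distance and
taking the nearest GG beyond it lets the first window of a G-run shadow
the others (the 5′-GG preference collapses), and acceptance-rejection
over the whole walk makes acceptance direction-dependent and distorts
the realised quadrant fractions. The per-site walk has neither problem.

**Naive capture.** Naive sites are drawn from all GG anchors on both
strands of the replicon, optionally weighted by a per-position hotspot
profile (uniform by default; real plasmids show transcription- and
AT-richness-driven hotspots that the default does not emulate), with the
same A/T 3′-end preference.

**Capture errors.** Each event draws a slip offset from `slip_dist`
(defaults: +1 3.0 %, −1 2.5 %, ±2 0.8 %, +3 0.5 %, −3 0.4 %; the
remaining 92 % is canonical). A slip of `s` shifts the effective PAM
window `s` nt distal (+) or proximal (−) along the protospacer strand, so
a −1 slip incorporates the first PAM G at the spacer's 3′ end. Spacer
length is 32 nt with a 33 nt minority (`p_len33` = 0.10) and rare other
lengths (`p_len_other` = 0.005, uniform over 30/31/34/35 nt); minus slips
instead draw from a long-biased distribution (uniform 33–36 nt),
encoding the observed coupling between proximal misregistration and
over-long spacers. With probability `p_flip_given_small_slip` (0.002, |s|
≤ 1) or `p_flip_given_big_slip` (0.05, |s| ≥ 2) the captured duplex
integrates flipped: the emitted spacer is the reverse complement, so its
mapped protospacer sits on the opposite strand with a CC-type motif 5′ of
it.

Slip categories are defined *observationally*: a slip of `s` means the
nearest GG to the emitted protospacer's canonical PAM window lies at
offset `s`. The simulator draws the category first and resamples capture
sites until the emitted context reads back as that category (flipped
captures skip the check — their slip is unobservable after reorientation,
mirroring the analysis-side exclusion of flip candidates). Without this
conditioning no analyzer could recover `slip_dist`: for example a −1 slip
followed by a G reads as canonical, and about a quarter of −1 slips
would be miscalled.

**Feedback and termination.** After the first event, a truncated
geometric number of additional events follows (`feedback_mean` = 1.5,
capped at 6), each seeded by the *immediately preceding* event, not the
original PPS. This single rule reproduces both the PS+1 quadrant bias and
the strand alternation / travel-direction signatures of later orders.
With probability `chrom_event_rate` (0.0005) a chromosomal capture is
appended; if its PAM is canonical the cell acquires nothing further
(self-targeting is assumed lethal before further expansion), while
escape-PAM chromosomal captures let feedback continue — so the
chromosomal spacer is leader-proximal-terminal exactly when it is
interference-proficient.

**Locus assignment.** Each cell assigns its whole chain to one CRISPR
locus, drawn by the incorporation weights (defaults 0.70 / 0.28 / 0.02).
This keeps array order identical to acquisition order, which is the
regime in which S+k statistics are interpretable; the alternative, one
independent locus draw per event (`locus_per_event=True`), spreads chains
across arrays and structurally dilutes the PS+1 quadrant fraction below
the configured weight (a real effect in multi-locus systems, available
for studying exactly that dilution). Locus-share recovery is identical
under both modes.

**Emission.** One merged read per (cell, locus) with ≥ 1 new spacer:
barcode + leader tail + (repeat + spacer) with the last-acquired event
leader-proximal + repeat + first pre-existing spacer + repeat + 3′ primer
tag, in random orientation (p = 0.5), optional per-base substitution
noise (default 0), FASTQ with constant quality, plus a TSV truth log and
a read↔cell map.

## Analysis conventions

- **Demultiplexing** requires both terminal tags to match exactly, in
  either read orientation; no error correction.
- **Dereplication** is exact full-string identity (length included),
  performed before extraction; cluster sizes propagate as read counts and
  all downstream tallies are read-weighted.
- **Repeat finding** is a sliding Hamming comparison against the known
  repeat, substitutions only, tolerance 3, greedy left-most on overlaps.
  The amplicon design fixes the repeat, so de novo repeat discovery is
  unnecessary. Spacer length bounds are [20, 45] nt.
- **Mapping** is exact-match only on both strands (doubled-sequence
  search for circular replicons). Spacers hitting nothing are "unknown";
  multi-location spacers are "ambiguous" and excluded from positional
  statistics. Flanks are always 5 nt each side, read from the reference
  on the protospacer strand (covering the ±3 slip window with context);
  at linear replicon edges missing flank bases are padded with N, which
  never matches a motif.
- **Slip calling** searches offsets 0, ±1, ±2, ±3 in order of |s|,
  ties resolved toward +s (distal slips are the better-behaved class);
  no GG within the radius is "other". **Flip candidacy** tests only CC
  (not NC/CN) with its start at offsets −3..+1 from the 5′ boundary;
  candidates are excluded from slip tallies so no hit is counted in both.
- **Travel distances** anchor at protospacer midpoints (configurable to
  the PAM-proximal end); the sign is evaluated on the destination
  protospacer's strand; shortest arc on circles, with exact antipodal
  ties excluded. Heatmap bin width defaults to 100 nt.
- **Density tracks** use a 150 nt window sliding in 10 nt steps by
  default (the chromosome-scale analysis uses 3,000 nt windows, same
  10 nt step); windows wrap on circular replicons, so a track has
  ⌈L/step⌉ windows and each hit is counted in window/step of them.
- **Summary percentages** are rounded half-away-from-zero to 2 decimals,
  and both table sections share one grand total (the target-class sum,
  including "unknown") — this is the convention under which the published
  table's printed counts reproduce its printed percentages exactly.
- **Hotspots** are runs of ≥ `min_windows` consecutive windows at
  ≥ `min_fold` × the median of nonzero windows (a plain median is zero on
  sparse chromosome tracks); runs merge across the origin. The fold and
  run-length defaults (5, 3) are pragmatic choices — the visual hotspot
  calls they stand in for were never algorithmic.
- **Rarefaction** subsamples reads without replacement (so full depth
  recovers the exact unique count with zero variance); expectations
  follow the hypergeometric closed form.
- **Replicate QC** flags a sample when one S+1 spacer carries strictly
  more than 30 % (configurable; the threshold is this package's choice)
  of read-weighted arrays, the signature of founder-clone enrichment.

## Problem sizes and what the tests show

The default synthetic reference is an 8 kb circular plasmid (PPS on the
minus strand at its midpoint, TG PAM) and a 40 kb circular stand-in
chromosome — large enough for hundreds of GG sites per strand and
negligible antipode effects, small enough that the parameter-recovery
suite (10,000 cells, ~18,000 events, full pipeline) runs in seconds.
Recovery tests compare pipeline estimates with configured values within
3 binomial standard errors.

Passing recovery demonstrates that extraction, mapping, PAM calling and
order statistics are mutually consistent and unbiased *under the model's
assumptions*. Real data differ in ways the generator deliberately does
not emulate: PCR amplification bias and chimeras, sequencing error
(available via `read_error_rate` but off by default), non-uniform naive
hotspot landscapes, locus-switching chains, unknown-target spacers from
sequencing error, and latent flip rates in ambiguous contexts (the
analysis deliberately reports flip *candidates*, a superset dominated by
chance CC occurrences, rather than estimating the latent rate).

## Known limitations

- Exact-match mapping cannot place spacers carrying sequencing errors;
  an optional Hamming-rescue exists for self-priming exploration but
  rescued hits are excluded from PAM statistics by design.
- Repeat matching tolerates substitutions only; indel-containing repeat
  copies drop the read.
- The translocation kernel (geometric over GG hops, nt-calibrated) and
  the feedback-length distribution are modelling choices; the underlying
  biology constrains their qualitative shape, not their parametric form.
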