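# Methods

## Spatial phylotype mapping

### Read model and classification

Read 1 carries a 25-base coordinate barcode (CID, bases 1–25) identifying a
chip spot and a 10-base molecular barcode (MID, bases 26–35); read 2 is a
75-base fragment of the symbiont 16S sequence. The two phylotypes differ at
exactly one base, so classification happens inside a 47-nt diagnostic
window containing that base.

Two classification paths are provided and tested against each other:

- **Sequence mode** (default, self-contained): a read is called A (or G)
  iff it contains the full 47-nt window of that reference with zero
  mismatches. Reads covering only part of the window, or carrying any
  substitution inside it, are `unclassified` — never force-assigned. The
  two windows differ at the diagnostic base, so no read can match both.
- **Alignment mode**: pre-aligned SAM records pass only with a unique hit
  (NH:i:1), mapping quality exactly 255 and a CIGAR that is a single
  contiguous 47-base match; the call is then decided by the read base over
  the diagnostic reference position. MAPQ 255 is honoured verbatim as the
  uniqueness convention of the aligner that produced the input, without
  reinterpretation. The two paths agree on indel-free reads (tested on
  simulated data through an idealised exact-matching aligner).

### Binning, dominance, heterogeneity

Spot coordinates are 0-based; bins are indexed by componentwise floor
division (`bin_size` default 20 spots, one spot = one DNA-nanoball pitch,
bin ≈ 10 µm ≈ one host cell). A bin is **valid** when its classified-read
total reaches `min_reads` (default 180; the threshold is inclusive:
exactly 180 is valid). A valid bin is **A-dominant** iff its A fraction
strictly exceeds the dominance level (default 0.95), which for integer
counts is exactly equivalent to n_A > 19·n_G — verified exhaustively over
all count pairs with total ≤ 500. The G side is evaluated as
n_G/total > 0.95 rather than frac_A < 0.05, because `1 − 0.95` is not
exactly representable in floating point and would mis-call the boundary
pair (1, 19).

Summaries are computed over valid bins only: a 20-interval frequency
histogram of the A fraction (width 5%, last interval closed), the extreme
share (A fraction ≤ 0.05 or ≥ 0.95), the single-phylotype fraction in both
a strict sense (minor count exactly 0) and a dominance sense (called A- or
G-dominant) — the two senses are reported side by side because either can
be meant by "bins with just one phylotype" — and neighbour discordance:
the fraction of 4-adjacent pairs of valid, dominant-called bins whose
calls differ (4-connectivity chosen as the simplest lattice adjacency; NaN
when no such pair exists). Sample-level phylotype frequency is the G share
of classified reads; `concordance_r2` (squared Pearson correlation)
compares it against an independent estimator.

MID deduplication (at most one count per spot–MID–call triple) is
available but off by default: raw read counts are the mapped signal, and
collapsing molecular duplicates is a separate design choice the caller
must opt into.

### Coordinate conventions

The diagnostic base of the real system is described both as "position 590"
of the 16S gene and as lying in a kept region spanning 907–953; these two
coordinate systems cannot both be literal for one 47-nt window. The
implementation therefore treats both the window and the diagnostic
position as parameters; the defaults place a 1500-nt mock reference with
window 907–953 and the diagnostic base at its midpoint (930).

## Synthetic data

The generator produces what the analysis assumes, nothing more:

- **References**: uniform-random 1500-nt sequences (full-16S scale),
  identical except at the diagnostic position. Tests that need dense
  window coverage use a 200-nt variant (window 100–146) — the geometry is
  parametric, not constant.
- **Fields**: `domain-mosaic` partitions the grid into contiguous stripes
  with randomly jittered boundaries along the longer axis, alternating
  pure phylotype (fraction 0/1) so adjacent domains always differ and the
  field has exactly `n_domains` single-phylotype regions — emulating
  spatially segregated symbiont pouches. `well-mixed` draws per-spot A
  fractions from Beta(β, β) (β = 1000 concentrates at 0.5 ± 0.011),
  emulating a tissue where both phylotypes co-occur everywhere. Stripes
  were chosen over a Voronoi tessellation because random labels on Voronoi
  cells cannot guarantee that adjacent domains differ, which the
  contiguous-region count relies on.
- **Reads**: per-spot read counts are Poisson(mean); no per-spot
  depth distribution is documented for the real chemistry, so Poisson is
  an explicit assumption. Fragment starts are uniform over the reference,
  and fragments that miss the window are emitted anyway — rejecting them
  is the classifier's job. Errors are i.i.d. substitutions (uniform over
  the three other bases); indels are not simulated because the 47M filter
  discards indel-containing alignments, so they add nothing testable.
- **Incubations**: expected filter DPM is
  `DPM_DIC × (1 − e^(−k·t)) + background`; optional Poisson counting
  noise; killed controls carry the background only (k = 0), matching
  acid-killed control filters.

All generators are pure functions of (config, seed); a fixed seed
reproduces byte-identical outputs.

What the generator does **not** emulate: chip optics and chemistry, PCR
and capture bias, chimeras, barcode sequencing errors (CIDs are read
error-free), spatially correlated error profiles, or rRNA secondary
structure effects. Passing tests therefore demonstrate the correctness of
the computational pipeline under its stated statistical assumptions, not
the behaviour of any particular instrument.

## Rate model

For one incubation, k = −ln(1 − DPM_POC/DPM_DIC)/t (day⁻¹), computed via
`log1p` for accuracy at the small fractions typical of tracer work
(f ≈ 10⁻⁵–10⁻²; the bounds f/t ≤ k ≤ (f+f²)/t hold for f ≤ 0.01). If the
(optionally blank-subtracted) filter DPM reaches the tracer DPM the record
is rejected by name. Blank subtraction (killed-control DPM, floored at
zero) is implemented but **off by default**, because the protocol
describes killed controls without stating how they enter the calculation.

Assimilation rate = k × [DIC] × 10⁶ × V × n. The 10⁶ converts mmol to
nmol and is a named constant (`NMOL_PER_MMOL`); with [DIC] in mmol·L⁻¹
and V in litres this reproduces the reported rate magnitudes
(k = 7.4 × 10⁻⁴, [DIC] = 2.64, V = 0.015 → 29.3 nmol·clam⁻¹·day⁻¹).
Volumes: 0.015 L (live clam), 0.010 L (gill vial, × 4 because one vial
holds a quarter clam's gill). Seawater rates are normalised per 100 ml;
the equivalence volume is 100 × clam_rate / seawater_rate (ml).

### Temperature response

Ordinary least squares on (temperature, k), degree 2 or 3, replicate-level
observations when available and means otherwise. Model comparison reports
adjusted R² (primary) and small-sample AICc. With exactly degree+1
distinct temperature means the fit interpolates (residuals < 10⁻⁹
relative). The thermal optimum of the cubic is the root of the derivative
quadratic that is a local maximum inside the measured range, solved with
the cancellation-stable (Citardauq) quadratic formula — the naive formula
loses four digits when the cubic coefficient is near zero — and
cross-checked against a 0.001 °C grid search (agreement within 0.002 °C,
also property-tested on random cubics). Fitting the four tabulated means
places the optimum at 14.75 °C; a replicate-level fit of the same system
is reported at 14.78 °C, a difference well inside the ±0.5 °C the
mean-vs-replicate distinction can introduce.

Rounding in reports follows the field's printed precision: integer
percentages, rates to one decimal, k to three significant figures.

## Problem sizes in the test suite

End-to-end tests run 100 × 100-spot grids (25 bins) at a mean of 4 reads
per spot with the 200-nt reference, giving ≈ 290 classified reads per bin —
comfortably above the 180-read validity bar while keeping the whole suite
under a minute. Poisson-recovery tests size their replicate counts so the
Monte-Carlo standard error of the mean k stays within a third of the 5%
acceptance band even at k = 10⁻⁵ (≈ 10⁴ replicates there, 100 at higher
rates).

## Known limitations

- Sequence-mode classification requires perfect 47-mers, so its
  sensitivity falls geometrically with the error rate
  (≈ 0.995⁴⁷ ≈ 0.79 of window-covering reads at 0.5% error); it trades
  recall for a zero-force-assignment guarantee.
- The heterogeneity summaries treat bins as independent units; no spatial
  smoothing or autocorrelation model is applied.
- The rate model assumes a single well-mixed DIC pool, no isotope
  fractionation, and no carbonate-system speciation.
- Alignment mode trusts the upstream aligner's NH/MAPQ semantics; it
  filters, it does not realign.
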