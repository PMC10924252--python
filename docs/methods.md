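# Methods

## Background model and detection

Linked-read (haplotagging) libraries tag every short read with the barcode of
its long DNA molecule of origin (here 40–60 kb).  For one chromosome cut
into `n = ceil(length/m)` windows of size `m` (default 10 kb, half-open,
final truncated window retained), the barcode sets `A_i` of reads starting in
each window give the symmetric sharing matrix

    J(i, j) = |A_i ∩ A_j| / |A_i ∪ A_j|,          J = 0 when both sets are empty.

Because molecules span several windows, J is large near the diagonal and, in
the absence of rearrangement, depends only on the diagonal distance
`x = |j − i|` through a double-exponential decay

    y(x) = exp(a + b · exp(−c · x)),

with `a` the asymptotic log background (coverage and barcode-collision
noise), `b` the near-diagonal log amplitude (coverage) and `c` the decay rate
per window, inversely related to molecule length.  The model is fitted by
nonlinear least squares in natural space over all upper-triangle cells with
`x ≥ 1` (the unit diagonal is excluded).  Because the within-distance scatter
contributes a parameter-free constant to the cell-level objective, the fit is
carried out on per-distance means weighted by cell counts — algebraically
identical, and verified against a direct cell-level fit in the tests.
Multi-start initialisation uses `c₀ ∈ {m/25 kb, m/50 kb, m/100 kb}` with
`a₀ = log(tail mean + ε)`, `b₀ = log((near mean + ε)/(tail mean + ε))`,
`ε = 1e−9`; bounds keep `c > 0`.  The cell-level residual standard deviation
σ combines curve misfit and within-distance scatter with 3 degrees of
freedom removed.

A cell at distance x is an outlier iff **both**

1. it falls outside the normal prediction band `y(x) ± z_{1−α/2}·σ`
   (α = 0.05; strict inequality — a cell exactly on the band is not an
   outlier), and
2. its per-distance Z-score `(J − mean_x)/sd_x` exceeds the threshold
   (default 2) in the same direction.

The conjunction is the package's resolution of an ambiguity in how the
Z-scaling interacts with the band: read as a joint condition it serves its
stated purpose of suppressing false positives near the diagonal, where
sharing is intrinsically noisy and the global band is far too tight.  At
offsets where `sd_x = 0` the Z condition falls back to the sign of the
deviation.  A floor of 1e−12 on σ guards the exactly-noise-free case against
floating-point dust.

Outlier cells within one window of each other in both matrix axes
(8-connectivity; `cluster_gap` widens this) merge into candidate SV calls.
A call reports its row-window and column-window breakpoint ranges and the
covering interval `[min window start, max window end)`, BED-style 0-based
half-open.  Calls are not classified into SV types.

The default detection direction is excess sharing; depletion and two-sided
modes exist because deletions deplete sharing over their footprint and
insertions (sequence present in the sample but absent from the reference)
leave *only* a depletion signature across the insertion point.  The
simulation benchmark therefore runs `direction="both"`, which also matches
the plain reading of "outside the prediction band".

When the background floor is exactly zero (every barcode unique to one
molecule, no collisions), `a` is unidentifiable — the optimiser pushes it to
its lower bound with a compensating `b`.  Prediction, bands and detection
are unaffected; only the individual parameter values lose their
interpretation.  Any realistic barcode-reuse floor restores
identifiability, and then `1/c` tracks molecule length in windows.

## Simulator

`induce_svs` places insertions, deletions and inversions left to right: each
event starts one `Exp(spacing_mean)` gap (mean 1/3 Mb) after the previous
event's end, making overlap impossible by construction; type and size are
drawn uniformly from the configured sets (sizes 1, 5, 10, 50, 100 kb by
default).  Inserted sequence is i.i.d. uniform A/C/G/T.  The derived genome
is assembled segment-wise and cross-checked in the tests against an
independent right-to-left splice of the truth list (byte equality).

A `CoordinateMap` partitions the derived genome into segments mapping to the
reference with orientation `+`/`−` or marked novel.  Reads are simulated on
the derived genome — molecules uniform in position, lengths uniform on
40–60 kb, one barcode per molecule drawn from a 96³ (≈885k) barcode space so
collisions occur at a realistic (rare) rate, reads Poisson-thinned per
molecule to the target depth — then lifted through the map: novel reads are
dropped as unmappable, inverted reads come back reverse-oriented at the
mirrored position, reads downstream of indels are shifted.  A read
straddling a segment boundary takes the frame of the segment containing its
midpoint (documented approximation; at most one read length of error).
Emitted records carry MAPQ 60, no duplicates and a valid BX tag, so they
pass the same alignment filters applied to real data (MAPQ ≥ 10, duplicates
dropped, untagged dropped).  All randomness flows through
`numpy.random.default_rng` with sub-seeds derived from the study seed.

Default study conditions: molecular coverage 25× and read coverage 10×.
Molecular coverage is set comfortably above the level where large-SV
sensitivity saturates (pooled-population haplotagging operates at tens of
molecules per position); both are configurable.

## Benchmark

For each truth event, calls overlapping at least `min_overlap = 0.9` of the
truth interval are ranked by overlap (descending), ties broken by the scaled
breakpoint error

    (|call.start − truth.start| + |call.end − truth.end|) / m   [windows],

and the top call is the match.  A truth event is a true positive at
threshold T iff matched with error ≤ T; sensitivity = TP/(TP+FN) is
tabulated per SV type, size and window size at T = 15, 20, 25 windows.
Calls may match several truth events; each truth event takes at most one
call.  Insertions have a zero-length reference footprint and are scored
against ± one window around the insertion point, since detection resolution
is window-limited.  A precision table is reported as a secondary output.

Reciprocal-overlap intersection of two call sets (shared vs specific at
fraction 0.8 of *both* intervals, one match per call) mirrors bedtools
`-f 0.8 -F 0.8 -u` and is tested against bedtools itself.

## Problem sizes and observed behaviour

The validation harness runs a 20-Mb single chromosome with ~40–60 events of
50/100 kb (or 1/5/10 kb for the small-SV check), chosen so the whole
simulate → matrix → detect → benchmark pipeline completes in seconds per
run.  Under these conditions sensitivity for ≥50-kb SVs at a 20-window error
threshold is 1.0 with 10-kb windows and ≈0.91 with 5-kb windows; the 5-kb
misses are 100-kb inversions whose bowtie edges extend roughly one molecule
length beyond the breakpoints, inflating the scaled error past the threshold
— the known behaviour of breakpoint estimation from bowtie edges at small
windows.

## What the generator does and does not emulate

It reproduces the geometry that carries the signal — molecule-scale linkage,
junction-spanning molecules, unmappable novel sequence, mirrored liftover —
and the barcode bookkeeping, under seeded determinism.  It does **not**
model sequencing error, mapping ambiguity or repeats, GC/coverage bias,
chimeric molecules, duplicate reads, or diploid/heterozygous variation
(induced SVs are effectively homozygous).  Consequently the synthetic
matrices are much cleaner than real ones: per-distance scatter is small and
even 5–10-kb events retain partial signal (a 5–10-kb event still empties
part of a 10-kb window at 10× depth), so small-SV sensitivity here
(~0.6–0.7 pooled) understates how thoroughly such events are lost in real
data.  Passing the large-SV benchmark demonstrates the detection geometry
and scoring are correct; it does not by itself demonstrate robustness to
real-data noise.

## Numerical and convention choices

- Windows, intervals and BED outputs are 0-based half-open; a read belongs
  to the window containing its leftmost coordinate.
- Matrix construction is blocked over rows with a deterministic reduction:
  results are bit-identical for any thread count.
- `sd_x` uses the population (ddof 0) standard deviation; offsets with a
  single cell record sd 0.
- Split-triangle merges put population A in the upper triangle and on the
  diagonal, population B below; splitting recovers both (B's diagonal is
  taken from the merged diagonal).
- Heatmap colour scales clip at the 0.99 off-diagonal quantile so the unit
  diagonal does not wash out structure.
- Barcode rendering follows the haplotagging AxxCxxBxxDxx convention with
  1-based zero-padded whitelist indices; 00 marks an unresolvable segment
  and invalidates the tag downstream.
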