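# Methods

## Scope and data model

The package analyzes intra-chromosomal (cis) Hi-C contact maps only; the
domain phenomenon it targets is intra-chromosomal, and trans contacts carry
no information about it. Coordinates are 0-based half-open everywhere. A
`BinGrid` tiles each chromosome in fixed-size bins (the last bin may be
short; its true length is kept for per-bp conversions). Contact matrices are
stored dense per chromosome — at the 5–50-kb resolutions used here a
chromosome is at most a few thousand bins, where dense linear algebra is
both simpler and faster than sparse bookkeeping.

## Matrix balancing

Balancing solves `w_i · Σ_j c_ij · w_j = 1` for one positive factor per
unmasked bin (the Knight–Ruiz contract: a symmetric diagonal scaling with
uniform row sums). The solver is a damped square-root fixed-point iteration
`w ← w · (s̄/s)^(θ/2)` on the row sums `s`, with the damping exponent halved
whenever the error grows; convergence is the maximum relative row-sum
deviation dropping below `tol` (default 1e-6, max 3000 iterations). Balanced
matrices are normalized to unit row sums so downstream scores are
depth-independent. Bins with zero marginal are masked automatically;
`mask_sparse_bins` additionally drops bins below a configurable marginal
quantile (default 0.5% per chromosome) before balancing — low-coverage bins
otherwise receive enormous weights and dominate every downstream score.
Matrices whose support admits no doubly stochastic scaling (e.g.
chain-graph support) raise a balancing error naming the worst bins; partial
weights are never returned. The test suite cross-checks the fixed point
against an independent alternating (Sinkhorn) scaling oracle.

## Distance decay and O/E

The expected value at bin distance `d` is the mean balanced value over all
unmasked pairs at that distance, pooled across chromosomes. The decay
exponent α is a least-squares slope of log value against log distance over a
configurable range (default bins 2 to n/4 — the first diagonal is dominated
by self-ligation-like signal and the far tail by noise). Distances with no
unmasked pair inherit the nearest defined distance's value so the O/E
transform has no holes at map edges.

## Domain calling

For every bin edge `i` and window `w` the TAD separation score takes the
mean of unmasked cells in the diamond `[i−w, i) × [i, i+w)` — the contacts
that *cross* the edge at scales up to `w`. Per-window scores are z-scored
per chromosome (z defined as 0 when the standard deviation vanishes, so
constant chromosomes score 0 everywhere) and averaged over windows into the
aggregate score S. Defaults: 50-kb resolution with windows of 2, 4, 6 and
10 bins (100–500 kb); presets for 10-kb and 25-kb resolutions cover the
same physical range.

Boundary candidates are strict local minima of S with prominence
(min of left/right maxima within the largest window, minus S) of at least
`delta` (default 0.01); edges where any window crosses a chromosome end are
not candidates. Significance is a one-sided Mann–Whitney test of the
candidate's diamond values, pooled over all windows, against the same
windows' diamonds one window-width to each side. Two numerical choices make
this test behave: (i) each window is compared against its own displaced
counterpart, so the distance composition of the two samples is identical
under the null; (ii) diamond values are first divided by the per-diagonal
chromosome mean, otherwise distance-decay variance within a diamond swamps
the domain signal that the test is meant to detect. Comparing only at the
largest window's displacement was evaluated and rejected: when domain size
is comparable to the largest window — exactly the regime of interest — the
displaced diamonds land on the neighboring boundaries and the test loses
essentially all power. Benjamini–Hochberg is applied over all candidates
genome-wide and calls with q ≤ fdr (default 0.05) are kept. Surviving calls
closer than `min_boundary_distance` (default half the largest window) are
deduplicated, keeping the lower S; this suppresses twin minima at one noisy
boundary without pruning genuinely adjacent domains — a full-window default
was found to delete true boundaries whenever domain spacing dipped below
the largest window.

Domains are the intervals between consecutive boundaries, extended to the
chromosome ends; they always partition the chromosome exactly. Summary
statistics report size percentiles, per-chromosome counts, and the
Pearson/Spearman correlation of count against chromosome length (flagged
undefined below three chromosomes).

## Strand inference, ORF filter, tracks, arrays

Unstranded transcript assemblies are oriented by their introns' terminal
dinucleotides on the forward genomic strand: GT..AG votes `+`, CT..AC
(the reverse complement) votes `−`, anything else abstains. The default
call is the majority of voting introns (ties → unknown); a strict mode
demands unanimity. Only the canonical dialect is accepted because splice-site
orientation is the sole strand evidence available — a non-canonical site is
as likely to be a misassembly as a real junction. Single-exon transcripts
are unoriented and excluded from tracks.

ORFs are sought on the sense strand of the spliced sequence only:
ATG-initiated, in-frame stop required, stop not counted. Transcripts with a
longest ORF under 60 aa are dropped before track construction.

Strand tracks assign each exon-covered bp the sum of TPMs of the retained
transcripts covering it, on each transcript's strand (exact per-bp
semantics; binned means are available for metaplots). Gene arrays are
maximal per-strand runs with signal ≥ 0.1 TPM, internal gaps ≤ 25 kb
bridged, runs < 100 kb dropped; opposite-strand overlaps go to the strand
with more integrated signal in the overlap. The length and gap defaults
reflect the scale of the phenomenon: domains span hundreds of kb to Mb, so
an array half is ≥ 100 kb, and inter-transcript spacing within an array is
tens of kb. Junctions between consecutive arrays are classified by the
strand pattern — (+,−) convergent, (−,+) divergent, otherwise tandem — at
the gap midpoint.

The nascent-transcription proxy counts a read as intronic when its alignment
has no intron-spanning gap and overlaps an annotated intron by ≥ 10 bp; the
unspliced fraction is intronic / (intronic + exonic-assigned), with reads
touching no transcript excluded.

## Correspondence and decompaction

Boundaries are matched to the nearest convergent junction within `max_dist`
(default one bin). The enrichment null preserves boundary spacing by
circularly rotating each chromosome's boundary set by a common uniform
offset; rotations smaller than the matching tolerance are excluded, since
they reproduce the observed configuration rather than drawing from the null
(on a single 10-Mb chromosome ~1% of uniform offsets would otherwise be
such self-matches, flooring the attainable p-value). A circular-shift null
was preferred over uniform resampling because boundaries are quasi-regularly
spaced, and uniform nulls overstate significance for regular point sets.

Metaplots average O/E submatrices (2-D) or strand-track windows (1-D)
across boundaries, dropping and counting anchors whose window crosses a
chromosome end (default flank: 10 bins, ±500 kb at 50 kb). Boundary
strength is the ratio of the mean O/E in the two flanking intra-domain
triangles to the mean O/E in the boundary diamond: 1 on a structureless
map, > 1 at an insulating boundary, and invariant to global scaling.

Cross-condition comparison fixes boundaries from the control map (the
question is how insulation at *the same loci* responds to treatment),
depth-matches all maps to the smallest total, and recomputes strengths per
condition on each map's own O/E. The decompaction trend statistic is the
mean over boundaries of the Spearman correlation between dose rank and
strength, with a one-sided (decreasing) permutation p from shuffling dose
labels within each boundary (default 9,999 permutations, seeded). A
rank correlation on per-condition *mean* strengths alone was rejected: with
the typical three-dose design its exact permutation p can never fall below
1/6, regardless of effect size; the per-boundary paired statistic has the
resolution the design needs.

## Synthetic data

The generator encodes the transcription-supercoiling domain picture: each
chromosome is partitioned into domains (default expected size 500 kb,
±20% jitter, snapped to the bin grid), and each domain is a reverse-strand
array followed by a forward-strand array. Consequently convergent junctions
coincide exactly with domain boundaries and divergent junctions sit strictly
inside domains — the layout the correspondence analysis is meant to detect.
Transcripts (12 per array by default, spaced so inter-transcript gaps stay
below the segmentation gap tolerance) are multi-exon with canonical GT..AG
introns on the sense strand and an embedded 200-aa ORF; TPMs are log-normal
(μ=1, σ=1 in log space). Contact intensity is
`λ_ij ∝ max(d,1)^-α · [(1−m)·F_ij + m]` with F = E (default 3) within an
array's own block, e (default 2, the "sub-domain" factor between the two
arrays of one domain) and 1 across domains; the upper triangle is scaled to
the target depth (default 2×10⁶ cis contacts per chromosome) and Poisson
sampled. The mixing parameter m interpolates to pure decay (m = 1) and is
the one-knob model of inhibitor-induced decompaction; condition series pair
each dose with a nascent fraction scaled by (1−m).

Reads are drawn from transcripts proportional to TPM. With probability
`nascent_fraction` a read is unspliced pre-mRNA, positioned to overlap an
intron (introns chosen proportional to length) — intron overlap being the
operational signature by which nascent RNA is counted; otherwise it is
mature mRNA and may span splice junctions. This makes the unspliced-fraction
estimator exactly calibrated on synthetic data. On real libraries, nascent
reads falling entirely within exons are invisible to the proxy, so the real
estimator *underestimates* the nascent share; passing tests demonstrate
correct counting and sensitivity to change, not absolute calibration on
real data.

Everything is a pure function of (config, seed); per-stage generators use
deterministically derived substreams of the root seed.

### What the simulation does not emulate

No biophysical polymer model, no realistic base composition or sequence
evolution, no non-canonical splice sites, no trans contacts, no
assembly/alignment artifacts, no multi-mapping ambiguity. Domain enrichment
and decay values are chosen for testability (clear but not overwhelming
signal at desk-scale depth), not measured from any organism.

## Problem sizes and determinism

The default study — one 10-Mb chromosome at 50-kb bins (200 bins, ~19
boundaries), 480 transcripts, 10⁴ reads, 2×10⁶ contacts — runs the full
pipeline in a few seconds; calibration suites (50 null maps, 200 enrichment
datasets) complete in well under a minute. These sizes give the acceptance
properties comfortable statistical room: boundary recovery is limited only
by the chromosome-end exclusion zone (the first planted boundary sometimes
lies within the largest window of the chromosome start), and binomial noise
at n = 10⁴ is ±0.01 on the unspliced fraction.

## Known limitations

- The boundary caller emulates the insulation-score family of TAD callers;
  it is not bit-compatible with any external tool, and printed domain counts
  from such tools are configuration-dependent quantities, not targets.
- No hierarchical or nested domain decomposition; sub-domain structure
  exists only as an enrichment level in the simulator.
- No loop or stripe detection (the target genomes show none).
- KR weights for a chromosome are computed independently per chromosome;
  there is no joint genome-wide balancing.
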