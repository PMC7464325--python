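# Methods

This note documents the models, numerical choices and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and coverage quantification

All genomic coordinates are 0-based, half-open, matching BED and bedGraph —
the only genomic formats consumed. Coverage is represented exactly as a step
function (sorted, non-overlapping `(start, end, value)` steps per
chromosome, `value ≥ 0` interpreted as density per base); region signal is
the area under that step function, computed by binary search over step
boundaries. This makes `signal([a,c)) = signal([a,b)) + signal([b,c))` hold
to floating-point accuracy and lets a per-base sum serve as a brute-force
oracle in tests. Chromosome names are matched by exact string comparison —
no `chr` aliasing — because silent aliasing hides mixed-assembly inputs; a
preflight warns when peak and track chromosome sets are disjoint. Strand is
ignored for peaks and coverage (H3K27ac is unstranded) and used only to
document gene TSS annotations.

## Super-enhancer calling

**Stitching.** Peaks within `max_gap = 12 500` bp are merged into candidate
enhancer regions; the gap test is inclusive (`next.start − current.end ≤
max_gap`), so touching or overlapping peaks always merge and a gap of
exactly 12.5 kb merges too. An optional TSS-exclusion window (off by
default) removes peaks fully contained within ±w of an annotated TSS before
stitching, mirroring the option the reference ROSE strategy offers;
it is off by default because the analysis this package reproduces does not
mention it.

**Scoring.** Region signal is the ChIP coverage area, optionally minus
`control_scale ×` the control-track area, clamped at zero. No input control
is assumed by default. An optional per-track library-size factor (see
differential analysis) replaces any attempt to emulate tag-directory
normalization internals of other tools; scoring itself is raw area.

**Cutoff geometry.** With signals sorted ascending and both axes scaled to
[0, 1] via `x_i = (i−1)/(n−1)`, `y_i = (s_i − s_1)/(s_n − s_1)`, the cutoff
is `argmin_i (y_i − x_i)` — the discrete point where a convex curve's
tangent reaches slope 1. This avoids noisy numeric differentiation and is
exact on analytic test curves: for `y = x^k` the tangent point is
`x* = k^(−1/(k−1))` and the discrete argmin lands within one grid step of
it. Min–max scaling (rather than `s/s_max`) makes two degenerate cases
explicit: a flat vector (cutoff at the top, zero super-enhancers, warning)
and a perfectly linear vector (`y − x ≡ 0`; ties resolve toward the largest
index, again zero super-enhancers). Rank ties elsewhere are broken by
genomic position so output is invariant to input order. A region is *super*
when its signal is strictly above the cutoff signal.

**Annotation.** Each region gets the gene with minimum |midpoint − TSS| on
its chromosome; equidistant TSSs resolve to the lexicographically smaller
symbol; regions on gene-free chromosomes are annotated `NA`.

## Differential analysis

Region identity across conditions is fixed by re-scoring the *control*
condition's stitched regions in the treated track (never re-stitching), so
"the same" super-enhancer is compared on both sides. Tracks are first
scaled to their geometric-mean total (factors logged and reported — the
comparison is never silently normalized). Each region's
`log2FC = log2(s_T + c) − log2(s_C + c)` uses pseudocount `c = 1` area unit
(configurable); the difference-of-logs form makes condition swap negate the
value exactly in floating point. Status: *decommissioned* = super in
control, not super in treated (both by each condition's own hockey-stick
cutoff); *attenuated* = still super but `log2FC ≤ −1` (2-fold, configurable);
otherwise *stable*.

Reference-point matrices average coverage density in 500 bp bins across
±50 kb around each region midpoint (window divisible by bin size enforced).
Bins protruding past chromosome position 0 are truncated and averaged over
covered length only. Rows are ordered by total signal, descending, matching
the usual heatmap presentation; 500 bp bins keep a ±50 kb matrix at 200
columns.

## Median-effect and combination-index analysis

Viability (fraction of vehicle control) converts to fraction affected
`fa = 1 − V`, clamped into `[ε, 1−ε]` with `ε = 1e−4`; clamped points are
flagged and excluded from fits when at least two clean points remain
(otherwise included with a warning). The fit is unweighted OLS of
`log10(fa/fu)` on `log10(D)` — the published median-effect method — with
`m` the slope and `Dm = 10^(−intercept/m)`; `r` is the Pearson correlation
of the linearized fit. A non-positive slope is returned flagged
`non-monotone` rather than raised, so degenerate series remain inspectable.

The combination index uses the two-term (mutually exclusive) form
`CI = D1/Dx1 + D2/Dx2`, matching the standard CompuSyn default; the
mutually nonexclusive third term is not implemented. CI is computed
point-wise at every observed combination dose pair from its measured fa
(the default, which handles multiple independent dose pairs); a
constant-ratio design can alternatively be fit as its own series and
inverted at chosen effect levels. Classification treats `|CI − 1| ≤ 0.05`
as additive — strict equality is unusable with noise — with a 1e−12 slack
on the band boundary so values such as 0.95 (one ulp outside 0.05 in
doubles) classify inclusively. Replicates are averaged (mean viability per
dose pair, SD reported) before fa conversion. Isobolograms report axis
intercepts `(Dx1, Dx2)` at the chosen effect level; raw mode admits
combination points within ±0.05 in fa of that level, normalized mode plots
`(D1/Dx1(fa_obs), D2/Dx2(fa_obs))`, whose coordinates sum to the point's CI.

## Assay formulas

ΔΔCq uses group-mean ΔCq (mean of ΔCq, not ΔCq of mean Cq) with
amplification efficiency fixed at 2, since the emulated protocol reports no
efficiency correction; fold change `= 2^(−ΔΔCq)`, shift-invariant to any
common Cq offset. ChIP-qPCR enrichment is expressed through the same
operation with IgG as the reference sample; no percent-input mode exists
because no input sample is modeled. Tumor volume is `L·W²/2` with a
swap-and-warn rule when width exceeds length. Group comparison is a
two-sided pooled-variance Student's t-test for two groups (Welch behind a
flag) and one-way ANOVA beyond, with stars * p<0.05, ** p<0.01,
*** p<0.001; all-zero within-group variance is reported explicitly
(p = 1 for equal means, p = 0 with a degeneracy warning otherwise).

## Synthetic-data generators

All generators take a seed and are byte-deterministic.

**ChIP landscape.** One 10 Mb synthetic chromosome carries 500 typical
enhancers (single ~1 kb peaks) and 10 planted super-enhancers (8
constituent peaks across 30 kb — the scale of well-known broad
super-enhancers — with inter-peak gaps well under 12.5 kb, so each planted
element stitches into exactly one region). Typical peak areas are lognormal
with median 1000 area units and log-sigma 1.15 — a right-skewed
distribution spanning roughly 1.5 orders of magnitude, the shape that makes
ranked-enhancer curves hockey-stick-like. Super-enhancer aggregate area is
`10 ×` the typical median with one-sided upward jitter (the floor is
guaranteed). A low uniform background (~0.01 per bp in 10 kb steps) adds
noise. The treated condition divides the peak heights of a configurable
subset of super-enhancers (default half) by `treatment_attenuation`
(default 4). Placement distributes free space uniformly among inter-element
gaps above a 15 kb minimum separation, so planted elements never co-stitch.

These shape parameters were calibrated jointly so the generator honors its
own contract — planted super-enhancers sit above the tangent cutoff
(recoverable) while attenuated ones fall below it (decommissionable): the
cutoff of a lognormal landscape lands near signal `e^{σz*}` × median with
`σz* + z*²/2 = ln(s_max/(σ√2π · median))`, so the attenuated band
(multiplier/4) must sit below that point and the super band (multiplier)
above it. Attenuating *all* super-enhancers uniformly would merely rescale
the curve's tail and leave every one of them super — which is why partial
decommissioning (a subset attenuated) is both the realistic scenario and
the default.

What the generator does **not** emulate: read-level sampling noise, GC or
mappability bias, antibody efficiency, copy-number effects, replicate
structure, or peak-calling errors (peaks are emitted as known intervals
because alignment and peak calling are out of scope). Passing tests
therefore demonstrate correctness of the stitching/ranking/cutoff/differential
machinery under a controlled landscape, not robustness to the full noise
structure of real ChIP-seq.

A known property of the tangent cutoff worth stating plainly: on *any*
smooth unimodal signal distribution with no planted outlier class (a null
landscape), the cutoff flags the distribution's convex upper tail —
numerically 4–12% of regions across lognormal shapes from very narrow to
extremely heavy-tailed. A near-zero super-enhancer call rate on null data
would require a tail so extreme (top signal hundreds of times the median)
that planted-element recovery breaks; the package reports the measured
null rate honestly rather than suppressing it.

**Dose–response.** Single-drug viability follows the median-effect equation
exactly (defaults: `m1 = 2, Dm1 = 1; m2 = 1.5, Dm2 = 5`; eight 2-fold doses
straddling each Dm). Combination viability at `(d1, d2)` is constructed by
solving `d1/Dx1(fa) + d2/Dx2(fa) = CI*` for fa by bracketed root-finding
(Brent, tolerance 1e−12), so the true combination index at every simulated
point equals the configured `CI*` by construction — `CI* = 1` is exact
Loewe additivity, and CI recovery is a well-posed test that assumes nothing
about the estimator. Dose pairs that bracket no root are skipped and
recorded. Measurement noise is multiplicative mean-one lognormal with
configurable CV; four replicate wells per dose (the usual viability-plate
design) are averaged before analysis.

**qPCR.** Control ΔCq ~ Normal(ΔCq₀, sd); treated ΔCq shifted by
−log2(true fold change); constant reference Cq (an abundant rRNA reference
is effectively invariant); n = 4 per group by default. Error propagation:
ΔΔCq is a difference of two group means, so sd(ΔΔCq) = sd·√(2/n).

**Tumor growth.** `V(t) = V₀·e^{rt}` per arm with mean-one lognormal noise;
caliper length/width back-computed at a fixed 1.5 length/width aspect
ratio; 9 animals per arm by default.

## Pipeline

`rosyn run` executes simulate → call-se → normalize/diff-se → synergy →
qPCR/tumor stages in order, writing per-stage TSVs, an append-only
timestamped log, a flat machine-readable `summary.json` and a
human-readable `report.txt` into the run directory. Configuration is a
single flat YAML file with CLI overrides (precedence CLI > file >
defaults); unknown keys are rejected before any stage runs. Exit codes:
0 success, 2 validation/configuration error, 3 stage failure. Given a
seed, reruns are bit-for-bit identical in every generated and derived
table (the log differs only in timestamps).

## Problem sizes

Default problem sizes (10 Mb chromosome, 510 regions, 50–100 seeded
replicates for rate estimates, 100 simulated viability experiments per CI
target) were chosen so a full test-and-acceptance cycle completes in a few
minutes on a laptop-class single core while keeping Monte-Carlo error on
reported rates near the percent level.

## Known limitations

- Exact super-enhancer counts from public datasets are not reproduction
  targets: they depend on upstream alignment/peak-calling choices and
  normalization internals outside this package's scope.
- No statistical differential testing at the region level (no replicate
  structure is modeled); the decommissioning call is threshold-based.
- The dose-reduction index, Bliss/HSA/ZIP synergy models and ≥3-drug
  combinations are out of scope; the CI analysis is the two-term
  mutually-exclusive form only.
- bigWig output is not produced (bedGraph only); BAM/FASTQ handling is
  explicitly out of scope.
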