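# rosyn

Super-enhancer calling, differential "decommissioning" analysis and
Chou–Talalay drug-synergy quantification — the computational core of a
combined epigenomics + pharmacology workflow, built to run end-to-end on
seeded synthetic data with recorded ground truth.

## What it does

**Super-enhancer calling (ROSE/HOMER strategy).** Starting from H3K27ac
peak calls (BED/narrowPeak) and coverage (bedGraph), peaks within 12.5 kb
are stitched into candidate enhancer regions, each region is scored by its
coverage area (optionally minus a scaled input control), and regions are
ranked by signal. On min–max-scaled rank/signal axes
(`x_i = (i−1)/(n−1)`, `y_i = (s_i − s_1)/(s_n − s_1)`) the super-enhancer
cutoff is the discrete tangent point of slope 1, located as
`argmin_i (y_i − x_i)`; regions above it are super-enhancers — the
inflection of the familiar "hockey stick" plot. Regions are annotated with
the gene whose TSS is nearest their midpoint.

**Differential analysis.** Two conditions (e.g. vehicle vs. a CDK7
inhibitor) are compared on the *same* stitched regions: coverage tracks
are library-size normalized to their geometric-mean total, regions are
re-scored in each track, and each control super-enhancer is classified as
*stable*, *attenuated* (`log2FC ≤ −1` but still super) or *decommissioned*
(no longer super after treatment). deeptools-style reference-point
matrices (±50 kb around region centers, 500 bp bins) and mean±SD profiles
summarize the landscape change.

**Drug synergy (median-effect / combination index).** Viability data are
converted to fraction affected `fa = 1 − V/V_control` and fit by the
linearized median-effect equation

```
fa/fu = (D/Dm)^m        ⇔        log10(fa/fu) = m·log10(D) − m·log10(Dm)
```

(`Dm` median-effect dose, `m` sigmoidicity, `fu = 1 − fa`). For a
combination point `(D1, D2)` producing effect `fa`, the two-term
combination index is

```
CI = D1/Dx1(fa) + D2/Dx2(fa),      Dxi(fa) = Dmi·(fa/fu)^(1/mi)
```

with CI < 1 synergistic, CI ≈ 1 additive, CI > 1 antagonistic.
Isobolograms (raw and normalized) and FA–CI plots are produced.

**Bench-assay formulas.** ΔΔCq fold change (`2^(−ΔΔCq)` against an 18S
reference), caliper tumor volume (`length × width² / 2`), per-arm growth
summaries, and Student's t / one-way ANOVA group comparisons with star
annotations.

**Synthetic data.** Every input is generated by seeded simulators with
ground truth on disk: an enhancer landscape with planted multi-peak
super-enhancers on a lognormal typical background (attenuated under
"treatment"), viability matrices constructed under exact Loewe additivity
scaled to a chosen true CI, qPCR Cq tables and exponential tumor-growth
cohorts. Identical seeds give byte-identical files.

## Worked example

Run the full pipeline on synthetic inputs (simulate → call → compare →
synergy → report):

```bash
rosyn run --seed 1 --out-dir demo_run
```

prints

```
done: n_super=42 decommissioned=5 mean_ci=0.50997
```

and `demo_run/summary.json` contains (abridged):

```json
{
  "n_regions": 510,
  "n_super": 42,
  "n_super_planted": 10,
  "n_decommissioned": 5,
  "mean_ci": 0.50997,
  "ci_classification": "synergistic",
  "qpcr_fold_change": 0.244849,
  "final_day_volume_combo": 186.28,
  "final_day_volume_vehicle": 1203.49,
  "final_day_anova_p": 3.015e-27
}
```

Reading: the 510 stitched regions include all 10 planted super-enhancers
among the 42 regions above the hockey-stick cutoff (the extra calls are
the convex upper tail of the typical-enhancer distribution — see
`docs/methods.md`); the 5 treatment-attenuated super-enhancers are all
called decommissioned; the viability experiment simulated with true
CI = 0.5 is recovered as mean CI ≈ 0.51, classified synergistic; the
qPCR simulation with true fold change 0.25 recovers 0.245; and the
combination arm's final tumor volume is ~6-fold below vehicle
(ANOVA p ≈ 3e-27).

Individual stages are also exposed (`rosyn call-se`, `rosyn diff-se`,
`rosyn synergy`, `rosyn qpcr`, `rosyn tumor-growth`,
`rosyn sim chip|dose`); run any with `--help`.

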