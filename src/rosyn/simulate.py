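"""Seeded generators for every input the pipeline consumes, with ground truth.

Four generators emulate the study's data classes:

* ``simulate_chip_landscape`` — an H3K27ac enhancer landscape on one
  synthetic chromosome: many narrow typical enhancers with lognormal
  signal, a minority of broad multi-peak super-enhancers whose aggregate
  area sits an order of magnitude above the typical median (the
  hockey-stick upper tail), and a treated condition in which a chosen
  subset of the super-enhancers is attenuated by a fold factor.
* ``simulate_dose_response`` — single-drug viability from the
  median-effect equation plus combination points constructed to have an
  exact ground-truth combination index (target_ci = 1 is exact Loewe
  additivity), with multiplicative lognormal noise.
* ``simulate_qpcr`` — dCq tables with a known fold change.
* ``simulate_tumor_growth`` — exponential tumor growth with lognormal
  measurement noise, lengths/widths back-computed at a fixed aspect ratio.

All generators are deterministic given their seed: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError
from .intervals import CoverageTrack, GenomicInterval, Peak, write_bed, write_bedgraph
from .assays import QpcrSample, TumorMeasurement

__all__ = [
    "ChipSimConfig",
    "DoseSimConfig",
    "ChipLandscape",
    "simulate_chip_landscape",
    "simulate_dose_response",
    "simulate_qpcr",
    "simulate_tumor_growth",
    "write_chip_landscape",
    "write_manifest",
]

#: Minimum separation enforced between distinct planted elements, chosen
#: above the 12.5 kb stitch distance so each planted element stitches into
#: exactly one region.
_MIN_SEPARATION = 15_000


@dataclass(frozen=True)
class ChipSimConfig:
    """Parameters of the synthetic enhancer landscape.

    ``se_span`` defaults to 30 kb, the scale of the broad multi-peak
    super-enhancers the pipeline is meant to recover (the canonical
    example in this study spans ~29 kb).  ``typical_signal_mean`` is the
    lognormal *median* area of a typical enhancer in arbitrary coverage
    area units; super-enhancer aggregate area is
    ``se_signal_multiplier`` times that.
    """

    seed: int = 0
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    n_typical: int = 500
    n_super: int = 10
    se_span: int = 30_000
    se_constituents: int = 8
    typical_signal_mean: float = 1000.0
    typical_signal_sigma: float = 1.15  # lognormal sigma in log space
    se_signal_multiplier: float = 10.0
    se_signal_jitter: float = 0.25
    background_rate: float = 0.01  # mean noise density per bp
    background_bin: int = 10_000
    typical_peak_width: int = 1000
    se_peak_width: int = 1500
    treatment_attenuation: float = 4.0
    attenuated_fraction: float = 0.5

    def validate(self) -> None:
        if self.se_signal_multiplier <= 1:
            raise ConfigurationError("se_signal_multiplier must be > 1")
        if self.treatment_attenuation < 1:
            raise ConfigurationError("treatment_attenuation must be >= 1")
        if not (0 <= self.attenuated_fraction <= 1):
            raise ConfigurationError("attenuated_fraction must be in [0, 1]")
        if self.se_constituents < 1 or self.n_typical < 0 or self.n_super < 0:
            raise ConfigurationError("counts must be non-negative (se_constituents >= 1)")
        widths = (
            self.n_typical * self.typical_peak_width + self.n_super * self.se_span
        )
        n_elements = self.n_typical + self.n_super
        if widths + (n_elements + 1) * _MIN_SEPARATION > self.chrom_length:
            raise ConfigurationError(
                "planted elements do not fit on the chromosome with the required "
                f"{_MIN_SEPARATION} bp separation; enlarge chrom_length or reduce counts"
            )


@dataclass(frozen=True)
class ChipLandscape:
    """A simulated landscape: inputs for the pipeline plus ground truth."""

    peaks: list[Peak]
    control: CoverageTrack
    treated: CoverageTrack
    truth: pd.DataFrame  # element_id, class, chrom, start, end, signal, attenuated, ...


def _place_elements(
    rng: np.random.Generator, widths: Sequence[int], chrom_length: int
) -> list[int]:
    """Non-overlapping starts for elements of the given widths.

    Free space beyond the minimum separation is split uniformly at random
    among the inter-element gaps (stick breaking), which guarantees every
    pair of elements is more than the stitch distance apart.
    """
    n = len(widths)
    slack = chrom_length - sum(widths) - (n + 1) * _MIN_SEPARATION
    if slack < 0:
        raise ConfigurationError("elements do not fit on the chromosome")
    cuts = np.sort(rng.uniform(0, slack, size=n + 1))
    extra = np.diff(np.concatenate([[0.0], cuts]))  # n+1 non-negative gaps
    starts = []
    pos = 0.0
    for w, e in zip(widths, extra):
        pos += _MIN_SEPARATION + e
        starts.append(int(round(pos)))
        pos = starts[-1] + w
    return starts


def _build_track(
    chrom: str,
    chrom_length: int,
    background: Sequence[tuple[int, int, float]],
    peaks: Sequence[tuple[int, int, float]],
) -> CoverageTrack:
    """Superimpose peak rectangles on the background via breakpoint sweep."""
    edges = set()
    for s, e, _ in background:
        edges.update((s, e))
    for s, e, _ in peaks:
        edges.update((s, e))
    cuts = np.array(sorted(edges), dtype=np.int64)
    if cuts.size == 0:
        return CoverageTrack()
    seg_starts = cuts[:-1]
    seg_ends = cuts[1:]
    values = np.zeros(seg_starts.size)
    for s, e, v in list(background) + list(peaks):
        i0 = np.searchsorted(seg_starts, s)
        i1 = np.searchsorted(seg_starts, e)
        values[i0:i1] += v
    keep = values > 0
    steps = [
        (chrom, int(s), int(e), float(v))
        for s, e, v in zip(seg_starts[keep], seg_ends[keep], values[keep])
    ]
    return CoverageTrack(steps)


def simulate_chip_landscape(config: ChipSimConfig) -> ChipLandscape:
    """Generate peaks, control/treated coverage and a ground-truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    # element order along the chromosome is random
    kinds = np.array(["typical"] * c.n_typical + ["super"] * c.n_super)
    rng.shuffle(kinds)
    widths = [c.typical_peak_width if k == "typical" else c.se_span for k in kinds]
    starts = _place_elements(rng, widths, c.chrom_length)

    n_attenuated = int(round(c.attenuated_fraction * c.n_super))
    se_indices = [i for i, k in enumerate(kinds) if k == "super"]
    attenuated_set = set(rng.choice(se_indices, size=n_attenuated, replace=False)) if se_indices else set()

    peaks: list[Peak] = []
    control_rects: list[tuple[int, int, float]] = []
    treated_rects: list[tuple[int, int, float]] = []
    truth_rows = []
    typical_median = c.typical_signal_mean  # lognormal median by construction

    for idx, (kind, start, width) in enumerate(zip(kinds, starts, widths)):
        if kind == "typical":
            area = typical_median * float(np.exp(c.typical_signal_sigma * rng.standard_normal()))
            height = area / c.typical_peak_width
            end = start + c.typical_peak_width
            name = f"peak_t{idx}"
            peaks.append(Peak(GenomicInterval(c.chrom, start, end), name, score=area))
            control_rects.append((start, end, height))
            treated_rects.append((start, end, height))
            truth_rows.append(
                dict(element_id=f"typ_{idx}", element_class="typical", chrom=c.chrom,
                     start=start, end=end, signal=area, attenuated=False,
                     expected_log2fc=0.0, expected_status="stable")
            )
        else:
            # aggregate area is guaranteed >= multiplier x typical median:
            # jitter is one-sided upward
            aggregate = (
                c.se_signal_multiplier * typical_median
                * float(np.exp(rng.uniform(0.0, c.se_signal_jitter)))
            )
            ncon = c.se_constituents
            w = c.se_peak_width
            if ncon == 1:
                offsets = [0]
            else:
                spacing = (c.se_span - w) / (ncon - 1)
                # jitter small enough that constituents never overlap or reorder
                scale = max(spacing - w, 0.0)
                jitter = rng.uniform(-0.2, 0.2, size=ncon) * scale
                offsets = [max(int(round(k * spacing + jitter[k])), 0) for k in range(ncon)]
            weightings = np.exp(0.3 * rng.standard_normal(ncon))
            weightings /= weightings.sum()
            attenuated = idx in attenuated_set
            for k, off in enumerate(offsets):
                p_start = start + off
                p_end = min(p_start + w, start + c.se_span)
                height = aggregate * weightings[k] / (p_end - p_start)
                name = f"peak_s{idx}_{k}"
                peaks.append(Peak(GenomicInterval(c.chrom, p_start, p_end), name,
                                  score=aggregate * weightings[k]))
                control_rects.append((p_start, p_end, height))
                treated_rects.append(
                    (p_start, p_end, height / c.treatment_attenuation if attenuated else height)
                )
            exp_fc = -float(np.log2(c.treatment_attenuation)) if attenuated else 0.0
            truth_rows.append(
                dict(element_id=f"se_{idx}", element_class="super", chrom=c.chrom,
                     start=start, end=start + c.se_span, signal=aggregate,
                     attenuated=attenuated, expected_log2fc=exp_fc,
                     expected_status="decommissioned" if attenuated else "stable")
            )

    # low uniform background noise in coarse bins
    background = []
    for b0 in range(0, c.chrom_length, c.background_bin):
        b1 = min(b0 + c.background_bin, c.chrom_length)
        background.append((b0, b1, c.background_rate * float(rng.uniform(0.5, 1.5))))

    control = _build_track(c.chrom, c.chrom_length, background, control_rects)
    treated = _build_track(c.chrom, c.chrom_length, background, treated_rects)
    truth = pd.DataFrame(truth_rows)
    return ChipLandscape(peaks, control, treated, truth)


def write_chip_landscape(landscape: ChipLandscape, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.bed",
        "control": out / "control.bedgraph",
        "treated": out / "treated.bedgraph",
        "truth": out / "truth.tsv",
    }
    write_bed(landscape.peaks, paths["peaks"])
    write_bedgraph(landscape.control, paths["control"])
    write_bedgraph(landscape.treated, paths["treated"])
    landscape.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Dose-response simulation
# ---------------------------------------------------------------------------

def _default_grid(dm: float) -> tuple[float, ...]:
    """Eight doses in two-fold steps straddling the median-effect dose."""
    return tuple(dm * 2.0 ** k for k in range(-4, 4))


@dataclass(frozen=True)
class DoseSimConfig:
    """Ground truth of a two-drug viability experiment.

    Default median-effect parameters describe two drugs of unequal potency
    and sigmoidicity; combination pairs sit at fixed fractions of the two
    Dm values so the solved effect levels span the informative mid-range.
    ``target_ci`` scales the Loewe additivity sum: 1 is exact additivity,
    < 1 synergy by construction.
    """

    seed: int = 0
    m1: float = 2.0
    Dm1: float = 1.0
    m2: float = 1.5
    Dm2: float = 5.0
    dose_grid1: tuple[float, ...] = ()
    dose_grid2: tuple[float, ...] = ()
    combo_pairs: tuple[tuple[float, float], ...] = ()
    target_ci: float = 1.0
    noise_cv: float = 0.0
    replicates: int = 4  # replicate wells per dose, the usual viability design
    fa_floor: float = 1e-6

    def validate(self) -> None:
        if min(self.m1, self.m2, self.Dm1, self.Dm2) <= 0:
            raise ConfigurationError("median-effect parameters m, Dm must be > 0")
        if self.target_ci <= 0:
            raise ConfigurationError("target_ci must be > 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")

    def grids(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        g1 = self.dose_grid1 or _default_grid(self.Dm1)
        g2 = self.dose_grid2 or _default_grid(self.Dm2)
        return g1, g2

    def pairs(self) -> tuple[tuple[float, float], ...]:
        if self.combo_pairs:
            return self.combo_pairs
        fr = [2.0 ** k for k in range(-2, 3)]  # 1/4 .. 4 of (Dm1, Dm2)/2
        return tuple((self.Dm1 * f / 2.0, self.Dm2 * f / 2.0) for f in fr)


def _median_effect_fa(dose: float, m: float, dm: float) -> float:
    ratio = (dose / dm) ** m
    return ratio / (1.0 + ratio)


def _loewe_fa(d1: float, d2: float, cfg: DoseSimConfig) -> Optional[float]:
    """Solve d1/Dx1(fa) + d2/Dx2(fa) = target_ci for fa by bracketed root-finding.

    The left side decreases monotonically in fa (equivalent doses grow
    with effect), so a sign change over (fa_floor, 1 - fa_floor) brackets
    a unique root.  Returns None when the pair cannot reach any effect in
    range (no bracket).
    """

    def g(fa: float) -> float:
        fu = 1.0 - fa
        dx1 = cfg.Dm1 * (fa / fu) ** (1.0 / cfg.m1)
        dx2 = cfg.Dm2 * (fa / fu) ** (1.0 / cfg.m2)
        return d1 / dx1 + d2 / dx2 - cfg.target_ci

    lo, hi = cfg.fa_floor, 1.0 - cfg.fa_floor
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        return None
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-14))


def simulate_dose_response(config: DoseSimConfig) -> tuple[pd.DataFrame, dict]:
    """Viability table (label, dose_1, dose_2, viability) plus a truth record.

    Single-drug viability follows the median-effect equation exactly;
    combination viability at (d1, d2) is constructed so the true
    combination index at that point equals ``target_ci``.  Replicate
    viabilities are multiplied by lognormal noise with the configured CV.
    Dose pairs that bracket no root are skipped and listed in the truth
    record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))

    def noisy(v: float) -> float:
        if sigma == 0:
            return v
        return v * float(np.exp(rng.normal(0.0, sigma) - sigma ** 2 / 2.0))

    rows = []
    g1, g2 = config.grids()
    for d in g1:
        fa = _median_effect_fa(d, config.m1, config.Dm1)
        for _ in range(config.replicates):
            rows.append(dict(label="drug1", dose_1=d, dose_2=0.0, viability=noisy(1.0 - fa)))
    for d in g2:
        fa = _median_effect_fa(d, config.m2, config.Dm2)
        for _ in range(config.replicates):
            rows.append(dict(label="drug2", dose_1=0.0, dose_2=d, viability=noisy(1.0 - fa)))
    skipped = []
    combo_truth = []
    for d1, d2 in config.pairs():
        fa = _loewe_fa(d1, d2, config)
        if fa is None:
            skipped.append((d1, d2))
            continue
        combo_truth.append(dict(dose_1=d1, dose_2=d2, true_fa=fa))
        for _ in range(config.replicates):
            rows.append(dict(label="combo", dose_1=d1, dose_2=d2, viability=noisy(1.0 - fa)))
    truth = dict(
        m1=config.m1, Dm1=config.Dm1, m2=config.m2, Dm2=config.Dm2,
        target_ci=config.target_ci, noise_cv=config.noise_cv,
        combo_points=combo_truth, skipped_pairs=skipped,
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# qPCR and tumor growth
# ---------------------------------------------------------------------------

def simulate_qpcr(
    seed: int,
    n_per_group: int = 4,
    true_fold_change: float = 0.25,
    cq_sd: float = 0.1,
    base_delta_cq: float = 10.0,
    reference_cq: float = 12.0,
) -> tuple[list[QpcrSample], list[QpcrSample], dict]:
    """Control/treated Cq tables with a known target fold change.

    Control dCq ~ Normal(base_delta_cq, cq_sd); treated dCq is shifted by
    ``-log2(true_fold_change)`` (lower viability of the transcript means a
    later threshold cycle).  The reference gene's Cq is constant — the
    abundant 18S rRNA is effectively invariant.  n defaults to 4 per
    group, the replicate count of the emulated experiment.
    """
    if true_fold_change <= 0:
        raise ConfigurationError("true_fold_change must be > 0")
    rng = np.random.default_rng(seed)
    shift = -float(np.log2(true_fold_change))
    controls = [
        QpcrSample(f"ctrl_{i + 1}", "control",
                   reference_cq + base_delta_cq + float(rng.normal(0, cq_sd)), reference_cq)
        for i in range(n_per_group)
    ]
    treateds = [
        QpcrSample(f"trt_{i + 1}", "treated",
                   reference_cq + base_delta_cq + shift + float(rng.normal(0, cq_sd)),
                   reference_cq)
        for i in range(n_per_group)
    ]
    truth = dict(true_fold_change=true_fold_change, cq_sd=cq_sd, n_per_group=n_per_group)
    return controls, treateds, truth


def simulate_tumor_growth(
    seed: int,
    growth_rates: dict[str, float],
    n_per_arm: int = 9,
    days: Sequence[int] = (0, 3, 7, 10, 14, 17, 21),
    v0: float = 100.0,
    noise_cv: float = 0.1,
    aspect_ratio: float = 1.5,
) -> tuple[dict[str, list[TumorMeasurement]], dict]:
    """Exponential tumor growth V(t) = V0 * exp(rate * t) per treatment arm.

    Noisy volumes get lognormal multiplicative noise; caliper length and
    width are back-computed assuming a fixed length/width aspect ratio
    (V = L * W^2 / 2 with L = aspect_ratio * W).  n defaults to 9 animals
    per arm, the size of the emulated cohorts.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
    out: dict[str, list[TumorMeasurement]] = {}
    for arm, rate in growth_rates.items():
        ms = []
        for i in range(n_per_arm):
            animal = f"{arm}_{i + 1}"
            for day in days:
                v = v0 * float(np.exp(rate * day))
                if sigma > 0:
                    v *= float(np.exp(rng.normal(0, sigma) - sigma ** 2 / 2))
                width = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                length = aspect_ratio * width
                ms.append(TumorMeasurement(animal, int(day), length, width))
        out[arm] = ms
    truth = dict(growth_rates=dict(growth_rates), v0=v0, noise_cv=noise_cv,
                 n_per_arm=n_per_arm, days=list(days), aspect_ratio=aspect_ratio)
    return out, truth


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def write_manifest(
    out_dir: str | Path, config: object, seed: int, files: dict[str, Path]
) -> Path:
    """Record the run: config echo, seed and sha256 checksums of outputs."""
    out = Path(out_dir)
    entries = {}
    for key, p in files.items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        entries[key] = {"path": str(Path(p).name), "sha256": h}
    cfg = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)  # type: ignore[arg-type]
    manifest = {"seed": seed, "config": cfg, "files": entries}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
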